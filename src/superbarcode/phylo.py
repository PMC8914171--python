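"""Minimal rooted/unrooted phylogenetic tree with branch lengths.

The tree is a plain parent/child node structure. It supports exactly what the
discrimination pipeline needs: deterministic Newick serialization, outgroup
rooting on an edge (splitting the edge length equally), monophyly queries, and
leaf-to-leaf path lengths. Anything heavier (bipartition encoding, tree
comparison metrics) is delegated to dendropy in the test suite.
"""

from __future__ import annotations

import itertools
from typing import Dict, FrozenSet, Iterator, List, Optional, Sequence, Set, Tuple

import numpy as np

from .errors import IdentityError, RootingError


class TreeNode:
    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name: Optional[str] = None, length: float = 0.0):
        self.name = name
        self.length = float(length)
        self.children: List["TreeNode"] = []
        self.parent: Optional["TreeNode"] = None

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<TreeNode {self.name or ''} {kind} len={self.length:g}>"


class PhyloTree:
    """A tree over accession-labelled leaves.

    An unrooted tree is represented with a basal multifurcation (root with
    three or more children); a rooted tree has a degree-2 root.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        names = [leaf.name for leaf in self.leaves()]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise IdentityError(f"duplicate leaf names: {dupes}")

    # -- basic structure ---------------------------------------------------

    @property
    def rooted(self) -> bool:
        return len(self.root.children) == 2

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[TreeNode]:
        out: List[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> List[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    @property
    def leaf_names(self) -> Set[str]:
        return {leaf.name for leaf in self.leaves()}

    def n_leaves(self) -> int:
        return len(self.leaves())

    def copy(self) -> "PhyloTree":
        def clone(node: TreeNode) -> TreeNode:
            new = TreeNode(node.name, node.length)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return PhyloTree(clone(self.root))

    def clades(self) -> List[Tuple[TreeNode, FrozenSet[str]]]:
        """(node, descendant leaf names) for every node, root included."""
        sets: Dict[int, FrozenSet[str]] = {}
        result: List[Tuple[TreeNode, FrozenSet[str]]] = []
        for node in self.postorder():
            if node.is_leaf:
                s = frozenset([node.name])
            else:
                s = frozenset(itertools.chain.from_iterable(sets[id(c)] for c in node.children))
            sets[id(node)] = s
            result.append((node, s))
        return result

    # -- queries -----------------------------------------------------------

    def is_monophyletic(self, leaf_set: Sequence[str]) -> bool:
        """True iff some node's complete leaf descendants equal ``leaf_set``."""
        target = frozenset(leaf_set)
        if not target:
            raise IdentityError("empty leaf set")
        unknown = target - self.leaf_names
        if unknown:
            raise IdentityError(f"unknown leaves: {sorted(unknown)}")
        return any(s == target for _, s in self.clades())

    def mrca_clade(self, leaf_set: Sequence[str]) -> FrozenSet[str]:
        """Leaf set of the smallest clade containing every name in ``leaf_set``."""
        target = frozenset(leaf_set)
        unknown = target - self.leaf_names
        if unknown:
            raise IdentityError(f"unknown leaves: {sorted(unknown)}")
        best: Optional[FrozenSet[str]] = None
        for _, s in self.clades():
            if target <= s and (best is None or len(s) < len(best)):
                best = s
        assert best is not None
        return best

    def path_lengths(self, ids: Sequence[str]) -> np.ndarray:
        """Symmetric matrix of leaf-to-leaf path lengths in ``ids`` order."""
        idx = {name: i for i, name in enumerate(ids)}
        if len(idx) != len(ids):
            raise IdentityError("duplicate ids in path_lengths request")
        n = len(ids)
        D = np.zeros((n, n), dtype=float)

        def rec(node: TreeNode) -> Dict[str, float]:
            if node.is_leaf:
                return {node.name: 0.0} if node.name in idx else {}
            below: List[Dict[str, float]] = []
            for child in node.children:
                sub = rec(child)
                below.append({k: v + child.length for k, v in sub.items()})
            for a, b in itertools.combinations(below, 2):
                for na, da in a.items():
                    for nb, db in b.items():
                        i, j = idx[na], idx[nb]
                        D[i, j] = D[j, i] = da + db
            merged: Dict[str, float] = {}
            for sub in below:
                merged.update(sub)
            return merged

        rec(self.root)
        return D

    # -- rooting -----------------------------------------------------------

    def rooted_with_outgroup(self, outgroup_ids: Sequence[str]) -> "PhyloTree":
        """Root on the edge separating the outgroup clade, splitting it equally."""
        og = frozenset(outgroup_ids)
        if not og:
            raise RootingError("empty outgroup")
        names = self.leaf_names
        unknown = og - names
        if unknown:
            raise IdentityError(f"outgroup leaves not in tree: {sorted(unknown)}")
        tree = self.copy()
        complement = frozenset(names - og)
        target: Optional[TreeNode] = None
        for node, s in tree.clades():
            if node is tree.root:
                continue
            if s == og or s == complement:
                target = node
                break
        if target is None:
            raise RootingError(
                f"outgroup does not form a clade: {sorted(og)}"
            )
        parent = target.parent
        assert parent is not None
        parent.children.remove(target)
        target.parent = None
        half = target.length / 2.0
        _rehang(parent)
        new_root = TreeNode()
        target.length = half
        new_root.add_child(target)
        parent.length = half
        new_root.add_child(parent)
        # Collapse any unary node left behind by re-hanging a rooted tree.
        _suppress_unary(new_root)
        # Present the outgroup side first for readable Newick output.
        first = new_root.children[0]
        first_set = _leafset(first)
        if not (first_set <= og or og <= first_set):
            new_root.children.reverse()
        return PhyloTree(new_root)

    # -- serialization -----------------------------------------------------

    def newick(self, precision: int = 6) -> str:
        def fmt(node: TreeNode, top: bool) -> str:
            if node.is_leaf:
                body = node.name or ""
            else:
                body = "(" + ",".join(fmt(c, False) for c in node.children) + ")"
            if top:
                return body
            return f"{body}:{node.length:.{precision}f}"

        return fmt(self.root, True) + ";"

    def ladderize(self) -> "PhyloTree":
        """Sort children by their smallest descendant leaf name (in place)."""
        keys: Dict[int, str] = {}
        for node in self.postorder():
            if node.is_leaf:
                keys[id(node)] = node.name
            else:
                node.children.sort(key=lambda c: keys[id(c)])
                keys[id(node)] = keys[id(node.children[0])]
        return self


def _leafset(node: TreeNode) -> FrozenSet[str]:
    out = set()
    stack = [node]
    while stack:
        cur = stack.pop()
        if cur.is_leaf:
            out.add(cur.name)
        stack.extend(cur.children)
    return frozenset(out)


def _rehang(node: TreeNode) -> None:
    """Reverse parent links from ``node`` to the old root; ``node`` becomes a root."""
    chain: List[TreeNode] = []
    cur: Optional[TreeNode] = node
    while cur is not None:
        chain.append(cur)
        cur = cur.parent
    for lower, upper in zip(chain, chain[1:]):
        upper.children.remove(lower)
        upper.length = lower.length
        lower.children.append(upper)
        upper.parent = lower
    node.parent = None


def _suppress_unary(root: TreeNode) -> None:
    stack = [root]
    while stack:
        node = stack.pop()
        for child in list(node.children):
            while len(child.children) == 1:
                only = child.children[0]
                only.length += child.length
                only.parent = node
                node.children[node.children.index(child)] = only
                child = only
            stack.append(child)
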