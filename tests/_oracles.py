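"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's vectorized code paths: plain Python
loops, pair enumeration, and exact rational arithmetic where sums of floats
would otherwise differ in association order.
"""

from fractions import Fraction
from itertools import combinations

import numpy as np

ACGT = set("ACGT")


def bf_p_distance(a: str, b: str):
    """Pairwise-deletion p-distance by direct column enumeration."""
    assert len(a) == len(b)
    compared = diffs = 0
    for x, y in zip(a, b):
        if x in ACGT and y in ACGT:
            compared += 1
            if x != y:
                diffs += 1
    if compared == 0:
        return float("nan"), 0
    return diffs / compared, compared


def bf_distance_matrix(seqs):
    n = len(seqs)
    D = np.full((n, n), 0.0)
    C = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d, c = bf_p_distance(seqs[i], seqs[j])
            D[i, j] = d
            C[i, j] = c
    return D, C


def bf_pi_complete(seqs) -> Fraction:
    """Complete-deletion Pi as an exact fraction; None when undefined."""
    n = len(seqs)
    keep = [
        k
        for k in range(len(seqs[0]))
        if all(s[k] in ACGT for s in seqs)
    ]
    if not keep:
        return None
    total = Fraction(0)
    for i, j in combinations(range(n), 2):
        diffs = sum(1 for k in keep if seqs[i][k] != seqs[j][k])
        total += Fraction(diffs, len(keep))
    return total / Fraction(n * (n - 1), 2)


def bf_variable_and_informative(seqs):
    n_var = n_pis = 0
    for k in range(len(seqs[0])):
        col = [s[k] for s in seqs if s[k] in ACGT]
        states = set(col)
        if len(states) >= 2:
            n_var += 1
        if sum(1 for b in states if col.count(b) >= 2) >= 2:
            n_pis += 1
    return n_var, n_pis


def bf_monophyly(newick: str, leaf_set) -> bool:
    """Enumerate all clades of a rooted Newick tree via dendropy."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    target = frozenset(leaf_set)
    for node in tree.preorder_node_iter():
        clade = frozenset(l.taxon.label for l in node.leaf_iter())
        if clade == target:
            return True
    return False


def rf_distance(newick_a: str, newick_b: str) -> int:
    """Unrooted Robinson-Foulds distance via dendropy."""
    import dendropy
    from dendropy.calculate import treecompare

    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(
        data=newick_a, schema="newick", taxon_namespace=tns, preserve_underscores=True
    )
    tb = dendropy.Tree.get(
        data=newick_b, schema="newick", taxon_namespace=tns, preserve_underscores=True
    )
    ta.is_rooted = tb.is_rooted = False
    ta.update_bipartitions()
    tb.update_bipartitions()
    return int(treecompare.symmetric_difference(ta, tb))


def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """Random unrooted binary tree with positive branch lengths.

    Returns (PhyloTree, ids, additive distance matrix).
    """
    from superbarcode.phylo import PhyloTree, TreeNode

    ids = [f"t{i:02d}" for i in range(n_taxa)]

    def blen():
        return float(rng.uniform(0.5, 2.0))

    root = TreeNode()
    for name in ids[:3]:
        root.add_child(TreeNode(name, blen()))
    edges = list(root.children)
    for name in ids[3:]:
        edge_child = edges[int(rng.integers(len(edges)))]
        parent = edge_child.parent
        mid = TreeNode(None, edge_child.length / 2)
        edge_child.length /= 2
        parent.children[parent.children.index(edge_child)] = mid
        mid.parent = parent
        mid.add_child(edge_child)
        leaf = mid.add_child(TreeNode(name, blen()))
        edges.extend([mid, leaf])
    tree = PhyloTree(root)
    return tree, ids, tree.path_lengths(ids)
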