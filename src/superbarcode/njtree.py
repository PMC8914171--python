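"""Neighbor-joining trees, outgroup rooting, and species-monophyly testing.

This is the Tree-Building discrimination method: build an NJ tree from
uncorrected p-distances, root it with the designated outgroup(s), and score a
species as a success when all of its individuals form a monophyletic group.

The agglomeration is the Saitou-Nei algorithm with the Studier-Keppler Q
criterion, Q(i,j) = (r-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k). Ties in Q are
broken by the lexicographically smallest (id_i, id_j) pair, where a cluster is
identified by its smallest member accession — this makes the output
deterministic and independent of taxon input order. Negative limb lengths are
clamped to zero with the deficit moved to the sister limb, the common NJ
convention; the monophyly criterion is purely topological, so clamping only
affects reported branch lengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .distmat import DistanceMatrix, distance_matrix
from .errors import IncompleteMatrixError, ParameterError, RootingError
from .phylo import PhyloTree, TreeNode
from .seqio import LabeledAlignment, SpeciesMap


def neighbor_joining(dist: DistanceMatrix) -> PhyloTree:
    """Unrooted NJ tree; requires a complete matrix over >= 3 taxa."""
    n = len(dist.ids)
    if n < 3:
        raise ParameterError(f"neighbor joining requires >= 3 taxa, got {n}")
    bad = dist.undefined_pairs()
    if bad:
        a, b = bad[0]
        raise IncompleteMatrixError(
            f"distance undefined for pair ({a}, {b}); {len(bad)} undefined pair(s)"
        )
    D = dist.values.astype(float).copy()
    nodes: List[TreeNode] = [TreeNode(name) for name in dist.ids]
    labels: List[str] = list(dist.ids)  # smallest member id per cluster

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        tol = 1e-12 * max(1.0, abs(qmin))
        cand = np.argwhere(Q <= qmin + tol)
        i, j = min(
            ((int(a), int(b)) for a, b in cand if a < b),
            key=lambda ij: tuple(sorted((labels[ij[0]], labels[ij[1]]))),
        )
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        elif lj < 0:
            lj, li = 0.0, dij
        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        du = 0.5 * (D[i] + D[j] - dij)
        du = np.maximum(du, 0.0)
        keep = [k for k in range(m) if k not in (i, j)]
        newD = np.zeros((m - 1, m - 1))
        newD[:-1, :-1] = D[np.ix_(keep, keep)]
        newD[-1, :-1] = newD[:-1, -1] = du[keep]
        D = newD
        new_label = min(labels[i], labels[j])
        nodes = [nodes[k] for k in keep] + [parent]
        labels = [labels[k] for k in keep] + [new_label]

    # final three-point join: closed-form limb lengths around a central node
    (i, j, k) = (0, 1, 2)
    center = TreeNode()
    lengths = (
        0.5 * (D[i, j] + D[i, k] - D[j, k]),
        0.5 * (D[i, j] + D[j, k] - D[i, k]),
        0.5 * (D[i, k] + D[j, k] - D[i, j]),
    )
    for node, length in sorted(
        zip(nodes, lengths), key=lambda nl: labels[nodes.index(nl[0])]
    ):
        node.length = max(0.0, length)
        center.add_child(node)
    tree = PhyloTree(center)
    tree.ladderize()
    return tree


def root_with_outgroup(tree: PhyloTree, outgroup_ids) -> PhyloTree:
    """Root on the edge separating the outgroup clade (or single leaf),
    splitting that edge's length equally."""
    rooted = tree.rooted_with_outgroup(sorted(outgroup_ids))
    rooted.ladderize()
    return rooted


def is_monophyletic(tree: PhyloTree, leaf_set) -> bool:
    """True iff some node's complete leaf descendants equal ``leaf_set``."""
    return tree.is_monophyletic(leaf_set)


@dataclass(frozen=True)
class SpeciesMonophyly:
    species: str
    n_individuals: int
    monophyletic: Optional[bool]  # None only if the species is absent
    singleton: bool


@dataclass(frozen=True)
class MonophylyResult:
    entries: Tuple[SpeciesMonophyly, ...]
    tree: PhyloTree

    @property
    def n_scored(self) -> int:
        return sum(1 for e in self.entries if not e.singleton)

    @property
    def n_success(self) -> int:
        return sum(1 for e in self.entries if not e.singleton and e.monophyletic)

    @property
    def rate(self) -> float:
        return self.n_success / self.n_scored if self.n_scored else math.nan

    def per_species(self) -> Dict[str, Optional[bool]]:
        return {
            e.species: (None if e.singleton else e.monophyletic) for e in self.entries
        }

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#species\tn_individuals\tmonophyletic\tsingleton\tmethod\n")
            for e in self.entries:
                fh.write(
                    f"{e.species}\t{e.n_individuals}\t{e.monophyletic}\t{e.singleton}\tNJ\n"
                )


def tree_method(
    aln: LabeledAlignment,
    species: SpeciesMap,
    dist: Optional[DistanceMatrix] = None,
) -> MonophylyResult:
    """Distance matrix -> NJ -> outgroup rooting -> per-species monophyly.

    If the full outgroup set does not form a clade in the NJ tree (possible
    with two or more outgroups), rooting falls back to the single
    lexicographically-first outgroup leaf, which is always a valid rooting
    point.

    Singleton species are flagged and excluded from the success denominator;
    their recorded flag is True only when the singleton is not nested inside
    another species' minimal clade.
    """
    outgroups = sorted(set(species.outgroup_ids) & set(aln.ids))
    if not outgroups:
        raise ParameterError("tree method requires outgroup accessions in the alignment")
    if dist is None:
        dist = distance_matrix(aln)
    tree = neighbor_joining(dist)
    try:
        rooted = root_with_outgroup(tree, outgroups)
    except RootingError:
        rooted = root_with_outgroup(tree, [outgroups[0]])

    groups = species.ingroup_species()
    present = set(aln.ids)
    multi_clades = {
        sp: rooted.mrca_clade(accs)
        for sp, accs in groups.items()
        if len(accs) >= 2 and set(accs) <= present
    }
    entries: List[SpeciesMonophyly] = []
    for sp, accs in groups.items():
        if not set(accs) <= present:
            entries.append(SpeciesMonophyly(sp, len(accs), None, len(accs) < 2))
            continue
        if len(accs) >= 2:
            mono = rooted.is_monophyletic(accs)
            entries.append(SpeciesMonophyly(sp, len(accs), mono, False))
        else:
            leaf = accs[0]
            nested = any(
                leaf in clade for osp, clade in multi_clades.items() if osp != sp
            )
            entries.append(SpeciesMonophyly(sp, 1, not nested, True))
    return MonophylyResult(tuple(entries), rooted)
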