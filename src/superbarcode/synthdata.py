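"""Species-structured sequence community simulator with full ground truth.

Generates aligned communities that emulate a multi-accession plastome study:
~21 species with 2-6 individuals each, small within-species divergence, an
order of magnitude more between-species divergence, shared indels, one distant
outgroup, and optionally one species planted as paraphyletic (half of its
individuals grafted onto another species' stem, the way *F. cirrhosa*
accessions split into two clades in real plastome data).

Model
-----
* Species tree: a Yule (pure-birth) tree over the species, rescaled so the
  mean tip-to-tip path length equals ``interspecific_scale`` minus
  ``intraspecific_scale`` (individual pendants add the intraspecific scale to
  every between-species pair, so realized individual-level distances match the
  requested scale). Species stem branches can be floored at
  ``min_species_stem`` to guarantee a minimum between-species separation.
* Individuals: a star subtree per species, each pendant of length
  ``intraspecific_scale / 2`` (expected within-species pairwise distance =
  the intraspecific scale). No within-species genealogy is modelled: the
  discrimination criteria are functions of distances only.
* Sequences: Jukes-Cantor evolution from a uniform-composition root; a branch
  of length t (expected substitutions/site) changes each site with
  probability 3/4 (1 - exp(-4t/3)), to one of the three other bases uniformly.
* Indels: a Poisson number of events (``indel_rate`` per alignment column),
  geometric lengths, each applied as a shared gap run to all descendants of a
  random tree node — homology stays exact and the output needs no re-alignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .errors import ParameterError
from .phylo import PhyloTree, TreeNode
from .seqio import (
    AlignmentRecord,
    LabeledAlignment,
    SpeciesMap,
    write_alignment,
    write_species_table,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_GAP = ord("-")

#: Individuals per species matching a 21-species / 73-accession community.
COMMUNITY_COUNTS: Tuple[int, ...] = (
    6, 2, 4, 4, 3, 5, 3, 2, 3, 4, 3, 6, 3, 3, 3, 4, 3, 3, 3, 3, 3,
)


@dataclass(frozen=True)
class SimulationParams:
    seed: int
    n_species: int = 21
    individuals_per_species: Union[int, Tuple[int, int], Tuple[int, ...]] = (2, 6)
    alignment_length: int = 20_000
    interspecific_scale: float = 0.0041
    intraspecific_scale: float = 0.0003
    indel_rate: float = 0.01
    indel_length_mean: float = 8.0
    paraphyly_species: Optional[int] = None
    outgroup_divergence: float = 0.03
    min_species_stem: float = 0.0
    gc_content: float = 0.37  # root base composition; plastomes are AT-rich

    def validate(self) -> None:
        if self.seed is None:
            raise ParameterError("seed is mandatory")
        if self.n_species < 1:
            raise ParameterError("need at least one species")
        if self.alignment_length < 1:
            raise ParameterError("alignment length must be positive")
        if not (0.0 <= self.gc_content <= 1.0):
            raise ParameterError("gc_content must be in [0, 1]")
        for name in (
            "interspecific_scale",
            "intraspecific_scale",
            "indel_rate",
            "indel_length_mean",
            "outgroup_divergence",
            "min_species_stem",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        counts = self.resolve_counts(np.random.default_rng(0))
        if any(c < 1 for c in counts):
            raise ParameterError("every species needs at least one individual")
        if self.paraphyly_species is not None and not (
            0 <= self.paraphyly_species < self.n_species
        ):
            raise ParameterError("paraphyly_species index out of range")

    def resolve_counts(self, rng: np.random.Generator) -> List[int]:
        ips = self.individuals_per_species
        if isinstance(ips, int):
            return [ips] * self.n_species
        ips = tuple(ips)
        if len(ips) == 2 and self.n_species != 2:
            lo, hi = ips
            return list(rng.integers(lo, hi + 1, size=self.n_species))
        if len(ips) != self.n_species:
            raise ParameterError(
                f"individuals_per_species has {len(ips)} entries for "
                f"{self.n_species} species"
            )
        return list(ips)


@dataclass(frozen=True)
class SimulationTruth:
    species_of: Dict[str, str]
    outgroup_ids: Tuple[str, ...]
    tree_newick: str  # full genealogy (species tree + individual pendants)
    split_species: Optional[str]
    moved_ids: Tuple[str, ...]
    params: SimulationParams

    def species_map(self) -> SpeciesMap:
        return SpeciesMap(self.species_of, frozenset(self.outgroup_ids))

    def write(self, path) -> None:
        import yaml

        payload = {
            "species_of": dict(self.species_of),
            "outgroup_ids": list(self.outgroup_ids),
            "tree_newick": self.tree_newick,
            "split_species": self.split_species,
            "moved_ids": list(self.moved_ids),
            "params": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(self.params).items()
            },
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def _yule_species_tree(n: int, rng: np.random.Generator) -> Tuple[TreeNode, List[TreeNode]]:
    """Ultrametric pure-birth tree; returns (root, tips in creation order)."""
    root = TreeNode("tip")
    tips = [root]
    while len(tips) < n:
        t = rng.exponential(1.0 / len(tips))
        for tip in tips:
            tip.length += t
        k = int(rng.integers(len(tips)))
        parent = tips[k]
        left, right = TreeNode("tip"), TreeNode("tip")
        parent.add_child(left)
        parent.add_child(right)
        tips[k] = left
        tips.append(right)
    t = rng.exponential(1.0 / n)
    for tip in tips:
        tip.length += t
    return root, tips


def _tip_path_mean(root: TreeNode, tips: Sequence[TreeNode]) -> float:
    depths: Dict[int, float] = {}

    def walk(node: TreeNode, depth: float) -> None:
        depths[id(node)] = depth
        for c in node.children:
            walk(c, depth + c.length)

    walk(root, 0.0)
    # mean pairwise path = mean(d_i + d_j - 2 d_mrca); compute directly O(n^2)
    names = {id(t): i for i, t in enumerate(tips)}
    n = len(tips)
    total, pairs = 0.0, 0

    tip_depth = {names[id(t)]: depths[id(t)] for t in tips}

    def rec(node: TreeNode) -> List[int]:
        if not node.children:
            return [names[id(node)]]
        nonlocal total, pairs
        sides = [rec(c) for c in node.children]
        for i in range(len(sides)):
            for j in range(i + 1, len(sides)):
                for a in sides[i]:
                    for b in sides[j]:
                        total += tip_depth[a] + tip_depth[b] - 2 * depths[id(node)]
                        pairs += 1
        merged: List[int] = []
        for s in sides:
            merged.extend(s)
        return merged

    rec(root)
    return total / pairs if pairs else 0.0


def _scale_tree(root: TreeNode, factor: float) -> None:
    stack = [root]
    while stack:
        node = stack.pop()
        node.length *= factor
        stack.extend(node.children)


def _evolve(parent_seq: np.ndarray, t: float, rng: np.random.Generator) -> np.ndarray:
    """Jukes-Cantor: each site changes with prob 3/4(1-exp(-4t/3))."""
    child = parent_seq.copy()
    if t <= 0:
        return child
    p = 0.75 * (1.0 - math.exp(-4.0 * t / 3.0))
    hit = np.flatnonzero(rng.random(child.size) < p)
    if hit.size:
        shift = rng.integers(1, 4, size=hit.size).astype(np.uint8)
        idx = np.searchsorted(_BASES, child[hit])
        child[hit] = _BASES[(idx + shift) % 4]
    return child


def simulate_community(params: SimulationParams) -> Tuple[LabeledAlignment, SimulationTruth]:
    """Simulate one aligned community; deterministic given params (incl. seed)."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    n_sp = params.n_species
    counts = params.resolve_counts(rng)
    species_names = [f"sp{i + 1:02d}" for i in range(n_sp)]

    # species tree
    if n_sp > 1:
        sroot, tips = _yule_species_tree(n_sp, rng)
        target = max(params.interspecific_scale - params.intraspecific_scale, 0.0)
        mean_path = _tip_path_mean(sroot, tips)
        if mean_path > 0 and target > 0:
            _scale_tree(sroot, target / mean_path)
        elif target == 0:
            _scale_tree(sroot, 0.0)
        for tip in tips:
            tip.length = max(tip.length, params.min_species_stem)
    else:
        sroot = TreeNode("tip", 0.0)
        tips = [sroot]

    # individuals: star subtrees at each species tip
    pendant = params.intraspecific_scale / 2.0
    leaves_of: Dict[str, List[TreeNode]] = {}
    for tip, sp, k in zip(tips, species_names, counts):
        tip.name = None
        leaves_of[sp] = []
        for j in range(k):
            leaf = tip.add_child(TreeNode(f"{sp}_i{j + 1}", pendant))
            leaves_of[sp].append(leaf)

    # planted paraphyly: re-graft half of one species onto the longest other stem
    split_species: Optional[str] = None
    moved_ids: Tuple[str, ...] = ()
    if params.paraphyly_species is not None and n_sp >= 2:
        p = params.paraphyly_species
        sp_name = species_names[p]
        host_idx = max(
            (i for i in range(n_sp) if i != p),
            key=lambda i: (tips[i].length, -i),
        )
        host = tips[host_idx]
        k = counts[p]
        moved = leaves_of[sp_name][k - k // 2 :] if k >= 2 else []
        if moved:
            split_species = sp_name
            moved_ids = tuple(leaf.name for leaf in moved)
            hparent = host.parent
            attach = TreeNode(None, host.length / 2.0)
            host.length = host.length / 2.0
            hparent.children[hparent.children.index(host)] = attach
            attach.parent = hparent
            attach.add_child(host)
            # Pendants long enough that each moved individual is nearer to the
            # host species than to its own conspecifics: the split species then
            # fails both the tree and the top-hit criteria, while the host's
            # tight crown keeps the host monophyletic and self-hitting.
            moved_pendant = host.length + 2.0 * params.intraspecific_scale
            for leaf in moved:
                leaf.parent.children.remove(leaf)
                leaf.length = moved_pendant
                attach.add_child(leaf)

    # outgroup above the ingroup root
    root = TreeNode()
    sroot.length = 0.0
    root.add_child(sroot)
    out_leaf = root.add_child(TreeNode("outgroup_i1", params.outgroup_divergence))
    genealogy = PhyloTree(root)

    # evolve sequences preorder
    seqs: Dict[str, np.ndarray] = {}
    gc = params.gc_content
    base_freqs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    root_seq = _BASES[rng.choice(4, size=params.alignment_length, p=base_freqs)]

    def descend(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            cseq = _evolve(seq, child.length, rng)
            if child.is_leaf:
                seqs[child.name] = cseq
            descend(child, cseq)

    descend(root, root_seq)

    # superimpose shared indel events
    order: List[str] = ["outgroup_i1"]
    for sp in species_names:
        order.extend(leaf.name for leaf in leaves_of[sp])
    row_of = {name: i for i, name in enumerate(order)}
    M = np.stack([seqs[name] for name in order])
    L = params.alignment_length
    nodes = [n for n in genealogy.preorder() if n is not root]
    clade_rows: List[List[int]] = []
    for node in nodes:
        rows = [
            row_of[leaf.name]
            for leaf in genealogy.leaves()
            if _is_descendant(leaf, node)
        ]
        clade_rows.append(rows)
    n_events = rng.poisson(params.indel_rate * L) if params.indel_rate > 0 else 0
    for _ in range(n_events):
        node_idx = int(rng.integers(len(nodes)))
        start = int(rng.integers(0, L))
        length = int(rng.geometric(1.0 / max(params.indel_length_mean, 1.0)))
        end = min(L, start + length)
        M[clade_rows[node_idx], start:end] = _GAP

    records = []
    for name in order:
        sp = "outgroup" if name == "outgroup_i1" else name.rsplit("_", 1)[0]
        records.append(
            AlignmentRecord(
                name, sp, M[row_of[name]].tobytes().decode("ascii"), header=name
            )
        )
    aln = LabeledAlignment(records, name="simulated_community")
    truth = SimulationTruth(
        species_of={r.accession_id: r.species_label for r in records},
        outgroup_ids=("outgroup_i1",),
        tree_newick=genealogy.newick(precision=8),
        split_species=split_species,
        moved_ids=moved_ids,
        params=params,
    )
    return aln, truth


def _is_descendant(leaf: TreeNode, ancestor: TreeNode) -> bool:
    cur: Optional[TreeNode] = leaf
    while cur is not None:
        if cur is ancestor:
            return True
        cur = cur.parent
    return False


# ---------------------------------------------------------------------------
# presets


def preset(name: str, seed: int = 0) -> SimulationParams:
    """Named study conditions.

    * ``clean``: 21 species / 73 individuals with a wide, guaranteed barcoding
      gap (inter/intra ratio 20, floored species stems) — every method should
      discriminate every species.
    * ``fritillaria_like``: the realistic condition — 21 species / 73
      individuals, genome-scale alignment, intraspecific mean ~0.03% and
      interspecific mean ~0.41% p-distance, heavy shared indels.
    * ``paraphyletic``: ``fritillaria_like`` plus one six-accession species
      split across two clades.
    """
    if name == "clean":
        return SimulationParams(
            seed=seed,
            n_species=21,
            individuals_per_species=COMMUNITY_COUNTS,
            alignment_length=20_000,
            interspecific_scale=0.006,
            intraspecific_scale=0.0003,
            indel_rate=0.002,
            indel_length_mean=6.0,
            outgroup_divergence=0.03,
            min_species_stem=0.0015,
        )
    if name == "fritillaria_like":
        return SimulationParams(
            seed=seed,
            n_species=21,
            individuals_per_species=COMMUNITY_COUNTS,
            alignment_length=157_507,
            interspecific_scale=0.0041,
            intraspecific_scale=0.0003,
            indel_rate=0.04,
            indel_length_mean=10.0,
            outgroup_divergence=0.03,
            min_species_stem=0.0003,
        )
    if name == "paraphyletic":
        return replace(preset("fritillaria_like", seed), paraphyly_species=0)
    raise ParameterError(f"unknown preset {name!r}")


def write_simulation(aln: LabeledAlignment, truth: SimulationTruth, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_alignment(aln, outdir / "community.fasta")
    write_species_table(truth.species_map(), outdir / "species.tsv")
    truth.write(outdir / "truth.yaml")
    (outdir / "tree.nwk").write_text(truth.tree_newick + "\n")
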