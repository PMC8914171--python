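"""Pairwise p-distances, per-dataset variability statistics, and the
barcoding-gap (Distance-method) discrimination criterion.

p-distances are uncorrected proportions of differing sites. Sites where either
sequence carries a gap or an ambiguity code (anything outside A/C/G/T) are
excluded pair by pair — the MEGA pairwise-deletion convention. This coexists
deliberately with the complete-deletion rule used for Pi in
:mod:`superbarcode.regionscan`: the two conventions mirror the two tools
(MEGA, DnaSP) classically used for these statistics.

A species shows a barcoding gap when its smallest interspecific p-distance is
strictly larger than its largest intraspecific one. Species with a single
individual have no intraspecific distance; they are flagged and excluded from
the success denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import AlignmentShapeError, IdentityError, ParameterError
from .seqio import LabeledAlignment, SpeciesMap

_ACGT = frozenset(b"ACGT")
_ACGT_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class DistanceMatrix:
    """Symmetric p-distance matrix with per-pair comparable-site counts.

    Cells with no comparable sites are NaN (never silently 0); their
    ``comparable_sites`` entry is 0.
    """

    ids: List[str]
    values: np.ndarray
    comparable_sites: np.ndarray

    def index(self, accession_id: str) -> int:
        try:
            return self.ids.index(accession_id)
        except ValueError:
            raise IdentityError(f"accession {accession_id!r} not in distance matrix") from None

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def subset(self, accession_ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.index(a) for a in accession_ids]
        return DistanceMatrix(
            list(accession_ids),
            self.values[np.ix_(idx, idx)].copy(),
            self.comparable_sites[np.ix_(idx, idx)].copy(),
        )

    def undefined_pairs(self) -> List[Tuple[str, str]]:
        out = []
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                if math.isnan(self.values[i, j]):
                    out.append((self.ids[i], self.ids[j]))
        return out

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("id\t" + "\t".join(self.ids) + "\n")
            for i, a in enumerate(self.ids):
                row = "\t".join(
                    "NA" if math.isnan(v) else f"{v:.6f}" for v in self.values[i]
                )
                fh.write(f"{a}\t{row}\n")

    def to_long_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#id_a\tid_b\tdistance\tn_compared\n")
            n = len(self.ids)
            for i in range(n):
                for j in range(i + 1, n):
                    v = self.values[i, j]
                    d = "NA" if math.isnan(v) else f"{v:.6f}"
                    fh.write(
                        f"{self.ids[i]}\t{self.ids[j]}\t{d}\t{int(self.comparable_sites[i, j])}\n"
                    )


def p_distance(seq_a: str, seq_b: str) -> Tuple[float, int]:
    """Uncorrected p-distance with pairwise deletion.

    Returns ``(distance, n_compared)``; the distance is NaN when no site is
    comparable.
    """
    if len(seq_a) != len(seq_b):
        raise AlignmentShapeError(
            f"sequence lengths differ: {len(seq_a)} vs {len(seq_b)}"
        )
    a = np.frombuffer(seq_a.upper().encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(seq_b.upper().encode("ascii"), dtype=np.uint8)
    va = np.isin(a, _ACGT_CODES)
    vb = np.isin(b, _ACGT_CODES)
    valid = va & vb
    n = int(valid.sum())
    if n == 0:
        return math.nan, 0
    diffs = int(((a != b) & valid).sum())
    return diffs / n, n


def distance_matrix(aln: LabeledAlignment) -> DistanceMatrix:
    """All pairwise p-distances (pairwise deletion per pair)."""
    if aln.n < 2:
        raise ParameterError("distance matrix requires at least 2 records")
    M = aln.matrix()
    valid = np.isin(M, _ACGT_CODES)
    n = aln.n
    values = np.zeros((n, n), dtype=float)
    counts = np.zeros((n, n), dtype=np.int64)
    for i in range(n - 1):
        pair_valid = valid[i] & valid[i + 1 :]
        comp = pair_valid.sum(axis=1)
        diffs = ((M[i] != M[i + 1 :]) & pair_valid).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(comp > 0, diffs / np.maximum(comp, 1), math.nan)
        values[i, i + 1 :] = d
        values[i + 1 :, i] = d
        counts[i, i + 1 :] = comp
        counts[i + 1 :, i] = comp
    np.fill_diagonal(counts, valid.sum(axis=1))
    return DistanceMatrix(list(aln.ids), values, counts)


@dataclass(frozen=True)
class VariabilityStats:
    """Table-2-style summary of one aligned dataset."""

    aligned_length: int
    n_variable_sites: int
    n_parsimony_informative: int
    n_indel_events: int
    gc_content: float
    pi: float
    intra_range: Tuple[float, float]
    intra_mean: float
    inter_range: Tuple[float, float]
    inter_mean: float

    def summary(self) -> str:
        fmtpct = lambda x: "NA" if math.isnan(x) else f"{100 * x:.2f}%"
        return (
            f"aligned length {self.aligned_length} bp; "
            f"{self.n_variable_sites} variable sites; "
            f"{self.n_parsimony_informative} parsimony-informative sites; "
            f"{self.n_indel_events} indel events; "
            f"GC {100 * self.gc_content:.1f}%; Pi {self.pi:.5f}; "
            f"intra {fmtpct(self.intra_range[0])}-{fmtpct(self.intra_range[1])} "
            f"(mean {fmtpct(self.intra_mean)}); "
            f"inter {fmtpct(self.inter_range[0])}-{fmtpct(self.inter_range[1])} "
            f"(mean {fmtpct(self.inter_mean)})"
        )


def _gap_runs(row: np.ndarray) -> List[Tuple[int, int]]:
    gap = row == ord("-")
    if not gap.any():
        return []
    runs: List[Tuple[int, int]] = []
    padded = np.concatenate(([False], gap, [False]))
    d = np.diff(padded.astype(np.int8))
    run_starts = np.flatnonzero(d == 1)
    run_ends = np.flatnonzero(d == -1)
    for s, e in zip(run_starts, run_ends):
        runs.append((int(s), int(e)))
    return runs


def variability_stats(
    aln: LabeledAlignment,
    species: Optional[SpeciesMap] = None,
    dist: Optional[DistanceMatrix] = None,
) -> VariabilityStats:
    """Variable/parsimony-informative site counts, indel events, GC, Pi, and
    intra/interspecific p-distance summaries.

    A variable site has >= 2 distinct unambiguous nucleotides; a parsimony-
    informative site has >= 2 such nucleotides each in >= 2 records. Indel
    events are distinct maximal gap runs (unique (start, end) across records).
    Outgroup accessions (from ``species``) are excluded from the distance
    summaries.
    """
    if aln.n < 2:
        raise ParameterError("variability statistics require at least 2 records")
    from .regionscan import nucleotide_diversity

    M = aln.matrix()
    counts = np.stack([(M == c).sum(axis=0) for c in _ACGT_CODES])
    n_variable = int(((counts >= 1).sum(axis=0) >= 2).sum())
    n_pis = int(((counts >= 2).sum(axis=0) >= 2).sum())
    acgt_total = counts.sum()
    gc = float((counts[1] + counts[2]).sum() / acgt_total) if acgt_total else math.nan

    runs = set()
    for row in M:
        runs.update(_gap_runs(row))
    n_indels = len(runs)

    if species is None:
        species = SpeciesMap.from_alignment(aln)
    if dist is None:
        dist = distance_matrix(aln)
    intra, inter = _split_distances(dist, species)
    summarize = lambda v: (
        ((float(np.min(v)), float(np.max(v))), float(np.mean(v)))
        if len(v)
        else ((math.nan, math.nan), math.nan)
    )
    intra_range, intra_mean = summarize(intra)
    inter_range, inter_mean = summarize(inter)
    return VariabilityStats(
        aligned_length=aln.length,
        n_variable_sites=n_variable,
        n_parsimony_informative=n_pis,
        n_indel_events=n_indels,
        gc_content=gc,
        pi=nucleotide_diversity(aln, deletion="complete"),
        intra_range=intra_range,
        intra_mean=intra_mean,
        inter_range=inter_range,
        inter_mean=inter_mean,
    )


def _split_distances(dist: DistanceMatrix, species: SpeciesMap):
    """Defined intra- and inter-specific distances among ingroup accessions."""
    intra: List[float] = []
    inter: List[float] = []
    ids = [a for a in dist.ids if a not in species.outgroup_ids]
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            v = dist.get(a, b)
            if math.isnan(v):
                continue
            (intra if species.species_of(a) == species.species_of(b) else inter).append(v)
    return np.asarray(intra), np.asarray(inter)


@dataclass(frozen=True)
class SpeciesGap:
    species: str
    n_individuals: int
    max_intra: float  # NaN for singletons
    min_inter: float
    success: Optional[bool]  # None when undefined (singleton / no defined pair)

    @property
    def singleton(self) -> bool:
        return self.n_individuals < 2


@dataclass(frozen=True)
class GapReport:
    entries: Tuple[SpeciesGap, ...]

    @property
    def n_scored(self) -> int:
        return sum(1 for e in self.entries if e.success is not None)

    @property
    def n_success(self) -> int:
        return sum(1 for e in self.entries if e.success)

    @property
    def rate(self) -> float:
        return self.n_success / self.n_scored if self.n_scored else math.nan

    def per_species(self) -> Dict[str, Optional[bool]]:
        return {e.species: e.success for e in self.entries}

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#species\tn_individuals\tmax_intra\tmin_inter\tsuccess\n")
            for e in self.entries:
                mi = "NA" if math.isnan(e.max_intra) else f"{e.max_intra:.6f}"
                mn = "NA" if math.isnan(e.min_inter) else f"{e.min_inter:.6f}"
                s = "NA" if e.success is None else str(e.success)
                fh.write(f"{e.species}\t{e.n_individuals}\t{mi}\t{mn}\t{s}\n")


def barcoding_gap(dist: DistanceMatrix, species: SpeciesMap) -> GapReport:
    """Distance-method criterion: min interspecific > max intraspecific
    (strict), per ingroup species. Outgroups never enter the comparison."""
    groups = species.ingroup_species()
    if len(groups) < 2:
        raise ParameterError("barcoding gap requires at least 2 ingroup species")
    for accs in groups.values():
        for a in accs:
            dist.index(a)  # raises IdentityError if absent
    entries: List[SpeciesGap] = []
    for sp, accs in groups.items():
        others = [a for osp, oaccs in groups.items() if osp != sp for a in oaccs]
        intra = [
            dist.get(a, b)
            for i, a in enumerate(accs)
            for b in accs[i + 1 :]
            if not math.isnan(dist.get(a, b))
        ]
        inter = [
            dist.get(a, b) for a in accs for b in others if not math.isnan(dist.get(a, b))
        ]
        max_intra = max(intra) if intra else math.nan
        min_inter = min(inter) if inter else math.nan
        if len(accs) < 2 or math.isnan(max_intra) or math.isnan(min_inter):
            success: Optional[bool] = None
        else:
            success = min_inter > max_intra
        entries.append(SpeciesGap(sp, len(accs), max_intra, min_inter, success))
    return GapReport(tuple(entries))
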