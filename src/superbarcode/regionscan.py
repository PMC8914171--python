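"""Sliding-window nucleotide diversity, HVR delineation, and region extraction.

Nucleotide diversity (Pi) is the average per-site proportion of pairwise
differences, Pi = (sum_{i<j} d_ij) / C(n, 2). Two missing-data rules are
supported:

* ``complete`` deletion (default, the DnaSP convention): every column
  containing a gap or ambiguity in any sequence is dropped before the pairwise
  proportions are computed, so all pairs share one denominator.
* ``pairwise`` deletion: each pair is compared over its own comparable sites.

A high-variable region (HVR) is a run of windows whose Pi reaches a threshold;
nearby passing windows are merged. The threshold can be given directly or as a
percentile of the window Pi distribution, since delineating HVRs by eye from a
diversity profile amounts to picking a high quantile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import CoordinateError, ParameterError
from .seqio import Feature, FeatureTable, LabeledAlignment, reverse_complement

_ACGT_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)
_GAP_CODE = ord("-")


@dataclass(frozen=True)
class Window:
    start: int
    end: int
    pi: float  # NaN when undefined (no usable columns)
    n_sites_used: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.pi)


@dataclass(frozen=True)
class DiversityTrack:
    windows: Tuple[Window, ...]
    window_length: int
    step: int

    def max_pi(self) -> float:
        vals = [w.pi for w in self.windows if w.defined]
        return max(vals) if vals else math.nan

    def pi_percentile(self, q: float) -> float:
        vals = [w.pi for w in self.windows if w.defined]
        if not vals:
            return math.nan
        return float(np.percentile(vals, q))


@dataclass(frozen=True)
class HvrCall:
    name: str
    start: int
    end: int
    peak_pi: float


def _column_stats(aln: LabeledAlignment) -> Tuple[np.ndarray, np.ndarray]:
    """Per-column (all-rows-canonical mask, mean pairwise mismatch fraction).

    The per-column mismatch fraction is 1 - sum_b C(c_b, 2) / C(n, 2) where
    c_b are the base counts; summed over complete-deletion columns this equals
    the pair-enumeration definition of Pi exactly.
    """
    M = aln.matrix()
    n = aln.n
    counts = np.stack([(M == c).sum(axis=0) for c in _ACGT_CODES])
    ok = counts.sum(axis=0) == n
    pairs_total = n * (n - 1) / 2.0
    pairs_same = (counts * (counts - 1) / 2.0).sum(axis=0)
    col_pi = 1.0 - pairs_same / pairs_total
    return ok, col_pi


def nucleotide_diversity(aln: LabeledAlignment, deletion: str = "complete") -> float:
    """Per-site nucleotide diversity (Pi); NaN when no usable columns remain."""
    if aln.n < 2:
        raise ParameterError("nucleotide diversity requires at least 2 sequences")
    if deletion == "complete":
        ok, col_pi = _column_stats(aln)
        if not ok.any():
            return math.nan
        return float(col_pi[ok].mean())
    if deletion == "pairwise":
        from .distmat import distance_matrix

        dm = distance_matrix(aln)
        iu = np.triu_indices(aln.n, k=1)
        vals = dm.values[iu]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            return math.nan
        return float(vals.mean())
    raise ParameterError(f"unknown deletion rule {deletion!r}")


def sliding_window_pi(
    aln: LabeledAlignment,
    window_length: int = 600,
    step: int = 200,
    deletion: str = "complete",
) -> DiversityTrack:
    """Window Pi profile; windows start at 0, step, 2*step, ...

    Full windows are emitted while they fit; if the last full window does not
    already end at the alignment end, one truncated terminal window is added
    provided it is at least ``step`` long, so terminal diversity is not lost.
    """
    if window_length <= 0 or step <= 0:
        raise ParameterError("window_length and step must be positive")
    L = aln.length
    if L < window_length:
        raise ParameterError(f"alignment length {L} < window length {window_length}")
    if deletion == "complete":
        ok, col_pi = _column_stats(aln)
    elif deletion != "pairwise":
        raise ParameterError(f"unknown deletion rule {deletion!r}")

    starts = list(range(0, L - window_length + 1, step))
    bounds = [(s, s + window_length) for s in starts]
    last_end = bounds[-1][1]
    if last_end < L:
        trunc_start = starts[-1] + step
        if L - trunc_start >= step:
            bounds.append((trunc_start, L))

    windows: List[Window] = []
    for s, e in bounds:
        if deletion == "complete":
            mask = ok[s:e]
            used = int(mask.sum())
            pi = float(col_pi[s:e][mask].mean()) if used else math.nan
        else:
            sub = aln.slice_columns(np.arange(s, e))
            pi = nucleotide_diversity(sub, deletion="pairwise")
            used = e - s
        windows.append(Window(s, e, pi, used))
    return DiversityTrack(tuple(windows), window_length, step)


def call_hvrs(
    track: DiversityTrack,
    pi_threshold: float,
    merge_gap: int,
    features: Optional[FeatureTable] = None,
) -> List[HvrCall]:
    """Threshold-and-merge HVR calling on a diversity track.

    Windows with ``pi >= pi_threshold`` are kept; kept windows whose gap is
    smaller than ``merge_gap`` are merged into one region spanning their
    union. Names come from overlapping gene features when a table is given
    (first and last overlapping gene, joined by "-"), else are positional.
    """
    if not track.windows:
        raise ParameterError("empty diversity track")
    kept = sorted(
        (w for w in track.windows if w.defined and w.pi >= pi_threshold),
        key=lambda w: w.start,
    )
    if not kept:
        return []
    groups: List[List[Window]] = [[kept[0]]]
    for w in kept[1:]:
        if w.start - groups[-1][-1].end < merge_gap:
            groups[-1].append(w)
        else:
            groups.append([w])
    calls: List[HvrCall] = []
    for i, grp in enumerate(groups):
        start, end = grp[0].start, max(w.end for w in grp)
        peak = max(w.pi for w in grp)
        name = f"HVR_{i + 1}"
        if features is not None:
            overlapping = [
                f for f in features.by_kind("gene") if f.start < end and f.end > start
            ]
            if overlapping:
                overlapping.sort(key=lambda f: f.start)
                first, last = overlapping[0].name, overlapping[-1].name
                name = first if first == last else f"{first}-{last}"
        calls.append(HvrCall(name, start, end, peak))
    return calls


def extract_region(aln: LabeledAlignment, feature: Feature) -> LabeledAlignment:
    """Column slice for one feature; minus strand is reverse-complemented and
    columns that are gaps in every record are removed."""
    return extract_intervals(aln, [feature], name=feature.name)


def extract_intervals(
    aln: LabeledAlignment,
    intervals: Sequence[Feature],
    name: Optional[str] = None,
) -> LabeledAlignment:
    """Concatenate interval slices (multi-exon genes) in annotation order."""
    if not intervals:
        raise ParameterError("no intervals to extract")
    L = aln.length
    for f in intervals:
        if f.end > L:
            raise CoordinateError(
                f"feature {f.name!r} interval [{f.start}, {f.end}) exceeds alignment length {L}"
            )
    cols = np.concatenate([np.arange(f.start, f.end) for f in intervals])
    sub = aln.slice_columns(cols, name=name or intervals[0].name)
    # drop columns that are gaps in every record
    M = sub.matrix()
    keep = ~(M == _GAP_CODE).all(axis=0)
    sub = sub.slice_columns(np.flatnonzero(keep), name=sub.name)
    strand = intervals[0].strand
    if strand == "-":
        from dataclasses import replace

        recs = [replace(r, sequence=reverse_complement(r.sequence)) for r in sub.records]
        sub = LabeledAlignment(recs, name=sub.name)
    return sub


def extract_named(aln: LabeledAlignment, table: FeatureTable, name: str, kind: str = "gene") -> LabeledAlignment:
    return extract_intervals(aln, table.intervals_for(name, kind), name=name)


def derive_igs(features: FeatureTable) -> FeatureTable:
    """Intergenic spacers between consecutive genes, named "prevGene-nextGene".

    Multi-interval genes contribute their full span; zero-length or negative
    spans (overlapping genes) are skipped.
    """
    genes = features.by_kind("gene")
    if len({f.name for f in genes}) < 2:
        raise ParameterError("need at least 2 genes to derive intergenic spacers")
    spans = {}
    for f in genes:
        s, e = spans.get(f.name, (f.start, f.end))
        spans[f.name] = (min(s, f.start), max(e, f.end))
    ordered = sorted(spans.items(), key=lambda kv: (kv[1][0], kv[1][1]))
    igs: List[Feature] = []
    for (na, (_, ea)), (nb, (sb, _)) in zip(ordered, ordered[1:]):
        if sb > ea:
            igs.append(Feature(f"{na}-{nb}", "IGS", ea, sb, "+"))
    return FeatureTable(igs)


def write_track(track: DiversityTrack, path) -> None:
    with open(path, "w") as fh:
        fh.write("#start\tend\tpi\tn_sites_used\n")
        for w in track.windows:
            pi = "NA" if not w.defined else f"{w.pi:.6f}"
            fh.write(f"{w.start}\t{w.end}\t{pi}\t{w.n_sites_used}\n")


def write_hvr_calls(calls: Sequence[HvrCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("#name\tstart\tend\tpeak_pi\n")
        for c in calls:
            fh.write(f"{c.name}\t{c.start}\t{c.end}\t{c.peak_pi:.6f}\n")
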