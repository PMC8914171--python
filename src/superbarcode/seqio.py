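"""Alignment, species-table, feature-table, and tree I/O.

Defines the labeled-alignment data model every other module consumes, and
reads/writes the plain-text formats the pipeline touches: aligned FASTA,
GenBank flat files (features only), tab-delimited interval tables, and Newick.

Conventions
-----------
* Internal coordinates are 0-based, half-open. GenBank 1-based inclusive
  coordinates are converted at the I/O boundary only.
* Residues are upper-cased on input and ``U`` is normalized to ``T``. IUPAC
  ambiguity codes and ``N`` are retained in storage; downstream distance code
  treats anything outside ``{A, C, G, T}`` as missing.
* Species labels come from a header rule (``species|accession`` or
  ``Species_accession``) or from a separate two-column table.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from Bio import SeqIO

from .errors import (
    AlignmentShapeError,
    CoordinateError,
    FormatError,
    IdentityError,
    ParameterError,
)
from .phylo import PhyloTree, TreeNode

IUPAC_CHARS = frozenset("ACGTNRYSWKMBDHV-")
CANONICAL = "ACGT"
GAP = "-"

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV-", "TGCANYRSWMKVHDB-")


@dataclass(frozen=True)
class AlignmentRecord:
    accession_id: str
    species_label: str
    sequence: str
    header: Optional[str] = None  # raw FASTA header, kept for round-tripping


class LabeledAlignment:
    """Equal-length sequence matrix with accession ids and species labels."""

    def __init__(self, records: Sequence[AlignmentRecord], name: str = "alignment"):
        records = tuple(records)
        if not records:
            raise ParameterError("alignment must contain at least one record")
        length = len(records[0].sequence)
        for rec in records:
            if len(rec.sequence) != length:
                raise AlignmentShapeError(
                    f"record {rec.accession_id!r} has length {len(rec.sequence)}, "
                    f"expected {length}"
                )
            if not rec.species_label:
                raise FormatError(f"record {rec.accession_id!r} has no species label")
            bad = set(rec.sequence) - IUPAC_CHARS
            if bad:
                pos = next(i for i, c in enumerate(rec.sequence) if c in bad)
                raise FormatError(
                    f"record {rec.accession_id!r}: unknown residue "
                    f"{rec.sequence[pos]!r} at position {pos}"
                )
        ids = [rec.accession_id for rec in records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise IdentityError(f"duplicate accession ids: {dupes}")
        self.records = records
        self.name = name
        self._matrix: Optional[np.ndarray] = None

    # -- shape -------------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def length(self) -> int:
        return len(self.records[0].sequence)

    @property
    def ids(self) -> List[str]:
        return [rec.accession_id for rec in self.records]

    @property
    def species_labels(self) -> List[str]:
        return [rec.species_label for rec in self.records]

    def record(self, accession_id: str) -> AlignmentRecord:
        for rec in self.records:
            if rec.accession_id == accession_id:
                return rec
        raise IdentityError(f"unknown accession {accession_id!r}")

    def matrix(self) -> np.ndarray:
        """(n, length) uint8 matrix of residue byte codes (cached)."""
        if self._matrix is None:
            self._matrix = np.frombuffer(
                "".join(rec.sequence for rec in self.records).encode("ascii"),
                dtype=np.uint8,
            ).reshape(self.n, self.length)
        return self._matrix

    # -- derived alignments ------------------------------------------------

    def subset(self, accession_ids: Sequence[str], name: Optional[str] = None) -> "LabeledAlignment":
        wanted = list(accession_ids)
        by_id = {rec.accession_id: rec for rec in self.records}
        missing = [a for a in wanted if a not in by_id]
        if missing:
            raise IdentityError(f"unknown accessions: {missing}")
        return LabeledAlignment([by_id[a] for a in wanted], name or self.name)

    def slice_columns(self, columns: np.ndarray, name: Optional[str] = None) -> "LabeledAlignment":
        sub = self.matrix()[:, columns]
        recs = [
            replace(rec, sequence=sub[i].tobytes().decode("ascii"))
            for i, rec in enumerate(self.records)
        ]
        return LabeledAlignment(recs, name or self.name)


@dataclass(frozen=True)
class SpeciesMap:
    """accession -> species mapping, with outgroup accessions set aside."""

    mapping: Mapping[str, str]
    outgroup_ids: FrozenSet[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "mapping", dict(self.mapping))
        object.__setattr__(self, "outgroup_ids", frozenset(self.outgroup_ids))
        unknown = self.outgroup_ids - set(self.mapping)
        if unknown:
            raise IdentityError(f"outgroup ids not in mapping: {sorted(unknown)}")

    @classmethod
    def from_alignment(cls, aln: LabeledAlignment, outgroup_ids: Iterable[str] = ()) -> "SpeciesMap":
        return cls({r.accession_id: r.species_label for r in aln.records}, frozenset(outgroup_ids))

    def species_of(self, accession_id: str) -> str:
        try:
            return self.mapping[accession_id]
        except KeyError:
            raise IdentityError(f"unknown accession {accession_id!r}") from None

    @property
    def ingroup_ids(self) -> List[str]:
        return [a for a in self.mapping if a not in self.outgroup_ids]

    def ingroup_species(self) -> Dict[str, List[str]]:
        """species -> sorted accession list, outgroups excluded."""
        out: Dict[str, List[str]] = {}
        for acc, sp in self.mapping.items():
            if acc in self.outgroup_ids:
                continue
            out.setdefault(sp, []).append(acc)
        return {sp: sorted(accs) for sp, accs in sorted(out.items())}


@dataclass(frozen=True)
class Feature:
    """A named half-open interval on the alignment or reference."""

    name: str
    kind: str  # gene | IGS | HVR
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not self.name:
            raise FormatError("feature without a name")
        if not (0 <= self.start < self.end):
            raise CoordinateError(
                f"feature {self.name!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"feature {self.name!r}: bad strand {self.strand!r}")

    @property
    def span(self) -> int:
        return self.end - self.start


class FeatureTable:
    """Ordered list of features; multi-exon genes appear as repeated names."""

    def __init__(self, features: Sequence[Feature]):
        feats = tuple(features)
        seen: Set[Tuple[str, str, int, int]] = set()
        for f in feats:
            key = (f.kind, f.name, f.start, f.end)
            if key in seen:
                raise IdentityError(f"duplicate feature {f.kind}/{f.name} [{f.start},{f.end})")
            seen.add(key)
        self.features = feats

    def __iter__(self):
        return iter(self.features)

    def __len__(self):
        return len(self.features)

    def by_kind(self, kind: str) -> List[Feature]:
        return [f for f in self.features if f.kind == kind]

    def names(self, kind: Optional[str] = None) -> List[str]:
        feats = self.features if kind is None else self.by_kind(kind)
        out: List[str] = []
        for f in feats:
            if f.name not in out:
                out.append(f.name)
        return out

    def intervals_for(self, name: str, kind: str = "gene") -> List[Feature]:
        """All intervals of one (possibly multi-exon) feature, in annotation order."""
        feats = [f for f in self.features if f.kind == kind and f.name == name]
        if not feats:
            raise IdentityError(f"no {kind} feature named {name!r}")
        return feats


# ---------------------------------------------------------------------------
# coordinate conversion


def genbank_to_internal(start_1based: int, end_inclusive: int) -> Tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start_1based - 1, end_inclusive


def internal_to_genbank(start: int, end: int) -> Tuple[int, int]:
    """0-based half-open -> 1-based inclusive (involution partner)."""
    return start + 1, end


# ---------------------------------------------------------------------------
# alignment I/O


def _parse_header(header: str, label_rule: str) -> Tuple[str, str]:
    rule = label_rule
    if rule == "auto":
        rule = "pipe" if "|" in header else "underscore"
    if rule == "pipe":
        if "|" not in header:
            raise FormatError(f"header {header!r} has no '|' separator")
        species, accession = header.rsplit("|", 1)
    elif rule == "underscore":
        if "_" not in header:
            raise FormatError(f"header {header!r} has no '_' separator")
        species, accession = header.rsplit("_", 1)
    else:
        raise ParameterError(f"unknown label rule {label_rule!r}")
    if not species or not accession:
        raise FormatError(f"header {header!r}: empty species or accession")
    return accession, species


def read_species_table(path) -> Dict[str, str]:
    """Two/three-column TSV: accession, species[, 'outgroup' flag]."""
    mapping: Dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 2:
            raise FormatError(f"{path}:{lineno}: expected at least 2 columns")
        mapping[parts[0]] = parts[1]
    return mapping


def read_outgroup_column(path) -> FrozenSet[str]:
    """Accessions whose third column is 'outgroup' in a species table."""
    out: Set[str] = set()
    for line in Path(path).read_text().splitlines():
        parts = line.strip().split("\t") if "\t" in line else line.strip().split()
        if len(parts) >= 3 and parts[2].lower() == "outgroup":
            out.add(parts[0])
    return frozenset(out)


def read_alignment(
    path,
    label_rule: str = "auto",
    species_table: Optional[Mapping[str, str]] = None,
    name: Optional[str] = None,
) -> LabeledAlignment:
    """Read an aligned FASTA file into a :class:`LabeledAlignment`.

    When ``species_table`` is given, the full header (first whitespace-free
    token) is the accession id and the table supplies the species; otherwise
    ``label_rule`` splits each header into (species, accession).
    """
    records: List[AlignmentRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.id
        seq = str(rec.seq).upper().replace("U", "T")
        if species_table is not None:
            accession = header
            if accession not in species_table:
                raise IdentityError(f"accession {accession!r} missing from species table")
            species = species_table[accession]
        else:
            accession, species = _parse_header(header, label_rule)
        records.append(AlignmentRecord(accession, species, seq, header=header))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return LabeledAlignment(records, name=name or Path(str(path)).stem)


def write_alignment(aln: LabeledAlignment, path, wrap: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in aln.records:
            header = rec.header or f"{rec.species_label}_{rec.accession_id}"
            fh.write(f">{header}\n")
            seq = rec.sequence
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")


def write_species_table(species: SpeciesMap, path) -> None:
    with open(path, "w") as fh:
        for acc in sorted(species.mapping):
            flag = "\toutgroup" if acc in species.outgroup_ids else ""
            fh.write(f"{acc}\t{species.mapping[acc]}{flag}\n")


# ---------------------------------------------------------------------------
# feature I/O


_GENBANK_FEATURE_KINDS = {"gene": "gene"}


def read_features(path) -> FeatureTable:
    """Read features from a GenBank flat file or a tab-delimited interval table.

    The interval table is 0-based half-open with columns
    ``name kind start end strand``; GenBank coordinates are converted from
    1-based inclusive, and ``join(...)`` spans become separate intervals
    sharing the gene name.
    """
    text = Path(path).read_text()
    first = next((ln for ln in text.splitlines() if ln.strip()), "")
    if first.startswith("LOCUS"):
        return _read_features_genbank(path)
    return _read_features_tsv(path, text)


def _read_features_tsv(path, text: str) -> FeatureTable:
    feats: List[Feature] = []
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 4:
            raise FormatError(f"{path}:{lineno}: expected 'name kind start end [strand]'")
        name, kind, start, end = parts[0], parts[1], int(parts[2]), int(parts[3])
        strand = parts[4] if len(parts) > 4 else "+"
        if end <= start:
            raise CoordinateError(f"{path}:{lineno}: end {end} <= start {start}")
        feats.append(Feature(name, kind, start, end, strand))
    return FeatureTable(feats)


def _read_features_genbank(path) -> FeatureTable:
    feats: List[Feature] = []
    for gbrec in SeqIO.parse(str(path), "genbank"):
        for feat in gbrec.features:
            kind = _GENBANK_FEATURE_KINDS.get(feat.type)
            if kind is None:
                continue
            quals = feat.qualifiers
            name = (quals.get("gene") or quals.get("locus_tag") or [None])[0]
            if name is None:
                raise FormatError(f"{path}: {feat.type} feature without gene/locus_tag name")
            strand = "-" if feat.location.strand == -1 else "+"
            for part in feat.location.parts:
                start, end = int(part.start), int(part.end)  # already 0-based half-open
                if end <= start:
                    raise CoordinateError(f"{path}: {name}: end {end} <= start {start}")
                feats.append(Feature(name, kind, start, end, strand))
    return FeatureTable(feats)


def write_features(table: FeatureTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("#name\tkind\tstart\tend\tstrand\n")
        for f in table:
            fh.write(f"{f.name}\t{f.kind}\t{f.start}\t{f.end}\t{f.strand}\n")


# ---------------------------------------------------------------------------
# tree I/O


def write_newick(tree: PhyloTree, path, precision: int = 6) -> None:
    if tree.n_leaves() < 2:
        raise ParameterError("tree must have at least 2 leaves")
    with open(path, "w") as fh:
        fh.write(tree.newick(precision=precision) + "\n")


def read_newick(path) -> PhyloTree:
    """Parse a Newick file (via dendropy) into a :class:`PhyloTree`."""
    import dendropy

    dtree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    return _from_dendropy(dtree)


def _from_dendropy(dtree) -> PhyloTree:
    def convert(dnode) -> TreeNode:
        name = dnode.taxon.label if dnode.taxon is not None else None
        node = TreeNode(name, dnode.edge.length or 0.0)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    return PhyloTree(convert(dtree.seed_node))


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
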