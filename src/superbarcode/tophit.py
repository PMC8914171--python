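"""BLAST-style top-hit species discrimination on aligned datasets.

For same-locus, pre-aligned datasets a seeded local-alignment search is
unnecessary: the top hit is defined here by maximal aligned similarity,
score = 1 - p-distance, with the same comparable-site rule as the distance
module. For full-length homologous barcodes this coincides in practice with
the BLAST top hit; the E-value cutoff of a real BLAST search is replaced by
the requirement that the pair share at least one comparable site. This is a
deliberate, documented methodological substitution.

Each ingroup accession is queried in turn against all *other* ingroup
accessions (leave-one-out; a query never hits itself). Ties are retained as a
set, and a species succeeds only when every individual's entire tie set is
conspecific — a strict reading of "top hit of only the conspecific
individuals". Singleton species can never have a conspecific hit and are
excluded from the success denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .distmat import DistanceMatrix, distance_matrix, p_distance
from .errors import ParameterError
from .seqio import LabeledAlignment, SpeciesMap


def similarity_score(seq_a: str, seq_b: str) -> float:
    """1 - p-distance over comparable sites; NaN when none are comparable."""
    d, n = p_distance(seq_a, seq_b)
    return math.nan if n == 0 else 1.0 - d


@dataclass(frozen=True)
class QueryHit:
    accession_id: str
    species: str
    best_hit_ids: Tuple[str, ...]  # every accession attaining the maximal score
    best_score: float
    conspecific: Optional[bool]  # None when the query had no defined score


@dataclass(frozen=True)
class TopHitResult:
    queries: Tuple[QueryHit, ...]
    species_success: Dict[str, Optional[bool]]

    @property
    def n_scored(self) -> int:
        return sum(1 for v in self.species_success.values() if v is not None)

    @property
    def n_success(self) -> int:
        return sum(1 for v in self.species_success.values() if v)

    @property
    def rate(self) -> float:
        return self.n_success / self.n_scored if self.n_scored else math.nan

    def per_species(self) -> Dict[str, Optional[bool]]:
        return dict(self.species_success)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#query\tspecies\tbest_hits\tbest_score\tconspecific\n")
            for q in self.queries:
                score = "NA" if math.isnan(q.best_score) else f"{q.best_score:.6f}"
                fh.write(
                    f"{q.accession_id}\t{q.species}\t{','.join(q.best_hit_ids)}\t"
                    f"{score}\t{q.conspecific}\n"
                )


def tophit_method(
    aln: LabeledAlignment,
    species: SpeciesMap,
    dist: Optional[DistanceMatrix] = None,
) -> TopHitResult:
    """Leave-one-out nearest-neighbour classification of every ingroup
    accession; outgroups are excluded from both queries and database."""
    ingroup = [a for a in aln.ids if a not in species.outgroup_ids]
    if len(ingroup) < 2:
        raise ParameterError("top-hit method requires at least 2 ingroup accessions")
    if dist is None:
        dist = distance_matrix(aln.subset(ingroup))
    sub = dist.subset(ingroup)
    sims = 1.0 - sub.values
    np.fill_diagonal(sims, -np.inf)
    sims = np.where(np.isnan(sims), -np.inf, sims)

    queries: List[QueryHit] = []
    per_individual: Dict[str, List[Optional[bool]]] = {}
    for i, acc in enumerate(ingroup):
        sp = species.species_of(acc)
        best = sims[i].max()
        if best == -np.inf:
            queries.append(QueryHit(acc, sp, (), math.nan, None))
            per_individual.setdefault(sp, []).append(None)
            continue
        hit_idx = np.flatnonzero(sims[i] == best)
        hits = tuple(sorted(ingroup[j] for j in hit_idx))
        conspecific = all(species.species_of(h) == sp for h in hits)
        queries.append(QueryHit(acc, sp, hits, float(best), conspecific))
        per_individual.setdefault(sp, []).append(conspecific)

    success: Dict[str, Optional[bool]] = {}
    for sp, accs in species.ingroup_species().items():
        flags = per_individual.get(sp)
        if flags is None:
            continue  # species not present in this alignment
        if len(accs) < 2 or any(f is None for f in flags):
            success[sp] = None
        else:
            success[sp] = all(flags)
    return TopHitResult(tuple(queries), success)
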