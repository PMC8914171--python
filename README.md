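# superbarcode

Evaluation pipeline for chloroplast-genome **super-barcodes**: given a
labeled, aligned multi-accession plastome matrix, it measures sequence
variability along the genome, extracts candidate barcode regions, and scores
how well each region discriminates species under the three classical DNA
barcoding criteria. A built-in community simulator with full ground truth
makes every stage testable without downloading a single GenBank record.

It is written for molecular ecologists and pharmacognosists screening
plastid markers in taxonomically difficult plant genera (the motivating case
is *Fritillaria*, whose medicinal species defeat the universal barcodes
*rbcL*, *matK*, *trnH*-*psbA*, and ITS), but nothing in it is
genus-specific.

## What it computes

**Variability.** Nucleotide diversity per site,

&nbsp;&nbsp;&nbsp;&nbsp;π = Σ_{i<j} d_ij / C(n, 2),

where d_ij is the proportion of differing sites between sequences *i* and
*j* (complete deletion of gapped/ambiguous columns, the DnaSP convention),
scanned in sliding windows (default 600 bp windows, 200 bp step). Windows
above a diversity threshold are merged into high-variable regions (HVRs).
Per-dataset summaries report aligned length, variable and
parsimony-informative sites, indel events (distinct maximal gap runs), GC
content, and intra/interspecific p-distance ranges and means.

**Discrimination.** Three criteria per region, each scored per species over
the ingroup (singletons flagged and excluded from the denominator):

* **blast** — leave-one-out top hit by aligned similarity (1 − p-distance);
  a species succeeds when every individual's entire best-hit tie set is
  conspecific.
* **distance** — barcoding gap: the species' minimum uncorrected
  interspecific p-distance must be strictly larger than its maximum
  intraspecific distance (MEGA-style pairwise deletion).
* **tree** — neighbor joining (Saitou–Nei with the Studier–Keppler Q
  criterion, deterministic lexicographic tie-breaking) from the same
  p-distance matrix, rooted on the outgroup; a species succeeds when its
  individuals form a monophyletic group.

**Simulation.** Jukes–Cantor evolution down a Yule species tree with
star-shaped within-species subtrees, shared indel events, an outgroup, and
optionally one species planted as paraphyletic — with the generating
genealogy serialized next to the alignment.

## Worked example

Simulate a realistic 21-species / 73-accession genome-scale community in
which one six-accession species is split across two clades, then score it:

```python
from superbarcode import (
    preset, simulate_community, evaluate_region, build_report, variability_stats,
)

aln, truth = simulate_community(preset("paraphyletic", seed=1))
species = truth.species_map()

ingroup = aln.subset(sorted(species.ingroup_ids))
print(variability_stats(ingroup, species).summary())

result = evaluate_region(aln, species, name="genome", kind="genome")
report = build_report([result])
print(report.summary_text())
failed = [sp for sp, ok in result.outcomes["tree"].per_species.items() if ok is False]
print("non-monophyletic species:", failed, "| planted split:", truth.split_species)
```

prints

```
aligned length 157507 bp; 6494 variable sites; 4300 parsimony-informative sites; 6072 indel events; GC 37.0%; Pi 0.00405; intra 0.02%-0.53% (mean 0.08%); inter 0.09%-0.53% (mean 0.42%)
kind      method    n  mean_rate  sd_rate
genome    blast      1     0.952    0.000
genome    distance   1     0.952    0.000
genome    tree       1     0.952    0.000
non-monophyletic species: ['sp01'] | planted split: sp01
```

All three criteria discriminate 20 of the 21 species (rate 0.952); the one
failure is exactly the planted paraphyletic species, whose individuals sit
in two clades of the NJ tree — the signature of a species whose boundary the
plastome cannot track.

The same operations are available from the shell:

```sh
barcode-eval simulate --preset clean --seed 42 --outdir sim/
barcode-eval scan --in sim/community.fasta --species-table sim/species.tsv --out track.tsv
barcode-eval discriminate --in sim/community.fasta --species-table sim/species.tsv --outdir report/
```

Real aligned matrices work identically: supply the alignment FASTA (headers
`Species_accession` or `species|accession`, or a separate two-column species
table with an optional `outgroup` flag column), and a GenBank flat file or
interval TSV for gene/IGS extraction (`barcode-eval extract`,
`barcode-eval run --config run.yaml`).

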