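# Methods

This note documents the statistical definitions, conventions, and design
choices behind `superbarcode`, and what the simulation-based tests do and do
not demonstrate about real data.

## Data model

The substrate of every computation is a `LabeledAlignment`: an equal-length
residue matrix in which each row carries an accession id and a species
label. Residues are upper-cased on input, `U` is normalized to `T`, and
IUPAC ambiguity codes and `N` are retained in storage; every statistic
downstream treats anything outside `{A, C, G, T}` as missing. A
`SpeciesMap` separates outgroup accessions (used only for tree rooting)
from the ingroup over which discrimination is scored. Intervals
(`FeatureTable`) are 0-based half-open internally; GenBank 1-based
inclusive coordinates are converted at the I/O boundary, and `join(...)`
spans of multi-exon genes are kept as separate intervals sharing the gene
name, extracted as the concatenation of their exons in annotation order.
Because multi-exon genes repeat a name, feature-name uniqueness is enforced
on `(kind, name, start, end)` rather than bare names.

## Distances and diversity: two deletion rules on purpose

* **p-distance** (pairwise deletion): for each sequence pair, sites where
  either sequence has a gap or ambiguity are excluded; the distance is
  differing/compared sites. A pair with no comparable sites is *undefined*
  (NaN plus a zero count), never silently zero. This mirrors MEGA's default,
  the tool classically used for barcoding distance tables.
* **Nucleotide diversity π** (complete deletion): every column containing a
  gap or ambiguity in *any* sequence is dropped first, then
  π = Σ_{i<j} d_ij / C(n,2) over the kept columns. This mirrors DnaSP,
  the tool classically used for sliding-window diversity. Internally π is
  computed from per-column base counts
  (π_col = 1 − Σ_b C(c_b,2)/C(n,2)), which is algebraically identical to
  pair enumeration and O(n·L); the test suite verifies the identity against
  an exact-fraction pair-enumeration oracle.

The two rules coexist deliberately: distance-based criteria use pairwise
deletion, diversity profiles use complete deletion within each window.
Whether the original tools were run with non-default deletion settings is
not knowable from their outputs; the defaults are assumed and documented
here. Pairwise-deletion π (mean of defined pairwise distances) is available
behind a flag.

## Sliding windows and HVR calling

Windows of `window_length` (default 600 bp) start at multiples of `step`
(default 200 bp). If the last full window does not already end at the
alignment end, one truncated terminal window is emitted provided it is at
least `step` long — discarding the tail could lose a terminal hypervariable
region. Windows whose π is undefined are reported with a flag, not dropped.

HVR delineation in practice is done by eye on the diversity profile; here it
is parameterized as *threshold + merge*: windows with π at or above a
threshold are kept, and kept windows separated by less than `merge_gap`
bases are merged into one region. The threshold may be given directly or as
a percentile of the window-π distribution (the pipeline default is the 94th
percentile, which reproduces a ~10-region call set on a genome-scale
profile with ~790 windows). Called regions are named from the first and
last overlapping annotated genes when an annotation is supplied
(`matK-trnG` style), else positionally.

Region extraction slices the column interval, drops columns that are gaps in
every record (so region lengths better match per-region re-alignment), and
reverse-complements minus-strand features. Intergenic spacers are derived
between consecutive gene spans (multi-exon genes use their full span), named
`prevGene-nextGene`; overlapping or abutting genes yield no spacer.
Alignment itself is out of scope: the pipeline's contract starts at an
externally aligned matrix.

## Discrimination criteria

All three criteria score *species*, over ingroup species with at least two
individuals. Singletons are flagged and excluded from the denominator — a
maximum intraspecific distance does not exist for them, and a leave-one-out
query can never find a conspecific hit. Outgroups never enter any
criterion; they exist only to root the tree.

* **Top hit ("blast")**: each ingroup accession is queried against all other
  ingroup accessions; the hit set is the argmax of aligned similarity
  (1 − p-distance), with ties retained. A species succeeds iff every
  individual's entire tie set is conspecific (ties against a heterospecific
  accession count as failure). For same-locus, pre-aligned datasets the
  aligned-similarity top hit and a BLAST top hit coincide in practice, so no
  seeded local alignment is performed; the comparable-sites requirement
  replaces the E-value cutoff. This substitution is the one deliberate
  methodological departure from common practice and is flagged prominently.
* **Barcoding gap ("distance")**: success iff min interspecific >
  max intraspecific, with strict inequality — equality at the boundary is a
  failure.
* **Monophyly ("tree")**: NJ (Saitou–Nei agglomeration, Studier–Keppler
  Q criterion) on the same p-distance matrix used by the distance criterion
  (one matrix instance per region, so the two can never diverge through
  recomputation). Ties in Q are broken by the lexicographically smallest
  pair of cluster ids (a cluster is identified by its smallest member
  accession), making output deterministic and input-order invariant.
  Negative limb lengths are clamped to zero with the deficit moved to the
  sister limb; this affects only reported lengths, never topology, and thus
  never the criterion. The tree is rooted on the edge separating the
  outgroup clade, splitting that edge's length equally; if a multi-accession
  outgroup fails to form a clade, rooting falls back to the single
  lexicographically-first outgroup leaf (always a valid rooting point). A
  species succeeds iff some node's complete descendant leaf set equals its
  accession set. Bootstrap support never gates success.

Reports aggregate per-kind (genome / gene / IGS / HVR) mean and sample
standard deviation (ddof = 1; 0 for a single region) of rates per method,
and rank regions by rate with ties broken by shorter aligned length —
shorter loci are more practical barcodes.

## The community simulator

The simulator is the stand-in for field sampling, sequencing, and assembly;
it generates the study conditions the evaluation is tested under.

* **Species tree**: Yule (pure-birth), made ultrametric, rescaled so the
  mean species-pair path length equals `interspecific_scale −
  intraspecific_scale`; individual pendants then add the intraspecific
  scale back to every between-species pair, so realized individual-level
  inter means land on the requested scale (minus a ≲1% Jukes–Cantor
  saturation bias at these depths). `min_species_stem` floors terminal
  species branches, bounding the closest species pair away from the
  intraspecific cloud.
* **Individuals**: star subtrees, each pendant `intraspecific_scale / 2`
  (expected within-species pairwise distance = the intraspecific scale). No
  within-species coalescent structure is modelled; the discrimination
  criteria are functions of distances, not genealogies.
* **Substitution**: Jukes–Cantor only — per branch of length *t*, each site
  changes with probability 3/4·(1 − e^(−4t/3)) to a uniformly chosen other
  base. No rate heterogeneity or GTR: JC is sufficient to realize the
  distance structure the tests need and keeps the generator an exact,
  auditable oracle. The root composition is drawn at 37% GC to match the
  AT-richness of plastomes.
* **Indels**: a Poisson number of events (`indel_rate` per column),
  geometric lengths, each applied as a gap run shared by all descendants of
  a uniformly chosen tree branch. Gaps overwrite columns rather than
  inserting new ones, so ground-truth homology is exact and no aligner
  enters the test loop.
* **Paraphyly planting**: half of the chosen species' individuals are
  re-grafted onto the midpoint of the longest other species' stem, with
  pendants long enough (`half-stem + 2 × intraspecific_scale`) that each
  moved individual is nearer to the host species than to its own
  conspecifics. The split species then fails both the tree and the top-hit
  criteria, while the host's tight crown keeps the host monophyletic — the
  planted failure is unique.
* **Outgroup**: a single accession at `outgroup_divergence` above the
  ingroup root; the tree criterion needs only a rooting point.

Presets define the standard conditions: `clean` (21 species, 73
individuals, 20 kb, inter/intra = 0.006/0.0003 with floored stems — a
guaranteed barcoding gap), `fritillaria_like` (21 species / 73 individuals
at genome scale: 157,507 columns, intra ≈ 0.03%, inter ≈ 0.41%, indel rate
0.04/column — matching the variability profile of a real congeneric
plastome panel), and `paraphyletic` (the same with species `sp01`, six
accessions, split). The per-species accession counts (6, 2, 4, … summing to
73) follow the sampling design of a real 21-species survey. The 20-kb
length of `clean` keeps the repeated-seed recovery tests fast; at the
clean preset's separation the criteria are already deterministic in
practice, so nothing is learned from longer sequences.

**What passing simulations do not show.** The generator produces
star-shaped species, homogeneous rates, and alignment-free homology. Real
plastome panels have within-species structure, mutation hotspots,
alignment error around indel-rich spacers, and incomplete lineage sorting —
so full recovery on `clean` communities demonstrates the correctness of
the criteria, not that any real genus will be fully discriminated.

## Numerical and degenerate-input conventions

* Undefined statistics (no comparable sites, no usable columns) are NaN
  plus an explicit flag/count, and propagate as "undefined", never as 0;
  NJ refuses matrices with undefined cells, naming the offending pair.
* A constant region is a valid input: the distance criterion records
  failure for every species (0 is not strictly greater than 0) rather than
  raising.
* Report TSVs fix float formatting (6 decimals) and row ordering, and the
  Newick writer fixes 6-decimal branch lengths, so identical configs and
  seeds reproduce outputs byte for byte.
* All randomness flows through a single `numpy` generator seeded from the
  user-supplied seed; RNG consumption order is fixed by construction order,
  never by hash iteration.

## Known limitations

* The top-hit criterion is an aligned-similarity surrogate for a true BLAST
  search; on partially overlapping or mis-aligned loci the two could
  disagree.
* IR-duplicated genes are reported as annotated; de-duplication of the
  inverted repeat's gene copies is left to the caller.
* No model-corrected distances (JC/K2P) and no ML/MP/Bayesian trees: the
  evaluated criteria are defined on uncorrected p-distances and NJ
  topology only.
* Multi-interval minus-strand genes are concatenated in annotation order
  and then reverse-complemented as a unit; annotations listing exons in
  transcription order on the minus strand should be pre-sorted by
  coordinate.
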