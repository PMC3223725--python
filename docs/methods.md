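# Methods

This note records the models, parameter choices and numerical conventions
behind `genecontext`, and what the synthetic benchmarks do and do not
demonstrate about real data.

## The evidence model

The pipeline's premise is that prokaryotic chromosomal context predicts
function. Functionally related prokaryotic genes are frequently co-localized
— in operons, as divergently transcribed pairs, or as near-neighbours — and
on average roughly 35% of bacterial metabolic genes sit in such clusters.
Context evidence is homology-independent, so it can annotate families for
which sequence similarity to characterized proteins says nothing.

**Functional coupling (FC).** For an unordered pair of protein families, FC
is the number of *dereplicated genome groups* containing at least one genome
in which members of both families occur in the same vicinity. Counting
groups rather than genomes prevents dozens of sequenced strains of one
species from inflating the signal: all near-identical strains in which a
pair co-localizes are counted as one. Dereplication collapses genomes whose
pairwise identity is strictly above `derep_identity` (default 0.95) by
single linkage; genomes at 95% identity or less remain distinct. Note the
deliberate asymmetry with phyletic spread (below): two divergent strains of
one named species can legitimately contribute two groups to FC, because the
grouping criterion is sequence identity, not taxonomy.

**Vicinity.** The literature motivates both operonic and strand-blind
notions of "near each other", and no single quantitative definition is
canonical. Three modes are implemented:

* `same_strand_run` — maximal runs of ≥ 2 consecutive same-strand genes
  whose intergenic gaps are all strictly under `cluster_gap_bp`
  (default 300 bp, the classic operon-run heuristic);
* `window` — any two genes within `neighbor_window_genes` positions
  (default ±5), regardless of strand, capturing divergently transcribed
  pairs and loose neighbourhoods;
* `either` — the union of the two relations. This is the pipeline default,
  on the view that informative co-localization encompasses both arrangements.

**Evidence codes.** `cwn` ("in cluster with non-hypothetical") fires when a
family has FC ≥ `fc_min_for_code` (default 5, inclusive — FC = 5 qualifies,
FC = 4 does not) to at least one partner of established function; `cwh` is
the analogue for hypothetical partners. Families whose only annotations are
vague ("ATPase", "putative protein") count as hypothetical partners.
**Cluster length** is the maximum run length (in genes) over all runs
containing a family member, 1 for a family never found in a run, 0 for a
family absent from the panel; the maximum (rather than a mode or per-genome
report) was chosen as the most informative single summary. Length is
measured over operon-like runs; positional windows are neighbourhoods, not
clusters, and bound the length only when no run detection was performed.
**CBSS** (clustering-based subsystems) are connected components of the
coupling graph restricted to edges with FC ≥ `fc_min_for_code` between
hypothetical families; components of ≥ 2 families get deterministic ids.

**Phyletic spread** counts distinct prokaryotic *species* (not genomes, not
groups) harboring a family, matching the usual "how widely distributed"
question; strain duplication cannot change it.

## The selection sieve

Eukaryote families are single-linkage connected components of the
within-proteome hit graph at `evalue < evalue_max`. Component clustering
stands in for heavier Markov-style family builders: the analysis uses family
structure only as a size filter (families of ≥ 4 members are dropped because
large families mix functions), and components reproduce that semantics with
one parameter. The known cost is that a single spurious inter-family edge
merges two true families; this is tested and documented rather than patched.
The within-proteome E-value threshold reuses `evalue_max` (configurable), as
no separate value is established for family building.

The homolog screen applies **strict** inequality — "better than 10⁻¹⁰"
admits 10⁻¹², rejects 10⁻⁸, and rejects exactly 10⁻¹⁰. No identity or
coverage floor is applied at the screen by default. The status rules run in
a fixed, documented order (subsystem class; uncharacterized-only
subsystems; PUF list; vague-pattern match; specific vs empty function
string); the precedence is an explicit design choice, configurable in the
sense that each input is optional, and the vague-pattern list ships as an
editable text file. The candidate set is: families with at least one member
passing the screen and no member classified known, where vague counts as
unknown.

Ranking replaces expert manual sorting with an explicit linear score
(weights `cwn:3, cwh:1, fc:2, length:1, spread:2, model:1`; FC and length
saturate at 10; spread is normalized by panel species count) so that runs
are reproducible and the weighting is inspectable. A lexicographic
alternative (cwn, FC, cwh, spread, model organism, length) is provided for
users who prefer ordinal reasoning. Annotation projection applies a
similarity guard — best within-family hit with identity ≥ 30% and query
coverage ≥ 0.7 (members with no within-family hit, or unknown coverage on
the qualifying hit's subject side, are handled conservatively: no hit means
"uncertain"; unknown coverage passes and only the identity floor applies).

## The synthetic pangenome

The generator plants the structure the analysis assumes, with defaults that
define the package's standing benchmark conditions:

* **Panel**: 30 species, 1–3 strains each. Strains share gene content and
  order up to a few adjacent-token swaps and coordinate jitter. Emulated
  whole-genome identity is drawn 0.955–0.995 within species and 0.55–0.85
  between species — a stated proxy, since no nucleotide sequence is stored;
  dereplication by identity therefore reproduces the strain-group labels by
  construction.
* **Genomes**: one linear contig, genes fixed at 900 bp, intergenic gaps
  50–500 bp (10–250 bp inside clusters) so gap-based run detection has
  signal to find. About 400 genes per genome drawn from 500 families
  (per-family presence probability ≈ 0.8 with jitter); this density keeps
  chance co-localization from recurring in the same family pair often
  enough to cross the FC ≥ 5 code threshold (the measured decoy
  evidence-code rate is ≈ 0.05–0.07).
* **Planted clusters**: five two-family clusters, each retained per species
  with probability 0.7; retained clusters are contiguous, same-strand,
  tight-gapped in every strain. Planted families are always hypothetical —
  they model the conserved unknown operons the method exists to find.
  A fraction (0.35) of annotated "metabolic" families is additionally
  grouped into *per-species* background operons; because the grouping is
  redrawn independently per species it contributes realistic run structure
  but no conserved coupling.
* **Eukaryote proteome**: 60 shared families — the 10 planted ones, 40
  hypothetical decoys, 10 annotated — with sizes drawn from
  {1: 0.55, 2: 0.25, 3: 0.12, 4+: 0.08} (singleton-heavy, matching the
  shape of real proteome family-size tables; the 4+ draw exists to
  exercise the size filter), plus eukaryote-only genes including two
  larger decoy families. Shared families map only to prokaryotic families
  actually present in the panel.
* **Hits** are generated from true family co-membership (star within each
  prokaryotic family, all pairs within eukaryote families, eukaryote gene ×
  every prokaryotic member of its family), with E-values log-uniform in
  [1e-50, 1e-12] for true pairs; optional false positives draw from
  [1e-9, 1] and false negatives drop true edges. Family membership, not
  sequence, is the primary truth, so no aligner runs inside the benchmark;
  protein sequences are optional decorations (per-family random core with
  10% point mutations) used for file round-trips and the aligner fixtures.

What passing benchmarks show: the sieves, coupling engine, dereplication and
ranking implement their definitions exactly and recover planted signal under
noise-free and mildly noisy homology. What they do not show: robustness to
real-world annotation errors, horizontal transfer, paralog interference,
genome rearrangement hotspots, or biased taxon sampling — the generator's
species are exchangeable and carry no phylogeny.

## Numerical conventions

* Coordinates are GFF3-style 1-based inclusive everywhere; the intergenic
  gap between coordinate-sorted neighbours is `start₂ − end₁ − 1`; gap and
  identity thresholds are strict (`<`, `>`), the evidence-code threshold is
  inclusive (`≥`).
* Funnel percentages are rounded half-away-from-zero to one decimal
  (`Decimal` arithmetic, not binary floats).
* Best hits break ties by smaller E-value, then higher bit score, then
  lexicographic subject id; ranks break score ties lexicographically by
  family id, so all orderings are total and permutation-invariant.
* Family ids are deterministic (`FAM_` + smallest member gene id; `CBSS_` +
  smallest family id); all output tables are sorted, making repeated runs
  byte-identical.
* The built-in aligner is Smith–Waterman under BLOSUM62 with
  BLAST-convention affine gaps (open 11, extend 1, i.e. a length-g gap
  costs 11 + g), fixed gapped Karlin–Altschul parameters (λ = 0.267,
  K = 0.041) and a per-pair search space E = m·n·2^(−bits). It deliberately
  omits composition statistics, masking and database-scale corrections; the
  production path is precomputed BLAST tabular input.
* Genes spanning the origin of a circular contig are rejected with a
  warning rather than modeled (end < start is disallowed); only CDS
  features are read — RNA genes and pseudogenes are outside the model, as
  the clustering evidence concerns protein families.

## Benchmark sizes and runtime

The shipped test suite and acceptance script run on one CPU in a few
minutes: the coupling-engine cross-check uses 50 random panels of ≤ 10
genomes × ≤ 40 genes against an exhaustive pairwise enumerator; invariance
checks use 10 six-species fixtures; parameter recovery runs the full
pipeline on 20 seeded 30-species panels (~24,000 prokaryotic genes each).
These sizes were chosen as the smallest at which each property is
statistically meaningful; all scale linearly if enlarged.

## Known limitations

* Single-linkage families merge on any spurious edge; there is no MCL-style
  clustering and no domain-level (partial-gene) family splitting or fusion
  detection.
* FC treats all genome groups equally; there is no tree-aware correction,
  so clade-specific sampling biases inflate or deflate coupling.
* The status rules depend entirely on supplied subsystem tables, function
  strings and PUF lists; no literature mining or GO reasoning is attempted
  (an optional metadata column lets users inject literature-derived
  "known" flags).
* Manual steps of the original workflow — linking candidates to metabolic
  areas and formulating testable hypotheses — are supported by the CBSS
  groupings, co-occurrence profiles and evidence tables but intentionally
  not automated.
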