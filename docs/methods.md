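# Methods

## Scope and data model

The package compares two annotated single-cell UMI atlases — "human" and
"mouse" by convention, but nothing depends on the names — in the space of
their one-to-one orthologous genes. Matrices are `AnnData` objects
(cells × genes, sparse integer counts) carrying per-cell metadata
(species, sex XX/XY, stage, cell type) and a `layer` tag that
distinguishes raw counts from log-normalized values; every operation
checks the tag it requires. On disk, one species' atlas is an
uncompressed MatrixMarket triplet (genes × cells) plus `features.tsv`,
`barcodes.tsv` and a `cells.tsv` metadata table, and the ortholog table
is a TSV of (gene_a, gene_b, homology_class) records in which each gene
may appear in at most one one-to-one pair.

## Quality control and normalization

Genes are kept when detected (count > 0) in at least 3 cells of the
input; cells are then kept when they express at least 50 of the retained
genes. The filter is a single gene-then-cell pass; this is not a fixed
point in general (removing cells can push a gene back under the
threshold), so the QC report states whether the output is stable and a
`fixpoint=True` option iterates to stability. Normalization scales each
cell to a fixed total (default 10,000 — a fixed constant is comparable
across runs, unlike a data-dependent median) and applies ln(1 + x).
Normalization runs *after* the merge, so library size is computed over
the shared ortholog space for both species identically. An optional
per-gene OLS residualization on total UMI (`regress_out_depth`) mirrors
a depth-regression step but is off by default: all downstream statistics
here are rank- or detection-based and gain nothing from it.

The cluster-uniqueness rule used for lineage annotation reads
"expression" as the detection fraction: a gene is unique to a cluster
when detected in > 50% of its cells, in ≤ 10% of every other cluster's
cells, and its BH-adjusted Wilcoxon p (cluster vs rest) is ≤ 0.05. The
resulting per-cluster sets are disjoint by construction.

## Ortholog merge and UMI accounting

The merged gene axis keeps the one-to-one pairs whose two members are
each detected (≥ 1 UMI in ≥ 1 cell) in their species' post-QC matrix —
the weakest reading of "expressed in both datasets" consistent with the
QC gene filter. Canonical gene IDs are the pair string `gene_a|gene_b`,
which is unambiguous and order-stable. UMI accounting is computed per
species on the full post-QC matrix (before the ortholog restriction):
exact integer totals, the integer sum on one-to-one genes, and the
percentage kept at one decimal. The two sums are conserved exactly:
one-to-one UMIs plus other UMIs equal the total.

## Cross-species correlation

A pseudo-profile is the arithmetic mean of log-normalized expression
over all cells of a (species, cell type) — mean of logs, not log of mean
counts, as the plainest reading of comparing "expression levels between
cell populations". Spearman's ρ is computed by average-ranking each
profile over all merged orthologs (no highly-variable-gene subset) and
Pearson-correlating the ranks; a zero-variance profile yields NaN, never
a coerced 0. The combined type set is ordered by average-linkage
agglomeration on d = 1 − ρ. Average linkage is a stated choice — it is
the common default for correlation-distance heatmaps — and rows enter
the linkage in lexicographic (species, type) order so tie-breaking is
deterministic.

## Differential expression and the directional Venn

Each supporting type (Sertoli, pre-granulosa, supporting-like) is
compared to the pre-supporting progenitor within one species. Genes are
tested when detected in ≥ 10% of either group (max-of-groups, the
classic toolkit default). The test is the two-sided Mann-Whitney U on
log-normalized values, using the normal approximation with tie
correction and a 0.5 continuity correction; when both groups have at
most 8 cells the p-value comes instead from exact enumeration of the
group-assignment permutation distribution on midranks (which handles
ties), so that small worked examples are exact. The fold change is
ln((mean(expm1 x_in) + 1)/(mean(expm1 x_out) + 1)) and BH adjustment
runs across all tested genes of one comparison. Thresholds: logFC > 0.25
and adjusted p < 0.05, with "up" meaning higher in the supporting type.

The cross-species Venn is directional: a DEG is shared only when the
gene and its one-to-one ortholog pass in the *same* direction; genes
without a one-to-one partner, and genes discordant in direction, count
as species-exclusive in each direction's partition. Summary arithmetic
(per-direction totals, overall total, shared count, percent shared at
one decimal) is validated at construction and re-checked when the run
report is written.

## Elastic-net identity signatures

Training sets are balanced by sampling up to 1000 cells per cell type
without replacement (reproducible from the seed). Features are the genes
expressed in more than 3 training cells, standardized to zero mean and
unit variance on the training subset. The response is the 0/1 indicator
of the target type and the model is a *linear* elastic net — the fit is
used as a continuous identity score, so penalized least squares is the
plainest choice; a logistic variant was deliberately not added because
no downstream consumer needs calibrated probabilities. The objective is
‖y − Xw − b‖²/(2n) + λ(α‖w‖₁ + (1−α)‖w‖₂²/2) with α = 0.5 by default,
solved by cyclic coordinate descent (scikit-learn). λ defaults to a
5-fold cross-validated grid with the one-standard-error rule: the
largest (sparsest) λ whose CV error is within one SE of the minimum.
The 1-SE rule is the standard conservative grid choice and matters here
because signatures are *positive-weight gene sets*: the CV-minimum λ
drags in many near-zero noise weights that would dilute the signature.
The CV grid spans two decades below the critical λ that zeroes all
weights; the discarded lower range only produces the dense models the
1-SE rule never selects. Both α and λ are overridable per run.

Scoring any cell — of either species — is intercept + standardized
expression · weights, with model genes matched to merged-atlas columns
through the ortholog map. A gene absent from the scored atlas
contributes its standardized training mean (0); the count of missing
genes is reported and more than 50% missing is an error. Signature
overlap between species counts one-to-one pairs present in both
positive-weight lists; exclusives are the remainder, so shared +
exclusive reproduces each species' signature size exactly.

## Over-representation analysis

Functional enrichment is a self-contained upper-tail hypergeometric test
against user-supplied GMT collections (no bundled term databases): for a
query of n genes in a universe of N containing K set members, p =
Σ_{i≥k} C(K,i)·C(N−K,n−i)/C(N,n), BH-adjusted across the tested sets.
The recommended universe is the genes tested in the corresponding DE
comparison. The statistic is identical to the one-sided Fisher exact
test on the 2×2 table, which the tests verify.

## Synthetic dual atlas

The generator plants everything the pipeline is supposed to find.
Homologous cell types share identical baseline expression programs in
ortholog space: per-ortholog-pair baseline log-weights ~ N(0, 1) are
drawn once and used by both species, so conservation is the null and
divergence exists only where planted. Each type receives conserved
markers (chosen among ortholog pairs, hence mapped across species) and
per-species specific markers; a marker adds δ to the type's log-weight
for that gene before renormalizing to a probability vector. Markers are
drawn from genes above the 25th percentile of baseline weight — a
marker is, by definition, a gene its cell type detectably expresses —
and marker sets are disjoint across types within a species and
ortholog-disjoint across species for the specific class. Counts are
negative binomial with mean L_c·p(type, gene) and variance m + m²/φ
(gamma-Poisson, one dispersion knob φ), with per-cell library size L_c
log-normal, rescaled analytically to a configured mean depth. One global
seed drives a spawned per-purpose seed sequence (baselines, marker
assignment, library sizes, counts per species), so runs are bit-for-bit
reproducible and components are independently stable.

Defaults describe the desk-scale study conditions: 6 cell types
(pre-supporting, Sertoli, pre-granulosa, supporting-like, germ,
endothelial) × 300 cells per type per species, 2,000 ortholog pairs with
20% of each species' genes unpaired, 15 conserved + 10 specific markers
per type, δ = 1.2, φ = 2, library sizes log-normal(0, 0.35) at mean
depth 5,000. These choices keep a full replicate under ten seconds while
preserving the statistical regime of droplet data (overdispersed counts,
~60% zeros, realistic detection fractions). DE ground truth follows from
the markers: relative to the progenitor, a supporting type's markers are
up and the progenitor's markers are down, with the conserved subsets
being the planted shared Venn content. Sex and stage are round-robin
metadata without expression effect — the comparison operates on cell-type
labels, so planting sex/stage effects would test nothing the pipeline
reads.

What the generator does *not* emulate: doublets, ambient RNA, batch
effects, continuous differentiation trajectories, or correlated gene
programs beyond the planted markers. Passing recovery tests therefore
shows the statistics behave correctly under the assumed count model, not
that real atlases satisfy that model.

## Numerical and degenerate-input conventions

Empty QC results name the threshold that caused them; zero-total cells
are rejected before normalization; zero-variance profiles propagate as
missing correlations and block clustering explicitly; single-class
training sets and > 50% missing model genes are errors. Percentages
reported at one decimal are `round(100·x, 1)`. The elastic net runs at
tolerance 1e-7 (fixed fits) and 1e-5 within CV; Wilcoxon p-values are
clipped to [0, 1] and a zero-variance gene gets p = 1.

## Validation studies and problem sizes

`orthatlas.validation` runs the recovery studies used by the acceptance
checks: 20 replicate simulations at the default conditions measure
correlation-argmax homology recovery, conserved-DEG recall into the
shared Venn cell, signature precision/recall against planted markers,
and cross-species score-transfer ranking; 20 matched null replicates
(δ = 0) measure the false-shared rate and the BH rejection rate. The
replicate count and per-replicate size (3,600 cells, 2,000 orthologs)
were chosen so the full study completes in a few minutes on one CPU
while leaving the binomial noise on pooled rates well below the margins
being asserted.

## Known limitations

- One-to-many and many-to-many orthology is carried in the map but never
  resolved; such genes only ever count as "other" in UMI accounting and
  as exclusives in Venn partitions.
- Cross-species batch/species-effect correction is out of scope; the
  merge assumes annotation is trustworthy and comparable.
- The Wilcoxon normal approximation is inaccurate below ~10 cells per
  group; the exact path covers toys (≤ 8 vs ≤ 8) but intermediate sizes
  rely on the approximation.
- Percent-shared denominators follow the printed partition totals; no
  attempt is made to reconcile alternative denominators.
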