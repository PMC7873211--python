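# Methods

This note documents the models, numerical choices, and limitations of
the `syndromics` pipeline. Nothing here reports an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Mapper topology over subjects

The subject graph is canonical Mapper: standardize → lens → cover →
within-bin clustering → nerve graph.

* **Standardization.** Each outcome column is centered and scaled to
  unit sample (n−1) SD over its non-missing entries; constant columns
  are dropped with a warning; missing cells are mean-imputed (0 after
  standardization) rather than listwise-deleted, so every subject can
  appear in the topology. Pooled trials with unequal outcome batteries
  make imputation the lesser evil; the imputed cells bias node means
  toward the cohort mean, which overlays inherit.
* **Lens.** Default is the projection onto the first two eigenvectors
  of the covariance of the standardized matrix; any named column pair
  can be substituted. Eigenvectors are oriented so their
  largest-magnitude entry is positive, making node ids and overlays
  reproducible.
* **Cover.** Per lens axis the observed range is split into
  `resolution` equal base intervals of width w, each dilated
  symmetrically to w·(1+gain); d-dimensional bins are Cartesian
  products. Every lens point is covered for any gain ∈ [0,1); with
  gain = 0 the bins partition the range (boundary points may sit in two
  closed bins).
* **Within-bin clustering.** Single linkage on Euclidean (or
  correlation) distance, cut at the lower edge of the first empty bin
  of the pairwise-distance histogram (`cluster_histogram_bins` bins,
  default 10) — the standard first-gap heuristic. Bins with ≤ 2
  members form a single cluster: a lone pairwise distance carries no
  gap evidence, and histogramming it always fabricates an empty first
  bin that would split close pairs into isolated singletons.
* **Consensus.** Subjects are resampled with replacement `n_bootstrap`
  times; co-occurrence(i,j) is the fraction of replicates drawing both
  i and j in which they shared a node (pairs never jointly drawn are
  reported missing, not 0). The consensus graph keeps a full-data edge
  when the mean co-occurrence over its cross-node member pairs reaches
  `consensus_threshold`; consensus edges are therefore always a subset
  of full-data edges.

Parameters that matter: `resolution` (bins per axis; ~n/10 points per
bin is a sane target — 6 for cohorts of a few dozen, 10 for ~160),
`gain` (0.3–0.5; higher values connect more aggressively), and
`consensus_threshold` (0.5 by default: an edge must be supported in
half the replicates). The defaults are exposed, not claimed optimal;
the commercial TDA tool the field often uses does not disclose its
internals, so no parameter setting here reproduces any published
figure.

## Syndromic PCA and retention

Components come from `numpy.linalg.eigh` on the Pearson correlation
matrix, pairwise-complete by default (complete-case fallback with a
warning if the pairwise matrix is not positive semidefinite). Loadings
are eigenvector × √eigenvalue, i.e. variable–component correlations;
`variance_explained = λ/p`; negative round-off eigenvalues are clipped
at 0.

Retention is the conjunction of three rules, each audited per
component:

1. **Kaiser**: eigenvalue > 1.0.
2. **Scree elbow**: the elbow is the component index (2..p−1)
   maximizing the second difference (acceleration) of the
   log-eigenvalue sequence, and the scree admits components strictly
   before it. The log scale makes the elbow respond to proportional
   flattening of the decline rather than to the (always large) drop
   after the first component — with a raw-scale second difference the
   elbow would almost always sit at index 2 and retain one component
   regardless of spectrum shape. Eigenvalues are clipped at 1e−12
   before the log.
3. **Over-determination**: ≥ 3 loadings with |loading| > 0.4. With
   fewer than 3 variables this rule is undefined and retention raises.

Scores are standardized-outcome rows (mean-imputed as above) projected
on eigenvectors and rescaled by 1/√λ to unit variance; subjects with
every outcome missing get NaN and are flagged. Naming of retained
components from their salient loadings is left to the analyst via the
audit table — semantics are not automated.

Dose–response testing builds orthogonal polynomial contrasts by QR
(Gram–Schmidt) orthogonalization of powers of centered dose codes
(actual dose values when supplied, equally spaced codes otherwise),
unit-normalized; group labels that parse as numbers are ordered
numerically. Contrast t statistics use the pooled ANOVA MSE with
Σc²/nₖ variance (standard GLM practice under unequal n; coefficients
are not reweighted). The inverted-U flag requires a negative quadratic
estimate with p < 0.05.

## Co-expression procedure

* **bicor.** u = (x − median)/(9·MAD) with unscaled MAD; weights
  (1−u²)² for |u| < 1, else 0; correlation of weighted median-centered
  deviations. Zero MAD falls back to Pearson with a warning. The
  matrix version normalizes each gene's weighted deviation vector once
  and takes one matrix product; it is exactly the pairwise definition.
* **Sample screening.** Connectivity K_i = mean inter-sample Pearson
  correlation; samples with standardized Z.K < −2 are removed
  iteratively (worst first); removing more than half the cohort aborts.
* **Detection.** Complete linkage on 1 − bicor, cut at the
  `cut_quantile` (default 0.10) quantile of off-diagonal distances —
  i.e. only gene pairs among the strongest 10% of pairwise signed
  correlations can share a cluster. Clusters of ≥ `min_module_size`
  (12) genes become modules, ordered by size; everything else is
  unassigned. The mapping from "top correlations" to a cut height is
  an interpretation (the cut is a static height, signed correlations);
  both the quantile and a future absolute-correlation variant are
  parameters, not hard-coded.
* **Eigengenes and merging.** Gene rows are z-scored; the eigengene is
  the first right-singular vector scaled to unit variance and oriented
  to correlate positively with its members on average (sign-stable
  merging). Merging is strictly iterative: find the pair with the
  highest eigengene Pearson correlation, merge if above
  `merge_threshold` (0.85), recompute that eigengene and all pairwise
  correlations, repeat. After convergence no eigengene pair correlates
  above the threshold, which the tests assert directly.
* **kME** is every gene's Pearson correlation with every final
  eigengene, assigned or not; constant genes are flagged undefined.
* **Module–trait.** One-way ANOVA of the eigengene across
  reference/vehicle/treated with Tukey–Kramer post-hocs; the reversion
  flag requires a significant omnibus, a significant vehicle–reference
  Tukey contrast, and a treated mean strictly between vehicle and
  reference means.

Batch correction is not re-implemented; the matrix is accepted as
already corrected (an optional per-batch median-centering flag exists
for convenience).

## Differential expression, reversal, enrichment

Counts are normalized to log2(CPM + 1). Per-gene tests are Welch
two-sample t on log-expression with BH adjustment across all genes;
"significant" means adjusted p < 0.05. A transparent t test rather
than a count-model DE tool keeps the downstream reversal logic exactly
checkable against closed-form oracles; the comparison functions accept
any table with the same columns, so a different DE back-end can be
plugged in. Reversal classes for injury-altered genes: **full** when
the treated−vehicle shift opposes the vehicle−reference shift and
treated-vs-reference is not significant; **partial** when the direction
opposes but the difference remains significant; **none** otherwise.
"Opposes" is a sign condition, so an overshoot past the reference still
counts as partial. Enrichment is the one-sided hypergeometric upper
tail per gene set (sets intersected with the count-matrix universe,
empty sets dropped), BH-adjusted across sets.

## Synthetic-data generators

`simulate_trial` emulates a pooled 159-subject, 5-arm preclinical SCI
cohort. Injury severity (tissue-deformation-like, uniform over
600–1800 µm) drives a latent lesion factor; a latent recovery factor is
negatively coupled to severity (loading −0.6) with residual variance
restoring unit scale. Behavioral outcomes load 0.8 on recovery,
histological outcomes 0.8 on lesion, with residual noise SD 0.6, so a
single syndromic axis genuinely spans both domains. The treated arm
(4 active dose levels plus within-arm vehicle; subjects allocated
round-robin over all arm × dose cells, ~17–18 per cell) adds a
dose-indexed shift to the recovery factor, default (0, 1.0, 1.6, 1.0,
0) — an inverted-U peaking at intermediate dose, sized as a
moderate-to-large latent effect. Per-arm sample sizes and dose levels
are not public for the motivating study; these defaults are design
choices, not reproductions. Missingness is completely at random
(default 2%); behavioral scales are continuous (ordinal discretization
such as 0–5 grooming scores is deliberately omitted to keep closed-form
oracles exact).

`simulate_expression` emulates a 3-group × 5-sample RNA-seq study over
a 350-gene panel. Module member genes share a per-module latent factor
built from per-group means plus within-group variation (uniform draws,
then z-scored), with gene noise orthogonalized against the factor and
scaled so the realized mean intra-module correlation sits at
`within_module_cor` rather than below it. Group-structured,
light-tailed factors mirror injury/treatment-responsive eigengenes and
avoid lone extreme samples that the biweight midcorrelation would
downweight — with a heavy-tailed factor the realized bicor of module
pairs falls well short of the Pearson target. Injury genes (default
100, alternating up/down by 2 log2 units in both lesioned groups) and
reversal genes (default 80 of them, moved back toward reference in the
treated group by `reversal_fraction`, default full) live in the
background block. Eleven high-expression, low-variance housekeeping
genes dominate the library mass so that per-sample totals are stable
and CPM normalization does not induce compositional correlation across
the small panel; their count (11) is deliberately below the minimum
module size so they can never form a module. Counts are Poisson draws
from the log-normal intensities with per-sample library sizes
(log-normal around 2×10⁶).

What the generators do **not** emulate: longitudinal behavior curves,
ordinal score granularity, batch structure, count overdispersion beyond
log-normal–Poisson, gene-length effects, and correlated missingness.
Passing tests therefore demonstrate correctness of the algorithms under
a faithful but idealized data model, not performance on real cohorts.

## Known limitations

* With 15 samples, pairwise correlations inside a module of 50 genes
  have irreducible sampling spread (~0.1 SD at a 0.7 target): a
  rank-15 Gram matrix cannot hold 50 unit vectors near equicorrelation
  0.7 with smaller spread than the frame bound. The complete-linkage
  diameter of such a module therefore exceeds the static top-10% cut
  height, the dendrogram cut fragments each module, and only fragments
  of ≥ 12 genes survive; eigengene merging then re-unifies the
  fragments into the correct number of pure modules, but genes stranded
  in sub-12 fragments stay unassigned. On the 3 × 50-gene default
  instance the pipeline recovers exactly 3 modules with high purity
  while the all-genes adjusted Rand index is capped well below perfect
  recovery. Larger sample counts, tighter modules, or a dynamic cut
  (out of scope) lift the cap.
* The scree elbow is a numeric proxy for a visual judgment; spectra
  with several comparable drops have ambiguous elbows, and the
  log-scale acceleration is one defensible choice among several.
* Mean imputation before PCA/Mapper shrinks scores of
  incomplete subjects toward zero; at the default 2% missingness the
  effect is negligible, at high missingness it is not.
* Welch t with n = 5 per group has limited power for small shifts; the
  planted 2-log2-unit effects are detected nearly perfectly, smaller
  ones will not be.
* Repeated-measures behavior curves are reduced to per-subject
  summaries before the one-way ANOVA; mixed-effects machinery is out
  of scope.
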