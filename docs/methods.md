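# Methods

This note records the statistical models implemented in `immunaging`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions that matter for
reproducing results.

## Cohort model and preprocessing

Expression is handled as log₂(TPM+1), genes × samples, with per-sample
age (integer years ≥ 1), sex (two-level factor, reference level taken
alphabetically) and batch.  `lognorm_tpm` applies the transform;
`filter_genes` keeps genes with strictly positive expression in at least
⌈`min_fraction`·n⌉ samples (default 0.75).  "Expressed" is defined as
> 0 on the TPM scale — the simplest reproducible rule.  The pipeline
default is filter → correct; the order is configurable
(`filter_before_correct`) since either convention is found in practice.

`combat_adjust` implements the parametric empirical-Bayes location/scale
adjustment: per gene, OLS on [batch indicators | covariates] (age and
sex by default, so age- and sex-associated signal is retained through
standardization), standardization by the pooled residual SD, per-batch
gene-wise means γ̂ and variances δ̂², normal/inverse-gamma priors fit by
moment matching across genes, and the iterative conditional update of
(γ*, δ*²) to convergence (absolute tolerance 1e-6, max 100 iterations).
Genes whose pooled residual variance is ≤ 1e-10 are passed through
unadjusted — this also makes a noiseless batch-free cohort an exact
fixed point.  A batch factor perfectly confounded with a covariate
column makes the model unidentifiable and is rejected up front.

A property worth stating because it is often assumed away: EB shrinkage
pulls each gene's batch mean toward the cross-gene prior, so when an
injected batch offset is *identical* for every gene the estimated
per-gene batch means retain roughly half of their sampling noise
(n·τ² ≈ δ² in the standardized scale).  Exact per-batch centring is the
behaviour of plain standardization, not of this algorithm; our tests
assert the EB behaviour (residual batch-mean differences within the
batch-mean standard error, and agreement with an independent
implementation) rather than exact centring.

## Linear age model

Per gene: y = α + β₁·age + β₂·sex + ε by OLS, all genes solved in one
QR-based pass against the shared design.  Type II sums of squares —
SS(age | sex) and SS(sex | age) — give F statistics on (1, n−3) degrees
of freedom.  Benjamini–Hochberg step-up adjustment across genes yields
q-values.  Conventions: all threshold comparisons are strict (q < 0.05
for DEGs, |β₁| > 0.005 for enrichment eligibility); constant genes
report β = 0, p = 1 rather than aborting the run; noiseless non-constant
fits (residual variance below machine tolerance with nonzero effect SS)
report p = 0.  Both the q-only DEG count and the additionally
β-filtered count are exposed, since the two are used for different
downstream purposes (counting vs. enrichment input).

## LOESS trajectories and shape clustering

LOESS is locally weighted polynomial regression of degree 2 with the
tricube kernel over the q = ⌈span·n⌉ nearest neighbours (span 0.75), no
robustness iterations — the default semantics of the classic
implementation.  Because the smoother is linear in y, a single hat
matrix (grid × samples) is built per cohort and applied to every gene,
which makes atlas construction O(genes · grid · span·n).  The age grid
is integer years over the observed range, matching cohorts whose ages
are recorded in whole years.  When a grid point coincides with ≥ q tied
x values the kernel degenerates; the fit then averages the exact-match
points.

Curves are z-scored across the grid (shape, not level).  Genes with
numerically zero curve variance have no defined z-score and are parked
in a reserved "flat" cluster (label 0) before clustering.  Clustering is
agglomerative with Euclidean distance and complete linkage (the
classical default; configurable), cut at a user-chosen k enforced to
6–12 — choosing k within that range is a user decision, and per-k
silhouette scores are recorded (`silhouette_by_k`) to inform it without
claiming a selection rule.  Labels are renumbered by first appearance in
gene order so repeated runs give identical labellings.

## Sliding-window scan (DE-SWAN)

Centres run over 10–90 in 1-year steps (configurable); each centre's
window is ±10 years, binarized low = [k−10, k), high = [k, k+10] — the
boundary age k goes to "high" by the half-open convention.  Per centre,
the same Type II machinery as the linear model is applied with the
window indicator in place of age; BH adjustment is within centre, across
genes, matching the per-centre count presentation.  Centres with fewer
than 3 samples on either side, or a single-sex window, are flagged
underpowered and excluded from counting.  DEG counts are recorded at
nested cutoffs (0.05, 0.01, 0.001 by default) and are necessarily
pointwise ordered.

Crest detection runs on the count curve after a width-3 moving-average
smoother (width 1 = raw): a run of equal values is a crest when it
exceeds both neighbouring runs, endpoint runs qualify against their
single neighbour, and plateaus report their midpoint.  No crest
criterion exists in the source methodology, so the detector is
deterministic and parameterized, and a `min_height` filter is provided
for calibration: the 95th percentile of per-seed maximal counts from a
matched null simulation (`null_crest_threshold`) is the recommended
height cutoff.  Top crest genes use strict q < 0.01 and |β| > 0.5.

## Cell-level statistics

`score_gene_set` reproduces the binned-control convention: genes are
ranked by dataset-mean expression and cut into `n_bins` (default 25)
equal-rank bins; each signature gene draws `ctrl_size` (default 50)
controls without replacement from its bin, excluding signature genes;
the per-cell score is mean(signature) − mean(control union).  Sampling
is seeded for reproducibility, and a `control_pool` hook lets tests pin
the control set.  The default signature is the 20-gene SASP panel
(CCL2 … AREG).  Defaults for bins/controls follow the established
single-cell scoring convention and are exposed.

`rank_sum_de` uses the two-sided Wilcoxon rank-sum with midranks and
tie-corrected normal approximation, switching to exact enumeration when
both groups have ≤ 10 cells and the values are tie-free — small
fixtures deserve exact p-values.  log₂ fold change is
log₂((expm1(mean log A)+ε)/(expm1(mean log B)+ε)), ε = 1e-9, the
convention under which the 0.25 threshold is defined; DEGs require
q < 0.05 *and* log₂FC > 0.25, both strict.

Cell-type fractions are computed per sample (they sum to 1 by
construction); Pearson correlation with donor age is reported with
|PCC| > 0.2 and > 0.4 flags and a least-squares polynomial trend
(degree 2 by default, configurable).  Zero-variance fractions report
PCC 0 with a flag; types absent from more than half the samples carry a
sparsity flag.  The frailty rule is strict on both margins: frail ⇔
age > 65 and deficit index > 0.2.

## TCR clonality

Gini uses the pair-difference definition Σᵢⱼ|xᵢ−xⱼ| / (2n²x̄), computed
via the sorted O(n log n) identity (tested against the double loop).
Expansion is 1 − H/H_max over clone frequencies with base-2 entropy; a
monoclonal repertoire (H_max = 0) is defined as 1, the limiting value of
vanishing evenness.  The transition index of a subtype averages, over
clones present in it, the Shannon entropy (bits) of the clone's cell
distribution across subtypes, weighted by the clone's cell count in that
subtype.  The pairwise variant restricts to cells of the two subtypes
and weights by the clone's cells within the pair, which makes
transition(A,B) = transition(B,A) — the symmetric reading of "restricted
to the pair".  Indices are computed per sample and never pooled across
donors.  Entropy base 2 throughout, so transition values are in bits.

## Synthetic-data generator

The generator emulates the statistical structure the pipeline assumes,
with ground truth recorded for recovery testing:

* **Trajectory archetypes.** flat; linear (slope in log-units/year);
  saturating — a logistic approach to a plateau with scale = half_width,
  for the early-life-change shapes; transient — a logistic *level shift*
  compressed into change_age ± half_width (inner scale half_width/4).
  The transient shape deliberately models a wave: genes whose level
  shifts around age c are exactly what concentrates low-vs-high window
  significance at centre c.  A rise-and-return bump centred at c does
  the opposite — its window contrast vanishes at c and peaks at the bump
  edges c ± h (verified numerically: count-curve argmax ≈ 33 for a bump
  at 40 with h = 8) — so a bump is the wrong generative model for a
  crest at a known age, and is not used.
* **Cohort assembly.** Ages are integer years, uniform (or optionally
  evenly spaced) over the requested range; the sampling scheme is a
  parameter because real cohorts only approximate uniformity.  Sexes are
  exactly balanced and shuffled; batches are round-robin.  Values are
  archetype mean(age, sex) + batch offset + batch scale × Gaussian
  noise — precisely the location/scale model the EB batch correction
  assumes, so injected distortions are recoverable by construction.
* **Cells.** Log-expression is Gaussian around per-gene baselines with
  per-type marker shifts, clipped at 0; metadata carries type, sample,
  donor age and the age-group vocabulary (child 1–11, young 23–58, aged
  60–72, advanced-aged 77–100; gap ages attach to the nearest bin).
* **Clonotypes.** Clone sizes are singleton, geometric or Zipf
  (power-law); each clone has a primary subtype and its cells land in
  subtypes per a row-stochastic sharing matrix (identity = no sharing).
  Clones are abstract labels; no receptor sequences are simulated.

What the generator does **not** emulate: mean–variance coupling and
zero inflation of counts, library-size and composition effects,
correlated gene modules, non-Gaussian batch distortions, cell-type
specific expression co-structure, or clone-size dependence on subtype.
Passing recovery tests therefore demonstrates correctness of the
estimators under their own assumptions, not robustness to every
property of real data.

## Validation design and problem sizes

The validation suite and `scripts/acceptance.py` use cohorts of 180
samples over ages 1–99 with 2,000 genes (200 transient for crest
recovery), noise SD 0.5 in log₂ units, 20 Monte-Carlo replicates for
sampling-distribution checks, and 4 × 50 genes at noise 0.3 for
trajectory-cluster recovery — sizes chosen to match a realistic
bulk-cohort analysis while keeping a full validation run in the
seconds-to-minutes range.  Monte-Carlo assertions compare means to truth
within 2 Monte-Carlo standard errors; replicate seeds are derived from
independent `SeedSequence` streams per scenario so that scenarios do not
share noise draws.  Null-crest calibration uses the 95th percentile of
per-replicate maximal null counts as the crest-height threshold.

## Known limitations

* The EB batch adjustment does not exactly centre batches (see above);
  for gene-identical offsets the residual is ~half the batch-mean
  sampling noise.  This is inherent to the algorithm, shared by the
  reference implementations, and documented rather than patched.
* LOESS predictions are computed by direct per-grid-point weighted
  least squares; implementations that interpolate over a vertex tree may
  differ at the 1e-3 level in sparse age regions.
* The q-values are BH-adjusted p-values; a Storey-type estimator would
  be less conservative at dense signal and is not implemented.
* Crest detection on a step-1 grid with a width-3 smoother can merge
  crests closer than ~3 years; the smoother width is exposed.
* `rank_sum_de` treats cells as exchangeable replicates; donor-level
  pseudo-replication is not modelled.
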