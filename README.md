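# immunaging

Age dynamics of immune transcriptomes: linear, nonlinear and transient
age-associated expression change in peripheral blood mononuclear cell
(PBMC) cohorts, with the surrounding machinery — batch correction,
per-cell gene-set scoring, cell-type composition trends, frailty
classification and T-cell receptor (TCR) clonality — validated end to end
on synthetic cohorts with known ground truth.

## Who this is for

Groups analysing bulk or single-cell blood transcriptomes across a wide
age span (childhood to frail old age) who want the standard
aging-dynamics toolkit as tested, reusable library code rather than a
one-off script pile: which genes drift linearly with age, which follow
nonlinear trajectories, and at which ages "waves" of transient change
occur.

## The models

**Linear age model.** Per gene, OLS of log₂(TPM+1) expression on age with
a sex covariate,

&nbsp;&nbsp;&nbsp;&nbsp;*y<sub>g</sub>* = α + β₁·age + β₂·sex + ε,

tested with Type II sums of squares (F test of each term adjusted for the
other) and Benjamini–Hochberg adjustment across genes.  Age-DEGs are
genes with *q* < 0.05; an additional |β₁| > 0.005 filter marks genes
carried into enrichment analyses.

**LOESS trajectories.** Each gene is smoothed against age by locally
weighted quadratic regression (tricube kernel, span 0.75) on an integer
age grid; curves are z-scored so shape, not level, drives agglomerative
(complete-linkage) clustering into a user-chosen 6–12 groups.

**DE-SWAN (sliding-window differential expression).** For each age
centre *k* from 10 to 90, samples inside *k* ± 10 years are binarized
into below-*k* and at-or-above-*k* groups and each gene is fit with

&nbsp;&nbsp;&nbsp;&nbsp;*y<sub>g</sub>* = α + β₁·I<sub>k</sub> + β₂·sex + ε,

where I<sub>k</sub> is the window indicator.  Counting genes below a
*q* cutoff per centre yields a count-vs-age curve whose local maxima
("crests") are the ages of concentrated transcriptomic change.

**Cell-level statistics.** Binned-control gene-set scoring (default: a
20-gene SASP cytokine/chemokine panel; score = mean signature minus mean
expression-matched controls), Wilcoxon rank-sum DE with *q* < 0.05 and
log₂FC > 0.25, Pearson correlation of per-sample cell-type fractions
with donor age, and the Rockwood deficit-accumulation frailty rule
(frail ⇔ age > 65 and index > 0.2).

**TCR clonality.** Gini coefficient of clone sizes, entropy-based clonal
expansion 1 − H/H<sub>max</sub>, and a clone-sharing transition index
(Shannon entropy, in bits, of each clone's spread across T-cell subtypes).

**Batch correction** uses the parametric empirical-Bayes location/scale
model (standardize per gene retaining age/sex effects, shrink per-batch
means and variances across genes, back-transform), with before/after QC
on batch medians and sample–sample correlations.

## Worked example

```python
import immunaging as ia

# 500-gene cohort: 300 flat, 100 linear (slope 0.02/yr), 100 transient
# (level shift of 1.0 log-units around age 40), batch offset +1 on one batch
arch = (
    [ia.TrajectoryArchetype("flat", baseline=2.0)] * 300
    + [ia.TrajectoryArchetype("linear", baseline=2.0, slope=0.02)] * 100
    + [ia.TrajectoryArchetype("transient", baseline=2.0, change_age=40,
                              half_width=8, amplitude=1.0)] * 100
)
truth = ia.CohortTruth(noise_sd=0.5, batch_offsets={"batch1": 1.0}, seed=0)
cohort, truth = ia.generate_cohort(180, (1, 99), arch, truth)

cohort = ia.filter_genes(cohort)           # expressed in >= 75% of samples
corrected = ia.combat_adjust(cohort)
qc = ia.batch_qc(cohort, corrected)
print(f"between-batch median spread: {qc.spread_before:.3f} -> {qc.spread_after:.3f}")

table = ia.fit_gene_age_model(corrected)
labels = ia.classify_degs(table)
print(f"age-DEGs (q<0.05): {labels['deg'].sum()}")

prof = ia.deswan_scan(corrected, crest_min_height=25)
print(f"DE-SWAN crest ages: {prof.crests}")
```

prints

```
between-batch median spread: 0.990 -> 0.002
age-DEGs (q<0.05): 202
DE-SWAN crest ages: [41.]
```

The batch offset is removed (median spread 0.99 → 0.002), the 202
age-DEGs are essentially the 100 linear genes plus the 100 transient
genes (whose shift is monotone, so the linear model also flags them),
and the sliding-window scan places the crest at 41 — the injected
change age of 40 to within one centre.

A command-line front end mirrors the library
(`immunaging --seed 3 --outdir run run-all`, or per-stage subcommands
`simulate`, `preprocess`, `agelm`, `trajectory`, `deswan`, `scscore`,
`scde`, `proportions`, `repertoire`); every run writes TSV tables plus a
`manifest.json` with parameters, fanned-out seeds and file checksums.

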