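"""Cohort container, gene filtering, log-TPM normalisation and batch correction.

The batch adjustment is the parametric empirical-Bayes location/scale
model: per gene, standardize retaining covariate (age, sex) effects,
estimate per-batch means and variances of the standardized data, shrink
them across genes toward pooled priors with the iterative moment-matching
update, and back-transform.  Genes with (numerically) zero residual
variance are passed through unadjusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionCohort",
    "BatchQCReport",
    "filter_genes",
    "lognorm_tpm",
    "combat_adjust",
    "batch_qc",
]


@dataclass
class ExpressionCohort:
    """Genes x samples log2(TPM+1) matrix with per-sample metadata.

    ``values``: DataFrame indexed by gene id, columns = sample ids.
    ``meta``: DataFrame indexed by sample id with columns ``age`` (integer
    years, >= 1), ``sex`` (two-level factor), ``batch`` and optionally
    ``group``.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self):
        if list(self.values.columns) != list(self.meta.index):
            raise ValueError("metadata rows must match sample columns exactly")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression matrix must be finite")
        if self.values.index.has_duplicates:
            raise ValueError("gene ids must be unique")
        if "age" in self.meta and (self.meta["age"] < 1).any():
            raise ValueError("ages must be >= 1")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "ExpressionCohort":
        return ExpressionCohort(self.values.copy(), self.meta.copy())

    # --- TSV round trip ---------------------------------------------------
    def to_tsv(self, expr_path, meta_path) -> None:
        self.values.to_csv(expr_path, sep="\t", index_label="gene")
        self.meta.to_csv(meta_path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, expr_path, meta_path) -> "ExpressionCohort":
        values = pd.read_csv(expr_path, sep="\t", index_col="gene")
        meta = pd.read_csv(meta_path, sep="\t", index_col="sample")
        return cls(values, meta)


@dataclass
class BatchQCReport:
    """Batch-correction QC: per-batch medians and sample correlations.

    ``median_before`` / ``median_after``: Series of per-batch median
    expression.  ``corr_before`` / ``corr_after``: sample x sample Pearson
    correlation matrices.  ``spread_*``: max - min of the per-batch
    medians, the headline between-batch statistic.
    """

    median_before: pd.Series
    median_after: pd.Series
    corr_before: pd.DataFrame
    corr_after: pd.DataFrame
    spread_before: float = field(init=False)
    spread_after: float = field(init=False)

    def __post_init__(self):
        self.spread_before = float(self.median_before.max() - self.median_before.min())
        self.spread_after = float(self.median_after.max() - self.median_after.min())

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "median_before": self.median_before,
                "median_after": self.median_after,
            }
        )


def lognorm_tpm(raw_tpm) -> pd.DataFrame:
    """log2(TPM + 1), elementwise.  Rejects negative input."""
    arr = np.asarray(raw_tpm, dtype=float) if not isinstance(raw_tpm, pd.DataFrame) else raw_tpm
    if (np.asarray(arr) < 0).any():
        raise ValueError("TPM values must be nonnegative")
    out = np.log2(np.asarray(arr, dtype=float) + 1.0)
    if isinstance(raw_tpm, pd.DataFrame):
        return pd.DataFrame(out, index=raw_tpm.index, columns=raw_tpm.columns)
    return out


def filter_genes(cohort: ExpressionCohort, min_fraction: float = 0.75) -> ExpressionCohort:
    """Keep genes expressed (> 0) in at least ``min_fraction`` of samples.

    The threshold is ceil(min_fraction * n_samples); gene order is
    preserved.  An empty result is valid (a warning is emitted).
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    need = int(np.ceil(min_fraction * cohort.n_samples))
    n_expressed = (cohort.values > 0).sum(axis=1)
    keep = n_expressed >= need
    if not keep.any():
        warnings.warn("gene filter removed every gene", stacklevel=2)
    return ExpressionCohort(cohort.values.loc[keep], cohort.meta)


def _covariate_design(meta: pd.DataFrame, covariates) -> np.ndarray:
    cols = [np.ones(len(meta))]
    for c in covariates:
        v = meta[c]
        if v.dtype.kind in "if":
            cols.append(v.to_numpy(dtype=float))
        else:
            levels = sorted(v.unique())
            for lev in levels[1:]:  # reference level = first alphabetically
                cols.append((v == lev).to_numpy(dtype=float))
    return np.column_stack(cols)


def combat_adjust(
    cohort: ExpressionCohort,
    covariates=("age", "sex"),
    max_iter: int = 100,
    tol: float = 1e-6,
    eps_var: float = 1e-10,
) -> ExpressionCohort:
    """Parametric empirical-Bayes location/scale batch adjustment.

    Standardizes each gene retaining covariate effects, estimates
    per-batch gene-wise location (gamma) and scale (delta^2) on the
    standardized data, shrinks them toward pooled normal / inverse-gamma
    priors with the iterative update, removes the shrunken batch effects
    and back-transforms.  Covariate-associated signal (age, sex by
    default) is preserved.  A single-batch cohort is returned unchanged;
    genes with zero residual variance are passed through unadjusted.
    """
    batches = cohort.meta["batch"].astype(str)
    batch_levels = sorted(batches.unique())
    if len(batch_levels) < 2:
        return cohort.copy()
    counts = batches.value_counts()
    if (counts < 2).any():
        raise ValueError("each batch needs >= 2 samples")

    Y = cohort.values.to_numpy(dtype=float)
    n_genes, n = Y.shape
    B = np.column_stack([(batches == b).to_numpy(float) for b in batch_levels])
    C = _covariate_design(cohort.meta, covariates)[:, 1:]  # drop intercept; B spans it
    X = np.column_stack([B, C]) if C.size else B
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "batch is perfectly confounded with a covariate column; "
            "the location/scale model is not identifiable"
        )

    # per-gene OLS of expression on [batch indicators | covariates]
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # (p, n_genes)
    n_b = counts.reindex(batch_levels).to_numpy(dtype=float)
    grand = (n_b / n) @ beta[: len(batch_levels)]  # weighted grand mean per gene
    fitted_cov = C @ beta[len(batch_levels):] if C.size else 0.0  # (n, n_genes)
    stand_mean = grand[None, :] + fitted_cov  # (n, n_genes)

    resid = Y.T - X @ beta
    var_pooled = (resid**2).sum(axis=0) / n  # per gene
    ok = var_pooled > eps_var

    Z = np.full_like(Y.T, np.nan)
    Z[:, ok] = (Y.T - stand_mean)[:, ok] / np.sqrt(var_pooled[ok])[None, :]

    adjusted = Y.T.copy()
    Zc = Z[:, ok]
    if ok.any():
        bayes = np.zeros_like(Zc)
        for bi, b in enumerate(batch_levels):
            rows = (batches == b).to_numpy()
            nb = rows.sum()
            Zb = Zc[rows]
            gamma_hat = Zb.mean(axis=0)
            delta_hat = Zb.var(axis=0, ddof=1)
            # hyperpriors by moment matching across genes
            gamma_bar = gamma_hat.mean()
            tau2 = gamma_hat.var(ddof=1)
            v = delta_hat.mean()
            s2 = delta_hat.var(ddof=1)
            lam = (v**2 + 2 * s2) / s2 if s2 > 0 else 2.0  # inverse-gamma shape
            theta = (v**3 + v * s2) / s2 if s2 > 0 else v  # inverse-gamma scale
            gamma_star = gamma_hat.copy()
            delta_star = delta_hat.copy()
            for _ in range(max_iter):
                g_new = (nb * tau2 * gamma_hat + delta_star * gamma_bar) / (
                    nb * tau2 + delta_star
                )
                ss = ((Zb - g_new[None, :]) ** 2).sum(axis=0)
                d_new = (theta + 0.5 * ss) / (nb / 2.0 + lam - 1.0)
                change = max(
                    np.abs(g_new - gamma_star).max(), np.abs(d_new - delta_star).max()
                )
                gamma_star, delta_star = g_new, d_new
                if change < tol:
                    break
            bayes[rows] = (Zb - gamma_star[None, :]) / np.sqrt(delta_star)[None, :]
        adjusted_ok = bayes * np.sqrt(var_pooled[ok])[None, :] + stand_mean[:, ok]
        adjusted[:, ok] = adjusted_ok

    out = pd.DataFrame(adjusted.T, index=cohort.genes, columns=cohort.samples)
    return ExpressionCohort(out, cohort.meta)


def batch_qc(before: ExpressionCohort, after: ExpressionCohort) -> BatchQCReport:
    """QC a batch adjustment: per-batch medians and sample Pearson correlations."""
    if before.values.shape != after.values.shape or list(before.samples) != list(
        after.samples
    ) or list(before.genes) != list(after.genes):
        raise ValueError("before/after cohorts must share genes and samples")

    def _medians(c: ExpressionCohort) -> pd.Series:
        return c.values.T.groupby(c.meta["batch"]).median().median(axis=1)

    return BatchQCReport(
        median_before=_medians(before),
        median_after=_medians(after),
        corr_before=before.values.corr(),
        corr_after=after.values.corr(),
    )
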