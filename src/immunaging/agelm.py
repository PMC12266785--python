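"""Per-gene linear modelling of expression on age with a sex covariate.

The model is ``expression ~ alpha + beta_age * age + beta_sex * sex + eps``
fit by OLS per gene; age and sex are tested with Type II sums of squares
(each term adjusted for the other), p-values come from the F distribution,
and Benjamini-Hochberg adjustment across genes yields q-values.  Genes
with q_age < 0.05 are age-DEGs; those additionally passing |beta_age| >
0.005 are flagged enrichment-eligible.  All threshold comparisons are
strict.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import ExpressionCohort

__all__ = ["fit_gene_age_model", "bh_adjust", "classify_degs"]

_ZERO_VAR_EPS = 1e-12


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if np.isnan(p).any():
        raise ValueError("p-values must not contain NaN")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def _rss(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual sum of squares of each row of Y regressed on columns of X."""
    Q, _ = np.linalg.qr(X)
    proj = Y @ Q
    return (Y**2).sum(axis=1) - (proj**2).sum(axis=1)


def fit_gene_age_model(cohort: ExpressionCohort) -> pd.DataFrame:
    """Fit the age + sex linear model to every gene.

    Returns a DataFrame indexed by gene with columns alpha, beta_age,
    beta_sex, sigma2 (residual variance), F_age, F_sex, p_age, p_sex,
    q_age and direction (sign of beta_age).  Constant genes get
    beta_age = 0 and p_age = 1 rather than failing the run.
    """
    meta = cohort.meta
    ages = meta["age"].to_numpy(dtype=float)
    if np.ptp(ages) == 0:
        raise ValueError("age is constant across the cohort")
    sex_levels = sorted(meta["sex"].astype(str).unique())
    if len(sex_levels) < 2:
        raise ValueError("both sexes must be present")
    sex01 = (meta["sex"].astype(str) == sex_levels[1]).to_numpy(dtype=float)
    n = len(meta)
    if n <= 3:
        raise ValueError("need more than 3 samples for 3 parameters + residual")

    X_full = np.column_stack([np.ones(n), ages, sex01])
    X_no_age = X_full[:, [0, 2]]
    X_no_sex = X_full[:, [0, 1]]
    Y = cohort.values.to_numpy(dtype=float)

    beta, *_ = np.linalg.lstsq(X_full, Y.T, rcond=None)
    rss_full = _rss(X_full, Y)
    df_resid = n - 3
    sigma2 = rss_full / df_resid
    # Type II: SS of each term adjusted for the other
    ss_age = _rss(X_no_age, Y) - rss_full
    ss_sex = _rss(X_no_sex, Y) - rss_full

    with np.errstate(divide="ignore", invalid="ignore"):
        F_age = np.where(sigma2 > _ZERO_VAR_EPS, ss_age / sigma2, 0.0)
        F_sex = np.where(sigma2 > _ZERO_VAR_EPS, ss_sex / sigma2, 0.0)
    F_age = np.clip(F_age, 0.0, None)
    F_sex = np.clip(F_sex, 0.0, None)
    p_age = stats.f.sf(F_age, 1, df_resid)
    p_sex = stats.f.sf(F_sex, 1, df_resid)

    # constant genes: no evidence either way
    const = Y.var(axis=1) <= _ZERO_VAR_EPS
    beta = beta.T  # (genes, 3)
    beta[const] = 0.0
    F_age[const] = 0.0
    F_sex[const] = 0.0
    p_age[const] = 1.0
    p_sex[const] = 1.0
    # noiseless but non-constant fits: sigma2 ~ 0 -> report p ~ 0
    perfect = (~const) & (sigma2 <= _ZERO_VAR_EPS)
    p_age[perfect & (ss_age > _ZERO_VAR_EPS)] = 0.0
    p_sex[perfect & (ss_sex > _ZERO_VAR_EPS)] = 0.0

    table = pd.DataFrame(
        {
            "alpha": beta[:, 0],
            "beta_age": beta[:, 1],
            "beta_sex": beta[:, 2],
            "sigma2": sigma2,
            "F_age": F_age,
            "F_sex": F_sex,
            "p_age": p_age,
            "p_sex": p_sex,
        },
        index=cohort.genes,
    )
    table["q_age"] = bh_adjust(table["p_age"].to_numpy())
    table["direction"] = np.sign(table["beta_age"]).astype(int)
    return table


def classify_degs(
    table: pd.DataFrame, q_cut: float = 0.05, beta_cut: float = 0.005
) -> pd.DataFrame:
    """Label age-DEGs: q_age < q_cut, split up/down by slope sign.

    ``enrichment_eligible`` additionally requires |beta_age| > beta_cut,
    the stricter slope filter applied before pathway enrichment.  Both
    comparisons are strict.
    """
    deg = table["q_age"] < q_cut
    out = pd.DataFrame(index=table.index)
    out["deg"] = deg
    out["direction"] = np.where(
        ~deg, "ns", np.where(table["beta_age"] > 0, "up", "down")
    )
    out["enrichment_eligible"] = deg & (table["beta_age"].abs() > beta_cut)
    return out
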