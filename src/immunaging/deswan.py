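"""Sliding-window differential expression along age (DE-SWAN).

For every age centre k, samples inside [k - hw, k + hw] are binarized
into a low group [k - hw, k) and a high group [k, k + hw], and each gene
is fit with ``expression ~ alpha + beta * I(high) + beta_sex * sex + eps``.
The window indicator is tested with a Type II F test, p-values are
BH-adjusted across genes within the centre, and genes below each q
cutoff are counted.  Local maxima of the count-vs-centre curve (crests)
mark ages of transient transcriptomic change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .agelm import bh_adjust
from .preprocess import ExpressionCohort

__all__ = [
    "DeswanProfile",
    "binarize_age",
    "deswan_scan",
    "find_crests",
    "null_crest_threshold",
    "top_degs",
]

DEFAULT_CENTERS = tuple(range(10, 91))
DEFAULT_CUTOFFS = (0.05, 0.01, 0.001)


def binarize_age(ages, center: float, half_width: float = 10.0) -> np.ndarray:
    """Assign each sample to 'low', 'high' or 'excluded' around a centre.

    low: age in [center - half_width, center); high: age in
    [center, center + half_width]; everything else excluded.  The boundary
    age == center goes to 'high' (half-open convention).
    """
    if half_width <= 0:
        raise ValueError("half_width must be > 0")
    ages = np.asarray(ages, dtype=float)
    out = np.full(ages.shape, "excluded", dtype=object)
    out[(ages >= center - half_width) & (ages < center)] = "low"
    out[(ages >= center) & (ages <= center + half_width)] = "high"
    return out


@dataclass
class DeswanProfile:
    """Result of a DE-SWAN scan.

    ``counts``: DataFrame indexed by centre with one column per q cutoff
    (NaN for underpowered centres).  ``stats``: long DataFrame (center,
    gene, beta, p, q).  ``crests``: crest ages detected on the count curve
    at ``crest_cutoff``.  ``underpowered``: centres skipped for lack of
    samples on one side.
    """

    centers: np.ndarray
    half_width: float
    q_cutoffs: tuple
    counts: pd.DataFrame
    stats: pd.DataFrame
    crests: np.ndarray
    crest_cutoff: float
    underpowered: list = field(default_factory=list)
    n_genes: int = 0


def _window_fit(Y: np.ndarray, indicator: np.ndarray, sex01: np.ndarray):
    """OLS of each gene on [1, indicator, sex]; Type II F test for the indicator."""
    n = indicator.size
    X_full = np.column_stack([np.ones(n), indicator, sex01])
    X_red = X_full[:, [0, 2]]

    def rss(X):
        Q, _ = np.linalg.qr(X)
        P = Y @ Q
        return (Y**2).sum(axis=1) - (P**2).sum(axis=1)

    beta, *_ = np.linalg.lstsq(X_full, Y.T, rcond=None)
    rss_full = rss(X_full)
    df_resid = n - 3
    sigma2 = rss_full / df_resid
    ss = rss(X_red) - rss_full
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(sigma2 > 1e-12, ss / sigma2, 0.0)
    F = np.clip(F, 0.0, None)
    p = stats.f.sf(F, 1, df_resid)
    perfect = (sigma2 <= 1e-12) & (ss > 1e-12)
    p[perfect] = 0.0
    return beta[1], p


def deswan_scan(
    cohort: ExpressionCohort,
    centers=DEFAULT_CENTERS,
    half_width: float = 10.0,
    q_cutoffs=DEFAULT_CUTOFFS,
    min_per_side: int = 3,
    crest_cutoff: float = 0.05,
    smooth_width: int = 3,
    crest_min_height: float = 0.0,
) -> DeswanProfile:
    """Run the sliding-window scan over all centres.

    Centres with fewer than ``min_per_side`` samples on either side, or a
    single-sex window, are flagged underpowered and skipped in counting.
    BH adjustment is within each centre, across genes.  Crest detection
    applies a moving-average smoother of ``smooth_width`` centres
    (width 1 = raw curve).
    """
    centers = np.asarray(list(centers), dtype=float)
    q_cutoffs = tuple(sorted(q_cutoffs, reverse=True))
    ages = cohort.meta["age"].to_numpy(dtype=float)
    sex_levels = sorted(cohort.meta["sex"].astype(str).unique())
    sex01_all = (cohort.meta["sex"].astype(str) == sex_levels[-1]).to_numpy(float)
    Y_all = cohort.values.to_numpy(dtype=float)
    n_genes = Y_all.shape[0]

    counts = pd.DataFrame(np.nan, index=centers, columns=list(q_cutoffs))
    counts.index.name = "center"
    stat_rows = []
    underpowered = []
    for k in centers:
        lab = binarize_age(ages, k, half_width)
        inside = lab != "excluded"
        n_low = int((lab == "low").sum())
        n_high = int((lab == "high").sum())
        sexes_in = np.unique(cohort.meta["sex"].astype(str).to_numpy()[inside])
        if n_low < min_per_side or n_high < min_per_side or sexes_in.size < 2:
            underpowered.append(float(k))
            continue
        Y = Y_all[:, inside]
        indicator = (lab[inside] == "high").astype(float)
        beta, p = _window_fit(Y, indicator, sex01_all[inside])
        q = bh_adjust(p)
        for cut in q_cutoffs:
            counts.loc[k, cut] = int((q < cut).sum())
        stat_rows.append(
            pd.DataFrame(
                {"center": k, "gene": cohort.genes, "beta": beta, "p": p, "q": q}
            )
        )
    if not stat_rows:
        raise ValueError("all centers underpowered; widen the window or add samples")
    stats_df = pd.concat(stat_rows, ignore_index=True)

    curve = counts[crest_cutoff].dropna()
    if len(curve) >= 3:
        crests = find_crests(
            curve.to_numpy(),
            centers=curve.index.to_numpy(),
            smooth_width=smooth_width,
            min_height=crest_min_height,
        )
    else:  # too few powered centers for peak detection
        crests = np.array([])
    return DeswanProfile(
        centers=centers,
        half_width=half_width,
        q_cutoffs=q_cutoffs,
        counts=counts,
        stats=stats_df,
        crests=crests,
        crest_cutoff=crest_cutoff,
        underpowered=underpowered,
        n_genes=n_genes,
    )


def find_crests(
    count_curve, centers=None, smooth_width: int = 1, min_height: float = 0.0
) -> np.ndarray:
    """Local maxima of a DEG-count curve; returns crest ages.

    After optional moving-average smoothing, a run of equal values is a
    crest when it exceeds both neighbouring runs; endpoint runs qualify
    when they exceed their single neighbour.  A plateau crest reports the
    plateau midpoint.  A constant curve has no crests.  ``min_height``
    drops crests whose (smoothed) count falls below it — pass the
    :func:`null_crest_threshold` of a matched null simulation to keep
    only calibrated crests.
    """
    y = np.asarray(count_curve, dtype=float)
    if y.size < 3:
        raise ValueError("count curve needs at least 3 points")
    centers = (
        np.arange(y.size, dtype=float) if centers is None else np.asarray(centers, float)
    )
    if smooth_width > 1:
        kernel = np.ones(smooth_width) / smooth_width
        pad = smooth_width // 2
        ypad = np.pad(y, pad, mode="edge")
        y = np.convolve(ypad, kernel, mode="valid")[: centers.size]
    # run-length encode
    starts = [0]
    for i in range(1, y.size):
        if y[i] != y[starts[-1]]:
            starts.append(i)
    runs = [(s, (starts[j + 1] - 1) if j + 1 < len(starts) else y.size - 1)
            for j, s in enumerate(starts)]
    if len(runs) == 1:
        return np.array([])
    crests = []
    for j, (s, e) in enumerate(runs):
        left_ok = j == 0 or y[runs[j - 1][0]] < y[s]
        right_ok = j == len(runs) - 1 or y[runs[j + 1][0]] < y[s]
        if left_ok and right_ok and y[s] >= min_height:
            crests.append((centers[s] + centers[e]) / 2.0)
    return np.array(crests)


def null_crest_threshold(max_counts, percentile: float = 95.0) -> float:
    """Calibrated crest threshold: the given percentile of per-seed maximal
    DEG counts under a null (no age effect) simulation."""
    return float(np.percentile(np.asarray(max_counts, dtype=float), percentile))


def top_degs(
    profile: DeswanProfile, q_cut: float = 0.01, beta_cut: float = 0.5
) -> pd.DataFrame:
    """Top significant genes at each crest centre.

    Genes with q < ``q_cut`` and |beta| > ``beta_cut`` at a crest centre
    (crest ages are rounded to the nearest scanned centre), labelled
    'increase' or 'decrease' by the sign of the window coefficient.
    """
    rows = []
    scanned = np.asarray(sorted(profile.stats["center"].unique()))
    for crest in profile.crests:
        k = scanned[np.argmin(np.abs(scanned - crest))]
        sub = profile.stats[profile.stats["center"] == k]
        hit = sub[(sub["q"] < q_cut) & (sub["beta"].abs() > beta_cut)].copy()
        hit["crest"] = crest
        hit["direction"] = np.where(hit["beta"] > 0, "increase", "decrease")
        rows.append(hit)
    if not rows:
        return pd.DataFrame(
            columns=["center", "gene", "beta", "p", "q", "crest", "direction"]
        )
    return pd.concat(rows, ignore_index=True)
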