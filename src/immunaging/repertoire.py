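"""TCR-repertoire clonality indices over cell-level clonotype tables.

A clonotype table has one row per T cell with its clone id, T-cell
subtype, sample and donor age.  Three indices summarise it:

* Gini coefficient of the clone-size distribution — 0 for a perfectly
  even repertoire, approaching 1 under extreme clonal dominance;
* clonal expansion — entropy-based unevenness, 1 - H/H_max over clone
  frequencies (base-2), 0 for all-singleton repertoires and 1 for a
  single clone (the H_max = 0 limit taken as fully clonal);
* cell-state transition potential — for clones represented in a subtype,
  the Shannon entropy (bits) of the clone's cells across subtypes,
  averaged with clone-size weights; high values mean clones freely span
  cell states.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "gini_coefficient",
    "expansion_index",
    "transition_index",
    "repertoire_by_group",
    "fit_age_trend",
    "compare_groups",
]

REQUIRED_COLUMNS = ("cell_id", "clone_id", "subtype", "sample")


def _check_sizes(clone_sizes) -> np.ndarray:
    sizes = np.asarray(clone_sizes, dtype=float)
    if sizes.size < 1:
        raise ValueError("need at least one clone")
    if (sizes <= 0).any():
        raise ValueError("clone sizes must be positive")
    return sizes


def gini_coefficient(clone_sizes) -> float:
    """Gini coefficient of clone sizes: sum_ij |x_i - x_j| / (2 n^2 mean)."""
    sizes = _check_sizes(clone_sizes)
    n = sizes.size
    if n == 1:
        return 0.0
    # O(n log n) via sorted cumulative form, equal to the double loop
    s = np.sort(sizes)
    i = np.arange(1, n + 1)
    return float(((2 * i - n - 1) * s).sum() / (n * n * s.mean()))


def expansion_index(clone_sizes, log_base: float = 2.0) -> float:
    """Entropy-based clonal expansion: 1 - H / H_max over clone frequencies.

    0 when every clone is a singleton (maximal entropy), 1 for a
    monoclonal repertoire (by convention; H_max = 0 there).
    """
    sizes = _check_sizes(clone_sizes)
    if sizes.size == 1:
        return 1.0
    p = sizes / sizes.sum()
    H = -(p * (np.log(p) / np.log(log_base))).sum()
    H_max = np.log(sizes.size) / np.log(log_base)
    val = 1.0 - H / H_max
    if abs(val) < 1e-12:  # uniform repertoire up to rounding
        return 0.0
    return float(np.clip(val, 0.0, 1.0))


def _entropy_bits(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def transition_index(table: pd.DataFrame, subtype: str, pair: str | None = None) -> float:
    """Cell-state transition potential of a subtype (bits).

    For each clone with at least one cell in ``subtype``, the Shannon
    entropy of the clone's cell distribution across all subtypes, averaged
    over clones weighted by the clone's cell count within ``subtype``.
    With ``pair`` given, the computation is restricted to cells of the
    {subtype, pair} subtype pair and weighted by the clone's cell count
    within the pair, which makes it symmetric in the two arguments.
    Clones confined to single subtypes contribute zero.
    """
    sub = table
    if pair is not None:
        sub = table[table["subtype"].isin([subtype, pair])]
    if subtype not in set(sub["subtype"]):
        raise ValueError(f"subtype {subtype!r} not present")
    dist = pd.crosstab(sub["clone_id"], sub["subtype"])
    if pair is None:
        anchored = dist[dist[subtype] > 0]
        weights = anchored[subtype].to_numpy(dtype=float)
    else:
        anchored = dist[dist.sum(axis=1) > 0]
        weights = anchored.sum(axis=1).to_numpy(dtype=float)
    if anchored.empty or weights.sum() == 0:
        return 0.0
    ent = np.array([_entropy_bits(row.to_numpy(dtype=float)) for _, row in anchored.iterrows()])
    return float((ent * weights).sum() / weights.sum())


def repertoire_by_group(
    table: pd.DataFrame,
    min_clones: int = 2,
) -> pd.DataFrame:
    """Per (sample, subtype) clonality indices with an age column.

    Returns one row per sample x subtype present: cell and clone counts,
    Gini, expansion, transition (across all subtypes), donor age if the
    table carries one, and a ``low_support`` flag for groups with fewer
    than ``min_clones`` clones.  Indices are computed per sample and
    never pooled across donors.
    """
    for c in ("clone_id", "subtype", "sample"):
        if c not in table.columns:
            raise ValueError(f"clonotype table missing column {c!r}")
    groups = table.groupby(["sample", "subtype"], observed=True)
    if groups.ngroups < 2:
        raise ValueError("need at least 2 (sample, subtype) groups")
    rows = []
    for (sample, subtype), sub in groups:
        sizes = sub["clone_id"].value_counts().to_numpy(dtype=float)
        full_sample = table[table["sample"] == sample]
        rows.append(
            {
                "sample": sample,
                "subtype": subtype,
                "n_cells": int(len(sub)),
                "n_clones": int(sizes.size),
                "gini": gini_coefficient(sizes),
                "expansion": expansion_index(sizes),
                "transition": transition_index(full_sample, subtype),
                "age": sub["age"].iloc[0] if "age" in sub else np.nan,
                "low_support": bool(sizes.size < min_clones),
            }
        )
    return pd.DataFrame(rows)


def fit_age_trend(
    index_table: pd.DataFrame, value: str, poly_degree: int = 2, min_age: float | None = None
) -> pd.DataFrame:
    """Polynomial trend of a clonality index against donor age, per subtype.

    Returns per-subtype polynomial coefficients (highest degree first) and
    the linear slope of a degree-1 fit on the same points; ``min_age``
    restricts the fit to donors older than the cut.
    """
    rows = []
    for subtype, sub in index_table.groupby("subtype", observed=True):
        sub = sub.dropna(subset=["age", value])
        if min_age is not None:
            sub = sub[sub["age"] >= min_age]
        if len(sub) <= poly_degree:
            continue
        x = sub["age"].to_numpy(dtype=float)
        y = sub[value].to_numpy(dtype=float)
        coeffs = np.polyfit(x, y, deg=poly_degree)
        slope = np.polyfit(x, y, deg=1)[0]
        rows.append({"subtype": subtype, "poly_coeffs": tuple(coeffs), "slope": float(slope)})
    return pd.DataFrame(rows)


def compare_groups(
    index_table: pd.DataFrame,
    value: str,
    group_col: str,
    group_a: str,
    group_b: str,
) -> dict:
    """Two-sided rank-sum comparison of an index between two named groups
    (e.g. clonal expansion of regulatory T cells, frail vs advanced-aged)."""
    va = index_table.loc[index_table[group_col] == group_a, value].to_numpy(float)
    vb = index_table.loc[index_table[group_col] == group_b, value].to_numpy(float)
    if va.size == 0 or vb.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.ptp(np.concatenate([va, vb])) == 0:
        return {"statistic": va.size * vb.size / 2.0, "p": 1.0}
    res = stats.mannwhitneyu(va, vb, alternative="two-sided", method="auto")
    return {"statistic": float(res.statistic), "p": float(res.pvalue)}
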