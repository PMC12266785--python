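"""Cell-level statistics: gene-set scoring, rank-sum DE, proportions, frailty.

The gene-set score follows the binned-control convention: genes are
binned by dataset-average expression, each signature gene draws
expression-matched control genes from its bin, and the per-cell score is
mean(signature expression) - mean(control expression).  The default
signature is a 20-gene senescence-associated secretory phenotype (SASP)
panel of cytokines, chemokines and matrix remodellers scored in
monocytes.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats

from .agelm import bh_adjust

__all__ = [
    "SASP_GENES",
    "GeneSetScore",
    "FrailtyRecord",
    "score_gene_set",
    "rank_sum_de",
    "proportion_age_correlation",
    "classify_frailty",
]

# Senescence-associated secretory phenotype signature (monocyte scoring)
SASP_GENES = (
    "CCL2", "CCL3", "CCL4", "CCL5",
    "CXCL1", "CXCL2", "CXCL3", "CXCL8", "CXCL10",
    "HMGB1", "ICAM1", "IL18", "IL1B", "IL6", "TNF",
    "MMP9", "MIF", "NRG1", "EREG", "AREG",
)


@dataclass
class GeneSetScore:
    """Per-cell gene-set score with the control-sampling parameters used."""

    scores: pd.Series
    gene_set: tuple
    control_genes: tuple
    n_bins: int
    ctrl_size: int
    seed: int

    def to_tsv(self, path):
        self.scores.rename("score").to_csv(path, sep="\t", index_label="cell")


@dataclass
class FrailtyRecord:
    """Deficit-accumulation frailty index for one donor.

    index = deficits_present / deficits_assessed, the Rockwood frailty
    index; always within [0, 1].
    """

    donor: str
    age: float
    deficits_present: int
    deficits_assessed: int

    def __post_init__(self):
        if self.deficits_assessed <= 0:
            raise ValueError("deficits_assessed must be > 0")
        if not 0 <= self.deficits_present <= self.deficits_assessed:
            raise ValueError("deficits_present must lie in [0, deficits_assessed]")

    @property
    def index(self) -> float:
        return self.deficits_present / self.deficits_assessed


def _matrix(cells: ad.AnnData) -> np.ndarray:
    X = cells.X
    return X.toarray() if hasattr(X, "toarray") else np.asarray(X, dtype=float)


def score_gene_set(
    cells: ad.AnnData,
    gene_set=SASP_GENES,
    n_bins: int = 25,
    ctrl_size: int = 50,
    seed: int = 0,
    control_pool=None,
) -> GeneSetScore:
    """Binned-control gene-set score per cell.

    Genes are ranked by mean expression across cells and cut into
    ``n_bins`` equal-rank bins; each signature gene contributes
    ``ctrl_size`` control genes sampled (without replacement, seeded)
    from its bin, excluding signature genes.  The score is
    mean(signature) - mean(control union) per cell.  ``control_pool``
    overrides control selection entirely (testing hook); passing the gene
    set itself yields an identically zero score.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    var_names = pd.Index(cells.var_names)
    present = [g for g in gene_set if g in var_names]
    if not present:
        raise ValueError(f"gene set entirely absent from the matrix: {list(gene_set)}")
    X = _matrix(cells)
    expr = pd.DataFrame(X, index=cells.obs_names, columns=var_names)

    if control_pool is not None:
        controls = [g for g in control_pool if g in var_names]
    else:
        rng = np.random.default_rng(seed)
        means = expr.mean(axis=0)
        ranks = means.rank(method="first")
        bins = pd.cut(ranks, n_bins, labels=False)
        controls = set()
        set_lookup = set(present)
        for g in present:
            pool = var_names[(bins == bins[g]).to_numpy()]
            pool = [c for c in pool if c not in set_lookup]
            take = min(ctrl_size, len(pool))
            if take:
                controls.update(rng.choice(pool, size=take, replace=False))
        controls = sorted(controls)
    set_mean = expr[present].mean(axis=1)
    ctrl_mean = expr[list(controls)].mean(axis=1) if len(controls) else 0.0
    scores = set_mean - ctrl_mean
    return GeneSetScore(
        scores=scores,
        gene_set=tuple(present),
        control_genes=tuple(controls),
        n_bins=n_bins,
        ctrl_size=ctrl_size,
        seed=seed,
    )


def rank_sum_de(
    cells: ad.AnnData,
    group_a,
    group_b,
    q_cut: float = 0.05,
    lfc_cut: float = 0.25,
    exact_max: int = 10,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum DE between two cell selections.

    ``group_a`` / ``group_b`` are boolean masks over cells.  Midranks with
    tie-corrected normal approximation; exact enumeration when both groups
    have at most ``exact_max`` cells and the values are tie-free.  Fold
    change is log2 of the ratio of expm1(mean log-expression) + 1e-9, the
    convention under which the default thresholds are defined; the DEG
    flag requires q < ``q_cut`` and log2FC > ``lfc_cut`` (A over B).
    """
    a = np.asarray(group_a, dtype=bool)
    b = np.asarray(group_b, dtype=bool)
    if a.sum() < 3 or b.sum() < 3:
        raise ValueError("each group needs at least 3 cells")
    X = _matrix(cells)
    Xa, Xb = X[a], X[b]
    eps = 1e-9
    lfc = np.log2(
        (np.expm1(Xa.mean(axis=0)) + eps) / (np.expm1(Xb.mean(axis=0)) + eps)
    )
    stats_out = np.empty(X.shape[1])
    pvals = np.empty(X.shape[1])
    small = a.sum() <= exact_max and b.sum() <= exact_max
    for j in range(X.shape[1]):
        va, vb = Xa[:, j], Xb[:, j]
        ties = np.unique(np.concatenate([va, vb])).size < va.size + vb.size
        method = "exact" if (small and not ties) else "asymptotic"
        if np.ptp(va) == 0 and np.ptp(vb) == 0 and va[0] == vb[0]:
            stats_out[j], pvals[j] = va.size * vb.size / 2.0, 1.0
            continue
        res = stats.mannwhitneyu(va, vb, alternative="two-sided", method=method)
        stats_out[j], pvals[j] = res.statistic, res.pvalue
    q = bh_adjust(pvals)
    out = pd.DataFrame(
        {"statistic": stats_out, "p": pvals, "q": q, "log2fc": lfc},
        index=cells.var_names,
    )
    out["deg"] = (out["q"] < q_cut) & (out["log2fc"] > lfc_cut)
    return out


def proportion_age_correlation(
    cells: ad.AnnData,
    sample_key: str = "sample",
    type_key: str = "cell_type",
    age_key: str = "age",
    poly_degree: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell-type correlation of compositional fraction with donor age.

    Returns (per-type table, per-sample fraction table).  The per-type
    table holds the Pearson correlation of the type's per-sample fraction
    with age, |PCC| > 0.2 and > 0.4 flags, least-squares polynomial trend
    coefficients (highest degree first), plus zero-variance and sparsity
    flags.  Zero-variance fractions report PCC 0.
    """
    obs = cells.obs
    fracs = (
        pd.crosstab(obs[sample_key], obs[type_key], normalize="index")
        .sort_index()
    )
    ages = obs.groupby(sample_key, observed=True)[age_key].first().reindex(fracs.index)
    if ages.notna().sum() < 4:
        raise ValueError("need at least 4 samples with known donor age")
    present_frac = (
        pd.crosstab(obs[sample_key], obs[type_key]) > 0
    ).mean(axis=0)
    rows = []
    for ct in fracs.columns:
        f = fracs[ct].to_numpy(dtype=float)
        age_v = ages.to_numpy(dtype=float)
        zero_var = np.ptp(f) == 0
        pcc = 0.0 if zero_var else float(stats.pearsonr(f, age_v)[0])
        coeffs = np.polyfit(age_v, f, deg=poly_degree)
        rows.append(
            {
                "cell_type": ct,
                "pcc": pcc,
                "abs_pcc_gt_0.2": abs(pcc) > 0.2,
                "abs_pcc_gt_0.4": abs(pcc) > 0.4,
                "poly_coeffs": tuple(coeffs),
                "zero_variance": bool(zero_var),
                "sparse": bool(present_frac[ct] < 0.5),
            }
        )
    return pd.DataFrame(rows).set_index("cell_type"), fracs


def classify_frailty(record: FrailtyRecord, age_cut: float = 65.0, index_cut: float = 0.2) -> str:
    """Frail iff the donor is over ``age_cut`` years AND the frailty index
    exceeds ``index_cut`` — both strictly."""
    return "frail" if (record.age > age_cut and record.index > index_cut) else "non-frail"
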