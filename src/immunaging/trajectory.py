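"""LOESS expression trajectories over age and hierarchical shape clustering.

Each gene's expression is smoothed against age by locally weighted
quadratic regression (tricube kernel over the span-nearest neighbours,
span 0.75 by default, no robustness iterations), evaluated on an integer
age grid spanning the observed range.  Curves are z-scored across the
grid so that clustering groups shapes, not levels, and grouped by
agglomerative clustering (Euclidean distance, complete linkage) with the
tree cut at a user-chosen k in 6..12.  Flat genes, whose z-score is
undefined, go to a dedicated cluster 0 before clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_score

from .preprocess import ExpressionCohort

__all__ = [
    "TrajectoryAtlas",
    "loess_fit",
    "loess_hat_matrix",
    "build_trajectory_atlas",
    "cluster_trajectories",
    "silhouette_by_k",
]

_FLAT_EPS = 1e-12
DEFAULT_K_RANGE = (6, 12)


def loess_hat_matrix(
    x: np.ndarray, grid: np.ndarray, span: float = 0.75, degree: int = 2
) -> np.ndarray:
    """Linear smoother matrix L with predictions = L @ y.

    Row g of L gives the local polynomial WLS weights for grid point g:
    tricube kernel over the span-nearest neighbours, polynomial of the
    given degree in (x - grid point).  Because LOESS is linear in y, one
    hat matrix serves every gene measured at the same ages.
    """
    x = np.asarray(x, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    n = x.size
    n_distinct = np.unique(x).size
    if n_distinct < max(4, degree + 2):
        raise ValueError(
            f"need at least {max(4, degree + 2)} distinct x values, got {n_distinct}"
        )
    q = min(n, int(np.ceil(span * n)))
    q = max(q, degree + 1)
    L = np.zeros((grid.size, n))
    for gi, g in enumerate(grid):
        d = np.abs(x - g)
        dq = np.sort(d)[q - 1]
        if dq <= 0:
            # grid point coincides with >= q tied x's: average them
            w = (d == 0).astype(float)
        else:
            u = np.clip(d / dq, 0.0, 1.0)
            w = (1.0 - u**3) ** 3
        active = w > 0
        xa = x[active] - g
        wa = w[active]
        A = np.vander(xa, degree + 1, increasing=True)  # [1, dx, dx^2...]
        WA = A * wa[:, None]
        # prediction at dx=0 is the intercept of the local WLS fit
        coef_map = np.linalg.pinv(A.T @ WA) @ WA.T  # (degree+1, n_active)
        L[gi, active] = coef_map[0]
    return L


def loess_fit(
    x, y, span: float = 0.75, degree: int = 2, grid=None
) -> tuple[np.ndarray, np.ndarray]:
    """LOESS-smooth y against x; returns (grid, predictions).

    The default grid is every integer year from min(x) to max(x).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if grid is None:
        grid = np.arange(int(np.min(x)), int(np.max(x)) + 1, dtype=float)
    else:
        grid = np.asarray(grid, dtype=float)
    L = loess_hat_matrix(x, grid, span=span, degree=degree)
    return grid, L @ y


@dataclass
class TrajectoryAtlas:
    """Per-gene LOESS curves on an age grid, z-scored, with cluster labels.

    ``curves``: genes x grid predicted log-expression.  ``zcurves``: the
    same curves z-scored per gene across the grid (flat genes -> all
    zeros).  ``labels``: Series of integer cluster labels (0 reserved for
    flat genes) or None before clustering.  ``cluster_means``: cluster x
    grid mean z-curves.
    """

    age_grid: np.ndarray
    curves: pd.DataFrame
    zcurves: pd.DataFrame
    labels: pd.Series | None = None
    cluster_means: pd.DataFrame | None = None

    @property
    def flat_genes(self) -> pd.Index:
        sd = self.curves.std(axis=1, ddof=0)
        return self.curves.index[sd <= _FLAT_EPS]


def build_trajectory_atlas(
    cohort: ExpressionCohort, span: float = 0.75, degree: int = 2, grid=None
) -> TrajectoryAtlas:
    """Fit the per-gene LOESS curves of a cohort on a shared age grid."""
    ages = cohort.meta["age"].to_numpy(dtype=float)
    if grid is None:
        grid = np.arange(int(ages.min()), int(ages.max()) + 1, dtype=float)
    else:
        grid = np.asarray(grid, dtype=float)
    L = loess_hat_matrix(ages, grid, span=span, degree=degree)
    preds = cohort.values.to_numpy(dtype=float) @ L.T
    curves = pd.DataFrame(preds, index=cohort.genes, columns=grid)
    mu = preds.mean(axis=1, keepdims=True)
    sd = preds.std(axis=1, ddof=0, keepdims=True)
    flat = sd[:, 0] <= _FLAT_EPS
    z = np.where(flat[:, None], 0.0, (preds - mu) / np.where(sd > 0, sd, 1.0))
    zcurves = pd.DataFrame(z, index=cohort.genes, columns=grid)
    return TrajectoryAtlas(age_grid=grid, curves=curves, zcurves=zcurves)


def cluster_trajectories(
    atlas: TrajectoryAtlas,
    k: int,
    k_range: tuple[int, int] = DEFAULT_K_RANGE,
    linkage_method: str = "complete",
    enforce_range: bool = True,
) -> TrajectoryAtlas:
    """Group z-scored trajectories by agglomerative clustering at k groups.

    Complete linkage on Euclidean distances by default; the tree is cut at
    the requested k, which must fall within ``k_range`` unless
    ``enforce_range`` is disabled (small test fixtures).  Flat genes keep
    the reserved label 0; non-flat clusters are labelled 1..k.  Labels are
    renumbered by first appearance in gene order so identical input yields
    identical labelling.
    """
    if enforce_range and not (k_range[0] <= k <= k_range[1]):
        raise ValueError(f"k={k} outside the allowed range {k_range}")
    flat = atlas.flat_genes
    active = atlas.zcurves.index.difference(flat, sort=False)
    if len(active) < k:
        raise ValueError(f"need at least k={k} non-flat genes, got {len(active)}")
    Z = linkage(atlas.zcurves.loc[active].to_numpy(), method=linkage_method)
    raw = fcluster(Z, t=k, criterion="maxclust")
    # deterministic renumbering by first appearance
    order, seen = {}, 1
    lab = np.empty_like(raw)
    for i, r in enumerate(raw):
        if r not in order:
            order[r] = seen
            seen += 1
        lab[i] = order[r]
    labels = pd.Series(0, index=atlas.zcurves.index, name="cluster")
    labels.loc[active] = lab
    means = atlas.zcurves.groupby(labels).mean()
    return TrajectoryAtlas(
        age_grid=atlas.age_grid,
        curves=atlas.curves,
        zcurves=atlas.zcurves,
        labels=labels,
        cluster_means=means,
    )


def silhouette_by_k(
    atlas: TrajectoryAtlas,
    k_range: tuple[int, int] = DEFAULT_K_RANGE,
    linkage_method: str = "complete",
) -> pd.Series:
    """Silhouette score of the z-curve partition for each k in the range.

    Recorded to help a user pick k; the pipeline does not choose
    automatically.
    """
    flat = atlas.flat_genes
    X = atlas.zcurves.drop(index=flat).to_numpy()
    Z = linkage(X, method=linkage_method)
    out = {}
    for k in range(k_range[0], k_range[1] + 1):
        labels = fcluster(Z, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            out[k] = np.nan
        else:
            out[k] = silhouette_score(X, labels)
    return pd.Series(out, name="silhouette")
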