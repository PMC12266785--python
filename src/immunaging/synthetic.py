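"""Synthetic cohorts with known ground truth.

Generates the three kinds of data the analysis pipeline consumes:

* bulk expression cohorts (genes x samples, log scale) whose genes follow
  one of four trajectory archetypes along age — flat, linear, saturating
  (early-life change that plateaus), or transient (a level shift confined
  to a narrow age window, the kind of gene that drives a sliding-window
  crest at that age) — with optional per-batch location/scale distortions;
* cell-level expression matrices (AnnData) with cell-type marker shifts;
* clonotype tables with power-law / geometric clone-size distributions and
  a controllable probability that clones span cell-state pairs.

Everything is seeded and reproducible bit-for-bit; the returned truth
objects carry the parameters needed to check downstream recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import anndata as ad
import numpy as np
import pandas as pd
from scipy.special import expit

from .preprocess import ExpressionCohort

__all__ = [
    "TrajectoryArchetype",
    "CohortTruth",
    "ClonotypeTruth",
    "AGE_GROUP_BINS",
    "assign_age_group",
    "generate_cohort",
    "generate_single_cell",
    "generate_clonotypes",
]

ARCHETYPE_KINDS = ("flat", "linear", "saturating", "transient")

# Age-group vocabulary used for cell metadata: child, young, aged,
# advanced-aged; "frail" is a status label assigned separately.
AGE_GROUP_BINS = {
    "child": (1, 11),
    "young": (23, 58),
    "aged": (60, 72),
    "advanced-aged": (77, 100),
}


def assign_age_group(age: float) -> str:
    """Map a donor age in years onto the cohort age-group vocabulary.

    Ages falling in the gaps between the published bins are attached to the
    nearest bin so that every donor receives a label.
    """
    for name, (lo, hi) in AGE_GROUP_BINS.items():
        if lo <= age <= hi:
            return name
    # gap ages -> nearest bin by distance to its edges
    best, best_d = None, np.inf
    for name, (lo, hi) in AGE_GROUP_BINS.items():
        d = min(abs(age - lo), abs(age - hi))
        if d < best_d:
            best, best_d = name, d
    return best


@dataclass(frozen=True)
class TrajectoryArchetype:
    """One gene's mean log-expression as a function of age and sex.

    kind
        "flat", "linear", "saturating" or "transient"; determines which of
        the remaining fields are read.
    baseline
        log-expression at the reference (age 0 for linear; the pre-change
        plateau for saturating; everywhere outside the bump for transient).
    slope
        log-expression change per year (linear only).
    change_age, half_width
        centre and half-width in years of the saturating or transient
        transition.  Saturating uses half_width directly as the logistic
        scale (a slow, decades-long approach to the plateau); transient
        compresses the whole shift into change_age +- half_width
        (logistic scale half_width / 4), which is what concentrates
        sliding-window differential expression at change_age.
    amplitude
        total log-expression change across the transition.
    sex_effect
        additive log-expression shift for the non-reference sex.
    """

    kind: str
    baseline: float = 0.0
    slope: float = 0.0
    change_age: float = 50.0
    half_width: float = 10.0
    amplitude: float = 0.0
    sex_effect: float = 0.0

    def __post_init__(self):
        if self.kind not in ARCHETYPE_KINDS:
            raise ValueError(f"unknown archetype kind {self.kind!r}")
        if self.half_width <= 0:
            raise ValueError("half_width must be > 0")
        if not np.isfinite(self.amplitude):
            raise ValueError("amplitude must be finite")

    def mean(self, age, sex01):
        """Mean log-expression at `age` for sex indicator `sex01` (0/1)."""
        age = np.asarray(age, dtype=float)
        sex01 = np.asarray(sex01, dtype=float)
        if self.kind == "flat":
            base = np.full_like(age, self.baseline)
        elif self.kind == "linear":
            base = self.baseline + self.slope * age
        elif self.kind == "saturating":
            # logistic step: baseline -> baseline + amplitude around change_age
            base = self.baseline + self.amplitude * expit(
                (age - self.change_age) / self.half_width
            )
        else:  # transient: level shift confined to change_age +- half_width
            s = self.half_width / 4.0
            base = self.baseline + self.amplitude * expit(
                (age - self.change_age) / s
            )
        return base + self.sex_effect * sex01


@dataclass
class CohortTruth:
    """Generator parameters recorded alongside a synthetic cohort."""

    archetypes: dict[str, TrajectoryArchetype] = field(default_factory=dict)
    batch_offsets: dict[str, float] = field(default_factory=dict)
    batch_scales: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.5
    n_batches: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for b, s in self.batch_scales.items():
            if s <= 0:
                raise ValueError(f"batch scale for {b!r} must be > 0")


@dataclass
class ClonotypeTruth:
    """Parameters of a synthetic clonotype table.

    distribution: "singleton", "geometric" (clone size ~ Geometric(rate) on
    {1,2,...}) or "powerlaw" (Zipf with the given exponent).  The sharing
    matrix is row-stochastic over subtypes: row = the clone's primary
    subtype, entries = probability each cell of that clone is observed in
    each subtype.  Identity = clones never span subtypes.
    """

    subtypes: tuple[str, ...] = ("CD4_naive", "CD8_CTL")
    distribution: str = "geometric"
    rate: float = 0.5
    exponent: float = 2.5
    sharing: np.ndarray | None = None
    cells_per_sample: int = 500
    sample_ages: tuple[int, ...] = (30, 70)
    seed: int = 0

    def __post_init__(self):
        if self.cells_per_sample < 1:
            raise ValueError("cells_per_sample must be >= 1")
        if self.distribution not in ("singleton", "geometric", "powerlaw"):
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if self.sharing is None:
            self.sharing = np.eye(len(self.subtypes))
        self.sharing = np.asarray(self.sharing, dtype=float)
        if self.sharing.shape != (len(self.subtypes), len(self.subtypes)):
            raise ValueError("sharing matrix shape must be n_subtypes^2")
        if (self.sharing < 0).any() or (self.sharing > 1).any():
            raise ValueError("sharing probabilities must lie in [0, 1]")


# ---------------------------------------------------------------------------
# bulk cohort


def generate_cohort(
    n_samples: int,
    age_range: tuple[int, int],
    archetypes,
    truth: CohortTruth | None = None,
    age_sampling: str = "uniform",
) -> tuple[ExpressionCohort, CohortTruth]:
    """Simulate a bulk expression cohort.

    Ages are integer years over ``age_range`` — drawn uniformly at random
    (``age_sampling="uniform"``) or evenly spaced (``"even"``).  Sexes are
    exactly balanced (within one sample) and shuffled; batches are assigned
    round-robin.  Each gene's value is its archetype mean at (age, sex),
    plus the batch's additive offset, plus batch-scale times Gaussian noise
    — exactly the location/scale model empirical-Bayes batch correction
    assumes, so injected distortions are recoverable.

    ``archetypes`` is a list of :class:`TrajectoryArchetype` (genes named
    G0000..) or a dict mapping gene id -> archetype.
    """
    if n_samples < 4:
        raise ValueError("n_samples must be >= 4")
    lo, hi = int(age_range[0]), int(age_range[1])
    if not (1 <= lo < hi <= 100):
        raise ValueError("age_range must be non-degenerate and within [1, 100]")
    if isinstance(archetypes, dict):
        arch_map = dict(archetypes)
    else:
        arch_map = {f"G{i:04d}": a for i, a in enumerate(archetypes)}
    if not arch_map:
        raise ValueError("archetype list must not be empty")
    if len(arch_map) != len(set(arch_map)):
        raise ValueError("gene ids must be unique")

    truth = truth if truth is not None else CohortTruth()
    truth = replace(truth, archetypes=arch_map)
    rng = np.random.default_rng(truth.seed)

    if age_sampling == "uniform":
        ages = rng.integers(lo, hi + 1, size=n_samples)
    elif age_sampling == "even":
        ages = np.round(np.linspace(lo, hi, n_samples)).astype(int)
    else:
        raise ValueError(f"unknown age_sampling {age_sampling!r}")

    sexes = np.array(["F", "M"] * (n_samples // 2 + 1))[:n_samples]
    rng.shuffle(sexes)
    sex01 = (sexes == "M").astype(float)

    batch_names = [f"batch{i}" for i in range(truth.n_batches)]
    batches = np.array([batch_names[i % truth.n_batches] for i in range(n_samples)])
    offsets = np.array([truth.batch_offsets.get(b, 0.0) for b in batches])
    scales = np.array([truth.batch_scales.get(b, 1.0) for b in batches])

    genes = list(arch_map)
    mat = np.empty((len(genes), n_samples))
    noise = rng.normal(0.0, truth.noise_sd, size=mat.shape) if truth.noise_sd > 0 else 0.0
    for i, g in enumerate(genes):
        mu = arch_map[g].mean(ages, sex01)
        eps = noise[i] if truth.noise_sd > 0 else np.zeros(n_samples)
        mat[i] = mu + offsets + scales * eps

    samples = [f"S{i:03d}" for i in range(n_samples)]
    values = pd.DataFrame(mat, index=genes, columns=samples)
    meta = pd.DataFrame(
        {"age": ages, "sex": sexes, "batch": batches}, index=samples
    )
    return ExpressionCohort(values, meta), truth


# ---------------------------------------------------------------------------
# single-cell matrix


def generate_single_cell(
    n_cells: int,
    cell_types,
    marker_spec: dict[str, dict[str, float]] | None = None,
    n_genes: int = 100,
    n_samples: int = 4,
    seed: int = 0,
    noise_sd: float = 1.0,
    sample_ages=None,
) -> ad.AnnData:
    """Simulate a cell x gene log-expression matrix with typed cells.

    Expression is log-normal: log values are Gaussian around a per-gene
    baseline, plus the per-type mean shifts in ``marker_spec``
    (type -> {gene: shift in log units}).  Cells carry type, sample id,
    donor age and age group in ``.obs``.
    """
    cell_types = list(cell_types)
    if n_cells < 10:
        raise ValueError("n_cells must be >= 10")
    if len(cell_types) < 2:
        raise ValueError("need at least 2 cell types")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    marker_spec = marker_spec or {}
    universe = set(genes)
    missing = [
        g for shifts in marker_spec.values() for g in shifts if g not in universe
    ]
    if missing:
        raise ValueError(f"marker genes absent from gene universe: {sorted(set(missing))}")

    if sample_ages is None:
        sample_ages = np.round(np.linspace(5, 90, n_samples)).astype(int)
    samples = [f"D{i:02d}" for i in range(n_samples)]

    base = rng.uniform(0.5, 2.0, size=n_genes)
    types = np.array([cell_types[i % len(cell_types)] for i in range(n_cells)])
    sample_of_cell = np.array([samples[i % n_samples] for i in range(n_cells)])
    shift = np.zeros((n_cells, n_genes))
    gene_idx = {g: j for j, g in enumerate(genes)}
    for t, shifts in marker_spec.items():
        rows = types == t
        for g, s in shifts.items():
            shift[rows, gene_idx[g]] += s
    X = rng.normal(0.0, noise_sd, size=(n_cells, n_genes)) + base[None, :] + shift
    X = np.clip(X, 0.0, None)  # log-normalized expression is nonnegative

    age_of_sample = dict(zip(samples, (int(a) for a in sample_ages)))
    ages = np.array([age_of_sample[s] for s in sample_of_cell])
    obs = pd.DataFrame(
        {
            "cell_type": types,
            "sample": sample_of_cell,
            "age": ages,
            "age_group": [assign_age_group(a) for a in ages],
        },
        index=[f"C{i:05d}" for i in range(n_cells)],
    )
    return ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=genes))


# ---------------------------------------------------------------------------
# clonotype tables


def _draw_clone_sizes(rng, truth: ClonotypeTruth, n_cells: int) -> np.ndarray:
    sizes = []
    total = 0
    while total < n_cells:
        if truth.distribution == "singleton":
            s = 1
        elif truth.distribution == "geometric":
            s = int(rng.geometric(truth.rate))
        else:
            s = int(rng.zipf(truth.exponent))
        s = min(s, n_cells - total)
        sizes.append(s)
        total += s
    return np.array(sizes)


def generate_clonotypes(truth: ClonotypeTruth) -> pd.DataFrame:
    """Simulate a cell-level clonotype table.

    Returns a DataFrame with columns cell_id, clone_id, subtype, sample,
    age — one row per T cell.  Clone sizes follow ``truth.distribution``;
    each clone has a primary subtype and its cells land in subtypes
    according to the corresponding row of the sharing matrix.
    """
    rng = np.random.default_rng(truth.seed)
    subtypes = list(truth.subtypes)
    rows = []
    cell_counter = 0
    for si, age in enumerate(truth.sample_ages):
        sample = f"D{si:02d}"
        sizes = _draw_clone_sizes(rng, truth, truth.cells_per_sample)
        for ci, size in enumerate(sizes):
            clone = f"{sample}_clone{ci:04d}"
            primary = int(rng.integers(len(subtypes)))
            p = truth.sharing[primary]
            p = p / p.sum()
            assigned = rng.choice(len(subtypes), size=size, p=p)
            for k in assigned:
                rows.append(
                    (f"cell{cell_counter:06d}", clone, subtypes[k], sample, age)
                )
                cell_counter += 1
    return pd.DataFrame(
        rows, columns=["cell_id", "clone_id", "subtype", "sample", "age"]
    )
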