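import numpy as np
import pandas as pd
import pytest

from immunaging import (
    CohortTruth,
    ExpressionCohort,
    TrajectoryArchetype,
    generate_cohort,
    generate_single_cell,
)


def make_cohort(n_samples=40, archetypes=None, noise_sd=0.0, seed=0, **truth_kw):
    """Small synthetic cohort helper shared across test modules."""
    if archetypes is None:
        archetypes = [
            TrajectoryArchetype("linear", baseline=2.0, slope=0.02),
            TrajectoryArchetype("flat", baseline=3.0),
        ]
    truth = CohortTruth(noise_sd=noise_sd, seed=seed, **truth_kw)
    return generate_cohort(n_samples, (1, 99), archetypes, truth)


@pytest.fixture
def linear_cohort():
    cohort, truth = make_cohort(n_samples=60, noise_sd=0.3, seed=11)
    return cohort, truth


@pytest.fixture
def typed_cells():
    return generate_single_cell(
        60,
        ["mono", "tcell"],
        {"mono": {"G0003": 2.0}},
        n_genes=80,
        seed=7,
    )


def manual_cohort(values: np.ndarray, ages, sexes, batches=None):
    """Build an ExpressionCohort directly from arrays (fixture plumbing)."""
    n = len(ages)
    samples = [f"S{i}" for i in range(n)]
    genes = [f"g{i}" for i in range(values.shape[0])]
    batches = batches if batches is not None else ["b0"] * n
    meta = pd.DataFrame(
        {"age": ages, "sex": sexes, "batch": batches}, index=samples
    )
    return ExpressionCohort(
        pd.DataFrame(values, index=genes, columns=samples), meta
    )
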