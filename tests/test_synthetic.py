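"""Ground-truth properties of the synthetic cohort/cell/clonotype generators."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from immunaging import (
    ClonotypeTruth,
    CohortTruth,
    TrajectoryArchetype,
    assign_age_group,
    expansion_index,
    generate_clonotypes,
    generate_cohort,
    generate_single_cell,
    gini_coefficient,
    rank_sum_de,
    transition_index,
)
from conftest import make_cohort


def ols_slope(ages, y):
    X = np.column_stack([np.ones_like(ages, dtype=float), ages])
    return np.linalg.lstsq(X, y, rcond=None)[0][1]


class TestCohort:
    def test_zero_noise_flat_gene_equals_baseline_exactly(self):
        cohort, _ = make_cohort(
            archetypes=[TrajectoryArchetype("flat", baseline=2.5)], noise_sd=0.0
        )
        assert (cohort.values.to_numpy() == 2.5).all()

    def test_noiseless_linear_gene_recovers_slope(self):
        cohort, _ = make_cohort(
            archetypes=[TrajectoryArchetype("linear", baseline=1.0, slope=0.02)],
            noise_sd=0.0,
        )
        slope = ols_slope(
            cohort.meta["age"].to_numpy(float), cohort.values.iloc[0].to_numpy()
        )
        assert slope == pytest.approx(0.02, abs=1e-10)

    def test_noisy_slope_estimator_is_unbiased(self):
        # Monte-Carlo sampling distribution of the OLS estimator
        slopes = []
        for seed in range(50):
            cohort, _ = make_cohort(
                n_samples=180,
                archetypes=[TrajectoryArchetype("linear", baseline=1.0, slope=0.02)],
                noise_sd=0.5,
                seed=seed,
            )
            slopes.append(
                ols_slope(
                    cohort.meta["age"].to_numpy(float),
                    cohort.values.iloc[0].to_numpy(),
                )
            )
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes) - 0.02) < 2 * se

    def test_seeded_generation_is_bit_identical(self):
        a, _ = make_cohort(noise_sd=0.4, seed=3)
        b, _ = make_cohort(noise_sd=0.4, seed=3)
        pd.testing.assert_frame_equal(a.values, b.values)
        pd.testing.assert_frame_equal(a.meta, b.meta)

    def test_sex_balance_age_coverage_and_batches(self):
        cohort, _ = make_cohort(n_samples=181, noise_sd=0.1, seed=5, n_batches=3)
        counts = cohort.meta["sex"].value_counts()
        assert abs(counts["F"] - counts["M"]) <= 1
        ages = cohort.meta["age"]
        assert ages.min() >= 1 and ages.max() <= 99
        assert ages.min() <= 6 and ages.max() >= 94  # covers the range
        # round-robin batches are near-equal in size
        bc = cohort.meta["batch"].value_counts()
        assert bc.max() - bc.min() <= 1

    def test_batch_effects_enter_as_location_scale(self):
        arch = [TrajectoryArchetype("flat", baseline=1.0)]
        truth = CohortTruth(
            noise_sd=0.0, batch_offsets={"batch1": 2.0}, seed=0, n_batches=2
        )
        cohort, _ = generate_cohort(20, (1, 99), arch, truth)
        vals = cohort.values.iloc[0]
        b = cohort.meta["batch"]
        assert (vals[b == "batch0"] == 1.0).all()
        assert (vals[b == "batch1"] == 3.0).all()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"archetypes": []},
            {"age_range": (40, 40)},
            {"n_samples": 3},
        ],
    )
    def test_invalid_inputs_rejected(self, kwargs):
        base = dict(n_samples=20, age_range=(1, 99), archetypes=[
            TrajectoryArchetype("flat", baseline=1.0)
        ])
        base.update(kwargs)
        with pytest.raises(ValueError):
            generate_cohort(base["n_samples"], base["age_range"], base["archetypes"])

    def test_transient_shift_is_confined_to_window(self):
        arch = TrajectoryArchetype(
            "transient", baseline=0.0, change_age=40, half_width=8, amplitude=1.0
        )
        ages = np.arange(1, 100)
        mu = arch.mean(ages, np.zeros_like(ages))
        assert mu[ages <= 30].max() < 0.05
        assert mu[ages >= 50].min() > 0.95
        assert abs(mu[ages == 40][0] - 0.5) < 1e-6


class TestSingleCell:
    def test_null_marker_shift_yields_no_degs(self):
        clean = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cells = generate_single_cell(60, ["a", "b"], {}, n_genes=60, seed=seed)
            t = cells.obs["cell_type"]
            de = rank_sum_de(cells, (t == "a").to_numpy(), (t == "b").to_numpy())
            if (de["q"] < 0.05).sum() == 0:
                clean += 1
        assert clean >= int(0.95 * n_seeds)

    def test_marker_shift_puts_markers_on_top(self):
        markers = {f"G{i:04d}": 2.0 for i in range(10)}
        cells = generate_single_cell(
            200, ["a", "b"], {"a": markers}, n_genes=100, seed=1
        )
        t = cells.obs["cell_type"]
        Xa = cells.X[(t == "a").to_numpy()]
        Xb = cells.X[(t == "b").to_numpy()]
        effect = pd.Series(Xa.mean(axis=0) - Xb.mean(axis=0), index=cells.var_names)
        assert set(effect.nlargest(10).index) == set(markers)

    def test_same_seed_bit_identical(self):
        a = generate_single_cell(30, ["a", "b"], seed=9)
        b = generate_single_cell(30, ["a", "b"], seed=9)
        assert (a.X == b.X).all()
        pd.testing.assert_frame_equal(a.obs, b.obs)

    def test_missing_marker_gene_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            generate_single_cell(20, ["a", "b"], {"a": {"NOPE": 1.0}})

    @pytest.mark.parametrize(
        "age,group",
        [(5, "child"), (30, "young"), (65, "aged"), (90, "advanced-aged")],
    )
    def test_age_group_bins(self, age, group):
        assert assign_age_group(age) == group


class TestClonotypes:
    def test_singleton_repertoire_has_zero_inequality(self):
        tab = generate_clonotypes(
            ClonotypeTruth(distribution="singleton", cells_per_sample=50, seed=0)
        )
        for _, sub in tab.groupby("sample"):
            sizes = sub["clone_id"].value_counts().to_numpy()
            assert gini_coefficient(sizes) == 0.0
            assert expansion_index(sizes) == 0.0

    def test_identity_sharing_gives_zero_transition(self):
        truth = ClonotypeTruth(
            distribution="geometric", rate=0.3, cells_per_sample=200, seed=1
        )
        tab = generate_clonotypes(truth)
        for s in truth.subtypes:
            assert transition_index(tab, s) == 0.0
            other = [t for t in truth.subtypes if t != s][0]
            assert transition_index(tab, s, pair=other) == 0.0

    def test_geometric_clone_sizes_match_analytic_mean(self):
        # E[Geometric(p)] = 1/p; truncation to the cell budget is negligible
        # when cells_per_sample >> 1/p
        rate = 0.5
        means = []
        for seed in range(10):
            tab = generate_clonotypes(
                ClonotypeTruth(
                    distribution="geometric",
                    rate=rate,
                    cells_per_sample=2000,
                    sample_ages=(50,),
                    seed=seed,
                )
            )
            means.append(tab["clone_id"].value_counts().mean())
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - 1 / rate) < 2 * se

    def test_invalid_truth_rejected(self):
        with pytest.raises(ValueError):
            ClonotypeTruth(cells_per_sample=0)
        with pytest.raises(ValueError):
            ClonotypeTruth(sharing=np.full((2, 2), 1.5))
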