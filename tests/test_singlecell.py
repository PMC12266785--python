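"""Gene-set scoring, rank-sum DE, proportion/age correlation, frailty rule."""

import itertools

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from immunaging import (
    FrailtyRecord,
    classify_frailty,
    generate_single_cell,
    proportion_age_correlation,
    rank_sum_de,
    score_gene_set,
)


@pytest.fixture
def cells30():
    return generate_single_cell(30, ["a", "b"], n_genes=200, seed=5)


class TestScoreGeneSet:
    def test_control_pool_equal_to_set_scores_zero(self, cells30):
        gene_set = ["G0000", "G0001", "G0002"]
        out = score_gene_set(cells30, gene_set, control_pool=gene_set)
        assert np.abs(out.scores.to_numpy()).max() == 0.0

    def test_all_zero_matrix_scores_zero(self):
        cells = ad.AnnData(
            X=np.zeros((12, 40)),
            var=pd.DataFrame(index=[f"G{i:04d}" for i in range(40)]),
        )
        out = score_gene_set(cells, ["G0000", "G0001"], n_bins=4, ctrl_size=5)
        assert np.abs(out.scores.to_numpy()).max() == 0.0

    def test_matches_two_pass_mean_oracle(self, cells30):
        gene_set = ["G0000", "G0010", "G0020"]
        out = score_gene_set(cells30, gene_set, n_bins=10, ctrl_size=20, seed=3)
        X = np.asarray(cells30.X)
        names = list(cells30.var_names)
        set_idx = [names.index(g) for g in gene_set]
        ctrl_idx = [names.index(g) for g in out.control_genes]
        for i in range(cells30.n_obs):
            expected = X[i, set_idx].mean() - X[i, ctrl_idx].mean()
            assert out.scores.iloc[i] == pytest.approx(expected, abs=1e-10)

    def test_shift_invariance_at_bin_level(self, cells30):
        gene_set = ["G0000", "G0010"]
        a = score_gene_set(cells30, gene_set, n_bins=10, ctrl_size=20, seed=1)
        shifted = cells30.copy()
        shifted.X = shifted.X + 5.0
        b = score_gene_set(shifted, gene_set, n_bins=10, ctrl_size=20, seed=1)
        np.testing.assert_allclose(a.scores, b.scores, atol=1e-10)

    def test_seeded_reproducibility(self, cells30):
        a = score_gene_set(cells30, ["G0001", "G0002"], seed=9)
        b = score_gene_set(cells30, ["G0001", "G0002"], seed=9)
        assert a.control_genes == b.control_genes
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_absent_gene_set_rejected(self, cells30):
        with pytest.raises(ValueError, match="absent"):
            score_gene_set(cells30, ["NOT_A_GENE"])


class TestRankSumDE:
    def test_identical_groups_give_no_degs(self, cells30):
        mask = np.zeros(cells30.n_obs, dtype=bool)
        mask[:10] = True
        doubled = ad.AnnData(
            X=np.vstack([cells30.X[mask], cells30.X[mask]]),
            var=cells30.var.copy(),
        )
        a = np.arange(20) < 10
        out = rank_sum_de(doubled, a, ~a)
        assert out["deg"].sum() == 0
        assert (out["p"] == 1.0).all()

    def test_separated_gene_matches_exact_enumeration(self):
        # 5 vs 5, one completely separated gene: U = 25 and the exact
        # two-sided p equals 2 / C(10,5) = 2/252
        X = np.zeros((10, 2))
        X[:5, 0] = [1.0, 2.0, 3.0, 4.0, 5.0]
        X[5:, 0] = [11.0, 12.0, 13.0, 14.0, 15.0]
        X[:, 1] = np.arange(10) * 0.1  # interleaved control gene
        cells = ad.AnnData(X=X, var=pd.DataFrame(index=["sep", "ctrl"]))
        a = np.arange(10) < 5
        out = rank_sum_de(cells, ~a, a)
        assert out.loc["sep", "statistic"] == 25.0
        assert out.loc["sep", "p"] == pytest.approx(2 / 252, abs=1e-12)
        # brute-force permutation enumeration oracle
        vals = X[:, 0]
        observed = stats.rankdata(vals)[~a].sum()
        stat_dist = [
            sum(stats.rankdata(vals)[list(c)])
            for c in itertools.combinations(range(10), 5)
        ]
        p_exact = np.mean(
            [abs(s - np.mean(stat_dist)) >= abs(observed - np.mean(stat_dist))
             for s in stat_dist]
        )
        assert out.loc["sep", "p"] == pytest.approx(p_exact, abs=1e-12)

    def test_lfc_threshold_excludes_small_fold_changes(self):
        rng = np.random.default_rng(0)
        # significant rank shift but fold change below 0.25
        X = np.zeros((40, 1))
        X[:20, 0] = rng.normal(1.00, 0.01, 20)
        X[20:, 0] = rng.normal(1.05, 0.01, 20)
        cells = ad.AnnData(X=X, var=pd.DataFrame(index=["g"]))
        a = np.arange(40) >= 20
        out = rank_sum_de(cells, a, ~a)
        assert out["q"].iloc[0] < 0.05
        assert out["log2fc"].iloc[0] < 0.25
        assert not out["deg"].iloc[0]

    def test_invariant_under_monotone_transform(self, cells30):
        t = cells30.obs["cell_type"]
        a, b = (t == "a").to_numpy(), (t == "b").to_numpy()
        p1 = rank_sum_de(cells30, a, b)["p"]
        warped = cells30.copy()
        warped.X = np.exp(warped.X)  # strictly monotone
        p2 = rank_sum_de(warped, a, b)["p"]
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_small_group_rejected(self, cells30):
        a = np.arange(cells30.n_obs) < 2
        with pytest.raises(ValueError):
            rank_sum_de(cells30, a, ~a)


class TestProportions:
    def _cells(self, fractions_by_age):
        # build cells whose per-sample type fractions are exact
        rows = []
        for si, (age, fracs) in enumerate(fractions_by_age.items()):
            n = 100
            for t, f in fracs.items():
                rows += [{"sample": f"D{si}", "age": age, "cell_type": t}] * int(f * n)
        obs = pd.DataFrame(rows, index=[f"c{i}" for i in range(len(rows))])
        X = np.zeros((len(obs), 3))
        return ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=["g1", "g2", "g3"]))

    def test_linear_fraction_has_unit_correlation(self):
        cells = self._cells(
            {
                10: {"t": 0.10, "o": 0.90},
                30: {"t": 0.20, "o": 0.80},
                50: {"t": 0.30, "o": 0.70},
                70: {"t": 0.40, "o": 0.60},
            }
        )
        table, fracs = proportion_age_correlation(cells)
        assert table.loc["t", "pcc"] == pytest.approx(1.0, abs=1e-12)
        assert table.loc["t", "abs_pcc_gt_0.2"] and table.loc["t", "abs_pcc_gt_0.4"]
        np.testing.assert_allclose(fracs.sum(axis=1), 1.0, atol=1e-12)

    def test_constant_fraction_reports_zero_with_flag(self):
        cells = self._cells(
            {a: {"t": 0.5, "o": 0.5} for a in (10, 30, 50, 70)}
        )
        table, _ = proportion_age_correlation(cells)
        assert table.loc["t", "pcc"] == 0.0
        assert table.loc["t", "zero_variance"]

    def test_observed_correlation_beats_permutation_null(self):
        cells = self._cells(
            {
                10: {"t": 0.05, "o": 0.95},
                25: {"t": 0.15, "o": 0.85},
                40: {"t": 0.25, "o": 0.75},
                55: {"t": 0.35, "o": 0.65},
                70: {"t": 0.45, "o": 0.55},
                85: {"t": 0.55, "o": 0.45},
            }
        )
        table, fracs = proportion_age_correlation(cells)
        obs_pcc = abs(table.loc["t", "pcc"])
        ages = np.array([10, 25, 40, 55, 70, 85], dtype=float)
        f = fracs["t"].to_numpy()
        rng = np.random.default_rng(0)
        exceed = 0
        n_perm = 1000
        for _ in range(n_perm):
            perm = rng.permutation(ages)
            if abs(stats.pearsonr(f, perm)[0]) >= obs_pcc:
                exceed += 1
        assert exceed / n_perm < 0.01

    def test_too_few_samples_rejected(self):
        cells = self._cells({10: {"t": 0.5, "o": 0.5}, 30: {"t": 0.5, "o": 0.5}})
        with pytest.raises(ValueError):
            proportion_age_correlation(cells)


class TestFrailty:
    @pytest.mark.parametrize(
        "age,index,expected",
        [
            (60, 0.15, "non-frail"), (60, 0.20, "non-frail"), (60, 0.25, "non-frail"),
            (66, 0.15, "non-frail"), (66, 0.20, "non-frail"), (66, 0.25, "frail"),
            (70, 0.15, "non-frail"), (70, 0.20, "non-frail"), (70, 0.25, "frail"),
        ],
    )
    def test_rule_over_age_index_grid(self, age, index, expected):
        # strict inequalities: over 65 years AND index above 0.2
        rec = FrailtyRecord("d", age, int(index * 100), 100)
        assert classify_frailty(rec) == expected

    def test_index_is_deficit_fraction(self):
        rec = FrailtyRecord("d", 70, 7, 35)
        assert rec.index == pytest.approx(0.2)

    def test_invalid_records_rejected(self):
        with pytest.raises(ValueError):
            FrailtyRecord("d", 70, 1, 0)
        with pytest.raises(ValueError):
            FrailtyRecord("d", 70, 5, 4)
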