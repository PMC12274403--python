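"""Variance-floored DE, two-stage FDR, dose-response and clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from newrna.differential import (
    DegenerateFitError,
    InsufficientReplicatesError,
    adjusted_t_test,
    cluster_responses,
    de_compound,
    de_screen,
    dose_response_fit,
    two_stage_fdr,
    variance_floor,
)
from newrna.simulate import _default_sd, simulate_minibulk_screen


class TestVarianceFloor:
    def test_linear_trend_recovered_exactly(self, rng):
        means = rng.uniform(1, 10, 100)
        variances = 0.3 * means + 0.05
        floor = variance_floor(means, variances, method="linear")
        np.testing.assert_allclose(floor(means), variances, atol=1e-8)

    def test_constant_variance_predicted_flat(self, rng):
        means = rng.uniform(1, 10, 200)
        floor = variance_floor(means, np.full(200, 0.7), method="lowess")
        np.testing.assert_allclose(floor(np.array([2.0, 5.0, 9.0])), 0.7, rtol=1e-6)

    def test_lowess_tracks_generative_trend(self):
        expr, _ = simulate_minibulk_screen(
            3000, 0, replicates=2, n_controls=12, seed=5, log_scale=True
        )
        vals = expr["new"]
        m = vals.mean(axis=1).to_numpy()
        v = vals.var(axis=1, ddof=1).to_numpy()
        floor = variance_floor(m, v, method="lowess")
        true_var = _default_sd(m) ** 2
        lo, hi = np.quantile(m, [0.1, 0.9])
        mask = (m >= lo) & (m <= hi)
        rel = np.abs(floor(m[mask]) - true_var[mask]) / true_var[mask]
        assert rel.max() < 0.2

    def test_all_zero_variances_degenerate(self, rng):
        with pytest.raises(DegenerateFitError):
            variance_floor(rng.uniform(1, 5, 50), np.zeros(50))


class TestAdjustedTTest:
    def test_constant_groups_with_floor_are_null(self):
        t, p, diff = adjusted_t_test([2.0, 2.0, 2.0], [2.0] * 10, lambda m: 0.5)
        assert t == 0.0 and p == 1.0 and diff == 0.0

    def test_reduces_to_welch_when_floor_inactive(self):
        treated = np.array([4.0, 5.0, 6.0])
        control = np.array([1.5, 2.5, 1.8, 2.2, 1.9, 2.1, 1.6, 2.4, 2.0, 2.0])
        t, p, diff = adjusted_t_test(treated, control, lambda m: 0.0)
        ref = stats.ttest_ind(treated, control, equal_var=False)
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)
        assert diff == pytest.approx(treated.mean() - control.mean())

    def test_scale_equivariance(self, rng):
        treated = rng.normal(3, 1, 3)
        control = rng.normal(2, 1, 10)
        c = 7.0
        t1, _, d1 = adjusted_t_test(treated, control, lambda m: 0.5)
        t2, _, d2 = adjusted_t_test(c * treated, c * control, lambda m: 0.5 * c**2)
        assert t2 == pytest.approx(t1, rel=1e-10)
        assert d2 == pytest.approx(c * d1, rel=1e-10)

    def test_flooring_never_decreases_p(self, rng):
        for _ in range(50):
            treated = rng.normal(0.5, 0.3, 3)
            control = rng.normal(0.0, 0.3, 10)
            _, p_raw, _ = adjusted_t_test(treated, control, None)
            _, p_floor, _ = adjusted_t_test(treated, control, lambda m: 1.0)
            assert p_floor >= p_raw - 1e-12

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            adjusted_t_test([1.0], [1.0, 2.0], None)


class TestTwoStageFDR:
    def test_all_ones_stay_ones(self):
        np.testing.assert_array_equal(two_stage_fdr(np.ones(6)), np.ones(6))

    def test_hand_computed_vector(self):
        # stage 1 at 0.05/1.05 rejects 3 of 5 -> m0 = 2; step-up with
        # factor (1+alpha)*m0/i, monotonized from the largest p
        q = two_stage_fdr([0.001, 0.01, 0.02, 0.8, 0.9])
        np.testing.assert_allclose(q, [0.0021, 0.0105, 0.014, 0.378, 0.378])

    def test_matches_statsmodels_reference(self, rng):
        from statsmodels.stats.multitest import fdrcorrection_twostage

        for _ in range(50):
            p = rng.beta(0.4, 1.2, size=rng.integers(1, 40))
            ref = np.clip(fdrcorrection_twostage(p, alpha=0.05, method="bky")[1], 0, 1)
            np.testing.assert_allclose(two_stage_fdr(p), ref, atol=1e-12)

    def test_empty_input(self):
        assert len(two_stage_fdr([])) == 0

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            two_stage_fdr([0.5, 1.2])


class TestDECompound:
    def _screen(self, seed=0, effects=None, n_genes=600):
        return simulate_minibulk_screen(
            n_genes, 1, replicates=3, n_controls=12, effect_spec=effects, seed=seed
        )

    def test_spiked_gene_attains_smallest_p(self):
        expr, _ = self._screen(
            seed=1,
            effects={("g10", "cmp0"): 2.0},
        )
        res = de_compound(
            expr, "cmp0", [f"cmp0_rep{i}" for i in range(3)],
            [f"DMSO_{i}" for i in range(12)], seed=3,
        )
        assert res.loc[res["p_value"].idxmin(), "gene_id"] == "g10"
        assert res.loc[res["gene_id"] == "g10", "q_value"].iloc[0] < 0.05

    def test_fixed_seed_reproducible(self):
        expr, _ = self._screen(seed=2)
        args = (expr, "cmp0", [f"cmp0_rep{i}" for i in range(3)],
                [f"DMSO_{i}" for i in range(12)])
        a = de_compound(*args, seed=11)
        b = de_compound(*args, seed=11)
        pd.testing.assert_frame_equal(a, b)
        c = de_compound(*args, seed=12)
        assert not np.allclose(a["p_value"], c["p_value"])

    def test_null_screen_controls_false_discoveries(self):
        # global null: fraction of q < 0.05 calls stays at or below 5%
        rejected = total = 0
        for seed in range(20):
            expr, _ = self._screen(seed=100 + seed, n_genes=400)
            res = de_compound(
                expr, "cmp0", [f"cmp0_rep{i}" for i in range(3)],
                [f"DMSO_{i}" for i in range(12)], seed=seed,
            )
            rejected += (res["q_value"] < 0.05).sum()
            total += len(res)
        assert rejected / total <= 0.05

    def test_wrong_replicate_count_skipped_in_screen(self):
        expr, _ = self._screen(seed=4)
        res = de_screen(
            expr,
            {"cmp0": [f"cmp0_rep{i}" for i in range(2)]},  # only 2 reps
            [f"DMSO_{i}" for i in range(12)],
        )
        assert res.empty
        with pytest.raises(InsufficientReplicatesError):
            de_compound(expr, "cmp0", ["cmp0_rep0"], [f"DMSO_{i}" for i in range(12)])


class TestDoseResponse:
    DOSES = [1, 10, 100, 1000, 10000]

    def _values(self, per_decade, noise_sd, n_genes, seed=0, controls=2):
        rng = np.random.default_rng(seed)
        cols = {}
        doses = {}
        x0 = np.log10(0.1)
        for i, d in enumerate(self.DOSES):
            name = f"d{i}"
            cols[name] = per_decade * (np.log10(d) - x0) + rng.normal(0, noise_sd, n_genes)
            doses[name] = d
        for j in range(controls):
            name = f"ctrl{j}"
            cols[name] = rng.normal(0, noise_sd, n_genes)
            doses[name] = 0
        values = pd.DataFrame(cols, index=[f"g{i}" for i in range(n_genes)])
        return values, doses

    def test_flat_expression_gives_zero_slope(self):
        values, doses = self._values(0.0, 0.0, 5)
        res = dose_response_fit(values, doses)
        np.testing.assert_allclose(res["slope"], 0.0, atol=1e-12)
        np.testing.assert_allclose(res["p_value"], 1.0)

    def test_exact_one_log2_per_decade(self):
        values, doses = self._values(1.0, 0.0, 5)
        res = dose_response_fit(values, doses)
        np.testing.assert_allclose(res["slope"], 1.0, atol=1e-10)

    def test_controls_enter_one_decade_below_minimum(self):
        # constructed so the exact fit holds only if controls sit at 0.1 nM
        values, doses = self._values(0.7, 0.0, 3)
        res = dose_response_fit(values, doses)
        np.testing.assert_allclose(res["slope"], 0.7, atol=1e-10)
        np.testing.assert_allclose(res["intercept"], 0.7, atol=1e-10)

    def test_slope_estimates_unbiased(self):
        slopes = []
        for seed in range(20):
            values, doses = self._values(0.5, 0.2, 50, seed=seed)
            slopes.append(dose_response_fit(values, doses)["slope"].to_numpy())
        slopes = np.concatenate(slopes)
        se = slopes.std(ddof=1) / np.sqrt(len(slopes))
        assert abs(slopes.mean() - 0.5) < 3 * se

    def test_too_few_dose_levels_rejected(self):
        values = pd.DataFrame({"a": [1.0], "b": [2.0]}, index=["g"])
        with pytest.raises(ValueError):
            dose_response_fit(values, {"a": 10, "b": 100})


class TestClusterResponses:
    def test_identical_drugs_merge_at_zero(self, rng):
        v = rng.normal(size=30)
        slopes = pd.DataFrame({"d1": v, "d2": v, "d3": rng.normal(size=30)})
        res = cluster_responses(slopes)
        assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert res.labels["d1"] == res.labels["d2"]

    def test_anticorrelated_drugs_never_cluster(self, rng):
        v = rng.normal(size=30)
        slopes = pd.DataFrame({"d1": v, "d2": -v})
        res = cluster_responses(slopes, r_cutoff=0.33)
        assert res.distance.loc["d1", "d2"] == pytest.approx(2.0)
        assert res.labels["d1"] != res.labels["d2"]

    def test_merge_heights_match_manual_average_linkage(self, rng):
        a = rng.normal(size=50)
        b = 0.9 * a + 0.45 * rng.normal(size=50)
        c = rng.normal(size=50)
        slopes = pd.DataFrame({"A": a, "B": b, "C": c})
        corr = slopes.corr()
        d_ab = 1 - corr.loc["A", "B"]
        d_ac = 1 - corr.loc["A", "C"]
        d_bc = 1 - corr.loc["B", "C"]
        res = cluster_responses(slopes)
        # A,B merge first (most correlated), then C joins at the average
        assert res.linkage[0, 2] == pytest.approx(d_ab, rel=1e-10)
        assert res.linkage[1, 2] == pytest.approx((d_ac + d_bc) / 2, rel=1e-10)

    def test_constant_column_dropped_with_warning(self, rng):
        slopes = pd.DataFrame(
            {"d1": rng.normal(size=20), "d2": rng.normal(size=20), "flat": 1.0}
        )
        with pytest.warns(UserWarning, match="flat"):
            res = cluster_responses(slopes)
        assert res.dropped == ["flat"]
        assert "flat" not in res.labels.index
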