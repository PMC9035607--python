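"""Observed-scale conversion, reliabilities, and trend estimation."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr, ndtri

from stillbirth_eval.evaluation import (
    genetic_trend,
    observed_scale,
    phenotypic_trend,
    reliability,
    spline_smooth,
    underlying_solutions,
)


class TestUnderlyingSolutions:
    def test_zero_group_solution_identity(self):
        random = pd.Series({"B1": 0.1, "B2": -0.2})
        groups = {"B1": "2010", "B2": "2010"}
        eps = underlying_solutions(random, pd.Series({"2010": 0.0}), groups)
        pd.testing.assert_series_equal(eps, random)

    def test_common_shift_preserves_differences(self):
        random = pd.Series({"B1": 0.1, "B2": -0.2, "B3": 0.4})
        groups = {b: "g" for b in random.index}
        eps = underlying_solutions(random, pd.Series({"g": 0.7}), groups)
        assert np.allclose(eps - eps["B1"], random - random["B1"])

    def test_hand_summed_three_bulls(self):
        random = pd.Series({"B1": 0.10, "B2": -0.05, "B3": 0.00})
        groups = {"B1": "2008", "B2": "2008", "B3": "2012"}
        gsol = pd.Series({"2008": 0.02, "2012": -0.03})
        eps = underlying_solutions(random, gsol, groups)
        assert eps["B1"] == pytest.approx(0.12)
        assert eps["B2"] == pytest.approx(-0.03)
        assert eps["B3"] == pytest.approx(-0.03)

    def test_missing_group_raises(self):
        with pytest.raises(KeyError):
            underlying_solutions(pd.Series({"B1": 0.1}), pd.Series({"g": 0.0}), {})


class TestObservedScale:
    def test_single_base_bull_anchoring_identity(self):
        eps = pd.Series({"B1": 0.23})
        out = observed_scale(eps, ["B1"], 5.0)
        assert out["B1"] == pytest.approx(5.0, abs=1e-9)

    def test_closed_form_offset_value(self):
        # base at 5%; a bull 0.1 above the (single-bull) base mean
        eps = pd.Series({"STAR": 0.0, "B": 0.1})
        out = observed_scale(eps, ["STAR"], 5.0, anchor="linear")
        expected = 100 * (1 - ndtr(ndtri(0.95) - 0.1))
        assert out["B"] == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(6.119083621334442, abs=1e-9)

    def test_monotone_in_epsilon_and_limits(self):
        eps = pd.Series({"lo": -30.0, "a": -0.5, "b": 0.0, "c": 0.5})
        out = observed_scale(eps, ["b"], 5.0)
        assert out["lo"] < 1e-8  # eps -> -inf gives %SB -> 0
        assert out["lo"] < out["a"] < out["b"] < out["c"]

    def test_exact_anchor_base_mean_matches_base_pct(self):
        rng = np.random.default_rng(0)
        eps = pd.Series(rng.normal(0.0, 0.25, 60), index=[f"B{i}" for i in range(60)])
        out = observed_scale(eps, eps.index, 5.0, anchor="exact")
        assert out.mean() == pytest.approx(5.0, abs=0.01)

    def test_linear_anchor_matches_exact_for_tight_base(self):
        eps = pd.Series(np.linspace(-1e-4, 1e-4, 11), index=[f"B{i}" for i in range(11)])
        lin = observed_scale(eps, eps.index, 7.0, anchor="linear")
        exa = observed_scale(eps, eps.index, 7.0, anchor="exact")
        assert np.abs(lin - exa).max() < 1e-6

    def test_degenerate_base_pct_rejected(self):
        eps = pd.Series({"B1": 0.0})
        for pct in (0.0, 100.0):
            with pytest.raises(ValueError):
                observed_scale(eps, ["B1"], pct)

    def test_empty_base_rejected(self):
        with pytest.raises(ValueError):
            observed_scale(pd.Series({"B1": 0.0}), [], 5.0)


class TestReliability:
    def test_no_information_floor_and_limit(self):
        sigma_a2 = 0.016
        assert reliability(np.array([1 / sigma_a2]), sigma_a2)[0] == 0.0
        assert reliability(np.array([1e12]), sigma_a2)[0] == pytest.approx(1.0, abs=1e-6)

    def test_rejects_nonpositive_inputs(self):
        with pytest.raises(ValueError):
            reliability(np.array([0.0]), 0.016)
        with pytest.raises(ValueError):
            reliability(np.array([1.0]), 0.0)

    def test_diagonal_formula_vs_dense_pev_oracle_relationship_free(self):
        """On an unrelated-bull toy system the diagonal approximation is
        never below the exact prediction-error-variance reliability."""
        rng = np.random.default_rng(3)
        sigma_a2 = 0.05
        n_bulls = 5
        counts = np.array([2, 5, 10, 40, 100])
        # sire model with a single mean: C = [[N, n'], [n, diag(n) + I/s2]]
        N = counts.sum()
        C = np.zeros((n_bulls + 1, n_bulls + 1))
        C[0, 0] = N
        C[0, 1:] = counts
        C[1:, 0] = counts
        C[1:, 1:] = np.diag(counts + 1.0 / sigma_a2)
        Cinv = np.linalg.inv(C)
        pev = np.diag(Cinv)[1:]
        rel_exact = 1.0 - pev / sigma_a2
        d = np.diag(C)[1:]
        rel_approx = reliability(d, sigma_a2)
        # the documented upward bias: ignoring the shared mean never
        # understates reliability
        assert (rel_approx >= rel_exact - 1e-12).all()
        # and without the shared mean the diagonal is exact
        pev_diag = 1.0 / d
        assert np.allclose(1.0 - pev_diag / sigma_a2, rel_approx, atol=1e-12)

    def test_reliability_nondecreasing_in_record_count(self):
        sigma_a2 = 0.016
        d = np.array([1 / sigma_a2 + k for k in range(0, 200, 10)], dtype=float)
        rel = reliability(d, sigma_a2)
        assert (np.diff(rel) >= 0).all()


class TestTrends:
    def test_constant_series_zero_slope(self):
        series = pd.Series(5.0, index=range(2000, 2010))
        est = phenotypic_trend(series)
        assert est.slope == 0.0 and est.p_value == 1.0

    def test_noiseless_line_recovered(self):
        years = np.arange(2000, 2016)
        series = pd.Series(2.0 - 0.1 * (years - 2000), index=years)
        est = phenotypic_trend(series)
        assert est.slope == pytest.approx(-0.1, abs=1e-12)
        assert est.p_value < 1e-12

    def test_too_few_years_rejected(self):
        with pytest.raises(ValueError):
            phenotypic_trend(pd.Series({2000: 1.0, 2001: 2.0}))

    def test_injected_trend_recovered_within_2se(self):
        rng = np.random.default_rng(5)
        years = np.arange(1995, 2016)
        true_slope = -0.12
        series = pd.Series(6.0 + true_slope * (years - 1995) + rng.normal(0, 0.4, years.size),
                           index=years)
        est = phenotypic_trend(series)
        from scipy.stats import linregress

        se = linregress(years.astype(float), series.to_numpy()).stderr
        assert abs(est.slope - true_slope) < 2 * se

    def test_genetic_trend_sign_recovery_over_replicates(self):
        rng = np.random.default_rng(6)
        years = np.arange(1995, 2016)
        hits = 0
        for _ in range(10):
            pta = pd.Series(5.0 + 0.05 * (years - 1995) + rng.normal(0, 0.25, years.size),
                            index=years)
            if genetic_trend(pta).slope > 0:
                hits += 1
        assert hits >= 9

    def test_all_equal_pta_zero_slope(self):
        est = genetic_trend(pd.Series(4.2, index=range(2000, 2008)))
        assert est.slope == 0.0


class TestSplineSmooth:
    def test_noiseless_line_reproduced(self):
        years = np.arange(2000, 2012)
        series = pd.Series(1.0 + 0.3 * (years - 2000), index=years)
        sm = spline_smooth(series)
        assert np.abs(sm - series).max() < 1e-6

    def test_heavy_penalty_flattens_noise(self):
        rng = np.random.default_rng(7)
        years = np.arange(1990, 2040)
        series = pd.Series(rng.standard_normal(years.size), index=years)
        sm = spline_smooth(series, lam=1e12)
        # penalty limit is the least-squares line; for pure noise it hugs the mean
        assert sm.std() < 0.25 * series.std()
        assert abs(sm.mean() - series.mean()) < 0.1

    def test_smoother_beats_raw_on_noisy_sine(self):
        rng = np.random.default_rng(8)
        x = np.arange(0, 60)
        signal = np.sin(2 * np.pi * x / 30.0)
        noisy = signal + rng.normal(0, 0.5, x.size)
        sm = spline_smooth(pd.Series(noisy, index=x))
        assert np.mean((sm.to_numpy() - signal) ** 2) < np.mean((noisy - signal) ** 2)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            spline_smooth(pd.Series({1: 1.0, 2: 2.0, 3: 1.5, 4: 2.5}))
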