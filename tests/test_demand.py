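"""Exponential demand model: prediction, fitting, Pmax and operant summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from demandomics.demand import (
    THRESHOLD_FR_SCHEDULE,
    DemandError,
    ExponentialDemand,
    bins_to_demand_points,
    consumption_change_summary,
    doses_to_demand_points,
    fit_demand,
    pr_breakpoint,
    predict_consumption,
    solve_pmax,
)


def brute_force_pmax(q0, alpha, k=2.0):
    """Independent expenditure-grid oracle: the first local maximum of C*Q(C).

    Expenditure rises again at extreme prices because predicted consumption
    floors at Q0*10^-k, so the peak of response output is the *first* local
    maximum (the inelastic-to-elastic transition), found by coarse scan and
    grid refinement.
    """
    grid = np.geomspace(1e-8, 1e8, 8000)
    e = grid * predict_consumption(q0, alpha, grid, k=k)
    interior = np.flatnonzero((e[1:-1] > e[:-2]) & (e[1:-1] > e[2:])) + 1
    best = int(interior[0])
    lo, hi = grid[best - 1], grid[best + 1]
    for _ in range(6):
        grid = np.geomspace(lo, hi, 2000)
        e = grid * predict_consumption(q0, alpha, grid, k=k)
        best = int(np.argmax(e))
        lo = grid[max(best - 1, 0)]
        hi = grid[min(best + 1, len(grid) - 1)]
    return grid[best]


class FitLike:
    def __init__(self, q0, alpha, k=2.0):
        self.q0, self.alpha, self.k = q0, alpha, k


class TestPredict:
    def test_identity_at_zero_price(self):
        assert predict_consumption(10, 0.01, 0.0) == pytest.approx(10.0)

    def test_asymptote_is_q0_times_10_to_minus_k(self):
        assert predict_consumption(10, 0.01, 1e9, k=2) == pytest.approx(0.1, rel=1e-9)

    def test_known_value_at_price_10(self):
        # log10 Q = 1 + 2*(e^-1 - 1) = -0.26424
        assert predict_consumption(10, 0.01, 10.0) == pytest.approx(0.5442, rel=1e-4)

    def test_strictly_decreasing_in_price(self):
        # below the numerical saturation of the 10^-k floor
        prices = np.geomspace(1e-3, 300, 300)
        q = predict_consumption(7.3, 0.004, prices)
        assert (np.diff(q) < 0).all()


class TestPmax:
    def test_matches_expenditure_grid_oracle(self):
        d = solve_pmax(FitLike(10, 0.01))
        assert d.pmax == pytest.approx(2.9028, rel=1e-4)
        assert d.pmax == pytest.approx(brute_force_pmax(10, 0.01), rel=1e-4)
        assert d.standardized_pmax == pytest.approx(29.028, rel=1e-4)

    def test_omax_is_expenditure_at_pmax(self):
        fit = FitLike(10, 0.01)
        d = solve_pmax(fit)
        assert d.omax == pytest.approx(d.pmax * predict_consumption(10, 0.01, d.pmax))
        assert d.omax == pytest.approx(9.10, rel=1e-2)

    def test_pmax_scales_inversely_with_alpha(self):
        d1 = solve_pmax(FitLike(10, 0.01))
        d2 = solve_pmax(FitLike(10, 0.1))
        assert d2.pmax == pytest.approx(d1.pmax / 10, rel=1e-10)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        q0=st.floats(1.0, 100.0),
        alpha=st.floats(1e-4, 1e-1),
    )
    def test_log_log_slope_is_minus_one_at_pmax(self, q0, alpha):
        pmax = solve_pmax(FitLike(q0, alpha)).pmax
        h = 1e-6
        lo, hi = pmax * (1 - h), pmax * (1 + h)
        slope = (math.log10(predict_consumption(q0, alpha, hi))
                 - math.log10(predict_consumption(q0, alpha, lo))) / (
            math.log10(hi) - math.log10(lo)
        )
        assert slope == pytest.approx(-1.0, abs=1e-4)

    def test_degenerate_small_k_has_no_pmax(self):
        with pytest.raises(DemandError, match="degenerate"):
            solve_pmax(FitLike(10, 0.01, k=0.1))


class TestFit:
    PRICES = np.array(THRESHOLD_FR_SCHEDULE, dtype=float)

    def test_recovers_generating_parameters_on_exact_data(self):
        q = predict_consumption(20.0, 0.005, self.PRICES)
        res = fit_demand((self.PRICES, q))
        assert res.converged
        assert res.q0 == pytest.approx(20.0, rel=1e-6)
        assert res.alpha == pytest.approx(0.005, rel=1e-6)
        assert res.sse < 1e-20

    def test_rescaling_consumption_rescales_q0_and_preserves_alpha_q0(self):
        q = predict_consumption(20.0, 0.005, self.PRICES)
        r1 = fit_demand((self.PRICES, q))
        r2 = fit_demand((self.PRICES, 2 * q))
        assert r2.q0 == pytest.approx(2 * r1.q0, rel=1e-5)
        assert r2.alpha * r2.q0 == pytest.approx(r1.alpha * r1.q0, rel=1e-5)

    def test_identical_prices_unidentifiable(self):
        with pytest.raises(DemandError, match="identical"):
            fit_demand(([5.0, 5.0, 5.0], [10.0, 11.0, 9.0]))

    def test_too_few_positive_points(self):
        with pytest.raises(DemandError, match=">= 3"):
            fit_demand(([1.0, 2.0, 3.0], [10.0, 0.0, 0.0]))

    def test_zero_consumption_points_dropped_and_counted(self):
        q = predict_consumption(20.0, 0.02, self.PRICES)
        q[-2:] = 0.0
        res = fit_demand((self.PRICES, q))
        assert res.n_dropped_zero == 2
        assert res.n_points == len(self.PRICES) - 2

    def test_poisson_weights_reduce_small_count_bias(self):
        """IRLS down-weights the low-count tail, pulling estimates toward truth."""
        rng = np.random.default_rng(11)
        errs = {"none": [], "poisson": []}
        for _ in range(30):
            lam = predict_consumption(20.0, 0.005, self.PRICES)
            q = np.minimum(20, rng.poisson(lam)).astype(float)
            if (q > 0).sum() < 3:
                continue
            for w in errs:
                res = fit_demand((self.PRICES, q), weights=w)
                errs[w].append(res.q0)
        assert abs(np.median(errs["poisson"]) - 20) < abs(np.median(errs["none"]) - 20)

    def test_mle_uses_zero_bins_and_recovers_truth(self):
        rng = np.random.default_rng(12)
        q0s = []
        for _ in range(30):
            lam = predict_consumption(20.0, 0.005, self.PRICES)
            q = np.minimum(20, rng.poisson(lam)).astype(float)
            res = fit_demand((self.PRICES, q), method="mle", cap=20)
            assert res.n_dropped_zero == 0
            assert res.n_points == 11
            q0s.append(res.q0)
        assert np.median(q0s) == pytest.approx(20.0, rel=0.2)

    def test_mle_requires_integer_counts(self):
        with pytest.raises(DemandError, match="integer"):
            fit_demand((self.PRICES, np.linspace(10, 0.5, 11)), method="mle")

    def test_unknown_method_rejected(self):
        with pytest.raises(DemandError, match="method"):
            fit_demand((self.PRICES, np.ones(11)), method="wls")

    def test_summary_mentions_estimates(self):
        q = predict_consumption(20.0, 0.005, self.PRICES)
        s = ExponentialDemand(self.PRICES, q).fit().summary()
        assert "Q0" in s and "alpha" in s and "Pmax" in s

    def test_standard_errors_positive_on_noisy_data(self):
        rng = np.random.default_rng(7)
        q = predict_consumption(20.0, 0.005, self.PRICES) * 10 ** rng.normal(0, 0.05, 11)
        res = fit_demand((self.PRICES, q))
        assert res.bse_q0 > 0 and res.bse_alpha > 0

    def test_expenditure_unimodal_up_to_pmax(self):
        res = fit_demand((self.PRICES, predict_consumption(15.0, 0.01, self.PRICES)))
        grid = np.geomspace(1e-3, res.pmax * 3, 500)
        e = res.expenditure(grid)
        peak = int(np.argmax(e))
        assert (np.diff(e[: peak + 1]) > 0).all()
        assert (np.diff(e[peak:]) < 0).all()


class TestPointConversion:
    def test_bins_to_points_definitions(self):
        bins = pd.DataFrame(
            {
                "fr_value": [1, 5],
                "reinforcers_earned": [20, 18],
                "responses": [20, 90],
            }
        )
        pts = bins_to_demand_points(bins, reinforcer_magnitude=1.0)
        assert list(pts["unit_price"]) == [1.0, 5.0]
        assert list(pts["consumption"]) == [20.0, 18.0]

    def test_threshold_schedule_gives_strictly_increasing_prices(self):
        bins = pd.DataFrame(
            {
                "fr_value": THRESHOLD_FR_SCHEDULE,
                "reinforcers_earned": [5] * 11,
                "responses": [5 * f for f in THRESHOLD_FR_SCHEDULE],
            }
        )
        pts = bins_to_demand_points(bins, 1.0)
        assert len(pts) == 11
        assert (np.diff(pts["unit_price"]) > 0).all()

    def test_body_weight_normalization(self):
        bins = pd.DataFrame({"fr_value": [1], "reinforcers_earned": [10], "responses": [10]})
        pts = bins_to_demand_points(bins, 20.0, body_weight_g=25.0)
        assert pts["consumption"].iloc[0] == pytest.approx(10 * 20.0 / 25.0)

    def test_empty_bins_error(self):
        with pytest.raises(DemandError, match="empty"):
            bins_to_demand_points(pd.DataFrame(columns=["fr_value", "reinforcers_earned"]), 1.0)

    def test_dose_conversion_arithmetic(self):
        # 1 mg/kg to a 30 g mouse = 0.03 mg/injection; FR1 -> 33.33 responses/mg
        pts = doses_to_demand_points([40], [1.0], body_weight_g=30.0, fr_value=1)
        assert pts["unit_price"].iloc[0] == pytest.approx(1 / 0.03, rel=1e-9)
        assert pts["consumption"].iloc[0] == pytest.approx(40.0)

    def test_price_strictly_decreases_with_dose(self):
        pts = doses_to_demand_points([10, 10, 10, 10], [0.1, 0.3, 1.0, 3.0], 30.0)
        assert (np.diff(pts["unit_price"]) < 0).all()
        assert pts["unit_price"].iloc[3] == pytest.approx(1 / 0.09, rel=1e-9)

    def test_zero_injections_flagged(self):
        pts = doses_to_demand_points([0, 5], [0.3, 1.0], 30.0)
        assert bool(pts["zero_consumption"].iloc[0])
        assert pts["consumption"].iloc[0] == 0.0

    def test_nonpositive_dose_rejected(self):
        with pytest.raises(DemandError, match="doses"):
            doses_to_demand_points([5], [0.0], 30.0)


class TestOperantSummaries:
    LADDER = (1, 3, 5, 6, 8, 10, 14, 18, 25, 31, 38, 45, 55, 85, 110, 140, 200)

    def test_breakpoint_is_largest_completed(self):
        completed = [1, 3, 5, 6, 8, 10, 14, 18, 25]
        assert pr_breakpoint(completed, self.LADDER) == 25

    def test_no_completions_gives_zero(self):
        assert pr_breakpoint([], self.LADDER) == 0

    def test_off_ladder_ratio_rejected(self):
        with pytest.raises(DemandError, match="26"):
            pr_breakpoint([1, 3, 26], self.LADDER)

    @pytest.mark.parametrize(
        "vr3,vr5,weight,expected",
        [([100.0], [120.0], 25.0, 0.8), ([50.0], [50.0], 10.0, 0.0), ([120.0], [100.0], 25.0, -0.8)],
    )
    def test_consumption_change_sign_and_scale(self, vr3, vr5, weight, expected):
        got = consumption_change_summary({"VR3": vr3, "VR5": vr5}, weight)
        assert got == pytest.approx(expected)

    def test_missing_schedule_error(self):
        with pytest.raises(DemandError, match="VR5"):
            consumption_change_summary({"VR3": [100.0]}, 25.0)
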