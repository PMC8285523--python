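"""Stratified rank-rank hypergeometric overlap maps and the pixel statistic."""

import math
from decimal import Decimal, getcontext
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from demandomics.rrho import (
    RankedList,
    default_step,
    hypergeometric_pixel,
    quadrant_peaks,
    rank_by_metric,
    rank_by_scores,
    rrho_map_stratified,
)


def decimal_tail_neglog10(N, i, j, m) -> float:
    """High-precision oracle: -log10 P[X >= m] from integer binomials + 50-digit logs."""
    lo = max(m, max(0, i + j - N))
    num = sum(comb(j, x) * comb(N - j, i - x) for x in range(lo, min(i, j) + 1))
    den = comb(N, i)
    if num == den:
        return 0.0
    getcontext().prec = 50
    return float(-(Decimal(num) / Decimal(den)).log10())


def stats_frame(scores: dict) -> pd.DataFrame:
    return pd.DataFrame(
        {"accession": list(scores), "log2_fc": list(scores.values()), "p_value": 0.5}
    )


class TestRankByMetric:
    def test_descending_order(self):
        rl = rank_by_metric(stats_frame({"p1": 2.0, "p2": -1.0, "p3": 0.5}))
        assert rl.accessions == ("p1", "p3", "p2")

    def test_ties_broken_lexicographically(self):
        rl = rank_by_metric(stats_frame({"p2": 1.0, "p1": 1.0}))
        assert rl.accessions == ("p1", "p2")

    def test_empty_stats_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            rank_by_metric(stats_frame({}))

    def test_duplicate_accession_rejected(self):
        df = pd.DataFrame({"accession": ["p1", "p1"], "log2_fc": [1.0, 2.0], "p_value": 0.5})
        with pytest.raises(ValueError, match="duplicate"):
            rank_by_metric(df)

    def test_signed_logp_metric(self):
        df = pd.DataFrame(
            {"accession": ["p1", "p2"], "log2_fc": [1.0, -1.0], "p_value": [0.01, 0.001]}
        )
        rl = rank_by_metric(df, metric="signed_logp")
        assert rl.accessions == ("p1", "p2")
        assert rl.scores[0] == pytest.approx(2.0)
        assert rl.scores[1] == pytest.approx(-3.0)


class TestPixel:
    def test_zero_overlap_threshold_is_certain(self):
        assert hypergeometric_pixel(20, 5, 5, 0) == 0.0

    def test_full_overlap_exact_enumeration(self):
        # only C(20,5)=15504 equally likely draws contain all 5 marked items once
        assert hypergeometric_pixel(20, 5, 5, 5) == pytest.approx(math.log10(15504), rel=1e-12)

    def test_forced_overlap_is_certain(self):
        assert hypergeometric_pixel(10, 10, 10, 10) == 0.0

    def test_argument_ordering_violations(self):
        with pytest.raises(ValueError):
            hypergeometric_pixel(10, 5, 5, 6)
        with pytest.raises(ValueError):
            hypergeometric_pixel(10, 12, 5, 1)

    def test_exact_and_float_paths_agree_where_tail_is_small(self):
        v_exact = hypergeometric_pixel(200, 40, 40, 25, method="exact")
        v_float = hypergeometric_pixel(200, 40, 40, 25, method="auto")
        assert v_float == pytest.approx(v_exact, rel=1e-9)

    @pytest.mark.parametrize("N", [7, 13, 30])
    def test_matches_decimal_oracle_across_all_arguments(self, N):
        step = 1 if N < 20 else 3
        for i in range(1, N + 1, step):
            for j in range(1, N + 1, step):
                for m in range(0, min(i, j) + 1):
                    v = hypergeometric_pixel(N, i, j, m)
                    ref = decimal_tail_neglog10(N, i, j, m)
                    if ref == 0.0:
                        assert v == 0.0
                    else:
                        assert v == pytest.approx(ref, rel=1e-12)


def random_ranked_list(rng, n, prefix="g") -> RankedList:
    accs = [f"{prefix}{i:03d}" for i in range(n)]
    scores = rng.normal(0, 1, size=n)
    scores = scores[scores != 0.0]  # exact zeros would pin the up stratum
    return rank_by_scores(accs[: len(scores)], scores)


class TestStratifiedMaps:
    def test_identical_lists_concordant_peaks_dominate(self):
        rng = np.random.default_rng(1)
        rl = random_ranked_list(rng, 60)
        maps = rrho_map_stratified(rl, rl, step=1)
        pk = quadrant_peaks(maps)["peaks"]
        assert max(pk["UU"], pk["DD"]) > 5.0
        assert max(pk["UD"], pk["DU"]) < min(pk["UU"], pk["DD"])

    def test_sign_flip_of_one_list_swaps_concordant_and_discordant(self):
        rng = np.random.default_rng(2)
        rl = random_ranked_list(rng, 50)
        maps = rrho_map_stratified(rl, rl.flipped(), step=1)
        pk = quadrant_peaks(maps)["peaks"]
        assert max(pk["UD"], pk["DU"]) > max(pk["UU"], pk["DD"])

    def test_double_sign_flip_identity(self):
        rng = np.random.default_rng(3)
        a = random_ranked_list(rng, 40, "a")
        b = rank_by_scores(a.accessions, rng.normal(0, 1, size=len(a.accessions)))
        maps = rrho_map_stratified(a, b, step=1)
        flipped = rrho_map_stratified(a.flipped(), b.flipped(), step=1)
        for q, q_flip in (("UU", "DD"), ("DD", "UU"), ("UD", "DU"), ("DU", "UD")):
            np.testing.assert_array_equal(maps[q].values, flipped[q_flip].values)

    def test_transpose_symmetry(self):
        rng = np.random.default_rng(4)
        a = random_ranked_list(rng, 30, "a")
        b = rank_by_scores(a.accessions, rng.normal(0, 1, size=len(a.accessions)))
        ab = rrho_map_stratified(a, b, step=1)
        ba = rrho_map_stratified(b, a, step=1)
        np.testing.assert_array_equal(ab["UU"].values, ba["UU"].values.T)
        np.testing.assert_array_equal(ab["DD"].values, ba["DD"].values.T)
        np.testing.assert_array_equal(ab["UD"].values, ba["DU"].values.T)
        np.testing.assert_array_equal(ab["DU"].values, ba["UD"].values.T)

    def test_every_pixel_matches_exact_enumeration_small_universe(self):
        rng = np.random.default_rng(5)
        a = random_ranked_list(rng, 24, "a")
        b = rank_by_scores(a.accessions, rng.normal(0, 1, size=len(a.accessions)))
        maps = rrho_map_stratified(a, b, step=1)
        N = a.universe_size
        strata = {
            "UU": (a.up_stratum(), b.up_stratum()),
            "DD": (a.down_stratum(), b.down_stratum()),
            "UD": (a.up_stratum(), b.down_stratum()),
            "DU": (a.down_stratum(), b.up_stratum()),
        }
        for q, (sa, sb) in strata.items():
            mp = maps[q]
            for r, i in enumerate(mp.threshold_indices_i):
                for c, j in enumerate(mp.threshold_indices_j):
                    m = len(set(sa[:i]) & set(sb[:j]))
                    ref = decimal_tail_neglog10(N, int(i), int(j), m)
                    got = mp.values[r, c]
                    assert got == pytest.approx(ref, rel=1e-12, abs=1e-300)

    def test_universe_mismatch_rejected(self):
        a = rank_by_scores(["x", "y"], [1.0, -1.0])
        b = rank_by_scores(["x", "z"], [1.0, -1.0])
        with pytest.raises(ValueError, match="z"):
            rrho_map_stratified(a, b)

    def test_one_sided_list_leaves_empty_down_quadrants(self):
        a = rank_by_scores([f"p{i}" for i in range(10)], np.linspace(1, 2, 10))
        maps = rrho_map_stratified(a, a, step=1)
        assert maps["DD"].values.size == 0
        assert maps["DD"].peak == 0.0
        assert maps["UU"].peak > 0.0

    def test_default_step_bounds_grid_size(self):
        assert default_step(50) == 1
        assert default_step(1000) == 10
        assert default_step(101) == 2

    def test_quadrant_peaks_reports_argmax_location(self):
        rng = np.random.default_rng(6)
        rl = random_ranked_list(rng, 40)
        out = quadrant_peaks(rrho_map_stratified(rl, rl, step=1))
        q, i, j = out["argmax"]
        assert q in ("UU", "DD")
        assert i >= 1 and j >= 1


def test_plot_writes_image(tmp_path):
    from demandomics.rrho import plot_rrho

    rng = np.random.default_rng(7)
    rl = random_ranked_list(rng, 30)
    maps = rrho_map_stratified(rl, rl, step=1)
    out = tmp_path / "rrho.png"
    plot_rrho(maps, out, title="self comparison")
    assert out.stat().st_size > 0
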