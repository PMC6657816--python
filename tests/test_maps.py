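import math

import numpy as np
import pytest

from primedyn import (
    CalibrationError,
    ModelParameters,
    analytic_boundaries,
    baseline_strategies,
    benefit_map,
    best_strategy,
    calibrate_baseline,
    combined_strategy_map,
    cost_ceiling,
    expected_benefit_under_predictability,
    relative_benefit,
)


class TestBestStrategy:
    def test_short_stress_favors_earlier_among_primed(self, params, strategies):
        assert best_strategy(params, 20.0, 0.3, strategies, include_naive=False) == ("earlier",)

    def test_short_stress_high_cost_is_naive(self, params, strategies):
        assert best_strategy(params, 20.0, 0.9, strategies) == ("naive",)
        # at the baseline cost the short-stress saving is also insufficient
        assert best_strategy(params, 20.0, 0.3, strategies) == ("naive",)

    def test_intermediate_stress_ties_earlier_and_faster(self, params, strategies):
        assert best_strategy(params, 50.0, 0.3, strategies, include_naive=False) == (
            "earlier",
            "faster",
        )

    def test_long_stress_favors_stronger(self, params, strategies):
        winners = best_strategy(params, 150.0, 0.3, strategies)
        assert winners == ("stronger",)
        assert relative_benefit(params, strategies["stronger"], TD=150.0, c_P=0.3) > 0.0

    def test_empty_strategy_set_rejected(self, params):
        with pytest.raises(ValueError):
            best_strategy(params, 20.0, 0.3, {}, include_naive=True)


class TestBenefitMap:
    def test_baseline_cell_is_all_way_tie(self, params, strategies):
        smap = benefit_map(params, [75.0], [0.3], strategies)
        assert smap.winner_at(75.0, 0.3) == ("earlier", "faster", "naive", "stronger")
        assert np.allclose(smap.data["benefit"], 0.0, atol=1e-9)

    def test_costless_priming_never_loses(self, params, strategies):
        smap = benefit_map(params, np.linspace(5.0, 150.0, 20), [0.0], strategies)
        assert not smap.data["winner"].str.contains("naive").any()

    def test_winner_attains_max_benefit(self, params, strategies):
        smap = benefit_map(params, [10.0, 40.0, 100.0], [0.1, 0.3], strategies)
        for (_, _), cell in smap.data.groupby(["TD", "c_P"]):
            winners = set(cell.iloc[0]["winner"].split("|")) - {"naive"}
            best = cell["benefit"].max()
            for w in winners:
                b = cell.loc[cell.strategy == w, "benefit"].iloc[0]
                assert b >= best - smap.eps

    def test_region_classification_stable_under_refinement(self, params, strategies):
        coarse_td = np.linspace(5.0, 150.0, 15)
        fine_td = np.linspace(5.0, 150.0, 29)  # nested: keeps the coarse points
        coarse = benefit_map(params, coarse_td, [0.1], strategies)
        fine = benefit_map(params, fine_td, [0.1], strategies)
        for td in coarse_td:
            assert coarse.winner_at(td, 0.1) == fine.winner_at(td, 0.1)


class TestAnalyticBoundaries:
    def test_critical_durations(self, params, strategies):
        bounds = analytic_boundaries(params, strategies)
        # earlier and faster savings coincide once both are at the floor:
        # L_p + buildup = 1 + 25 (the calibrated earlier response is the later one)
        assert bounds["td_tie_onset"] == pytest.approx(26.0, abs=1e-9)
        assert bounds["td_naive_response_complete"] == pytest.approx(30.0)
        assert bounds["td_stronger_takeover"] == pytest.approx(75.0, abs=1e-6)
        assert bounds["stronger_benefit_slope"] == pytest.approx(
            params.m_R - strategies["stronger"].m_Rp
        )

    def test_boundaries_agree_with_grid_winners(self, params, strategies):
        bounds = analytic_boundaries(params, strategies)
        step = 1.0
        for td_star, before, after in [
            (bounds["td_tie_onset"], ("earlier",), ("earlier", "faster")),
            (bounds["td_stronger_takeover"], ("earlier", "faster"), ("stronger",)),
        ]:
            assert best_strategy(params, td_star - step, 0.1, strategies, include_naive=False) == before
            assert best_strategy(params, td_star + step, 0.1, strategies, include_naive=False) == after

    def test_cost_ceiling_plateaus_at_baseline_cost(self, params, strategies):
        # beyond the buildup, earlier/faster can compensate exactly c_PB = 0.3
        for kind in ("earlier", "faster"):
            assert cost_ceiling(params, strategies[kind], 30.0) == pytest.approx(0.3, abs=1e-9)
            assert cost_ceiling(params, strategies[kind], 150.0) == pytest.approx(0.3, abs=1e-9)
            assert cost_ceiling(params, strategies[kind], 20.0) < 0.3
        # the stronger response keeps gaining with stress duration
        assert cost_ceiling(params, strategies["stronger"], 150.0) > 0.3

    def test_stronger_benefit_grows_linearly_beyond_floor(self, params, strategies):
        delta = params.m_R - strategies["stronger"].m_Rp
        b1 = math.log1p(relative_benefit(params, strategies["stronger"], TD=100.0, c_P=0.3))
        b2 = math.log1p(relative_benefit(params, strategies["stronger"], TD=120.0, c_P=0.3))
        assert (b2 - b1) / 20.0 == pytest.approx(delta, rel=1e-9)


class TestCostRankInvariance:
    def test_primed_ranking_independent_of_cost(self, params, strategies):
        rng = np.random.default_rng(5)
        tds = np.linspace(5.0, 150.0, 10)
        costs = rng.uniform(0.0, 0.9, size=20)
        for td in tds:
            reference = best_strategy(params, td, 0.0, strategies, include_naive=False)
            for cp in costs:
                assert best_strategy(params, td, cp, strategies, include_naive=False) == reference


class TestRobustnessToParameterPerturbations:
    """The earlier -> tie -> stronger layout survives parameter changes.

    The perturbation ranges are the neighborhood within which the baseline
    scenario itself stays feasible (the earlier response can save at most
    L (m_I - m_R), which caps how far g_I, L or m_I may move at c_PB = 0.3).
    """

    @pytest.mark.parametrize(
        "changes",
        [
            {"g_I": 0.0244, "m_I": 0.0488, "m_R": 0.0122},
            {"g_I": 0.0586, "m_I": 0.1172, "m_R": 0.0293},
            {"m_I": 0.08, "m_R": 0.02},
            {"m_I": 0.1464, "m_R": 0.0366},
            {"s_R": 0.021},
            {"s_R": 0.045},
            {"L": 4.2},
            {"L": 7.5},
        ],
    )
    def test_layout_preserved(self, changes):
        p = ModelParameters(**changes)
        strategies = baseline_strategies(p)
        onset = p.L + p.buildup
        seq = [
            best_strategy(p, td, 0.05, strategies, include_naive=False)
            for td in (0.6 * onset, 0.5 * (onset + 75.0), 110.0)
        ]
        assert seq[0] == ("earlier",)
        assert seq[1] == ("earlier", "faster")
        assert seq[2] == ("stronger",)

    def test_faster_naive_response_shrinks_earlier_region(self, params):
        # a higher naive s_R reduces t_R and the earlier-only region with it
        for lo, hi in [(0.03, 0.045), (0.021, 0.03)]:
            b_lo = analytic_boundaries(params.replace(s_R=lo), baseline_strategies(params.replace(s_R=lo)))
            b_hi = analytic_boundaries(params.replace(s_R=hi), baseline_strategies(params.replace(s_R=hi)))
            assert b_hi["td_tie_onset"] < b_lo["td_tie_onset"]

    def test_infeasible_perturbation_is_explicit(self, params):
        with pytest.raises(CalibrationError):
            baseline_strategies(params.replace(L=2.5))  # lag too short to repay c_PB


class TestPredictability:
    def test_perfect_cue_recovers_relative_benefit(self, params, strategies):
        for kind in ("earlier", "faster", "stronger"):
            full = relative_benefit(params, strategies[kind], TD=40.0, c_P=0.2)
            assert expected_benefit_under_predictability(
                params, strategies[kind], 40.0, 0.2, 1.0
            ) == pytest.approx(full, rel=1e-12)

    def test_false_cue_leaves_cost_only(self, params, strategies):
        expected = math.exp(-0.2928) - 1.0
        for kind in ("earlier", "faster", "stronger"):
            assert expected_benefit_under_predictability(
                params, strategies[kind], 75.0, 0.3, 0.0
            ) == pytest.approx(expected, rel=1e-12)

    def test_ranking_invariant_in_predictability(self, params, strategies):
        kinds = ("earlier", "faster", "stronger")
        for td, cp in [(20.0, 0.2), (50.0, 0.3), (150.0, 0.4)]:
            rankings = []
            for p_cue in (0.05, 0.3, 0.7, 1.0):
                vals = {
                    k: expected_benefit_under_predictability(params, strategies[k], td, cp, p_cue)
                    for k in kinds
                }
                rankings.append(tuple(sorted(kinds, key=lambda k: -round(vals[k], 12))))
            assert len(set(rankings)) == 1

    def test_invalid_probability_rejected(self, params, strategies):
        with pytest.raises(ValueError):
            expected_benefit_under_predictability(params, strategies["earlier"], 40.0, 0.2, 1.5)


class TestCombinedStrategies:
    def test_pair_winners_swap_with_stress_duration(self, params, all_strategies):
        pairs = {k: v for k, v in all_strategies.items() if "+" in k}
        smap = combined_strategy_map(params, [20.0, 150.0], 0.3, pairs)
        assert smap.winner_at(20.0, 0.3) == ("earlier+faster",)
        assert smap.winner_at(150.0, 0.3) == ("faster+stronger",)

    def test_crossover_is_a_tie(self, params, all_strategies):
        from scipy.optimize import brentq

        ef, fs = all_strategies["earlier+faster"], all_strategies["faster+stronger"]
        gap = lambda td: relative_benefit(params, ef, TD=td, c_P=0.3) - relative_benefit(
            params, fs, TD=td, c_P=0.3
        )
        td_star = brentq(gap, 30.0, 150.0, xtol=1e-12)
        assert 60.0 < td_star < 85.0
        assert abs(gap(td_star)) < 1e-9
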