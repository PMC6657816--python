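"""Strategy maps: which primed response wins where.

Grid scans over stress duration TD and priming cost c_P classify each cell
by the most beneficial response. In the exponential model the ranking among
primed strategies is independent of c_P (the cost penalizes all strategies
identically), so the region structure is governed by the mortality-integral
savings alone: the earlier response wins while the defense is still
building up (TD below the lag-plus-buildup duration), earlier and faster
tie once the response floor has been reached, and the stronger response
takes over beyond the baseline duration, where its lower floor accumulates
a linearly growing advantage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core import StressTimeline
from .params import ModelParameters
from .strategies import (
    PrimedStrategy,
    mortality_saving,
    relative_benefit,
    required_saving,
)

__all__ = [
    "StrategyMap",
    "best_strategy",
    "benefit_map",
    "analytic_boundaries",
    "cost_ceiling",
    "expected_benefit_under_predictability",
    "combined_strategy_map",
]


@dataclass
class StrategyMap:
    """Long-format map of per-cell strategy benefits and winners."""

    data: pd.DataFrame  # columns: TD, c_P, strategy, benefit, winner
    td_grid: np.ndarray
    cp_grid: np.ndarray
    eps: float

    def winners(self) -> pd.DataFrame:
        """Pivot of winner labels, rows TD x columns c_P."""
        cells = self.data.drop_duplicates(["TD", "c_P"])
        return cells.pivot(index="TD", columns="c_P", values="winner")

    def winner_at(self, TD: float, c_P: float) -> tuple[str, ...]:
        cells = self.data[(self.data.TD == TD) & (self.data.c_P == c_P)]
        if cells.empty:
            raise KeyError(f"({TD}, {c_P}) not on the map grid")
        return tuple(cells.iloc[0]["winner"].split("|"))

    def primed_fraction(self) -> float:
        """Fraction of cells where some primed strategy strictly beats naive."""
        cells = self.data.drop_duplicates(["TD", "c_P"])
        return float((~cells["winner"].str.contains("naive")).mean())


def _winner_set(benefits: Mapping[str, float], eps: float, include_naive: bool) -> tuple[str, ...]:
    mx = max(benefits.values())
    winners = sorted(k for k, b in benefits.items() if b >= mx - eps)
    if include_naive:
        if mx < -eps:
            return ("naive",)
        if mx <= eps:
            winners = sorted(set(winners) | {"naive"})
    return tuple(winners)


def best_strategy(
    params: ModelParameters,
    TD: float,
    c_P: float,
    strategies: Mapping[str, PrimedStrategy],
    eps: float = 1e-9,
    include_naive: bool = True,
    model: str = "exponential",
) -> tuple[str, ...]:
    """Most beneficial strategy at (TD, c_P); ties within ``eps`` reported as a set.

    With ``include_naive`` (the default), cells where every primed benefit is
    negative are labeled ``("naive",)`` and ties at zero include naive. With
    ``include_naive=False`` the ranking is among the primed strategies only
    (in the exponential model this ranking is the same for every c_P).
    """
    primed = {k: s for k, s in strategies.items() if k != "naive"}
    if not primed:
        raise ValueError("strategy set must contain at least one primed strategy")
    benefits = {k: relative_benefit(params, s, TD=TD, c_P=c_P, model=model) for k, s in primed.items()}
    return _winner_set(benefits, eps, include_naive)


def benefit_map(
    params: ModelParameters,
    td_grid: Sequence[float],
    cp_grid: Sequence[float],
    strategies: Mapping[str, PrimedStrategy],
    eps: float = 1e-9,
    include_naive: bool = True,
    model: str = "exponential",
) -> StrategyMap:
    """Apply :func:`best_strategy` to every (TD, c_P) cell of a grid."""
    td_grid = np.asarray(list(td_grid), dtype=float)
    cp_grid = np.asarray(list(cp_grid), dtype=float)
    if td_grid.size == 0 or cp_grid.size == 0:
        raise ValueError("grids must be non-empty")
    primed = {k: s for k, s in strategies.items() if k != "naive"}
    rows = []
    for td in td_grid:
        for cp in cp_grid:
            benefits = {
                k: relative_benefit(params, s, TD=td, c_P=cp, model=model)
                for k, s in primed.items()
            }
            winner = "|".join(_winner_set(benefits, eps, include_naive))
            for k, b in benefits.items():
                rows.append({"TD": td, "c_P": cp, "strategy": k, "benefit": b, "winner": winner})
    return StrategyMap(pd.DataFrame(rows), td_grid, cp_grid, eps)


def cost_ceiling(params: ModelParameters, strategy: PrimedStrategy, TD: float) -> float:
    """Maximal priming cost a strategy can compensate at stress duration TD.

    The benefit is zero when g_I c_P (t_TS - t_P) equals the mortality
    saving; the ceiling grows with TD until the strategy's full saving is
    accumulated (earlier/faster) or indefinitely (stronger).
    """
    window = params.g_I * (params.t_TS - params.t_P)
    if window == 0.0:
        return math.inf
    return min(mortality_saving(params, strategy, TD=TD) / window, 1.0)


def analytic_boundaries(
    params: ModelParameters,
    strategies: Mapping[str, PrimedStrategy],
    td_b: float = 75.0,
    c_pb: float = 0.3,
) -> dict[str, float]:
    """Critical durations and slopes of the exponential-model map.

    Returns the earlier-to-tie boundary, the naive response-completion
    duration (lag plus buildup), the tie-to-stronger boundary (the baseline
    duration, where the stronger saving overtakes the earlier/faster
    plateau), and the stronger strategy's linear benefit growth rate in TD
    beyond its effective t_R (the calibrated floor saving delta = m_R - m_Rp
    per unit TD).

    Note on the tie onset: under baseline calibration the earlier and faster
    savings are *exactly* equal from the moment both primed responses have
    reached the floor — max of their effective t_R, relative to t_TS (26 t
    with the default fixture) — and not only once the naive response
    completes (30 t): on the band in between, both primed strategies gain on
    the still-declining naive response at the identical rate.
    """
    naive_tl = StressTimeline.from_params(params.replace(TD=td_b))
    td_naive_complete = naive_tl.t_R - naive_tl.t_TS
    td_tie = td_naive_complete
    if "earlier" in strategies and "faster" in strategies:
        td_tie = max(
            StressTimeline.from_params(params.replace(TD=td_b), strategies[k]).t_R
            for k in ("earlier", "faster")
        ) - params.t_TS
    out = {
        "td_tie_onset": td_tie,
        "td_naive_response_complete": td_naive_complete,
        "td_stronger_takeover": td_b,
    }
    stronger = strategies.get("stronger")
    if stronger is not None:
        delta = params.m_R - stronger.m_Rp
        out["stronger_benefit_slope"] = delta
        # solve where the stronger saving crosses the earlier/faster plateau
        plateau = mortality_saving(params, strategies["earlier"], TD=max(td_b, 2 * td_tie)) \
            if "earlier" in strategies else required_saving(params, c_pb)

        def gap(td: float) -> float:
            return mortality_saving(params, stronger, TD=td) - plateau

        hi = 10.0 * td_b
        if gap(td_tie) < 0.0 < gap(hi):
            out["td_stronger_takeover"] = float(brentq(gap, td_tie, hi, xtol=1e-10))
    return out


def expected_benefit_under_predictability(
    params: ModelParameters,
    strategy: PrimedStrategy,
    TD: float,
    c_P: float,
    p: float,
) -> float:
    """Expected relative benefit when the cue predicts the trigger with probability p.

    With probability p the triggering stress follows the cue and the primed
    population realizes its full benefit; with probability 1-p no stress
    follows and the primed population retains only the cost penalty while
    the naive one is unstressed. The expectation is taken on log fitness:
    E[log(S_p/S_n)] = p (dM - cost) + (1-p)(-cost) = -cost + p dM.
    Rankings among strategies are therefore invariant for every p > 0.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"predictability p must lie in [0, 1], got {p}")
    pp = params.replace(TD=TD, c_P=c_P)
    log_with_trigger = math.log1p(relative_benefit(pp, strategy))
    log_without = -required_saving(pp)
    return math.expm1(p * log_with_trigger + (1.0 - p) * log_without)


def combined_strategy_map(
    params: ModelParameters,
    td_grid: Sequence[float],
    c_P: float,
    pairs: Mapping[str, PrimedStrategy],
    eps: float = 1e-9,
) -> StrategyMap:
    """Winner among combined (two-parameter) strategies along a TD grid."""
    return benefit_map(params, td_grid, [c_P], pairs, eps=eps, include_naive=False)
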