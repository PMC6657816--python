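"""Four-strategy community under generalized Lotka-Volterra competition.

Each population i follows
    dS_i/dt = g_i(t) S_i (1 - (S_i + alpha * sum_{j!=i} S_j)/K) - m_i(t) S_i,
with a joint carrying capacity K and interaction strength alpha in [0, 1]
(alpha = 0 decouples the populations into independent logistic dynamics;
alpha = 1 makes the density feedback depend on the total community size
only). The standard community pairs one naive population (non-primeable, no
priming cost) with the three baseline-calibrated primed responses, all of
which pay the growth cost c_P during the priming window.

By default the community starts at joint capacity (K/4 per population), an
established community disturbed by the stress. Note a structural property
of this equation: at alpha = 1 the density factor is common to all
populations, so between-population log-size differences reduce exactly to
differences of the time-integrated rates — strategies with equal mortality
integrals (earlier and faster beyond the buildup) tie exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .core import StressTimeline, Trajectory, resolve_response
from .params import ModelParameters, ParameterError
from .strategies import PrimedStrategy, baseline_strategies

__all__ = ["CommunityResult", "simulate_community", "community_strategy_map"]


@dataclass
class CommunityResult:
    """Shared-time trajectories of the community populations."""

    times: np.ndarray
    sizes: dict[str, np.ndarray]
    alpha: float
    K: float

    def trajectory(self, label: str) -> Trajectory:
        return Trajectory(self.times, self.sizes[label], label=label)

    def final_sizes(self) -> dict[str, float]:
        return {k: float(v[-1]) for k, v in self.sizes.items()}

    def to_frame(self) -> pd.DataFrame:
        frames = [
            pd.DataFrame({"time": self.times, "size": v, "strategy": k})
            for k, v in self.sizes.items()
        ]
        return pd.concat(frames, ignore_index=True)


def _community_system(
    params: ModelParameters,
    strategies: Mapping[str, PrimedStrategy],
    alpha: float,
    K: float,
    primeable: Mapping[str, bool],
):
    labels = list(strategies)
    effs = [resolve_response(params, strategies[k]) for k in labels]
    lag = np.array([e.L for e in effs])
    slope = np.array([e.s_R * params.m_I for e in effs])
    floor = np.array([e.m_R for e in effs])
    pays_cost = np.array([primeable[k] for k in labels])
    g_I, c_P, m_I = params.g_I, params.c_P, params.m_I
    t_P, t_TS, t_TE = params.t_P, params.t_TS, params.t_TE

    def rhs(t: float, S: np.ndarray) -> np.ndarray:
        g = np.full(len(labels), g_I)
        if t_P <= t < t_TS:
            g[pays_cost] = g_I * (1.0 - c_P)
        if t_TS <= t <= t_TE:
            u = t - t_TS
            m = np.where(u < lag, m_I, np.maximum(m_I - slope * (u - lag), floor))
        else:
            m = np.zeros(len(labels))
        total = S.sum()
        load = (S + alpha * (total - S)) / K
        return g * S * (1.0 - load) - m * S

    return labels, rhs


def simulate_community(
    params: ModelParameters,
    strategies: Mapping[str, PrimedStrategy] | None = None,
    alpha: float = 1.0,
    K: float | None = None,
    TD: float | None = None,
    c_P: float | None = None,
    S0: float | Mapping[str, float] | None = None,
    t_end: float | None = None,
    n: int = 301,
    primeable: Mapping[str, bool] | None = None,
    rtol: float = 1e-10,
    extra_times: Sequence[float] | None = None,
) -> CommunityResult:
    """Integrate the coupled community dynamics on [0, t_end].

    ``strategies`` defaults to naive plus the three baseline-calibrated
    primed responses; ``S0`` defaults to K divided by the number of
    populations (community at joint capacity). Populations with a naive
    strategy are treated as non-primeable (no priming cost) unless
    ``primeable`` states otherwise.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ParameterError(f"alpha must lie in [0, 1], got {alpha}")
    p = params
    if TD is not None:
        p = p.replace(TD=TD)
    if c_P is not None:
        p = p.replace(c_P=c_P)
    if K is None:
        K = p.K
    if not (math.isfinite(K) and K > 0.0):
        raise ParameterError(f"community model requires finite K > 0, got {K}")
    if strategies is None:
        strategies = baseline_strategies(p)
    if primeable is None:
        primeable = {k: s.kind != "naive" for k, s in strategies.items()}
    if t_end is None:
        t_end = p.t_TE
    if S0 is None:
        S0 = K / len(strategies)
    if not isinstance(S0, Mapping):
        S0 = {k: float(S0) for k in strategies}

    labels, rhs = _community_system(p, strategies, alpha, K, primeable)
    y0 = np.array([S0[k] for k in labels], dtype=float)

    bks = sorted(
        {b for k in labels for b in _breaks(p, strategies[k]) if 0.0 < b < t_end}
    )
    grids = [np.linspace(0.0, t_end, n), np.asarray(bks)]
    if extra_times is not None:
        extras = np.asarray(list(extra_times), dtype=float)
        grids.append(extras[(extras >= 0.0) & (extras <= t_end)])
    times = np.unique(np.concatenate(grids))
    edges = [0.0] + bks + [t_end]
    sizes = np.empty((len(labels), times.size))
    y = y0
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (times >= lo) & (times <= hi)
        if hi > lo:
            t_eval = np.unique(np.concatenate([times[mask], [lo, hi]]))
            sol = solve_ivp(rhs, (lo, hi), y, method="DOP853", t_eval=t_eval,
                            rtol=rtol, atol=1e-10 * K)
            if not sol.success:  # pragma: no cover - defensive
                raise RuntimeError(f"community integration failed on [{lo}, {hi}]: {sol.message}")
            idx = {t: i for i, t in enumerate(sol.t)}
            cols = [idx[t] for t in times[mask]]
            sizes[:, mask] = sol.y[:, cols]
            y = sol.y[:, -1]
        else:
            sizes[:, mask] = y[:, None]
    return CommunityResult(times, {k: sizes[i] for i, k in enumerate(labels)}, alpha, K)


def _breaks(params: ModelParameters, strategy: PrimedStrategy) -> list[float]:
    tl = StressTimeline.from_params(params, strategy)
    return [params.t_P, tl.t_TS, tl.t_L, tl.t_R, tl.t_TE]


def community_strategy_map(
    params: ModelParameters,
    td_grid: Sequence[float],
    cp_grid: Sequence[float],
    alpha: float,
    strategies: Mapping[str, PrimedStrategy] | None = None,
    eps: float = 1e-6,
    S0: float | None = None,
    K: float | None = None,
) -> pd.DataFrame:
    """Winning strategy (largest population at t_TE) per (TD, c_P) cell.

    The mortality schedule before t_TE does not depend on TD, so one
    integration per cost value serves the whole TD column; the winner at
    stress duration TD is read off the shared trajectory at t_TS + TD.
    Ties within relative tolerance ``eps`` are reported as a joined set.
    """
    td_grid = np.asarray(list(td_grid), dtype=float)
    cp_grid = np.asarray(list(cp_grid), dtype=float)
    if td_grid.size == 0 or cp_grid.size == 0:
        raise ValueError("grids must be non-empty")
    if strategies is None:
        strategies = baseline_strategies(params)
    td_max = float(td_grid.max())
    rows = []
    for cp in cp_grid:
        res = simulate_community(
            params,
            strategies,
            alpha=alpha,
            K=K,
            TD=td_max,
            c_P=cp,
            S0=S0,
            t_end=params.t_TS + td_max,
            n=max(301, int(2 * td_max)),
            extra_times=params.t_TS + td_grid,
        )
        labels = list(res.sizes)
        for td in td_grid:
            t = params.t_TS + td
            finals = {k: float(np.interp(t, res.times, res.sizes[k])) for k in labels}
            mx = max(finals.values())
            winners = sorted(k for k, v in finals.items() if v >= mx * (1.0 - eps))
            for k, v in finals.items():
                rows.append(
                    {
                        "TD": td,
                        "c_P": cp,
                        "alpha": alpha,
                        "strategy": k,
                        "size": v,
                        "winner": "|".join(winners),
                    }
                )
    return pd.DataFrame(rows)
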