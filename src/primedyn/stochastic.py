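"""Stochastic birth-death simulation of the stress phase and extinction risk.

Only the stress window [t_TS, t_TE] is simulated: each individual replicates
with propensity g_I*S and dies with the piecewise death schedule of the
deterministic model. Priming costs are realized as a reduced initial size at
stress onset, matching the deterministic growth deficit of the priming
phase. Extinction probability is the fraction of Monte-Carlo runs absorbed
at zero before the stress ends.

Two samplers are provided: the classical direct method with propensities
re-evaluated at every event (and a forced re-evaluation cap on the waiting
time, bounding the staleness error of the declining death rate), and an
exact thinning (rejection) sampler used as a cross-check. An analytic
benchmark for the extinction probability of the time-inhomogeneous linear
birth-death process (Kendall's formula) is included as an independent
oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.stats import binomtest

from . import _kernels
from .core import resolve_response
from .params import ModelParameters
from .strategies import PrimedStrategy

__all__ = [
    "StochasticRun",
    "ExtinctionEstimate",
    "initial_sizes_from_costs",
    "with_stress_intensity",
    "gillespie_run",
    "extinction_probability",
    "extinction_scan",
    "branching_extinction_probability",
]

DT_MAX = 0.1  # forced propensity re-evaluation interval, time units


@dataclass
class StochasticRun:
    """One jump trajectory of the stress window (times relative to t_TS)."""

    times: np.ndarray
    sizes: np.ndarray
    extinct: bool
    seed: int

    @property
    def final_size(self) -> int:
        return int(self.sizes[-1])


@dataclass(frozen=True)
class ExtinctionEstimate:
    """Monte-Carlo extinction probability with a 95% binomial CI."""

    n_runs: int
    n_extinct: int
    probability: float
    ci_low: float
    ci_high: float
    mean_final: float
    se_final: float


def initial_sizes_from_costs(S_np0: float, c_P: float, params: ModelParameters) -> int:
    """Primed initial size matching the deterministic priming-phase deficit.

    S_p0 = round(S_np0 * exp(-g_I c_P (t_TS - t_P))).
    """
    if S_np0 <= 0:
        raise ValueError(f"S_np0 must be > 0, got {S_np0}")
    deficit = params.g_I * c_P * (params.t_TS - params.t_P)
    s = int(round(S_np0 * math.exp(-deficit)))
    if s == 0:
        raise ValueError(
            f"priming cost c_P={c_P} drives the initial size to zero (S_np0={S_np0})"
        )
    return s


def with_stress_intensity(
    params: ModelParameters, strategy: PrimedStrategy, m_I: float
) -> tuple[ModelParameters, PrimedStrategy]:
    """Rescale the stress intensity: all mortality levels scale with m_I.

    The initial mortality, the naive floor and a calibrated stronger floor
    are multiplied by m_I / params.m_I; the normalized slope s_R (and a
    faster strategy's s_Rp) and the lag are intensity-invariant, so the
    response geometry (lag, buildup duration) is preserved.
    """
    if params.m_I <= 0.0:
        raise ValueError("cannot rescale from a zero-intensity parameter set")
    factor = m_I / params.m_I
    p2 = params.replace(m_I=m_I, m_R=params.m_R * factor)
    if strategy.m_Rp is not None:
        strategy = PrimedStrategy(strategy.kind, L_p=strategy.L_p, s_Rp=strategy.s_Rp,
                                  m_Rp=strategy.m_Rp * factor)
    return p2, strategy


def _kernel_args(params: ModelParameters, response: object | None) -> tuple[float, ...]:
    eff = resolve_response(params, response)
    slope = eff.s_R * params.m_I
    a = eff.L
    b = a + ((params.m_I - eff.m_R) / slope if slope > 0.0 and params.m_I > 0.0 else 0.0)
    return params.g_I, params.m_I, a, slope, b, eff.m_R


def gillespie_run(
    params: ModelParameters,
    response: object | None = None,
    S0: int = 1000,
    seed: int = 0,
    method: str = "direct",
    dt_max: float = DT_MAX,
) -> StochasticRun:
    """Simulate one stress window, recording every birth/death event.

    Pure-Python reference implementation of the same algorithms as the
    compiled ensemble kernels; sizes change by exactly +-1 per event and the
    state 0 is absorbing.
    """
    if S0 < 1 or S0 != int(S0):
        raise ValueError(f"S0 must be a positive integer, got {S0}")
    gI, mI, a, slope, b, mRf = _kernel_args(params, response)
    TD = params.TD
    rng = np.random.default_rng(seed)

    def death(t: float) -> float:
        if t < a:
            return mI
        if t < b:
            return mI - slope * (t - a)
        return mRf

    t, S = 0.0, int(S0)
    times, sizes = [0.0], [S]
    while S > 0 and t < TD:
        if method == "direct":
            total = (gI + death(t)) * S
            if total <= 0.0:
                break
            dt = rng.exponential(1.0 / total)
            if dt > dt_max:
                t += dt_max
                continue
            t += dt
            if t >= TD:
                break
            if rng.random() * total < gI * S:
                S += 1
            else:
                S -= 1
        elif method == "thinning":
            bound = (gI + death(t)) * S
            if bound <= 0.0:
                break
            t += rng.exponential(1.0 / bound)
            if t >= TD:
                break
            v = rng.random() * bound
            if v < gI * S:
                S += 1
            elif v < gI * S + death(t) * S:
                S -= 1
            else:
                continue  # thinned: no event recorded
        else:
            raise ValueError(f"unknown method {method!r}")
        times.append(t)
        sizes.append(S)
    times.append(min(t, TD))
    sizes.append(S)
    return StochasticRun(np.asarray(times), np.asarray(sizes, dtype=int), extinct=(S == 0), seed=seed)


def _run_seeds(seed: int, n_runs: int) -> np.ndarray:
    # independent per-run substreams, prefix-stable in n_runs
    state = np.random.SeedSequence(seed).generate_state(n_runs, dtype=np.uint32)
    return (state & np.uint32(0x7FFFFFFF)).astype(np.int64)


def extinction_probability(
    params: ModelParameters,
    response: object | None = None,
    S0: int = 1000,
    n_runs: int = 10_000,
    seed: int = 0,
    method: str = "direct",
    dt_max: float = DT_MAX,
) -> ExtinctionEstimate:
    """Monte-Carlo extinction probability over independent seeded runs."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if S0 < 1:
        raise ValueError("S0 must be >= 1")
    gI, mI, a, slope, b, mRf = _kernel_args(params, response)
    seeds = _run_seeds(seed, n_runs)
    finals = _kernels.batch_final(
        gI, mI, a, slope, b, mRf, params.TD, int(S0), seeds, dt_max, method == "thinning"
    )
    n_ext = int((finals == 0).sum())
    ci = binomtest(n_ext, n_runs).proportion_ci(confidence_level=0.95, method="exact")
    mean_final = float(finals.mean())
    se_final = float(finals.std(ddof=1) / math.sqrt(n_runs)) if n_runs > 1 else math.nan
    return ExtinctionEstimate(
        n_runs=n_runs,
        n_extinct=n_ext,
        probability=n_ext / n_runs,
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        mean_final=mean_final,
        se_final=se_final,
    )


def extinction_scan(
    params: ModelParameters,
    strategies: Mapping[str, PrimedStrategy],
    vary: str,
    grid: Sequence[float],
    n_runs: int = 10_000,
    seed: int = 0,
    S0_naive: int = 1000,
    c_P: float = 0.3,
    method: str = "direct",
) -> pd.DataFrame:
    """Extinction probability per strategy across an m_I or TD grid.

    ``vary="m_I"`` rescales the stress intensity (all mortality levels scale
    proportionally, response geometry preserved); ``vary="TD"`` varies the
    stress duration. The naive population starts at ``S0_naive``; primed
    populations start at the cost-matched reduced size.
    """
    if vary not in ("m_I", "TD"):
        raise ValueError(f"vary must be 'm_I' or 'TD', got {vary!r}")
    grid = list(grid)
    if not grid:
        raise ValueError("grid must be non-empty")
    children = np.random.SeedSequence(seed).spawn(len(strategies) * len(grid))
    rows = []
    for j, (label, strategy) in enumerate(sorted(strategies.items())):
        s0 = S0_naive if label == "naive" else initial_sizes_from_costs(S0_naive, c_P, params)
        for i, value in enumerate(grid):
            if vary == "m_I":
                p2, strat2 = with_stress_intensity(params, strategy, value)
            else:
                p2, strat2 = params.replace(TD=float(value)), strategy
            sub_seed = int(children[j * len(grid) + i].generate_state(1)[0] & 0x7FFFFFFF)
            est = extinction_probability(
                p2, strat2, S0=s0, n_runs=n_runs, seed=sub_seed, method=method
            )
            rows.append(
                {
                    "strategy": label,
                    "vary": vary,
                    "value": value,
                    "S0": s0,
                    "n_runs": est.n_runs,
                    "n_extinct": est.n_extinct,
                    "p_hat": est.probability,
                    "ci_lo": est.ci_low,
                    "ci_hi": est.ci_high,
                }
            )
    return pd.DataFrame(rows)


def branching_extinction_probability(
    params: ModelParameters, response: object | None = None, S0: int = 1000
) -> float:
    """Exact extinction probability of the linear birth-death process.

    For a time-inhomogeneous linear birth-death process with birth rate
    lambda(t) = g_I and death rate mu(t) (the stress schedule), one line of
    Kendall's solution gives the single-founder extinction probability by
    time TD as q = I/(1+I) with I = int_0^TD mu(s) exp(rho(s)) ds and
    rho(t) = int_0^t (mu - lambda). Founders are independent, so the
    population extinction probability is q**S0. Serves as an analytic oracle
    for the Monte-Carlo estimators.
    """
    gI, mI, a, slope, b, mRf = _kernel_args(params, response)
    TD = params.TD

    def mu(t: float) -> float:
        if t < a:
            return mI
        if t < b:
            return mI - slope * (t - a)
        return mRf

    def rho(t: float) -> float:
        # exact cumulative integral of mu - gI
        total = mI * min(t, a)
        if t > a:
            w = min(t, b) - a
            total += mI * w - 0.5 * slope * w * w
        if t > b:
            total += mRf * (t - b)
        return total - gI * t

    pts = sorted({0.0, min(a, TD), min(b, TD), TD})
    I = 0.0
    for lo, hi in zip(pts[:-1], pts[1:]):
        if hi > lo:
            val, _ = quad(lambda s: mu(s) * math.exp(rho(s)), lo, hi, limit=200)
            I += val
    q = I / (1.0 + I)
    return q**S0
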