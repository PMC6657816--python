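# primedyn

Cost–benefit modeling of **primed microbial stress responses**: when a mild
preparatory cue ("priming") precedes a strong triggering stress, a primed
population can respond *earlier* (shorter response lag), *faster* (steeper
defense buildup) or *stronger* (lower final mortality) than a naive one —
at a growth cost paid during the priming phase. `primedyn` simulates these
dynamics and answers, for a given stress duration and priming cost, which
response strategy is the most beneficial, how each strategy changes the
risk of stochastic extinction, and how competition between strategies
shifts the picture.

The package is aimed at theoretical ecologists and microbiologists studying
stress priming, cross-protection and acquired stress resistance.

## Model

A population of size S grows exponentially and suffers stress mortality:

```
dS/dt = g(P,t) S − m(T,t) S
```

The growth rate is g_I, reduced to g_I (1 − c_P) during the priming window
[t_P, t_TS) for a primeable population. The triggering stress of duration TD
adds a piecewise-linear mortality: the initial level m_I during a response
lag L, then a linear decline with normalized slope s_R down to the response
floor m_R, held until the stress ends at t_TE. A primed strategy modulates
L (earlier), s_R (faster) or m_R (stronger). Resource limitation replaces
the growth term by g S (1 − S/K); a four-strategy community couples the
populations through a generalized Lotka–Volterra term
(S_i + α Σ_{j≠i} S_j)/K with interaction strength α ∈ [0, 1].

Strategies are made comparable by a **baseline calibration**: the modulated
parameter is chosen so that the relative benefit of priming,
(S_primed − S_naive)/S_naive at t_TE, is exactly zero at a reference stress
duration (75 t) and cost (c_P = 0.3). In the exponential model this benefit
has the closed form `exp(−g_I c_P (t_TS − t_P) + ΔM) − 1`, where ΔM is the
cumulative mortality the primed response saves — so all map boundaries are
analytic and root-finding on the closed form is exact.

Stochastic extinction risk is estimated with a birth–death Gillespie
simulation of the stress window (direct method with a waiting-time cap,
plus an exact thinning sampler and Kendall's analytic branching-process
probability as cross-checks).

## Worked example

```python
import primedyn as pdn

p = pdn.ModelParameters()                 # default fixture: g_I=0.0488, m_I=2*g_I, ...
s = pdn.baseline_strategies(p)            # calibrated at TD=75, c_P=0.3
for td in (20, 50, 100):
    for k in ("earlier", "faster", "stronger"):
        b = pdn.relative_benefit(p, s[k], TD=td, c_P=0.2)
        print(f"TD={td:3d} {k:8s} benefit={b:+.4f}", end="  ")
    print("winner:", "|".join(pdn.best_strategy(p, td, 0.2, s)))
```

prints

```
TD= 20 earlier  benefit=+0.0039  TD= 20 faster   benefit=-0.0394  TD= 20 stronger benefit=-0.1773  winner: earlier
TD= 50 earlier  benefit=+0.1025  TD= 50 faster   benefit=+0.1025  TD= 50 stronger benefit=-0.0669  winner: earlier|faster
TD=100 earlier  benefit=+0.1025  TD=100 faster   benefit=+0.1025  TD=100 stronger benefit=+0.3028  winner: stronger
```

i.e. the earlier response wins short stresses, earlier and faster tie
exactly once both have reached the response floor, and the stronger
response takes over beyond the baseline duration, where its lower floor
keeps accumulating benefit.

The same analyses are available from the command line:

```
primedyn calibrate --out out/            # baseline parameter values
primedyn map --td-steps 30 --cp-steps 25 # best-strategy map (TD x c_P)
primedyn extinction --vary mI --grid 0.3,0.4,0.5 --runs 10000 --seed 1
primedyn community-map --alpha 1.0       # winners under competition
primedyn predictability --p-grid 0.25,0.5,1.0
```

`primedyn calibrate` reports, for the default fixture, the calibrated
earlier lag L_p = 1.0 t, faster slope s_Rp ≈ 0.0441 /t and stronger floor
m_Rp ≈ 0.0177 /t. Each command writes a delimited table plus a JSON run
manifest (parameters, seed, version) for reproducibility.

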