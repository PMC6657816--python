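# Methods

## Model and assumptions

`primedyn` describes one microbial population (biomass or CFU, arbitrary
units) in an abstract time unit t. Growth is exponential at rate g_I,
reduced by the priming cost fraction c_P during the priming window
[t_P, t_TS) if the population is primeable; a non-primeable population never
pays the cost, and the cost vanishes at stress onset (defense costs during
the stress are assumed equal for primed and naive responses). The
triggering stress of duration TD acts purely as added mortality m(t): the
initial level m_I throughout a response lag of length L, then a linear
decline dm/dt = −s_R·m_I (s_R is a normalized slope, so the buildup lasts
(m_I − m_R)/(s_R·m_I) regardless of intensity), then the response floor m_R
until the stress ends. There is no age or spatial structure, no memory
decay, and a single stress event per run.

A primed strategy modulates exactly one response parameter (or two, for
combined strategies): *earlier* shortens the lag to L_p, *faster* steepens
the slope to s_Rp, *stronger* lowers the floor to m_Rp. The naive
comparator keeps the original triple.

### Default parameters

| symbol | meaning                      | default | unit |
|--------|------------------------------|---------|------|
| g_I    | intrinsic growth rate        | 0.0488  | 1/t  (≈5% per step) |
| m_I    | initial stress mortality     | 0.0976  | 1/t  (= 2 g_I) |
| m_R    | response floor               | 0.0244  | 1/t  (= 0.25 m_I) |
| s_R    | normalized decline slope     | 0.03    | 1/t  (buildup 25 t) |
| L      | response lag                 | 5       | t    |
| t_P    | priming start                | 30      | t    |
| t_TS   | stress start                 | 50      | t    |
| TD     | stress duration              | varied (baseline 75) | t |
| c_P    | priming cost fraction        | varied (baseline 0.3) | – |
| K      | carrying capacity            | 10 000  | population units |

Timings are kept as *relative durations* (lag 5 t, buildup 25 t after the
lag): the alternative absolute listing (lag ending before the stress
starts) is internally inconsistent with the mortality schedule, so the
relative reading is used throughout. The baseline time point is likewise a
stress *duration* of 75 t measured from stress onset.

## Closed form and benefit

For the exponential model, S(t) = S0·exp(∫g − ∫m) with exact piecewise
integrals (rectangle + trapezoid + rectangle), which is the reference
implementation; ODE integration (DOP853, rtol 1e−12, restarted at every
rate breakpoint) is a cross-check. The relative priming benefit at the end
of the stress is

    B(TD, c_P) = exp(−g_I·c_P·(t_TS − t_P) + ΔM) − 1,

where ΔM is the cumulative mortality saved by the primed response. The
cost term penalizes every strategy identically, so the *ranking* among
primed strategies never depends on c_P (cost-rank invariance), and the
maximal compensable cost is ΔM(TD) / (g_I·(t_TS − t_P)).

## Baseline calibration

Each strategy parameter is calibrated by bracketed root-finding (brentq,
xtol 1e−12) on the closed-form benefit so that B(75, 0.3) = 0. Closed-form
values for the defaults: L_p = L − R/(m_I − m_R) = 1.0 t;
s_Rp from the decline-duration saving (triangle), d_p = 17 t, s_Rp ≈ 0.0441;
m_Rp from the quadratic floor saving, ≈ 0.0177 (the smaller root — the
larger one corresponds to a floor not reached within the stress). An
infeasible calibration (cost too high for any admissible parameter value)
raises an explicit error naming the binding bound rather than clamping.

Combined strategies split the required saving equally: each of the two
parameters is calibrated alone to deliver half, then combined. For
earlier+faster the two savings are exactly additive, so the pair lands on
zero benefit; for pairs involving the floor a slope–floor interaction makes
the combined saving deviate by a few percent — the split rule, not a zero
residual, defines the pair calibration. The rule is a package choice (the
least arbitrary symmetric construction); it reproduces the qualitative
result that earlier+faster wins short stresses and faster+stronger long
ones, with a crossover near 71 t.

### Map boundaries

Two exact boundaries structure the (TD, c_P) map: earlier and faster tie
*exactly* from the moment both primed responses have reached the floor
(TD = L_p + buildup = 26 t with defaults — note this is earlier than the
naive response completion at 30 t: on the band in between both strategies
gain on the still-declining naive response at the same rate, so "earlier
wins" holds only strictly below 26 t); and the stronger response overtakes
the earlier/faster plateau exactly at the baseline duration, by
construction of the calibration, gaining δ = m_R − m_Rp per unit TD beyond
its own floor time.

### Predictability

With cue predictability p, the expectation is taken on log fitness: with
probability p the trigger follows (full benefit), with 1−p it does not and
the primed population keeps only the cost penalty. E[log(S_p/S_n)] =
−cost + p·ΔM is affine in ΔM, so the strategy ranking is invariant for all
p > 0; predictability only moves the break-even cost.

## Stochastic extinction

Only the stress window is simulated as a linear birth–death process (birth
g_I·S, death m(t)·S with the deterministic schedule); priming costs enter as
the reduced initial size S_p0 = round(S_np0·exp(−g_I c_P (t_TS − t_P))),
default S_np0 = 1000 (hence 746 primed at c_P = 0.3). Absolute population
sizes are not pinned down by the study design, so extinction probabilities
are meaningful as *orderings and trends*, not absolute values.

Sampler: Gillespie's direct method with propensities re-evaluated at every
event. Because the death rate declines deterministically between events,
the direct method is approximate; a forced no-op re-evaluation caps the
waiting time at dt_max = 0.1 t, which bounds the staleness bias below
Monte-Carlo noise at the run counts used (at dt_max = 0.5 the bias is
visible, ~+0.01–0.03 in probability, against the exact references). Two
independent cross-checks are built in: an exact thinning (rejection)
sampler, valid because the death schedule is non-increasing, and Kendall's
analytic extinction probability for time-inhomogeneous linear birth–death
processes, q = I/(1+I) with I = ∫ μ e^{∫(μ−λ)}, applied per founder.

Stress-intensity scans scale the *whole* mortality schedule proportionally
(m_I, m_R and a calibrated stronger floor m_Rp all scale; lag and
normalized slope are invariant). Holding the calibrated floor absolute
while raising m_I would silently turn the stronger response into the safest
strategy (its floor would drop below the growth rate), inverting the
characteristic ordering earlier < faster < stronger < naive of extinction
risk; proportional scaling is the construction under which that ordering is
robust across intensities. The scan defaults probe m_I where extinction is
neither negligible nor certain at S0 = 1000 (≈0.3–0.5), and durations from
just past the response buildup upward — for very short stresses (TD ≲ 50 at
m_I = 0.4) the stronger strategy's cost is not yet repaid and its
extinction risk can exceed the naive one, which is outside the regime the
long-duration comparison addresses.

Reproducibility: a master seed spawns one substream per (strategy × grid
point) and per-run seeds within each, so estimates are exact functions of
(parameters, seed) and stable for prefix runs. The ensemble kernels are
numba-compiled; a pure-Python trajectory-recording implementation of the
same algorithms is the readable reference and is checked against the
kernels and the analytic oracle.

## Community competition

Four populations (naive + the three calibrated primed strategies) share a
carrying capacity through a generalized Lotka–Volterra term with
interaction strength α; the winner per (TD, c_P) cell is the largest
population at the end of the stress. The community starts at joint
capacity (K/4 per population) — an established community disturbed by the
stress; starting far below capacity mutes the density feedback during the
priming phase and with it the cost discount that makes competition favor
priming. Integration restarts at every rate breakpoint; since the
mortality schedule before t_TE does not depend on TD, one integration per
cost value serves an entire TD column of the map.

A structural property of this equation deserves emphasis: at α = 1 the
density factor (1 − S_tot/K) is common to all populations, so
log S_i − log S_j = ∫(m_j − m_i) exactly. Consequences: earlier and faster
tie exactly beyond the buildup; the stronger takeover stays exactly at the
baseline duration; and the only genuinely new α = 1 effect is that the
priming cost — paid in growth units — is discounted by density limitation,
so priming pays off at costs well above the single-species ceiling. For
α < 1 the self-weighted density term penalizes whichever population is
larger during the buildup (the earlier one), so the faster response gains a
small strict advantage (~0.3% at α = 0.5) — a priority effect in the
strict sense (earlier strictly outcompeting faster) cannot arise from this
equation for α ≤ 1. The stronger response's takeover is deferred by
competition relative to the single-species resource-limited case
(≈60 t at α = 0 → ≈70 t at α = 0.5 → 75 t at α = 1).

## Numerical choices and degenerate inputs

- Tie tolerance: 1e−9 on relative benefit (analytic maps; earlier/faster
  equality beyond the tie onset is exact, so ties are reported, not
  broken); 1e−6 relative on community sizes (absorbs integrator error
  without hiding the genuine α = 0.5 margins).
- TD = 0 means the stress never applies; L ≥ TD keeps mortality at m_I for
  the whole stress; m_I = 0 disables mortality entirely (pure birth).
- Strategy validation allows a 1e−9 relative slack so that calibrated
  values landing a rounding error past the naive bound resolve cleanly.
- Logistic/community integration: DOP853 with rtol 1e−10–1e−12 and
  breakpoint restarts; the α = 0 community reproduces independent
  single-species logistic solutions to better than 1e−8 relative.

## Problem sizes

The test suite and the acceptance script use 2000 Monte-Carlo runs per
strategy and grid point for extinction estimates (binomial CIs are reported
and all ordering checks are CI-aware), 100 random parameter sets for the
closed-form/ODE agreement check, and map grids of a few hundred cells;
these sizes resolve every claimed effect by several standard errors while
keeping a full run in the minutes range.

## Known limitations

- Priming costs, memory decay over time, repeated stress events and the
  "more sensitive" primed response are out of scope.
- Extinction probabilities depend on the (unstated) absolute population
  size at stress onset; only orderings and trends are robust outputs.
- The community analysis reports what the stated competition equation
  implies, including the exact earlier/faster tie at α = 1 and the slight
  faster advantage at α < 1 described above.
- The synthetic study conditions are idealized: deterministic rates, a
  single clean stress pulse, no environmental fluctuation. Passing tests
  demonstrate internal consistency of the model and its analysis, not
  predictions for any particular organism.
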