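# Methods

## Model

The state variable is the residual viable tumor burden `B_V(t)` (cc) of one
patient, measured from the end of treatment (t in days). An intrinsic
growth law `f(V)` — exponential `λV`, logistic `λV(1−V/K)`, or Gompertz
`λV·ln(K/V)` — is modulated by a minimum-viability factor:

    dB_V/dt = f(B_V) · (B_V/ε_V − 1).

The factor makes `B_V = ε_V` an unstable equilibrium: burdens below the
viability threshold decay deterministically to zero (cure), burdens above
it regrow. This is the deterministic, continuous analogue of an Allee
effect; it replaces stochastic-extinction machinery with a single threshold
parameter. `f` is evaluated at the viable burden itself (one state variable
per patient). Note that with `f(V)=λV` the *net* dynamics are not
exponential: the trajectory is subexponential near `ε_V` and
superexponential at larger burdens, with a finite-time blow-up — which is
harmless because every trajectory of interest is stopped far earlier, at
the detection threshold.

Recurrence for patient i is the indicator `R_i(t) = 1{B_V(t) ≥ ω_d}`
(right-continuous, crossing inclusive), and the cohort recurrence fraction
is the exact average `R(t) = (1/n) Σ R_i(t)`. The event-free curve
`1 − R(t)` is the simulated Kaplan-Meier-style curve. The method simulates
recurrence only; it is not a model of overall survival, and no censoring is
simulated (the model assumes perfect information and continuous
monitoring — a surveillance-schedule adaptation would round `t_R` up to the
next visit, and is deliberately not part of the default pipeline).

## Parameters

| symbol | meaning | units | typical default |
|--------|---------|-------|-----------------|
| `λ` | intrinsic regrowth rate, shared by all patients | 1/day | 0.0008–0.005 |
| `ε_V` | minimum viable burden (cure threshold) | cc | 0.01 (demo), 2.5e-4 (RT fit scenario) |
| `ω_d` | clinical detection threshold | cc | 0.056 (≈ 0.5 cm sphere), 0.4 (RT fit scenario) |
| `K` | carrying capacity (logistic/Gompertz only) | cc | 13.8, optionally per-patient |
| horizon | follow-up window | day | 7,300 (20 y) |

Curve features map one-to-one onto parameters: the y-intercept is
`1 − P(B_0 ≥ ω_d)`, the plateau is the cure fraction `P(B_0 ≤ ε_V)` (exact
lognormal CDF at `ε_V`), and `λ` controls the drop-off rate, proxied here by
the first time survival comes within 0.01 of its plateau (the drop-off is
qualitative in origin; a concrete, testable proxy is required, and 0.01 is
small against any feature contrast of interest).

Boundary tie-breaks: `B_0 = ω_d` counts as detectable at t = 0 (the
detection inequality is inclusive); `B_0 = ε_V` counts as cure (an
equilibrium below the detection threshold never crosses it). Both are
measure-zero under continuous sampling. Progressing patients whose crossing
falls beyond the horizon are flagged `beyond_horizon`, distinct from cures,
so the plateau is never silently overstated.

## Burden distributions

Residual burden across a cohort is lognormal, with the parameterization
convention an explicit, required field: `log_space` (location/scale of
`ln B`) or `arithmetic` (arithmetic mean and sd of `B`, both cc). The two
are exactly interconvertible and round-trip to machine precision. A silent
convention mix-up changes every downstream curve, which is why no inference
is attempted. A mixed constructor (`arithmetic mean` + ln-space scale)
covers carrying-capacity specifications quoted as "mean = 13.8 cc,
sd = 0.5", where 0.5 is only coherent as the ln-space scale — 0.5 cc as an
arithmetic sd would contradict the orders-of-magnitude spread such
capacity distributions are described with.

Sampling is seeded and prefix-stable (the first k draws do not depend on
the cohort size), "equally spaced virtual patients" are implemented as
equally spaced quantiles on [0.05, 0.95], and per-patient carrying
capacities are paired with burdens by index.

The two-arm demonstration scenario (`fig4_trial`) specifies only the arm
means (0.03 vs 0.05 cc); no scale is published, and no single shared scale
reproduces the quoted tail fractions, so the ln-scale is a free config
parameter (default 0.8, a plausible long-tailed unimodal shape) and only
orderings between the arms are asserted.

## Numerics

- Integration: adaptive RK45, rtol 1e-8, atol 1e-12 cc. Recurrence times
  use event detection (root-finding on `B(t) − ω_d`), never grid
  inspection, so they are solver-grid-independent.
- Exponential law: recurrence times and trajectories use the exact
  Bernoulli closed form; the ODE path is kept as an independent route and
  the two are held to 1e-6 (trajectory) / 1e-4 (crossing time) relative
  agreement in tests.
- Blow-up: the exponential-law net dynamics diverge in finite time above
  `ε_V`; integration halts at a ceiling (1e4 cc exponential, 10·K
  otherwise) with a truncation flag. Detection always triggers far below
  the ceiling.
- Gompertz at `V → 0`: `f(0) = 0` (continuous limit) with the log argument
  floored at 1e-30 cc against overflow.
- Curves are evaluated on a uniform grid (default 1-day step over 20
  years) from exact event times — the cohort average of step functions is
  computed exactly, not binned.
- Replicate envelopes are empirical 2.5/97.5 percentiles with linear
  interpolation; at 2 replicates this degenerates to min/max, documented
  rather than special-cased.

## Calibration

`fit_parameters` minimizes unweighted least squares between the
replicate-mean simulated survival (linearly interpolated to the observed
time points, summed across arms sharing global parameters) and observed
event-free fractions. The optimizer is Nelder-Mead (the replicate-averaged
loss is only piecewise-smooth; gradients are unreliable) in the
transformed space `(ln λ, ln ω_d, logit(ε_V/ω_d))`, which enforces
positivity and `ε_V < ω_d` by construction; at most 500 iterations,
loss tolerance 1e-6. Burden samples do not depend on the fitted
parameters, so all replicate cohorts are drawn once and reused for every
candidate: the loss surface is deterministic under a fixed seed. Burden-
distribution parameters are fixed inputs by default; they come from
upstream treatment modeling, and joint fitting is weakly identified.

Identifiability: the data constrain `λ` and the *cure fraction*
`P(B_0 ≤ ε_V)` well, but `ω_d` and `ε_V` individually only weakly (for
very wide burden distributions many `(ω_d, ε_V)` pairs give nearly the
same curve). Recovery tests therefore target `λ` (median relative error
< 15% over seeds) and the implied cure fraction (within 0.05), not the raw
thresholds. At the generating parameters the loss tends to the binomial
noise floor of the replicate mean, not to zero; tests assert a bound, not
exact equality. No between-arm statistical test is computed — feature
deltas only; a log-rank comparison is a natural extension point.

## Synthetic data and what tests show

The fixture generator produces cohort and curve CSVs for built-in
scenarios whose parameters are the demonstration values above, including a
two-arm radiotherapy-fractionation-like scenario (arms
`lognormal(μ=−8.0, σ=6.8)` and `(μ=−10.0, σ=7.6)` in log space, n = 265
per arm, `ε_V = 2.5e-4` cc, `ω_d = 0.4` cc, `λ = 0.005`/d). Synthetic
cohorts emulate lognormal burden heterogeneity with shared dynamics
parameters; they do not emulate censoring, surveillance schedules,
inter-patient `λ` or `ε_V` variation, multimodal burden mixtures, or
competing risks. Passing tests therefore validate the mapping from burden
distribution to curve shape and the self-consistency of calibration — not
fit quality on any real trial dataset, whose event-free points are not
shipped with the package.

## Scales used in tests

Deterministic checks run at full precision; stochastic checks use cohort
sizes of 1e3–1e4 (binomial tolerances stated per test), Monte-Carlo CDF
checks 1e6 draws, and calibration recovery 5 seeds × 2 arms × 500 patients
× 50 replicates — sizes chosen so every tolerance is a 3-sigma-style bound
under the stated sampling model.

## Known limitations

Deterministic extinction below `ε_V` (no stochastic survival of small
clones); one shared `λ` per scenario arm; unimodal lognormal burdens;
recurrence only (no overall survival, no competing risks); continuous
monitoring. The upstream treatment simulation that would produce a burden
distribution from a dose schedule is out of scope — distributions are
inputs here.
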