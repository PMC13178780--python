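# regrowth

Simulate population-level cancer recurrence curves from distributions of
post-treatment residual **viable tumor burden**.

After cytoreductive therapy (surgery, radiotherapy, some chemotherapies),
each patient is left with some residual viable burden `B_V` (cc). This
package models the post-treatment dynamics with a growth law `f(V)`
attenuated by an Allee-type *minimum viability threshold* `ε_V`:

```
dB_V/dt = f(B_V) · (B_V/ε_V − 1)
```

so that `B_V → 0` (cure) if and only if `B_V < ε_V`, and the burden regrows
otherwise. A patient *recurs* at the first time their burden reaches the
clinical *detection threshold* `ω_d`:

```
R_i(t) = 1  iff  B_V(t) ≥ ω_d
```

Sampling a virtual cohort from a lognormal burden distribution and averaging
the per-patient indicators, `R(t) = (1/n) Σ R_i(t)`, yields a simulated
Kaplan-Meier-style event-free curve `1 − R(t)` whose features map directly
onto the model parameters: `ω_d` sets the y-intercept, `ε_V` sets the
plateau (the cure fraction — exactly the burden mass below `ε_V`), and the
regrowth rate `λ` sets the rate of the drop-off in between. Growth laws
`f(V) = λV` (exponential), `λV(1−V/K)` (logistic), and `λV·ln(K/V)`
(Gompertz) are supported, with or without the viability term. The package is
for modelers in radiation oncology and biostatistics who want a mechanistic
reading of recurrence-curve shapes, in-silico two-arm trials, and
calibration of `(λ, ω_d, ε_V)` to observed event-free data.

With the exponential law the net equation is a Bernoulli ODE with the exact
solution `B(t) = 1/[1/ε_V + (1/B_0 − 1/ε_V)·e^{λt}]`, used throughout as an
oracle for the numerical integrator, and giving the closed-form recurrence
time `t_R = (1/λ)·ln[(1/ε_V − 1/ω_d)/(1/ε_V − 1/B_0)]`.

## Worked example

```python
import regrowth as rg

dist  = rg.BurdenDistribution("arithmetic", 0.05, 0.06)   # mean 0.05 cc, sd 0.06 cc
model = rg.RegrowthModel(rg.GrowthLawParams("exponential", 0.0015),
                         eps_V=0.01, omega_d=0.056)

t = rg.exponential_recurrence_time(0.02, 0.0015, 0.01, 0.056)
print(f"t_R = {t:.1f} d")                     # t_R = 331.0 d

curve = rg.simulate_cohort(dist, model, n=10_000, seed=2026)
f = rg.curve_features(curve)
print(f"intercept={f.y_intercept:.3f} plateau={f.plateau:.4f}")
print(f"exact cure fraction = {rg.fraction_below(dist, 0.01):.4f}")
```

prints

```
t_R = 331.0 d
intercept=0.716 plateau=0.1139
exact cure fraction = 0.1090
```

A patient starting at 0.02 cc crosses the 0.056 cc detection threshold after
331 days; 71.6% of the cohort is event-free at t = 0 (the rest is already
detectable), and the curve plateaus at the cure fraction — the 11% of the
burden distribution below `ε_V = 0.01` cc, up to binomial sampling error.

The same workflows are available from the shell, one subcommand per
experiment, with built-in scenarios:

```sh
regrowth simulate fig3_baseline --out-dir out
regrowth sweep fig3_baseline --param eps_V --values 0.010,0.014,0.018 --out-dir out
regrowth compare-arms fig4_trial --out-dir out
regrowth growth-laws fig5_growthlaws --out-dir out
regrowth fixtures rtog9003_like --out-dir fixtures --seed 0
```

Curves are written as CSV (`time_days, survival, recurrence_fraction`);
see `docs/methods.md` for the model details and numerical choices.

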