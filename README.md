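# boombust

Fitting and analysing boom–bust predator–prey cycles in ciliate
microcosms.

Laboratory populations of the predatory ciliate *Didinium nasutum* and
its prey *Paramecium bursaria* run through a single predator–prey
cycle when placed together in a small dish: the prey boom, the
predator peak follows, the prey crash, and the predator starves to
functional extinction (fewer than one individual per dish). How the
shape of that cycle — amplitude, peak timing, time to extinction —
changes with temperature can be traced back to the ecological rates
that drive it by fitting a mechanistic model to the observed time
series. This package provides that workflow for ecologists working
with microcosm time-series data: the model, the fitting machinery,
uncertainty quantification, validation by parameter recovery, and
cycle-shape summaries.

## The model

Prey density $R$ and predator density $C$ (individuals mL⁻¹, time in
days) follow

$$\frac{dR}{dt} = (r - r_{\mathrm{slope}} R)\,R - \frac{a R C}{1 + a h R + m\,(C - 0.167)_+}$$

$$\frac{dC}{dt} = e\,\frac{a R C}{1 + a h R + m\,(C - 0.167)_+} - C\,d\,e^{-R C_d}$$

- $r$, $r_{\mathrm{slope}}$ — logistic prey growth ($K = r/r_{\mathrm{slope}}$);
- $a$ — space clearance rate, $h$ — handling time (type-II functional
  response saturating at $1/h$);
- $m$ — mutual interference among predators, active only above the
  one-predator density 0.167 mL⁻¹ (one individual in the 6-mL dish);
- $e$ — conversion efficiency (predators produced per prey consumed);
- $d$, $C_d$ — predator mortality $d\,e^{-R C_d}$, maximal when prey
  are gone and negligible when prey are abundant.

Estimation minimises a χ² deviance between log-transformed observed
and predicted densities by multi-start bounded least squares in log₁₀
parameter space; confidence intervals come from profile likelihood
(Δχ² = 1, the ~68.5% / one-SD interval, stepped in log increments so
bounds stay positive) with a finite-difference Hessian fallback. In
the standard protocol $C_d$ is fixed at 40 and the remaining seven
parameters are free.

## Worked example

Generate a synthetic six-temperature experiment (six replicate dishes
per temperature, ~10% observation noise), fit the 23 °C
across-replicate mean series, and profile the space clearance rate:

```python
from boombust import (ExperimentDesign, fixture_parameter_sets,
                      generate_dataset, fit_model)
from boombust.uncertainty import profile_likelihood

design = ExperimentDesign(seed=0)            # six replicates, log-noise SD 0.1
params = fixture_parameter_sets()            # six synthetic temperature labels
data = generate_dataset(params, design)
mean23 = next(s for s in data if s.temperature == "23" and s.replicate == "mean")

fit = fit_model(mean23, starts=5, seed=0)    # C_d fixed at 40, 7 parameters free
print(f"chi2 = {fit.chi2:.2f} over {fit.n_obs} observations")
for name in fit.free:
    print(f"  {name:8s} = {getattr(fit.params, name):.4g}")

prof = profile_likelihood(mean23, fit, "a")
print(f"a 68.5% CI: [{prof.ci_low:.3f}, {prof.ci_high:.3f}] "
      f"({prof.low_status}/{prof.high_status})")
```

Output:

```
chi2 = 9.60 over 24 observations
  r        = 1.284
  r_slope  = 0.002075
  a        = 0.2279
  h        = 0.04555
  m        = 0.02724
  e        = 0.05504
  d        = 0.9468
a 68.5% CI: [0.212, 0.244] (threshold-crossed/threshold-crossed)
```

The generating values at this label were r = 1.3, r_slope = 0.00215,
a = 0.24, h = 0.046, m = 0.03, e = 0.055, d = 0.95: the fit recovers
every rate to within a few percent despite the observation noise, the
deviance is of the order of the observation count, and the profile CI
for the clearance rate brackets the truth.

The same steps are available from the shell via the `boombust` CLI
(`simulate`, `fit`, `profile`, `recover`, `summarize`, `contrast`,
`growth` subcommands); see `boombust --help`.

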