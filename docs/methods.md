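# Methods

## Model

The package implements a two-species consumer–resource ODE for closed
microcosms. Prey grow logistically, written as a per-capita rate
declining linearly in density, `(r − r_slope·R)·R`, which is
algebraically the logistic model with `K = r/r_slope` but converges
more reliably in fitting because `r` and `r_slope` are less strongly
correlated than `r` and `K` on these data. Consumption follows a
type-II functional response with mutual interference in the
denominator, `a·R / (1 + a·h·R + m·(C − c_offset)₊)`. The
interference term is offset by the density of a single predator in
the dish (`c_offset` = 1/6 mL⁻¹ for the 6-mL dish, displayed 0.167)
so that a lone predator experiences no interference, and the term is
clamped at zero below that density: without the clamp the denominator
would drop below `1 + a·h·R` and consumption would exceed the
zero-interference rate, which is unphysical. Predator mortality is
`d·exp(−R·C_d)`: maximal when prey are absent and effectively zero
once prey exceed a few times `1/C_d`. With `C_d = 40` mL·ind⁻¹,
mortality is switched off for essentially any visible prey density
and switches on sharply as prey collapse — this is what produces the
deterministic boom–bust shape: near-exponential predator growth
during the prey boom, then near-exponential predator decay at rate
`d` after the crash.

Assumptions worth keeping in mind: densities are continuous
(sub-individual densities are retained during integration and can
rebound; "functional extinction", density below one individual per
dish, is imposed only in summaries, never in the dynamics); the
environment is constant within a run (temperature enters only through
parameter values); there is no demographic stochasticity or spatial
structure.

## Parameters

| symbol | meaning | units | typical magnitude |
|---|---|---|---|
| r | prey max per-capita growth | day⁻¹ | 0.5–2 |
| r_slope | density dependence of prey growth | mL·ind⁻¹·day⁻¹ | 10⁻³–10⁻² |
| a | space clearance rate | mL·pred⁻¹·day⁻¹ | 0.05–0.5 |
| h | handling time | day·prey⁻¹ | 0.03–0.1 |
| m | mutual interference | mL·pred⁻¹ | 10⁻²–10⁻¹ |
| e | conversion efficiency | — | ~0.055 |
| d | predator max mortality | day⁻¹ | 0.5–2 |
| C_d | prey scale of mortality decline | mL·ind⁻¹ | 40 (fixed) |
| c_offset | one predator per dish | ind·mL⁻¹ | 1/6 |

The standard fitting protocol fixes `C_d = 40` (it is necessary for
fit quality but nearly unidentifiable from cycle data, since any
sufficiently large value produces the same on/off mortality switch)
and leaves the other seven free. `e` can additionally be pinned at
0.055, its near-temperature-invariant value; the `refit_with_fixed`
operation quantifies the χ² cost of doing so.

## Error model and deviance

Observed and predicted densities are compared on the log scale,
`g(x) = ln(x + δ)`, with `δ = c_offset/2` (half an individual per
dish) keeping zeros finite. The deviance is
`Σ ((g(obs) − g(pred))/σ)²` over both species and all retained time
points. Per-observation σ: for series carrying across-replicate SEs,
the density-scale SE is mapped to the log scale as `SE/(x + δ)` and
floored at 0.05; series without SEs get σ = 0.1, matching the noise
magnitude used in the recovery validation. These weights are a
package convention — reported χ² values are only comparable under
this weighting.

## Optimisation

Free parameters are searched in log₁₀ space (positivity by
construction) inside wide per-parameter boxes (e.g. r ∈ [10⁻³, 10²],
r_slope ∈ [10⁻⁶, 1]; see `fitting.DEFAULT_BOUNDS`). Multi-start:
Latin-hypercube starts in the log box (default 20), each refined by
trust-region least squares on the weighted residual vector;
integration failures return a large finite residual so the optimizer
retreats. Ties break to the lower χ², then the lower start index, and
the reported χ² is a fresh re-evaluation at the returned optimum.
Recovery runs include the generating truth among the starts: they
test estimator consistency, not global-search power.

## Profile likelihood and Hessian CIs

Profiles step the focal parameter multiplicatively (ratio 1.05, up to
200 steps per side), re-optimizing all other free parameters at each
step, warm-started from the neighbouring grid point. The CI bound is
log-linearly interpolated where the re-optimized χ² crosses the base
χ² + 1.0; Δχ² = 1 is the one-SD (~68.5%) convention — the exact χ²₁
quantile at 0.685 (≈1.01) differs negligibly. If integration fails
before crossing, the bound is clamped at the last feasible value and
flagged `integration-failure`; a profile flat to the end of the grid
is flagged `grid-exhausted`. The Hessian fallback differentiates χ²/2
in ln-parameter space by central finite differences (relative step
10⁻⁴) and reports `estimate·exp(±√(Δχ²·[H⁻¹]ᵢᵢ))`; non-invertible or
non-positive curvature flags the parameter unavailable rather than
raising.

## Synthetic experiment generator

The generator emulates the experiment's structure: six temperature
labels (17, 20, 23, 25, 27, 31 °C), 6-mL dishes inoculated at 30
prey/mL and 2 predators per dish (C₀ = 1/3 mL⁻¹), sampling on days
1–5 daily then every second day plus the terminal day
(1,2,3,4,5,7,9,11,13,15,17,18), six replicates per temperature,
multiplicative observation noise, and across-replicate means with
per-time SE = SD/√n. Observation noise is Normal(0, σ) added on the
ln(x + δ) scale (default σ = 0.1, i.e. ≈10% multiplicative error);
adding the draw on the raw density scale is supported via
`scale="raw"` but would be negligible against densities of 10²–10³
mL⁻¹, so log scale is the default and the convention used throughout
validation. The fitted timespan mirrors the experimental convention:
each species' series is truncated after the third consecutive
functionally-zero observation following its last positive one.

Features of real microcosm data the generator does *not* emulate:
demographic stochasticity (replicates differ only by observation
noise), the 0.1-mL subsample vs full-census counting protocol and its
density-dependent error structure, medium replacement, and
replicate-level failures (early predator extinctions). Passing
recovery tests therefore demonstrate that the estimator inverts its
own generative model under realistic noise — not robustness to
structural misspecification.

### Fixture parameter sets

`fixture_parameter_sets()` ships six synthetic stand-in parameter
sets, one per temperature label. They are not fitted values from any
experiment; they were hand-tuned, by forward simulation during
package construction, to reproduce the qualitative phenomenology:
one prey boom, a predator peak 3–4.5 days later, predator functional
extinction by day 18, and time-to-extinction decreasing monotonically
from the coldest label (day ~17.7) to the warmest (day ~10.4), with
`e = 0.055` and `C_d = 40` throughout and overall rates (growth,
clearance, mortality) increasing with temperature. Two constraints
discovered during tuning are worth recording: interference much above
m ≈ 0.05 prevents the prey crash entirely (the predator
self-regulates into coexistence), and combining fast dynamics with
high mortality frees the prey so early that the continuous-density
predator rebounds above one-per-dish within the 18-day horizon — the
well-known ODE artifact of recovery from functionally-zero density.
The shipped values keep both effects outside the observation window.

## Validation problem sizes

The test suite and the acceptance script validate at the scale of the
emulated experiment: 12 observation days × 2 species per series; six
fixture sets; 10 noise replicates per fixture per noise level for
recovery; 12 seeded replicates (one label, two free parameters) for
profile-CI coverage; solver cross-checks against a fixed-step RK4
oracle at dt = 10⁻³ day. These sizes make the full validation run in
minutes on one core while leaving the statistical checks meaningful.

## Numerical choices

- Integrator: LSODA (stiff-capable), rtol = 10⁻⁸, atol = 10⁻¹⁰
  density units; the prey crash with `C_d = 40` is a sharp transition
  that defeats loose-tolerance explicit solvers. Densities are
  clipped to ≥ 0 at output times; the right-hand side treats
  transiently negative solver states as zero.
- Integration failure is data, not an exception: `solve_trajectory`
  returns the partial trajectory with a failure time, `chi_squared`
  maps it to +∞, the optimizer to a large finite residual, and the
  profiler to a clamped, flagged bound.
- The mortality exponent `R·C_d` is capped at 700 before
  exponentiation to avoid overflow at extreme profile steps.
- Ties in peak finding resolve to the earliest time; extinction is
  the first post-peak crossing below threshold that never rebounds
  within the trajectory's horizon.

## Generation counts

Prey generation time is `1/r`, so a duration `T` spans `T·r` prey
generations. For the predator, the ratio of handling time to
conversion efficiency `h/e` has units of days per predator produced
at saturated consumption and is used as the default generation time
(`T·e/h` generations); the literal reciprocal convention `e/h` is
available behind a flag since both appear in the literature's
shorthand. With `e = 0.055` and `h ≈ 0.04–0.07` day, `h/e` ≈ 0.7–1.3
days per generation, giving the familiar ~3–25 predator generations
over an 18-day run depending on rates.

## Known limitations

- Interference `m` is weakly identified when small: at the coldest
  fixture the one-SD halfwidth of ln m is ≈0.5, so single-experiment
  estimates of `m` scatter by tens of percent under 10% observation
  noise. This is a property of the data design (one cycle, 12 time
  points), not of the optimizer — noiseless recovery is exact to
  <10⁻⁶ relative.
- χ² magnitudes depend on the package's σ conventions; only Δχ²
  within the same weighting are meaningful.
- The profile scan assumes a locally unimodal profile; multi-modal
  deviance surfaces would need a denser global scan.
- Continuous densities rebound from functionally-zero values; any
  horizon extension beyond the observed window should treat
  post-extinction dynamics as artifactual.
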