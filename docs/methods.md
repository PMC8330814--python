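# Methods

## Model family

Grain yield of paddy rice grown with a single weed species follows the
rectangular hyperbola `Y = Y₀ / (1 + βX)`, where `X` is the initial weed
density (plants m⁻²), `Y₀` the weed-free yield (t ha⁻¹) and `β` the
per-plant competitiveness. Across temperature environments the pair
`(Y₀, β)` is not constant; thermal time from transplanting to flowering
— growing degree days, `GDD = Σ max(T_day − T_base, 0)` with
`T_base = 10 °C` — indexes the environment. Three nested
parameterizations are fitted to the pooled multi-year data:

1. **per-level** (full): independent `(Y₀ᵢ, βᵢ)` at every year × regime
   level, `2k` parameters for `k` levels;
2. **intermediate**: `Y₀(GDD) = a + b·GDD + c·GDD²` shared across
   levels, level-specific `βᵢ`, `3 + k` parameters;
3. **combined**: additionally `β(GDD) = l + m·GDD`, 5 parameters.

Model functions return the algebraic value: the quadratic can go
negative outside the observed GDD range and `β` may be negative at low
GDD (the line's intercept `l` is negative). No clamping happens inside
the model or the fitting — least squares must see the true model — and
only the reporting layer displays negative predictions as 0, with an
explicit flag. Units are fixed (t ha⁻¹, plants m⁻², °C·days); nothing
converts units internally.

## Thermal-time accounting

GDD accumulates as a daily sum with per-day clamping at the base
temperature, over closed windows (start and end dates both included).
For mid-summer paddy temperatures, where every day is above base, this
equals `(mean T − T_base) × n_days`; the clamped daily sum is the robust
general convention and is what the accumulation invariants (additivity
over contiguous windows, monotonicity in any day's temperature,
non-negativity) are proven against in the property tests. Stage windows
all start at transplanting; default calendar June 1 / Aug 10 (tillering)
/ Aug 28 (flowering, an 89-day window) / Oct 15 (maturity). No hourly
interpolation, upper-threshold variant or photoperiod term is offered.

## Fitting

Nonlinear least squares uses a trust-region reflective solver with
analytic Jacobians and tight tolerances (ftol = xtol = gtol = 1e−12).
Initial values are deterministic:

* hyperbola: `Y₀⁰` = mean yield at the lowest density; `β⁰` from the
  linearization `1/Y = 1/Y₀ + (β/Y₀)X` (slope/intercept), guarded
  against non-positive yields;
* joint fits: `(a, b, c)` from an OLS quadratic of the per-level `Ŷ₀ᵢ`
  on GDD and `(l, m)` from an OLS line of the `β̂ᵢ` on GDD (the
  stage-2 regressions, also exposed as `fit_stage2_*`).

If the primary start fails to converge, a small fixed ladder of
fallback starts runs (multi-start as fallback, not as default), and a
convergence error with diagnostics is raised if all fail. Parameter
scales (`x_scale ≈ [10, 1e−2, 1e−5, 1e−2, 1e−5]` for the combined
model) condition the badly scaled quadratic-in-GDD design.

Standard errors are the conventional asymptotic NLS ones: the SVD
pseudo-inverse of `JᵀJ` at the optimum times the residual mean square
`RSS/df`. Fit quality is summarized by `RMS = √(RSS/df)` and
`pseudo-R² = 1 − RSS/TSS` (the plain, unadjusted form; flat responses
give NaN rather than an error inside the estimators). All observations
are equally weighted, and the stage-2 regressions are unweighted; no
bootstrap or Bayesian alternatives are provided.

**Level inclusion.** A level whose weed-free mean yield falls below
1.0 t ha⁻¹ (configurable) is excluded from the pooled fits: a
heat-collapsed level carries almost no information about `β` and
destabilises the joint estimation. Under the default simulator this
rule removes exactly the two hottest regimes of the hot year, leaving
10 of 12 levels — the structure the nested comparison is built on. A
per-level fit with weed-free yield < 1.0 t ha⁻¹, or with `se(β) > |β|`
and `se(β) > 0.02`, emits an `UnstableFitWarning` rather than an error.

## Lack-of-fit testing

Each reduction is tested with
`F = [(RSS_reduced − RSS_pred)/(df_reduced − df_pred)] / (RSS_full/df_full)`,
where the denominator is **always** the per-level (full) model's
residual mean square, for both sequential comparisons; this convention
is hard-coded because it is the one that exactly reproduces the
published comparison table from its printed RSS/df. The reduced model
is accepted when `F` is below the upper-5 % F quantile with
`(df_reduced − df_pred, df_full)` degrees of freedom; the report also
carries exact p-values and an asterisk label. For nonlinear least
squares the test is approximate; simulation from the combined-model
truth puts the empirical type-I rate at ≈ 4–5 % at α = 0.05 (checked in
the acceptance suite over 500 replicates, accepted band 2–9 %).

## Synthetic trials

The generator emulates a 3-year × 4-regime (ambient, +1.5, +3.0,
+5.0 °C) × 5-density × 3-replicate pot trial with one or two weed
species. Per regime-year it builds a daily temperature series — a
seasonal cosine (amplitude 4 °C, peak in early August) plus day-to-day
noise (SD 1.5 °C), re-centred so the flowering-window mean is exactly
the year's ambient value (24.1 / 26.4 / 29.0 °C for the three default
years) plus the regime offset — and accumulates GDD through the `gdd`
module, giving flowering-window GDDs of roughly 1250–2130. Yields are

```
Y = combined(truth, GDD, X) · sterility(T̄_flowering) + N(0, σ),  clamped at 0
```

with σ = 0.5 t ha⁻¹ by default (the magnitude of per-level residual RMS
in phytotron pot trials) and 8 % random pot dropout. Density sets are
{0, 10, 20, 40, 80} in the first year and {0, 20, 40, 80, 160}
afterwards. Everything derives from one seed via spawned substreams;
identical inputs give byte-identical output.

**Sterility.** Heat-induced spikelet sterility is a logistic
multiplier `1/(1 + exp(slope·(T̄ − t50)))` of the mean flowering-window
temperature. Its defaults (t50 = 31 °C, slope = 2 per °C) are
calibration choices of this simulator — chosen so the hot year's two
hottest regimes collapse to near-zero yield while cool years are
untouched — not estimates from any trial; they are plain config knobs.
The multiplier sits *outside* the combined model, so data generated
with sterility enabled deliberately violate the 5-parameter model at
collapsed levels (which the inclusion rule then removes); recovery and
calibration experiments disable it to generate exactly from the model.

**Generating parameters.** Late watergrass uses the published rounded
combined-model estimates (−16.0, 0.03, −1e−5, −0.021, 2e−5). The
published rounded water-chestnut quadratic is negative over the whole
realistic GDD range — a rounding artefact (its own peak evaluates to
−3.4 t ha⁻¹) — so the default truth for that species keeps the printed
curvature and competitiveness line but re-anchors `a, b` to the
reported ≈ 5.7 t ha⁻¹ weed-free peak near GDD 1500:
(−39.28, 0.06, −2e−5, −0.031, 3e−5).

**Yield components.** Each observation can be decomposed into panicle
count (density acts here, hyperbolically), grains per panicle (carries
the GDD response), % ripened grain (temperature acts here, via the
sterility logistic) and 1000-grain weight (constant 22 g), with the
product reconstructing the pre-noise yield to 1e−9. This reproduces the
dissociation seen in such trials — density depresses panicles but not
ripening; heat depresses ripening but not the weed-free panicle count —
and is what the correlation screen is tested against.

**What passing tests do not show.** The generator is additive-Gaussian
with a single variance, has no year × density interactions beyond the
model, no weed biomass dynamics, no CO₂ effects and no mechanistic
physiology; clamping at zero introduces a mild truncation bias at
near-zero yields. Parameter-recovery and calibration results on this
generator therefore validate the estimation machinery, not the
biological adequacy of the model for any real trial.

## Reporting choices

The correlation screen uses Pearson product-moment correlations with
two-sided t-tests at 5 % ("*" / "ns"); rank correlation would be a
one-line swap. Percent-of-weed-free tables quote one decimal place.
Grain yields are standardized to 12 % moisture via
`fresh · (1 − moisture)/0.88`. Published headline percent-of-weed-free
values are **not** reproducible from the published rounded parameters
(the rounded late-watergrass parameters give 71.4 % where 58.9 % was
reported from the unrounded fit), so they are treated as qualitative
anchors — monotone decline in GDD, 100 % at zero density — rather than
numeric targets.

## Problem sizes

The stochastic checks use 200 replicates for SE coverage, 500 for
F-test calibration, 50 datasets for the nesting invariant and 10
instances for the grid-search oracle — sizes at which the binomial
uncertainty of the empirical rates is well inside the accepted bands
while the whole suite completes in about a minute on one CPU.

## Known limitations

* Published growth-stage GDD values are not recomputable from the
  published window means (`(24.1 − 10) × 89 = 1254.9` vs a printed
  1,288); such tables are treated strictly as given inputs.
* Asymptotic SEs understate uncertainty for collapsed levels (flagged,
  not corrected).
* The F-test's nominal level relies on approximate linearity of the
  model near the optimum; calibration is verified only under the
  default design and noise level.
* The missing-pot mechanism in real trials is unknown; the simulator's
  uniform dropout is a neutral stand-in.
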