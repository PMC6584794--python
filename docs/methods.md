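# Methods

## Model and assumptions

The continuous-time yield of an aerosol constituent over a use session is the
integral of (constituent mass ratio × TPM concentration × volumetric flow
rate). The package discretises this puff-by-puff: within a puff the
concentration and mass ratio are held constant at the puff's mean flow rate
q = v/d and duration d, so the session yield is a sum of per-puff products
Ĉ(qₙ, dₙ)·vₙ. This discretisation is exact when emissions respond to the
(q, d) of a puff as a whole rather than to instantaneous flow, which is the
calibration condition of the underlying machine-puff experiments: the models
are *fit* to per-trial mean conditions, so *evaluating* them at per-puff mean
conditions is the consistent use.

Separating concentration (device/flow-path dependent) from mass ratio
(consumable dependent) assumes the two factor multiplicatively. For the
reference pairing the fitted mass ratio is flat in flow (β₂ ≈ −5·10⁻⁶ per
mL/s, indistinguishable from zero), so nicotine yield is effectively a fixed
≈1% of TPM yield. The TPM surface is quadratic in ln q with linear d,
ln d and q·d terms; it is empirical, not mechanistic, and should not be
trusted outside the fitted (q, d) envelope — the yield layer therefore flags
out-of-envelope puffs as extrapolations rather than refusing them.

The `ln(d/1000)` regressor is mathematically `ln d` plus a constant folded
out of the intercept; it is implemented literally so fitted intercepts are
directly comparable with published coefficient tables for this model form. A
reparameterisation test asserts the surface is invariant to the alternative
basis.

## Parameters that matter

| parameter | units | default | why |
|---|---|---|---|
| detection threshold | mL/s | 1.0 | below deliberate draws, above sensor noise |
| min puff duration | s | 0.1 | discards glitches |
| min inter-puff gap | s | 0.3 | bridges momentary dips within one draw |
| design envelope q | mL/s | 12–65 | span of session-mean flows seen in natural-environment vape-pen use |
| design envelope d | s | 1.0–4.4 | span of session-mean durations, same source |
| screening puff volume | mL | 55 | typical single-draw volume; the screening arm varies q and d inversely at this constant volume |
| target session volume | mL | 740 (522–1000) | cumulative aerosol volume per emissions trial |
| ln-scale TPM noise σ_ln | — | 0.15 | replicate-level scatter of ln C in machine-puff trials |
| mass-ratio noise σ_f | mg/mg | 0.0025 | replicate-level scatter of the pad nicotine/TPM ratio |
| observed-yield noise cv | — | 0.2 | lognormal multiplicative scatter of playback yield measurements |

Units are fixed package-wide (s, mL/s, mL, mg); the model coefficients are
unit-bound, so any conversion belongs at the I/O boundary.

## OLS implementation

The regression core is solved by QR factorisation; the basis
{ln q, (ln q)², q·d} is strongly correlated (condition number ~10⁴ on the
default design), and QR avoids squaring it. The normal-equations solve is
retained only as an independent test oracle, and `statsmodels` is used as a
second oracle for the diagnostic set. Standard errors use the n−p residual
variance and the diagonal of (XᵀX)⁻¹ computed from R⁻¹; p values are
two-sided from the t distribution with n−p degrees of freedom; RMSE is
√(SSR/(n−p)) on the response scale. Because the TPM response is ln C, the
report also carries a back-transformed natural-scale residual RMSE [mg/mL];
the two are different quantities and both are reported rather than conflated.
An exact (interpolating) fit is detected by comparing SSR against the
rounding floor of ‖y‖ and reported as zero SEs with infinite t statistics
instead of dividing by zero. Rank deficiency raises an error naming the
collinear columns. R² is the centred coefficient of determination, which
presumes an intercept in the design (true of both models here).

The through-origin agreement slope m = Σŷy/Σŷ² is the headline validation
statistic because deviation from 1 measures miscalibration against the ideal
1:1 line; the OLS slope/intercept and R² of the fitted line (with intercept)
are reported alongside, since a "slope" alone is ambiguous between the two
conventions.

## Synthetic-data generators

The generators emulate the laboratory workflow, not any particular dataset:

* **Design**: 10 screening conditions log-spaced in q with d = 55/q (constant
  puff volume), plus a 6×4 (q, d) grid; 6 replicate trials per condition
  give 204 trials. Repeated-puff counts are the integers bringing each
  trial's cumulative volume closest to 740 mL within [522, 1000] mL. The
  layout is deterministic; the nominal-vs-observed flow distinction of real
  machines is not modelled (a jitter would break the screening arm's
  constant-volume construction, which tests rely on).
* **Emissions**: ln C ~ Normal(surface, σ_ln = 0.15) per trial; the pad mass
  ratio is truncated-normal on (0, 1) — truncation is inert at f ≈ 0.01 and
  was chosen over a logit-normal for simplicity. Nicotine is assayed on the
  screening arm only, as in the reference protocol (60 of 204 trials).
  With the reference surface over the default design the signal spread is
  sd(ln C) ≈ 1.4, so refits at σ_ln = 0.15 have R² ≈ 0.99; a
  variance-decomposition test asserts the refit R² equals the ratio implied
  by the generated design rather than any particular published value.
* **Sessions**: lognormal puff durations, flows and inter-puff intervals
  (a pragmatic stand-in — the empirical family of natural-environment puff
  metrics is not established; the metrics are positive and right-skewed).
  Pulses are symmetric trapezoids (0.1 s rise/fall) whose plateau is scaled
  so pulse area equals q·d exactly, with breakpoints aligned to the 100 Hz
  sampling grid so trapezoidal integration of the rendered trace is exact.
  Seven exemplar profiles spanning light to heavy use are packaged as
  generator targets. Where a profile's (mean d, mean q, volume) targets are
  not consistent with an integer puff count (the heaviest profile implies
  1.3 puffs), the puff count is rounded and the volume target is met only up
  to that quantisation; per-puff metrics remain unbiased.
* **Observed yields**: predicted × LogNormal(0, cv) per replicate, with
  independent multipliers for the TPM and nicotine channels (different
  assays). Real pads would induce correlation between the two channels;
  none is modelled.

All generators derive their streams from a root seed through per-component
spawn keys, so stages are individually reproducible and mutually
independent under a shared seed.

What passing tests on these generators shows: the estimators are unbiased
and internally consistent under the model's own assumptions, the pipeline
composes end-to-end, and the agreement statistics behave correctly under
controlled noise. What they do not show: anything about model adequacy for
real aerosols — real emissions data exhibit device aging, coil-resistance
drift, battery effects and within-puff flow dynamics that the generators
deliberately omit.

## Numerical choices and degenerate inputs

* Trapezoidal rule for every time integral (dense sampling; order 2;
  deterministic).
* Per-puff q is v/d (volume-weighted), making q·d = v an identity that the
  yield summation relies on; it is not the arithmetic mean of flow samples.
* Puff detection: maximal runs of samples ≥ threshold; sub-`min_gap` dips are
  bridged (gap samples included in the window, conserving volume);
  sub-`min_duration` runs dropped. An empty or all-quiet trace is an empty
  result, not an error. Negative flows are clipped to zero on ingest and
  counted; non-monotone or duplicated timestamps are structural errors.
* Trace-path vs session-path yields: detected puff windows are quantised to
  the sampling grid, so (q, d) shift by about one sample; volumes agree to
  the sub-sample level while yields move by a few percent through the
  surface's flow sensitivity. The cross-path test budgets 6% for this.
* Agreement statistics require ≥3 pairs and non-constant predictions; a
  constant observed vector reports r = 0 rather than NaN.

## Problem sizes

The default test and acceptance runs use the full 204-trial design, 200
Monte-Carlo replicates for recovery studies, and 7×6 = 42 validation pairs —
the same sizes the reference protocol uses; the whole suite runs in well
under a minute on one core, so no down-scaling was needed.

## Known limitations

* Coefficients are product-specific; the packaged reference set characterises
  one vape-pen/e-liquid pairing and is not transferable.
* Only nicotine is instantiated as a constituent; the mass-ratio interface
  generalises to other constituents but none are packaged.
* No respiratory-deposition, vapor-phase, device-power or inter-puff-loss
  modelling; the yield is "delivered to the mouth".
* The published diagnostic the reference tables print as a natural-scale
  RMSE for the ln-response regression is ambiguous; this package reports
  ln-scale and natural-scale RMSEs separately and asserts neither equal to
  the printed value.
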