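# Methods

## Problem and estimand

Published oncology trials often report only a Kaplan–Meier (KM) plot, a
cohort size, and a median. When two such curves must be compared — for
example a CAR-T arm against matched real-world controls for
progression-free survival (PFS) in heavily pretreated multiple myeloma —
the median difference is a fragile summary: it depends only on the narrow
window where survival crosses 50%. The restricted mean survival time
(RMST) uses the whole curve instead:

    RMST(t*) = ∫₀^t* S(t) dt

the mean event-free time up to a milestone t*. `kmgain` implements the
digitize-and-integrate workflow for this estimand: read the (time,
probability) pairs produced by a plot digitizer, repair digitization noise,
truncate both arms at a common milestone, integrate by the trapezoidal
rule, and report the between-arm RMST gain next to the median gain.

## Pipeline stages

1. **Ingestion** (`curves.read_digitized_curve`). Two-column delimited text
   (comma/tab/semicolon sniffed), optional header. Probabilities on the
   percent scale are detected (any value > 1.5) and divided by 100. Rows
   are sorted by time with stable order so that duplicate-time pairs — the
   two corners of a vertical KM drop — stay adjacent.
2. **Shape repair** (`curves.enforce_km_shape`). Manual digitization adds
   pixel jitter that can locally break monotonicity. The cleaner prepends
   the (0, 1.0) anchor when missing, clamps probabilities into [0, 1], and
   takes the running minimum. The operation is idempotent; rejecting noisy
   curves instead would make the workflow unusable on real digitizer
   exports.
3. **Milestone** (`rmst.common_milestone`). t* = min of the two maximum
   follow-up times — the longest follow-up reached by *both* curves.
   Restricted means are only comparable at a common t*, and t* beyond a
   curve's follow-up would require extrapolation; `truncate_at` therefore
   rejects unreachable milestones.
4. **Integration** (`rmst.rmst_trapezoid`). The trapezoidal rule is applied
   to the digitized points as given, after truncation at t* with a linearly
   interpolated final point (linear interpolation is the geometry the
   trapezoid already assumes). A separate exact step-function integrator
   (`rmst_step_exact`) exists as an oracle: on digitizations that record
   both corners of every drop the two agree to floating-point precision,
   because vertical segments contribute zero area. On one-point-per-plateau
   digitizations the trapezoid cuts corners of the true step; this
   discrepancy is a property of the published method, documented rather
   than hidden, and shrinks with digitization density (empirically
   O(1/k²) on smooth curves).
5. **Medians** (`rmst.median_survival`). Right-continuous step convention:
   the smallest digitized time with S ≤ 0.5, `None` when the curve never
   reaches 0.5 — matching how trial medians are read from KM output.
   Linear interpolation is deliberately not used here.
6. **Uncertainty** (`ipd`). The published curve plus n determines a
   near-unique pseudo individual-patient dataset: walking drops left to
   right with risk set r, each drop to target S assigns
   d = round(r·(1 − S/S_real)) events, where S_real is the survival the
   reconstruction has realized so far. Using the realized rather than the
   printed previous value makes rounding self-correcting, which is what
   guarantees agreement within 1/(2n) at every drop time. Rounding is
   half-away-from-zero so results are bit-reproducible. All non-events are
   censored at final follow-up (minimal-information variant: no
   numbers-at-risk table is assumed). Confidence intervals are percentile
   bootstrap over subject resampling (a multinomial draw over the unique
   (time, event) categories, with the grouped product-limit estimate and
   its exact step integral vectorized across replicates); the two-arm
   p-value is a two-sided normal tail on gain / bootstrap-SE. These are
   this package's methods, labeled as such in every report — published
   letters of this type typically state a CI and a t-test without a
   variance formula, and we do not attempt to reverse-engineer one.

## Synthetic data generator

`synthetic` draws cohorts from exponential, Weibull, or
piecewise-exponential event models with independent exponential censoring
and an administrative cutoff, and emulates the digitization step itself:
the point budget (default 75, within the realistic 50–100 range for a
digitized figure) is spent on corner pairs at the largest drops first —
capped at half the budget so the remaining evenly spaced fill always covers
the whole time axis — and Gaussian jitter (default sd 0.01 probability
units, a plausible pixel-reading error) is added and clamped to [0, 1].
The emulator's output deliberately violates monotonicity the way real
digitizer exports do.

The default two-arm demo mirrors the geometry of the motivating
comparison: n = 128 treated vs 190 controls, 18-month administrative
cutoff, light random censoring (0.02/month), piecewise-exponential shapes
with higher early hazard calibrated so the generating medians are 11.30 and
3.50 months (treated: 0.09/mo before month 4, 0.04566/mo after; control:
0.19804/mo before month 6, 0.05/mo after). These shapes are illustrative —
early attrition is plausible in a heavily pretreated population, but the
true published curves are not machine-readable, so no point-for-point
reconstruction is attempted. Consequently, passing tests demonstrate
correctness of the pipeline on curves of this shape class, not agreement
with any specific trial's RMST values.

What the generator does not emulate: dependent censoring, delayed
separation or crossing hazards, digitizer time-axis error (jitter is on the
probability axis only), and numbers-at-risk information.

## Numerical choices and degenerate inputs

- Percent-scale detection threshold 1.5: survival probabilities cannot
  exceed 1, and percent plots essentially always contain values above 1.5.
- A flat curve (no events) reconstructs to an all-censored cohort; its
  bootstrap interval collapses to a point, which is correct, not a bug.
- If the bootstrap percentile interval fails to bracket the digitized
  point estimate (possible when digitization noise shifts the trapezoid
  away from the reconstruction's step integral), the interval is widened to
  include it, keeping the report internally consistent.
- A zero bootstrap SE (degenerate resampling) yields p = 1 for zero gain.
- Reconstruction rejects curves inconsistent with n (a drop requiring more
  events than subjects at risk), naming the drop time.
- Seeds: every stochastic operation takes one integer seed;
  `compare_arms` derives per-arm streams from (seed, arm index) so the two
  arms are independent yet jointly reproducible.

## Test problem sizes

The statistical suites use an exponential scenario with rate 0.1/month at
t* = 18 (closed-form RMST (1 − e^{−1.8})/0.1 ≈ 8.347): coverage of the
nominal 95% CI is checked over 200 replicates of n = 200 with B = 500
(accepting empirical coverage in [0.90, 0.98]); full-pipeline recovery is
checked on a fixed 20-seed panel at n = 2000, where the KM sampling
standard deviation (≈ 0.14 months) leaves headroom under the 0.5-month
recovery bound — at the lower end of cohort sizes (n ≈ 200) the sampling
noise alone (≈ 0.43 months) would dominate that bound, so recovery is a
large-cohort property.

## Known limitations

- No Guyot-style reconstruction from numbers-at-risk tables; with only
  (curve, n) the event/censoring split is identified only up to the
  final-follow-up censoring convention, and CI widths inherit that
  assumption (they tend to be conservative when real interim censoring is
  heavy).
- The trapezoid-on-digitized-points estimator inherits whatever bias the
  digitization carries; the emulator quantifies it for the jitter model
  above, not for systematic axis miscalibration.
- The z-test treats the bootstrap SE as known; at very small n a
  percentile-interval inversion would be more defensible.
- Hazard ratios and parametric fits are out of scope by design.
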