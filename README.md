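# kmgain

**Progression-free-survival gain from digitized Kaplan–Meier curves:
restricted mean survival time by trapezoidal AUC, pseudo-IPD bootstrap
inference.**

Many published trial comparisons expose nothing machine-readable beyond a
Kaplan–Meier (KM) plot, a cohort size and a median. Median differences are
fragile — they depend only on the short stretch of follow-up where survival
crosses 50%. The restricted mean survival time,

&nbsp;&nbsp;&nbsp;&nbsp;RMST(t\*) = ∫₀^t\* S(t) dt,

is the mean event-free time up to a milestone t\* and uses the entire curve.
`kmgain` implements the complete desk workflow for comparing two published
curves on the RMST scale:

1. read the (time, survival) coordinate pairs exported by a plot digitizer
   (50–100 points per curve, percent or probability scale, any common
   delimiter);
2. repair digitization jitter (running-minimum monotonicity, (0, 1) anchor);
3. truncate both arms at the common milestone t\* — the longest follow-up
   reached by both curves;
4. integrate each curve by the trapezoidal rule (AUC = RMST) and extract
   medians;
5. reconstruct pseudo individual-patient data by inverting the
   product-limit estimator against the cohort size, and bootstrap it for
   95% confidence intervals on each arm's RMST, on the between-arm RMST
   gain, and for a two-sided z-test of the gain.

It is aimed at health-technology-assessment analysts and biostatisticians
doing indirect comparisons from the published record — for instance CAR-T
versus matched real-world controls in heavily pretreated multiple myeloma,
where an 18-month milestone analysis turns a 7.8-month median gain into a
much more modest RMST gain. A synthetic-data module generates two-arm
cohorts with known closed-form RMST, KM curves, and emulated digitizations
so every stage is testable end to end.

## Worked example

Simulate the built-in two-arm demo (treated n = 128 vs control n = 190,
18-month cutoff, generating medians 11.3 / 3.5 months), then analyze the
emulated digitizations exactly as one would analyze real digitizer exports:

```bash
kmgain simulate --out-dir demo --seed 1
kmgain analyze --treated demo/treated.digitized.csv \
               --control demo/control.digitized.csv \
               --n-treated 128 --n-control 190 --seed 1
```

Output:

```
| Arm | n | t* (mos) | RMST (mos) | RMST 95% CI | Median (mos) |
|---|---|---|---|---|---|
| treated | 128 | 18.00 | 10.51 | 9.42 to 11.86 | 11.50 |
| control | 190 | 18.00 | 6.07 | 5.37 to 7.09 | 3.79 |

| Gain from RMST (mos) | Gain 95% CI | Gain from medians (mos) | p-value | B | seed |
|---|---|---|---|---|---|
| 4.44 | 2.94 to 5.88 | 7.71 | 2.222e-09 | 2000 | 1 |

CI and p-value: pseudo-IPD percentile bootstrap; bootstrap-SE z-test.
```

Reading it: at the common milestone t\* = 18 months the treated arm
accrues 10.51 event-free months on average against 6.07 for controls — an
RMST gain of 4.44 months (95% CI 2.94 to 5.88, p ≈ 2×10⁻⁹), well below the
7.71-month gap between the medians. The RMST gain is the more stable
summary because it averages over the whole curve rather than one crossing
point. The `--format json` / `--format csv` options serialize the same
report deterministically (identical seed ⇒ byte-identical JSON);
`<arm>.cleaned.csv` audit copies of the repaired curves are written next to
the inputs.

The same pipeline is available as a library — see `kmgain.run_analysis`,
`kmgain.rmst_trapezoid`, `kmgain.reconstruct_events`,
`kmgain.compare_arms`, and `kmgain.synthetic` for scenario configuration
(YAML-loadable exponential / Weibull / piecewise-exponential models).

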