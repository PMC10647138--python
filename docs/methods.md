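# Methods

## Problem and model

Waist-to-height ratio (WHtR = waist circumference / height, both in cm) is
a height-normalised index of central adiposity. The package derives and
validates *static* WHtR cut-offs that discriminate children and
adolescents (6–18 completed years) carrying clustered cardiometabolic risk
— at least k of the four non-waist metabolic-syndrome components (high BP,
high TG, low HDL-C, high FBG), with k = 2 in the main analysis and k = 3
as a sensitivity analysis. Components are flagged under either the IDF or
the modified NCEP pediatric definitions; the two differ in thresholds and
even in inequality direction (NCEP low HDL is `<= 40` mg/dL where IDF is
`< 40`), and all comparisons are implemented exactly as printed, with
"SBP/DBP >= X/Y" read as SBP >= X **or** DBP >= Y, the standard
hypertension convention.

A single dichotomising cut-off c (classifier: WHtR >= c, boundary
positive) yields one ROC operating point, so

    AUC = (sensitivity + specificity) / 2,
    Youden J = sensitivity + specificity − 1 = 2·AUC − 1,

and maximising J and maximising AUC select the same candidate. The 95% CI
for this AUC combines the two binomial variances,
`AUC ± 1.96·sqrt(se(1−se)/(4·n_pos) + sp(1−sp)/(4·n_neg))`, clipped to
[0, 1]; sensitivity and specificity get Wald intervals on their own
denominators. Swapping in a different interval estimator would not change
any point estimate or any selected optimum.

## Derivation design

Two independent search strategies, mirroring a two-pronged derivation
design:

1. **Percentile candidates.** Weight status is classified against a
   pluggable IOTF-style BMI reference (boundary BMI belongs to the heavier
   category; boundaries linearly interpolated between tabulated ages). Six
   nested weight-status subsamples (S1 all … S6 normal + overweight +
   obesity + morbid obesity) are formed; the *reference subsample* is the
   one with minimal clustering prevalence (ties to the smaller membership
   set, so normal-weight S2 wins exact ties). Sex- and age-specific WHtR
   percentiles P75–P95 are estimated on it, and each candidate percentile
   is evaluated as a person-specific threshold **on the full cohort**.
2. **Static grid.** WHtR values 0.42, 0.43, …, 0.56 (grid computed in
   integer hundredths; exactly 15 candidates) evaluated the same way.

Per stratum the Youden-optimal candidate is selected (ties: higher
sensitivity, then lower cut-off; tie-breaks are logged). Per-stratum static
optima are then consolidated per region group as the group **median,
rounded half-up to two decimals**, with min/max/IQR reported so the
clustering tendency of member optima stays inspectable. The default
grouping carries two archetypes, Europe/USA-like versus
Asia/Africa/South-America-like.

## External validation

A proposed cut-off is tested on independent cohorts two ways: (i) as a
dichotomised classifier (same metrics as derivation), and (ii) by logistic
regression of the clustering outcome on the exposure indicator
(WHtR >= cut-off), adjusted for sex and age, plus survey year in pooled
models when it varies. Age enters as a continuous completed-years term.
Fitting is maximum likelihood via IRLS (statsmodels GLM, binomial family),
tolerance 1e-8, at most 25 iterations; OR = exp(β) with Wald CI
exp(β ± 1.96·SE). Complete separation (runaway coefficient or infinite SE)
and rank-deficient designs raise diagnostics instead of returning unstable
estimates; unadjusted fits on all-binary data reproduce the 2×2
cross-product ratio to 1e-6 relative.

## Quantile convention

Percentiles use linear interpolation between the closest order statistics
(`numpy.quantile(..., method="linear")`), fixed package-wide and verified
against an independent sort-based oracle. The convention is a parameter:
note that duplication invariance (doubling every record leaving percentile
values unchanged) holds for pure empirical-CDF conventions such as
`inverted_cdf` but **not** for interpolating ones — `{0, 1}` versus
`{0, 0, 1, 1}` at P75 is a counterexample — so that property is asserted
under `inverted_cdf` only. Cells with fewer than 10 records (configurable)
raise an error listing the cells; adjacent ages are never silently pooled.

## Synthetic cohorts and what they do (not) show

The generator emulates a pooled multi-country school survey with a planted
ground truth:

- age uniform on 6–18 completed years, fair-coin sex; height from a linear
  sex/age growth curve (116.5 + 4.9/yr boys, 115.5 + 4.4/yr girls, SD 6 cm);
- WHtR ~ Normal(μ_region, 0.05) truncated to (0.30, 0.80): μ = 0.47 in
  region A (Europe/USA-like, planted cut-off c* = 0.50) and 0.44 in region
  B (Asia/Africa/South-America-like, c* = 0.46) — WHtR is kept flat in age
  (an age slope is exposed but defaults to 0), consistent with the observed
  stability of mean WHtR across these ages;
- BMI lognormal, mean rising with age (log-mean `log(16.2 + 0.38·(age−6))`),
  linked to WHtR with slope 4 on the log scale, residual SD 0.08; weight
  back-computed. The synthetic growth reference places its six category
  boundaries at fixed z-scores of this same log-BMI model, giving a
  realistic weight-status mix (roughly 13% thin / 17% overweight / 7%
  obese in the pooled setting);
- each component k is Bernoulli with
  `p_k(w) = expit(logit(p0_k) + jump·1[w >= c*] + slope·max(0, w − c*))`,
  defaults jump = 1.0 (log-odds step at c*), slope = 8.0 per unit WHtR,
  p0 = 0.07 per component (IDF-like) or 0.11 (NCEP-like). These baselines
  were fixed by integrating p_k over the WHtR distribution so pooled k=2
  prevalence lands near the 7.8% / 14.8% pooled figures; the config
  carries its target and the generator refuses (CalibrationError) configs
  whose implied prevalence misses it by more than a tolerance (0.05);
- flags are drawn first and biomarkers back-filled from truncated normals
  on the correct side of the generating criteria's thresholds (respecting
  each rule's strict/inclusive inequality, with the exceedance assigned to
  SBP with probability 0.75, else DBP), so re-flagging reproduces the
  drawn flags with zero discrepancies. A purely continuous model would
  only achieve this approximately;
- all randomness flows from one seeded `default_rng` in a fixed draw
  order: identical config ⇒ identical cohort.

Because the planted risk step straddles the pooled prevalence, the
population-level Youden optimum sits exactly at c*, so grid search
recovering c* ± 0.01 in ≥ 95% of seeds at n = 20,000 is the designed
behaviour, not luck. Null configs (jump = slope = 0) state their own
closed-form expected prevalence and give |J| < 0.05 at the selected
optimum for the tested seeds.

What passing these tests does **not** show: the generator has no LMS-grade
growth curves, no within-school clustering or survey weights, no
measurement error or inter-device BP differences, components independent
given WHtR (real components correlate beyond adiposity), and linear height
growth. Recovery on this generator demonstrates correctness of the search
machinery under the stated model, not field performance of any cut-off.

## Numerical choices and degenerate inputs

- Grid values are integer hundredths (`i/100`), never accumulated floats.
- Consolidation rounds half-up via `Decimal` on the shortest repr, so a
  median of 0.455 proposes 0.46.
- Strata whose outcome is degenerate (no positives or no negatives) raise
  `DegenerateOutcomeError`; the pipeline logs and skips them and fails
  only if every stratum fails.
- BP reference lookups clamp out-of-band heights to the nearest band with
  a logged warning; age 18 deliberately errors, pointing callers to the
  static 130/85 rule.
- Unit conversion uses fixed molar factors (TG 88.57, cholesterol 38.67,
  glucose 18.016 mg/dL per mmol/L) and only at the I/O boundary; internal
  units are mg/dL, cm, kg, mmHg throughout. Ages are truncated to
  completed years on ingest. Rejected rows are reported with row-indexed
  diagnostics, never imputed.

## Problem sizes

Defaults used by the test-suite and `scripts/acceptance.py`: derivation
cohorts n = 20,000 per region; calibration checks n = 50,000 pooled;
recovery 100 seeds × 3 planted cut-offs (tests; 20 × 3 in the script);
held-out validation n = 2,000–2,500 per cohort. The full suite runs in
about 20 s and the acceptance script in about 5 s on one CPU.

## Known limitations

- Percentile tables require every (sex, age) cell present in the cohort;
  sparse real-world cells must be handled upstream (no pooling is offered).
- Sex is modelled as a male/female binary, as in the underlying criteria.
- The consolidation grouping is supplied by configuration; the package
  does not infer region membership from data.
- Published IOTF and child-BP reference tables are not bundled; the
  synthetic tables have the correct shape and the loaders accept drop-in
  CSVs of the published values.
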