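# Methods

## Scientific setting

After bariatric surgery, ectopic and visceral fat depots shrink on very
different time scales. Longitudinal quantitative MRI can track four
compartments in the same patient: percentage liver fat (%-LF, the mean
proton-density fat fraction over the segmented liver), total liver volume
(TLV, cm³), and visceral and subcutaneous adipose-tissue volume (VAT and
SAT, here in litres). The schedule is three presurgical scan sessions
(treated as replicate measurements at t = 0 months) followed by scans at
3, 6, 12 and 24 months. This package implements the full computational
chain for such a study — mask-based quantification, kinetic modelling,
reproducibility and comparison statistics, and blood-parameter
associations — together with a synthetic cohort and phantom generator so
every stage is testable without patient data.

## Kinetic model

Every compartment trajectory is modelled as exponential decay with a
late linear rebound:

    Y(t) = exp(A + B·t) + A1·t

- **A** — log of the initial value (`exp(A) = Y(0)`); units log-% for
  %-LF, log-cm³ for TLV, log-L for VAT/SAT.
- **B** — decay rate per month, negative for a shrinking compartment.
  The *decay constant* reported everywhere is −B, so larger means faster
  fat loss. The model is reported per-compartment in this
  parameterization; VAT/SAT in litres and TLV in cm³ are chosen so that
  exp(A) of the default fixed effects lands on realistic baselines
  (exp(7.4392) ≈ 1701 cm³ liver).
- **A1** — slope of the ascending process (units of Y per month),
  non-negative: after a nadir the compartment slowly re-expands.

With B < 0 and A1 > 0 the curve has a unique interior minimum at
t\* = ln(−A1/(B·e^A))/B; with A1 = 0 it decays monotonically. The form is
a reconstruction: it is the simplest curve consistent with "log initial
value + decay + ascending slope" and it reproduces the observed nadir-
then-rebound of liver volume (≈1701 cm³ at baseline, minimum near one
year, ≈1392 cm³ at 24 months under the default fixed effects).

## Subject fits and the two-stage population summary

`kinetics.fit_subject` minimizes the ordinary residual sum of squares
Σ(y − Y(t))² by damped Gauss–Newton: full step from the normal equations,
halved (up to 40 times) until the RSS does not increase; convergence when
the relative RSS change drops below 1e-10, capped at 500 iterations
(unconverged fits are flagged and excluded from population summaries).
The initializer is deterministic: A from the log of the mean of the
earliest-time replicates, B from a log-linear regression over the first
three distinct times, A1 from the slope of the last inter-visit interval
floored at 0. Standard errors come from σ̂²(JᵀJ)⁻¹ at the optimum. Fits
with B > 0 are flagged (`positive_decay_rate`) but not discarded: the
sign convention is enforced at reporting time as decay constant = −B.

`kinetics.fit_population` is a deliberate two-stage approximation of a
nonlinear mixed-effects model: fixed effects are the arithmetic mean of
converged per-subject estimates, between-subject SDs the sample SD, and
the SE of a fixed effect is SD/√n. Two-stage estimation is unbiased for
the fixed effects under the generator's model and keeps every per-subject
decay constant available for the paired signed-rank comparisons; a full
marginal-likelihood NLME refinement is intentionally out of scope.

A known identifiability limit: at the default liver-fat measurement noise
(22% CV, see calibration below) the rebound slope A1 of %-LF is weakly
determined — its per-subject estimate has an SD larger than the fixed
effect itself, so the population mean carries a relative SE near 40%
regardless of estimator (an efficient log-scale fit improves it only
marginally). A and B are estimated to a few percent; A1 is precise for
the volumetric compartments, whose rebound is strong relative to noise.

## Synthetic cohort generator

The generator draws per-subject parameters around population fixed
effects and simulates noisy observations:

1. **Decay rates** B across the four compartments are multivariate
   normal with per-compartment means/SDs and a common pairwise
   correlation `rho_decay` (default 0.5; a positive coupling of fat-loss
   rates across depots is physiologically plausible and is what powers
   the paired comparisons). Draws are rejected until all four B are
   negative; A and A1 are independent normals, A1 truncated at 0
   (`truncate_rebound`, on by default).
2. **Observations** are the exact model curve times an independent
   unit-mean lognormal factor with per-compartment CV; the three t = 0
   visits are replicate measurements of the same underlying value.
3. **Blood analytes** follow linear links to liver fat
   (analyte = intercept + subject intercept + slope·%-LF + noise), with
   slopes set to the target association strengths (e.g. fasting insulin
   0.299 μU/mL per %-LF) and intercepts anchoring the preoperative means
   (glucose 5.3 mmol/L, insulin 7.3 μU/mL, …). HOMA-IR is never
   generated: it is always computed as glucose·insulin/22.5.
4. **BMI** uses a descriptive trajectory — subject baseline
   (40.6 ± 4.0 kg/m²) times a fixed shape anchored at the cohort means of
   the five visit months — because the exp-plus-line kinetic form cannot
   hold BMI's late plateau (≈27.4 kg/m² at 12–24 months).
5. **Missingness** mirrors the study's assay schedule: blood is drawn
   once preoperatively (replicate visits 2–3 carry no panel), lipids are
   skipped at 3 months, glucose/insulin at 24 months.

### Default parameters and their calibration

| compartment | A | B | A1 | sd(A) | sd(B) | sd(A1) | within CV |
|---|---|---|---|---|---|---|---|
| %-LF | 2.3328 | −0.2084 | 0.0417 | 0.665 | 0.09 | 0.0104 | 0.22 |
| TLV  | 7.4392 | −0.0839 | 48.5448 | 0.202 | 0.02 | 12.136 | 0.09 |
| VAT  | 1.5025 | −0.0989 | 0.0492 | 0.420 | 0.03 | 0.0123 | 0.10 |
| SAT  | 2.9518 | −0.0999 | 0.2787 | 0.216 | 0.02 | 0.0697 | 0.07 |

- sd(B) equals the reported between-subject spread of the decay
  constants (0.09 / 0.02 / 0.03 / 0.02).
- sd(A) is set from the cohort's baseline spread: for %-LF the baseline
  between-subject SD is 9.6 around a mean near 13, which a lognormal
  exp(A) reproduces at σ = 0.665; TLV/VAT/SAT use the two-stage identity
  sd = SE·√16 applied to the population SEs.
- sd(A1) defaults to a 25% coefficient of variation of the fixed effect
  — a modest, always-positive rebound heterogeneity.
- The within-measurement CVs are calibrated in closed form to the target
  triplicate-baseline ICCs (0.88 / 0.83 / 0.94 / 0.90): with lognormal
  between-subject truth, the pooled within-replicate variance is
  E[Y²]·CV², so CV = σ_w/√E[Y²] with σ_w = σ_b·√(1/ICC − 1). For %-LF
  this gives σ_b = 9.6, σ_w = 3.55, CV = 0.221.

### What the generator does and does not emulate

It reproduces the study's design (n, schedule, replicate baselines),
the marginal and joint distribution of subject kinetic parameters, the
measurement-noise level implied by the reported reproducibility, and the
strength of the cross-sectional fat–blood associations. It does **not**
emulate surgery-type or sex strata, physiological drift between the
three baseline sessions, non-lognormal measurement error, time-varying
association structure, or dropout other than the fixed assay schedule.
Passing tests on synthetic cohorts therefore demonstrate correctness of
the estimators under the assumed data-generating process, not the
clinical findings themselves.

## Phantom and quantification

Volumes are exact by definition: count of label voxels × voxel volume
(mm³ → cm³), no resampling, so volume is additive over disjoint masks and
a file round trip through NIfTI preserves it bit-for-bit. %-LF is the
unweighted arithmetic mean of the fat-fraction map over the liver mask
(the aggregation is a documented choice; a volume-weighted variant across
acquisitions would differ only with anisotropic multi-sequence input).
Fat fractions are clipped to [0, 100] at construction. Axial confinement
takes a half-open slice interval [z_low, z_high) in 0-based voxel
indices — landmark detection is out of scope, mirroring the manual
confinement between the ninth thoracic vertebra and the femoral head.
The phantom (ellipsoidal liver, elliptic SAT shell, seeded spherical VAT
blobs) uses a voxel-center inclusion rule; its voxelized sphere volume is
within 2% of (4/3)πr³ at 2 mm voxels and converges as voxels shrink.

## Statistics

- **ICC**: one-way random-effects, single measurement —
  (MSB − MSW)/(MSB + (k−1)·MSW). One-way is the standard variant for
  test–retest of a single method; it requires complete replicate tables.
- **Wilcoxon signed-rank** (paired, two-sided): zero differences dropped
  (Wilcoxon's rule), midranks for tied absolute differences. The p-value
  is exact — the full 2ⁿ sign-assignment distribution, computed by
  dynamic programming — whenever n ≤ 20 and there are no ties; otherwise
  a normal approximation with tie and continuity corrections. Two-sided
  p = min(1, 2·min(P(W ≤ w), P(W ≥ w))). All six compartment pairs are
  tested unadjusted.
- **Comparisons vs baseline**: paired t-tests per follow-up month,
  Bonferroni-multiplied by the family size per parameter (the number of
  months actually compared for that analyte), capped at 1.
- **Simple regression**: ordinary least squares of the blood parameter
  (response) on the fat measure (predictor) at each time point, absolute
  and Δ-vs-Δ from the preoperative value, p-values unadjusted. A perfect
  fit reports SE 0 with the smallest positive double as p sentinel.
  Baselines for Δ: MRI compartments use the mean of the three t = 0
  replicates; blood and BMI use the single preoperative value.
- **HOMA-IR** = glucose [mmol/L] × insulin [μU/mL] / 22.5, computed
  row-wise, never simulated directly.
- **Percent decline** = 100·(1 − value/baseline); cohort summaries are
  the mean of per-subject declines (mean of ratios, not ratio of means).

## Numerical choices and degenerate inputs

- Gauss–Newton convergence: relative RSS change < 1e-10 or 500
  iterations; a stalled line search at a stationary point counts as
  converged. Fewer than 4 points, identical times, or non-positive
  values are errors.
- Decay-rate correlation matrices are factored via Cholesky with an
  eigen-decomposition fallback so perfectly correlated (singular) but
  valid specifications still draw; negative-definite specifications are
  configuration errors.
- All randomness flows from a single `numpy` Generator seeded by the
  configuration; identical configuration + seed gives bit-identical
  tables and phantom volumes.
- Pipeline problem sizes: the default run is one 16-subject cohort, one
  96×96×72 phantom at 2 mm voxels, 64 subject fits, 6 paired tests and
  ~250 regressions; it completes in seconds on one CPU. Monte-Carlo
  checks in the test suite use 100–200 seeded replicates and n = 2000
  parameter draws, chosen to make 5–15% tolerance bands statistically
  comfortable while keeping the suite fast.

## Known limitations

- The two-stage population fit ignores shrinkage; with very noisy
  subjects its between-subject SDs overstate the true heterogeneity
  (estimation noise is not subtracted).
- The %-LF rebound slope is weakly identified at realistic measurement
  noise (see above); its population estimate should be read with its SE.
- The generator's associations are static cross-sectional links to
  liver fat; it cannot reproduce time-point-specific association
  patterns.
- The exact Wilcoxon switches to the approximation in the presence of
  ties even for small n; with heavily tied data the reported p is
  asymptotic.
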