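# Methods

This note documents the models behind `glygfr`, the synthetic-cohort
generator and its calibration, the numerical choices, and the known
limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Closed-form equations

**Du Bois BSA.** `dubois_bsa(h, w) = 0.007184 · (100·h)^0.725 · w^0.425`
with height in metres (converted to cm internally) and weight in kg.
Strictly increasing in both arguments; non-positive inputs raise a domain
error.

**CKD-EPI (2009, creatinine).** Only the non-black constants are
implemented, as this package targets populations where that is the form
applied; no race multiplier is exposed. Four branches keyed by sex and the
sex-specific creatinine knot (0.7 mg/dL women, 0.9 mg/dL men):
`eGFR = k · (SCR/κ)^α · 0.993^age` with k = 144 (F) / 141 (M), α = −0.329
(F, SCR ≤ κ), −0.411 (M, SCR ≤ κ) and −1.209 above the knot. The two
branches agree at the knot for any age (continuity is a tested property).

**MDRD.** `175 · SCR^−1.154 · age^−0.203 (· 0.742 if female)`. Age 0 is a
domain error (negative power of zero).

**Stratified approximating equations (`EquationSpec`).** A set of sex ×
creatinine-interval strata, each carrying an intercept and coefficients
for age, HbA1c, FPG and SCR on the log scale; the prediction is
`exp(intercept + Σ β_v · x_v / scale_v)`. Intervals are half-open
`[lo, hi)` — the lower bound belongs to the stratum — with the bottom
stratum starting at 0 and the top extending to +∞, so every positive
creatinine maps to exactly one stratum per sex; validation rejects gaps
and overlaps.

**Scaling of the built-in `pima` spec.** The published stratified
coefficients come without stated variable units, and raw-unit evaluation
gives implausible magnitudes (e.g. −0.14 per *year* of age). The shipped
spec therefore declares explicit divisors: **age in decades, FPG per
100 mg/dL, HbA1c and SCR unscaled**. This is an inference, not a
published statement; it is supported by the companion longitudinal
regression for log aGFR, whose per-year age coefficient (−0.0100) and
per-10 mg/dL FPG coefficient (+0.0061) match the stratified coefficients
(≈ −0.1 per decade, ≈ +0.06 per 100 mg/dL). Predictions from the shipped
spec should be treated as provisional; re-deriving coefficients from data
with `cross_validate` is the canonical route. Two typographic anomalies in
the source table are normalized (the men's top-stratum HbA1c coefficient
"00.328" → 0.0328 and its interval label "SCR ≥ −0.90" → SCR ≥ 0.90).

**Hyperfiltration.** Default rule: measured aGFR strictly greater than
120 mL/min/1.73 m²; the comparison is configurable (`"ge"`) because usage
varies between strict and inclusive in the literature. Labels for ROC
analysis always come from measured aGFR, never from an estimator.

**Eligibility.** Exams with CKD-EPI eGFR < 60 mL/min/1.73 m² are excluded
(hyperfiltration cannot, by definition, occur in established CKD, and
creatinine equations perform well below 60). The filter strictly excludes
< 60 and keeps 60.0; it preserves subject grouping and re-sequences
`exam_index`. An `agfr` mode filters on measured aGFR instead, provided
as a sensitivity-analysis convenience.

## 2. The synthetic cohort generator

The generator emulates a longitudinal cohort of adults with type 2
diabetes followed with repeated iothalamate clearance studies: by default
269 subjects contributing exactly 2798 eligible examinations. It exists
because the data it emulates are private; it gives the derivation and
evaluation machinery a realistic, fully known truth to be tested against.

Structure, per subject:

* sex female with probability 1948/2798 (the cohort's female share of
  exams);
* entry age ~ Normal(32.2 + 0.9·male, 7.0²) truncated to the 18–65
  recruitment range;
* raw exam count 1 + Binomial(14, p) with mean 12.2. A binomial rather
  than a Poisson keeps count dispersion modest: with ~12 exams spaced ~3
  years apart, high-count subjects dominate the exam-level age spread, and
  Poisson dispersion inflated the exam-level age SD well beyond the
  cohort's ~10–11 years;
* inter-exam gaps ~ Normal(2.60, 1.9²) truncated at 0.25 y. The raw mean
  2.60 is calibrated so the **observed** mean gap between retained
  adjacent exams is ≈ 3.3 y: truncation and the removal of ineligible
  exams (which merges adjacent gaps) both stretch observed gaps;
* height fixed per subject; weight = subject effect + exam noise, with the
  published per-sex means/SDs and a 2/3-between / 1/3-within variance
  split (the published SDs conflate both levels; the split is a modelling
  choice);
* FPG and HbA1c: a standardized bivariate pair with cross-correlation
  0.71 at both the subject level and within subjects (Gaussian copula),
  the within part a stationary AR(1); scaled to the per-sex means/SDs and
  clipped to physiological ranges (FPG ≥ 50, HbA1c in [4.5, 18]);
* serum creatinine through the reciprocal scale:
  `1/SCR = 1.4931 + 0.2821·female − 0.0082·age + 0.0287·HbA1c −
  0.0043·FPG/10 + u`, u a stationary AR(1) residual; SCR = 1/(1/SCR),
  clipped to [0.3, 15] mg/dL. Generating on 1/SCR is both the scale on
  which creatinine was modelled and a guarantee of positivity;
* log aGFR: `5.8502 − 0.2151·female − 0.0100·age − 0.8639·SCR +
  0.0061·FPG/10 + 0.0061·HbA1c + v`, v a stationary AR(1) residual;
  measured (unadjusted) GFR is back-computed as aGFR·BSA/1.73;
* diabetes duration = entry duration (≥ 0, mean ≈ 1 y) + elapsed
  follow-up.

AR(1) residuals are indexed by **exam order**, not elapsed time — the
simplest reading of "autoregressive within-subject correlation" when the
original indexing is unspecified — with lag-1 correlation 0.6 by default.

Exams failing the eligibility filter are dropped and the surplus is
trimmed deterministically (last exams of the largest subjects first) so
the eligible total is exact. The returned `SimulatedCohort` carries the
latent AR(1) residuals row-aligned with the cohort, so tests can verify
the generative state directly. Everything is deterministic given the
seed.

### Calibration

The regression skeletons above are fixed; the free parameters — the two
residual SDs, the AR lag-1 correlation, the copula correlation, the entry
age distribution, the count distribution and the raw gap mean — were
calibrated once, by simulation, against the published cohort statistics:
the per-sex covariate means/SDs, the FPG–HbA1c correlation (0.71), the
mean measured aGFR (130.45), the observed mean inter-exam gap (3.3 y), and
the variance-explained decomposition of log aGFR (≈ 44.8% from
age + sex + SCR, ≈ +2.7 points from adding FPG + HbA1c). The frozen
values are the dataclass defaults (`1/SCR` residual SD 0.50, log-aGFR
residual SD 0.24). Two headline quantities are deliberately **not**
parameterized and emerge from the interplay of the skeletons: the mean
CKD-EPI eGFR (≈ 104.7 simulated vs 104.73 published) and the mean
aGFR − eGFR gap (≈ 25.5 vs 25.7).

### What the generator does not reproduce

* **Per-sex aGFR symmetry.** The published cohort shows essentially equal
  mean aGFR in men and women (130.5/130.4). The published log-aGFR
  regression evaluated at the per-sex covariate means, however, implies
  women ≈ 4–6% below men, and any generator built on those two published
  layers inherits the asymmetry (simulated ≈ 138 men / ≈ 127 women; the
  pooled mean matches). The real cohort's covariate joint distribution
  evidently differs from the independence structure a moment-matching
  simulator imposes. Tests therefore assert pooled means.
* **Diabetes duration level.** Duration must advance in lockstep with
  follow-up time (mean elapsed ≈ 15 y at the exam level), so its
  exam-level mean (~15.5 y) overshoots the published 12.5/13.5 y; in the
  real cohort duration and follow-up were decoupled by staggered entry.
  Duration is excluded from the approximating equations, so this affects
  only the difference-model covariate.
* No treatment effects, no assay-era creatinine drift, no informative
  dropout. Passing tests on simulated cohorts demonstrate that the
  *machinery* is correct under a known truth resembling the study
  conditions — not that the shipped coefficients transfer to any real
  population.

## 3. The derivation pipeline

**AR(1) maximum-likelihood regression** (`fit_lmm_ar1`). For subject *i*
with mᵢ exams, residuals are modelled N(0, σ²R(ρ)) with R_jk = ρ^|j−k|.
The likelihood is evaluated in closed form via the Prais–Winsten
whitening transform (first exam scaled by √(1−ρ²), later exams replaced
by eₜ − ρ·eₜ₋₁), which gives |R| = (1−ρ²)^(mᵢ−1) and reduces each profile
evaluation to one least-squares solve. ρ is profiled out by golden-section
search on (−0.99, 0.99) with tolerance 10⁻⁴ (the profile is smooth and
unimodal in practice; the search needs ~20 evaluations). Estimation is by
**maximum likelihood, not REML**, so AIC values are comparable across
fixed-effect sets — the whole point of the model search. AIC counts the
fixed effects, σ and (when estimated) ρ. Fixed-effect covariances come
from the whitened normal equations with the ML σ̂² (no degrees-of-freedom
correction; p-values are normal-based). With one exam per subject and
ρ fixed at 0 the fit reduces exactly to OLS (a tested oracle). Singular
designs raise an error naming the collinear columns. `marginal_r2`
reports 1 − RSS(Xβ̂)/TSS on the raw scale — the "proportion of variance
explained" used for the 44.8%/2.7% decomposition.

**All-subsets AIC selection.** All 2^k − 1 non-empty subsets of the
candidate covariates are fit (k ≤ 10); failures are recorded per subset
rather than raised. Ties break toward fewer variables, then
lexicographically. On default simulated cohorts the selected model
excludes BSA (which has no generative effect) in most seeds.

**Stratification.** Creatinine quartile cut points are computed at the
**exam** level (the published stratum sizes are near-equal in exams, not
subjects), separately by sex, with linear interpolation between order
statistics (quantile "type 7"). Within each of the 8 strata, log aGFR is
regressed on age, HbA1c, FPG and SCR by **ordinary least squares**: these
are prediction equations, not inferential fits, the source reports no
standard errors for them, and OLS matches the prediction objective.
Degenerate (tied) cut points collapse to fewer strata with a warning;
strata with ≤ 5 exams raise an error naming the stratum.

**Cross-validation.** Subjects (never exams) are randomly partitioned
into k = 10 folds whose sizes differ by at most one (269 → nine folds of
27 and one of 26). For each fold, cut points *and* stratified equations
are estimated on the training subjects only — cut points are re-estimated
per fold rather than fixed from the full data, the leakage-safe choice
when the original protocol is unspecified — and predictions are made for
the held-out subjects, so every exam receives exactly one out-of-fold
prediction from a fit that never saw its subject. The final equation set
averages the 10 training fits stratum-by-stratum (strata aligned by
creatinine rank within sex; cut points averaged). Fold assignment takes a
required seed.

**Difference model.** The accuracy gap aGFR − CKD-EPI eGFR is regressed
on sex, age, SCR, FPG/10, HbA1c and duration via the same AR(1) fit; on
default cohorts the glycemia coefficients are positive (glycemia raises
measured filtration but not creatinine-based estimates).

## 4. Evaluation

* **P30**: share of estimates with |estimate − aGFR| ≤ 0.30·aGFR — the
  band is **inclusive** at exactly 30%. Scale-invariant by construction.
* **Bias** is reported as mean(aGFR − estimate), positive when the
  estimator runs low; `bias_by_level` shows it within equal-count
  (default 10) bins of measured aGFR, exposing the level-dependent
  underestimation of creatinine-only equations.
* **Dependent correlations**: the Meng–Rosenthal–Rubin Fisher-z test for
  two overlapping correlations sharing the measured aGFR, using the
  correlation between the two estimators. n is the number of exams;
  with ~10 exams per subject this overstates the effective sample size,
  so its p-values are anticonservative for clustered data — the caveat
  travels with the CLI output. Identical estimators short-circuit to
  z = 0, p = 1.
* **ROC/AUC**: thresholds sweep the midpoints between adjacent unique
  scores (plus ±∞); a case is called positive when the estimate is ≥ the
  threshold. The AUC is the Mann–Whitney statistic computed from average
  ranks, giving ties half credit; tests verify exact agreement with
  exhaustive pair counting.
* **DeLong test**: placement values per positive and per negative case
  give the covariance of the two AUCs; the variance of the difference
  feeds a normal z. Verified against a paired bootstrap (within 20% on a
  60-point set) and calibrated under the null (~5% rejection at α=0.05).
* **threshold_at_specificity** returns the smallest threshold whose
  specificity meets the target (hence the most sensitive qualifying
  operating point), with the achieved specificity.

## 5. Numerical and interface conventions

* Natural logarithms throughout (the log-aGFR intercept 5.85 ≈ ln 130 is
  only coherent in base e).
* Cohort CSV: comma-separated, UTF-8, "." decimal, header required,
  empty cell = missing (legal only for duration and the GFR columns); sex
  coded M/F case-insensitively. Invalid rows are reported with line
  numbers and skipped, or fatal under `--strict`.
* Equation specs serialize to flat JSON and round-trip bit-exactly
  (±∞ included). The built-in `pima` spec ships as a packaged resource.
* CLI exit codes: 0 ok, 1 usage, 2 validation, 3 computation failure.
  Every run logs version, seed, a config hash and input-file SHA-256s;
  outputs are never overwritten without `--force`.
* Simulation problem sizes in tests: most properties use a 60-subject /
  600-exam configuration; calibration and recovery checks use the full
  269/2798 cohort, with 5 seeds for moment targets and 20 seeds for
  coefficient recovery — enough to put Monte-Carlo error well inside
  every stated tolerance.

## 6. Known limitations

* The shipped `pima` coefficients inherit the scaling inference above and
  the source table's typographic ambiguities; they are provided for
  reproducibility, not clinical use.
* Only mg/dL units are supported (no µmol/L or mmol/L auto-conversion);
  no cystatin-C, 2021-refit or pediatric equations.
* The AR(1) correlation is discrete-lag; continuous-time decay,
  compound symmetry, random slopes and GEE are out of scope.
* The dependent-correlation and DeLong tests treat exams as independent;
  no design-effect correction for repeated measures is applied.
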