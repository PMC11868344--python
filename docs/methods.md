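# Methods note

This note records the statistical model behind `retroscore`, what the
synthetic cohort generator does and does not emulate, and the numerical
conventions the package commits to. It is the reference for anyone
extending the package or comparing its output to other implementations.

## 1. Data model and scoring

The unit of observation is one rated school report: a
(participant, school year, term, rater) cell carrying exactly 22 scores —
11 criterion scales (A1a–A1i inattention subcriteria, A2H hyperactivity,
A2I impulsivity) × 2 valences. Symptom scores are ordinal 0/1/2;
competency scores binary 0/1. "Not mentioned" is an explicit 0, never a
missing value: a teacher's silence about a behaviour is treated as absence
of evidence for it, which is a substantive modelling commitment and the
reason complete 22-score reports are enforced at validation time.

Scoring proceeds in two aggregation steps:

1. **Year scores** — per scale, the mean over the report terms available
   in that school year (1 or 2, weighted equally), then summed across
   scales per valence: `symptom_sum` ∈ [0, 22], `competency_sum` ∈ [0, 11].
   Inattention means over the nine A1 subcriteria are kept alongside.
2. **Participant summaries** — the unweighted mean of the yearly values
   over whatever school years the participant has (no imputation of
   missing years), and the integrated index

   `integrated_index = summary_competencies − summary_symptoms`,

   i.e. symptom weight −1, competency weight +1, so cases score **low**.

Binary classification against a threshold *t* is strict: a value exactly
at the threshold is classified negative for every orientation. The default
threshold rules are symptoms > 2.94, competencies < 1.93, and integrated
index < −0.59. The last is stored on the index's own (competencies −
symptoms) scale; it is equivalent to flagging a symptoms-minus-competencies
difference strictly greater than 0.59.

When a table contains several raters, scoring refuses to aggregate
silently (`AmbiguityError`); the caller must either `select_rater` (the
pipeline defaults to rater "R1", the convention that the primary rater's
codes are analysed and the second rater exists for reliability) or form
`consensus_scores`, the per-record mean of the two raters (fractional
scores are then legitimate downstream).

## 2. Reliability

Interrater agreement per (scale, valence) is Cohen's kappa with quadratic
weights w_ij = (i − j)², computed on the full category grid (3 symptom
categories, 2 competency categories) even when a category is unobserved,
so that weights keep their intended meaning on sparse tables. For binary
scales quadratic weighting coincides with unweighted kappa. When the
chance-expected weighted disagreement is zero (e.g. both raters constant)
kappa is undefined and the package raises `UndefinedStatisticError`
rather than returning a conventional value.

## 3. ROC, cutpoints, DeLong

AUC is computed by the Mann–Whitney identity via midranks (cross-class
ties count ½). ROC thresholds are the midpoints between consecutive
distinct scores, plus endpoints below and above the score range; with
strict `>`/`<` decisions this enumerates every achievable
(sensitivity, specificity) pair exactly, with no interpolation.

Cutpoint selection is exhaustive over these candidates, under two
objectives: `max_youden` (maximise J = sensitivity + specificity − 1) and
`max_sens_at_spec` (maximise sensitivity subject to specificity ≥ floor;
an unachievable floor raises `InfeasibleConstraintError`). Ties are broken
deterministically — by higher specificity, then by the larger threshold —
so results are reproducible across platforms.

Correlated ROC curves are compared with DeLong's test using placement
values (structural components) with ½-credit for ties; the variance of the
AUC difference comes from the empirical covariance of the placement
values. Identical score vectors short-circuit to z = 0, p = 1; a zero
variance with unequal vectors (e.g. two perfectly separating scales)
raises `UndefinedStatisticError`.

The package ships a small reference table of published cutpoints
(`REFERENCE_CUTPOINTS`) with a `youden_consistent` flag per row: two of
the nine rows do not satisfy J = se + sp − 1 at printed precision, and the
flag records that rather than silently "correcting" the source.

## 4. Mixed models

Yearly scores are modelled with a linear mixed model

    y_ij = β₀ + β_g·case_i + Σ_y β_y·1[year_j = y]
         + Σ_y β_{gy}·case_i·1[year_j = y] + u_i + ε_ij

with a participant random intercept (school year enters as a categorical
fixed effect; year 1 is the reference level). Fitting uses
`statsmodels.MixedLM`, REML by default, ML whenever likelihoods are
compared across fixed-effects specifications.

Inference on the group effect is organised as four Wald chi-square
families built from linear contrasts c′β with statistic
(c′β)² / (c′V̂c) ~ χ²(1):

1. **group_overall** — the group difference averaged over the four years;
2. **group_by_year_linear** — the linear trend of the group difference
   across centred school years;
3. **per-year group differences** — four contrasts, Holm-corrected;
4. **year-1 vs each later year** within the group difference — three
   contrasts, Holm-corrected.

Holm correction is applied within a family, never across families.

Optionally, a random-structure selection ladder compares (a) correlated
random intercept + year slope, (b) uncorrelated intercept + slope, and
(c) intercept only, descending by ML likelihood-ratio tests whose p-values
are halved to account for the variance-at-boundary null. With only two
distinct years the slope is confounded with the residual and the ladder
returns the intercept model; with a single year even the intercept model
is unidentifiable against the residual and selection raises
`EstimationError` (fitting a fixed intercept-only structure on one year is
still allowed, selection is not).

## 5. Synthetic cohort generator

The generator exists to exercise the pipeline and to provide
known-truth calibration targets; it is not a calibrated simulation of any
real cohort. Its data-generating process:

* latent scale propensity for participant i, year offset y₀ = year − 1:

      η = β_group·g + β_year·y₀ + β_interaction·g·y₀ + u_i + ε,
      u_i ~ N(0, σ²_p),  ε ~ N(0, 1) per (report, scale)

* symptom score by ordered probit with fixed cutpoints (0.75, 1.75);
* competency score ~ Bernoulli(expit(c₀ − c_g·g − κ·(u_i + ε))), i.e.
  competencies are negatively coupled to the same latent liability;
* per year, 2 report terms with probability `p_two_reports`, else 1;
* case reports flagged `medicated` with probability `p_medicated` per term;
* a second rater obtained by perturbing each score by ±1 (clamped to the
  score domain) with probability `rater_error`.

**Defaults** (chosen a priori to give a recognisable clinical-vs-control
contrast with imperfect separation, not tuned to outputs): 100 cases +
100 controls, β_group = 1.5, β_year = 0.0, β_interaction = −0.3,
σ_p = 0.8, cutpoints (0.75, 1.75), c₀ = 0.5, c_g = 1.5, κ = 0.5,
p_two_reports = 0.85, rater_error = 0.05, p_medicated = 0.2.

**Reproducibility design.** Every participant gets an independent RNG
substream `default_rng([seed, stream, index])` (streams: 0 cases,
1 controls, 2/3 the second rater's perturbations). Consequences: output
is byte-identical across runs and platforms for a given config, and
enlarging the cohort never changes previously generated participants.

**What it deliberately does not emulate**: teacher-specific writing
styles, non-stationary rater drift, correlated missingness of school
years, any dependence between medication and observed scores (the flag is
random, so medication-exclusion reruns test plumbing, not confounding),
and real-cohort score distributions.

**Closed-form truth helpers** for calibration tests: the expected ordinal
symptom score marginal over u is Φ̄((c₁−μ)/s) + Φ̄((c₂−μ)/s) with
s = √(1+σ²_p); `expected_symptom_sum_difference` is 11× the case−control
difference of that expectation; `latent_auc` = Φ(Δ/√(2+2σ²_p)) is the AUC
of a **single** latent record, not of the multi-year summary score (the
summary averages away noise and sits between that value and the
infinite-report bound Φ(Δ/(√2·σ_p)); the tests check exactly that
sandwich).

## 6. Numerical conventions

* Ties at a classification threshold are negative; cutpoint ties break to
  higher specificity then larger threshold (§3).
* JSON outputs are deterministic: keys sorted, floats serialised at 12
  significant digits (`f"{x:.12g}"`), LF line endings; CSV output is
  written in a fixed canonical sort order.
* Derived seeds are kept below 2³¹.
* Estimation failures, undefined statistics, degenerate inputs and
  infeasible constraints raise typed exceptions
  (`EstimationError`, `UndefinedStatisticError`, `DegenerateInputError`,
  `InfeasibleConstraintError`) instead of returning NaN.
* Test problem sizes were fixed before results were inspected: 200
  random instances for the AUC and cutpoint oracle-equivalence checks,
  2000 bootstrap replicates (15% tolerance) for the DeLong variance, 500
  null replicates of 40 + 40 participants for the type-I-error check
  (observed rate is asserted within 0.05 ± 0.02), and 100 + 100
  participants for effect recovery within two standard errors.

## 7. Limitations

* The random-intercept LMM treats yearly scores as Gaussian although they
  are bounded sums of ordinal items; with 22-point sums this is the usual
  pragmatic approximation, but tail probabilities from the Wald tests
  should not be over-interpreted.
* Wald chi-squares use the estimated covariance without small-sample
  (Kenward–Roger-type) correction; the type-I calibration above shows this
  is adequate at 40 + 40 participants under the generator's null, not in
  general.
* Kappa is computed per scale; no pooled or hierarchical reliability model
  is provided.
* The published threshold values (2.94, 1.93, −0.59) are fixed constants
  from prior work; the package can re-derive sample-specific cutpoints but
  makes no claim that the shipped constants transfer to other populations,
  school systems or languages.
* The generator's competency channel is a single Bernoulli layer coupled
  to the symptom liability; it cannot represent competencies that are
  informative *beyond* symptoms in more structured ways.
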