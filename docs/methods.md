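# Methods

## The triage model

The sequential algorithm is a deterministic decision rule over two serum
indices. All interval boundaries are closed-low / open-high:

| input | rule | output |
|---|---|---|
| FIB-4 < 1.30 | first-line rule-out | F0–1 |
| FIB-4 ≥ 2.67 | first-line rule-in | F3–4 |
| 1.30 ≤ FIB-4 < 2.67, ELF < 8.30 | second-line rule-out | F0–1 |
| 1.30 ≤ FIB-4 < 2.67, ELF ≥ 9.50 | second-line rule-in | F3–4 |
| 1.30 ≤ FIB-4 < 2.67, 8.30 ≤ ELF < 9.50 | doubly intermediate | F2–4 (indeterminate) |

`assign_tier` is total on its precondition domain, monotone in each
biomarker, and lazy in ELF: outside the intermediate FIB-4 band the tier is
invariant to ELF, including a missing ELF. A strict mode
(`CutoffConfig(require_elf_always=True)`) demands ELF for every record, for
cohorts where the second-line assay was run universally. Ages are accepted
real-valued; the FIB-4 formula is evaluated without rounding, so boundary
classification never depends on display precision.

Transient elastography is an *advisory overlay*, never a reclassifier: for
a valid exam (IQR/median < 0.30 and ≥ 10 measurements) the overlay reports
concordance of stiffness with 9.6 kPa (F3–4 tier), 7.0 kPa (F2–4 tier) and
8 kPa (the F ≥ 2 union of the two high-risk tiers). Invalid exams yield
all-n/a concordance. Concordance is gated on validity because quality
criteria are part of the measurement's definition; whether any source
cohort applied the gate when summarising stiffness is not decidable from
printed summaries.

HOMA-IR = glucose[mg/dL] · insulin[µU/mL] / 405 is a first-class tri-state
(value / excluded / missing): patients on insulin treatment return an
explicit `HOMA_EXCLUDED` marker — the model assumes endogenous insulin —
so downstream summaries can report true denominators. IR is flagged at
HOMA-IR ≥ 3.02.

## Accuracy evaluation

Four binary tasks dichotomise the 0–4 biopsy stage: detect-F0–1 ({0,1}),
detect-F3–4 ({3,4}), detect-F2–4 and detect-F≥2 (both {2,3,4}; the former
is predicted by the indeterminate tier alone, the latter by the union of
the two high-risk tiers). For the F0–1 and F3–4 tasks the indeterminate
tier is neither positive nor negative by rule; an explicit policy decides:

* `negative` (default): indeterminate counts as test-negative, keeping
  full-cohort denominators — under which PPV/NPV computed from counts
  coincide with the Bayes identity at the empirical prevalence to
  machine precision, and which reproduces the published predictive values
  for the rule-out/rule-in rows;
* `exclude`: indeterminate records leave the table (reported in
  `n_excluded`), the convention some diagnostic studies use for "grey
  zone" results;
* `positive`: the conservative screening reading.

Proportion CIs default to Wilson score intervals (Clopper–Pearson
available); the CI method behind the published tables is unstated, and
Wilson has the better small-sample coverage. Empirical coverage at n = 50,
p = 0.8 sits within [0.92, 0.98] over 5,000 replicates (tested).

ROC-AUC is the Mann–Whitney probability with half-credit ties. CIs:
stratified bootstrap (2,000 resamples, seeded) by default, DeLong-style
rank-variance closed form as the cheap alternative. For the two-cut-off
algorithm the AUC score is the ordinal tier (F0–1 < F2–4 < F3–4), oriented
per task; the F2–4 task uses the tier-membership indicator instead, since
the middle tier is not ordinally extreme. How the published algorithm AUCs
were computed is unstated; the ordinal-tier convention is documented here
as this package's choice.

Logistic fits (the bivariate FIB-4 + ELF model) use Newton/IRLS maximum
likelihood and raise an explicit separation error — rather than returning
divergent coefficients — when the likelihood has no interior maximum. No
multiple-testing correction is applied anywhere.

## Synthetic cohorts

The generator emulates two cohort shapes:

* **labelled NASH-like** (default n = 140): exact per-stage counts
  38 / 23 / 79 for F0–1 / F2 / F3–4 (stratified sampling, prevalence is
  never stochastic), stage-conditional FIB-4/ELF/stiffness lognormals,
  coarse stage labels refined uniformly (F0 vs F1, F3 vs F4 — only coarse
  groups are published), T2D assigned Bernoulli(0.66) and sex
  Bernoulli(81/140 female) to match the published cohort composition;
* **unlabelled primary-care-like** (T2D follow-up, n = 141; CLD initial
  study, n = 138; any n on request): a single marginal FIB-4/ELF pair.

Biomarkers are lognormal because they are positive and right-skewed and
the sources publish medians with IQRs. From a printed median (Q1–Q3) the
symmetric log-quartile estimator sets μ = ln(median),
σ = (ln Q3 − ln Q1) / (2 z₀.₇₅). This preserves the median exactly and the
IQR in log width; when printed quartiles are log-asymmetric (the T2D FIB-4
summary is: ln(Q3/med) = 0.251 vs ln(med/Q1) = 0.336) the fitted Q1/Q3
individually shift a few percent while their ratio is preserved — the
documented approximation. Parameter recovery from sample quartiles at
n = 10⁵ is tested on the natural scale (median within 2% relative, σ
within 2%); the log-location μ itself sits near zero for FIB-4, where
relative error is ill-posed.

The FIB-4/ELF joint distribution is a Gaussian copula on the log scale
with correlation ρ, default 0: the sources publish marginals only, and
independence already reproduces the published staged fractions within the
acceptance tolerance. ρ is configurable in [−1, 1] and reported in all
outputs. `tier_probabilities_closed_form` integrates the copula over the
nine threshold rectangles (bivariate normal CDFs; products of univariate
CDFs at ρ = 0) and is the analytic oracle against which sampled staged
fractions are tested (within 3 binomial SEs at n = 10⁵ for
ρ ∈ {0, 0.3, 0.6}).

PRNG contract: one master `SeedSequence` spawns one child per stage (or
marginal pool) and, within each, separate streams for biomarkers, TE,
histology refinement and covariates — enabling TE sampling cannot perturb
the FIB-4/ELF draws. Same (spec, seed) ⇒ byte-identical cohorts (tested by
checksum).

ELF draws are truncated to the assay plausibility window [5, 15]
(truncation mass ~10⁻⁵ for the calibrated specifications), so every
generated record passes record validation. Histology components other than
the fibrosis stage (steatosis, inflammation, ballooning) are drawn
uniform and uncalibrated — only the stage carries truth. TE draws are
independent of FIB-4/ELF given the stage, and simulated exam quality is
always valid (IQR/M ~ U(0.05, 0.25), 10 shots).

What passing tests therefore do **not** show about real data: the
generator has no FIB-4–ELF dependence beyond the copula, no biopsy
misclassification (real biopsies misgrade a substantial minority of
cases), no age–ELF dependence (ELF rises with age in reality), and no
per-stage covariate shifts. Accuracy numbers computed on synthetic
cohorts validate the *machinery* (counting, CIs, Bayes closure,
additivity), not the published point estimates, which would require the
original patient data.

## Numerical choices

* Unit guard: platelets are strictly 10⁹/L; values > 1000 are rejected as
  probable cells/µL (configurable), because the mis-unit silently scales
  FIB-4 by ×10⁻³.
* Rounding: rendered percentages use decimal half-up (0.805 → 81;
  scaling happens in decimal arithmetic because 0.805·100 = 80.4999… in
  binary floats); machine outputs keep full precision.
* Tier probabilities are validated to sum to 1 within 10⁻⁸ and
  renormalised; bivariate CDF calls special-case ρ = 0 and infinite
  bounds.
* Undefined metrics (empty denominators, single-class AUC) are explicit
  `None`-valued estimates with reasons, never NaNs.
* Logistic convergence requires gradient norm < 10⁻⁸; fitted
  probabilities within 10⁻¹⁰ of 0/1 are treated as quasi-separation.

## Problem sizes

The test suite and the acceptance script simulate primary-care cohorts at
n = 10⁵ (binomial SE on a tier fraction ≈ 0.14 percentage points, an
order of magnitude below the ±3-point acceptance band) and labelled
cohorts at the published n = 140. Bootstrap AUC CIs use 2,000 resamples.

## Known limitations

* The ELF immunoassay's analyte-combination formula is not implemented;
  ELF is a consumed numeric input.
* No TE-only staging pathway and no age-adjusted ELF cut-offs.
* The F2–4 and F ≥ 2 published rows are not Bayes-consistent with
  full-cohort denominators; the denominators actually used are not
  recoverable from the publication, which is why all three indeterminate
  policies are exposed rather than one guessed.
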