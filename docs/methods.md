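# Methods

## The screen

`mwascreen` implements a medication-wide association study (MWAS) of
pregnancy outcomes: every prescription medication a delivery cohort was
exposed to during pregnancy is tested, one at a time, against each of
three binary delivery outcomes — cesarean section, preterm birth, and
stillbirth — with a fixed set of comorbidity adjustments. The analysis
model for a medication *m* and outcome *Y* is the logistic regression

    logit P(Y = 1) = β₀ + β₁·E_m + β₂·age + γ'·C

where `E_m` is a binary pregnancy-exposure indicator, `age` is maternal
age at delivery in completed years (continuous, untransformed), and `C`
is a vector of 16 binary comorbidity flags. The reported quantity is the
adjusted odds ratio `exp(β₁)` with a Wald 95 % interval
`exp(β₁ ± 1.959964·SE)` and a two-sided Wald p-value. Bonferroni
correction multiplies each nominal p by the family size *m* (capped at
1); the default family is every medication × outcome pair in the screen,
and both the size and the definition of the family are printed in every
report header, because per-outcome families are an equally defensible
choice and the two give different corrected inferences. The stricter
significance flag (`**`) requires both the nominal and the corrected p
to be at or below α.

Deliveries are analysed as independent observations even when one
patient contributes several; an optional patient-clustered sandwich
variance (`cluster_groups`) is provided as an extension and is off by
default.

### Exposure definition

A delivery is exposed to a medication variable iff the patient has at
least one order of any raw drug name mapping to that variable dated
between 280 days and 1 day before the delivery date, both bounds
inclusive. The bounds are whole-day arithmetic; inclusivity was chosen
so that "280 days before" and "1 day before" are both in-window.
Brand/generic merging happens through a many-to-one drug-name map before
any counting, so exposure is invariant to how orders are spelled.
Combination products with additional active ingredients keep their own
variable. Variables prescribed to fewer than 10 distinct patients
in-window are dropped before the screen (a privacy measure that also
avoids hopeless estimation); counting distinct patients rather than
deliveries follows the usual phrasing of such thresholds, and
delivery-level counting is available as a switch.

### Covariates

The 16 default comorbidity covariates are infectious disease, obesity,
cancer, cardiovascular disease, circulatory disease, cerebrovascular
disease, respiratory disease, immune disorders, organ transplant,
obstetric history, maternal care, preeclampsia, multiple birth, drug
allergies, procedures, and drug resistance. Reference cohort tables in
this literature sometimes tabulate a slightly different comorbidity list
(17 rows, with adverse-drug and toxic-effect rows and no drug
resistance); the covariate set is therefore config-driven, with the
16-name list as the default. A flag is set iff at least one matching
diagnosis falls in the lookback window of 730 days before delivery up to
the day before delivery. "Two years" is implemented as exactly 730 days
rather than calendar-year arithmetic so the window is deterministic
across leap years. Delivery-day diagnoses are excluded: they are
usually part of the delivery episode (often the outcome itself), not
pre-existing conditions.

### ICD code matching

Codes are normalized (uppercase, periods stripped) before matching, so
dotted/undotted and cased dialects are interchangeable. A code set holds
exact members and optional prefixes; prefix matching exists because
phenotype lists are often stated at the parent-code level while billing
uses child codes, and it can be disabled per set. The inferred ICD
revision label is informational only; codes beginning with E or V are
left unresolved since both revisions use those letters. The packaged
vocabulary is deliberately small and illustrative — real analyses should
load their own curated lists through the same file format.

### Outcome ascertainment

An outcome flag is set iff at least one diagnosis for the patient dated
ON the delivery date matches the outcome's code set. Delivery-day
matching is the default because outcome codes are billed with the
delivery; a configurable backward window exists for sensitivity
analyses. Duplicate same-day delivery rows for a patient collapse to one
delivery (a twin birth is a multiple-birth covariate, not two
deliveries).

## Numerical choices

- Maximum-likelihood logistic fits use Newton's method
  (`statsmodels.Logit`, up to 100 iterations).
- **Separation**: if the fit fails, does not converge, or the exposure
  coefficient exceeds 10 in absolute value on the log-odds scale, the
  pair is flagged and no estimate is reported. Flag-and-withhold was
  chosen over penalized (Firth-type) likelihood to keep the reported
  estimand the plain MLE throughout.
- **Nuisance pruning**: adjustment columns that are constant, or binary
  columns whose carriers show no outcome variation, are dropped from
  that fit. Their own MLE is infinite (quasi-separation in a nuisance
  covariate), which stalls Newton without carrying information about the
  exposure coefficient; pruning them leaves the exposure estimate and
  its variance essentially unchanged. This matters mainly in small
  simulated cohorts where rare comorbidities have a handful of carriers.
- Degenerate inputs (constant outcome or exposure vector) produce a
  structured error for a single fit and a flagged row inside a screen;
  a screen never aborts wholesale.
- Percentages in cohort summaries are rounded half-up to two decimals,
  matching the convention of printed clinical tables.
- Results are sorted by (medication, outcome), and every computation is
  invariant to input row order.

## The synthetic generator

Real obstetric EHR cohorts are not shareable, so validation runs on a
synthetic generator whose parameters are exactly the quantities the
screen estimates. Per delivery: comorbidities are Bernoulli with
configured prevalences; maternal age is Normal(29.48, 6.08) truncated to
[12, 55]; each medication exposure is Bernoulli on a logistic scale with
a base rate plus comorbidity terms (treatment by indication); each
outcome is Bernoulli on a logistic scale with a base rate, an optional
age term, comorbidity terms, and the planted medication log odds ratios.
Planted effects are the estimands a correct screen must recover;
comorbidity→exposure together with comorbidity→outcome terms create
genuine confounding that adjustment must remove.

Defaults emulate the margins of a large US tertiary-care obstetric
cohort of ~63,000 deliveries: outcome prevalences 32.99 % / 6.15 % /
0.81 % (cesarean / preterm / stillbirth), the 16 comorbidity prevalences
led by preeclampsia at 8.01 %, and ten candidate medications with base
exposure probabilities equal to their observed exposed-delivery
fractions (together ≈ 3.9 % any-exposure). Two comorbidity prevalences
are reported in the reference tables only as "fewer than 10 patients";
their defaults are the guess 5/63,334 and should be treated as such.
Patients have 1–3 deliveries (weights 0.78/0.19/0.03, mean 1.25,
matching a 63,334-deliveries-per-50,560-patients cohort), generated
independently by default; a patient-level random intercept is available
for robustness experiments. Confounding magnitudes (odds ratios 1.5–4
for comorbidity→outcome, 1.5–3 for comorbidity→prescription) are
plausible values, not estimates.

The latent per-delivery draws are serialized as event tables: exposures
become 1–3 dated orders inside the exposure window with brand/generic
spelling variation; comorbidities become diagnoses dated uniformly in
the lookback, plus a configurable fraction (default 10 %) of stale
diagnoses dated 731–1095 days before delivery that a correct lookback
must ignore; outcomes become delivery-day diagnoses coded from the
outcome sets. Seeding is hierarchical: one named substream per
generation stage, derived from the single seed, so identical configs
give byte-identical tables. A fast path
(`simulate_analysis_matrix`) draws the delivery-level analysis matrix
directly — same generative law, no event serialization — for
replication-heavy calibration studies.

What the generator does **not** emulate: visit-level utilization,
inpatient/outpatient structure, dose/route/duration, coding drift over
calendar time, within-patient outcome correlation (by default), and
informative missingness. Passing tests therefore demonstrate that the
*machinery* is correct under a cohort with the stated marginal and
confounding structure, not that real-data estimates would be unbiased —
confounding by indication in real EHRs is not guaranteed to be captured
by 16 diagnosis flags.

An exact-margins fixture (`exact_margins_fixture`) constructs a
63,334-row delivery table hitting the reference stratum counts exactly,
for validating the summary arithmetic (e.g. 20,894/63,334 → 32.99 %)
independently of any random draw.

## Candidate-drug rule engine

Exclusions are applied drug-wise in a fixed order (no approval →
post-2017 approval → non-pharmaceutical → HIV-only indication → no
reproductive-age female participants), and each excluded drug carries
the first rule it matched, making reason counts well-defined. The
cutoff year is a parameter (default 2017, the end of the observation
window). Trial-wise bookkeeping and registry querying are out of scope.

## Privacy

Every user-facing table passes through small-cell suppression: counts
below 10 render as `*`, and the percentages derived from them are
masked too (a percentage over a known denominator reveals the count).
Sub-threshold counts are also kept out of log messages — dropped
medication variables are logged by name only.

## Validation design and problem sizes

The test suite validates the machinery at four levels, with simulation
sizes chosen to keep the full suite in the minutes range:

1. **Arithmetic** — summary percentages recomputed from the exact-margins
   fixture (n = 63,334, deterministic).
2. **Oracle equivalence** — for 2×2 data without covariates the logistic
   MLE has the closed form OR = ad/(bc); 1,000 random tables with cells
   in [5, 500] must agree to 1e-6 relative error.
3. **Operating characteristics** — type-I error and family-wise error
   under the null generator (confounding on, planted effects zero;
   n = 20,000 deliveries × 200 replicates), planted-OR recovery
   (OR 2.0, n = 50,000 × 30 seeds), and confounding removal
   (true OR 1, n = 100,000, one seed, directional).
4. **Invariants** — rule-engine determinism, window boundary tables,
   and the suppression property under fuzzed configurations.

`scripts/acceptance.py` recomputes the same families of quantities at
moderate sizes (60 null replicates at n = 10,000; 5 recovery seeds at
n = 50,000) plus one end-to-end pipeline run, writing everything to
JSON.

## Known limitations

- Wald intervals and p-values are asymptotic. For the rarest outcome
  (stillbirth, 0.81 %) crossed with lightly prescribed medications, the
  exposed-event count is a small discrete variable and the Wald tail
  approximation becomes *anti-conservative*: occasional 3-events-among-50
  configurations yield nominal p ≈ 1e-3 whose exact null probability is
  nearer 1e-2. Per-test type-I error at α = 0.05 remains calibrated, but
  the family-wise error of the Bonferroni screen can exceed its nominal
  bound because Bonferroni's guarantee presumes valid p-values. This is
  a property of the plain-MLE Wald screen itself; exact or
  likelihood-ratio tests would behave better in that corner and are a
  natural extension.
- Exposure is prescription-based; filling and adherence are unobserved.
- The screen is hypothesis-generating: no causal claim survives the
  design (confounding by indication, outcome-linked prescribing such as
  tocolytic indomethacin).
- Trimester-specific windows are deliberately out of scope; the window
  is constant across pregnancies because conception dates are not
  reliably observed.
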