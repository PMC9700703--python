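# mwascreen

Medication-wide association screening (MWAS) of pregnancy outcomes from
EHR-style event tables.

Information on medication safety in pregnancy is scarce because pregnant
patients are systematically excluded from clinical trials. One way to
generate safety hypotheses is to screen retrospective electronic health
records: take every medication prescribed during pregnancy in a delivery
cohort and test it, one at a time, against adverse delivery outcomes,
analogous to how GWAS/PheWAS screen variants and phenotypes. `mwascreen`
implements that pipeline end to end for three outcomes — cesarean
section, preterm birth, and stillbirth — from four raw event tables
(patients, deliveries, medication orders, diagnoses):

1. **Candidate filtering** — a rule engine applies exclusions to an
   annotated candidate-drug table (no regulatory approval, approval
   after the observation window, non-pharmaceutical products, HIV-only
   indications, trials without reproductive-age female participants).
2. **Outcome ascertainment** — delivery-day ICD-9/ICD-10 diagnosis codes,
   matched against named code sets with dialect normalization and
   optional prefix semantics.
3. **Exposure construction** — a delivery is exposed to a medication iff
   it has ≥1 order of any brand/generic spelling of that ingredient
   dated 280 to 1 days before delivery (inclusive); medications with
   fewer than 10 exposed patients are dropped.
4. **Covariates** — 16 binary comorbidity flags from diagnoses in a
   2-year pre-delivery lookback (delivery day excluded), plus maternal
   age in completed years.
5. **The screen** — for each medication × outcome, a maximum-likelihood
   logistic regression

       logit P(Y=1) = β₀ + β₁·exposure + β₂·age + γ'·covariates

   reporting OR = exp(β₁), a Wald 95 % CI, a two-sided Wald p-value,
   and a Bonferroni-corrected p over the whole screen.
6. **Reporting** — cohort summary and association tables with small-cell
   suppression (counts < 10 masked), forest-plot data export, and a run
   manifest sufficient to rerun bit-identically.

Because real obstetric EHR data cannot be shared, the package includes a
first-class synthetic cohort generator whose parameters (outcome
prevalences, comorbidity prevalences, confounding structure, planted
medication effects) are exactly the quantities the screen estimates, so
every stage is testable without data access. See `docs/methods.md` for
the model, defaults, and limitations.

Intended users: pharmacoepidemiologists and clinical informaticists
prototyping medication-safety screens, and anyone needing a tested,
privacy-aware reference implementation of the exposure-window /
lookback / screen-and-correct pattern.

## Worked example

```python
import mwascreen as mw

# a synthetic cohort at the default study conditions, scaled down
cfg = mw.default_config(n_patients=20_000, seed=7)
cohort = mw.simulate(cfg)

vocab = mw.load_vocabulary(mw.data_path("toy_vocabulary.csv"))
drug_map = mw.DrugMap.read_csv(mw.data_path("drug_map.csv"))

model = mw.MedicationScreen.from_tables(
    cohort.patients, cohort.deliveries, cohort.orders, cohort.diagnoses,
    vocab, drug_map, min_patients=10,
)
results = model.fit()
print(results.summary())
```

which prints (abridged):

```
Medication-wide association screen
======================================================================
deliveries: 25,085   medications: 10   outcomes: 3
adjustment columns: 17
alpha = 0.05; Bonferroni m = 30 (family = all medication x outcome tests in this screen; per-outcome families are a configuration option)
----------------------------------------------------------------------
medication                  outcome      n_exp  OR (95% CI)           p        flags
amoxicillin                 cesarean       124    0.92 (0.63-1.35)    6.86e-01
amoxicillin                 preterm        124    0.84 (0.41-1.74)    6.43e-01
amoxicillin                 stillbirth     124    2.18 (0.53-8.88)    2.78e-01
aspirin                     cesarean        61    0.73 (0.42-1.28)    2.70e-01
aspirin                     preterm         61    1.69 (0.79-3.59)    1.75e-01
...
```

Reading the rows: `n_exp` is the number of exposed deliveries; the OR is
the covariate-adjusted odds ratio for that outcome (here the generator
planted no effects, so estimates scatter around 1); `*`/`**` mark
nominal / Bonferroni significance at α = 0.05; `SEP` marks pairs where
the data cannot support an estimate (e.g. zero stillbirths among the
exposed — the estimate is withheld rather than reported as a huge
spurious OR). `results.frame` gives the same content as a tidy
DataFrame, `results.association_table()` the wide one-row-per-medication
view, and `results.forest_rows()` the significant-effects export.

The same run from the shell:

```bash
mwascreen simulate --n-patients 20000 --seed 7 --out-dir scratch/tables
mwascreen screen --tables scratch/tables --out scratch/results.csv
mwascreen run-all --seed 7 --out-dir scratch/run     # full pipeline + masked reports
```

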