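"""Synthetic obstetric-EHR generator.

Real delivery cohorts assembled from hospital EHRs cannot be shared, so
this module generates the four event tables the screening pipeline
consumes -- patients, deliveries, medication orders, diagnoses -- from an
explicit generative model whose parameters are the quantities the
downstream analysis estimates.  The model is, delivery by delivery:

1. comorbidity covariates  ``C_j ~ Bernoulli(prevalence_j)``
2. maternal age            ``A ~ Normal(mean, sd)`` truncated to [12, 55]
3. medication exposures    ``E_m ~ Bernoulli(expit(logit(base_m) + sum_j C_j * gamma_{j,m}))``
4. delivery outcomes       ``Y_o ~ Bernoulli(expit(logit(base_o) + beta_o (A - mean) + sum_j C_j * theta_{j,o} + sum_m E_m * lambda_{m,o}))``

``lambda`` are the *planted* medication log odds ratios: the estimands a
correctly working screen should recover after adjustment.  ``gamma`` and
``theta`` induce covariate confounding between exposure and outcome.

The latent delivery-level variables are then serialized as events: each
exposed medication becomes 1-3 dated orders inside the pregnancy
exposure window (280 to 1 days before delivery, mixing brand and generic
spellings); each covariate becomes a diagnosis dated inside the 2-year
lookback, plus a configurable fraction of *stale* diagnoses dated 731 to
1095 days before delivery that a correct lookback must ignore; each
outcome becomes a diagnosis coded from the outcome code set and dated on
the delivery day.

Default parameters emulate the margins of a large US tertiary-care
obstetric cohort (~63 000 deliveries, 2010-2017): cesarean section
32.99%, preterm birth 6.15%, stillbirth 0.81%, preeclampsia 8.01%,
mean maternal age 29.48 (SD 6.08), and ~4% of deliveries exposed to the
candidate medications.  See :func:`default_config` for the field-by-field
account.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .errors import ConfigError

__all__ = [
    "SimConfig",
    "SimulatedCohort",
    "default_config",
    "simulate",
    "simulate_analysis_matrix",
    "exact_margins_fixture",
]

OUTCOMES = ("cesarean", "preterm", "stillbirth")

#: The 16 comorbidity covariates adjusted for in the screen, with default
#: prevalences per delivery.  Values follow the reference cohort margins;
#: cerebrovascular disease and drug resistance are reported there only as
#: "fewer than 10 patients", so their defaults are the guess 5/63,334.
DEFAULT_COVARIATE_PREVALENCE = {
    "infectious_disease": 0.0198,
    "obesity": 0.0174,
    "cancer": 0.0063,
    "cardiovascular": 0.0097,
    "circulatory": 0.0007,
    "cerebrovascular": 5 / 63334,
    "respiratory": 0.0027,
    "immune_disorders": 0.0007,
    "organ_transplant": 0.0006,
    "obstetric_history": 0.0029,
    "maternal_care": 0.0042,
    "preeclampsia": 0.0801,
    "multiple_birth": 0.0247,
    "drug_allergies": 0.0049,
    "procedures": 0.0034,
    "drug_resistance": 5 / 63334,
}

#: Default per-medication probability of exposure during pregnancy,
#: set to the observed exposed-delivery fractions of the ten most
#: commonly prescribed candidate medications in the reference cohort.
DEFAULT_MEDICATION_EXPOSURE = {
    "famotidine": 508 / 63334,
    "heparin": 345 / 63334,
    "prenatal_multivitamin": 309 / 63334,
    "amoxicillin": 278 / 63334,
    "enoxaparin": 238 / 63334,
    "folic acid": 162 / 63334,
    "azithromycin": 154 / 63334,
    "oseltamivir": 152 / 63334,
    "aspirin": 136 / 63334,
    "methylprednisolone": 124 / 63334,
}

# Confounding structure: comorbidities raise both the odds of specific
# prescriptions (treatment by indication) and the odds of adverse
# outcomes.  Magnitudes are plausible rather than estimated.
DEFAULT_COVARIATE_OUTCOME_LOG_ODDS = {
    ("preeclampsia", "cesarean"): math.log(2.0),
    ("preeclampsia", "preterm"): math.log(3.0),
    ("preeclampsia", "stillbirth"): math.log(2.0),
    ("multiple_birth", "cesarean"): math.log(3.0),
    ("multiple_birth", "preterm"): math.log(4.0),
    ("obesity", "cesarean"): math.log(1.5),
    ("cardiovascular", "preterm"): math.log(1.5),
    ("infectious_disease", "preterm"): math.log(1.5),
}
DEFAULT_COVARIATE_EXPOSURE_LOG_ODDS = {
    ("preeclampsia", "aspirin"): math.log(3.0),
    ("preeclampsia", "enoxaparin"): math.log(2.0),
    ("preeclampsia", "heparin"): math.log(2.0),
    ("cardiovascular", "heparin"): math.log(2.0),
    ("cardiovascular", "enoxaparin"): math.log(2.0),
    ("infectious_disease", "amoxicillin"): math.log(3.0),
    ("infectious_disease", "azithromycin"): math.log(3.0),
    ("infectious_disease", "oseltamivir"): math.log(2.0),
    ("obesity", "famotidine"): math.log(1.5),
}

#: Raw ICD spellings the generator emits for each phenotype, chosen to
#: match exactly one code set of the packaged toy vocabulary.  Mixed
#: dotted/undotted and cased spellings exercise dialect normalization.
REPRESENTATIVE_CODES = {
    "cesarean": ["O82", "669.70", "669.71"],
    "preterm": ["O60.14X0", "o60.13x1", "644.21"],
    "stillbirth": ["Z37.1", "656.40", "Z37.4"],
    "infectious_disease": ["O98.52", "647.61"],
    "obesity": ["E66.01", "278.00"],
    "cancer": ["C50.912", "174.9"],
    "cardiovascular": ["I25.10", "414.01"],
    "circulatory": ["I87.2", "459.81"],
    "cerebrovascular": ["I63.9", "434.91"],
    "respiratory": ["J45.40", "493.92"],
    "immune_disorders": ["D80.1", "279.06"],
    "organ_transplant": ["Z94.0", "V42.0"],
    "obstetric_history": ["Z87.51", "V23.41"],
    "maternal_care": ["O34.21", "654.21"],
    "preeclampsia": ["O14.13", "o14.03", "642.41"],
    "multiple_birth": ["O30.003", "651.01"],
    "drug_allergies": ["Z88.0", "V14.0"],
    "procedures": ["Z98.890", "V45.89"],
    "drug_resistance": ["Z16.10", "V09.0"],
}

#: Brand/generic spellings used for emitted orders (raw -> variable
#: merging is the exposure stage's job; the generator deliberately mixes
#: spellings of the same ingredient).
DEFAULT_DRUG_SYNONYMS = {
    "famotidine": ["famotidine", "Pepcid"],
    "heparin": ["heparin"],
    "prenatal_multivitamin": ["calcium carbonate/folic acid/pyridoxine/vitamin B12", "Folbecal"],
    "amoxicillin": ["amoxicillin", "Amoxil"],
    "enoxaparin": ["enoxaparin", "Lovenox"],
    "folic acid": ["folic acid"],
    "azithromycin": ["azithromycin", "Zithromax"],
    "oseltamivir": ["oseltamivir", "Tamiflu"],
    "aspirin": ["aspirin"],
    "methylprednisolone": ["methylprednisolone", "Medrol"],
}


@dataclass
class SimConfig:
    """Full parameterization of the synthetic cohort.

    ``seed`` determines every random draw; two runs with an identical
    config produce byte-identical tables.
    """

    n_patients: int = 50_560
    deliveries_per_patient_dist: dict[int, float] = field(
        default_factory=lambda: {1: 0.78, 2: 0.19, 3: 0.03}
    )
    outcome_base_prevalence: dict[str, float] = field(
        default_factory=lambda: {"cesarean": 0.3299, "preterm": 0.0615, "stillbirth": 0.0081}
    )
    covariate_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_PREVALENCE)
    )
    covariate_outcome_log_odds: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_OUTCOME_LOG_ODDS)
    )
    covariate_exposure_log_odds: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EXPOSURE_LOG_ODDS)
    )
    medication_base_exposure_prob: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MEDICATION_EXPOSURE)
    )
    planted_log_or: dict[tuple[str, str], float] = field(default_factory=dict)
    age_outcome_log_odds: dict[str, float] = field(default_factory=dict)
    maternal_age_mean_sd: tuple[float, float] = (29.48, 6.08)
    seed: int = 0
    date_range: tuple[date, date] = (date(2010, 1, 1), date(2017, 12, 31))
    stale_diagnosis_fraction: float = 0.10
    patient_random_intercept_sd: float = 0.0
    drug_name_synonyms: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_DRUG_SYNONYMS.items()}
    )

    # -- validation -------------------------------------------------
    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be >= 0")
        for name, p in {
            **self.outcome_base_prevalence,
            **self.covariate_prevalence,
            **self.medication_base_exposure_prob,
        }.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability for {name!r} outside [0, 1]: {p}")
        if not 0.0 <= self.stale_diagnosis_fraction <= 1.0:
            raise ConfigError("stale_diagnosis_fraction must be in [0, 1]")
        ks, ps = zip(*self.deliveries_per_patient_dist.items())
        if any(k not in (1, 2, 3) for k in ks) or any(p < 0 for p in ps):
            raise ConfigError("deliveries_per_patient_dist must weight {1,2,3} nonnegatively")
        if abs(sum(ps) - 1.0) > 1e-9:
            raise ConfigError("deliveries_per_patient_dist must sum to 1")
        for (cov, out) in self.covariate_outcome_log_odds:
            if cov not in self.covariate_prevalence or out not in self.outcome_base_prevalence:
                raise ConfigError(f"covariate_outcome_log_odds references unknown pair {(cov, out)}")
        for (cov, med) in self.covariate_exposure_log_odds:
            if cov not in self.covariate_prevalence or med not in self.medication_base_exposure_prob:
                raise ConfigError(f"covariate_exposure_log_odds references unknown pair {(cov, med)}")
        for (med, out) in self.planted_log_or:
            if med not in self.medication_base_exposure_prob or out not in self.outcome_base_prevalence:
                raise ConfigError(f"planted_log_or references unknown pair {(med, out)}")
        start, end = self.date_range
        max_k = max(k for k, p in self.deliveries_per_patient_dist.items() if p > 0)
        if (end - start).days < (max_k - 1) * 740 + 1:
            raise ConfigError("date_range too short for the configured deliveries per patient")
        mean, sd = self.maternal_age_mean_sd
        if sd <= 0 or not 12 <= mean <= 55:
            raise ConfigError("maternal_age_mean_sd must have 12<=mean<=55 and sd>0")

    @property
    def medications(self) -> list[str]:
        return list(self.medication_base_exposure_prob)

    @property
    def covariates(self) -> list[str]:
        return list(self.covariate_prevalence)


@dataclass
class SimulatedCohort:
    """The four event tables plus the planted truth, for assertions."""

    patients: pd.DataFrame  # patient_id, birth_date
    deliveries: pd.DataFrame  # patient_id, delivery_id, delivery_date
    orders: pd.DataFrame  # patient_id, order_date, drug_name, ingredient
    diagnoses: pd.DataFrame  # patient_id, date, code
    truth: dict

    def write(self, out_dir) -> None:
        """Write the four tables (CSV, ISO dates) plus the truth file."""
        import json
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("patients", "deliveries", "orders", "diagnoses"):
            getattr(self, name).to_csv(out / f"{name}.csv", index=False, date_format="%Y-%m-%d")
        truth = {
            "planted_log_or": {f"{m}|{o}": v for (m, o), v in self.truth["planted_log_or"].items()},
            "seed": self.truth["seed"],
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=2))


def default_config(**overrides) -> SimConfig:
    """The default study conditions; keyword overrides are applied on top.

    Defaults, field by field:

    - ``n_patients`` 50,560 patients, 1-3 deliveries each with weights
      0.78/0.19/0.03 (mean 1.25 deliveries per patient, ~63k deliveries).
    - outcome prevalences 0.3299 / 0.0615 / 0.0081 for cesarean section,
      preterm birth and stillbirth.
    - the 16 comorbidity covariates with reference-cohort prevalences
      (see :data:`DEFAULT_COVARIATE_PREVALENCE`; the two suppressed below
      10 patients default to the guess 5/63,334).
    - ten candidate medications with base exposure probabilities equal
      to their reference exposed-delivery fractions (~3.8% any-exposure).
    - treatment-by-indication confounding on (see module docstring);
      all planted medication effects zero (a null screen).
    - maternal age Normal(29.48, 6.08) truncated to [12, 55]; no direct
      age effect on outcomes by default.
    """
    cfg = replace(SimConfig(), **overrides)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------
# latent delivery-level draws (shared by both entry points)
# ---------------------------------------------------------------------

def _draw_truncated_age(rng: np.random.Generator, n: int, mean: float, sd: float) -> np.ndarray:
    """Normal(mean, sd) truncated to [12, 55] by rejection."""
    out = rng.normal(mean, sd, size=n)
    bad = (out < 12) | (out > 55)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < 12) | (out > 55)
    return out


def _draw_latents(cfg: SimConfig, n_del: int, streams: dict[str, np.random.Generator],
                  patient_of_delivery: np.ndarray | None = None):
    """Covariates, age, exposures and outcomes for ``n_del`` deliveries."""
    covs = cfg.covariates
    meds = cfg.medications
    rng_cov, rng_age, rng_exp, rng_out = (
        streams["covariates"], streams["age"], streams["exposures"], streams["outcomes"],
    )

    C = np.column_stack(
        [rng_cov.random(n_del) < cfg.covariate_prevalence[c] for c in covs]
    ).astype(np.int8) if covs else np.zeros((n_del, 0), np.int8)

    mean, sd = cfg.maternal_age_mean_sd
    age = _draw_truncated_age(rng_age, n_del, mean, sd)

    E = np.zeros((n_del, len(meds)), np.int8)
    for j, m in enumerate(meds):
        base = cfg.medication_base_exposure_prob[m]
        if base <= 0.0:
            continue
        lp = np.full(n_del, logit(base))
        for i, c in enumerate(covs):
            g = cfg.covariate_exposure_log_odds.get((c, m), 0.0)
            if g:
                lp += g * C[:, i]
        E[:, j] = rng_exp.random(n_del) < expit(lp)

    intercepts = np.zeros(n_del)
    if cfg.patient_random_intercept_sd > 0:
        rng_ri = streams["random_intercept"]
        if patient_of_delivery is None:
            intercepts = rng_ri.normal(0.0, cfg.patient_random_intercept_sd, n_del)
        else:
            n_pat = int(patient_of_delivery.max()) + 1 if n_del else 0
            per_pat = rng_ri.normal(0.0, cfg.patient_random_intercept_sd, n_pat)
            intercepts = per_pat[patient_of_delivery]

    Y = np.zeros((n_del, len(OUTCOMES)), np.int8)
    for k, o in enumerate(OUTCOMES):
        base = cfg.outcome_base_prevalence[o]
        lp = np.full(n_del, logit(base)) + intercepts
        lp += cfg.age_outcome_log_odds.get(o, 0.0) * (age - mean)
        for i, c in enumerate(covs):
            t = cfg.covariate_outcome_log_odds.get((c, o), 0.0)
            if t:
                lp += t * C[:, i]
        for j, m in enumerate(meds):
            lam = cfg.planted_log_or.get((m, o), 0.0)
            if lam:
                lp += lam * E[:, j]
        Y[:, k] = rng_out.random(n_del) < expit(lp)
    return C, age, E, Y


def _streams(cfg: SimConfig) -> dict[str, np.random.Generator]:
    """Named substreams derived deterministically from the seed, one per
    table/stage, so that enlarging one stage never reshuffles another."""
    names = ("structure", "covariates", "age", "exposures", "outcomes",
             "orders", "diagnoses", "random_intercept")
    children = np.random.SeedSequence(cfg.seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def simulate_analysis_matrix(cfg: SimConfig, n_deliveries: int | None = None) -> pd.DataFrame:
    """Draw the delivery-level analysis matrix directly, skipping events.

    Same generative law as :func:`simulate`, without serializing orders
    and diagnoses; deliveries are independent.  Intended for
    replication-heavy calibration studies where only the regression
    inputs matter.  Columns: one per covariate, ``maternal_age``, one per
    medication (prefixed ``rx_``), one per outcome.
    """
    cfg.validate()
    if n_deliveries is None:
        mean_k = sum(k * p for k, p in cfg.deliveries_per_patient_dist.items())
        n_deliveries = int(round(cfg.n_patients * mean_k))
    streams = _streams(cfg)
    C, age, E, Y = _draw_latents(cfg, n_deliveries, streams)
    df = pd.DataFrame(C, columns=cfg.covariates)
    df["maternal_age"] = age
    for j, m in enumerate(cfg.medications):
        df[f"rx_{m}"] = E[:, j]
    for k, o in enumerate(OUTCOMES):
        df[o] = Y[:, k]
    df.index.name = "delivery_id"
    return df


# ---------------------------------------------------------------------
# event-table serialization
# ---------------------------------------------------------------------

_EPOCH = np.datetime64("1970-01-01")


def _as_dates(days: np.ndarray) -> pd.Series:
    return pd.Series(_EPOCH + days.astype("timedelta64[D]")).astype("datetime64[ns]")


def simulate(cfg: SimConfig) -> SimulatedCohort:
    """Generate the four EHR-style event tables from ``cfg``.

    Reproducible: the seed fully determines the output.  An empty cohort
    (``n_patients == 0``) yields empty, correctly-typed tables.
    """
    cfg.validate()
    streams = _streams(cfg)
    rng = streams["structure"]
    start, end = cfg.date_range
    start_d, end_d = (np.datetime64(start) - _EPOCH).astype(int), (np.datetime64(end) - _EPOCH).astype(int)

    # deliveries per patient and delivery dates (same-patient deliveries
    # at least ~18 months apart)
    ks, ws = zip(*sorted(cfg.deliveries_per_patient_dist.items()))
    n_per_patient = rng.choice(ks, size=cfg.n_patients, p=ws) if cfg.n_patients else np.array([], int)
    n_del = int(n_per_patient.sum())

    patient_idx = np.repeat(np.arange(cfg.n_patients), n_per_patient)
    order_within = np.concatenate([np.arange(k) for k in n_per_patient]) if n_del else np.array([], int)

    # first delivery uniform in the range left after reserving room for
    # later deliveries; gaps of 540-739 days (max gap 739 is what the
    # slack reserves, so no delivery can fall past the range end)
    span = end_d - start_d
    slack = span - (n_per_patient - 1) * 740
    first = start_d + (rng.random(cfg.n_patients) * np.maximum(slack, 1)).astype(int) if cfg.n_patients else np.array([], int)
    if n_del:
        gaps = np.where(order_within == 0, 0, 540 + rng.integers(0, 200, size=n_del))
        csum = np.cumsum(gaps)
        # within-patient cumulative gap = csum minus csum at the
        # patient's first delivery (where the gap is zero)
        at_first = np.repeat(csum[order_within == 0], n_per_patient)
        del_days = first[patient_idx] + (csum - at_first)
    else:
        del_days = np.array([], int)

    C, age_first, E, Y = _draw_latents(cfg, n_del, streams, patient_of_delivery=patient_idx)

    # one birth date per patient, anchored at the first delivery's drawn age
    if n_del:
        first_delivery_day = del_days[order_within == 0]
        age_at_first = age_first[order_within == 0]
        birth_days = first_delivery_day - np.round(age_at_first * 365.25).astype(int)
    else:
        birth_days = np.array([], int)
    patients_with_delivery = np.unique(patient_idx)
    patient_ids = np.array([f"P{i:06d}" for i in range(cfg.n_patients)])
    patients = pd.DataFrame(
        {
            "patient_id": patient_ids[patients_with_delivery],
            "birth_date": _as_dates(birth_days).values,
        }
    )

    delivery_ids = np.array([f"D{i:07d}" for i in range(n_del)])
    deliveries = pd.DataFrame(
        {
            "patient_id": patient_ids[patient_idx],
            "delivery_id": delivery_ids,
            "delivery_date": _as_dates(del_days).values,
        }
    )

    # orders: 1-3 per exposed (delivery, medication), uniform in the
    # exposure window [delivery-280, delivery-1]
    rng_ord = streams["orders"]
    meds = cfg.medications
    d_idx, m_idx = np.nonzero(E)
    n_orders = rng_ord.integers(1, 4, size=d_idx.size) if d_idx.size else np.array([], int)
    rep_d = np.repeat(d_idx, n_orders)
    rep_m = np.repeat(m_idx, n_orders)
    offsets = rng_ord.integers(1, 281, size=rep_d.size) if rep_d.size else np.array([], int)
    names = []
    for m, r in zip(rep_m, rng_ord.integers(0, 10_000, size=rep_m.size) if rep_m.size else []):
        syn = cfg.drug_name_synonyms.get(meds[m], [meds[m]])
        names.append(syn[r % len(syn)])
    orders = pd.DataFrame(
        {
            "patient_id": patient_ids[patient_idx[rep_d]] if rep_d.size else pd.Series([], dtype=str),
            "order_date": _as_dates(del_days[rep_d] - offsets).values if rep_d.size else pd.Series([], dtype="datetime64[ns]").values,
            "drug_name": pd.Series(names, dtype=str) if names else pd.Series([], dtype=str),
            "ingredient": pd.Series([meds[m] for m in rep_m], dtype=str) if rep_m.size else pd.Series([], dtype=str),
        }
    )

    # diagnoses: covariate events in the 2-year lookback, stale noise
    # events beyond it, outcome events on the delivery day
    rng_dx = streams["diagnoses"]
    covs = cfg.covariates
    rows = {"patient_id": [], "date": [], "code": []}

    def _emit(del_rows: np.ndarray, code_key_idx: np.ndarray, keys: list[str], day: np.ndarray):
        for dr, ck, dy in zip(del_rows, code_key_idx, day):
            key = keys[ck]
            codes = REPRESENTATIVE_CODES.get(key, [key])
            rows["patient_id"].append(patient_ids[patient_idx[dr]])
            rows["date"].append(dy)
            rows["code"].append(codes[int(rng_dx.integers(0, len(codes)))])

    dc_d, dc_c = np.nonzero(C)
    if dc_d.size:
        lag = rng_dx.integers(1, 731, size=dc_d.size)
        _emit(dc_d, dc_c, covs, del_days[dc_d] - lag)
        n_stale = int(round(cfg.stale_diagnosis_fraction * dc_d.size))
        if n_stale:
            sd_rows = rng_dx.integers(0, n_del, size=n_stale)
            sd_cov = rng_dx.integers(0, len(covs), size=n_stale)
            stale_lag = rng_dx.integers(731, 1096, size=n_stale)
            _emit(sd_rows, sd_cov, covs, del_days[sd_rows] - stale_lag)
    oy_d, oy_k = np.nonzero(Y)
    if oy_d.size:
        _emit(oy_d, oy_k, list(OUTCOMES), del_days[oy_d])

    diagnoses = pd.DataFrame(
        {
            "patient_id": pd.Series(rows["patient_id"], dtype=str),
            "date": _as_dates(np.array(rows["date"], int)).values if rows["date"] else pd.Series([], dtype="datetime64[ns]").values,
            "code": pd.Series(rows["code"], dtype=str),
        }
    )
    diagnoses = diagnoses.sort_values(["patient_id", "date", "code"], kind="stable").reset_index(drop=True)

    truth = {
        "planted_log_or": dict(cfg.planted_log_or),
        "seed": cfg.seed,
        "n_deliveries": n_del,
        "medications": meds,
        "covariates": covs,
    }
    return SimulatedCohort(patients, deliveries, orders, diagnoses, truth)


# ---------------------------------------------------------------------
# exact-margins fixture
# ---------------------------------------------------------------------

#: Reference cohort margins used by the arithmetic validation fixture:
#: counts by exposure stratum (unexposed, exposed) for each outcome and
#: for three common comorbidities, plus totals.
REFERENCE_MARGINS = {
    "n_total": 63_334,
    "n_exposed": 2_830,
    "cesarean": (19_856, 1_038),
    "preterm": (3_601, 296),
    "stillbirth": (487, 29),
    "preeclampsia": (4_718, 353),
    "multiple_birth": (1_415, 147),
    "infectious_disease": (965, 290),
}


def exact_margins_fixture() -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """A synthetic delivery table hitting the reference margins *exactly*.

    Returns ``(cohort, exposed, covariates)``: a cohort frame with the
    three binary outcome columns, a boolean any-candidate-exposure
    Series, and a covariate frame with three comorbidity flags plus
    ``maternal_age`` in whole years whose mean rounds to 29.48.  Outcome
    and comorbidity flags are assigned to the first rows of each
    exposure stratum, which reproduces every stratum count at once
    (flags are tabulated marginally, so overlaps are irrelevant).
    """
    m = REFERENCE_MARGINS
    n, n_exp = m["n_total"], m["n_exposed"]
    n_unexp = n - n_exp
    exposed = pd.Series(np.r_[np.zeros(n_unexp, bool), np.ones(n_exp, bool)])

    def flags(unexp_count, exp_count):
        v = np.zeros(n, np.int8)
        v[:unexp_count] = 1
        v[n_unexp : n_unexp + exp_count] = 1
        return v

    cohort = pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(n)],
            "delivery_id": [f"D{i:07d}" for i in range(n)],
            **{o: flags(*m[o]) for o in OUTCOMES},
        }
    )
    covs = pd.DataFrame(
        {c: flags(*m[c]) for c in ("preeclampsia", "multiple_birth", "infectious_disease")}
    )
    # integer ages averaging 29.4800 -> renders as 29.48 at 2 decimals
    n_30 = 30_400
    covs["maternal_age"] = np.r_[np.full(n_30, 30), np.full(n - n_30, 29)]
    cohort.index.name = covs.index.name = "delivery_id_idx"
    return cohort, exposed, covs
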