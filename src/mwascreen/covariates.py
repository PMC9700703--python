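"""Comorbidity covariate matrix for adjustment.

Each delivery gets a binary flag per configured comorbidity: 1 iff the
patient has at least one matching diagnosis dated inside the lookback
window of 2 years before delivery (730 days, inclusive) up to the day
*before* delivery.  Delivery-day diagnoses are excluded because they are
usually part of the delivery episode itself, not pre-existing
conditions; diagnoses older than the lookback are excluded to bound
EHR-missingness bias.  Maternal age at delivery (whole years, floored)
is appended as a continuous adjustment column.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .codesets import SetRole, Vocabulary
from .errors import ValidationError

__all__ = ["LOOKBACK_DAYS", "in_lookback", "build_covariates", "DEFAULT_COVARIATES"]

LOOKBACK_DAYS = 730  # 2 years, implemented as days for leap-year determinism

#: The default 16-comorbidity adjustment set.
DEFAULT_COVARIATES = (
    "infectious_disease",
    "obesity",
    "cancer",
    "cardiovascular",
    "circulatory",
    "cerebrovascular",
    "respiratory",
    "immune_disorders",
    "organ_transplant",
    "obstetric_history",
    "maternal_care",
    "preeclampsia",
    "multiple_birth",
    "drug_allergies",
    "procedures",
    "drug_resistance",
)


def in_lookback(diag_date, delivery_date, lookback_days: int = LOOKBACK_DAYS):
    """True iff ``delivery - lookback <= diagnosis <= delivery - 1``.

    Scalar or vectorized over aligned datetime inputs.
    """
    delta = pd.to_datetime(delivery_date) - pd.to_datetime(diag_date)
    days = delta.dt.days if hasattr(delta, "dt") else delta.days
    return (days >= 1) & (days <= lookback_days)


def _age_whole_years(birth: pd.Series, delivery: pd.Series) -> np.ndarray:
    """Completed calendar years between birth and delivery (floored)."""
    birth, delivery = pd.to_datetime(birth), pd.to_datetime(delivery)
    years = delivery.dt.year.values - birth.dt.year.values
    before_birthday = (delivery.dt.month.values < birth.dt.month.values) | (
        (delivery.dt.month.values == birth.dt.month.values)
        & (delivery.dt.day.values < birth.dt.day.values)
    )
    return years - before_birthday.astype(int)


def build_covariates(
    cohort: pd.DataFrame,
    diagnoses: pd.DataFrame,
    vocab: Vocabulary,
    patients: pd.DataFrame,
    covariate_names: tuple[str, ...] | list[str] | None = None,
    lookback_days: int = LOOKBACK_DAYS,
    missing_birth_date: str = "fail",
) -> pd.DataFrame:
    """Delivery x (comorbidity flags + maternal_age) adjustment matrix.

    Parameters
    ----------
    covariate_names : which covariate code sets to use; defaults to all
        COVARIATE-role sets in the vocabulary.
    missing_birth_date : ``"fail"`` (default) raises on deliveries whose
        patient lacks a birth date; ``"impute"`` substitutes the cohort
        mean age with a logged warning.

    Absence of any matching diagnosis means flag 0 -- there are no
    missing flags.  Adding diagnosis rows can only set flags, never
    clear them, and row order is irrelevant.
    """
    if covariate_names is None:
        covariate_names = vocab.names(SetRole.COVARIATE)
    for name in covariate_names:
        if name not in vocab:
            raise ValidationError(f"vocabulary lacks covariate code set {name!r}")

    out = pd.DataFrame(index=pd.Index(cohort["delivery_id"], name="delivery_id"))
    dl = cohort[["patient_id", "delivery_id", "delivery_date"]].copy()
    dl["delivery_date"] = pd.to_datetime(dl["delivery_date"])

    dx = diagnoses.copy()
    if len(dx):
        dx["date"] = pd.to_datetime(dx["date"])
    for name in covariate_names:
        if not len(dx):
            out[name] = np.zeros(len(dl), np.int8)
            continue
        hits = dx[vocab.match_series(dx["code"], name)]
        merged = dl.merge(hits[["patient_id", "date"]], on="patient_id", how="left")
        days = (merged["delivery_date"] - merged["date"]).dt.days
        ok = (days >= 1) & (days <= lookback_days)
        flag = ok.groupby(merged["delivery_id"]).any()
        out[name] = out.index.map(flag).fillna(False).astype(np.int8)

    pt = patients[["patient_id", "birth_date"]].copy()
    merged = dl.merge(pt, on="patient_id", how="left")
    missing = merged["birth_date"].isna()
    if missing.any():
        if missing_birth_date == "fail":
            offenders = sorted(merged.loc[missing, "patient_id"].unique())[:20]
            raise ValidationError(
                f"{int(missing.sum())} deliveries lack a patient birth date: {offenders}"
            )
        elif missing_birth_date != "impute":
            raise ValidationError(f"unknown missing_birth_date policy {missing_birth_date!r}")
    age = np.full(len(merged), np.nan)
    have = ~missing
    age[have.values] = _age_whole_years(
        merged.loc[have, "birth_date"], merged.loc[have, "delivery_date"]
    )
    if missing.any():
        import logging

        logging.getLogger(__name__).warning(
            "imputed cohort mean age for %d deliveries missing birth dates",
            int(missing.sum()),
        )
        age[missing.values] = np.nanmean(age)
    out["maternal_age"] = age
    bad = out["maternal_age"] < 0
    if bad.any():
        raise ValidationError(
            f"negative maternal age for deliveries: {list(out.index[bad])[:20]}"
        )
    return out
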