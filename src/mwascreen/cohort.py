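"""Delivery cohort assembly and outcome ascertainment.

Outcomes (cesarean section, preterm birth, stillbirth) are ascertained
from diagnosis billing codes dated ON the delivery day: a delivery gets
an outcome flag iff at least one of the patient's diagnoses on the
delivery date matches that outcome's code set.  The matching window is
configurable (``window_days`` extends it backwards) but the delivery-day
default is the intended ascertainment rule, because outcome codes are
billed with the delivery itself.
"""

from __future__ import annotations

import logging
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .codesets import Vocabulary
from .errors import ValidationError
from .simulate import OUTCOMES

__all__ = ["build_cohort", "summarize_cohort", "round_half_up"]

logger = logging.getLogger(__name__)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.005 -> 0.01), matching printed tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def build_cohort(
    deliveries: pd.DataFrame,
    diagnoses: pd.DataFrame,
    vocab: Vocabulary,
    patients: pd.DataFrame | None = None,
    outcomes: tuple[str, ...] = OUTCOMES,
    window_days: int = 0,
) -> pd.DataFrame:
    """One row per delivery with binary outcome flags.

    Parameters
    ----------
    deliveries : frame with patient_id, delivery_id, delivery_date.
    diagnoses : frame with patient_id, date, code.
    vocab : vocabulary containing one OUTCOME code set per outcome name.
    patients : optional frame with patient_id; when given, deliveries
        referencing unknown patients raise :class:`ValidationError`.
    window_days : match diagnoses dated in
        ``[delivery_date - window_days, delivery_date]`` (default: the
        delivery day only).

    Duplicate (patient_id, delivery_date) rows are collapsed to one
    delivery with a logged warning: same-day events are one delivery
    (a twin birth is a multiple-birth covariate, not two deliveries).
    """
    for col in ("patient_id", "delivery_id", "delivery_date"):
        if col not in deliveries.columns:
            raise ValidationError(f"deliveries table missing column {col!r}")
    for name in outcomes:
        if name not in vocab:
            raise ValidationError(f"vocabulary lacks outcome code set {name!r}")

    if patients is not None:
        known = set(patients["patient_id"])
        unknown = sorted(set(deliveries["patient_id"]) - known)
        if unknown:
            shown = ", ".join(map(str, unknown[:20]))
            raise ValidationError(
                f"{len(unknown)} deliveries reference unknown patients: {shown}"
            )

    dl = deliveries.copy()
    dl["delivery_date"] = pd.to_datetime(dl["delivery_date"])
    dup = dl.duplicated(subset=["patient_id", "delivery_date"], keep="first")
    if dup.any():
        logger.warning(
            "collapsed %d duplicate same-day delivery rows to one delivery each",
            int(dup.sum()),
        )
        dl = dl[~dup]
    cohort = dl[["patient_id", "delivery_id", "delivery_date"]].reset_index(drop=True)

    dx = diagnoses.copy()
    if len(dx):
        dx["date"] = pd.to_datetime(dx["date"])
    for name in outcomes:
        if not len(dx):
            cohort[name] = np.zeros(len(cohort), np.int8)
            continue
        hits = dx[vocab.match_series(dx["code"], name)]
        merged = cohort.merge(
            hits[["patient_id", "date"]], on="patient_id", how="left"
        )
        delta = (merged["delivery_date"] - merged["date"]).dt.days
        in_window = (delta >= 0) & (delta <= window_days)
        flag = in_window.groupby(merged["delivery_id"]).any()
        cohort[name] = (
            cohort["delivery_id"].map(flag).fillna(False).astype(np.int8)
        )
    return cohort


def _pct(count: int, total: int) -> float:
    return round_half_up(100.0 * count / total) if total else 0.0


def summarize_cohort(
    cohort: pd.DataFrame,
    exposure_flags: pd.Series,
    covariates: pd.DataFrame | None = None,
    outcomes: tuple[str, ...] = OUTCOMES,
) -> pd.DataFrame:
    """Cohort characteristics table, stratified by any-exposure.

    One row per outcome (and per comorbidity covariate if ``covariates``
    is given), with counts and percentages in the unexposed stratum, the
    exposed stratum, and overall.  Percentages are 100*count/stratum
    total, rounded half-up to two decimals.  A mean maternal age row
    (mean, SD to 2 decimals) is appended when the covariate frame has a
    ``maternal_age`` column.

    Returned counts are unmasked; apply
    :func:`mwascreen.reporting.render_summary` before showing the table
    to a user, which masks cells below the small-cell threshold.
    """
    exposed = np.asarray(exposure_flags, bool)
    if len(exposed) != len(cohort):
        raise ValidationError("exposure_flags length does not match cohort")
    n_total = len(cohort)
    n_exp = int(exposed.sum())
    n_unexp = n_total - n_exp

    rows = []

    def add(section, name, flags):
        flags = np.asarray(flags, bool)
        ce, cu = int(flags[exposed].sum()), int(flags[~exposed].sum())
        rows.append(
            {
                "section": section,
                "row": name,
                "unexposed_n": cu,
                "unexposed_pct": _pct(cu, n_unexp),
                "exposed_n": ce,
                "exposed_pct": _pct(ce, n_exp),
                "total_n": cu + ce,
                "total_pct": _pct(cu + ce, n_total),
            }
        )

    add("cohort", "deliveries", np.ones(n_total, bool))
    for o in outcomes:
        add("pregnancy_outcome", o, cohort[o].values)
    if covariates is not None:
        for c in covariates.columns:
            if c == "maternal_age":
                continue
            add("comorbidity", c, covariates[c].values)
        if "maternal_age" in covariates.columns:
            age = covariates["maternal_age"].astype(float).values
            rows.append(
                {
                    "section": "maternal_age",
                    "row": "mean_sd",
                    "unexposed_n": round_half_up(age[~exposed].mean()) if n_unexp else np.nan,
                    "unexposed_pct": round_half_up(age[~exposed].std(ddof=1)) if n_unexp > 1 else np.nan,
                    "exposed_n": round_half_up(age[exposed].mean()) if n_exp else np.nan,
                    "exposed_pct": round_half_up(age[exposed].std(ddof=1)) if n_exp > 1 else np.nan,
                    "total_n": round_half_up(age.mean()) if n_total else np.nan,
                    "total_pct": round_half_up(age.std(ddof=1)) if n_total > 1 else np.nan,
                }
            )
    return pd.DataFrame(rows)
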