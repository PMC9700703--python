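"""Per-delivery medication exposure variables.

A delivery is *exposed* to a medication variable iff the patient has at
least one order of any raw drug name mapping to that variable dated in
the pregnancy exposure window: 280 days before delivery up to 1 day
before delivery, both bounds inclusive.  Exposure is binary -- repeat
prescriptions do not count extra.  Brand and generic spellings of the
same ingredient are merged through a :class:`DrugMap` before anything is
counted, so splitting orders across equivalent names never changes the
matrix.  Combination products with additional active ingredients keep
their own variable and are never merged into a single-ingredient one.

To protect privacy and avoid unstable estimates for rarely prescribed
drugs, variables prescribed to fewer than ten distinct patients inside
the window are dropped (:func:`apply_min_patient_filter`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "EXPOSURE_WINDOW_DAYS",
    "DrugMap",
    "ExposureMatrix",
    "in_exposure_window",
    "build_exposures",
    "apply_min_patient_filter",
]

logger = logging.getLogger(__name__)

EXPOSURE_WINDOW_DAYS = 280  # longest window start, days before delivery
MIN_PATIENTS_DEFAULT = 10


def in_exposure_window(order_date, delivery_date) -> bool | np.ndarray:
    """True iff ``delivery - 280 <= order <= delivery - 1`` (whole days).

    Accepts scalars or aligned datetime Series/arrays; inclusive at both
    bounds, so an order exactly 280 days before delivery and one the day
    before delivery both count, while an order on the delivery day does
    not.
    """
    delta = (pd.to_datetime(delivery_date) - pd.to_datetime(order_date))
    days = delta.dt.days if hasattr(delta, "dt") else delta.days
    return (days >= 1) & (days <= EXPOSURE_WINDOW_DAYS)


@dataclass
class DrugMap:
    """Many-to-one map from raw drug names to medication variables."""

    entries: dict[str, str]

    def __post_init__(self):
        self.entries = {str(k).strip(): str(v).strip() for k, v in self.entries.items()}

    @property
    def variables(self) -> list[str]:
        return sorted(set(self.entries.values()))

    def resolve(self, raw_name: str) -> str | None:
        return self.entries.get(str(raw_name).strip())

    @classmethod
    def read_csv(cls, path: str | Path) -> "DrugMap":
        """Load a (raw_name, variable) delimited file."""
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
        missing = {"raw_name", "variable"} - set(df.columns)
        if missing:
            raise ValidationError(f"drug map {path} missing columns: {sorted(missing)}")
        dup = df["raw_name"].str.strip().duplicated()
        if dup.any():
            raise ValidationError(
                f"drug map {path}: raw names mapped more than once: "
                f"{sorted(df.loc[dup, 'raw_name'].unique())}"
            )
        return cls(dict(zip(df["raw_name"], df["variable"])))


@dataclass
class ExposureMatrix:
    """Binary delivery x medication matrix plus patient-level counts.

    ``data`` is indexed by delivery_id with one 0/1 column per
    medication variable; ``patient_counts`` gives, per variable, the
    number of *distinct patients* with at least one exposed delivery;
    ``delivery_counts`` the number of exposed deliveries.
    """

    data: pd.DataFrame
    patient_counts: pd.Series
    delivery_counts: pd.Series

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    def any_exposure(self) -> pd.Series:
        """Per delivery: exposed to at least one variable."""
        if self.data.shape[1] == 0:
            return pd.Series(False, index=self.data.index)
        return self.data.any(axis=1)

    def to_csv(self, path) -> None:
        self.data.to_csv(path)


def build_exposures(
    orders: pd.DataFrame,
    cohort: pd.DataFrame,
    drug_map: DrugMap,
) -> ExposureMatrix:
    """Binary exposure matrix over the cohort's deliveries.

    Orders whose drug name the map cannot resolve are excluded and
    logged (with a distinct-name count, not the raw names).  An empty
    cohort yields an empty matrix.
    """
    for col in ("patient_id", "order_date", "drug_name"):
        if col not in orders.columns:
            raise ValidationError(f"orders table missing column {col!r}")

    index = pd.Index(cohort["delivery_id"], name="delivery_id")
    variables = drug_map.variables
    if len(cohort) == 0 or len(orders) == 0:
        data = pd.DataFrame(0, index=index, columns=variables, dtype=np.int8)
        zero = pd.Series(0, index=variables, dtype=int)
        return ExposureMatrix(data, zero, zero.copy())

    od = orders.copy()
    od["variable"] = od["drug_name"].map(drug_map.entries)
    unresolved = od["variable"].isna()
    if unresolved.any():
        logger.warning(
            "excluded %d orders with %d unmapped drug names",
            int(unresolved.sum()),
            od.loc[unresolved, "drug_name"].nunique(),
        )
        od = od[~unresolved]
    od["order_date"] = pd.to_datetime(od["order_date"])

    dl = cohort[["patient_id", "delivery_id", "delivery_date"]].copy()
    dl["delivery_date"] = pd.to_datetime(dl["delivery_date"])
    merged = dl.merge(od[["patient_id", "order_date", "variable"]], on="patient_id", how="inner")
    days = (merged["delivery_date"] - merged["order_date"]).dt.days
    merged = merged[(days >= 1) & (days <= EXPOSURE_WINDOW_DAYS)]

    cells = merged[["delivery_id", "variable"]].drop_duplicates()
    wide = (
        pd.crosstab(cells["delivery_id"], cells["variable"])
        .clip(upper=1)
        .reindex(index=index, columns=variables, fill_value=0)
        .astype(np.int8)
    )
    exposed = wide.set_axis(dl["patient_id"].values, axis=0)
    patient_counts = pd.Series(
        {
            v: int(exposed.loc[exposed[v] == 1].index.nunique())
            for v in variables
        },
        dtype=int,
    )
    delivery_counts = wide.sum(axis=0).astype(int)
    return ExposureMatrix(wide, patient_counts, delivery_counts)


def apply_min_patient_filter(
    m: ExposureMatrix,
    threshold: int = MIN_PATIENTS_DEFAULT,
    count_deliveries: bool = False,
) -> ExposureMatrix:
    """Drop medication variables below the inclusion threshold.

    By default the threshold counts *distinct patients* with an exposed
    delivery; ``count_deliveries=True`` counts exposed deliveries
    instead.  The dropped variables are logged by name only -- their
    sub-threshold counts are themselves small cells and are not shown.
    """
    if threshold < 1:
        raise ValidationError("threshold must be >= 1")
    counts = m.delivery_counts if count_deliveries else m.patient_counts
    keep = [v for v in m.variables if counts[v] >= threshold]
    dropped = [v for v in m.variables if counts[v] < threshold]
    if dropped:
        logger.info(
            "dropped %d medication variables below the %d-patient threshold: %s",
            len(dropped), threshold, ", ".join(dropped),
        )
    return ExposureMatrix(
        m.data[keep], m.patient_counts[keep], m.delivery_counts[keep]
    )
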