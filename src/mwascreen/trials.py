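"""Candidate-drug exclusion rules.

Repurposed-drug candidates are harvested upstream from a clinical-trial
registry and annotated by hand; this module applies the screening
exclusions to that annotated table.  Rules are applied in a fixed,
documented order and each excluded drug carries exactly the *first*
rule it matched:

1. no regulatory (FDA) approval
2. approved after the cutoff year (default 2017, the end of the
   observation window -- a later approval cannot have produced in-window
   prescriptions under its new indication)
3. not a pharmaceutical or biological product
4. sole approved indication is HIV treatment (HIV status is not
   observable in the study data, so these exposures cannot be adjusted)
5. trials did not include female participants of reproductive age

The registry query itself (search terms, download, manual labeling) is
out of scope; the module starts from the annotated table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import ValidationError

__all__ = ["CandidateDrug", "ExclusionReason", "apply_exclusions", "load_candidates"]


@dataclass(frozen=True)
class CandidateDrug:
    """One annotated candidate from the trial-registry harvest."""

    name: str
    fda_approved: bool
    approval_year: int | None
    hiv_only_indication: bool
    pharmaceutical_or_biological: bool
    trial_includes_reproductive_age_females: bool

    def validate(self) -> None:
        if not str(self.name).strip():
            raise ValidationError("candidate drug with empty name")
        if self.fda_approved and self.approval_year is None:
            raise ValidationError(
                f"candidate {self.name!r}: approval_year required when fda_approved"
            )


class ExclusionReason:
    NOT_APPROVED = "not FDA approved"
    POST_CUTOFF = "approved after cutoff"
    NON_PHARMA = "non-pharmaceutical/biological product"
    HIV_ONLY = "HIV-only indication"
    NO_REPRODUCTIVE_AGE_FEMALES = "no reproductive-age female participants"

    ORDER = (NOT_APPROVED, POST_CUTOFF, NON_PHARMA, HIV_ONLY, NO_REPRODUCTIVE_AGE_FEMALES)


def _first_matching_rule(d: CandidateDrug, cutoff_year: int) -> str | None:
    if not d.fda_approved:
        return ExclusionReason.NOT_APPROVED
    if d.approval_year is not None and d.approval_year > cutoff_year:
        return ExclusionReason.POST_CUTOFF
    if not d.pharmaceutical_or_biological:
        return ExclusionReason.NON_PHARMA
    if d.hiv_only_indication:
        return ExclusionReason.HIV_ONLY
    if not d.trial_includes_reproductive_age_females:
        return ExclusionReason.NO_REPRODUCTIVE_AGE_FEMALES
    return None


def apply_exclusions(
    drugs: list[CandidateDrug], cutoff_year: int = 2017
) -> tuple[list[CandidateDrug], list[tuple[CandidateDrug, str]]]:
    """Partition candidates into (kept, excluded-with-reason).

    Order-stable: kept drugs appear in input order, and
    ``kept + [d for d, _ in excluded]`` is a permutation of the input
    preserving each list's relative order.  Raising ``cutoff_year``
    never shrinks the kept list.
    """
    kept: list[CandidateDrug] = []
    excluded: list[tuple[CandidateDrug, str]] = []
    for d in drugs:
        d.validate()
        reason = _first_matching_rule(d, cutoff_year)
        if reason is None:
            kept.append(d)
        else:
            excluded.append((d, reason))
    return kept, excluded


def exclusion_report(excluded: list[tuple[CandidateDrug, str]]) -> pd.DataFrame:
    """Reason counts in rule order (zero-count rules included)."""
    counts = {r: 0 for r in ExclusionReason.ORDER}
    for _, reason in excluded:
        counts[reason] += 1
    return pd.DataFrame(
        {"reason": list(counts), "n_excluded": list(counts.values())}
    )


_BOOL = {"1": True, "true": True, "yes": True, "0": False, "false": False, "no": False}


def load_candidates(path: str | Path) -> list[CandidateDrug]:
    """Read an annotated candidate table (delimited text).

    Columns: name, fda_approved, approval_year (blank when not
    approved), hiv_only_indication, pharmaceutical_or_biological,
    trial_includes_reproductive_age_females.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    required = {
        "name", "fda_approved", "approval_year", "hiv_only_indication",
        "pharmaceutical_or_biological", "trial_includes_reproductive_age_females",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"candidate file {path} missing columns: {sorted(missing)}")

    def to_bool(record, column, value):
        key = str(value).strip().lower()
        if key not in _BOOL:
            raise ValidationError(
                f"candidate {record!r}: field {column!r} is not a boolean: {value!r}"
            )
        return _BOOL[key]

    out = []
    for _, row in df.iterrows():
        year = row["approval_year"]
        year = None if pd.isna(year) or not str(year).strip() else int(float(year))
        d = CandidateDrug(
            name=str(row["name"]).strip(),
            fda_approved=to_bool(row["name"], "fda_approved", row["fda_approved"]),
            approval_year=year,
            hiv_only_indication=to_bool(row["name"], "hiv_only_indication", row["hiv_only_indication"]),
            pharmaceutical_or_biological=to_bool(
                row["name"], "pharmaceutical_or_biological", row["pharmaceutical_or_biological"]
            ),
            trial_includes_reproductive_age_females=to_bool(
                row["name"],
                "trial_includes_reproductive_age_females",
                row["trial_includes_reproductive_age_females"],
            ),
        )
        d.validate()
        out.append(d)
    return out
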