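"""ICD-9/ICD-10 code sets for outcome and covariate phenotyping.

Diagnosis phenotypes (delivery outcomes and comorbidity covariates) are
defined as named collections of ICD billing codes.  Codes appear in EHR
extracts in mixed dialects -- dotted ("O14.1") and undotted ("O141"),
upper and lower case -- so all matching happens on a normalized form:
uppercase with periods stripped.  A :class:`CodeSet` holds exact member
codes plus optional prefixes; a record matches if its normalized code is
an exact member or extends any prefix.  Prefix matching exists because
real ICD usage bills child codes (O14.10, O14.12, ...) under a concept a
phenotype list may state only at the parent level; it can be disabled
per set.

The ICD revision (9 vs 10) is *inferred* from the code shape and is
informational only -- it never affects matching.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ValidationError

__all__ = [
    "IcdSystem",
    "IcdCode",
    "CodeSet",
    "Vocabulary",
    "normalize_code",
    "matches",
    "load_vocabulary",
]


class IcdSystem(str, enum.Enum):
    ICD9 = "ICD9"
    ICD10 = "ICD10"
    UNKNOWN = "UNKNOWN"


class SetRole(str, enum.Enum):
    OUTCOME = "OUTCOME"
    COVARIATE = "COVARIATE"


@dataclass(frozen=True)
class IcdCode:
    """A single diagnosis code: raw spelling plus normalized form."""

    raw: str
    normalized: str
    system: IcdSystem

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.normalized


def _infer_system(normalized: str) -> IcdSystem:
    """Label the ICD revision from the code's leading character.

    Codes starting with a digit are ICD-9.  Codes starting with a letter
    are ICD-10, except E and V which are ambiguous (ICD-9 external-cause
    and supplementary codes also start with E/V) and stay UNKNOWN.  The
    label never affects matching.
    """
    head = normalized[0]
    if head.isdigit():
        return IcdSystem.ICD9
    if head in ("E", "V"):
        return IcdSystem.UNKNOWN
    return IcdSystem.ICD10


def normalize_code(raw: str) -> IcdCode:
    """Normalize a raw ICD code: trim, uppercase, strip periods.

    Dotted and undotted spellings of the same code normalize
    identically; normalization is idempotent.

    Raises
    ------
    ValidationError
        If ``raw`` is empty or whitespace.
    """
    if raw is None or not str(raw).strip():
        raise ValidationError(f"empty ICD code in input record: {raw!r}")
    normalized = str(raw).strip().upper().replace(".", "")
    if not normalized:
        raise ValidationError(f"ICD code empty after normalization: {raw!r}")
    return IcdCode(raw=str(raw), normalized=normalized, system=_infer_system(normalized))


@dataclass
class CodeSet:
    """A named phenotype: exact member codes plus optional prefixes."""

    name: str
    role: SetRole
    members: frozenset[str] = field(default_factory=frozenset)
    prefix_members: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        self.members = frozenset(normalize_code(c).normalized for c in self.members)
        self.prefix_members = frozenset(
            normalize_code(c).normalized for c in self.prefix_members
        )

    def without_prefixes(self) -> "CodeSet":
        """Copy of this set with prefix matching disabled."""
        return CodeSet(self.name, self.role, self.members, frozenset())


def matches(code: IcdCode | str, cs: CodeSet) -> bool:
    """True iff ``code`` belongs to ``cs``.

    Exact membership is checked before prefixes, so a code counted as a
    member is never double-counted through a prefix.
    """
    normalized = code.normalized if isinstance(code, IcdCode) else normalize_code(code).normalized
    if normalized in cs.members:
        return True
    return any(normalized.startswith(p) for p in cs.prefix_members)


class Vocabulary:
    """A collection of uniquely-named code sets.

    Provides vectorized matching against a pandas Series of raw codes,
    which is what the cohort and covariate builders use.
    """

    def __init__(self, codesets: list[CodeSet]):
        names = [cs.name for cs in codesets]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValidationError(f"duplicate code set names in vocabulary: {sorted(dupes)}")
        self._sets: dict[str, CodeSet] = {cs.name: cs for cs in codesets}

    def __getitem__(self, name: str) -> CodeSet:
        return self._sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def names(self, role: SetRole | str | None = None) -> list[str]:
        if role is None:
            return list(self._sets)
        role = SetRole(role)
        return [n for n, cs in self._sets.items() if cs.role == role]

    def match_series(self, raw_codes: pd.Series, set_name: str) -> pd.Series:
        """Boolean Series: which raw codes belong to ``set_name``."""
        cs = self._sets[set_name]
        normalized = (
            raw_codes.astype(str).str.strip().str.upper().str.replace(".", "", regex=False)
        )
        hit = normalized.isin(cs.members)
        for p in cs.prefix_members:
            hit |= normalized.str.startswith(p)
        return hit


def load_vocabulary(path: str | Path) -> Vocabulary:
    """Read a vocabulary file: columns set_name, role, code, is_prefix.

    Delimited text (comma or tab inferred).  Codes are validated and
    normalized on load.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    required = {"set_name", "role", "code", "is_prefix"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"vocabulary file {path} missing columns: {sorted(missing)}")
    sets: dict[tuple[str, SetRole], dict[str, set]] = {}
    for i, row in df.iterrows():
        try:
            role = SetRole(str(row["role"]).strip().upper())
        except ValueError:
            raise ValidationError(
                f"vocabulary row {i}: unknown role {row['role']!r}"
            ) from None
        code = normalize_code(row["code"]).normalized
        is_prefix = str(row["is_prefix"]).strip().lower() in ("1", "true", "yes")
        bucket = sets.setdefault((str(row["set_name"]).strip(), role), {"m": set(), "p": set()})
        bucket["p" if is_prefix else "m"].add(code)
    return Vocabulary(
        [
            CodeSet(name=name, role=role, members=frozenset(b["m"]), prefix_members=frozenset(b["p"]))
            for (name, role), b in sets.items()
        ]
    )
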