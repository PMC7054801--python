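"""Domain types, code normalization, and delimited-text I/O for claims data.

The package works with two tables throughout:

``base`` -- one row per beneficiary (demographics, annual coverage flags,
vital status), the analogue of an annual Medicare enrollment "base file".

``claims`` -- one row per dated medical code (ICD-9 diagnosis, ICD-9
procedure, CPT, or HCPCS) with its claim source and, optionally, the
provider specialty.

Both are plain pandas DataFrames with validated schemas; the dataclasses
below give row-level semantics and are convenient for constructing small
fixtures.  Codes are stored dotless and uppercase internally ("332.0" and
"3320" are the same code); readers normalize on ingest.
"""

from __future__ import annotations

import dataclasses
import datetime
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CODE_SYSTEMS",
    "CLAIM_SOURCES",
    "SEXES",
    "RACE_CATEGORIES",
    "STUDY_YEARS",
    "NEUROLOGY_SPECIALTY",
    "BASE_COLUMNS",
    "CLAIMS_COLUMNS",
    "SchemaError",
    "ValidationError",
    "BeneficiaryRecord",
    "ClaimEvent",
    "CodeList",
    "normalize_code",
    "read_base_file",
    "write_base_file",
    "read_claims",
    "write_claims",
    "read_code_list",
]

CODE_SYSTEMS = ("ICD9_DX", "ICD9_PROC", "CPT", "HCPCS")
CLAIM_SOURCES = ("carrier", "outpatient", "inpatient", "snf", "dme", "home_health")
SEXES = ("male", "female")
RACE_CATEGORIES = (
    "white",
    "black",
    "asian",
    "hispanic",
    "native_american",
    "pacific_islander_other",
    "unknown",
)
#: Reference years for which the base file carries coverage flags.
STUDY_YEARS = tuple(range(2009, 2015))
#: Documented free-text token marking a claim from a neurologist.
NEUROLOGY_SPECIALTY = "neurology"

BASE_COLUMNS = (
    ["beneficiary_id", "birth_date", "sex", "race_ethnicity", "death_date"]
    + [f"part_ab_{y}" for y in STUDY_YEARS]
    + [f"non_medicare_{y}" for y in STUDY_YEARS]
    + ["us_residence"]
)
CLAIMS_COLUMNS = [
    "beneficiary_id",
    "service_date",
    "code",
    "code_system",
    "claim_source",
    "provider_specialty",
]


class SchemaError(ValueError):
    """A file does not conform to the documented column dictionary."""


class ValidationError(ValueError):
    """A row violates a domain invariant (reported with line numbers)."""


@dataclasses.dataclass(frozen=True)
class BeneficiaryRecord:
    """One person's demographics, coverage, and vital status."""

    beneficiary_id: str
    birth_date: datetime.date
    sex: str
    race_ethnicity: str
    death_date: datetime.date | None = None
    part_ab_coverage: dict[int, bool] = dataclasses.field(default_factory=dict)
    non_medicare_coverage: dict[int, bool] = dataclasses.field(default_factory=dict)
    us_residence: bool = True

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"unknown sex {self.sex!r}")
        if self.race_ethnicity not in RACE_CATEGORIES:
            raise ValidationError(f"unknown race_ethnicity {self.race_ethnicity!r}")
        if self.death_date is not None and self.death_date < self.birth_date:
            raise ValidationError(
                f"{self.beneficiary_id}: death_date precedes birth_date"
            )


@dataclasses.dataclass(frozen=True)
class ClaimEvent:
    """One dated medical code; ``code`` is stored normalized."""

    beneficiary_id: str
    service_date: datetime.date
    code: str
    code_system: str
    claim_source: str = "carrier"
    provider_specialty: str | None = None

    def __post_init__(self) -> None:
        if self.code_system not in CODE_SYSTEMS:
            raise ValidationError(f"unknown code_system {self.code_system!r}")
        if self.claim_source not in CLAIM_SOURCES:
            raise ValidationError(f"unknown claim_source {self.claim_source!r}")
        object.__setattr__(
            self, "code", normalize_code(self.code, self.code_system)
        )


class CodeList:
    """A labelled set of (code, code_system) pairs.

    Entries are normalized on construction and duplicates collapse.  The
    canonical term key for a pair is ``"{code}:{system}"``, the same key
    used by coefficient sets and feature vectors.
    """

    def __init__(self, entries, label: str = ""):
        seen: dict[tuple[str, str], str] = {}
        for entry in entries:
            code, system, *rest = entry
            key = (normalize_code(code, system), system)
            if system not in CODE_SYSTEMS:
                raise ValidationError(f"unknown code_system {system!r}")
            seen.setdefault(key, rest[0] if rest else "")
        self._entries = seen
        self.label = label

    @property
    def entries(self) -> frozenset[tuple[str, str]]:
        return frozenset(self._entries)

    def term_keys(self) -> list[str]:
        return sorted(f"{c}:{s}" for c, s in self._entries)

    def codes_for(self, system: str) -> frozenset[str]:
        return frozenset(c for c, s in self._entries if s == system)

    def label_of(self, code: str, system: str) -> str:
        return self._entries[(normalize_code(code, system), system)]

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, pair) -> bool:
        code, system = pair
        return (normalize_code(code, system), system) in self._entries

    def __iter__(self):
        return iter(sorted(self._entries))

    def to_frame(self) -> pd.DataFrame:
        rows = sorted((c, s, lab) for (c, s), lab in self._entries.items())
        return pd.DataFrame(rows, columns=["code", "code_system", "label"])


def normalize_code(raw: str, code_system: str) -> str:
    """Normalize a medical code: strip dots and whitespace, uppercase.

    ICD-9 codes circulate both dotted ("332.0") and dotless ("3320");
    both map to the same normalized value.  Idempotent.

    Raises
    ------
    ValidationError
        If ``raw`` is empty or whitespace-only.
    """
    out = str(raw).strip().replace(".", "").upper()
    if not out:
        raise ValidationError(f"empty code for system {code_system}")
    return out


# ---------------------------------------------------------------------------
# Readers / writers


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")


def _parse_dates(series: pd.Series, name: str, path) -> pd.Series:
    out = pd.to_datetime(series, format="%Y-%m-%d", errors="coerce")
    bad = series.notna() & (series.astype(str).str.len() > 0) & out.isna()
    if bad.any():
        lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()
        raise ValidationError(f"{path}: unparseable {name} on line(s) {lines[:10]}")
    return out


def read_base_file(path) -> pd.DataFrame:
    """Read a beneficiary base file (CSV, ISO-8601 dates) into a DataFrame.

    Validates the column dictionary and the death >= birth invariant;
    malformed rows are reported with their 1-based file line numbers
    (header is line 1).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"beneficiary_id": str})
    _require_columns(df, BASE_COLUMNS, path)
    df = df[list(BASE_COLUMNS)]
    df["birth_date"] = _parse_dates(df["birth_date"], "birth_date", path)
    df["death_date"] = _parse_dates(df["death_date"], "death_date", path)

    bad_sex = ~df["sex"].isin(SEXES)
    if bad_sex.any():
        lines = (np.flatnonzero(bad_sex.to_numpy()) + 2).tolist()
        raise ValidationError(f"{path}: invalid sex on line(s) {lines[:10]}")
    bad_race = ~df["race_ethnicity"].isin(RACE_CATEGORIES)
    if bad_race.any():
        lines = (np.flatnonzero(bad_race.to_numpy()) + 2).tolist()
        raise ValidationError(f"{path}: invalid race_ethnicity on line(s) {lines[:10]}")
    impossible = df["death_date"].notna() & (df["death_date"] < df["birth_date"])
    if impossible.any():
        lines = (np.flatnonzero(impossible.to_numpy()) + 2).tolist()
        raise ValidationError(
            f"{path}: death_date before birth_date on line(s) {lines[:10]}"
        )
    for y in STUDY_YEARS:
        df[f"part_ab_{y}"] = df[f"part_ab_{y}"].astype(bool)
        df[f"non_medicare_{y}"] = df[f"non_medicare_{y}"].astype(bool)
    df["us_residence"] = df["us_residence"].astype(bool)
    return df.reset_index(drop=True)


def write_base_file(df: pd.DataFrame, path) -> None:
    _require_columns(df, BASE_COLUMNS, path)
    out = df[list(BASE_COLUMNS)].copy()
    for col in ("birth_date", "death_date"):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_claims(path) -> pd.DataFrame:
    """Read a claims file into a DataFrame; codes are normalized on ingest.

    Rows come back stably ordered by (beneficiary_id, service_date).
    Unknown ``code_system`` or ``claim_source`` tokens raise
    :class:`SchemaError` with line numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"beneficiary_id": str, "code": str}, keep_default_na=False)
    _require_columns(df, CLAIMS_COLUMNS, path)
    df = df[list(CLAIMS_COLUMNS)]
    if len(df) == 0:
        df["service_date"] = pd.to_datetime(df["service_date"])
        return df
    df["service_date"] = _parse_dates(df["service_date"], "service_date", path)

    bad = ~df["code_system"].isin(CODE_SYSTEMS)
    if bad.any():
        lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()
        raise SchemaError(f"{path}: unknown code_system on line(s) {lines[:10]}")
    bad = ~df["claim_source"].isin(CLAIM_SOURCES)
    if bad.any():
        lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()
        raise SchemaError(f"{path}: unknown claim_source on line(s) {lines[:10]}")
    empty = df["code"].astype(str).str.strip().str.replace(".", "", regex=False) == ""
    if empty.any():
        lines = (np.flatnonzero(empty.to_numpy()) + 2).tolist()
        raise ValidationError(f"{path}: empty code on line(s) {lines[:10]}")
    df["code"] = (
        df["code"].astype(str).str.strip().str.replace(".", "", regex=False).str.upper()
    )
    df["provider_specialty"] = df["provider_specialty"].replace("", np.nan)
    return (
        df.sort_values(["beneficiary_id", "service_date"], kind="mergesort")
        .reset_index(drop=True)
    )


def write_claims(df: pd.DataFrame, path) -> None:
    _require_columns(df, CLAIMS_COLUMNS, path)
    out = df[list(CLAIMS_COLUMNS)].copy()
    out["service_date"] = pd.to_datetime(out["service_date"]).dt.strftime("%Y-%m-%d")
    out["provider_specialty"] = out["provider_specialty"].fillna("")
    out.to_csv(path, index=False)


def read_code_list(path, label: str = "") -> CodeList:
    """Read a code-list CSV (columns: code, code_system, label)."""
    df = pd.read_csv(path, dtype={"code": str})
    _require_columns(df, ["code", "code_system"], path)
    lab = df["label"] if "label" in df.columns else pd.Series([""] * len(df))
    entries = list(zip(df["code"], df["code_system"], lab.fillna("")))
    return CodeList(entries, label=label or str(path))
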