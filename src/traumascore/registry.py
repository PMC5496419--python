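"""Trauma-registry data model and delimited-text I/O.

A registry is a patient-level table with the canonical columns
``age, sex, mechanism, gcs, sbp, rr, spo2, iss, died``.  Missing values are
written as empty fields (and read from empty or ``NA`` cells); a
non-measurable SpO2 — clinically distinct from an unrecorded one — is
round-tripped as the sentinel token ``NM`` and tracked in the boolean
``spo2_nm`` column in memory.

Validation never silently coerces: every rejected row is enumerated with
its row index and offending field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_COLUMNS",
    "MISSING_TOKENS",
    "NM_TOKEN",
    "PatientRecord",
    "Registry",
    "RegistryError",
    "read_registry",
    "write_registry",
    "apply_cohort_filter",
]

CANONICAL_COLUMNS = ("age", "sex", "mechanism", "gcs", "sbp", "rr", "spo2", "iss", "died")
#: Tokens read as missing-at-random cells.
MISSING_TOKENS = ("", "NA")
#: Sentinel for non-measurable SpO2.
NM_TOKEN = "NM"

_SEXES = ("male", "female")
_CORE_MECHANISMS = ("blunt", "penetrating")
_DIED_TRUE = ("1", "true", "yes")
_DIED_FALSE = ("0", "false", "no")


class RegistryError(ValueError):
    """Unreadable file, missing mandatory columns, or zero valid rows."""


@dataclass(frozen=True)
class PatientRecord:
    """One registry row.

    ``spo2_non_measurable`` marks an SpO2 that could not be obtained (e.g.
    profound shock); ``spo2`` is then ``None`` but the cell is not treated
    as missing at random.
    """

    age: int
    sex: str
    mechanism: str
    gcs: int | None
    sbp: float | None
    rr: float | None
    spo2: float | None
    iss: int | None
    died: bool
    spo2_non_measurable: bool = False

    def validate(self) -> list[str]:
        """Hard-invariant violations, empty when the record is valid.

        Mechanism is only required to be a non-empty token here: rows with
        other mechanisms (burns, drowning, ...) are legal registry content
        and are removed — and tallied — by :func:`apply_cohort_filter`.
        """
        problems = []
        if not float(self.age).is_integer() or self.age < 0:
            problems.append(f"age must be a non-negative integer, got {self.age!r}")
        if self.sex not in _SEXES:
            problems.append(f"sex must be one of {_SEXES}, got {self.sex!r}")
        if not self.mechanism:
            problems.append("mechanism is empty")
        if self.gcs is not None and (not float(self.gcs).is_integer() or not 3 <= self.gcs <= 15):
            problems.append(f"gcs must be an integer in [3, 15], got {self.gcs!r}")
        if self.sbp is not None and self.sbp < 0:
            problems.append(f"sbp must be non-negative, got {self.sbp!r}")
        if self.rr is not None and self.rr < 0:
            problems.append(f"rr must be non-negative, got {self.rr!r}")
        if self.spo2 is not None and not 0 <= self.spo2 <= 100:
            problems.append(f"spo2 must lie in [0, 100], got {self.spo2!r}")
        if self.spo2 is not None and self.spo2_non_measurable:
            problems.append("spo2 cannot be both a value and non-measurable")
        if self.iss is not None and (not float(self.iss).is_integer() or not 1 <= self.iss <= 75):
            problems.append(f"iss must be an integer in [1, 75], got {self.iss!r}")
        return problems

    @property
    def missing_fields(self) -> tuple[str, ...]:
        out = [name for name in ("gcs", "sbp", "rr", "iss") if getattr(self, name) is None]
        if self.spo2 is None and not self.spo2_non_measurable:
            out.append("spo2")
        return tuple(sorted(out))


@dataclass
class Registry:
    """An ordered collection of patient rows backed by a pandas DataFrame.

    The frame carries the canonical columns plus ``spo2_nm``; ``rejected``
    lists ``(row_index, message)`` diagnostics from parsing.
    """

    df: pd.DataFrame
    label: str = ""
    rejected: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "Registry":
        return Registry(self.df.copy(), self.label, list(self.rejected))

    @classmethod
    def from_records(cls, records, label: str = "") -> "Registry":
        rows = []
        for r in records:
            rows.append(
                {
                    "age": r.age,
                    "sex": r.sex,
                    "mechanism": r.mechanism,
                    "gcs": np.nan if r.gcs is None else float(r.gcs),
                    "sbp": np.nan if r.sbp is None else float(r.sbp),
                    "rr": np.nan if r.rr is None else float(r.rr),
                    "spo2": np.nan if r.spo2 is None else float(r.spo2),
                    "iss": np.nan if r.iss is None else float(r.iss),
                    "died": bool(r.died),
                    "spo2_nm": bool(r.spo2_non_measurable),
                }
            )
        return cls(pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS) + ["spo2_nm"]), label)

    def to_records(self) -> list[PatientRecord]:
        out = []
        for row in self.df.itertuples(index=False):
            out.append(
                PatientRecord(
                    age=int(row.age),
                    sex=row.sex,
                    mechanism=row.mechanism,
                    gcs=None if pd.isna(row.gcs) else int(row.gcs),
                    sbp=None if pd.isna(row.sbp) else float(row.sbp),
                    rr=None if pd.isna(row.rr) else float(row.rr),
                    spo2=None if pd.isna(row.spo2) else float(row.spo2),
                    iss=None if pd.isna(row.iss) else int(row.iss),
                    died=bool(row.died),
                    spo2_non_measurable=bool(row.spo2_nm),
                )
            )
        return out


def _parse_cell(token: str, kind: str, problems: list[str], name: str):
    token = token.strip()
    if token in MISSING_TOKENS:
        return None
    try:
        if kind == "int":
            v = float(token)
            if not v.is_integer():
                raise ValueError
            return int(v)
        return float(token)
    except ValueError:
        problems.append(f"{name} is not a number: {token!r}")
        return None


def read_registry(
    path,
    *,
    delimiter: str = ",",
    aliases: dict | None = None,
    label: str = "",
    strict: bool = False,
) -> Registry:
    """Read a delimited registry file into a validated :class:`Registry`.

    Parameters
    ----------
    aliases : mapping of file column name -> canonical name, for registries
        whose headers differ from the canonical vocabulary.
    strict : raise on the first invalid row instead of dropping it.

    Rows violating hard invariants are rejected and enumerated in
    ``Registry.rejected`` with row-indexed diagnostics.
    """
    path = Path(path)
    if not path.exists():
        raise RegistryError(f"no such file: {path}")
    try:
        raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    except Exception as exc:  # noqa: BLE001 - re-raise under the module error
        raise RegistryError(f"unreadable file {path}: {exc}") from exc
    if aliases:
        raw = raw.rename(columns=aliases)
    missing_cols = [c for c in CANONICAL_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise RegistryError(f"missing mandatory columns: {missing_cols}")

    records, rejected = [], []
    for idx, row in enumerate(raw.itertuples(index=False)):
        row = dict(zip(raw.columns, row))
        problems: list[str] = []
        age = _parse_cell(row["age"], "int", problems, "age")
        if age is None and not problems:
            problems.append("age is mandatory")
        gcs = _parse_cell(row["gcs"], "int", problems, "gcs")
        sbp = _parse_cell(row["sbp"], "float", problems, "sbp")
        rr = _parse_cell(row["rr"], "float", problems, "rr")
        iss = _parse_cell(row["iss"], "int", problems, "iss")
        spo2_token = row["spo2"].strip()
        nm = spo2_token == NM_TOKEN
        spo2 = None if nm else _parse_cell(spo2_token, "float", problems, "spo2")
        died_token = row["died"].strip().lower()
        if died_token in _DIED_TRUE:
            died = True
        elif died_token in _DIED_FALSE:
            died = False
        else:
            problems.append(f"died is not boolean: {row['died']!r}")
            died = False
        record = PatientRecord(
            age=age if age is not None else -1,
            sex=row["sex"].strip(),
            mechanism=row["mechanism"].strip(),
            gcs=gcs,
            sbp=sbp,
            rr=rr,
            spo2=spo2,
            iss=iss,
            died=died,
            spo2_non_measurable=nm,
        )
        problems.extend(record.validate())
        if problems:
            diagnostic = f"row {idx}: " + "; ".join(problems)
            if strict:
                raise RegistryError(diagnostic)
            rejected.append((idx, diagnostic))
        else:
            records.append(record)
    if not records:
        raise RegistryError(f"zero valid rows in {path}")
    registry = Registry.from_records(records, label=label or path.stem)
    registry.rejected = rejected
    return registry


def _format_cell(value) -> str:
    if pd.isna(value):
        return ""
    value = float(value)
    return str(int(value)) if value.is_integer() else repr(value)


def write_registry(registry: Registry, path, *, delimiter: str = ",") -> None:
    """Write a registry as delimited text with the canonical header.

    Missing cells become empty fields; non-measurable SpO2 is written as
    the ``NM`` sentinel; death as 1/0.
    """
    if len(registry) == 0:
        raise RegistryError("refusing to write an empty registry")
    df = registry.df
    out = pd.DataFrame(
        {
            "age": df["age"].astype(int).astype(str),
            "sex": df["sex"],
            "mechanism": df["mechanism"],
            "gcs": df["gcs"].map(_format_cell),
            "sbp": df["sbp"].map(_format_cell),
            "rr": df["rr"].map(_format_cell),
            "spo2": df["spo2"].map(_format_cell),
            "iss": df["iss"].map(_format_cell),
            "died": df["died"].astype(int).astype(str),
        }
    )
    out.loc[df["spo2_nm"].astype(bool).to_numpy(), "spo2"] = NM_TOKEN
    try:
        out.to_csv(path, sep=delimiter, index=False)
    except OSError as exc:
        raise RegistryError(f"unwritable path {path}: {exc}") from exc


def apply_cohort_filter(registry: Registry) -> tuple[Registry, dict]:
    """Apply the study inclusion/exclusion flow and tally removals.

    Inclusion: blunt or penetrating mechanism, and age >= 15 years.  When
    the optional boolean columns ``dead_on_arrival`` or ``ed_discharge``
    are present they trigger the corresponding exclusions.  Each removed
    row is counted once, under the first criterion it fails (mechanism,
    then age, then exclusions), mirroring a sequential enrolment flow.
    """
    df = registry.df
    n = len(df)
    removed = np.zeros(n, dtype=bool)
    tally = {"mechanism": 0, "age_lt_15": 0, "dead_on_arrival": 0, "ed_discharge": 0}

    bad_mech = ~df["mechanism"].isin(_CORE_MECHANISMS).to_numpy()
    tally["mechanism"] = int(bad_mech.sum())
    removed |= bad_mech

    young = (df["age"].to_numpy() < 15) & ~removed
    tally["age_lt_15"] = int(young.sum())
    removed |= young

    for col, key in (("dead_on_arrival", "dead_on_arrival"), ("ed_discharge", "ed_discharge")):
        if col in df.columns:
            flagged = df[col].astype(bool).to_numpy() & ~removed
            tally[key] = int(flagged.sum())
            removed |= flagged

    kept = Registry(df.loc[~removed].reset_index(drop=True), registry.label, list(registry.rejected))
    return kept, tally
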