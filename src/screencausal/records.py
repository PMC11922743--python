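"""Cohort data model for AI-supported double-reading screening records.

One row per screened woman. The table carries the reading covariates
(age, breast density, screening round, reader-set and reader identities,
supervision), the AI worklist predictions (normal triage tag, safety-net
trigger/shown/accepted), the derived study-group assignment, the outcome
chain consensus -> recall -> biopsy -> cancer detection, and tumor
attributes for detected cancers.

File dialect: UTF-8 CSV, RFC-4180 quoting, mandatory header, booleans as
0/1, missing values as the empty string. A companion data dictionary in a
``field: type | domain`` key-value format can be written alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FIELDS",
    "CohortTable",
    "ValidationReport",
    "SchemaError",
    "DomainError",
    "read_cohort",
    "write_cohort",
    "write_dictionary",
    "derive_group",
    "apply_exclusions",
    "validate_cohort",
]


class SchemaError(ValueError):
    """A required column is missing or mistyped."""


class DomainError(ValueError):
    """A cell value falls outside its declared domain."""


# kind: id | int | bool | tribool (0/1/NA) | cat (closed token set)
@dataclass(frozen=True)
class FieldSpec:
    name: str
    kind: str
    domain: tuple = ()
    nullable: bool = False
    note: str = ""


FIELDS: tuple[FieldSpec, ...] = (
    FieldSpec("woman_id", "id", note="opaque unique identifier"),
    FieldSpec("age_years", "int", nullable=True, note="age at screening, nominally 50-69"),
    FieldSpec("density_class", "cat", ("nondense", "dense", "missing"),
              note="ACR I/II -> nondense, III/IV -> dense"),
    FieldSpec("screening_round", "cat", ("first", "followup")),
    FieldSpec("reader_set_id", "id", note="double-reading radiologist pair"),
    FieldSpec("reader1_id", "id"),
    FieldSpec("reader2_id", "id"),
    FieldSpec("supervised", "bool", note="third supervising radiologist involved"),
    FieldSpec("reader1_used_ai", "bool"),
    FieldSpec("reader2_used_ai", "bool"),
    FieldSpec("study_group", "cat", ("ai", "control"), note="derived: ai if any reader used the AI viewer"),
    FieldSpec("ai_normal_tag", "bool", note="AI normal-triage worklist tag"),
    FieldSpec("safety_net_triggered", "bool"),
    FieldSpec("safety_net_shown", "tribool", nullable=True, note="NA outside the AI group"),
    FieldSpec("safety_net_accepted", "tribool", nullable=True, note="NA outside the AI group"),
    FieldSpec("consensus", "bool", note="consensus conference held"),
    FieldSpec("recall", "bool"),
    FieldSpec("biopsy", "bool", note="preoperative biopsy recommended"),
    FieldSpec("cancer_detected", "bool"),
    FieldSpec("invasiveness", "cat", ("dcis", "invasive", "other", "none")),
    FieldSpec("stage", "cat", ("0", "1", "2", "3", "4", "X", "missing"), nullable=True),
    FieldSpec("grade", "cat", ("1", "2", "3", "X", "missing"), nullable=True, note="invasive only"),
    FieldSpec("size_class", "cat", ("le10mm", "10to20mm", "gt20mm", "missing"), nullable=True,
              note="invasive only"),
    FieldSpec("outcome_missing", "bool"),
    FieldSpec("cancelled", "bool"),
)

FIELD_NAMES = tuple(f.name for f in FIELDS)
_BY_NAME = {f.name: f for f in FIELDS}

SCHEMA_VERSION = "1"

#: loader option mapping ACR density codings onto the dictionary tokens
ACR_DENSITY_MAP = {
    "I": "nondense", "II": "nondense", "III": "dense", "IV": "dense",
    "1": "nondense", "2": "nondense", "3": "dense", "4": "dense",
    "a": "nondense", "b": "nondense", "c": "dense", "d": "dense",
}


@dataclass
class CohortTable:
    """Ordered collection of screening records with provenance."""

    df: pd.DataFrame
    provenance: str = "loaded"  # "simulated" | "loaded"
    schema_version: str = SCHEMA_VERSION
    extra_columns: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "CohortTable":
        return CohortTable(self.df.copy(), self.provenance, self.schema_version,
                           self.extra_columns)


@dataclass
class ValidationReport:
    """Per-rule violation counts plus exclusion tallies."""

    violations: dict = field(default_factory=dict)
    excluded_missing_outcome: int = 0
    excluded_cancelled: int = 0

    @property
    def total_violations(self) -> int:
        return int(sum(self.violations.values()))

    @property
    def passed(self) -> bool:
        return self.total_violations == 0

    def __str__(self) -> str:  # pragma: no cover - convenience only
        lines = [f"valid: {self.passed}"]
        for rule, n in sorted(self.violations.items()):
            lines.append(f"  {rule}: {n}")
        lines.append(f"  excluded (missing outcome): {self.excluded_missing_outcome}")
        lines.append(f"  excluded (cancelled): {self.excluded_cancelled}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# parsing / writing


def _parse_column(raw: pd.Series, spec: FieldSpec) -> pd.Series:
    s = raw.astype("string").fillna("")
    empty = s == ""
    if spec.kind == "id":
        return s.astype(object)
    if spec.kind == "int":
        if (empty & ~pd.Series([spec.nullable] * len(s), index=s.index)).any() and not spec.nullable:
            bad = int(np.flatnonzero(empty.to_numpy())[0])
            raise DomainError(f"column '{spec.name}': empty value at row {bad}")
        out = pd.to_numeric(s.where(~empty, None), errors="coerce")
        nonnum = out.isna() & ~empty
        if nonnum.any():
            bad = int(np.flatnonzero(nonnum.to_numpy())[0])
            raise DomainError(
                f"column '{spec.name}': unparseable integer {s.iloc[bad]!r} at row {bad}")
        return out.astype("Int64")
    if spec.kind in ("bool", "tribool"):
        allowed = {"0", "1"}
        vals = s.to_numpy()
        ok = np.isin(vals, list(allowed)) | (empty.to_numpy() & (spec.kind == "tribool" or spec.nullable))
        if not ok.all():
            bad = int(np.flatnonzero(~ok)[0])
            raise DomainError(
                f"column '{spec.name}': value {vals[bad]!r} at row {bad} not in allowed {{0,1}}")
        out = pd.to_numeric(s.where(~empty, None), errors="coerce").astype("Int64")
        if spec.kind == "bool":
            return out.astype("int64") if not out.isna().any() else out
        return out
    if spec.kind == "cat":
        vals = s.to_numpy()
        ok = np.isin(vals, spec.domain) | (empty.to_numpy() & spec.nullable)
        if not ok.all():
            bad = int(np.flatnonzero(~ok)[0])
            raise DomainError(
                f"column '{spec.name}': value {vals[bad]!r} at row {bad} not in allowed "
                f"{{{', '.join(spec.domain)}}}")
        return s.where(~empty, pd.NA).astype(object)
    raise AssertionError(spec.kind)


def read_cohort(path, dictionary: Sequence[FieldSpec] = FIELDS, *,
                density_coding: str = "token") -> CohortTable:
    """Read a cohort CSV, type and domain-check every dictionary column.

    Parameters
    ----------
    path:
        CSV file (or file-like / string buffer) with a header row.
    dictionary:
        Field specifications; defaults to the built-in data dictionary.
    density_coding:
        ``"token"`` (default) expects the dictionary tokens; ``"acr"``
        maps ACR categories I-IV (or a-d) onto nondense/dense.

    Unknown columns are preserved and flagged in ``extra_columns``.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    names = [f.name for f in dictionary]
    missing = [n for n in names if n not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if density_coding == "acr" and "density_class" in raw.columns:
        raw["density_class"] = raw["density_class"].map(
            lambda v: ACR_DENSITY_MAP.get(v, v))
    cols = {}
    for spec in dictionary:
        cols[spec.name] = _parse_column(raw[spec.name], spec)
    extra = tuple(c for c in raw.columns if c not in names)
    df = pd.DataFrame(cols)
    for c in extra:
        df[c] = raw[c]
    return CohortTable(df, provenance="loaded", extra_columns=extra)


def _format_column(s: pd.Series, spec: FieldSpec) -> pd.Series:
    if spec.kind in ("bool", "tribool", "int"):
        out = s.astype("Int64").astype("string")
        return out.fillna("")
    return s.astype("string").fillna("")


def write_cohort(table: CohortTable, path) -> None:
    """Write a cohort table in the canonical dialect (lossless round-trip)."""
    df = table.df
    out = {}
    for spec in FIELDS:
        out[spec.name] = _format_column(df[spec.name], spec)
    for c in table.extra_columns:
        out[c] = df[c].astype("string").fillna("")
    pd.DataFrame(out).to_csv(path, index=False, lineterminator="\n")


def write_dictionary(path, dictionary: Sequence[FieldSpec] = FIELDS) -> None:
    """Write the companion data dictionary as key-value text."""
    lines = []
    for f in dictionary:
        domain = "{" + ",".join(map(str, f.domain)) + "}" if f.domain else f.kind
        null = " (nullable)" if f.nullable else ""
        note = f"  # {f.note}" if f.note else ""
        lines.append(f"{f.name}: {f.kind} | {domain}{null}{note}")
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)


# ---------------------------------------------------------------------------
# derivations


def derive_group(reader1_used_ai, reader2_used_ai):
    """Derive study-group assignment from the two viewer flags.

    An examination belongs to the AI group when at least one of the two
    radiologists read and submitted the report with the AI-supported
    viewer; it is a control examination when neither did.

    Returns ``(study_group, n_ai_readers)`` where group is "ai"/"control"
    and ``n_ai_readers`` counts the AI-using readers (0, 1 or 2).
    Accepts scalars or aligned vectors.
    """
    r1 = np.asarray(reader1_used_ai)
    r2 = np.asarray(reader2_used_ai)
    scalar = r1.ndim == 0
    r1, r2 = np.atleast_1d(r1), np.atleast_1d(r2)
    for name, arr in (("reader1_used_ai", r1), ("reader2_used_ai", r2)):
        if pd.isna(arr).any():
            raise DomainError(f"{name} contains missing values; both viewer flags are required")
    n_ai = r1.astype(int) + r2.astype(int)
    group = np.where(n_ai > 0, "ai", "control")
    if scalar:
        return group[0], int(n_ai[0])
    return group, n_ai


def apply_exclusions(table: CohortTable) -> tuple[CohortTable, ValidationReport]:
    """Drop records with missing outcome data or cancelled examinations.

    Retained rows are returned unaltered (index reset); the report carries
    both exclusion counts.
    """
    df = table.df
    miss = df["outcome_missing"].astype(bool).to_numpy()
    canc = df["cancelled"].astype(bool).to_numpy() & ~miss
    keep = ~(miss | canc)
    report = ValidationReport(
        excluded_missing_outcome=int(miss.sum()),
        excluded_cancelled=int(canc.sum()),
    )
    out = CohortTable(df.loc[keep].reset_index(drop=True), table.provenance,
                      table.schema_version, table.extra_columns)
    return out, report


# ---------------------------------------------------------------------------
# validation

_CHAIN = ("consensus", "recall", "biopsy", "cancer_detected")


def validate_cohort(table: CohortTable) -> ValidationReport:
    """Check every record-level invariant; violations are counted, not thrown.

    Rules
    -----
    - monotone outcome chain: detection => biopsy => recall => consensus
    - safety-net chain: accepted => shown => triggered
    - normal tag and safety-net trigger are mutually exclusive
    - control group: no AI reader, safety-net shown/accepted must be NA
    - invasiveness "none" iff no cancer detected
    - grade/size present iff invasiveness is invasive
    - woman_id unique
    """
    df = table.df
    v: dict[str, int] = {}

    cons = df["consensus"].astype("Int64").fillna(0).to_numpy(int)
    rec = df["recall"].astype("Int64").fillna(0).to_numpy(int)
    bio = df["biopsy"].astype("Int64").fillna(0).to_numpy(int)
    det = df["cancer_detected"].astype("Int64").fillna(0).to_numpy(int)
    v["outcome_chain"] = int(((det > bio) | (bio > rec) | (rec > cons)).sum())

    trig = df["safety_net_triggered"].astype("Int64").fillna(0).to_numpy(int)
    shown = df["safety_net_shown"].astype("Int64").fillna(0).to_numpy(int)
    acc = df["safety_net_accepted"].astype("Int64").fillna(0).to_numpy(int)
    v["safety_net_chain"] = int(((acc > shown) | (shown > trig)).sum())

    tag = df["ai_normal_tag"].astype("Int64").fillna(0).to_numpy(int)
    v["tag_trigger_exclusive"] = int(((tag == 1) & (trig == 1)).sum())

    grp = df["study_group"].to_numpy(object)
    r1 = df["reader1_used_ai"].astype("Int64").fillna(0).to_numpy(int)
    r2 = df["reader2_used_ai"].astype("Int64").fillna(0).to_numpy(int)
    ctrl = grp == "control"
    v["group_consistency"] = int((ctrl & ((r1 == 1) | (r2 == 1))).sum()
                                 + (~ctrl & (r1 == 0) & (r2 == 0)).sum())
    sn_na = df["safety_net_shown"].isna().to_numpy() & df["safety_net_accepted"].isna().to_numpy()
    v["control_safety_net_na"] = int((ctrl & ~sn_na).sum())

    inv = df["invasiveness"].to_numpy(object)
    v["invasiveness_consistency"] = int((((inv == "none") != (det == 0))).sum())
    has_grade = df["grade"].notna().to_numpy()
    has_size = df["size_class"].notna().to_numpy()
    invasive = inv == "invasive"
    v["grade_size_invasive_only"] = int(((has_grade | has_size) & ~invasive).sum()
                                        + (invasive & ~(has_grade & has_size)).sum())

    v["woman_id_unique"] = int(df["woman_id"].duplicated().sum())

    return ValidationReport(violations=v)
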