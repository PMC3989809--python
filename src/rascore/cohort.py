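"""Domain types, derived clinical variables and CSV I/O.

A cohort is a collection of :class:`PatientRecord` objects, one per subject
undergoing simultaneous coronary and renal angiography.  The outcome flag
``ras_significant`` encodes renal artery stenosis of at least 50% lumen
narrowing in at least one renal artery; ``cad_significant`` encodes coronary
stenosis of at least 70% in at least one vessel.  Carotid intima-media
thickness (``cimt``, mm) is the mean of the right- and left-sided
measurements, and carotid plaque extent (``cap_extent``) is a three-level
category: none / unilateral / bilateral.

Derived variables follow the usual nephrology conventions: eGFR from the
four-variable IDMS-traceable MDRD equation, CKD stage >=3 as eGFR < 60
ml/min/1.73 m**2, and proteinuria as a random urine protein/creatinine ratio
strictly above 300 mg/g.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import RowParseError, SchemaError

logger = logging.getLogger(__name__)

CAP_CATEGORIES = ("none", "unilateral", "bilateral")

#: MDRD constant for IDMS-traceable serum creatinine assays.
MDRD_CONSTANT = 175.0
MDRD_FEMALE_FACTOR = 0.742

#: eGFR below this (ml/min/1.73 m**2) defines CKD stage >=3 (strict inequality).
CKD_STAGE3_EGFR = 60.0
#: Urine protein/creatinine ratio above this (mg/g) defines proteinuria (strict).
PROTEINURIA_UPCR = 300.0
#: Taking at least this many anti-hypertensive medications is the fixed
#: clinical risk category (not Youden-derived).
AHM_RISK_COUNT = 4

_TRUE_STRINGS = {"1", "true", "yes", "y", "t"}
_FALSE_STRINGS = {"0", "false", "no", "n", "f"}


@dataclass(frozen=True)
class PatientRecord:
    """One subject's raw covariates and outcome."""

    id: str
    age: float                  # years
    male: bool
    bmi: float                  # kg/m**2
    hypertension: bool
    n_ahm: int                  # number of anti-hypertensive medications
    diabetes: bool
    smoking: bool
    total_chol: float           # mg/dl
    hdl_chol: float             # mg/dl
    triglyceride: float         # mg/dl
    creatinine: float           # mg/dl
    upcr: float | None          # mg/g; may be missing
    cimt: float                 # mm, mean of right and left
    cap_extent: str             # one of CAP_CATEGORIES
    cad_significant: bool
    ras_significant: bool

    def __post_init__(self):
        if self.age <= 0:
            raise ValueError(f"age must be positive, got {self.age}")
        if self.bmi <= 0:
            raise ValueError(f"bmi must be positive, got {self.bmi}")
        if self.cimt <= 0:
            raise ValueError(f"cimt must be positive, got {self.cimt}")
        if self.n_ahm < 0 or int(self.n_ahm) != self.n_ahm:
            raise ValueError(f"n_ahm must be a non-negative integer, got {self.n_ahm}")
        for name in ("total_chol", "hdl_chol", "triglyceride", "creatinine"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.upcr is not None and self.upcr < 0:
            raise ValueError("upcr must be non-negative when present")
        if self.cap_extent not in CAP_CATEGORIES:
            raise ValueError(
                f"cap_extent must be one of {CAP_CATEGORIES}, got {self.cap_extent!r}"
            )


#: Default cut-offs for dichotomizing the continuous covariates, matching the
#: published model (age >=67 y, BMI <22 kg/m**2, CIMT >=1.0 mm, total
#: cholesterol >=158, HDL >=47, triglyceride >=119 mg/dl).
DEFAULT_CUTOFFS: dict[str, float] = {
    "age": 67.0,
    "bmi": 22.0,
    "cimt": 1.0,
    "total_chol": 158.0,
    "hdl_chol": 47.0,
    "triglyceride": 119.0,
}

#: Risk direction of each dichotomized covariate: ``ge`` means values at or
#: above the cut-off score as "risk present", ``lt`` means values strictly
#: below the cut-off do.  Low BMI is the risk direction (frailty/nutritional
#: status), high values are for all the others.
CUTOFF_DIRECTIONS: dict[str, str] = {
    "age": "ge",
    "bmi": "lt",
    "cimt": "ge",
    "total_chol": "ge",
    "hdl_chol": "ge",
    "triglyceride": "ge",
}

#: Canonical names of the indicator columns produced by dichotomization.
INDICATOR_NAMES: dict[str, str] = {
    "age": "age_ge_cut",
    "bmi": "bmi_lt_cut",
    "cimt": "cimt_ge_cut",
    "total_chol": "chol_ge_cut",
    "hdl_chol": "hdl_ge_cut",
    "triglyceride": "tg_ge_cut",
}


@dataclass(frozen=True)
class DerivedRecord:
    """A :class:`PatientRecord` augmented with derived clinical variables and
    the 0/1 indicators used by the regression model and the scoring system."""

    record: PatientRecord
    egfr: float
    ckd_stage_ge3: int
    proteinuria: int
    upcr_missing: bool
    indicators: Mapping[str, int] = field(default_factory=dict)

    def indicator_values(self) -> dict[str, int]:
        """All 0/1 modelling indicators, including the CAP dummies."""
        out = dict(self.indicators)
        out.update(
            ckd_stage_ge3=self.ckd_stage_ge3,
            proteinuria=self.proteinuria,
            ahm_ge4=int(self.record.n_ahm >= AHM_RISK_COUNT),
            cad_significant=int(self.record.cad_significant),
            hypertension=int(self.record.hypertension),
            diabetes=int(self.record.diabetes),
            smoking=int(self.record.smoking),
            male=int(self.record.male),
            cap_unilateral=int(self.record.cap_extent == "unilateral"),
            cap_bilateral=int(self.record.cap_extent == "bilateral"),
        )
        return out


@dataclass(frozen=True)
class GroupedScoreTable:
    """Per-score counts of subjects with and without the outcome.

    Rows are (score, n, events) with scores strictly increasing.
    """

    scores: tuple[int, ...]
    n: tuple[int, ...]
    events: tuple[int, ...]

    def __post_init__(self):
        if not (len(self.scores) == len(self.n) == len(self.events)):
            raise ValueError("scores, n and events must have equal length")
        if any(s2 <= s1 for s1, s2 in zip(self.scores, self.scores[1:])):
            raise ValueError("scores must be strictly increasing")
        for s, n_s, e_s in zip(self.scores, self.n, self.events):
            if not (0 <= e_s <= n_s):
                raise ValueError(f"score {s}: events {e_s} outside [0, n={n_s}]")

    @property
    def total_n(self) -> int:
        return int(sum(self.n))

    @property
    def total_events(self) -> int:
        return int(sum(self.events))

    def expand(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-subject (score, outcome) arrays implied by the counts."""
        score = np.repeat(self.scores, self.n).astype(float)
        outcome = np.concatenate(
            [
                np.r_[np.ones(e, dtype=int), np.zeros(n - e, dtype=int)]
                for n, e in zip(self.n, self.events)
            ]
            or [np.empty(0, dtype=int)]
        )
        return score, outcome

    @classmethod
    def from_csv(cls, path: str | Path) -> "GroupedScoreTable":
        df = pd.read_csv(path)
        for col in ("score", "n", "events"):
            if col not in df.columns:
                raise SchemaError(f"grouped-score CSV missing column {col!r}")
        return cls(
            scores=tuple(int(s) for s in df["score"]),
            n=tuple(int(v) for v in df["n"]),
            events=tuple(int(v) for v in df["events"]),
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"score": self.scores, "n": self.n, "events": self.events}
        ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Derived variables
# ---------------------------------------------------------------------------

def compute_egfr(
    creatinine: float,
    age: float,
    male: bool,
    constant: float = MDRD_CONSTANT,
) -> float:
    """Estimated GFR (ml/min/1.73 m**2) by the 4-variable IDMS MDRD equation.

    eGFR = constant * Scr**-1.154 * age**-0.203 * (0.742 if female).
    The race factor is omitted (no race field is collected).
    """
    if creatinine <= 0 or age <= 0:
        raise ValueError("creatinine and age must be positive")
    egfr = constant * creatinine ** -1.154 * age ** -0.203
    if not male:
        egfr *= MDRD_FEMALE_FACTOR
    return egfr


def derive_record(
    p: PatientRecord,
    cutoffs: Mapping[str, float] | None = None,
) -> DerivedRecord:
    """Attach eGFR/CKD/proteinuria and the threshold indicators to a record.

    ``cutoffs`` maps continuous covariate names (keys of
    :data:`DEFAULT_CUTOFFS`) to thresholds; directions are fixed by
    :data:`CUTOFF_DIRECTIONS`.  A missing urine protein/creatinine ratio is
    treated as "no proteinuria" and flagged via ``upcr_missing``.
    Idempotent for fixed cut-offs.
    """
    cuts = dict(DEFAULT_CUTOFFS)
    if cutoffs is not None:
        cuts.update(cutoffs)
    missing = set(DEFAULT_CUTOFFS) - set(cuts)
    if missing:
        raise ValueError(f"no cut-off provided for {sorted(missing)}")

    egfr = compute_egfr(p.creatinine, p.age, p.male)
    indicators = {}
    for var, ind_name in INDICATOR_NAMES.items():
        value = getattr(p, var)
        if CUTOFF_DIRECTIONS[var] == "ge":
            indicators[ind_name] = int(value >= cuts[var])
        else:
            indicators[ind_name] = int(value < cuts[var])
    upcr_missing = p.upcr is None
    return DerivedRecord(
        record=p,
        egfr=egfr,
        ckd_stage_ge3=int(egfr < CKD_STAGE3_EGFR),
        proteinuria=int(p.upcr is not None and p.upcr > PROTEINURIA_UPCR),
        upcr_missing=upcr_missing,
        indicators=indicators,
    )


# ---------------------------------------------------------------------------
# Frame-level equivalents (the modelling pipeline works on DataFrames)
# ---------------------------------------------------------------------------

_RECORD_FIELDS = [f.name for f in fields(PatientRecord)]


def cohort_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    """Tabulate a cohort as a DataFrame with canonical column names."""
    rows = []
    for r in records:
        row = {name: getattr(r, name) for name in _RECORD_FIELDS}
        row["upcr"] = np.nan if r.upcr is None else r.upcr
        rows.append(row)
    df = pd.DataFrame(rows, columns=_RECORD_FIELDS)
    for name in ("male", "hypertension", "diabetes", "smoking",
                 "cad_significant", "ras_significant"):
        df[name] = df[name].astype(int)
    return df


def derive_frame(
    df: pd.DataFrame,
    cutoffs: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Vectorized :func:`derive_record` over a cohort frame.

    Returns a copy of ``df`` with egfr, ckd_stage_ge3, proteinuria, ahm_ge4,
    the cut-off indicators and the two CAP dummies appended.
    """
    cuts = dict(DEFAULT_CUTOFFS)
    if cutoffs is not None:
        cuts.update(cutoffs)
    out = df.copy()
    male = df["male"].astype(bool).to_numpy()
    egfr = (
        MDRD_CONSTANT
        * df["creatinine"].to_numpy() ** -1.154
        * df["age"].to_numpy() ** -0.203
    )
    egfr = np.where(male, egfr, egfr * MDRD_FEMALE_FACTOR)
    out["egfr"] = egfr
    out["ckd_stage_ge3"] = (egfr < CKD_STAGE3_EGFR).astype(int)
    upcr = df["upcr"].to_numpy(dtype=float)
    out["proteinuria"] = ((~np.isnan(upcr)) & (upcr > PROTEINURIA_UPCR)).astype(int)
    out["upcr_missing"] = np.isnan(upcr)
    out["ahm_ge4"] = (df["n_ahm"].to_numpy() >= AHM_RISK_COUNT).astype(int)
    for var, ind_name in INDICATOR_NAMES.items():
        v = df[var].to_numpy(dtype=float)
        if CUTOFF_DIRECTIONS[var] == "ge":
            out[ind_name] = (v >= cuts[var]).astype(int)
        else:
            out[ind_name] = (v < cuts[var]).astype(int)
    out["cap_unilateral"] = (df["cap_extent"] == "unilateral").astype(int)
    out["cap_bilateral"] = (df["cap_extent"] == "bilateral").astype(int)
    return out


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _parse_bool(raw: str) -> bool:
    s = raw.strip().lower()
    if s in _TRUE_STRINGS:
        return True
    if s in _FALSE_STRINGS:
        return False
    raise ValueError(f"cannot parse boolean from {raw!r}")


def load_schema(path: str | Path) -> dict:
    """Load a YAML column-mapping: ``columns: {field: csv column}`` plus
    optional ``cap_aliases: {csv value: category}``."""
    with open(path) as fh:
        schema = yaml.safe_load(fh) or {}
    if not isinstance(schema, dict):
        raise SchemaError("schema YAML must be a mapping")
    return schema


def read_cohort(
    path: str | Path,
    schema: Mapping | None = None,
) -> list[PatientRecord]:
    """Read a patient-level CSV into records.

    ``schema`` may carry ``columns`` (canonical field -> CSV column name) and
    ``cap_aliases`` (raw cell value -> one of ``none/unilateral/bilateral``).
    Booleans accept 0/1/true/false/yes/no, case-insensitively; an empty
    ``upcr`` cell is treated as missing.
    """
    schema = dict(schema or {})
    colmap: dict[str, str] = {f: f for f in _RECORD_FIELDS}
    colmap.update(schema.get("columns", {}))
    cap_aliases = {
        str(k).strip().lower(): v for k, v in schema.get("cap_aliases", {}).items()
    }

    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for field_name, col in colmap.items():
            if col not in header:
                raise SchemaError(f"missing mandatory column {col!r} (field {field_name!r})")
        records = []
        for i, row in enumerate(reader):
            try:
                records.append(_parse_row(row, colmap, cap_aliases, i))
            except (ValueError, KeyError) as exc:
                raise RowParseError(str(exc), row_index=i) from exc
    return records


def _parse_row(row, colmap, cap_aliases, index) -> PatientRecord:
    def cell(field_name: str) -> str:
        return row[colmap[field_name]]

    cap_raw = cell("cap_extent").strip().lower()
    cap = cap_aliases.get(cap_raw, cap_raw)
    if cap not in CAP_CATEGORIES:
        raise ValueError(
            f"cap_extent value {cell('cap_extent')!r} is not one of {CAP_CATEGORIES}"
        )
    upcr_raw = cell("upcr").strip()
    return PatientRecord(
        id=cell("id").strip(),
        age=float(cell("age")),
        male=_parse_bool(cell("male")),
        bmi=float(cell("bmi")),
        hypertension=_parse_bool(cell("hypertension")),
        n_ahm=int(cell("n_ahm")),
        diabetes=_parse_bool(cell("diabetes")),
        smoking=_parse_bool(cell("smoking")),
        total_chol=float(cell("total_chol")),
        hdl_chol=float(cell("hdl_chol")),
        triglyceride=float(cell("triglyceride")),
        creatinine=float(cell("creatinine")),
        upcr=None if upcr_raw == "" else float(upcr_raw),
        cimt=float(cell("cimt")),
        cap_extent=cap,
        cad_significant=_parse_bool(cell("cad_significant")),
        ras_significant=_parse_bool(cell("ras_significant")),
    )


def write_cohort(records: Sequence[PatientRecord], path: str | Path) -> None:
    """Write a cohort to CSV with canonical column names (round-trips with
    :func:`read_cohort`)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_RECORD_FIELDS)
        for r in records:
            row = []
            for name in _RECORD_FIELDS:
                v = getattr(r, name)
                if v is None:
                    row.append("")
                elif isinstance(v, bool):
                    row.append(int(v))
                else:
                    row.append(v)
            writer.writerow(row)


def exclude_incomplete(df: pd.DataFrame, required: Sequence[str] | None = None) -> pd.DataFrame:
    """Drop rows missing any modelling variable (upcr excepted) and log the count."""
    required = list(
        required
        or [c for c in _RECORD_FIELDS if c not in ("id", "upcr")]
    )
    mask = df[required].notna().all(axis=1)
    n_dropped = int((~mask).sum())
    if n_dropped:
        logger.info("excluded %d rows with incomplete modelling data", n_dropped)
    return df.loc[mask].reset_index(drop=True)
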