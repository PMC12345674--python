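"""Cohort data model, delimited-text I/O, validation, and stratification.

A cohort is one row per child: group label (ASD or healthy control), sex,
age, an optional autism-severity score (CARS, Childhood Autism Rating
Scale), and the five urinary toxin measurements — either raw
concentrations (µmol/L) together with urinary creatinine (mmol/L), or
already creatinine-normalized values (µmol/mmol). An optional Bristol
stool-form score is carried through but never analyzed.

Stratification partitions the cohort into the analysis strata used by the
downstream descriptive, inferential, and burden modules: group, sex
within group, age band within group, and CARS severity class within the
ASD group.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .toxins import TOXIN_ORDER, Toxin

__all__ = [
    "Group",
    "Sex",
    "Subject",
    "Cohort",
    "StrataConfig",
    "StratifiedCohort",
    "ValidationFinding",
    "ValidationReport",
    "CohortSchemaError",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
    "assign_strata",
    "DEFAULT_COLUMNS",
]


class Group(str, Enum):
    ASD = "ASD"
    CONTROL = "CONTROL"


class Sex(str, Enum):
    BOY = "BOY"
    GIRL = "GIRL"


#: Study age range in years; ages outside are flagged unless permissive.
AGE_MIN, AGE_MAX = 2.0, 17.0

# Canonical column names of the cohort CSV dialect. Raw and normalized
# toxin columns are both optional per subject, but each analyzed toxin
# needs one of the two routes (raw + creatinine, or normalized).
_RAW_COL = {t: f"{t.value.lower()}_umol_l" for t in TOXIN_ORDER}
_NORM_COL = {t: f"{t.value.lower()}_umol_mmol" for t in TOXIN_ORDER}

DEFAULT_COLUMNS: tuple[str, ...] = (
    "subject_id",
    "group",
    "sex",
    "age_years",
    "cars_score",
    "creatinine_mmol_l",
    *(_RAW_COL[t] for t in TOXIN_ORDER),
    *(_NORM_COL[t] for t in TOXIN_ORDER),
    "bristol_stool",
)

_MANDATORY = ("subject_id", "group", "sex", "age_years")

_GROUP_ALIASES = {"asd": Group.ASD, "control": Group.CONTROL, "ctrl": Group.CONTROL}
_SEX_ALIASES = {
    "boy": Sex.BOY,
    "girl": Sex.GIRL,
    "m": Sex.BOY,
    "f": Sex.GIRL,
    "male": Sex.BOY,
    "female": Sex.GIRL,
}


class CohortSchemaError(ValueError):
    """Raised when a cohort file violates the schema (missing columns,
    unparseable values, duplicate ids)."""


@dataclass(frozen=True)
class Subject:
    """One child's demographic, clinical, and measurement record."""

    subject_id: str
    group: Group
    sex: Sex
    age_years: float
    cars_score: float | None = None
    creatinine: float | None = None
    toxin_raw: Mapping[Toxin, float] = field(default_factory=dict)
    toxin_norm: Mapping[Toxin, float] = field(default_factory=dict)
    bristol_stool: int | None = None

    def normalized(self, toxin: Toxin) -> float | None:
        """Creatinine-normalized concentration (µmol/mmol) for `toxin`,
        preferring a stored normalized value over raw/creatinine."""
        if toxin in self.toxin_norm:
            return self.toxin_norm[toxin]
        if toxin in self.toxin_raw and self.creatinine:
            return self.toxin_raw[toxin] / self.creatinine
        return None


class Cohort:
    """A cohort of subjects, backed by a pandas DataFrame in the canonical
    column layout. Row order is preserved from the source."""

    def __init__(self, frame: pd.DataFrame, meta: dict | None = None):
        frame = frame.copy()
        for col in DEFAULT_COLUMNS:
            if col not in frame.columns:
                frame[col] = np.nan
        self.frame = frame.reset_index(drop=True)
        self.meta = dict(meta or {})

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return self.frame[list(DEFAULT_COLUMNS)].equals(
            other.frame[list(DEFAULT_COLUMNS)]
        )

    @property
    def subject_ids(self) -> list[str]:
        return list(self.frame["subject_id"].astype(str))

    def subjects(self) -> Iterator[Subject]:
        for _, row in self.frame.iterrows():
            yield _row_to_subject(row)

    def normalized_values(self, toxin: Toxin) -> pd.Series:
        """Per-subject normalized concentration (µmol/mmol), indexed like
        the frame; NaN where neither route is available."""
        norm = pd.to_numeric(self.frame[_NORM_COL[toxin]], errors="coerce")
        raw = pd.to_numeric(self.frame[_RAW_COL[toxin]], errors="coerce")
        creat = pd.to_numeric(self.frame["creatinine_mmol_l"], errors="coerce")
        with np.errstate(divide="ignore", invalid="ignore"):
            derived = raw / creat.where(creat > 0)
        return norm.fillna(derived)

    def group_mask(self, group: Group) -> pd.Series:
        return self.frame["group"].astype(str).str.upper() == group.value

    @classmethod
    def from_subjects(cls, subjects: Iterable[Subject], meta: dict | None = None) -> "Cohort":
        rows = []
        for s in subjects:
            row: dict = {
                "subject_id": s.subject_id,
                "group": s.group.value,
                "sex": s.sex.value,
                "age_years": s.age_years,
                "cars_score": s.cars_score,
                "creatinine_mmol_l": s.creatinine,
                "bristol_stool": s.bristol_stool,
            }
            for t in TOXIN_ORDER:
                row[_RAW_COL[t]] = s.toxin_raw.get(t)
                row[_NORM_COL[t]] = s.toxin_norm.get(t)
            rows.append(row)
        frame = pd.DataFrame(rows, columns=list(DEFAULT_COLUMNS))
        return cls(frame, meta)


def _row_to_subject(row: pd.Series) -> Subject:
    def num(x):
        v = pd.to_numeric(pd.Series([x]), errors="coerce").iloc[0]
        return None if pd.isna(v) else float(v)

    raw = {t: num(row[_RAW_COL[t]]) for t in TOXIN_ORDER}
    norm = {t: num(row[_NORM_COL[t]]) for t in TOXIN_ORDER}
    bristol = num(row.get("bristol_stool"))
    return Subject(
        subject_id=str(row["subject_id"]),
        group=_GROUP_ALIASES[str(row["group"]).strip().lower()],
        sex=_SEX_ALIASES[str(row["sex"]).strip().lower()],
        age_years=float(row["age_years"]),
        cars_score=num(row.get("cars_score")),
        creatinine=num(row.get("creatinine_mmol_l")),
        toxin_raw={t: v for t, v in raw.items() if v is not None},
        toxin_norm={t: v for t, v in norm.items() if v is not None},
        bristol_stool=int(bristol) if bristol is not None else None,
    )


# ---------------------------------------------------------------------------
# I/O


def read_cohort(
    path: str | Path,
    delimiter: str = ",",
    column_map: Mapping[str, str] | None = None,
) -> Cohort:
    """Read a cohort from a delimited text file.

    Parameters
    ----------
    path:
        CSV (default) or TSV file, UTF-8, one row per subject, with a
        header row using the canonical column names (``DEFAULT_COLUMNS``).
    delimiter:
        Field delimiter; ``","`` or ``"\\t"``.
    column_map:
        Optional mapping from the file's header names to canonical names,
        for clinical exports whose headers differ. Unknown extra columns
        are preserved in the frame but ignored by all analyses.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(
        path, sep=delimiter, dtype={"subject_id": str}, float_precision="round_trip"
    )
    if column_map:
        frame = frame.rename(columns=dict(column_map))
    missing = [c for c in _MANDATORY if c not in frame.columns]
    if missing:
        raise CohortSchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    numeric_cols = [
        c
        for c in DEFAULT_COLUMNS
        if c in frame.columns and c not in ("subject_id", "group", "sex")
    ]
    for col in numeric_cols:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna() & (frame[col].astype(str).str.strip() != "")
        if bad.any():
            line = int(bad.idxmax()) + 2  # 1-based + header line
            raise CohortSchemaError(
                f"unparseable numeric value in column '{col}' at line {line}: "
                f"{frame[col][bad].iloc[0]!r}"
            )
        frame[col] = coerced

    for col, aliases in (("group", _GROUP_ALIASES), ("sex", _SEX_ALIASES)):
        normalized = frame[col].astype(str).str.strip().str.lower()
        unknown = ~normalized.isin(aliases)
        if unknown.any():
            line = int(unknown.idxmax()) + 2
            raise CohortSchemaError(
                f"unrecognized {col} label at line {line}: {frame[col][unknown].iloc[0]!r}"
            )
        frame[col] = normalized.map(lambda v: aliases[v].value)

    dup = frame["subject_id"].duplicated()
    if dup.any():
        raise CohortSchemaError(
            f"duplicate subject_id: {frame['subject_id'][dup].iloc[0]!r}"
        )
    return Cohort(frame, meta={"source": str(path)})


def write_cohort(cohort: Cohort, path: str | Path, delimiter: str = ",") -> None:
    """Write a cohort in the canonical CSV dialect (empty cells for
    missing values; round-trips through `read_cohort`)."""
    out = cohort.frame[list(DEFAULT_COLUMNS)]
    out.to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# Validation


@dataclass(frozen=True)
class ValidationFinding:
    subject_id: str
    severity: str  # "error" | "warning"
    message: str


@dataclass
class ValidationReport:
    """Per-subject violations of the cohort invariants. An empty report
    (no errors, no warnings) means the cohort is analysis-ready."""

    findings: list[ValidationFinding] = field(default_factory=list)

    @property
    def errors(self) -> list[ValidationFinding]:
        return [f for f in self.findings if f.severity == "error"]

    @property
    def warnings(self) -> list[ValidationFinding]:
        return [f for f in self.findings if f.severity == "warning"]

    def __bool__(self) -> bool:  # truthy iff something was found
        return bool(self.findings)

    def to_text(self) -> str:
        if not self.findings:
            return "cohort valid: no findings\n"
        lines = [
            f"[{f.severity.upper()}] subject {f.subject_id}: {f.message}"
            for f in self.findings
        ]
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_errors": len(self.errors),
                "n_warnings": len(self.warnings),
                "findings": [vars(f) for f in self.findings],
            },
            indent=2,
        )


def validate_cohort(cohort: Cohort, permissive_age: bool = False) -> ValidationReport:
    """Check every subject against the cohort invariants without mutating
    the data.

    Errors: age outside the study range (unless ``permissive_age``),
    negative concentrations, non-positive creatinine when raw values are
    present, a toxin with neither measurement route, a CARS score on a
    control. Warnings: ASD subject without a CARS score (excluded from
    severity strata), Bristol stool score outside 1–7.
    """
    report = ValidationReport()
    add = report.findings.append
    frame = cohort.frame

    for idx, row in frame.iterrows():
        sid = str(row["subject_id"])
        group = str(row["group"]).upper()
        age = row["age_years"]
        cars = row["cars_score"]
        creat = row["creatinine_mmol_l"]

        if pd.isna(age):
            add(ValidationFinding(sid, "error", "age_years missing"))
        elif not (AGE_MIN <= float(age) <= AGE_MAX) and not permissive_age:
            add(
                ValidationFinding(
                    sid,
                    "error",
                    f"age_years {age:g} outside study range [{AGE_MIN:g}, {AGE_MAX:g}]",
                )
            )

        if group == Group.CONTROL.value and not pd.isna(cars):
            add(ValidationFinding(sid, "error", "cars_score set on a control subject"))
        if group == Group.ASD.value and pd.isna(cars):
            add(
                ValidationFinding(
                    sid, "warning", "ASD subject without cars_score; excluded from CARS strata"
                )
            )

        if not pd.isna(creat) and float(creat) <= 0:
            add(ValidationFinding(sid, "error", f"creatinine {creat:g} mmol/L is not > 0"))

        for t in TOXIN_ORDER:
            raw, norm = row[_RAW_COL[t]], row[_NORM_COL[t]]
            has_raw = not pd.isna(raw)
            has_norm = not pd.isna(norm)
            if has_raw and float(raw) < 0:
                add(ValidationFinding(sid, "error", f"{t.value} raw concentration {raw:g} < 0"))
            if has_norm and float(norm) < 0:
                add(ValidationFinding(sid, "error", f"{t.value} normalized value {norm:g} < 0"))
            raw_route = has_raw and not pd.isna(creat) and float(creat) > 0
            if not raw_route and not has_norm:
                add(
                    ValidationFinding(
                        sid,
                        "error",
                        f"{t.value}: neither (raw + creatinine) nor normalized value present",
                    )
                )

        bristol = row["bristol_stool"]
        if not pd.isna(bristol) and not (1 <= int(bristol) <= 7):
            add(ValidationFinding(sid, "warning", f"bristol_stool {bristol:g} outside 1–7"))

    return report


# ---------------------------------------------------------------------------
# Stratification


@dataclass(frozen=True)
class StrataConfig:
    """Stratum boundaries.

    Age bands are half-open ``[low, high)`` intervals so every age maps
    to exactly one band (5.95 is "younger", 6.0 is "older"); the clinical
    labels ("2-5.9y") follow the convention of printing the last tenth
    inside the band. CARS severity: mild/moderate iff score ≤
    ``cars_mild_max`` (default 36.0), severe iff score ≥
    ``cars_severe_min`` (default 36.5). CARS is half-point granular so
    the open gap (36.0, 36.5) is empty in practice; a score strictly
    inside it is excluded from severity strata and reported.
    """

    age_bands: tuple[tuple[float, float, str], ...] = (
        (2.0, 6.0, "2-5.9y"),
        (6.0, 18.0, "6-17y"),
    )
    cars_mild_max: float = 36.0
    cars_severe_min: float = 36.5

    def __post_init__(self):
        bands = sorted(self.age_bands)
        for (lo, hi, _), (lo2, _, _) in zip(bands, bands[1:]):
            if hi > lo2:
                raise ValueError("age bands overlap")
        for lo, hi, _ in bands:
            if not lo < hi:
                raise ValueError("empty age band")
        if self.cars_mild_max > self.cars_severe_min:
            raise ValueError("cars_mild_max must be ≤ cars_severe_min")

    def age_band(self, age: float) -> str | None:
        for lo, hi, label in self.age_bands:
            if lo <= age < hi:
                return label
        return None

    def cars_class(self, score: float | None) -> str | None:
        if score is None or (isinstance(score, float) and np.isnan(score)):
            return None
        if score <= self.cars_mild_max:
            return "mild_moderate"
        if score >= self.cars_severe_min:
            return "severe"
        return None  # inside the (mild_max, severe_min) gap


CARS_MILD = "cars_mild_moderate"
CARS_SEVERE = "cars_severe"
CARS_UNCLASSIFIED = "cars_unclassified"


@dataclass
class StratifiedCohort:
    """A cohort together with its named analysis strata.

    ``strata`` maps a stratum label to the list of member subject ids.
    Labels: ``asd``/``control``; ``<group>_boys``/``<group>_girls``;
    ``<group>_<ageband>``; and for ASD subjects with a CARS score,
    ``cars_mild_moderate``/``cars_severe`` (``cars_unclassified`` collects
    ASD subjects without a usable score).
    """

    cohort: Cohort
    config: StrataConfig
    strata: dict[str, list[str]]

    @property
    def labels(self) -> list[str]:
        return list(self.strata)

    def n(self, label: str) -> int:
        return len(self.strata.get(label, []))

    def mask(self, label: str) -> pd.Series:
        ids = set(self.strata.get(label, []))
        return self.cohort.frame["subject_id"].astype(str).isin(ids)

    def values(self, label: str, toxin: Toxin) -> np.ndarray:
        """Normalized concentrations for one stratum, complete cases only."""
        series = self.cohort.normalized_values(toxin)[self.mask(label)]
        return series.dropna().to_numpy(dtype=float)


def assign_strata(cohort: Cohort, config: StrataConfig | None = None) -> StratifiedCohort:
    """Partition the cohort into analysis strata.

    Stratum membership is a pure function of (group, sex, age_years,
    cars_score); subject order never affects it. Age bands cover the
    study range, so band strata within a group partition that group.
    """
    config = config or StrataConfig()
    frame = cohort.frame
    strata: dict[str, list[str]] = {}

    def put(label: str, sid: str) -> None:
        strata.setdefault(label, []).append(sid)

    # keep deterministic label order even for empty strata
    for g in ("control", "asd"):
        strata[g] = []
        for s in ("boys", "girls"):
            strata[f"{g}_{s}"] = []
        for _, _, band in config.age_bands:
            strata[f"{g}_{band}"] = []
    for label in (CARS_MILD, CARS_SEVERE, CARS_UNCLASSIFIED):
        strata[label] = []

    for _, row in frame.iterrows():
        sid = str(row["subject_id"])
        g = "asd" if str(row["group"]).upper() == Group.ASD.value else "control"
        sex = "boys" if str(row["sex"]).upper() == Sex.BOY.value else "girls"
        put(g, sid)
        put(f"{g}_{sex}", sid)
        band = config.age_band(float(row["age_years"]))
        if band is not None:
            put(f"{g}_{band}", sid)
        if g == "asd":
            cars = row["cars_score"]
            cls = config.cars_class(None if pd.isna(cars) else float(cars))
            if cls == "mild_moderate":
                put(CARS_MILD, sid)
            elif cls == "severe":
                put(CARS_SEVERE, sid)
            else:
                put(CARS_UNCLASSIFIED, sid)

    return StratifiedCohort(cohort=cohort, config=config, strata=strata)
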