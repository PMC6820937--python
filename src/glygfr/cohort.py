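"""Cohort container: longitudinal GFR examinations, one row per clinic visit.

A :class:`Cohort` wraps a :class:`pandas.DataFrame` with a fixed column
schema.  Each row is one GFR study: demographics, anthropometrics, glycemic
labs, serum creatinine and (when available) the measured iothalamate GFR,
either raw (``mgfr_ml_min``) or indexed to 1.73 m2 body surface area
(``agfr_ml_min_1p73``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

from .errors import InputError, ValidationError

#: Canonical column order of the cohort table (also the CSV schema).
COLUMNS = [
    "subject_id",
    "exam_index",
    "age_years",
    "sex",
    "height_m",
    "weight_kg",
    "scr_mg_dl",
    "fpg_mg_dl",
    "hba1c_pct",
    "duration_years",
    "mgfr_ml_min",
    "agfr_ml_min_1p73",
]

#: Columns that may legitimately be missing (empty cell in the CSV).
OPTIONAL_COLUMNS = frozenset({"duration_years", "mgfr_ml_min", "agfr_ml_min_1p73"})

_NUMERIC = [c for c in COLUMNS if c not in ("subject_id", "sex")]


def normalize_sex(value) -> str:
    """Normalize a sex code to ``"M"`` or ``"F"`` (case-insensitive)."""
    s = str(value).strip().upper()
    if s in ("M", "MALE"):
        return "M"
    if s in ("F", "FEMALE"):
        return "F"
    raise InputError(f"unknown sex code {value!r}; expected M/F")


@dataclass
class Examination:
    """A single GFR study for one subject.

    Units: age in years, height in metres, weight in kg, serum creatinine
    (scr) and fasting plasma glucose (fpg) in mg/dL, HbA1c in percent,
    GFR values in mL/min (mgfr) or mL/min/1.73m2 (agfr).
    """

    subject_id: str
    exam_index: int
    age: float
    sex: str
    height: float
    weight: float
    scr: float
    fpg: float
    hba1c: float
    duration: Optional[float] = None
    mgfr: Optional[float] = None
    agfr: Optional[float] = None

    def __post_init__(self) -> None:
        self.sex = normalize_sex(self.sex)
        self.validate()

    def validate(self) -> None:
        problems = validate_exam_values(
            age=self.age, scr=self.scr, height=self.height, weight=self.weight,
            fpg=self.fpg, hba1c=self.hba1c, agfr=self.agfr,
        )
        if problems:
            raise ValidationError(
                f"examination ({self.subject_id}, #{self.exam_index}): "
                + "; ".join(problems)
            )


def validate_exam_values(*, age, scr, height, weight, fpg, hba1c, agfr=None) -> list[str]:
    """Return a list of invariant violations (empty when the values are valid)."""
    problems = []
    if not age > 0:
        problems.append(f"age must be > 0 (got {age})")
    if not scr > 0:
        problems.append(f"scr must be > 0 (got {scr})")
    if not height > 0:
        problems.append(f"height must be > 0 (got {height})")
    if not weight > 0:
        problems.append(f"weight must be > 0 (got {weight})")
    if not fpg > 0:
        problems.append(f"fpg must be > 0 (got {fpg})")
    if not 0 < hba1c < 25:
        problems.append(f"hba1c must lie in (0, 25) (got {hba1c})")
    if agfr is not None and not (isinstance(agfr, float) and np.isnan(agfr)):
        if not agfr > 0:
            problems.append(f"agfr must be > 0 when present (got {agfr})")
    return problems


@dataclass
class Cohort:
    """Ordered examinations grouped by subject.

    The wrapped frame always carries :data:`COLUMNS`, is sorted by
    ``(subject_id, exam_index)`` and uses a ``RangeIndex``.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"cohort table is missing columns: {missing}")
        df = df[COLUMNS].copy()
        df["sex"] = df["sex"].map(normalize_sex)
        for c in _NUMERIC:
            df[c] = pd.to_numeric(df[c], errors="raise")
        df = df.sort_values(["subject_id", "exam_index"], kind="stable")
        df = df.reset_index(drop=True)
        self.frame = df

    # -- basic introspection -------------------------------------------------
    @property
    def n_exams(self) -> int:
        return len(self.frame)

    @property
    def n_subjects(self) -> int:
        return self.frame["subject_id"].nunique()

    @property
    def subject_ids(self) -> np.ndarray:
        return self.frame["subject_id"].unique()

    def __len__(self) -> int:
        return self.n_exams

    def groupby_subject(self):
        return self.frame.groupby("subject_id", sort=False)

    def examinations(self) -> Iterator[Examination]:
        """Iterate over the rows as typed :class:`Examination` records."""
        for row in self.frame.itertuples(index=False):
            yield Examination(
                subject_id=row.subject_id,
                exam_index=int(row.exam_index),
                age=row.age_years,
                sex=row.sex,
                height=row.height_m,
                weight=row.weight_kg,
                scr=row.scr_mg_dl,
                fpg=row.fpg_mg_dl,
                hba1c=row.hba1c_pct,
                duration=_opt(row.duration_years),
                mgfr=_opt(row.mgfr_ml_min),
                agfr=_opt(row.agfr_ml_min_1p73),
            )

    # -- construction helpers ------------------------------------------------
    @classmethod
    def from_examinations(cls, exams: Iterable[Examination]) -> "Cohort":
        rows = [
            {
                "subject_id": e.subject_id,
                "exam_index": e.exam_index,
                "age_years": e.age,
                "sex": e.sex,
                "height_m": e.height,
                "weight_kg": e.weight,
                "scr_mg_dl": e.scr,
                "fpg_mg_dl": e.fpg,
                "hba1c_pct": e.hba1c,
                "duration_years": e.duration,
                "mgfr_ml_min": e.mgfr,
                "agfr_ml_min_1p73": e.agfr,
            }
            for e in exams
        ]
        if not rows:
            raise ValidationError("cannot build a cohort from zero examinations")
        return cls(pd.DataFrame(rows))

    def with_frame(self, frame: pd.DataFrame) -> "Cohort":
        return Cohort(frame)

    def resequence(self) -> "Cohort":
        """Re-number ``exam_index`` 1..n within each subject, preserving order."""
        df = self.frame.copy()
        df["exam_index"] = df.groupby("subject_id", sort=False).cumcount() + 1
        return Cohort(df)


def _opt(x) -> Optional[float]:
    return None if x is None or (isinstance(x, float) and np.isnan(x)) else float(x)
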