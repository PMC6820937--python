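"""Cohort CSV reading and writing with row-level validation.

The on-disk schema is one header row with the columns of
:data:`glygfr.cohort.COLUMNS` (comma-separated, UTF-8, "." decimal); an
empty cell means missing, which is only legal for diabetes duration and
the measured/adjusted GFR columns.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .cohort import COLUMNS, OPTIONAL_COLUMNS, Cohort, normalize_sex, validate_exam_values
from .errors import InputError, ValidationError

__all__ = ["read_cohort", "write_cohort", "file_sha256"]

log = logging.getLogger("glygfr")


def read_cohort(path: Union[str, Path], strict: bool = False) -> Cohort:
    """Load and validate a cohort CSV.

    Rows violating examination invariants are reported with their line
    numbers and skipped (warning), or the load fails when ``strict=True``.
    Exams are sorted by (subject_id, exam_index).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such cohort file: {path}")
    try:
        df = pd.read_csv(path, dtype={"subject_id": str})
    except pd.errors.EmptyDataError as e:
        raise ValidationError(f"{path}: empty file") from e
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: header is missing columns {missing}")
    if df.empty:
        raise ValidationError(f"{path}: no data rows")

    bad: list[str] = []
    keep = np.ones(len(df), dtype=bool)
    for i, row in enumerate(df.itertuples(index=False)):
        lineno = i + 2  # 1-based, after the header
        problems = []
        try:
            normalize_sex(row.sex)
        except InputError as e:
            problems.append(str(e))
        problems += validate_exam_values(
            age=row.age_years, scr=row.scr_mg_dl, height=row.height_m,
            weight=row.weight_kg, fpg=row.fpg_mg_dl, hba1c=row.hba1c_pct,
            agfr=row.agfr_ml_min_1p73,
        )
        for col in COLUMNS:
            if col in OPTIONAL_COLUMNS or col in ("subject_id", "sex"):
                continue
            v = getattr(row, col)
            if pd.isna(v):
                problems.append(f"required column {col} is empty")
        if problems:
            bad.append(f"line {lineno}: " + "; ".join(problems))
            keep[i] = False
    if bad:
        msg = f"{path}: {len(bad)} invalid row(s):\n  " + "\n  ".join(bad[:20])
        if strict:
            raise ValidationError(msg)
        log.warning("%s (rows skipped)", msg)
        df = df.loc[keep]
    if df.empty:
        raise ValidationError(f"{path}: every row was invalid")
    return Cohort(df)


def write_cohort(cohort: Cohort, path: Union[str, Path]) -> None:
    """Write a cohort to CSV in the canonical schema (full float precision)."""
    cohort.frame.to_csv(path, index=False)


def file_sha256(path: Union[str, Path]) -> str:
    """Hex SHA-256 of a file, for run-provenance logging."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
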