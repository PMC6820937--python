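"""Closed-form renal equations and the stratified approximating-equation type.

Implements the Du Bois body-surface-area power law, the CKD-EPI (2009,
creatinine, non-black constants) and MDRD eGFR equations, eligibility
filtering at eGFR >= 60 mL/min/1.73m2, hyperfiltration classification, and
the stratified log-linear ``EquationSpec`` used both for the shipped
glycemia-aware equations and for freshly derived ones.

All creatinine and glucose concentrations are in mg/dL, heights in metres,
weights in kg and GFRs in mL/min (raw) or mL/min/1.73m2 (BSA-indexed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, Examination, normalize_sex
from .errors import DomainError, InputError, ValidationError

__all__ = [
    "dubois_bsa",
    "adjust_gfr",
    "ckd_epi",
    "mdrd",
    "Stratum",
    "EquationSpec",
    "stratum_for",
    "predict_equation",
    "predict_cohort",
    "HyperfiltrationRule",
    "classify_hyperfiltration",
    "filter_eligible",
    "ckd_epi_cohort",
    "mdrd_cohort",
    "bsa_cohort",
]


# ---------------------------------------------------------------------------
# scalar closed forms
# ---------------------------------------------------------------------------

def dubois_bsa(height_m: float, weight_kg: float) -> float:
    """Du Bois body surface area (m2) from height (m) and weight (kg).

    BSA = 0.007184 * height_cm**0.725 * weight_kg**0.425, evaluated with
    height converted to centimetres.
    """
    height_m = np.asarray(height_m, dtype=float)
    weight_kg = np.asarray(weight_kg, dtype=float)
    if np.any(height_m <= 0) or np.any(weight_kg <= 0):
        raise DomainError("dubois_bsa requires height > 0 and weight > 0")
    out = 0.007184 * (height_m * 100.0) ** 0.725 * weight_kg ** 0.425
    return float(out) if out.ndim == 0 else out


def adjust_gfr(mgfr_ml_min: float, bsa_m2: float) -> float:
    """Index a measured GFR to 1.73 m2 of body surface area."""
    mgfr_ml_min = np.asarray(mgfr_ml_min, dtype=float)
    bsa_m2 = np.asarray(bsa_m2, dtype=float)
    if np.any(bsa_m2 <= 0):
        raise DomainError("adjust_gfr requires bsa > 0")
    if np.any(mgfr_ml_min < 0):
        raise DomainError("adjust_gfr requires mgfr >= 0")
    # multiply by the ratio so the reference BSA is an exact identity
    out = mgfr_ml_min * (1.73 / bsa_m2)
    return float(out) if out.ndim == 0 else out


# CKD-EPI 2009 creatinine equation, non-black constants, as four branches
# keyed by sex and the sex-specific creatinine knot (0.7 F, 0.9 M).
_CKD_EPI = {
    "F": (144.0, 0.7, -0.329, -1.209),
    "M": (141.0, 0.9, -0.411, -1.209),
}


def ckd_epi(sex: str, age_years: float, scr_mg_dl: float) -> float:
    """CKD-EPI creatinine eGFR (mL/min/1.73m2), non-black constants.

    eGFR = k * (SCR/kappa)**alpha * 0.993**age, with alpha depending on
    whether SCR is below or above the sex-specific knot kappa.
    """
    sex = normalize_sex(sex)
    age = np.asarray(age_years, dtype=float)
    scr = np.asarray(scr_mg_dl, dtype=float)
    if np.any(scr <= 0):
        raise DomainError("ckd_epi requires scr > 0")
    if np.any(age < 0):
        raise DomainError("ckd_epi requires age >= 0")
    k, kappa, a_low, a_high = _CKD_EPI[sex]
    alpha = np.where(scr <= kappa, a_low, a_high)
    out = k * (scr / kappa) ** alpha * 0.993 ** age
    return float(out) if out.ndim == 0 else out


def mdrd(sex: str, age_years: float, scr_mg_dl: float) -> float:
    """MDRD study equation eGFR (mL/min/1.73m2).

    eGFR = 175 * SCR**-1.154 * age**-0.203, times 0.742 for women.
    """
    sex = normalize_sex(sex)
    age = np.asarray(age_years, dtype=float)
    scr = np.asarray(scr_mg_dl, dtype=float)
    if np.any(scr <= 0):
        raise DomainError("mdrd requires scr > 0")
    if np.any(age <= 0):
        raise DomainError("mdrd requires age > 0")
    out = 175.0 * scr ** -1.154 * age ** -0.203
    if sex == "F":
        out = out * 0.742
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# stratified approximating equations
# ---------------------------------------------------------------------------

#: Covariates an EquationSpec may use, in canonical order.
SPEC_VARIABLES = ("age", "hba1c", "fpg", "scr")


@dataclass(frozen=True)
class Stratum:
    """One sex x creatinine-interval stratum of a stratified equation.

    The creatinine interval is half-open, ``[scr_lo, scr_hi)``; the bottom
    stratum of each sex uses ``scr_lo = 0`` and the top ``scr_hi = inf``.
    """

    sex: str
    scr_lo: float
    scr_hi: float
    intercept: float
    coefficients: Mapping[str, float]

    def contains(self, sex: str, scr: float) -> bool:
        return self.sex == sex and self.scr_lo <= scr < self.scr_hi

    def label(self) -> str:
        sex_word = "women" if self.sex == "F" else "men"
        return f"{sex_word} [{self.scr_lo:g}, {self.scr_hi:g}) mg/dL"


@dataclass(frozen=True)
class EquationSpec:
    """A stratified log-linear GFR approximating equation.

    Prediction for an examination falling in stratum *s*:

        aGFR-hat = exp( intercept_s + sum_v beta_{s,v} * x_v / scale_v )

    where ``scaling`` holds the per-variable divisors (e.g. age in decades
    is ``scaling["age"] = 10``).  Strata partition (sex x positive SCR) with
    no gap or overlap; this is validated at construction.
    """

    name: str
    strata: Sequence[Stratum]
    scaling: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "strata", tuple(self.strata))
        object.__setattr__(self, "scaling", dict(self.scaling))
        self.validate()

    def validate(self) -> None:
        if not self.strata:
            raise ValidationError(f"spec {self.name!r} has no strata")
        for s in self.strata:
            if s.sex not in ("M", "F"):
                raise ValidationError(f"stratum sex must be M/F, got {s.sex!r}")
            if not (0 <= s.scr_lo < s.scr_hi):
                raise ValidationError(
                    f"stratum interval [{s.scr_lo}, {s.scr_hi}) is empty or negative"
                )
            for v in s.coefficients:
                if v not in SPEC_VARIABLES:
                    raise ValidationError(f"unknown equation variable {v!r}")
                if v not in self.scaling:
                    raise ValidationError(f"variable {v!r} has no scaling entry")
        for v, d in self.scaling.items():
            if not d > 0:
                raise ValidationError(f"scaling divisor for {v!r} must be > 0")
        # per-sex intervals must tile (0, inf) exactly
        for sex in ("M", "F"):
            intervals = sorted(
                (s.scr_lo, s.scr_hi) for s in self.strata if s.sex == sex
            )
            if not intervals:
                raise ValidationError(f"spec {self.name!r} covers no {sex} strata")
            if intervals[0][0] != 0:
                raise ValidationError(
                    f"{sex} strata leave a gap below {intervals[0][0]:g}"
                )
            for (lo1, hi1), (lo2, _) in zip(intervals, intervals[1:]):
                if hi1 < lo2:
                    raise ValidationError(f"{sex} strata have a gap at {hi1:g}")
                if hi1 > lo2:
                    raise ValidationError(f"{sex} strata overlap at {lo2:g}")
            if intervals[-1][1] != math.inf:
                raise ValidationError(
                    f"{sex} strata end at {intervals[-1][1]:g}, not +inf"
                )

    def strata_for_sex(self, sex: str) -> list[Stratum]:
        return [s for s in self.strata if s.sex == normalize_sex(sex)]


def stratum_for(spec: EquationSpec, sex: str, scr: float) -> Stratum:
    """Return the unique stratum whose sex matches and interval contains scr."""
    sex = normalize_sex(sex)
    if not scr > 0:
        raise DomainError("stratum_for requires scr > 0")
    for s in spec.strata:
        if s.contains(sex, scr):
            return s
    raise ValidationError(  # unreachable for a validated spec
        f"no stratum of {spec.name!r} contains (sex={sex}, scr={scr})"
    )


def predict_equation(spec: EquationSpec, exam: Examination) -> float:
    """Approximated GFR (mL/min/1.73m2) for one examination under a spec."""
    values = {"age": exam.age, "hba1c": exam.hba1c, "fpg": exam.fpg, "scr": exam.scr}
    s = stratum_for(spec, exam.sex, exam.scr)
    x = s.intercept
    for v, beta in s.coefficients.items():
        value = values.get(v)
        if value is None:
            raise InputError(f"examination lacks covariate {v!r} required by {spec.name!r}")
        x += beta * value / spec.scaling.get(v, 1.0)
    return math.exp(x)


def predict_cohort(spec: EquationSpec, cohort: Cohort) -> pd.Series:
    """Vectorized :func:`predict_equation` over a cohort; aligned to its frame."""
    df = cohort.frame
    x = np.full(len(df), np.nan)
    sex = df["sex"].to_numpy()
    scr = df["scr_mg_dl"].to_numpy(float)
    if np.any(scr <= 0):
        raise DomainError("predict_cohort requires scr > 0 in every exam")
    values = {
        "age": df["age_years"].to_numpy(float),
        "hba1c": df["hba1c_pct"].to_numpy(float),
        "fpg": df["fpg_mg_dl"].to_numpy(float),
        "scr": scr,
    }
    for s in spec.strata:
        mask = (sex == s.sex) & (scr >= s.scr_lo) & (scr < s.scr_hi)
        if not mask.any():
            continue
        lin = np.full(mask.sum(), s.intercept)
        for v, beta in s.coefficients.items():
            lin += beta * values[v][mask] / spec.scaling.get(v, 1.0)
        x[mask] = lin
    return pd.Series(np.exp(x), index=df.index, name=spec.name)


# ---------------------------------------------------------------------------
# hyperfiltration and eligibility
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HyperfiltrationRule:
    """Threshold rule for hyperfiltration on the measured-aGFR scale.

    Default: aGFR strictly above 120 mL/min/1.73m2.  ``comparison`` may be
    ``"gt"`` (strict) or ``"ge"`` (inclusive).
    """

    threshold: float = 120.0
    comparison: str = "gt"

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise ValidationError("hyperfiltration threshold must be > 0")
        if self.comparison not in ("gt", "ge"):
            raise ValidationError("comparison must be 'gt' or 'ge'")

    def apply(self, agfr) -> np.ndarray:
        agfr = np.asarray(agfr, dtype=float)
        if self.comparison == "gt":
            return agfr > self.threshold
        return agfr >= self.threshold


def classify_hyperfiltration(agfr: float, rule: HyperfiltrationRule = HyperfiltrationRule()) -> bool:
    """True when the measured aGFR qualifies as hyperfiltration under the rule."""
    if np.any(np.asarray(agfr, dtype=float) < 0):
        raise DomainError("classify_hyperfiltration requires agfr >= 0")
    out = rule.apply(agfr)
    return bool(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# cohort-level conveniences
# ---------------------------------------------------------------------------

def _per_sex(cohort: Cohort, fn) -> pd.Series:
    df = cohort.frame
    out = np.empty(len(df))
    for sex in ("M", "F"):
        mask = (df["sex"] == sex).to_numpy()
        if mask.any():
            out[mask] = fn(sex, df.loc[mask])
    return pd.Series(out, index=df.index)


def ckd_epi_cohort(cohort: Cohort) -> pd.Series:
    """CKD-EPI eGFR for every exam of a cohort."""
    return _per_sex(
        cohort,
        lambda sex, d: ckd_epi(sex, d["age_years"].to_numpy(), d["scr_mg_dl"].to_numpy()),
    ).rename("ckd_epi")


def mdrd_cohort(cohort: Cohort) -> pd.Series:
    """MDRD eGFR for every exam of a cohort."""
    return _per_sex(
        cohort,
        lambda sex, d: mdrd(sex, d["age_years"].to_numpy(), d["scr_mg_dl"].to_numpy()),
    ).rename("mdrd")


def bsa_cohort(cohort: Cohort) -> pd.Series:
    """Du Bois BSA for every exam of a cohort."""
    df = cohort.frame
    return pd.Series(
        dubois_bsa(df["height_m"].to_numpy(), df["weight_kg"].to_numpy()),
        index=df.index,
        name="bsa",
    )


def filter_eligible(cohort: Cohort, mode: str = "ckd_epi_egfr", threshold: float = 60.0) -> Cohort:
    """Drop exams whose eligibility criterion falls below the threshold.

    ``mode="ckd_epi_egfr"`` (default) retains exams with CKD-EPI eGFR >= 60
    mL/min/1.73m2; ``mode="agfr"`` filters on the measured aGFR instead.
    Subject grouping and exam order are preserved and ``exam_index`` is
    re-sequenced within each subject.
    """
    df = cohort.frame
    if mode == "ckd_epi_egfr":
        crit = ckd_epi_cohort(cohort)
    elif mode == "agfr":
        crit = df["agfr_ml_min_1p73"]
        if crit.isna().any():
            bad = df.loc[crit.isna(), ["subject_id", "exam_index"]].iloc[0]
            raise InputError(
                "filter_eligible(mode='agfr') needs agfr on every exam; missing at "
                f"subject {bad['subject_id']} exam {int(bad['exam_index'])}"
            )
    else:
        raise InputError(f"unknown eligibility mode {mode!r}")
    kept = df.loc[crit.to_numpy() >= threshold]
    if kept.empty:
        raise ValidationError("eligibility filter removed every examination")
    return Cohort(kept).resequence()
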