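"""Derivation of GFR approximating equations from a longitudinal cohort.

The pipeline mirrors the classical prediction-equation workflow for
clustered GFR data:

1. linear models with an AR(1) within-subject residual correlation, fit by
   maximum likelihood (so AIC is comparable across fixed-effect sets);
2. exhaustive all-subsets AIC selection over candidate covariates;
3. stratification into sex x creatinine-quartile groups, each with its own
   log-linear equation (this absorbs nonlinearity in creatinine);
4. subject-level 10-fold cross-validation: equations are fit on 90% of the
   subjects, predictions made for the held-out 10%, and the final equation
   is the stratum-wise average of the ten training fits.

The AR(1) likelihood is evaluated directly per subject via the
Prais-Winsten whitening transform (closed-form banded inverse), and the
autocorrelation is profiled out with a golden-section search on
(-0.99, 0.99).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort
from .equations import (
    EquationSpec,
    Stratum,
    bsa_cohort,
    ckd_epi_cohort,
    predict_cohort,
)
from .errors import FitError, InputError, ValidationError

__all__ = [
    "LmmFit",
    "FoldAssignment",
    "CvResult",
    "fit_lmm_ar1",
    "select_model_aic",
    "scr_quartile_cutpoints",
    "fit_stratified_equations",
    "assign_folds",
    "cross_validate",
    "difference_model",
    "DEFAULT_SCALING",
]

#: Covariates accepted by :func:`fit_lmm_ar1`.  ``sex`` is coded female = 1
#: and ``fpg10`` is fasting glucose per 10 mg/dL, so coefficients are
#: directly comparable with the generative models.
MODEL_VARIABLES = ("age", "sex", "scr", "bsa", "duration", "fpg10", "hba1c")

OUTCOMES = ("log_agfr", "inv_scr", "diff_agfr_egfr")

#: Default per-variable divisors for derived equations: age in decades and
#: glucose per 100 mg/dL keep coefficients O(0.1), the scale on which
#: stratified GFR equations are conventionally printed.
DEFAULT_SCALING: Mapping[str, float] = {"age": 10.0, "hba1c": 1.0, "fpg": 100.0, "scr": 1.0}


# ---------------------------------------------------------------------------
# AR(1) maximum-likelihood regression
# ---------------------------------------------------------------------------

@dataclass
class LmmFit:
    """A fitted linear model with AR(1) within-subject residual correlation."""

    outcome: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    sigma: float          # marginal residual sd
    rho: float            # lag-1 residual autocorrelation
    loglik: float
    aic: float
    n_obs: int
    n_subjects: int
    n_params: int         # parameters counted by the AIC
    marginal_r2: float    # 1 - RSS(fixed effects)/TSS on the raw scale

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"beta": self.params, "se": self.bse, "p": self.pvalues}
        )


def _design(cohort: Cohort, outcome: str, covariates: Sequence[str]):
    df = cohort.frame
    if outcome not in OUTCOMES:
        raise InputError(f"unknown outcome {outcome!r}; expected one of {OUTCOMES}")
    for v in covariates:
        if v not in MODEL_VARIABLES:
            raise InputError(f"unknown covariate {v!r}; expected from {MODEL_VARIABLES}")

    if outcome == "log_agfr":
        agfr = df["agfr_ml_min_1p73"]
        if agfr.isna().any():
            raise InputError("outcome log_agfr requires agfr on every exam")
        y = np.log(agfr.to_numpy(float))
    elif outcome == "inv_scr":
        y = 1.0 / df["scr_mg_dl"].to_numpy(float)
    else:  # diff_agfr_egfr
        agfr = df["agfr_ml_min_1p73"]
        if agfr.isna().any():
            raise InputError("outcome diff_agfr_egfr requires agfr on every exam")
        y = agfr.to_numpy(float) - ckd_epi_cohort(cohort).to_numpy()

    cols = {"intercept": np.ones(len(df))}
    for v in covariates:
        if v == "age":
            cols[v] = df["age_years"].to_numpy(float)
        elif v == "sex":
            cols[v] = (df["sex"] == "F").to_numpy(float)
        elif v == "scr":
            cols[v] = df["scr_mg_dl"].to_numpy(float)
        elif v == "bsa":
            cols[v] = bsa_cohort(cohort).to_numpy()
        elif v == "duration":
            dur = df["duration_years"]
            if dur.isna().any():
                raise InputError("covariate 'duration' is missing on some exams")
            cols[v] = dur.to_numpy(float)
        elif v == "fpg10":
            cols[v] = df["fpg_mg_dl"].to_numpy(float) / 10.0
        elif v == "hba1c":
            cols[v] = df["hba1c_pct"].to_numpy(float)
    X = np.column_stack(list(cols.values()))
    groups = df["subject_id"].to_numpy()
    return y, X, list(cols.keys()), groups


def _whiten(y, X, groups, rho):
    """Prais-Winsten transform of (y, X) within each subject block."""
    yw = y.copy()
    Xw = X.copy()
    # groups are contiguous because cohorts are sorted by (subject, exam)
    starts = np.flatnonzero(np.r_[True, groups[1:] != groups[:-1]])
    c = math.sqrt(1.0 - rho * rho)
    inner = np.ones(len(y), dtype=bool)
    inner[starts] = False
    yw[inner] = y[inner] - rho * y[np.flatnonzero(inner) - 1]
    Xw[inner] = X[inner] - rho * X[np.flatnonzero(inner) - 1]
    yw[starts] *= c
    Xw[starts] *= c
    return yw, Xw, int(len(starts))


def _profile_loglik(y, X, groups, rho):
    """Profile log-likelihood at rho (beta and sigma maximised out)."""
    n = len(y)
    yw, Xw, n_subj = _whiten(y, X, groups, rho)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    rss = float(np.sum((yw - Xw @ beta) ** 2))
    if rss <= 0:
        rss = 1e-300
    sigma2 = rss / (n * (1.0 - rho * rho))
    ll = (
        -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)
        - 0.5 * (n - n_subj) * math.log(1.0 - rho * rho)
    )
    return ll, beta, sigma2


def _golden_section_max(f, lo, hi, tol=1e-4):
    """Golden-section maximisation of a unimodal scalar function."""
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return (a + b) / 2.0


def fit_lmm_ar1(cohort: Cohort, outcome: str, covariates: Sequence[str],
                rho: Optional[float] = None) -> LmmFit:
    """Maximum-likelihood linear regression with AR(1) residuals per subject.

    ``rho=None`` (default) profiles the autocorrelation out of the
    likelihood; passing a number fixes it (``rho=0`` with one exam per
    subject reproduces ordinary least squares).

    Raises :class:`FitError` on singular designs (naming the collinear
    columns) or when there are fewer observations than parameters.
    """
    y, X, names, groups = _design(cohort, outcome, covariates)
    n, p = X.shape
    if cohort.n_subjects < 2:
        raise FitError("fit_lmm_ar1 requires at least 2 subjects")
    if n < p + 1:
        raise FitError(f"{n} observations cannot identify {p} fixed effects")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # identify offending columns via the QR diagonal
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [names[i] for i in range(p) if diag[i] < 1e-8 * diag.max()]
        raise FitError(f"singular design; collinear columns: {bad or names}")

    estimated_rho = rho is None
    if estimated_rho:
        rho_hat = _golden_section_max(
            lambda r_: _profile_loglik(y, X, groups, r_)[0], -0.99, 0.99, tol=1e-4
        )
    else:
        if not -1.0 < rho < 1.0:
            raise InputError("fixed rho must lie in (-1, 1)")
        rho_hat = float(rho)

    ll, beta, sigma2 = _profile_loglik(y, X, groups, rho_hat)
    yw, Xw, _ = _whiten(y, X, groups, rho_hat)
    cov = sigma2 * (1.0 - rho_hat**2) * np.linalg.inv(Xw.T @ Xw)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))

    k = p + 1 + (1 if estimated_rho else 0)  # fixed effects + sigma (+ rho)
    resid = y - X @ beta
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / tss if tss > 0 else np.nan

    idx = pd.Index(names)
    return LmmFit(
        outcome=outcome,
        params=pd.Series(beta, index=idx),
        bse=pd.Series(se, index=idx),
        pvalues=pd.Series(pvals, index=idx),
        sigma=math.sqrt(sigma2),
        rho=rho_hat,
        loglik=ll,
        aic=-2.0 * ll + 2.0 * k,
        n_obs=n,
        n_subjects=cohort.n_subjects,
        n_params=k,
        marginal_r2=r2,
    )


# ---------------------------------------------------------------------------
# exhaustive AIC model selection
# ---------------------------------------------------------------------------

def select_model_aic(cohort: Cohort, outcome: str,
                     candidate_vars: Sequence[str]) -> tuple[LmmFit, pd.DataFrame]:
    """Fit every non-empty covariate subset and return the minimum-AIC fit.

    Returns ``(best_fit, table)`` where the table ranks all 2^k - 1 subsets
    by AIC (failed fits are recorded with their error, not raised, unless
    every subset fails).  Ties break toward fewer variables, then
    lexicographically.
    """
    candidate_vars = list(candidate_vars)
    if not candidate_vars:
        raise InputError("candidate_vars must be non-empty")
    if len(candidate_vars) > 10:
        raise InputError("exhaustive enumeration is limited to 10 candidates")
    rows = []
    fits = {}
    for r in range(1, len(candidate_vars) + 1):
        for subset in itertools.combinations(candidate_vars, r):
            try:
                fit = fit_lmm_ar1(cohort, outcome, subset)
                rows.append(
                    {"variables": subset, "n_vars": r, "aic": fit.aic,
                     "loglik": fit.loglik, "error": None}
                )
                fits[subset] = fit
            except (FitError, InputError) as e:
                rows.append(
                    {"variables": subset, "n_vars": r, "aic": np.nan,
                     "loglik": np.nan, "error": str(e)}
                )
    table = pd.DataFrame(rows)
    ok = table.dropna(subset=["aic"])
    if ok.empty:
        raise FitError("every candidate subset failed to fit")
    ok = ok.sort_values(
        ["aic", "n_vars", "variables"], kind="stable"
    )
    best = fits[ok.iloc[0]["variables"]]
    table = table.sort_values(["aic", "n_vars", "variables"], kind="stable",
                              na_position="last").reset_index(drop=True)
    return best, table


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------

def scr_quartile_cutpoints(cohort: Cohort) -> dict[str, np.ndarray]:
    """Per-sex creatinine quartile cut points (three values each).

    Quartiles are computed at the exam level with linear interpolation
    between order statistics (quantile "type 7").  Requires at least four
    exams of each sex.
    """
    df = cohort.frame
    out = {}
    for sex in ("M", "F"):
        scr = df.loc[df["sex"] == sex, "scr_mg_dl"].to_numpy(float)
        if len(scr) == 0:
            raise InputError(f"cohort contains no exams of sex {sex!r}")
        if len(scr) < 4:
            raise InputError(f"need >= 4 exams of sex {sex!r} for quartiles")
        cuts = np.quantile(scr, [0.25, 0.5, 0.75], method="linear")
        if len(np.unique(cuts)) < 3:
            warnings.warn(
                f"degenerate creatinine quartiles for sex {sex!r}; "
                "stratification will collapse strata",
                stacklevel=2,
            )
        out[sex] = cuts
    return out


def _sex_edges(cuts: np.ndarray) -> np.ndarray:
    edges = np.concatenate([[0.0], np.unique(cuts), [np.inf]])
    return edges


def fit_stratified_equations(cohort: Cohort,
                             cutpoints: Mapping[str, np.ndarray],
                             scaling: Mapping[str, float] = DEFAULT_SCALING,
                             name: str = "derived") -> EquationSpec:
    """Fit one log-linear equation per sex x creatinine stratum.

    Within each stratum, log aGFR is regressed by ordinary least squares on
    age, HbA1c, FPG and SCR (scaled by ``scaling``); the result is a
    complete :class:`EquationSpec`.  A stratum with five or fewer exams
    raises :class:`FitError` naming the stratum.
    """
    df = cohort.frame
    agfr = df["agfr_ml_min_1p73"]
    if agfr.isna().any():
        raise InputError("fit_stratified_equations requires agfr on every exam")
    strata = []
    for sex in ("M", "F"):
        edges = _sex_edges(np.asarray(cutpoints[sex], dtype=float))
        sub = df.loc[df["sex"] == sex]
        for lo, hi in zip(edges[:-1], edges[1:]):
            rows = sub.loc[(sub["scr_mg_dl"] >= lo) & (sub["scr_mg_dl"] < hi)]
            label = f"{'women' if sex == 'F' else 'men'} [{lo:g}, {hi:g})"
            if len(rows) <= 5:
                raise FitError(
                    f"stratum {label} has only {len(rows)} exams; "
                    "too few to fit intercept + 4 coefficients"
                )
            X = np.column_stack(
                [
                    np.ones(len(rows)),
                    rows["age_years"].to_numpy(float) / scaling["age"],
                    rows["hba1c_pct"].to_numpy(float) / scaling["hba1c"],
                    rows["fpg_mg_dl"].to_numpy(float) / scaling["fpg"],
                    rows["scr_mg_dl"].to_numpy(float) / scaling["scr"],
                ]
            )
            yv = np.log(rows["agfr_ml_min_1p73"].to_numpy(float))
            beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
            strata.append(
                Stratum(
                    sex=sex, scr_lo=float(lo), scr_hi=float(hi),
                    intercept=float(beta[0]),
                    coefficients={
                        "age": float(beta[1]),
                        "hba1c": float(beta[2]),
                        "fpg": float(beta[3]),
                        "scr": float(beta[4]),
                    },
                )
            )
    return EquationSpec(name=name, strata=strata, scaling=dict(scaling))


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class FoldAssignment:
    """Subject-level fold labels, 1..k; sizes differ by at most one subject."""

    assignments: Mapping[str, int]
    k: int

    def fold_of(self, subject_id: str) -> int:
        return self.assignments[subject_id]

    def subjects_in(self, fold: int) -> list[str]:
        return [s for s, f in self.assignments.items() if f == fold]


def assign_folds(cohort: Cohort, k: int = 10, seed: int = 0) -> FoldAssignment:
    """Randomly partition subjects into k folds of near-equal size."""
    subjects = list(cohort.subject_ids)
    if k > len(subjects):
        raise InputError(f"cannot split {len(subjects)} subjects into {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    assignments = {}
    for pos, idx in enumerate(order):
        assignments[subjects[idx]] = pos % k + 1
    return FoldAssignment(assignments=assignments, k=k)


@dataclass
class CvResult:
    """Output of subject-level k-fold cross-validation."""

    assignment: FoldAssignment
    fold_specs: list          # EquationSpec fit on each training split
    fold_cutpoints: list      # per-fold {sex: cuts}
    predictions: pd.Series    # out-of-fold prediction for every exam
    final_spec: EquationSpec  # stratum-wise average of the fold fits


def cross_validate(cohort: Cohort, k: int = 10, seed: int = 0,
                   scaling: Mapping[str, float] = DEFAULT_SCALING) -> CvResult:
    """Derive stratified equations with subject-level k-fold cross-validation.

    For each fold: creatinine cut points and stratified equations are
    estimated on the training subjects only (no leakage), and predictions
    are made for the held-out subjects.  The final equation averages the
    ten training fits stratum by stratum (strata aligned by creatinine rank
    within sex; cut points averaged).
    """
    assignment = assign_folds(cohort, k=k, seed=seed)
    df = cohort.frame
    fold_labels = df["subject_id"].map(assignment.assignments)
    predictions = pd.Series(np.nan, index=df.index, name="cv_prediction")
    fold_specs, fold_cuts = [], []
    for fold in range(1, k + 1):
        train = Cohort(df.loc[fold_labels != fold])
        test_idx = df.index[fold_labels == fold]
        try:
            cuts = scr_quartile_cutpoints(train)
            spec = fit_stratified_equations(
                train, cuts, scaling=scaling, name=f"cv_fold_{fold}"
            )
        except FitError as e:
            raise FitError(
                f"fold {fold}: {e}; consider fewer strata or larger folds"
            ) from e
        fold_specs.append(spec)
        fold_cuts.append(cuts)
        test = Cohort(df.loc[test_idx])
        predictions.loc[test_idx] = predict_cohort(spec, test).to_numpy()
    final = _average_specs(fold_specs, fold_cuts, scaling)
    return CvResult(
        assignment=assignment,
        fold_specs=fold_specs,
        fold_cutpoints=fold_cuts,
        predictions=predictions,
        final_spec=final,
    )


def _average_specs(specs: Sequence[EquationSpec],
                   cuts: Sequence[Mapping[str, np.ndarray]],
                   scaling: Mapping[str, float]) -> EquationSpec:
    strata = []
    for sex in ("M", "F"):
        per_fold = [sorted(s.strata_for_sex(sex), key=lambda t: t.scr_lo) for s in specs]
        counts = {len(p) for p in per_fold}
        if len(counts) != 1:
            raise FitError(
                f"cannot average folds with differing stratum counts for sex {sex}: {counts}"
            )
        n_strata = counts.pop()
        mean_cuts = np.mean([np.asarray(c[sex], dtype=float) for c in cuts], axis=0)
        edges = _sex_edges(mean_cuts)
        if len(edges) - 1 != n_strata:
            raise FitError("averaged cut points collapse strata inconsistently")
        for j in range(n_strata):
            intercept = float(np.mean([p[j].intercept for p in per_fold]))
            coef_names = per_fold[0][j].coefficients.keys()
            coefs = {
                v: float(np.mean([p[j].coefficients[v] for p in per_fold]))
                for v in coef_names
            }
            strata.append(
                Stratum(sex=sex, scr_lo=float(edges[j]), scr_hi=float(edges[j + 1]),
                        intercept=intercept, coefficients=coefs)
            )
    return EquationSpec(name="cv_final", strata=strata, scaling=dict(scaling))


# ---------------------------------------------------------------------------
# accuracy-gap regression
# ---------------------------------------------------------------------------

def difference_model(cohort: Cohort,
                     covariates: Sequence[str] = ("sex", "age", "scr", "fpg10",
                                                  "hba1c", "duration")) -> LmmFit:
    """AR(1) regression of the accuracy gap (aGFR - CKD-EPI eGFR) on covariates."""
    return fit_lmm_ar1(cohort, "diff_agfr_egfr", covariates)
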