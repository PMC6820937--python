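"""Precision, accuracy and discrimination metrics for GFR estimators.

* :func:`evaluate_estimator` — Pearson r, r2, RMSE, mean bias and P30 (the
  share of estimates within 30% of the measured aGFR, band inclusive).
* :func:`compare_dependent_correlations` — Fisher-z test for two
  overlapping dependent correlations sharing the measured aGFR (the
  Steiger/Meng family); appropriate when two estimators are compared on
  the same exams.  n is taken as the number of exams; with repeated
  measurements per subject this overstates the effective sample size, a
  caveat that travels with the result.
* :func:`roc_curve` / :func:`delong_compare` — discrimination of
  hyperfiltration (labels always derive from measured aGFR); AUC is the
  Mann-Whitney statistic with half-credit for ties, and correlated AUCs
  are compared with the DeLong placement-value variance.
* :func:`threshold_at_specificity` — the operating threshold achieving a
  target specificity, with its sensitivity.
* :func:`bias_by_level` — mean (aGFR - estimate) within equal-count bins
  of aGFR, exposing level-dependent bias.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import stats

from .equations import HyperfiltrationRule
from .errors import DomainError, InputError, ValidationError

__all__ = [
    "EvalReport",
    "RocResult",
    "CorrelationComparison",
    "DeLongComparison",
    "evaluate_estimator",
    "compare_dependent_correlations",
    "dependent_correlation_z",
    "roc_curve",
    "delong_compare",
    "threshold_at_specificity",
    "bias_by_level",
]


def _aligned(*vectors) -> list[np.ndarray]:
    arrs = [np.asarray(v, dtype=float) for v in vectors]
    n = {len(a) for a in arrs}
    if len(n) != 1:
        raise InputError(f"vectors must be aligned; got lengths {sorted(n)}")
    for a in arrs:
        if np.isnan(a).any():
            raise InputError("input vectors must not contain NaN")
    return arrs


# ---------------------------------------------------------------------------
# precision / accuracy
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Agreement between an estimator and the measured aGFR."""

    n: int
    r: float
    r2: float
    rmse: float      # mL/min/1.73m2
    bias: float      # mean (aGFR - estimate)
    p30: float       # fraction of |estimate - aGFR| <= 0.30 * aGFR

    def as_dict(self) -> dict:
        return {"n": self.n, "r": self.r, "r2": self.r2,
                "rmse": self.rmse, "bias": self.bias, "p30": self.p30}


def evaluate_estimator(agfr, estimates) -> EvalReport:
    """Precision and accuracy of an estimate vector against measured aGFR."""
    agfr, est = _aligned(agfr, estimates)
    n = len(agfr)
    if n == 0:
        raise InputError("cannot evaluate an empty estimate set")
    if n < 3:
        raise InputError("need at least 3 pairs to estimate a correlation")
    if np.any(agfr <= 0):
        raise DomainError("measured aGFR must be positive")
    if np.ptp(agfr) == 0 or np.ptp(est) == 0:
        r = float("nan")  # correlation undefined for a constant vector
    else:
        r = float(stats.pearsonr(agfr, est).statistic)
    diff = agfr - est
    return EvalReport(
        n=n,
        r=r,
        r2=r * r,
        rmse=float(np.sqrt(np.mean(diff**2))),
        bias=float(np.mean(diff)),
        p30=float(np.mean(np.abs(est - agfr) <= 0.30 * agfr)),
    )


# ---------------------------------------------------------------------------
# dependent-correlation comparison
# ---------------------------------------------------------------------------

@dataclass
class CorrelationComparison:
    """Fisher-z comparison of two overlapping dependent correlations."""

    r1: float    # corr(aGFR, estimator 1)
    r2: float    # corr(aGFR, estimator 2)
    r12: float   # corr(estimator 1, estimator 2)
    n: int
    z: float
    p: float


def dependent_correlation_z(r1: float, r2: float, r12: float, n: int) -> float:
    """Meng-Rosenthal-Rubin z statistic for two overlapping correlations.

    ``r1`` and ``r2`` share one variable; ``r12`` is the correlation of the
    two non-shared variables.  Pure function of the three correlations and
    n, exposed so its shape (e.g. monotonicity in |r1 - r2|) can be probed
    directly.
    """
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    rbar2 = (r1 * r1 + r2 * r2) / 2.0
    f = min((1.0 - r12) / (2.0 * (1.0 - rbar2)), 1.0)
    h = (1.0 - f * rbar2) / (1.0 - rbar2)
    return float((z1 - z2) * np.sqrt((n - 3.0) / (2.0 * (1.0 - r12) * h)))


def compare_dependent_correlations(agfr, est1, est2) -> CorrelationComparison:
    """Test r(aGFR, est1) against r(aGFR, est2) on the same exams.

    Meng-Rosenthal-Rubin z-test for two overlapping correlations that share
    one variable, accounting for the correlation r12 between the two
    estimators.  Two-sided p.  Identical estimators (r12 = 1 with r1 = r2)
    return z = 0, p = 1; any other perfect correlation is degenerate.
    """
    agfr, e1, e2 = _aligned(agfr, est1, est2)
    n = len(agfr)
    if n < 10:
        raise InputError("need at least 10 triples to compare correlations")
    r1 = float(stats.pearsonr(agfr, e1).statistic)
    r2 = float(stats.pearsonr(agfr, e2).statistic)
    r12 = float(stats.pearsonr(e1, e2).statistic)
    if abs(r12) >= 1.0 - 1e-12 and abs(r1 - r2) < 1e-12:
        return CorrelationComparison(r1=r1, r2=r2, r12=r12, n=n, z=0.0, p=1.0)
    for name, r in (("r1", r1), ("r2", r2), ("r12", r12)):
        if abs(r) >= 1.0 - 1e-12:
            raise DomainError(f"degenerate input: |{name}| = 1")
    z = dependent_correlation_z(r1, r2, r12, n)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return CorrelationComparison(r1=r1, r2=r2, r12=r12, n=n, z=z, p=max(p, np.finfo(float).tiny))


# ---------------------------------------------------------------------------
# ROC analysis
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    """ROC sweep of an estimator against hyperfiltration labels.

    A case is called positive when the estimate is >= the threshold.
    Thresholds are midpoints between adjacent unique scores, bracketed by
    -inf and +inf, so every attainable operating point appears once.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    rule: HyperfiltrationRule
    n_pos: int
    n_neg: int


def roc_curve(agfr, estimates,
              rule: HyperfiltrationRule = HyperfiltrationRule()) -> RocResult:
    """ROC curve for detecting hyperfiltration (labelled from measured aGFR).

    The AUC is computed as the Mann-Whitney statistic — the probability
    that a randomly chosen hyperfiltering exam scores above a randomly
    chosen non-hyperfiltering one, with half-credit for ties.
    """
    agfr, est = _aligned(agfr, estimates)
    labels = rule.apply(agfr)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValidationError(
            f"both classes required: {n_pos} hyperfiltering / {n_neg} not"
        )

    uniq = np.unique(est)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])
    pos_scores = np.sort(est[labels])
    neg_scores = np.sort(est[~labels])
    # predicted positive: score >= threshold
    tp = n_pos - np.searchsorted(pos_scores, thresholds, side="left")
    fp = n_neg - np.searchsorted(neg_scores, thresholds, side="left")
    sens = tp / n_pos
    spec = 1.0 - fp / n_neg

    ranks = stats.rankdata(est)  # average ranks give ties half credit
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return RocResult(
        thresholds=thresholds, sensitivity=sens, specificity=spec,
        auc=float(auc), rule=rule, n_pos=n_pos, n_neg=n_neg,
    )


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values: V10 (per positive) and V01 (per negative)."""
    m, n = len(pos), len(neg)
    allv = np.concatenate([pos, neg])
    ranks = stats.rankdata(allv)
    pos_ranks = ranks[:m]
    neg_ranks = ranks[m:]
    v10 = (pos_ranks - stats.rankdata(pos)) / n
    v01 = 1.0 - (neg_ranks - stats.rankdata(neg)) / m
    return v10, v01


@dataclass
class DeLongComparison:
    """Paired DeLong test of two correlated AUCs."""

    auc1: float
    auc2: float
    var_diff: float
    z: float
    p: float


def delong_compare(agfr, est1, est2,
                   rule: HyperfiltrationRule = HyperfiltrationRule()) -> DeLongComparison:
    """Compare the hyperfiltration AUCs of two estimators on the same exams.

    Paired DeLong test: the variance of the AUC difference comes from the
    empirical covariance of the placement values across the shared cases.
    """
    agfr, e1, e2 = _aligned(agfr, est1, est2)
    labels = HyperfiltrationRule(rule.threshold, rule.comparison).apply(agfr)
    m = int(labels.sum())
    n = int(len(labels) - m)
    if m == 0 or n == 0:
        raise ValidationError(f"both classes required: {m} positive / {n} negative")
    v10 = np.empty((2, m))
    v01 = np.empty((2, n))
    aucs = np.empty(2)
    for i, est in enumerate((e1, e2)):
        p10, p01 = _placements(est[labels], est[~labels])
        v10[i], v01[i] = p10, p01
        aucs[i] = p10.mean()
    s10 = np.cov(v10) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(v01) if n > 1 else np.zeros((2, 2))
    var = (
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    )
    diff = aucs[0] - aucs[1]
    if var <= 0:
        z = 0.0
        p = 1.0
        if diff != 0:
            z = np.inf if diff > 0 else -np.inf
            p = 0.0
    else:
        z = float(diff / np.sqrt(var))
        p = float(2.0 * stats.norm.sf(abs(z)))
    return DeLongComparison(auc1=float(aucs[0]), auc2=float(aucs[1]),
                            var_diff=float(var), z=z, p=p)


def threshold_at_specificity(roc: RocResult, target_spec: float) -> tuple[float, float, float]:
    """Smallest threshold whose specificity meets the target.

    Returns ``(threshold, sensitivity, achieved_specificity)``; the
    achieved specificity is always >= the target.  Raises
    :class:`InputError` when no operating point reaches the target.
    """
    if not 0 < target_spec < 1:
        raise InputError("target specificity must lie in (0, 1)")
    ok = np.flatnonzero(roc.specificity >= target_spec)
    if ok.size == 0:
        raise InputError(f"no threshold achieves specificity >= {target_spec}")
    # specificity is non-decreasing in threshold, so the first qualifying
    # index is the smallest threshold (and the most sensitive choice)
    i = int(ok[0])
    return float(roc.thresholds[i]), float(roc.sensitivity[i]), float(roc.specificity[i])


# ---------------------------------------------------------------------------
# level-dependent bias
# ---------------------------------------------------------------------------

def bias_by_level(agfr, estimates, n_bins: int = 10) -> pd.DataFrame:
    """Mean (aGFR - estimate) within equal-count bins of measured aGFR.

    Returns one row per bin (bin edges, n, mean aGFR, mean difference) with
    the overall mean difference in ``DataFrame.attrs["overall_bias"]``.
    """
    agfr, est = _aligned(agfr, estimates)
    if n_bins < 2:
        raise InputError("n_bins must be >= 2")
    if len(agfr) < n_bins:
        raise InputError(f"{len(agfr)} points cannot fill {n_bins} bins")
    order = np.argsort(agfr, kind="stable")
    splits = np.array_split(order, n_bins)
    rows = []
    for i, idx in enumerate(splits):
        a, e = agfr[idx], est[idx]
        rows.append(
            {"bin": i + 1, "agfr_lo": float(a.min()), "agfr_hi": float(a.max()),
             "n": len(idx), "mean_agfr": float(a.mean()),
             "mean_diff": float((a - e).mean())}
        )
    out = pd.DataFrame(rows)
    out.attrs["overall_bias"] = float((agfr - est).mean())
    return out
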