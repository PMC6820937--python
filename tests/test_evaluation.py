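"""Evaluation metrics against independent oracles.

The AUC is checked against exhaustive concordant-pair counting, the DeLong
variance against a paired bootstrap, and the dependent-correlation test
against its Monte-Carlo type-I error.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glygfr.equations import HyperfiltrationRule
from glygfr.errors import DomainError, InputError, ValidationError
from glygfr.evaluation import (
    bias_by_level,
    compare_dependent_correlations,
    delong_compare,
    dependent_correlation_z,
    evaluate_estimator,
    roc_curve,
    threshold_at_specificity,
)


def auc_pair_oracle(labels: np.ndarray, scores: np.ndarray) -> float:
    """Exhaustive Mann-Whitney AUC: concordant pairs + half-credit ties."""
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestEvaluateEstimator:
    def test_perfect_estimates(self):
        agfr = np.array([90.0, 120.0, 150.0, 200.0])
        rep = evaluate_estimator(agfr, agfr)
        assert rep.r == pytest.approx(1.0)
        assert rep.rmse == 0.0
        assert rep.bias == 0.0
        assert rep.p30 == 1.0

    def test_p30_band_boundary_inclusive(self):
        agfr = np.array([100.0, 100.0, 100.0])
        outside = evaluate_estimator(agfr, np.array([130.1, 100.0, 100.0]))
        at_edge = evaluate_estimator(agfr, np.array([130.0, 100.0, 100.0]))
        inside = evaluate_estimator(agfr, np.array([129.9, 100.0, 100.0]))
        assert outside.p30 == pytest.approx(2 / 3)
        assert at_edge.p30 == 1.0  # |est - agfr| = 0.30 * agfr counts as within
        assert inside.p30 == 1.0

    def test_toy_set_hand_values(self):
        agfr = np.array([100.0, 120.0, 140.0])
        est = np.array([80.0, 100.0, 150.0])
        rep = evaluate_estimator(agfr, est)
        assert rep.p30 == 1.0
        assert rep.bias == pytest.approx(10.0)
        assert rep.rmse >= abs(rep.bias)

    @given(c=st.floats(0.01, 100))
    @settings(max_examples=30, deadline=None)
    def test_p30_scale_invariance(self, c):
        rng = np.random.default_rng(4)
        agfr = rng.uniform(60, 200, 50)
        est = agfr * rng.uniform(0.6, 1.4, 50)
        assert (
            evaluate_estimator(agfr, est).p30
            == evaluate_estimator(c * agfr, c * est).p30
        )

    def test_r_matches_two_pass_oracle(self):
        rng = np.random.default_rng(5)
        agfr = rng.uniform(60, 200, 200)
        est = agfr + rng.normal(0, 30, 200)
        r = evaluate_estimator(agfr, est).r
        xa, xe = agfr - agfr.mean(), est - est.mean()
        oracle = float(np.sum(xa * xe) / np.sqrt(np.sum(xa**2) * np.sum(xe**2)))
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_small_and_empty_inputs_rejected(self):
        with pytest.raises(InputError):
            evaluate_estimator([], [])
        with pytest.raises(InputError):
            evaluate_estimator([100, 110], [100, 110])


class TestDependentCorrelations:
    def test_identical_estimators(self):
        rng = np.random.default_rng(6)
        agfr = rng.uniform(60, 200, 50)
        est = agfr + rng.normal(0, 20, 50)
        cc = compare_dependent_correlations(agfr, est, est)
        assert cc.z == 0.0
        assert cc.p == 1.0

    def test_perfect_correlation_rejected(self):
        rng = np.random.default_rng(60)
        agfr = np.linspace(60, 200, 50)
        est2 = agfr + rng.normal(0, 20, 50)
        with pytest.raises(DomainError):
            # est1 is an exact affine image of agfr: r1 = 1
            compare_dependent_correlations(agfr, agfr * 2 + 1, est2)

    @pytest.mark.parametrize("gap", [0.04, 0.08, 0.15])
    def test_z_increases_with_correlation_gap(self, gap):
        base = abs(dependent_correlation_z(0.60, 0.60, 0.5, 500))
        wider = abs(dependent_correlation_z(0.60 + gap, 0.60 - gap, 0.5, 500))
        widest = abs(dependent_correlation_z(0.60 + 2 * gap, 0.60 - 2 * gap, 0.5, 500))
        assert base < wider < widest

    def test_type_one_error_calibrated(self):
        """Under equal true correlations the test rejects at ~5%."""
        rng = np.random.default_rng(7)
        n, reps, alpha = 500, 1000, 0.05
        rejections = 0
        for _ in range(reps):
            x = rng.normal(size=n)
            agfr = x + rng.normal(0, 1.0, n)
            est1 = x + rng.normal(0, 1.0, n)
            est2 = x + rng.normal(0, 1.0, n)
            if compare_dependent_correlations(agfr, est1, est2).p < alpha:
                rejections += 1
        assert 0.03 <= rejections / reps <= 0.07


class TestRoc:
    def test_perfect_separation(self):
        agfr = np.array([100.0] * 5 + [140.0] * 5)
        est = np.array([90.0] * 5 + [150.0] * 5)
        roc = roc_curve(agfr, est)
        assert roc.auc == 1.0

    def test_twelve_point_tie_set_matches_pair_oracle(self):
        agfr = np.array([100, 100, 130, 130, 90, 150, 125, 110, 121, 119, 140, 80.0])
        est = np.array([105, 110, 110, 140, 85, 150, 105, 110, 130, 119, 119, 80.0])
        roc = roc_curve(agfr, est)
        labels = agfr > 120
        assert roc.auc == pytest.approx(auc_pair_oracle(labels, est), abs=1e-12)

    @given(st.data())
    @settings(max_examples=40, deadline=None)
    def test_auc_equals_pair_counting_on_random_instances(self, data):
        n = data.draw(st.integers(6, 30))
        scores = np.array(
            data.draw(st.lists(st.integers(0, 8), min_size=n, max_size=n)),
            dtype=float,
        )
        labels = np.array(
            data.draw(
                st.lists(st.booleans(), min_size=n, max_size=n).filter(
                    lambda ls: any(ls) and not all(ls)
                )
            )
        )
        agfr = np.where(labels, 140.0, 100.0)
        roc = roc_curve(agfr, scores)
        assert roc.auc == pytest.approx(auc_pair_oracle(labels, scores), abs=1e-12)

    def test_independent_scores_give_half_auc(self):
        rng = np.random.default_rng(8)
        agfr = rng.uniform(60, 200, 4000)
        est = rng.uniform(60, 200, 4000)
        assert roc_curve(agfr, est).auc == pytest.approx(0.5, abs=0.04)

    def test_monotone_sensitivity_specificity(self, default_sim):
        from glygfr.equations import ckd_epi_cohort
        agfr = default_sim.cohort.frame.agfr_ml_min_1p73.to_numpy()
        roc = roc_curve(agfr, ckd_epi_cohort(default_sim.cohort).to_numpy())
        assert (np.diff(roc.sensitivity) <= 1e-12).all()
        assert (np.diff(roc.specificity) >= -1e-12).all()

    def test_single_class_rejected(self):
        agfr = np.full(10, 100.0)
        with pytest.raises(ValidationError):
            roc_curve(agfr, agfr)

    def test_inclusive_rule_changes_labels(self):
        agfr = np.array([120.0] * 5 + [100.0] * 5)
        est = np.arange(10, dtype=float)
        with pytest.raises(ValidationError):
            roc_curve(agfr, est)  # strict: no positives at exactly 120
        roc = roc_curve(agfr, est, HyperfiltrationRule(comparison="ge"))
        assert roc.n_pos == 5


class TestDeLong:
    def test_identical_estimators(self):
        rng = np.random.default_rng(9)
        agfr = rng.uniform(60, 200, 100)
        est = agfr + rng.normal(0, 25, 100)
        dl = delong_compare(agfr, est, est)
        assert dl.auc1 == dl.auc2
        assert dl.z == 0.0
        assert dl.p == 1.0

    def test_aucs_match_separate_roc_runs(self):
        rng = np.random.default_rng(10)
        agfr = rng.uniform(60, 200, 150)
        est1 = agfr + rng.normal(0, 25, 150)
        est2 = agfr + rng.normal(0, 45, 150)
        dl = delong_compare(agfr, est1, est2)
        assert dl.auc1 == pytest.approx(roc_curve(agfr, est1).auc, abs=1e-12)
        assert dl.auc2 == pytest.approx(roc_curve(agfr, est2).auc, abs=1e-12)

    def test_variance_against_paired_bootstrap(self):
        """DeLong variance of the AUC difference vs a 2000-rep bootstrap."""
        rng = np.random.default_rng(11)
        n = 60
        agfr = rng.uniform(80, 180, n)
        est1 = agfr + rng.normal(0, 20, n)
        est2 = agfr + rng.normal(0, 35, n)
        dl = delong_compare(agfr, est1, est2)
        labels = agfr > 120

        def auc(lbl, s):
            from scipy.stats import rankdata
            rk = rankdata(s)
            m = lbl.sum()
            return (rk[lbl].sum() - m * (m + 1) / 2) / (m * (len(s) - m))

        diffs = []
        for _ in range(2000):
            idx = rng.integers(0, n, n)
            lb = labels[idx]
            if lb.all() or not lb.any():
                continue
            diffs.append(auc(lb, est1[idx]) - auc(lb, est2[idx]))
        boot_var = np.var(diffs, ddof=1)
        assert dl.var_diff == pytest.approx(boot_var, rel=0.20)

    def test_null_rejection_rate(self):
        """Two noisy copies of one score: DeLong rejects at ~5%."""
        rng = np.random.default_rng(12)
        reject = 0
        reps = 1000
        for _ in range(reps):
            agfr = rng.uniform(80, 180, 120)
            base = agfr + rng.normal(0, 30, 120)
            est1 = base + rng.normal(0, 10, 120)
            est2 = base + rng.normal(0, 10, 120)
            if delong_compare(agfr, est1, est2).p < 0.05:
                reject += 1
        assert 0.03 <= reject / reps <= 0.07


class TestThresholdAtSpecificity:
    def _toy_roc(self):
        # 3 positives score {3, 5, 6}, 3 negatives score {1, 2, 4}
        agfr = np.array([130, 130, 130, 100, 100, 100.0])
        est = np.array([3, 5, 6, 1, 2, 4.0])
        return roc_curve(agfr, est)

    def test_hand_swept_toy(self):
        roc = self._toy_roc()
        thr, sens, spec = threshold_at_specificity(roc, 0.65)
        # smallest threshold with specificity >= 0.65 is 2.5 (spec 2/3),
        # where all three positives still test positive
        assert thr == pytest.approx(2.5)
        assert spec == pytest.approx(2 / 3)
        assert sens == pytest.approx(1.0)

    def test_perfect_classifier(self):
        agfr = np.array([130.0] * 4 + [100.0] * 4)
        est = np.array([10.0] * 4 + [1.0] * 4)
        thr, sens, spec = threshold_at_specificity(roc_curve(agfr, est), 0.99)
        assert sens == 1.0
        assert spec == 1.0
        assert 1.0 < thr < 10.0

    def test_monotone_in_target(self):
        roc = self._toy_roc()
        thresholds = [
            threshold_at_specificity(roc, t)[0] for t in (0.2, 0.5, 0.7, 0.95)
        ]
        assert all(a <= b for a, b in zip(thresholds, thresholds[1:]))

    def test_achieved_specificity_at_least_target(self):
        roc = self._toy_roc()
        for t in (0.1, 0.34, 0.5, 0.66, 0.9):
            _, _, spec = threshold_at_specificity(roc, t)
            assert spec >= t

    def test_bad_target_rejected(self):
        with pytest.raises(InputError):
            threshold_at_specificity(self._toy_roc(), 1.5)


class TestBiasByLevel:
    def test_constant_shift(self):
        rng = np.random.default_rng(13)
        agfr = rng.uniform(60, 200, 100)
        table = bias_by_level(agfr, agfr - 25.7, n_bins=5)
        assert np.allclose(table.mean_diff, 25.7)
        assert table.attrs["overall_bias"] == pytest.approx(25.7)

    def test_unbiased_estimates(self):
        rng = np.random.default_rng(14)
        agfr = rng.uniform(60, 200, 2000)
        est = agfr + rng.normal(0, 5, 2000)
        table = bias_by_level(agfr, est, n_bins=4)
        assert np.abs(table.mean_diff).max() < 1.0

    def test_ckd_epi_underestimates_more_at_high_agfr(self, default_sim):
        from glygfr.equations import ckd_epi_cohort
        agfr = default_sim.cohort.frame.agfr_ml_min_1p73.to_numpy()
        est = ckd_epi_cohort(default_sim.cohort).to_numpy()
        table = bias_by_level(agfr, est, n_bins=10)
        # strongly increasing level-dependent bias
        assert table.mean_diff.iloc[-1] > table.mean_diff.iloc[0] + 20
        corr = np.corrcoef(table.mean_agfr, table.mean_diff)[0, 1]
        assert corr > 0.9

    def test_errors(self):
        with pytest.raises(InputError):
            bias_by_level([100.0, 110.0], [100.0, 110.0], n_bins=3)
        with pytest.raises(InputError):
            bias_by_level([100.0] * 5, [100.0] * 5, n_bins=1)
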