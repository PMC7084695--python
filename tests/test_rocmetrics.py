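import numpy as np
import pytest
from scipy.special import expit
from sklearn.metrics import roc_auc_score

from aapanel.best_subset import CAIC
from aapanel.cohort import generate_cohort, planted_signal_config
from aapanel.crossval import CVConfig
from aapanel.errors import UndefinedRocError, ValidationError
from aapanel.logit import LogitModel
from aapanel.panel import DatasetSplit
from aapanel.rocmetrics import (
    auc_score,
    confusion_at,
    evaluate_protocol,
    optimal_threshold,
    risk_curve,
    roc_curve,
)

from conftest import build_panel


class TestAuc:
    def test_constant_scores_give_half(self):
        assert auc_score([3.0] * 8, [0, 1] * 4) == 0.5

    def test_perfect_separation_gives_one(self):
        assert auc_score([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]) == 1.0

    def test_matches_brute_force_pair_counting(self, rng):
        for _ in range(30):
            n = int(rng.integers(6, 20))
            scores = rng.integers(0, 6, size=n).astype(float)  # force ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert auc_score(scores, labels) == pytest.approx(
                wins / (len(pos) * len(neg))
            )

    def test_matches_sklearn(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        assert auc_score(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_sign_flip_complements_auc(self, rng):
        scores = rng.normal(size=30)  # continuous: no ties
        labels = np.r_[np.zeros(15, int), np.ones(15, int)]
        assert auc_score(scores, labels) + auc_score(-scores, labels) == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedRocError):
            auc_score([1.0, 2.0], [1, 1])


class TestRocCurve:
    def test_sensitivity_non_increasing_in_threshold(self, rng):
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        rep = roc_curve(scores, labels)
        assert np.all(np.diff(rep.sensitivity_at) <= 1e-12)
        assert np.all(np.diff(rep.specificity_at) >= -1e-12)

    def test_sentinel_thresholds_cover_extremes(self):
        rep = roc_curve([1.0, 2.0, 3.0, 4.0], [0, 0, 1, 1])
        assert rep.thresholds[0] == -np.inf and rep.thresholds[-1] == np.inf
        assert rep.sensitivity_at[0] == 1.0 and rep.specificity_at[0] == 0.0
        assert rep.sensitivity_at[-1] == 0.0 and rep.specificity_at[-1] == 1.0

    def test_auto_orientation_flips_decreasing_marker(self):
        # marker decreases with injury, as glycine does
        scores = np.array([900.0, 850, 800, 780, 640, 600, 580, 550])
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        rep = roc_curve(scores, labels, orient="auto")
        assert rep.orientation == -1
        assert rep.auc >= 0.5


class TestOptimalThreshold:
    def test_separable_scores_return_gap_midpoint(self):
        rep = roc_curve([1, 2, 3, 8, 9, 10], [0, 0, 0, 1, 1, 1])
        assert optimal_threshold(rep) == pytest.approx(5.5)

    def test_matches_exhaustive_scan_on_worked_set(self):
        scores = np.array([0.2, 0.9, 1.4, 1.6, 2.3, 3.1])
        labels = np.array([0, 0, 1, 0, 1, 1])
        rep = roc_curve(scores, labels)
        best_j, best_t = -np.inf, None
        for t in np.linspace(-1, 4, 2001):
            cm = confusion_at(scores, labels, t)
            j = cm.sensitivity + cm.specificity - 1
            if j > best_j + 1e-12:
                best_j, best_t = j, t
        chosen = optimal_threshold(rep)
        cm = confusion_at(scores, labels, chosen)
        assert cm.sensitivity + cm.specificity - 1 == pytest.approx(best_j)

    def test_symmetric_gaussians_cross_near_midpoint(self, rng):
        n = 4000
        scores = np.r_[rng.normal(0, 1, n), rng.normal(2, 1, n)]
        labels = np.r_[np.zeros(n, int), np.ones(n, int)]
        thr = optimal_threshold(roc_curve(scores, labels))
        assert abs(thr - 1.0) < 0.25


class TestConfusionAt:
    def test_par_is_weighted_mean_of_s_and_sp(self, rng):
        scores = rng.normal(size=37)
        labels = rng.integers(0, 2, size=37)
        cm = confusion_at(scores, labels, 0.1)
        expected = (
            cm.sensitivity * cm.positive + cm.specificity * cm.negative
        ) / (cm.positive + cm.negative)
        assert cm.accuracy == expected  # exact identity, no rounding

    def test_threshold_below_all_scores(self):
        cm = confusion_at([1.0, 2.0, 3.0, 4.0], [0, 1, 0, 1], -10.0)
        assert cm.sensitivity == 1.0 and cm.specificity == 0.0

    def test_rule_is_greater_equal(self):
        cm = confusion_at([1.0, 2.0], [0, 1], 2.0)
        assert cm.t_positive == 1 and cm.t_negative == 1

    def test_infinite_threshold_rejected(self):
        with pytest.raises(ValidationError):
            confusion_at([1.0], [1], np.inf)


class TestRiskCurve:
    def test_logistic_shape_and_symmetry(self):
        model = LogitModel(["GLY"], 0.0, [1.0], -1.0, 10, 1, True, False)
        grid = np.linspace(-6, 6, 121)
        curve = risk_curve(model, grid)
        probs = curve[:, 1]
        assert probs[60] == pytest.approx(0.5)  # P(score=0)
        np.testing.assert_allclose(probs + probs[::-1], 1.0, atol=1e-12)
        assert np.all(np.diff(probs) > 0)

    def test_threshold_maps_consistently_through_logistic(self):
        thr = 0.439  # a logit-score threshold
        curve = risk_curve(
            LogitModel(["X"], 0.0, [1.0], -1.0, 10, 1, True, False), [thr]
        )
        assert curve[0, 1] == pytest.approx(expit(thr))


class TestEvaluateProtocol:
    def _splits(self, seed=42):
        cfg = planted_signal_config(
            signal_set=("GLY", "TAU", "ORN"),
            analyte_names=("ALA", "GLY", "ORN", "PHE", "TAU"),
            seed=seed,
        )
        dev = DatasetSplit("development", generate_cohort(cfg))
        val_cfg = planted_signal_config(
            signal_set=("GLY", "TAU", "ORN"),
            analyte_names=("ALA", "GLY", "ORN", "PHE", "TAU"),
            n_uninjured=4, n_injured=5, seed=seed + 1,
        )
        val = DatasetSplit("validation", generate_cohort(val_cfg))
        exp_cfg = planted_signal_config(
            signal_set=("GLY", "TAU", "ORN"),
            analyte_names=("ALA", "GLY", "ORN", "PHE", "TAU"),
            n_uninjured=0, n_injured=10, seed=seed + 2, injured_timepoint="8d",
        )
        exp = DatasetSplit("exploration", generate_cohort(exp_cfg))
        return dev, val, exp

    def test_four_way_report_shape(self):
        dev, val, exp = self._splits()
        report = evaluate_protocol(
            dev, val, exp, CAIC, CVConfig(k=5, repetitions=2, seed=0),
            subset=("GLY", "TAU", "ORN"),
        )
        assert report.development.positive == 25
        assert np.isfinite(report.development.sensitivity)
        assert np.isfinite(report.cv_metrics.accuracy_mean)
        assert np.isfinite(report.validation.specificity)
        assert report.exploration_sensitivity is not None
        assert report.exploration is None  # no negatives: S only, per protocol

    def test_same_distribution_val_tracks_dev(self):
        dev, val, exp = self._splits(seed=90)
        report = evaluate_protocol(
            dev, val, None, CAIC, None, subset=("GLY", "TAU", "ORN")
        )
        # validation drawn from the same generator: accuracy within sampling
        # error of the development accuracy (n_val = 9 → wide band)
        assert abs(report.validation.accuracy - report.development.accuracy) < 0.45

    def test_multivariate_auc_beats_univariate(self):
        dev, _, _ = self._splits(seed=7)
        report = evaluate_protocol(dev, None, None, CAIC, None,
                                   subset=("GLY", "TAU", "ORN"))
        uni = max(
            roc_curve(dev.panel.values([a])[:, 0], dev.panel.labels, orient="auto").auc
            for a in dev.panel.analyte_names
        )
        assert report.development_auc >= uni - 1e-12
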