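"""ROC analysis, optimal thresholds, confusion metrics and the three-cohort
evaluation protocol.

Scores are oriented so that larger means more injured-like; a sample is
classified injured when its score is at or above the threshold.  The three
diagnostic summaries are

    S   (sensitivity)           = TPositive / Positive
    SP  (specificity)           = TNegative / Negative
    PAR (overall accuracy rate) = (TNegative + TPositive) / (Negative + Positive)

AUC is computed by the rank (Mann–Whitney) identity with half-credit for
ties, which equals the trapezoidal area under the empirical step curve.
The optimal threshold maximises Youden's J = S + SP - 1, resolving ties
toward higher specificity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import rankdata

from .best_subset import CriterionSpec
from .errors import UndefinedRocError, ValidationError
from .logit import FitOptions, LogitModel, fit_logit
from .panel import DatasetSplit


@dataclass
class ConfusionMetrics:
    """Counts and rates at one threshold.

    ``sensitivity``/``specificity``/``accuracy`` are fractions in [0, 1]
    (NaN when the corresponding class is absent); the ``*_pct`` properties
    give display percentages rounded to integers.
    """

    t_positive: int
    t_negative: int
    positive: int
    negative: int
    threshold: float = math.nan

    @property
    def sensitivity(self) -> float:
        return self.t_positive / self.positive if self.positive else math.nan

    @property
    def specificity(self) -> float:
        return self.t_negative / self.negative if self.negative else math.nan

    @property
    def accuracy(self) -> float:
        total = self.positive + self.negative
        return (self.t_positive + self.t_negative) / total if total else math.nan

    @property
    def sensitivity_pct(self) -> float:
        return round(100.0 * self.sensitivity) if self.positive else math.nan

    @property
    def specificity_pct(self) -> float:
        return round(100.0 * self.specificity) if self.negative else math.nan

    @property
    def accuracy_pct(self) -> float:
        return round(100.0 * self.accuracy) if self.positive + self.negative else math.nan


@dataclass
class RocReport:
    """An empirical ROC curve on one score vector."""

    thresholds: np.ndarray  # ascending; -inf/+inf sentinels included
    sensitivity_at: np.ndarray
    specificity_at: np.ndarray
    auc: float
    curve_domain: str = "logit score"
    orientation: int = 1  # +1: raw scores used; -1: scores were sign-flipped


def _check_labels(labels: np.ndarray) -> None:
    classes = np.unique(labels)
    if not set(classes.tolist()) <= {0, 1} or len(classes) < 2:
        raise UndefinedRocError("ROC requires both classes among the labels")


def auc_score(scores, labels) -> float:
    """Rank-based AUC: P(score_injured > score_uninjured) + ½·P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_labels(labels)
    ranks = rankdata(scores)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    u1 = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u1 / (n0 * n1))


def roc_curve(scores, labels, curve_domain: str = "logit score", orient: str = "as-is") -> RocReport:
    """Empirical ROC curve with thresholds at midpoints between distinct scores.

    ``orient="auto"`` flips the score sign when the raw AUC is below 0.5, so
    that analytes that *decrease* with injury (e.g. glycine) report
    AUC ≥ 0.5; the flip is recorded in ``orientation``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not np.all(np.isfinite(scores)):
        raise ValidationError("scores must be finite")
    _check_labels(labels)
    orientation = 1
    if orient == "auto" and auc_score(scores, labels) < 0.5:
        scores = -scores
        orientation = -1
    elif orient not in ("as-is", "auto"):
        raise ValidationError(f"unknown orientation rule {orient!r}")

    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if len(uniq) > 1 else np.array([])
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    # classify injured when score >= threshold
    sens = np.array([(scores[pos] >= t).sum() / n1 for t in thresholds])
    spec = np.array([(scores[~pos] < t).sum() / n0 for t in thresholds])
    return RocReport(
        thresholds=thresholds,
        sensitivity_at=sens,
        specificity_at=spec,
        auc=auc_score(scores, labels),
        curve_domain=curve_domain,
        orientation=orientation,
    )


def optimal_threshold(report: RocReport) -> float:
    """Threshold maximising Youden's J = S + SP - 1 (ties → higher specificity)."""
    j = report.sensitivity_at + report.specificity_at - 1.0
    best_j = j.max()
    candidates = np.flatnonzero(j >= best_j - 1e-12)
    # thresholds ascend, so specificity is non-decreasing along candidates
    specs = report.specificity_at[candidates]
    best = candidates[specs >= specs.max() - 1e-12]
    choice = best[0]
    if not np.isfinite(report.thresholds[choice]):
        finite = best[np.isfinite(report.thresholds[best])]
        if len(finite):
            choice = finite[0]
    return float(report.thresholds[choice])


def confusion_at(scores, labels, threshold: float) -> ConfusionMetrics:
    """Classify injured when score ≥ threshold and count the confusion table."""
    if not np.isfinite(threshold):
        raise ValidationError("threshold must be finite")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionMetrics(
        t_positive=int((pred & pos).sum()),
        t_negative=int((~pred & ~pos).sum()),
        positive=int(pos.sum()),
        negative=int((~pos).sum()),
        threshold=float(threshold),
    )


def risk_curve(model: LogitModel, score_grid) -> np.ndarray:
    """Map logit scores to injury probability P = expit(score) over a grid.

    Returns an (m, 2) array of (score, probability); strictly increasing.
    """
    grid = np.asarray(score_grid, dtype=float)
    return np.column_stack([grid, expit(grid)])


@dataclass
class ProtocolReport:
    """Output of the four-way evaluation protocol."""

    subset: tuple[str, ...]
    model: LogitModel
    threshold: float
    development: ConfusionMetrics
    development_auc: float
    cv_metrics: "object | None"
    validation: ConfusionMetrics | None
    exploration_sensitivity: float | None
    exploration: ConfusionMetrics | None = None
    exploration_note: str | None = None
    consensus: "object | None" = None


def evaluate_protocol(
    dev: DatasetSplit,
    val: DatasetSplit | None,
    exp: DatasetSplit | None,
    criterion: CriterionSpec,
    config,
    subset=None,
    options: FitOptions | None = None,
    records=None,
) -> ProtocolReport:
    """Run the four-way evaluation of a biomarker panel.

    1. Fit the (consensus) subset on the full development split, choose the
       Youden-optimal ROC threshold there and report S/SP/PAR in-sample.
    2. Report repeated-CV mean ± SD of S/SP/PAR (thresholds chosen on each
       training fold only).
    3. Apply the development-fitted model and its threshold, unchanged, to
       the validation split.
    4. Apply them to the exploration split; only sensitivity is reported
       when that split has no uninjured samples (its usual composition).

    When ``subset`` is None the consensus panel is first discovered by
    repeated-CV best-subset selection on the development split.
    """
    from .crossval import cv_prediction_metrics, run_cv_selection, summarize_consensus

    consensus = None
    if subset is None:
        if records is None:
            records = run_cv_selection(dev.panel, config, criterion, options=options)
        consensus = summarize_consensus(records)
        subset = consensus.consensus_subset
    subset = tuple(subset)

    model = fit_logit(dev.panel, subset, options)
    dev_scores = model.scores(dev.panel)
    report = roc_curve(dev_scores, dev.panel.labels)
    threshold = optimal_threshold(report)
    dev_metrics = confusion_at(dev_scores, dev.panel.labels, threshold)

    cv_metrics = None
    if records is None and config is not None:
        records = run_cv_selection(dev.panel, config, criterion, options=options)
    if records is not None:
        size_m = consensus.optimal_size_m if consensus is not None else len(subset)
        cv_metrics = cv_prediction_metrics(
            records, dev.panel, size_m, subset_rule="per_iteration", options=options
        )

    val_metrics = None
    if val is not None:
        val_metrics = confusion_at(model.scores(val.panel), val.panel.labels, threshold)

    exp_metrics = exp_sens = exp_note = None
    if exp is not None:
        cm = confusion_at(model.scores(exp.panel), exp.panel.labels, threshold)
        exp_sens = cm.sensitivity
        if cm.negative > 0:
            exp_metrics = cm
            exp_note = (
                "exploration split contains uninjured samples; specificity and "
                "accuracy reported in addition to sensitivity"
            )

    return ProtocolReport(
        subset=subset,
        model=model,
        threshold=threshold,
        development=dev_metrics,
        development_auc=report.auc,
        cv_metrics=cv_metrics,
        validation=val_metrics,
        exploration_sensitivity=exp_sens,
        exploration=exp_metrics,
        exploration_note=exp_note,
        consensus=consensus,
    )
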