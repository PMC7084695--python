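"""Repeated k-fold cross-validation around the exhaustive subset search.

Each of the k·repetitions iterations runs the full best-subset search (sizes
1..pp) on its training folds only; the held-out fold never touches selection.
Per-size criterion values are then averaged over all iterations to choose the
optimal panel size m (arg-min of the mean CAIC curve), and the consensus
panel is the size-m subset selected most often across iterations — the
"consistently or repeatedly selected" rule.  Prediction metrics are computed
by refitting on each training fold, choosing the ROC threshold on that
training fold, and scoring the held-out fold.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .best_subset import CriterionSpec, SubsetScore, best_subsets_by_size
from .errors import FoldError, IterationError
from .logit import FitOptions, fit_logit
from .panel import AnalytePanel

logger = logging.getLogger(__name__)


@dataclass
class CVConfig:
    """Repeated k-fold layout: k folds, `repetitions` independent splits.

    Stratified assignment (default) preserves the class ratio within ±1
    sample per fold; ``group_by_animal`` instead keeps all samples of one
    animal in the same fold, for designs where pre/post samples share
    animals and leakage across folds is a concern.
    """

    k: int = 5
    repetitions: int = 5
    seed: int = 0
    stratified: bool = True
    group_by_animal: bool = False

    def __post_init__(self) -> None:
        if self.k < 2:
            raise FoldError("k must be at least 2")
        if self.repetitions < 1:
            raise FoldError("repetitions must be at least 1")


@dataclass
class IterationRecord:
    """One CV iteration: its partition and the per-size best subsets."""

    iteration_index: int  # 1-based over all k * repetitions iterations
    train_indices: np.ndarray
    test_indices: np.ndarray
    best_by_size: dict[int, SubsetScore] = field(default_factory=dict)
    test_metrics: "object | None" = None


@dataclass
class CVMetrics:
    """Mean ± SD of test-fold S/SP/PAR (percent) and training thresholds."""

    sensitivity_mean: float
    sensitivity_sd: float
    specificity_mean: float
    specificity_sd: float
    accuracy_mean: float
    accuracy_sd: float
    threshold_mean: float
    threshold_sd: float
    n_iterations: int
    n_excluded_sensitivity: int = 0
    n_excluded_specificity: int = 0


def make_folds(panel: AnalytePanel, config: CVConfig) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic (train, test) index pairs, k per repetition.

    Within each repetition every sample appears in exactly one test fold, so
    over the whole schedule each sample is tested exactly ``repetitions``
    times.  Fold membership is driven by explicit index permutations from a
    counter-based substream of the seed (one substream per repetition), so
    repetition r is unaffected by how many repetitions run.
    """
    n = panel.n_samples
    if config.k > n:
        raise FoldError(f"k={config.k} exceeds sample count {n}")
    labels = panel.labels
    if config.stratified and not config.group_by_animal:
        counts = np.bincount(labels, minlength=2)
        present = counts[counts > 0]
        if config.k > present.min():
            raise FoldError(
                f"stratified k={config.k} exceeds smallest class count {present.min()}"
            )

    pairs: list[tuple[np.ndarray, np.ndarray]] = []
    all_idx = np.arange(n)
    for rep in range(config.repetitions):
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(2, rep)))
        folds: list[list[int]] = [[] for _ in range(config.k)]
        if config.group_by_animal:
            animals = panel.data["animal_id"].to_numpy()
            uniq = list(dict.fromkeys(animals))  # first-appearance order
            if config.k > len(uniq):
                raise FoldError(f"k={config.k} exceeds animal count {len(uniq)}")
            order = rng.permutation(len(uniq))
            for pos, a_i in enumerate(order):
                folds[pos % config.k].extend(np.flatnonzero(animals == uniq[a_i]))
        elif config.stratified:
            for cls in np.unique(labels):
                cls_idx = np.flatnonzero(labels == cls)
                perm = cls_idx[rng.permutation(len(cls_idx))]
                for f, chunk in enumerate(np.array_split(perm, config.k)):
                    folds[f].extend(chunk)
        else:
            perm = rng.permutation(n)
            for f, chunk in enumerate(np.array_split(perm, config.k)):
                folds[f].extend(chunk)
        for f in range(config.k):
            test = np.sort(np.array(folds[f], dtype=int))
            train = np.setdiff1d(all_idx, test)
            pairs.append((train, test))
    return pairs


def run_cv_selection(
    panel: AnalytePanel,
    config: CVConfig,
    criterion: CriterionSpec,
    sizes=None,
    options: FitOptions | None = None,
) -> list[IterationRecord]:
    """Best-subset selection on every training fold; test folds untouched."""
    records = []
    for i, (train, test) in enumerate(make_folds(panel, config), start=1):
        train_panel = panel.take(train)
        if len(np.unique(train_panel.labels)) < 2:
            raise IterationError(f"training fold of iteration {i} contains one class")
        best = best_subsets_by_size(
            train_panel, criterion, sizes=sizes, options=options, refit_winners=False
        )
        m_star = min(best, key=lambda p: best[p].criterion_value)
        logger.info(
            "iteration %d: best size-%d subset %s (criterion %.3f)",
            i, m_star, "+".join(best[m_star].subset), best[m_star].criterion_value,
        )
        records.append(IterationRecord(i, train, test, best))
    return records


@dataclass
class ConsensusResult:
    """Per-size criterion aggregates and the consensus panel."""

    caic_mean_by_size: dict[int, float]
    caic_sd_by_size: dict[int, float]
    optimal_size_m: int
    consensus_subset: tuple[str, ...]
    subset_frequency: dict[tuple[str, ...], int]
    consensus_frequency: int
    tie: bool = False
    cv_metrics: CVMetrics | None = None

    @property
    def n_iterations(self) -> int:
        return sum(self.subset_frequency.values())


def summarize_consensus(records: list[IterationRecord]) -> ConsensusResult:
    """Aggregate per-size criterion values and pick the consensus subset.

    m is the strict arg-min of the mean criterion curve (ties → smaller
    size, favouring parsimony).  The consensus subset is the modal size-m
    winner over iterations; modal ties break by summed per-variable
    selection frequency, then lexicographically, and are flagged.
    """
    if not records:
        raise ValueError("no iteration records to summarize")
    sizes = sorted(records[0].best_by_size)
    for rec in records:
        if sorted(rec.best_by_size) != sizes:
            raise ValueError("iteration records carry inconsistent size ranges")

    mean_by = {}
    sd_by = {}
    for p in sizes:
        vals = np.array([rec.best_by_size[p].criterion_value for rec in records])
        mean_by[p] = float(vals.mean())
        sd_by[p] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    m = min(sizes, key=lambda p: (mean_by[p], p))

    winners = [rec.best_by_size[m].subset for rec in records]
    freq = Counter(winners)
    top_count = max(freq.values())
    modal = [s for s, c in freq.items() if c == top_count]
    tie = len(modal) > 1
    if tie:
        var_freq = Counter(v for s in winners for v in s)
        modal.sort(key=lambda s: (-sum(var_freq[v] for v in s), s))
        logger.warning(
            "modal-subset tie at size %d between %s; broken by per-variable frequency",
            m, modal,
        )
    consensus = modal[0]
    return ConsensusResult(
        caic_mean_by_size=mean_by,
        caic_sd_by_size=sd_by,
        optimal_size_m=m,
        consensus_subset=tuple(consensus),
        subset_frequency=dict(freq),
        consensus_frequency=top_count,
        tie=tie,
    )


def cv_prediction_metrics(
    records: list[IterationRecord],
    panel: AnalytePanel,
    size_m: int,
    subset_rule: str = "per_iteration",
    consensus_subset=None,
    options: FitOptions | None = None,
) -> CVMetrics:
    """Held-out S/SP/PAR (percent, mean ± SD) over the CV iterations.

    Per iteration: fit the size-m panel on the training fold, choose the
    Youden-optimal threshold on *training* scores, then score the test fold.
    ``subset_rule="per_iteration"`` uses each iteration's own best size-m
    subset; ``"consensus"`` uses one fixed panel everywhere.  Iterations
    whose test fold lacks a class contribute nothing to the undefined metric
    (counted and logged).
    """
    from .rocmetrics import confusion_at, optimal_threshold, roc_curve

    if subset_rule not in ("per_iteration", "consensus"):
        raise ValueError(f"unknown subset_rule {subset_rule!r}")
    if subset_rule == "consensus" and consensus_subset is None:
        raise ValueError("consensus_subset required for subset_rule='consensus'")

    sens, spec, acc, thresholds = [], [], [], []
    excluded_s = excluded_sp = 0
    for rec in records:
        subset = (
            tuple(consensus_subset)
            if subset_rule == "consensus"
            else rec.best_by_size[size_m].subset
        )
        train_panel = panel.take(rec.train_indices)
        test_panel = panel.take(rec.test_indices)
        model = fit_logit(train_panel, subset, options)
        train_scores = model.scores(train_panel)
        thr = optimal_threshold(roc_curve(train_scores, train_panel.labels))
        cm = confusion_at(model.scores(test_panel), test_panel.labels, thr)
        rec.test_metrics = cm
        thresholds.append(thr)
        if cm.positive:
            sens.append(cm.sensitivity)
        else:
            excluded_s += 1
            logger.info("iteration %d: test fold has no positives; S skipped", rec.iteration_index)
        if cm.negative:
            spec.append(cm.specificity)
        else:
            excluded_sp += 1
            logger.info("iteration %d: test fold has no negatives; SP skipped", rec.iteration_index)
        acc.append(cm.accuracy)

    def _ms(xs, scale=100.0):
        if not xs:
            return float("nan"), float("nan")
        arr = np.array(xs) * scale
        return float(arr.mean()), float(arr.std(ddof=1)) if len(arr) > 1 else 0.0

    s_m, s_sd = _ms(sens)
    sp_m, sp_sd = _ms(spec)
    a_m, a_sd = _ms(acc)
    t_m, t_sd = _ms(thresholds, scale=1.0)
    return CVMetrics(
        sensitivity_mean=s_m, sensitivity_sd=s_sd,
        specificity_mean=sp_m, specificity_sd=sp_sd,
        accuracy_mean=a_m, accuracy_sd=a_sd,
        threshold_mean=t_m, threshold_sd=t_sd,
        n_iterations=len(records),
        n_excluded_sensitivity=excluded_s,
        n_excluded_specificity=excluded_sp,
    )
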