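import numpy as np
import pytest

from aapanel.best_subset import CAIC, SubsetScore
from aapanel.cohort import generate_cohort, null_config, planted_signal_config
from aapanel.crossval import (
    CVConfig,
    IterationRecord,
    cv_prediction_metrics,
    make_folds,
    run_cv_selection,
    summarize_consensus,
)
from aapanel.errors import FoldError

from conftest import build_panel


ANALYTES8 = ("ALA", "ARG", "CIT", "GLY", "LEU", "ORN", "PHE", "TAU")


class TestMakeFolds:
    def test_repeated_five_fold_layout(self, small_panel):
        cfg = CVConfig(k=5, repetitions=5, seed=1)
        pairs = make_folds(small_panel, cfg)
        assert len(pairs) == 25
        for train, test in pairs:
            assert len(test) == small_panel.n_samples // 5
            assert len(np.intersect1d(train, test)) == 0
            assert len(np.union1d(train, test)) == small_panel.n_samples

    def test_each_sample_tested_once_per_repetition(self, small_panel):
        cfg = CVConfig(k=5, repetitions=3, seed=2)
        pairs = make_folds(small_panel, cfg)
        counts = np.zeros(small_panel.n_samples, dtype=int)
        for _, test in pairs:
            counts[test] += 1
        assert np.all(counts == 3)

    def test_deterministic_for_seed(self, small_panel):
        a = make_folds(small_panel, CVConfig(seed=7))
        b = make_folds(small_panel, CVConfig(seed=7))
        for (ta, sa), (tb, sb) in zip(a, b):
            np.testing.assert_array_equal(ta, tb)
            np.testing.assert_array_equal(sa, sb)

    def test_stratification_balances_classes(self, small_panel):
        for train, test in make_folds(small_panel, CVConfig(k=5, seed=3)):
            labels = small_panel.labels[test]
            assert abs((labels == 1).sum() - (labels == 0).sum()) <= 1

    def test_k_larger_than_class_count_rejected(self):
        panel = build_panel(np.abs(np.random.default_rng(0).normal(50, 9, (10, 2))),
                            [1] * 7 + [0] * 3)
        with pytest.raises(FoldError):
            make_folds(panel, CVConfig(k=4, repetitions=1, seed=0))

    def test_group_by_animal_keeps_animals_intact(self):
        panel = generate_cohort(planted_signal_config(seed=13))
        cfg = CVConfig(k=5, repetitions=2, seed=5, group_by_animal=True)
        animals = panel.data["animal_id"].to_numpy()
        for train, test in make_folds(panel, cfg):
            assert set(animals[train]).isdisjoint(set(animals[test]))


class TestRunCvSelection:
    def test_toy_two_fold_structure(self):
        rng = np.random.default_rng(4)
        X = np.abs(rng.normal(40, 8, size=(8, 2)))
        X[:, 0] += 30 * np.repeat([0, 1], 4)
        panel = build_panel(X, np.repeat([0, 1], 4))
        records = run_cv_selection(panel, CVConfig(k=2, repetitions=1, seed=0), CAIC)
        assert len(records) == 2
        np.testing.assert_array_equal(
            np.sort(np.concatenate([records[0].test_indices, records[1].test_indices])),
            np.arange(8),
        )

    def test_planted_variables_dominate_selection_frequency(self):
        """In a planted 3-signal cohort the planted analytes are the most
        frequently selected variables among per-iteration size-3 winners."""
        cfg = planted_signal_config(
            signal_set=("GLY", "TAU", "ORN"), analyte_names=ANALYTES8, seed=102
        )
        panel = generate_cohort(cfg)
        records = run_cv_selection(panel, CVConfig(k=5, repetitions=5, seed=34), CAIC)
        from collections import Counter

        freq = Counter(v for rec in records for v in rec.best_by_size[3].subset)
        top3 = {name for name, _ in freq.most_common(3)}
        assert top3 == {"GLY", "TAU", "ORN"}

    def test_null_cohort_mean_caic_increases_beyond_size_one(self):
        cfg = null_config(analyte_names=ANALYTES8, seed=55)
        panel = generate_cohort(cfg)
        records = run_cv_selection(panel, CVConfig(k=5, repetitions=2, seed=8), CAIC)
        cons = summarize_consensus(records)
        means = [cons.caic_mean_by_size[p] for p in sorted(cons.caic_mean_by_size)]
        # beyond the smallest sizes the penalty dominates pure-noise fits
        assert means[-1] > means[1]
        assert means[-2] > means[2]


def _record(i, subset, value, size=None):
    size = size if size is not None else len(subset)
    return IterationRecord(
        i, np.arange(5), np.arange(5, 8),
        {size: SubsetScore(tuple(subset), size, value, -5.0)},
    )


class TestSummarizeConsensus:
    def test_unanimous_selection(self):
        records = [_record(i, ("GLY", "ORN", "TAU"), 40.0) for i in range(25)]
        cons = summarize_consensus(records)
        assert cons.optimal_size_m == 3
        assert cons.consensus_subset == ("GLY", "ORN", "TAU")
        assert cons.consensus_frequency == 25
        assert not cons.tie

    def test_majority_pattern_24_of_25(self):
        records = [_record(i, ("GLY", "ORN", "TAU"), 40.0) for i in range(24)]
        records.append(_record(24, ("ALA", "GLY", "TAU"), 41.0))
        cons = summarize_consensus(records)
        assert cons.consensus_subset == ("GLY", "ORN", "TAU")
        assert cons.subset_frequency[("GLY", "ORN", "TAU")] == 24
        assert cons.subset_frequency[("ALA", "GLY", "TAU")] == 1

    def test_modal_tie_broken_by_variable_frequency_and_flagged(self):
        records = [_record(i, ("A", "B", "C"), 40.0) for i in range(12)]
        records += [_record(12 + i, ("A", "B", "D"), 40.0) for i in range(12)]
        records.append(_record(24, ("A", "C", "E"), 40.0))
        cons = summarize_consensus(records)
        assert cons.tie
        # C appears 13 times vs D's 12, so the A+B+C panel wins the tie
        assert cons.consensus_subset == ("A", "B", "C")

    def test_invariant_to_iteration_order(self):
        records = [_record(i, ("GLY", "TAU"), 40.0 + (i % 3), size=2) for i in range(10)]
        forward = summarize_consensus(records)
        backward = summarize_consensus(records[::-1])
        assert forward.consensus_subset == backward.consensus_subset
        assert forward.caic_mean_by_size == backward.caic_mean_by_size

    def test_optimal_size_argmin_of_mean(self):
        records = []
        for i in range(4):
            records.append(
                IterationRecord(
                    i, np.arange(5), np.arange(5, 8),
                    {
                        1: SubsetScore(("A",), 1, 50.0 + i, -5.0),
                        2: SubsetScore(("A", "B"), 2, 44.0 + i, -5.0),
                        3: SubsetScore(("A", "B", "C"), 3, 47.0 + i, -5.0),
                    },
                )
            )
        cons = summarize_consensus(records)
        assert cons.optimal_size_m == 2


class TestCvPredictionMetrics:
    def test_separable_cohort_perfect_metrics(self):
        rng = np.random.default_rng(10)
        y = np.repeat([0, 1], 20)
        X = np.abs(rng.normal(30, 3, size=(40, 2)))
        X[:, 0] += 100.0 * y  # huge gap: every fold separates
        panel = build_panel(X, y)
        records = run_cv_selection(panel, CVConfig(k=5, repetitions=2, seed=0), CAIC,
                                   sizes=[1, 2])
        metrics = cv_prediction_metrics(records, panel, 1)
        assert metrics.sensitivity_mean == pytest.approx(100.0)
        assert metrics.specificity_mean == pytest.approx(100.0)
        assert metrics.accuracy_mean == pytest.approx(100.0)
        assert metrics.accuracy_sd == pytest.approx(0.0)

    def test_null_cohort_accuracy_near_chance(self):
        cfg = null_config(analyte_names=ANALYTES8, n_uninjured=30, n_injured=30, seed=77)
        panel = generate_cohort(cfg)
        records = run_cv_selection(panel, CVConfig(k=5, repetitions=2, seed=1), CAIC,
                                   sizes=[1])
        metrics = cv_prediction_metrics(
            records, panel, 1, subset_rule="consensus", consensus_subset=("ALA",)
        )
        assert 30.0 < metrics.accuracy_mean < 70.0

    def test_consensus_rule_uses_fixed_subset(self, small_panel):
        records = run_cv_selection(small_panel, CVConfig(k=5, repetitions=1, seed=2),
                                   CAIC, sizes=[1, 2])
        metrics = cv_prediction_metrics(
            records, small_panel, 2, subset_rule="consensus",
            consensus_subset=("A01", "A02"),
        )
        assert metrics.n_iterations == 5
        assert np.isfinite(metrics.threshold_mean)
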