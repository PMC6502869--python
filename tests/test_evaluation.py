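"""Tests for ROC analysis, the hierarchical bootstrap, and breakdowns."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from stainmap.evaluation import (
    SingleClassError, auc_score, bootstrap_ci, bootstrap_replicates,
    grade_group_breakdown, pvalue_by_ci_inversion, render_prediction_map,
    roc_curve, youden_cutoff,
)
from stainmap.grid import AnalysisSquare


def concordance_auc(scores, labels):
    """Brute-force pairwise concordance with ties counted 1/2."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation(self):
        curve = roc_curve(np.array([1, 2, 3, 10, 11, 12]),
                          np.array([0, 0, 0, 1, 1, 1]))
        assert curve.auc == 1.0

    def test_all_ties_give_half(self):
        curve = roc_curve(np.full(10, 5.0), np.array([0, 1] * 5))
        assert curve.auc == pytest.approx(0.5)

    def test_eight_point_instance_matches_pair_counting(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8, 0.8, 0.2, 0.7, 0.4])
        labels = np.array([0, 0, 1, 1, 0, 1, 1, 0])
        assert roc_curve(scores, labels).auc == pytest.approx(
            concordance_auc(scores, labels))

    def test_trapezoid_equals_concordance_on_random_instances(self):
        rng = np.random.default_rng(0)
        for n in (5, 20, 60, 200):
            scores = np.round(rng.normal(size=n), 1)  # force ties
            labels = rng.integers(0, 2, size=n)
            if len(np.unique(labels)) < 2:
                labels[0], labels[1] = 0, 1
            assert roc_curve(scores, labels).auc == pytest.approx(
                concordance_auc(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(SingleClassError):
            roc_curve(np.arange(4.0), np.ones(4))

    def test_curve_monotone_with_unit_endpoints(self):
        rng = np.random.default_rng(1)
        curve = roc_curve(rng.normal(size=50), rng.integers(0, 2, size=50))
        assert (np.diff(curve.fpr) >= 0).all() and (np.diff(curve.tpr) >= 0).all()
        assert curve.fpr[0] == curve.tpr[0] == 0.0
        assert curve.fpr[-1] == curve.tpr[-1] == 1.0


class TestYouden:
    def test_perfect_separation(self):
        curve = roc_curve(np.array([1.0, 2, 9, 10]), np.array([0, 0, 1, 1]))
        cutoff, sens, spec = youden_cutoff(curve)
        assert sens == 1.0 and spec == 1.0
        assert 2 < cutoff <= 9

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        curve = roc_curve(scores, labels)
        cutoff, sens, spec = youden_cutoff(curve)
        best = -np.inf
        for c in np.unique(scores):
            s = float(((scores >= c) & (labels == 1)).sum() / (labels == 1).sum())
            p = float(((scores < c) & (labels == 0)).sum() / (labels == 0).sum())
            best = max(best, s + p - 1)
        assert sens + spec - 1 == pytest.approx(best, abs=1e-12)

    def test_tie_prefers_higher_specificity(self):
        # two thresholds with equal J: scores 1,2 benign / 3,4 cancer but
        # with one error each side gives a J plateau
        scores = np.array([1.0, 3.0, 2.0, 4.0])
        labels = np.array([0, 0, 1, 1])
        curve = roc_curve(scores, labels)
        cutoff, sens, spec = youden_cutoff(curve)
        j = curve.tpr - curve.fpr
        plateau = np.flatnonzero(j == j.max())
        assert len(plateau) > 1
        assert spec == pytest.approx(1 - curve.fpr[plateau].min())


def grouped_dataset(rng, n_groups=20, per_group=10, delta=1.0):
    rows = []
    for g in range(n_groups):
        labels = np.array([0, 1] * (per_group // 2))
        scores = rng.normal(size=per_group) + delta * labels
        for s, y in zip(scores, labels):
            rows.append({"group": f"g{g}", "score": s, "y": y})
    return pd.DataFrame(rows)


def stat_auc(df):
    return auc_score(df["score"].to_numpy(), df["y"].to_numpy())


class TestBootstrap:
    def test_constant_statistic(self):
        rng = np.random.default_rng(3)
        data = grouped_dataset(rng)
        lo, hi = bootstrap_ci(lambda df: 7.5, data, n_boot=50, seed=0)
        assert (lo, hi) == (7.5, 7.5)

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(4)
        data = grouped_dataset(rng)
        point = stat_auc(data)
        lo, hi = bootstrap_ci(stat_auc, data, n_boot=300, seed=1)
        assert lo <= point <= hi

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(5)
        data = grouped_dataset(rng)
        a = bootstrap_replicates(stat_auc, data, n_boot=100, seed=9)
        b = bootstrap_replicates(stat_auc, data, n_boot=100, seed=9)
        assert np.array_equal(a, b)

    def test_test_mode_keeps_groups_intact(self):
        rng = np.random.default_rng(6)
        data = grouped_dataset(rng, n_groups=6, per_group=4)
        originals = {g: sorted(sub["score"]) for g, sub in data.groupby("group")}

        def audit(df):
            for g, sub in df.groupby("group"):
                scores = sorted(sub["score"])
                k = len(scores) // len(originals[g])
                assert scores == sorted(originals[g] * k)
            return 0.0

        bootstrap_replicates(audit, data, mode="test", n_boot=20, seed=2)

    def test_train_mode_resamples_within_groups(self):
        rng = np.random.default_rng(7)
        data = grouped_dataset(rng, n_groups=4, per_group=10)
        sizes = data.groupby("group").size()
        saw_within_resample = []

        def audit(df):
            merged = df.groupby("group").size()
            for g in merged.index:
                assert merged[g] % sizes[g] == 0
            # within-group duplication is the signature of the second level
            dup = df.groupby(["group", "score"]).size().max()
            saw_within_resample.append(dup > 1)
            return 0.0

        bootstrap_replicates(audit, data, mode="train", n_boot=20, seed=3)
        assert any(saw_within_resample)

    def test_single_class_replicates_redrawn(self):
        # one group is entirely benign; test-mode replicates drawing only
        # that group must be redrawn rather than crash
        rows = []
        for g, label in (("a", 0), ("b", 1)):
            for i in range(5):
                rows.append({"group": g, "score": float(i) + (5 if label else 0),
                             "y": label})
        data = pd.DataFrame(rows)
        reps = bootstrap_replicates(stat_auc, data, n_boot=50, seed=4)
        assert np.isfinite(reps).all()

    def test_nominal_coverage_on_synthetic_datasets(self):
        """Percentile CI coverage of a known AUC stays near the nominal 95%."""
        delta = 1.0
        true_auc = norm.cdf(delta / np.sqrt(2))
        rng = np.random.default_rng(8)
        hits = 0
        n_datasets = 200
        for _ in range(n_datasets):
            data = grouped_dataset(rng, n_groups=20, per_group=10, delta=delta)
            lo, hi = bootstrap_ci(stat_auc, data, mode="test", n_boot=300,
                                  seed=int(rng.integers(2**31)))
            hits += lo <= true_auc <= hi
        coverage = hits / n_datasets
        assert abs(coverage - 0.95) <= 0.05


class TestPValueInversion:
    def test_all_positive_differences(self):
        reps = np.abs(np.random.default_rng(9).normal(size=1000)) + 0.01
        assert pvalue_by_ci_inversion(reps) <= 0.002

    def test_symmetric_differences(self):
        base = np.random.default_rng(10).normal(size=500)
        reps = np.concatenate([base, -base])
        assert pvalue_by_ci_inversion(reps) >= 0.99

    def test_agrees_with_direct_tail_probability(self):
        rng = np.random.default_rng(11)
        for shift in (0.5, 1.0, 2.0):
            reps = rng.normal(loc=shift, scale=1.0, size=2000)
            p = pvalue_by_ci_inversion(reps)
            direct = 2 * min((reps <= 0).mean(), (reps >= 0).mean())
            assert p == pytest.approx(max(direct, 1 / len(reps)), abs=0.01)


class TestGradeGroupBreakdown:
    def test_grade_group_assignment(self):
        scores = np.array([5.0, 5.0, 5.0, 0.0])
        labels = np.array([1, 1, 1, 0])
        gleason = ["3 + 4", "4 + 3", "3 + 3", None]
        table = grade_group_breakdown(scores, 1.0, gleason, labels)
        low = table[table["type"] == "GG <= 2"].iloc[0]
        high = table[table["type"] == "GG >= 3"].iloc[0]
        assert low["n_squares"] == 2 and high["n_squares"] == 1
        assert table[table["type"] == "Totals"].iloc[0]["n_squares"] == 3

    def test_all_detected_gives_unit_sensitivity(self):
        scores = np.full(6, 10.0)
        labels = np.ones(6, dtype=int)
        labels[-1] = 0
        gleason = ["3 + 3", "3 + 4", "4 + 3", "4 + 4", "5 + 4", None]
        table = grade_group_breakdown(scores, 1.0, gleason, labels)
        assert (table["sensitivity"].dropna() == 1.0).all()

    def test_counts_partition_totals(self):
        rng = np.random.default_rng(12)
        gs_pool = ["3 + 3", "3 + 4", "4 + 3", "4 + 4", "4 + 5", "5 + 4"]
        labels = rng.integers(0, 2, size=60)
        gleason = [gs_pool[i % 6] if y else None for i, y in enumerate(labels)]
        scores = rng.normal(size=60)
        table = grade_group_breakdown(scores, 0.0, gleason, labels)
        low = int(table[table["type"] == "GG <= 2"]["n_squares"].iloc[0])
        high = int(table[table["type"] == "GG >= 3"]["n_squares"].iloc[0])
        total = int(table[table["type"] == "Totals"]["n_squares"].iloc[0])
        assert low + high == total == labels.sum()


class TestPredictionMap:
    def _grid(self):
        return [AnalysisSquare(row=r, col=c, bounds=(c * 10, r * 10,
                                                     (c + 1) * 10, (r + 1) * 10))
                for r in range(2) for c in range(3)]

    def test_all_zero_predictions_empty_mask(self):
        heat, mask = render_prediction_map(self._grid(), np.zeros(6), 2.6, (20, 30))
        assert not mask.any()
        assert np.nanmax(heat) == 0.0

    def test_single_square_above_cutoff(self):
        preds = np.zeros(6)
        preds[4] = 50.0
        heat, mask = render_prediction_map(self._grid(), preds, 2.6, (20, 30))
        expected = np.zeros((20, 30), dtype=bool)
        expected[10:20, 10:20] = True
        assert np.array_equal(mask, expected)

    def test_mask_consistent_with_thresholding(self):
        rng = np.random.default_rng(13)
        grid = self._grid()
        preds = rng.uniform(0, 100, size=6)
        cutoff = 40.0
        _, mask = render_prediction_map(grid, preds, cutoff, (20, 30))
        for sq, p in zip(grid, preds):
            x0, y0, x1, y1 = sq.bounds
            assert mask[y0:y1, x0:x1].all() == (p > cutoff)
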