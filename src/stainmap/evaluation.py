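"""Square-level evaluation: ROC analysis, hierarchical bootstrap, and
grade-group breakdowns.

Predicted % malignant epithelium (raw, unclipped) is scored against the
square labels with ROC curve analysis; the operating cutoff is the
maximum of the Youden index (sensitivity + specificity - 1). Confidence
intervals come from a hierarchical bootstrap that respects the grouping
of analysis squares within WSI pairs: the test-set procedure resamples
whole pairs only, while the training-set procedure resamples pairs and
then squares within each sampled pair. Two-sided p-values for paired
statistic differences are obtained by inverting the bootstrap CIs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

from .grid import AnalysisSquare

logger = logging.getLogger(__name__)

__all__ = [
    "ROCCurve",
    "EvalSummary",
    "roc_curve",
    "youden_cutoff",
    "auc_score",
    "bootstrap_replicates",
    "bootstrap_ci",
    "pvalue_by_ci_inversion",
    "grade_group_breakdown",
    "render_prediction_map",
    "GG_LOW_INTERMEDIATE",
    "GG_HIGH",
]

#: Gleason grade-group convention: GG <= 2 is low/intermediate, GG >= 3 high.
GG_LOW_INTERMEDIATE = ("3 + 3", "3 + 4")
GG_HIGH = ("4 + 3", "4 + 4", "4 + 5", "5 + 4")


class SingleClassError(ValueError):
    """ROC is undefined when only one class is present."""


@dataclass(frozen=True)
class ROCCurve:
    thresholds: np.ndarray   # descending; predicted positive when score >= threshold
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass(frozen=True)
class EvalSummary:
    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    ci_auc: tuple[float, float]
    ci_sens: tuple[float, float]
    ci_spec: tuple[float, float]
    n_boot: int
    seed: int


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> ROCCurve:
    """ROC over all distinct score thresholds; AUC by the trapezoid rule
    (equal to the pairwise concordance probability with ties counted 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise SingleClassError("ROC requires both classes to be present")
    fpr, tpr, thresholds = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def auc_score(scores: np.ndarray, labels: np.ndarray) -> float:
    return roc_curve(scores, labels).auc


def youden_cutoff(curve: ROCCurve) -> tuple[float, float, float]:
    """(cutoff, sensitivity, specificity) at the Youden-index maximum.

    Ties in J = tpr - fpr are broken toward higher specificity.
    """
    j = curve.tpr - curve.fpr
    best = j.max()
    tied = np.flatnonzero(j == best)
    idx = tied[np.argmin(curve.fpr[tied])]
    return float(curve.thresholds[idx]), float(curve.tpr[idx]), float(1.0 - curve.fpr[idx])


def _group_indices(groups: np.ndarray) -> dict:
    idx = {}
    for g in np.unique(groups):
        idx[g] = np.flatnonzero(groups == g)
    return idx


def bootstrap_replicates(statistic: Callable[[pd.DataFrame], float],
                         data: pd.DataFrame,
                         mode: str = "test",
                         n_boot: int = 1000,
                         seed: int = 0,
                         group_col: str = "group",
                         max_redraws: int = 100_000) -> np.ndarray:
    """Hierarchical bootstrap replicates of a statistic.

    ``mode="test"`` resamples WSI-pair groups with replacement, keeping
    every square of each sampled group; ``mode="train"`` additionally
    resamples squares with replacement within each sampled group (at the
    group's original size). Replicates on which the statistic is undefined
    (single-class resample) are redrawn and counted.
    """
    if mode not in ("test", "train"):
        raise ValueError("mode must be 'test' or 'train'")
    groups = data[group_col].to_numpy()
    by_group = _group_indices(groups)
    names = list(by_group)
    if len(names) < 2:
        raise ValueError("bootstrap requires at least two groups")
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    redraws = 0
    i = 0
    while i < n_boot:
        chosen = rng.integers(0, len(names), size=len(names))
        parts = []
        for gi in chosen:
            rows = by_group[names[gi]]
            if mode == "train":
                rows = rows[rng.integers(0, len(rows), size=len(rows))]
            parts.append(rows)
        idx = np.concatenate(parts)
        try:
            reps[i] = statistic(data.take(idx))
        except SingleClassError:
            redraws += 1
            if redraws > max_redraws:
                raise RuntimeError("bootstrap could not draw two-class replicates")
            continue
        i += 1
    if redraws:
        logger.info("bootstrap redrew %d single-class replicates", redraws)
    return reps


def bootstrap_ci(statistic: Callable[[pd.DataFrame], float],
                 data: pd.DataFrame,
                 mode: str = "test",
                 n_boot: int = 1000,
                 level: float = 0.95,
                 seed: int = 0,
                 group_col: str = "group") -> tuple[float, float]:
    """Seeded percentile bootstrap CI of ``statistic`` at ``level``."""
    reps = bootstrap_replicates(statistic, data, mode=mode, n_boot=n_boot,
                                seed=seed, group_col=group_col)
    lo, hi = np.quantile(reps, [(1 - level) / 2, (1 + level) / 2])
    return float(lo), float(hi)


def pvalue_by_ci_inversion(replicates: np.ndarray, grid_step: float = 0.001) -> float:
    """Two-sided p-value for a statistic difference by CI inversion.

    The p-value is the smallest alpha on a grid for which the
    (1 - alpha) percentile CI of the bootstrap difference replicates
    excludes zero, floored at 1/n_replicates (the resolution the
    replicate set can support).
    """
    reps = np.asarray(replicates, dtype=float)
    floor = 1.0 / len(reps)
    alphas = np.arange(grid_step, 1.0 + grid_step / 2, grid_step)
    qs = np.quantile(reps, np.concatenate([alphas / 2, 1 - alphas / 2]))
    lo, hi = qs[:len(alphas)], qs[len(alphas):]
    excludes = (lo > 0) | (hi < 0)
    if not excludes.any():
        return 1.0
    return float(max(alphas[excludes.argmax()], floor))


def grade_group_breakdown(scores: np.ndarray, cutoff: float,
                          gleason: Sequence[str | None],
                          labels: np.ndarray) -> pd.DataFrame:
    """Sensitivity of cancer detection broken down by Gleason score and
    grade group (predicted positive when score >= cutoff).

    Returns one row per observed Gleason score plus aggregated
    ``GG <= 2`` / ``GG >= 3`` and ``Totals`` rows. Cancer squares with a
    Gleason score outside the known vocabulary contribute to the totals
    but not to the grouped rows.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    gleason = np.asarray([g if g is not None else "" for g in gleason], dtype=object)
    cancer = labels == 1
    predicted = scores >= cutoff

    rows = []

    def add_row(name: str, mask: np.ndarray) -> None:
        n = int(mask.sum())
        correct = int((mask & predicted).sum())
        rows.append({"type": name, "n_squares": n, "n_correct": correct,
                     "sensitivity": correct / n if n else np.nan})

    known = set(GG_LOW_INTERMEDIATE) | set(GG_HIGH)
    observed = [g for g in sorted(set(gleason[cancer])) if g]
    for gs in observed:
        if gs not in known:
            logger.warning("unknown Gleason score %r excluded from grade-group rows", gs)
        add_row(gs, cancer & (gleason == gs))
    add_row("GG <= 2", cancer & np.isin(gleason, GG_LOW_INTERMEDIATE))
    add_row("GG >= 3", cancer & np.isin(gleason, GG_HIGH))
    add_row("Totals", cancer)
    return pd.DataFrame(rows)


def render_prediction_map(grid: Sequence[AnalysisSquare],
                          predictions: Mapping[str, float] | np.ndarray,
                          cutoff: float,
                          image_shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Per-square prediction heatmap and thresholded outline mask.

    ``predictions`` is either an array aligned with ``grid`` or a mapping
    from square_id. The heatmap carries the (clipped) predicted
    % malignant epithelium over each square's pixels (NaN outside the
    grid); the binary mask marks squares with prediction strictly above
    the cutoff.
    """
    heat = np.full(image_shape, np.nan)
    mask = np.zeros(image_shape, dtype=bool)
    for i, sq in enumerate(grid):
        if isinstance(predictions, Mapping):
            if sq.square_id not in predictions:
                continue
            value = predictions[sq.square_id]
        else:
            value = predictions[i]
        x0, y0, x1, y1 = sq.bounds
        heat[y0:y1, x0:x1] = np.clip(value, 0.0, 100.0)
        if value > cutoff:
            mask[y0:y1, x0:x1] = True
    return heat, mask
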