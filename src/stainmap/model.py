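"""Elastic-net regression of % cancerous epithelium.

The model minimizes

    (1/2m) ||X w - y||_2^2  +  alpha rho ||w||_1  +  (alpha (1-rho)/2) ||w||_2^2

over the feature weights ``w``, where ``m`` is the number of training
examples. Features are standardized (zero mean, unit variance, statistics
from the training portion only) before penalization and an unpenalized
intercept is carried; ``y`` stays on its native 0-100 scale.
Optimization is cyclic coordinate descent with soft-thresholding,
started at w = 0 and iterated until the largest weight change falls
below ``tol``.

Hyperparameters (alpha, rho) are selected by grouped cross-validation in
which each fold holds out all analysis squares of a single WSI pair, and
the selection criterion is the mean held-out value of the penalized
objective itself (held-out MSE is available as an alternative criterion).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingSet",
    "ElasticNetSpec",
    "objective",
    "fit",
    "cross_validate",
    "select_hyperparameters",
    "predict",
    "DEFAULT_ALPHA_GRID",
    "DEFAULT_RHO_GRID",
]

DEFAULT_ALPHA_GRID: tuple[float, ...] = tuple(np.logspace(-4, 1, 13))
DEFAULT_RHO_GRID: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9, 1.0)


@dataclass(frozen=True)
class TrainingSet:
    """Feature matrix, % cancerous epithelium targets, and WSI-pair groups."""

    X: np.ndarray
    y: np.ndarray
    groups: np.ndarray
    feature_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=float)
        groups = np.asarray(self.groups)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (examples x features)")
        if len(y) != X.shape[0] or len(groups) != X.shape[0]:
            raise ValueError("X, y and groups must agree on the number of examples")
        if np.any(y < 0) or np.any(y > 100):
            raise ValueError("targets must be percentages in [0, 100]")
        if self.feature_names and len(self.feature_names) != X.shape[1]:
            raise ValueError("feature_names length must match X columns")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "groups", groups)

    @property
    def m(self) -> int:
        return self.X.shape[0]

    @property
    def n(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class ElasticNetSpec:
    """A fitted elastic net: weights on the standardized scale plus the
    standardization parameters needed to apply it to raw features."""

    omega: np.ndarray
    intercept: float
    alpha: float
    rho: float
    feature_set: str = "full"
    mean: np.ndarray = field(default_factory=lambda: np.zeros(0))
    scale: np.ndarray = field(default_factory=lambda: np.ones(0))
    feature_names: tuple[str, ...] = ()

    def to_json(self) -> str:
        return json.dumps({
            "omega": list(map(float, self.omega)),
            "intercept": float(self.intercept),
            "alpha": float(self.alpha),
            "rho": float(self.rho),
            "feature_set": self.feature_set,
            "mean": list(map(float, self.mean)),
            "scale": list(map(float, self.scale)),
            "feature_names": list(self.feature_names),
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ElasticNetSpec":
        d = json.loads(text)
        return cls(omega=np.asarray(d["omega"], dtype=float),
                   intercept=float(d["intercept"]),
                   alpha=float(d["alpha"]), rho=float(d["rho"]),
                   feature_set=d.get("feature_set", "full"),
                   mean=np.asarray(d["mean"], dtype=float),
                   scale=np.asarray(d["scale"], dtype=float),
                   feature_names=tuple(d.get("feature_names", ())))


def objective(X: np.ndarray, y: np.ndarray, omega: np.ndarray,
              alpha: float, rho: float, intercept: float = 0.0) -> float:
    """Evaluate the penalized objective on (X, y) for weights ``omega``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    omega = np.asarray(omega, dtype=float)
    if X.shape[0] != len(y) or X.shape[1] != len(omega):
        raise ValueError(f"shape mismatch: X {X.shape}, y {y.shape}, omega {omega.shape}")
    if alpha < 0 or not (0.0 <= rho <= 1.0):
        raise ValueError("alpha must be >= 0 and rho in [0, 1]")
    m = X.shape[0]
    resid = X @ omega + intercept - y
    return (float(resid @ resid) / (2 * m)
            + alpha * rho * float(np.abs(omega).sum())
            + alpha * (1 - rho) / 2 * float(omega @ omega))


def _soft_threshold(z: float, gamma: float) -> float:
    if z > gamma:
        return z - gamma
    if z < -gamma:
        return z + gamma
    return 0.0


def _coordinate_descent(Xs: np.ndarray, yc: np.ndarray, alpha: float, rho: float,
                        tol: float = 1e-8, max_iter: int = 5_000) -> np.ndarray:
    """Minimize the objective on standardized features / centered targets.

    Cyclic coordinate descent on the Gram formulation: for n features the
    per-coordinate update needs only X'X and X'y. With exactly collinear
    columns and alpha near 0 the weight vector is not unique and the
    sweep-to-sweep change decays slowly; the iteration cap then returns a
    point whose objective is converged even though individual weights may
    still drift along the flat direction.
    """
    m, n = Xs.shape
    omega = np.zeros(n)
    gram = (Xs.T @ Xs) / m
    xty = (Xs.T @ yc) / m
    diag = np.diag(gram).copy()
    l1 = alpha * rho
    l2 = alpha * (1 - rho)
    grad_cache = xty - gram @ omega              # (1/m) X'(yc - Xs omega)
    y_half = float(yc @ yc) / (2 * m)

    def current_objective() -> float:
        quad = y_half - float(xty @ omega) + float(omega @ (gram @ omega)) / 2
        return quad + l1 * float(np.abs(omega).sum()) + l2 / 2 * float(omega @ omega)

    last_obj = current_objective()
    for it in range(max_iter):
        max_delta = 0.0
        for j in range(n):
            if diag[j] == 0.0:
                continue
            old = omega[j]
            zj = grad_cache[j] + diag[j] * old
            new = _soft_threshold(zj, l1) / (diag[j] + l2)
            if new != old:
                grad_cache -= gram[:, j] * (new - old)
                omega[j] = new
                max_delta = max(max_delta, abs(new - old))
        if max_delta < tol:
            break
        if (it + 1) % 20 == 0:
            # flat-direction guard for collinear columns at alpha ~ 0: the
            # objective converges long before individual weights settle
            obj = current_objective()
            if last_obj - obj < 1e-10 * (1.0 + abs(obj)):
                break
            last_obj = obj
    else:
        logger.debug("coordinate descent stopped at max_iter=%d (max sweep change %.3g)",
                     max_iter, max_delta)
    return omega


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    degenerate = scale == 0
    if degenerate.any():
        logger.info("constant feature column(s) %s; weights forced to 0",
                    np.flatnonzero(degenerate).tolist())
        scale = np.where(degenerate, 1.0, scale)
    return (X - mean) / scale, mean, scale


def fit(train: TrainingSet, alpha: float, rho: float, feature_set: str = "full",
        tol: float = 1e-8) -> ElasticNetSpec:
    """Fit the elastic net on standardized features; deterministic."""
    if train.m < 1:
        raise ValueError("at least one training example is required")
    # a single example yields the intercept-only model (all features are
    # constant after centering), which leave-one-group-out CV relies on
    if alpha < 0 or not (0.0 <= rho <= 1.0):
        raise ValueError("alpha must be >= 0 and rho in [0, 1]")
    Xs, mean, scale = _standardize(train.X)
    ybar = float(train.y.mean())
    omega = _coordinate_descent(Xs, train.y - ybar, alpha, rho, tol=tol)
    return ElasticNetSpec(omega=omega, intercept=ybar, alpha=alpha, rho=rho,
                          feature_set=feature_set, mean=mean, scale=scale,
                          feature_names=train.feature_names)


def predict(spec: ElasticNetSpec, X_new: np.ndarray, clip: bool = False) -> np.ndarray:
    """Predicted % cancerous epithelium (raw; set ``clip`` for [0, 100])."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != len(spec.omega):
        raise ValueError(f"expected {len(spec.omega)} feature columns, got {X_new.shape[1]}")
    Xs = (X_new - spec.mean) / spec.scale
    out = spec.intercept + Xs @ spec.omega
    return np.clip(out, 0.0, 100.0) if clip else out


def _heldout_value(spec: ElasticNetSpec, X: np.ndarray, y: np.ndarray,
                   criterion: str) -> float:
    Xs = (X - spec.mean) / spec.scale
    if criterion == "objective":
        return objective(Xs, y - spec.intercept, spec.omega, spec.alpha, spec.rho)
    if criterion == "mse":
        resid = predict(spec, X) - y
        return float((resid ** 2).mean())
    raise ValueError(f"unknown criterion {criterion!r}")


def cross_validate(train: TrainingSet, alpha: float, rho: float,
                   feature_set: str = "full",
                   criterion: str = "objective") -> tuple[np.ndarray, float]:
    """Leave-one-WSI-pair-out cross-validation.

    Each fold holds out all squares of one group; the held-out value of
    the chosen criterion (penalized objective by default) is computed with
    weights fitted on the remaining groups. Returns (per-fold values in
    sorted-group order, their mean).
    """
    unique_groups = np.unique(train.groups)
    if len(unique_groups) < 2:
        raise ValueError("cross-validation needs at least two distinct groups")
    values = []
    for g in unique_groups:
        test = train.groups == g
        if np.ptp(train.y[test]) == 0:
            logger.info("fold %r has constant targets; retained", g)
        sub = TrainingSet(train.X[~test], train.y[~test], train.groups[~test],
                          train.feature_names)
        spec = fit(sub, alpha, rho, feature_set=feature_set)
        values.append(_heldout_value(spec, train.X[test], train.y[test], criterion))
    per_fold = np.asarray(values)
    return per_fold, float(per_fold.mean())


def select_hyperparameters(train: TrainingSet,
                           alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
                           rho_grid: Sequence[float] = DEFAULT_RHO_GRID,
                           feature_set: str = "full",
                           criterion: str = "objective") -> tuple[float, float, list[dict]]:
    """Grid-search (alpha, rho) minimizing the mean CV criterion.

    Ties are broken toward larger alpha, then larger rho (the sparser
    model). Returns (alpha*, rho*, per-grid-point report records).
    """
    if not len(alpha_grid) or not len(rho_grid):
        raise ValueError("hyperparameter grids must be non-empty")
    report = []
    for alpha in alpha_grid:
        for rho in rho_grid:
            _, mean_value = cross_validate(train, alpha, rho, feature_set=feature_set,
                                           criterion=criterion)
            report.append({"alpha": float(alpha), "rho": float(rho),
                           "mean_cv_value": mean_value})
    best_value = min(r["mean_cv_value"] for r in report)
    ties = [r for r in report if r["mean_cv_value"] == best_value]
    best = max(ties, key=lambda r: (r["alpha"], r["rho"]))
    return best["alpha"], best["rho"], report
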