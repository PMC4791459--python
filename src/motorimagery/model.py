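"""RBF-kernel SVM with grid-searched hyperparameters under k-fold cross-validation.

The classifier is a soft-margin support vector machine,

    min  (1/2)||a||^2 + c * sum_i xi_i
    s.t. w_i y(x_i) >= 1 - xi_i,  xi_i >= 0,

solved in its dual under the radial basis function kernel
``k(u, v) = exp(-gamma ||u - v||^2)``.  The penalty ``c`` and kernel width
``gamma`` are chosen by an exhaustive grid search over ``c in (0, 100]`` and
``gamma in (0, 3]``, scoring each pair by stratified k-fold (default tenfold)
cross-validation accuracy.

Two details matter for honest accuracy estimates on segmented trial data:

* features are standardized (per-feature center/spread) using statistics of
  the *training* portion only, refit inside every fold;
* folds are stratified at the *trial* level, with all segments of a trial
  following it into the same fold, so within-trial correlation cannot leak
  across the split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from .features import FeatureMatrix

__all__ = [
    "SVMConfig",
    "TrainedSVM",
    "GridSpec",
    "CVReport",
    "rbf_kernel",
    "train_svm",
    "predict_svm",
    "grid_search",
    "evaluate",
    "stratified_trial_folds",
]


@dataclass(frozen=True)
class SVMConfig:
    """RBF-SVM hyperparameters: penalty factor ``c`` and kernel width ``gamma``."""

    c: float = 10.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if not self.c > 0:
            raise ValueError(f"penalty factor c must be > 0, got {self.c}")
        if not self.gamma > 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")


@dataclass
class TrainedSVM:
    """A fitted SVM plus the feature scaling frozen from its training data."""

    svc: SVC
    config: SVMConfig
    center: np.ndarray
    spread: np.ndarray
    classes: np.ndarray

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self.svc.decision_function(self._scale(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.svc.predict(self._scale(X))

    def _scale(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.center) / self.spread


@dataclass(frozen=True)
class GridSpec:
    """Hyperparameter grid and CV protocol for model selection.

    Default grid: ``c`` in {1, 5, 10, 15, 30, 50, 70, 90, 100} and ``gamma``
    in {0.1, 0.2, ..., 3.0} — a coarse-in-c, fine-in-gamma tiling of the
    search region c in (0, 100], gamma in (0, 3].
    """

    c_values: tuple[float, ...] = (1, 5, 10, 15, 30, 50, 70, 90, 100)
    gamma_values: tuple[float, ...] = tuple(round(0.1 * k, 1) for k in range(1, 31))
    folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.c_values):
            raise ValueError("all c values must be > 0")
        if any(g <= 0 for g in self.gamma_values):
            raise ValueError("all gamma values must be > 0")
        if self.folds < 2:
            raise ValueError(f"folds must be >= 2, got {self.folds}")


@dataclass
class CVReport:
    """Cross-validation outcome: per-fold accuracies, selected model, errors.

    ``grid_accuracies[i, j]`` is the mean CV accuracy at
    ``(c_values[i], gamma_values[j])``; ``cumulative_errors`` counts
    misclassified segments over the concatenated, fold-ordered test sets.
    """

    fold_accuracies: np.ndarray  # percent, one per fold (of the best config)
    best_config: SVMConfig | None = None
    grid_accuracies: np.ndarray | None = None
    c_values: tuple[float, ...] = ()
    gamma_values: tuple[float, ...] = ()
    confusion: np.ndarray = field(default_factory=lambda: np.zeros((2, 2), dtype=int))
    cumulative_errors: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    class_names: Sequence[str] = ()

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1)) if len(self.fold_accuracies) > 1 else 0.0

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "best_config": None
            if self.best_config is None
            else {"c": self.best_config.c, "gamma": self.best_config.gamma},
            "confusion": self.confusion.tolist(),
            "cumulative_errors": self.cumulative_errors.tolist(),
            "class_names": list(self.class_names),
        }
        if self.grid_accuracies is not None:
            payload["grid"] = {
                "c_values": list(self.c_values),
                "gamma_values": list(self.gamma_values),
                "mean_accuracies": self.grid_accuracies.tolist(),
            }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def grid_to_tsv(self, path: str | Path) -> None:
        if self.grid_accuracies is None:
            raise ValueError("report holds no accuracy grid")
        import pandas as pd

        df = pd.DataFrame(
            self.grid_accuracies,
            index=[f"c={c:g}" for c in self.c_values],
            columns=[f"gamma={g:g}" for g in self.gamma_values],
        )
        df.to_csv(path, sep="\t")


def rbf_kernel(u: np.ndarray, v: np.ndarray, gamma: float) -> float:
    """The radial basis function kernel exp(-gamma * ||u - v||^2)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    return float(np.exp(-gamma * np.sum(np.square(u - v))))


def _check_two_classes(y: np.ndarray) -> np.ndarray:
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training data contains a single class")
    if len(classes) > 2:
        raise ValueError(f"binary classifier got {len(classes)} classes")
    return classes


def train_svm(F: FeatureMatrix, cfg: SVMConfig = SVMConfig()) -> TrainedSVM:
    """Fit the soft-margin RBF-SVM on a two-class feature matrix.

    Features are standardized with training-set statistics that are stored in
    the returned model; the fit is deterministic for fixed input.
    """
    X = F.values
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")
    classes = _check_two_classes(F.labels)
    center = X.mean(axis=0)
    spread = X.std(axis=0)
    spread = np.where(spread > 0, spread, 1.0)
    # scale by sqrt(d) on top of per-feature standardization so that
    # ||u - v||^2 is O(1) regardless of feature count; this makes gamma
    # dimension-free and puts the search interval (0, 3] in the regime where
    # the kernel actually varies across the data
    spread = spread * np.sqrt(X.shape[1])
    svc = SVC(C=cfg.c, gamma=cfg.gamma, kernel="rbf", tol=1e-8, cache_size=200)
    svc.fit((X - center) / spread, F.labels)
    return TrainedSVM(svc=svc, config=cfg, center=center, spread=spread, classes=classes)


def predict_svm(model: TrainedSVM, X: np.ndarray) -> np.ndarray:
    """Predict class codes for raw (unscaled) feature rows."""
    return model.predict(X)


def stratified_trial_folds(
    trial_labels: np.ndarray,
    k: int,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Assign trials to ``k`` stratified folds; returns per-fold trial index arrays.

    Within each class, trials are shuffled and dealt round-robin, so fold
    class proportions match the data as closely as integer counts allow.
    """
    trial_labels = np.asarray(trial_labels)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(trial_labels):
        idx = np.flatnonzero(trial_labels == cls)
        if len(idx) < k:
            raise ValueError(
                f"class {cls} has {len(idx)} trials, fewer than {k} folds"
            )
        idx = rng.permutation(idx)
        for j, t in enumerate(idx):
            folds[j % k].append(int(t))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def _trial_table(F: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Unique trial ids and one label per trial (segments inherit trial labels)."""
    if F.trial_ids is None:
        trials = np.arange(F.n_segments)
        return trials, F.labels
    trials, first = np.unique(F.trial_ids, return_index=True)
    return trials, F.labels[first]


def _segment_folds(F: FeatureMatrix, k: int, seed: int) -> list[np.ndarray]:
    """Trial-level stratified folds, expressed as segment index arrays."""
    trials, trial_labels = _trial_table(F)
    rng = np.random.default_rng(seed)
    trial_folds = stratified_trial_folds(trial_labels, k, rng)
    if F.trial_ids is None:
        return trial_folds
    return [np.flatnonzero(np.isin(F.trial_ids, trials[tf])) for tf in trial_folds]


def _subset(F: FeatureMatrix, idx: np.ndarray) -> FeatureMatrix:
    return FeatureMatrix(
        values=F.values[idx],
        feature_names=F.feature_names,
        labels=F.labels[idx],
        trial_ids=None if F.trial_ids is None else F.trial_ids[idx],
        class_names=F.class_names,
    )


def _cv_predictions(
    F: FeatureMatrix, cfg: SVMConfig, folds: list[np.ndarray]
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Out-of-fold predictions for every segment, scaling refit per fold."""
    pred = np.empty(F.n_segments, dtype=int)
    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(F.n_segments), test_idx)
        model = train_svm(_subset(F, train_idx), cfg)
        pred[test_idx] = model.predict(F.values[test_idx])
    accs = [100.0 * np.mean(pred[t] == F.labels[t]) for t in folds]
    return pred, [np.asarray(a) for a in accs]


def grid_search(F: FeatureMatrix, grid: GridSpec = GridSpec()) -> CVReport:
    """Exhaustive (c, gamma) search scored by stratified k-fold CV accuracy.

    Returns the full accuracy grid and the best pair (ties broken toward the
    smallest ``c``, then the smallest ``gamma``), with per-fold accuracies,
    confusion counts and the cumulative error curve of the winning pair.
    Bit-for-bit reproducible for a fixed ``grid.seed``.
    """
    _check_two_classes(F.labels)
    folds = _segment_folds(F, grid.folds, grid.seed)
    acc_grid = np.empty((len(grid.c_values), len(grid.gamma_values)))
    for i, c in enumerate(grid.c_values):
        for j, g in enumerate(grid.gamma_values):
            _, accs = _cv_predictions(F, SVMConfig(c=c, gamma=g), folds)
            acc_grid[i, j] = np.mean(accs)
    best_i, best_j = np.unravel_index(np.argmax(acc_grid), acc_grid.shape)
    # argmax returns the first maximum in row-major order, which is already
    # the smallest-c-then-smallest-gamma tie-break given ascending grids
    best = SVMConfig(c=grid.c_values[best_i], gamma=grid.gamma_values[best_j])
    pred, accs = _cv_predictions(F, best, folds)
    order = np.concatenate(folds)
    errors = (pred[order] != F.labels[order]).astype(int)
    n_classes = len(np.unique(F.labels))
    confusion = np.zeros((n_classes, n_classes), dtype=int)
    for t, p in zip(F.labels, pred):
        confusion[t, p] += 1
    return CVReport(
        fold_accuracies=np.array([float(a) for a in accs]),
        best_config=best,
        grid_accuracies=acc_grid,
        c_values=tuple(grid.c_values),
        gamma_values=tuple(grid.gamma_values),
        confusion=confusion,
        cumulative_errors=np.cumsum(errors),
        class_names=list(F.class_names),
    )


def evaluate(
    F_train: FeatureMatrix,
    F_test: FeatureMatrix,
    cfg: SVMConfig = SVMConfig(),
) -> tuple[float, np.ndarray]:
    """Train on ``F_train``, test on ``F_test``; returns (accuracy %, confusion).

    Refuses train/test splits that share a trial: segments of one trial are
    strongly correlated and must not straddle the split.
    """
    if F_train.trial_ids is not None and F_test.trial_ids is not None:
        shared = np.intersect1d(F_train.trial_ids, F_test.trial_ids)
        if len(shared):
            raise ValueError(
                f"train/test leakage: trials {shared.tolist()} appear on both sides"
            )
    model = train_svm(F_train, cfg)
    pred = model.predict(F_test.values)
    accuracy = 100.0 * float(np.mean(pred == F_test.labels))
    n_classes = max(len(np.unique(F_train.labels)), len(np.unique(F_test.labels)))
    confusion = np.zeros((n_classes, n_classes), dtype=int)
    for t, p in zip(F_test.labels, pred):
        confusion[t, p] += 1
    return accuracy, confusion
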