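"""Comparison pipelines: CSP, filter-bank CSP and logarithmic band power.

All three feed a shrinkage-regularized linear discriminant:

* **CSP** — spatial filters from simultaneous diagonalization of the two
  class-average covariance matrices; the projected log-variance of the most
  discriminative components are the features.
* **FBCSP** — CSP fitted independently inside each band of a filter bank;
  the pooled log-variance features are ranked by mutual information with the
  class label and the top few retained.
* **Band power** — per channel and band, the log variance of the band-pass
  filtered signal (the classical Graz-style feature).

Band filtering inside the filter bank uses a zero-phase 4th-order Butterworth,
which realizes narrow (4 Hz) bands on 250-sample windows where a long FIR
cannot be applied.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import scipy.linalg
from scipy import signal
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .features import FeatureMatrix
from .model import CVReport, stratified_trial_folds
from .preprocess import SegmentSet

__all__ = [
    "SpatialFilterBank",
    "FilterBankSpec",
    "LDAModel",
    "fit_csp",
    "csp_from_covariances",
    "csp_features",
    "fit_fbcsp",
    "fbcsp_features",
    "bandpower_features",
    "fit_lda",
    "predict_lda",
    "crossval_baseline",
    "mutual_information",
]

#: Default filter bank: 4 Hz bands tiling 4-40 Hz, clipped to the 6-40 Hz
#: analysis band (so the lowest band is 6-8 Hz).
DEFAULT_BANDS: tuple[tuple[float, float], ...] = (
    (6, 8), (8, 12), (12, 16), (16, 20), (20, 24),
    (24, 28), (28, 32), (32, 36), (36, 40),
)


@dataclass
class SpatialFilterBank:
    """CSP projection matrix with the eigenvalue of each retained component.

    ``W`` holds one spatial filter per column; eigenvalues are the class-1
    variance fractions of each component, ordered so the first ``n_pairs``
    are the largest and the last ``n_pairs`` the smallest.
    """

    W: np.ndarray  # channels x components
    eigenvalues: np.ndarray
    band: tuple[float, float] | None = None
    n_pairs: int = 3

    @property
    def n_components(self) -> int:
        return self.W.shape[1]


@dataclass(frozen=True)
class FilterBankSpec:
    """Filter bank bands and the number of pooled CSP features to keep."""

    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS
    n_select: int = 12

    def __post_init__(self) -> None:
        for lo, hi in self.bands:
            if not 0 < lo < hi:
                raise ValueError(f"invalid band ({lo}, {hi})")
        if self.n_select < 1:
            raise ValueError("n_select must be >= 1")


@dataclass
class LDAModel:
    """Linear decision function w.x + b; positive side is ``classes[1]``."""

    weights: np.ndarray
    bias: float
    classes: np.ndarray


# ---------------------------------------------------------------------------
# CSP


def _class_covariances(segs: SegmentSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Trace-normalized per-segment covariances, averaged within each class."""
    classes = np.unique(segs.labels)
    if len(classes) != 2:
        raise ValueError(f"CSP needs exactly 2 classes, got {len(classes)}")
    covs = []
    for cls in classes:
        X = segs.data[segs.labels == cls]
        if X.shape[0] < 2:
            raise ValueError(f"class {cls} has fewer than 2 segments")
        C = np.einsum("scn,sdn->scd", X, X) / X.shape[2]
        tr = np.trace(C, axis1=1, axis2=2)
        if np.any(tr <= 0):
            raise ValueError("zero-variance segment encountered in covariance estimation")
        covs.append(np.mean(C / tr[:, None, None], axis=0))
    return covs[0], covs[1], classes


def csp_from_covariances(
    C1: np.ndarray,
    C2: np.ndarray,
    n_pairs: int = 3,
    band: tuple[float, float] | None = None,
) -> SpatialFilterBank:
    """Spatial filters from two class covariance matrices.

    Solves the generalized eigenproblem ``C1 w = lambda (C1 + C2) w`` so that
    ``W.T (C1 + C2) W = I`` and ``W.T C1 W`` is diagonal; returns the
    ``n_pairs`` most extreme components from each end of the spectrum.  Each
    eigenvalue is the fraction of composite variance carried by class 1 in
    that component, so the two class variances sum to 1 componentwise.
    """
    C1 = np.asarray(C1, dtype=float)
    C2 = np.asarray(C2, dtype=float)
    n_ch = C1.shape[0]
    if 2 * n_pairs > n_ch:
        raise ValueError(f"{n_pairs} pairs need >= {2 * n_pairs} channels, have {n_ch}")
    comp = C1 + C2
    eps = 1e-8 * np.trace(comp) / n_ch
    comp = comp + eps * np.eye(n_ch)
    try:
        vals, vecs = scipy.linalg.eigh(C1, comp)
    except scipy.linalg.LinAlgError as exc:
        raise ValueError(
            "singular composite covariance; consider stronger regularization"
        ) from exc
    order = np.argsort(vals)[::-1]  # descending class-1 variance fraction
    vals, vecs = vals[order], vecs[:, order]
    keep = np.concatenate([np.arange(n_pairs), np.arange(n_ch - n_pairs, n_ch)])
    return SpatialFilterBank(
        W=vecs[:, keep], eigenvalues=vals[keep], band=band, n_pairs=n_pairs
    )


def fit_csp(segs: SegmentSet, n_pairs: int = 3) -> SpatialFilterBank:
    """Fit CSP filters on a two-class segment set."""
    C1, C2, _ = _class_covariances(segs)
    return csp_from_covariances(C1, C2, n_pairs=n_pairs)


def csp_features(segs: SegmentSet, bank: SpatialFilterBank) -> FeatureMatrix:
    """Log normalized variance of each CSP component, per segment."""
    if segs.n_channels != bank.W.shape[0]:
        raise ValueError(
            f"bank fitted on {bank.W.shape[0]} channels, data has {segs.n_channels}"
        )
    Z = np.einsum("ck,scn->skn", bank.W, segs.data)
    var = Z.var(axis=2)
    total = var.sum(axis=1)
    if np.any(total <= 0):
        raise ValueError("zero-variance segment; cannot form log-variance features")
    feats = np.log(var / total[:, None])
    suffix = "" if bank.band is None else f".{bank.band[0]:g}-{bank.band[1]:g}Hz"
    names = [f"csp{k}{suffix}" for k in range(bank.n_components)]
    return FeatureMatrix(
        values=feats,
        feature_names=names,
        labels=segs.labels.copy(),
        trial_ids=segs.parent_trial.copy(),
        class_names=list(segs.class_names),
    )


# ---------------------------------------------------------------------------
# filter bank CSP


def band_filter(data: np.ndarray, band: tuple[float, float], fs: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass along the last axis."""
    lo, hi = band
    if hi >= fs / 2:
        raise ValueError(f"band edge {hi} Hz reaches Nyquist ({fs / 2} Hz)")
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, data, axis=-1)


def _band_segments(segs: SegmentSet, band: tuple[float, float]) -> SegmentSet:
    return replace(segs, data=band_filter(segs.data, band, segs.fs))


def mutual_information(x: np.ndarray, y: np.ndarray, bins: int = 8) -> float:
    """Mutual information (nats) between a real feature and a discrete label.

    The feature is discretized by equal-frequency binning; MI is then the
    plug-in estimate on the contingency table.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    edges = np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1])
    xd = np.searchsorted(edges, x, side="right")
    mi = 0.0
    n = len(x)
    for xv in np.unique(xd):
        px = np.mean(xd == xv)
        for yv in np.unique(y):
            pxy = np.sum((xd == xv) & (y == yv)) / n
            if pxy > 0:
                py = np.mean(y == yv)
                mi += pxy * np.log(pxy / (px * py))
    return float(mi)


def fit_fbcsp(
    segs: SegmentSet,
    spec: FilterBankSpec = FilterBankSpec(),
    n_pairs: int = 3,
) -> tuple[list[SpatialFilterBank], np.ndarray]:
    """Fit per-band CSP filters and select the most informative pooled features.

    Returns the per-band filter banks and the indices (into the pooled
    feature columns) of the ``n_select`` features with highest estimated
    mutual information with the class label.  Selection uses the training
    data only; apply :func:`fbcsp_features` with the returned pair.
    """
    banks = [
        replace(fit_csp(_band_segments(segs, band), n_pairs=n_pairs), band=band)
        for band in spec.bands
    ]
    pooled = _pooled_fbcsp_values(segs, banks)
    selected = _select_by_mi(pooled, segs.labels, spec, banks[0].n_components)
    return banks, selected


def _select_by_mi(
    pooled: np.ndarray, y: np.ndarray, spec: FilterBankSpec, per_band: int
) -> np.ndarray:
    """Rank pooled columns by mutual information with the label; keep the top
    ``n_select`` plus, for each, its variance-complement CSP component from
    the same band (the component at the opposite end of the eigenvalue
    spectrum), as in the standard filter-bank selection scheme."""
    n_total = pooled.shape[1]
    if spec.n_select > n_total:
        raise ValueError(f"n_select={spec.n_select} exceeds {n_total} pooled features")
    mis = np.array([mutual_information(pooled[:, j], y) for j in range(n_total)])
    top = np.argsort(-mis, kind="stable")[: spec.n_select]
    keep = set()
    for j in top:
        band_idx, comp = divmod(int(j), per_band)
        keep.add(int(j))
        keep.add(band_idx * per_band + (per_band - 1 - comp))
    return np.array(sorted(keep), dtype=int)


def _pooled_fbcsp_values(segs: SegmentSet, banks: list[SpatialFilterBank]) -> np.ndarray:
    cols = []
    for bank in banks:
        assert bank.band is not None
        cols.append(csp_features(_band_segments(segs, bank.band), bank).values)
    return np.hstack(cols)


def fbcsp_features(
    segs: SegmentSet,
    banks: list[SpatialFilterBank],
    selected: np.ndarray,
) -> FeatureMatrix:
    """Apply fitted per-band CSP filters and keep the selected pooled columns."""
    pooled = _pooled_fbcsp_values(segs, banks)
    names = []
    for bank in banks:
        assert bank.band is not None
        names += [
            f"csp{k}.{bank.band[0]:g}-{bank.band[1]:g}Hz" for k in range(bank.n_components)
        ]
    return FeatureMatrix(
        values=pooled[:, selected],
        feature_names=[names[j] for j in selected],
        labels=segs.labels.copy(),
        trial_ids=segs.parent_trial.copy(),
        class_names=list(segs.class_names),
    )


# ---------------------------------------------------------------------------
# band power


def bandpower_features(
    segs: SegmentSet,
    bands: Sequence[tuple[float, float]] = DEFAULT_BANDS,
) -> FeatureMatrix:
    """Logarithmic band power: per segment, channel and band, log variance
    of the band-pass-filtered signal."""
    cols = []
    names = []
    chans = list(segs.channel_labels) or [str(i) for i in range(segs.n_channels)]
    for band in bands:
        filtered = band_filter(segs.data, band, segs.fs)
        var = filtered.var(axis=2)  # segments x channels
        if np.any(var <= 0):
            raise ValueError(f"zero variance in band {band}; cannot take log")
        cols.append(np.log(var))
        names += [f"{ch}.bp{band[0]:g}-{band[1]:g}Hz" for ch in chans]
    return FeatureMatrix(
        values=np.hstack(cols),
        feature_names=names,
        labels=segs.labels.copy(),
        trial_ids=segs.parent_trial.copy(),
        class_names=list(segs.class_names),
    )


# ---------------------------------------------------------------------------
# linear discriminant


def fit_lda(F: FeatureMatrix, shrinkage: str | float = "auto") -> LDAModel:
    """Fisher discriminant with shrinkage-regularized pooled covariance."""
    classes = np.unique(F.labels)
    if len(classes) != 2:
        raise ValueError(f"LDA baseline needs exactly 2 classes, got {len(classes)}")
    lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=shrinkage)
    lda.fit(F.values, F.labels)
    return LDAModel(
        weights=lda.coef_.ravel().copy(),
        bias=float(lda.intercept_[0]),
        classes=classes,
    )


def predict_lda(model: LDAModel, F: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Classify by the side of the hyperplane; ties go to the first class code."""
    X = F.values if isinstance(F, FeatureMatrix) else np.asarray(F, dtype=float)
    score = X @ model.weights + model.bias
    return np.where(score > 0, model.classes[1], model.classes[0])


# ---------------------------------------------------------------------------
# cross-validated baseline pipelines


def crossval_baseline(
    segs: SegmentSet,
    method: str,
    *,
    n_pairs: int = 3,
    fb_spec: FilterBankSpec = FilterBankSpec(),
    bands: Sequence[tuple[float, float]] = DEFAULT_BANDS,
    shrinkage: str | float = "auto",
    n_repeats: int = 10,
    n_folds: int = 10,
    seed: int = 0,
) -> CVReport:
    """Repeated stratified k-fold CV of one comparison pipeline.

    ``method`` is ``"csp"``, ``"fbcsp"`` or ``"bandpower"``.  Folds are drawn
    at the trial level; spatial filters and feature selection are refit inside
    every training fold.  Default protocol: ten repetitions of tenfold CV with
    distinct seeded shuffles (100 fold accuracies).
    """
    if method not in ("csp", "fbcsp", "bandpower"):
        raise ValueError(f"unknown baseline method {method!r}")
    trials, trial_labels = np.unique(segs.parent_trial, return_index=True)
    trial_labels = segs.labels[trial_labels]

    # band filtering is label-independent: precompute once, outside the folds
    if method == "fbcsp":
        band_data = {band: _band_segments(segs, band) for band in fb_spec.bands}
    elif method == "bandpower":
        all_feats = bandpower_features(segs, bands)

    fold_accs: list[float] = []
    first_pred: np.ndarray | None = None
    first_order: np.ndarray | None = None
    for rep in range(n_repeats):
        rng = np.random.default_rng([seed, rep])
        trial_folds = stratified_trial_folds(trial_labels, n_folds, rng)
        pred = np.empty(segs.n_segments, dtype=int)
        for tf in trial_folds:
            test = np.flatnonzero(np.isin(segs.parent_trial, trials[tf]))
            train = np.setdiff1d(np.arange(segs.n_segments), test)
            tr_segs = _subset_segments(segs, train)
            if method == "csp":
                bank = fit_csp(tr_segs, n_pairs=n_pairs)
                F_tr = csp_features(tr_segs, bank)
                F_te = csp_features(_subset_segments(segs, test), bank)
            elif method == "fbcsp":
                banks, selected = _fit_fbcsp_prefiltered(
                    segs, band_data, train, fb_spec, n_pairs
                )
                F_tr = _fbcsp_prefiltered_features(segs, band_data, train, banks, selected)
                F_te = _fbcsp_prefiltered_features(segs, band_data, test, banks, selected)
            else:
                F_tr = _subset_features(all_feats, train)
                F_te = _subset_features(all_feats, test)
            lda = fit_lda(F_tr, shrinkage=shrinkage)
            pred[test] = predict_lda(lda, F_te)
            fold_accs.append(100.0 * float(np.mean(pred[test] == segs.labels[test])))
        if rep == 0:
            first_pred = pred.copy()
            first_order = np.concatenate(
                [np.flatnonzero(np.isin(segs.parent_trial, trials[tf])) for tf in trial_folds]
            )
    assert first_pred is not None and first_order is not None
    n_classes = len(np.unique(segs.labels))
    confusion = np.zeros((n_classes, n_classes), dtype=int)
    for t, p in zip(segs.labels, first_pred):
        confusion[t, p] += 1
    errors = (first_pred[first_order] != segs.labels[first_order]).astype(int)
    return CVReport(
        fold_accuracies=np.array(fold_accs),
        best_config=None,
        confusion=confusion,
        cumulative_errors=np.cumsum(errors),
        class_names=list(segs.class_names),
    )


def _subset_segments(segs: SegmentSet, idx: np.ndarray) -> SegmentSet:
    return SegmentSet(
        data=segs.data[idx],
        labels=segs.labels[idx],
        parent_trial=segs.parent_trial[idx],
        fs=segs.fs,
        channel_labels=list(segs.channel_labels),
        class_names=list(segs.class_names),
    )


def _subset_features(F: FeatureMatrix, idx: np.ndarray) -> FeatureMatrix:
    return FeatureMatrix(
        values=F.values[idx],
        feature_names=F.feature_names,
        labels=F.labels[idx],
        trial_ids=None if F.trial_ids is None else F.trial_ids[idx],
        class_names=F.class_names,
    )


def _fit_fbcsp_prefiltered(
    segs: SegmentSet,
    band_data: dict[tuple[float, float], SegmentSet],
    train: np.ndarray,
    spec: FilterBankSpec,
    n_pairs: int,
) -> tuple[list[SpatialFilterBank], np.ndarray]:
    banks = []
    for band in spec.bands:
        tr = _subset_segments(band_data[band], train)
        banks.append(replace(fit_csp(tr, n_pairs=n_pairs), band=band))
    pooled = np.hstack(
        [
            csp_features(_subset_segments(band_data[b.band], train), b).values
            for b in banks
        ]
    )
    selected = _select_by_mi(pooled, segs.labels[train], spec, banks[0].n_components)
    return banks, selected


def _fbcsp_prefiltered_features(
    segs: SegmentSet,
    band_data: dict[tuple[float, float], SegmentSet],
    idx: np.ndarray,
    banks: list[SpatialFilterBank],
    selected: np.ndarray,
) -> FeatureMatrix:
    pooled = np.hstack(
        [csp_features(_subset_segments(band_data[b.band], idx), b).values for b in banks]
    )
    return FeatureMatrix(
        values=pooled[:, selected],
        feature_names=[f"f{j}" for j in selected],
        labels=segs.labels[idx],
        trial_ids=segs.parent_trial[idx],
        class_names=list(segs.class_names),
    )
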