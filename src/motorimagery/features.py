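"""Time-domain feature extraction: AR coefficients, RMS amplitude, waveform length.

Each 250-ms analysis window of each channel yields six features: the four
coefficients of an order-4 autoregressive fit, the root-mean-square amplitude,
and the waveform length (sum of absolute consecutive differences).  With 20
channels this gives the 120-dimensional feature vector fed to the classifier.

AR coefficients are returned in the *prediction* sign convention,

    x[n] = a1 x[n-1] + a2 x[n-2] + ... + ap x[n-p] + e[n],

so a positive ``a1`` means positive lag-1 correlation.  The default estimator
is Burg's method, which behaves well on short windows; Yule-Walker is
available as an alternative.  The segment mean is removed before the AR fit
(the coefficients describe the fluctuation spectrum, not the DC offset); RMS
and WL are computed on the unmodified samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.regression.linear_model import burg as _sm_burg
from statsmodels.regression.linear_model import yule_walker as _sm_yule_walker

from .preprocess import SegmentSet

__all__ = [
    "ARModelSpec",
    "FeatureMatrix",
    "ar_coefficients",
    "rms_amplitude",
    "waveform_length",
    "feature_names",
    "extract_features",
]

FEATURE_KINDS = ("ar", "rms", "wl")


@dataclass(frozen=True)
class ARModelSpec:
    """Autoregressive model specification: order ``p`` and estimator name."""

    order: int = 4
    method: str = "burg"  # or "yule-walker"

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError(f"AR order must be >= 1, got {self.order}")
        if self.method not in ("burg", "yule-walker"):
            raise ValueError(f"unknown AR method {self.method!r}")


@dataclass
class FeatureMatrix:
    """Segments x features table with feature provenance names.

    ``feature_names[j]`` encodes column ``j`` as ``"<channel>.<kind>"``
    (e.g. ``"C3.ar2"``, ``"C4.rms"``).  ``trial_ids`` carries each segment's
    parent trial so model selection can split folds at the trial level.
    """

    values: np.ndarray
    feature_names: Sequence[str]
    labels: np.ndarray
    trial_ids: np.ndarray | None = None
    class_names: Sequence[str] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("FeatureMatrix.values must be 2-D")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must equal number of columns")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("labels length must equal number of rows")
        if self.trial_ids is not None:
            self.trial_ids = np.asarray(self.trial_ids, dtype=int)
            if len(self.trial_ids) != self.values.shape[0]:
                raise ValueError("trial_ids length must equal number of rows")

    @property
    def n_segments(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, columns=list(self.feature_names))
        df.insert(0, "label", self.labels)
        if self.trial_ids is not None:
            df.insert(1, "trial", self.trial_ids)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t")
        labels = df.pop("label").to_numpy(dtype=int)
        trials = df.pop("trial").to_numpy(dtype=int) if "trial" in df.columns else None
        return cls(
            values=df.to_numpy(dtype=float),
            feature_names=list(df.columns),
            labels=labels,
            trial_ids=trials,
        )


def ar_coefficients(x: np.ndarray, spec: ARModelSpec = ARModelSpec()) -> np.ndarray:
    """Fit an AR(p) model and return its p prediction coefficients.

    Raises on constant or too-short input, for which the autoregression is
    singular.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("ar_coefficients expects a 1-D sequence")
    if len(x) <= spec.order:
        raise ValueError(f"sequence of length {len(x)} too short for AR({spec.order})")
    if not np.all(np.isfinite(x)):
        raise ValueError("sequence contains non-finite values")
    if np.ptp(x) == 0:
        raise ValueError("constant sequence: AR estimation is singular")
    if spec.method == "burg":
        coefs, _ = _sm_burg(x, order=spec.order, demean=True)
    else:
        coefs, _ = _sm_yule_walker(x - x.mean(), order=spec.order, method="mle")
    return np.asarray(coefs, dtype=float)


def rms_amplitude(x: np.ndarray) -> float:
    """Root-mean-square amplitude, sqrt(mean(x_i^2))."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("rms_amplitude of an empty sequence is undefined")
    return float(np.sqrt(np.mean(np.square(x))))


def waveform_length(x: np.ndarray) -> float:
    """Waveform length: sum of absolute consecutive sample differences."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("waveform_length needs at least 2 samples")
    return float(np.sum(np.abs(np.diff(x))))


def feature_names(
    channel_labels: Sequence[str],
    spec: ARModelSpec = ARModelSpec(),
    kinds: Iterable[str] = FEATURE_KINDS,
) -> list[str]:
    """Column names in the fixed channel-major order: ar1..arp, rms, wl."""
    kinds = _check_kinds(kinds)
    names: list[str] = []
    for ch in channel_labels:
        if "ar" in kinds:
            names += [f"{ch}.ar{i}" for i in range(1, spec.order + 1)]
        if "rms" in kinds:
            names.append(f"{ch}.rms")
        if "wl" in kinds:
            names.append(f"{ch}.wl")
    return names


def _check_kinds(kinds: Iterable[str]) -> tuple[str, ...]:
    kinds = tuple(k for k in FEATURE_KINDS if k in set(kinds))
    if not kinds:
        raise ValueError(f"kinds must be a non-empty subset of {FEATURE_KINDS}")
    return kinds


def extract_features(
    segs: SegmentSet,
    spec: ARModelSpec = ARModelSpec(),
    kinds: Iterable[str] = FEATURE_KINDS,
) -> FeatureMatrix:
    """Per-segment, per-channel time-domain features, concatenated channel-major.

    With all three kinds enabled the feature count is
    ``channels * (p + 2)``; column meaning is fully determined by
    ``feature_names``.
    """
    kinds = _check_kinds(kinds)
    n_seg, n_ch, _ = segs.data.shape
    per_ch = ("ar" in kinds) * spec.order + ("rms" in kinds) + ("wl" in kinds)
    values = np.empty((n_seg, n_ch * per_ch))
    for s in range(n_seg):
        col = 0
        for c in range(n_ch):
            x = segs.data[s, c]
            if "ar" in kinds:
                try:
                    values[s, col : col + spec.order] = ar_coefficients(x, spec)
                except ValueError as exc:
                    raise ValueError(
                        f"AR estimation failed on segment {s}, channel "
                        f"{segs.channel_labels[c] if segs.channel_labels else c}: {exc}"
                    ) from exc
                col += spec.order
            if "rms" in kinds:
                values[s, col] = rms_amplitude(x)
                col += 1
            if "wl" in kinds:
                values[s, col] = waveform_length(x)
                col += 1
    return FeatureMatrix(
        values=values,
        feature_names=feature_names(
            segs.channel_labels or [str(i) for i in range(n_ch)], spec, kinds
        ),
        labels=segs.labels.copy(),
        trial_ids=segs.parent_trial.copy(),
        class_names=list(segs.class_names),
    )
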