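"""Band-pass filtering and fixed-length segmentation of epochs.

The comparison pipelines band-pass their input from 6 to 40 Hz with a
linear-phase FIR filter; all pipelines then chop each trial into short
non-overlapping analysis windows (250 ms by default) from which features are
computed.  Filtering is applied forward-backward (zero net phase) because the
whole scheme runs offline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal

from .io import EpochSet

__all__ = ["FilterSpec", "SegmentSet", "design_fir", "bandpass", "segment"]


@dataclass(frozen=True)
class FilterSpec:
    """FIR band-pass specification.

    ``order`` is the filter order (tap count minus one); default 250 gives a
    ~13 Hz transition width at 1000 Hz sampling with a Hamming window, sharp
    enough for a 6-40 Hz analysis band.
    """

    low_hz: float = 6.0
    high_hz: float = 40.0
    order: int = 250
    design: str = "hamming"

    def validate(self, fs: float) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError(f"need 0 < low_hz < high_hz, got ({self.low_hz}, {self.high_hz})")
        if self.high_hz >= fs / 2:
            raise ValueError(
                f"high band edge {self.high_hz} Hz reaches Nyquist ({fs / 2} Hz)"
            )
        if self.order < 2:
            raise ValueError(f"filter order must be >= 2, got {self.order}")


@dataclass
class SegmentSet:
    """Short analysis windows cut from an :class:`~motorimagery.io.EpochSet`.

    Every segment inherits the label of its parent trial; ``parent_trial``
    records the provenance so cross-validation can split at the trial level.
    """

    data: np.ndarray  # segments x channels x samples_per_segment
    labels: np.ndarray  # class code per segment
    parent_trial: np.ndarray  # trial index per segment
    fs: float
    channel_labels: Sequence[str] = ()
    class_names: Sequence[str] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.parent_trial = np.asarray(self.parent_trial, dtype=int)
        if not (len(self.labels) == len(self.parent_trial) == self.data.shape[0]):
            raise ValueError("labels, parent_trial and data first dimension must agree")

    @property
    def n_segments(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def samples_per_segment(self) -> int:
        return self.data.shape[2]


def design_fir(spec: FilterSpec, fs: float) -> np.ndarray:
    """Design the linear-phase band-pass taps for ``spec`` at rate ``fs``."""
    spec.validate(fs)
    numtaps = spec.order + 1
    if numtaps % 2 == 0:
        numtaps += 1  # odd tap count keeps a band-pass realizable (type I)
    return signal.firwin(
        numtaps,
        [spec.low_hz, spec.high_hz],
        pass_zero=False,
        window=spec.design,
        fs=fs,
    )


def bandpass(epochs: EpochSet, spec: FilterSpec = FilterSpec()) -> EpochSet:
    """Zero-phase FIR band-pass of every channel of every trial.

    The filter runs forward then backward, so the net phase response is zero
    and the magnitude response is squared.  Edge transients are contained by
    even-reflection padding of one filter length.
    """
    taps = design_fir(spec, epochs.fs)
    padlen = min(len(taps), epochs.samples_per_epoch - 1)
    out = signal.filtfilt(taps, [1.0], epochs.data, axis=-1, padtype="even", padlen=padlen)
    return EpochSet(
        data=out,
        labels=epochs.labels.copy(),
        fs=epochs.fs,
        channel_labels=list(epochs.channel_labels),
        class_names=list(epochs.class_names),
    )


def segment(
    epochs: EpochSet,
    segment_duration: float = 0.25,
    overlap: float = 0.0,
) -> SegmentSet:
    """Chop each trial into fixed-length windows.

    Windows are consecutive and non-overlapping by default (``overlap`` is the
    fraction of a window shared with its predecessor); a trailing remainder
    shorter than one window is discarded.  3 s trials at 1000 Hz with 250 ms
    windows give 12 segments of 250 samples per trial.
    """
    n_seg_samp = int(round(segment_duration * epochs.fs))
    n_epoch_samp = epochs.samples_per_epoch
    if n_seg_samp > n_epoch_samp:
        raise ValueError(
            f"segment of {n_seg_samp} samples longer than epoch of {n_epoch_samp}"
        )
    if not 0 <= overlap < 1:
        raise ValueError(f"overlap fraction must be in [0, 1), got {overlap}")
    step = max(int(round(n_seg_samp * (1 - overlap))), 1)
    starts = np.arange(0, n_epoch_samp - n_seg_samp + 1, step)
    chunks = [epochs.data[:, :, s : s + n_seg_samp] for s in starts]
    data = np.concatenate(chunks, axis=0) if chunks else np.empty((0, epochs.n_channels, n_seg_samp))
    # chunks stack window-major; reorder trial-major so segments of one trial are contiguous
    n_trials = epochs.n_trials
    order = np.argsort(np.tile(np.arange(n_trials), len(starts)), kind="stable")
    data = data[order]
    parent = np.repeat(np.arange(n_trials), len(starts))
    labels = epochs.labels[parent]
    return SegmentSet(
        data=data,
        labels=labels,
        parent_trial=parent,
        fs=epochs.fs,
        channel_labels=list(epochs.channel_labels),
        class_names=list(epochs.class_names),
    )
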