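"""Synthetic EEG with class-dependent sensorimotor rhythm modulation.

Real motor-imagery EEG shows *event-related desynchronization* (ERD): during
an imagined movement, the power of the mu (8-12 Hz) and beta (18-26 Hz)
rhythms over sensorimotor cortex (electrodes C3/C4) drops, while it stays
high at rest.  The generator reproduces exactly that statistical structure:

* per channel, a stable AR(4) background process (broadband 1/f-ish noise);
* per channel and rhythm band, narrowly band-pass-filtered Gaussian noise
  whose amplitude is scaled during task epochs by a per-class, per-channel
  multiplier (multiplier < 1 models ERD);
* the trial protocol of the emulated experiment: 1000 Hz sampling, 20
  channels, 3 s task epochs separated by 5-7 s rests, with labelled events
  at each trial onset.

Everything is a deterministic function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

from .io import CHANNELS_20, Event, Recording

__all__ = ["SimSpec", "simulate_recording", "simulate_ar_sequence", "null_spec"]

#: Rhythm bands: name -> ((low_hz, high_hz), background amplitude in uV SD).
DEFAULT_RHYTHMS: dict[str, tuple[tuple[float, float], float]] = {
    "mu": ((8.0, 12.0), 6.0),
    "beta": ((18.0, 26.0), 4.0),
}

#: Default ERD pattern: imagined grasp and elbow flexion attenuate the mu and
#: beta rhythms on the sensorimotor electrodes C3/C4, with slightly different
#: band emphasis so the two movements are also mutually discriminable.
DEFAULT_MODULATION: dict[str, dict[str, dict[str, float]]] = {
    "grasp": {"C3": {"mu": 0.3, "beta": 0.4}, "C4": {"mu": 0.3, "beta": 0.4}},
    "elbow": {"C3": {"mu": 0.45, "beta": 0.3}, "C4": {"mu": 0.45, "beta": 0.3}},
}


@dataclass(frozen=True)
class SimSpec:
    """Parameters of one synthetic subject/recording.

    ``modulation[class][channel][band]`` multiplies that band's rhythm
    amplitude on that channel during epochs of that class; unlisted entries
    default to 1 (no change).  ``ar_coeffs`` define the stable AR(4)
    background with innovation SD ``noise_scale`` (uV).
    """

    fs: float = 1000.0
    channel_labels: tuple[str, ...] = CHANNELS_20
    classes: tuple[str, ...] = ("rest", "grasp", "elbow")
    n_trials: int = 20  # per class
    epoch_s: float = 3.0
    rest_gap_s: tuple[float, float] = (5.0, 7.0)
    rhythms: Mapping[str, tuple[tuple[float, float], float]] = field(
        default_factory=lambda: dict(DEFAULT_RHYTHMS)
    )
    modulation: Mapping[str, Mapping[str, Mapping[str, float]]] = field(
        default_factory=lambda: {k: {c: dict(b) for c, b in v.items()} for k, v in DEFAULT_MODULATION.items()}
    )
    ar_coeffs: tuple[float, ...] = (0.55, -0.25, 0.1, -0.05)
    noise_scale: float = 4.0
    ramp_s: float = 0.1
    lead_in_s: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        _check_stable(self.ar_coeffs)
        for cls, per_ch in self.modulation.items():
            for ch, per_band in per_ch.items():
                for band, m in per_band.items():
                    if m < 0:
                        raise ValueError(
                            f"negative amplitude multiplier {m} for {cls}/{ch}/{band}"
                        )


def null_spec(**overrides) -> SimSpec:
    """A contrast-free spec: identical rhythm statistics in every class."""
    return SimSpec(modulation={}, **overrides)


def _check_stable(coeffs: Sequence[float]) -> None:
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.size == 0:
        raise ValueError("AR coefficient vector is empty")
    roots = np.roots(np.concatenate([[1.0], -coeffs]))
    if np.any(np.abs(roots) >= 1):
        raise ValueError(
            f"unstable AR process: characteristic root magnitudes {np.abs(roots)}"
        )


def simulate_ar_sequence(
    coeffs: Sequence[float],
    n: int,
    noise_sd: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw ``n`` samples of x_t = sum_i coeffs_i x_{t-i} + e_t, e ~ N(0, sd^2).

    A burn-in of 10x the model order is generated and discarded so the
    returned samples are (near-)stationary.  Deterministic in ``seed``.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    _check_stable(coeffs)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    burn = 10 * len(coeffs)
    e = rng.standard_normal(n + burn) * noise_sd
    a_poly = np.concatenate([[1.0], -coeffs])
    x = signal.lfilter([1.0], a_poly, e)
    return x[burn:]


def simulate_recording(spec: SimSpec = SimSpec()) -> Recording:
    """Generate one synthetic recording according to ``spec``.

    Trials of all classes are interleaved in seeded random order; each trial
    onset carries an event with the class label.  Rhythm amplitude envelopes
    transition with a short cosine ramp (``ramp_s``) at epoch edges to avoid
    spectral clicks.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    fs = spec.fs
    epoch_n = int(round(spec.epoch_s * fs))

    # trial order and onsets
    labels = np.repeat(np.arange(len(spec.classes)), spec.n_trials)
    rng.shuffle(labels)
    onsets = []
    cursor = int(round(spec.lead_in_s * fs))
    for _ in labels:
        onsets.append(cursor)
        gap = rng.uniform(*spec.rest_gap_s)
        cursor += epoch_n + int(round(gap * fs))
    total = cursor + int(round(spec.lead_in_s * fs))

    ramp_n = int(round(spec.ramp_s * fs))
    ramp = 0.5 * (1 - np.cos(np.linspace(0, np.pi, ramp_n))) if ramp_n > 1 else None

    n_ch = len(spec.channel_labels)
    data = np.empty((n_ch, total))
    for ci, ch in enumerate(spec.channel_labels):
        x = simulate_ar_sequence(spec.ar_coeffs, total, spec.noise_scale, rng)
        for band_name, (band, base_amp) in spec.rhythms.items():
            noise = rng.standard_normal(total)
            sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
            rhythm = signal.sosfilt(sos, noise)
            rhythm *= base_amp / rhythm.std()
            env = np.ones(total)
            for onset, lab in zip(onsets, labels):
                mult = (
                    spec.modulation.get(spec.classes[lab], {})
                    .get(ch, {})
                    .get(band_name, 1.0)
                )
                if mult != 1.0:
                    env[onset : onset + epoch_n] = mult
                    if ramp is not None:
                        env[onset : onset + ramp_n] = 1 + (mult - 1) * ramp
                        env[onset + epoch_n - ramp_n : onset + epoch_n] = mult + (
                            1 - mult
                        ) * ramp
            x = x + rhythm * env
        data[ci] = x

    events = [Event(int(o), spec.classes[lab]) for o, lab in zip(onsets, labels)]
    return Recording(
        data=data,
        fs=fs,
        channel_labels=list(spec.channel_labels),
        events=events,
    )
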