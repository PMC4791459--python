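"""Recording I/O and the canonical in-memory data model.

A :class:`Recording` is a continuous multichannel EEG signal in microvolts
with a sampling rate, ordered channel labels and a list of task-onset
:class:`Event` markers.  Trials are cut from it into an :class:`EpochSet`.

Two on-disk dialects are supported:

``edf``
    Plain EDF (16-bit), read through :mod:`mne`.  Event markers travel in a
    sidecar ``<file>.events.tsv`` (columns ``onset_sample``, ``label``);
    EDF+ annotations, when present, are also mapped to events via a
    configurable label map.

``matrix``
    A delimited numeric body (one row per channel) beside a small key-value
    text header ``<file>.hdr`` holding the sampling rate, channel labels and
    the event table.  Human-readable and diffable; the fixture dialect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "CHANNELS_20",
    "TASK_LABELS",
    "Event",
    "Recording",
    "EpochSet",
    "read_recording",
    "write_recording",
    "extract_epochs",
]

#: The twenty scalp electrodes used throughout (10–20 style labels).
CHANNELS_20 = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T7", "T8", "P7", "P8", "Fz", "Nas", "Pz", "Oz",
)

#: Permitted event labels: imagined rest, imagined grasp, imagined elbow flexion.
TASK_LABELS = ("rest", "grasp", "elbow")


@dataclass(frozen=True)
class Event:
    """A labelled trial onset, as a 0-based sample index into the recording."""

    onset_sample: int
    label: str

    def __post_init__(self) -> None:
        if self.onset_sample < 0:
            raise ValueError(f"event onset_sample must be >= 0, got {self.onset_sample}")
        if self.label not in TASK_LABELS:
            raise ValueError(
                f"unknown event label {self.label!r}; permitted labels: {TASK_LABELS}"
            )


@dataclass
class Recording:
    """Continuous multichannel EEG.

    Parameters
    ----------
    data
        Channels x samples array, in microvolts.
    fs
        Sampling rate in Hz (positive).
    channel_labels
        One label per row of ``data``.
    events
        Labelled trial onsets; every onset must lie inside the recording.
    """

    data: np.ndarray
    fs: float
    channel_labels: Sequence[str]
    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("Recording.data must be 2-D (channels x samples)")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} channel labels for {self.data.shape[0]} data rows"
            )
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        n = self.data.shape[1]
        for ev in self.events:
            if not 0 <= ev.onset_sample < n:
                raise ValueError(
                    f"event at sample {ev.onset_sample} outside recording of {n} samples"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EpochSet:
    """Fixed-length labelled trial windows cut from a :class:`Recording`.

    ``labels`` are integer class codes; ``class_names[label]`` recovers the
    original event label.
    """

    data: np.ndarray  # trials x channels x samples_per_epoch
    labels: np.ndarray  # int code per trial
    fs: float
    channel_labels: Sequence[str]
    class_names: Sequence[str] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.data.ndim != 3:
            raise ValueError("EpochSet.data must be 3-D (trials x channels x samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must equal number of trials")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def samples_per_epoch(self) -> int:
        return self.data.shape[2]


# ---------------------------------------------------------------------------
# matrix dialect


def _matrix_header_path(path: Path) -> Path:
    return path.with_name(path.name + ".hdr")


def _write_matrix(rec: Recording, path: Path) -> None:
    np.savetxt(path, rec.data, delimiter="\t", fmt="%.10g")
    lines = [f"fs\t{rec.fs!r}", "channels\t" + ",".join(rec.channel_labels)]
    for ev in rec.events:
        lines.append(f"event\t{ev.onset_sample}\t{ev.label}")
    _matrix_header_path(path).write_text("\n".join(lines) + "\n")


def _read_matrix(path: Path, label_map: Mapping[str, str] | None) -> Recording:
    hdr = _matrix_header_path(path)
    if not hdr.exists():
        raise FileNotFoundError(f"matrix header {hdr} not found beside {path}")
    fs: float | None = None
    channels: list[str] | None = None
    events: list[Event] = []
    for lineno, line in enumerate(hdr.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        key, _, rest = line.partition("\t")
        if key == "fs":
            try:
                fs = float(rest)
            except ValueError as exc:
                raise ValueError(f"{hdr}:{lineno}: unparseable fs value {rest!r}") from exc
        elif key == "channels":
            channels = [c for c in rest.split(",") if c]
        elif key == "event":
            onset_s, _, lab = rest.partition("\t")
            try:
                onset = int(onset_s)
            except ValueError as exc:
                raise ValueError(f"{hdr}:{lineno}: unparseable event onset {onset_s!r}") from exc
            events.append(Event(onset, _map_label(lab, label_map)))
        else:
            raise ValueError(f"{hdr}:{lineno}: unknown header field {key!r}")
    if fs is None:
        raise ValueError(f"{hdr}: missing required field 'fs'")
    if channels is None:
        raise ValueError(f"{hdr}: missing required field 'channels'")
    data = np.loadtxt(path, delimiter="\t", ndmin=2)
    if data.shape[0] != len(channels):
        raise ValueError(
            f"{path}: header field 'channels' declares {len(channels)} channels "
            f"but the matrix has {data.shape[0]} rows"
        )
    return Recording(data=data, fs=fs, channel_labels=channels, events=events)


# ---------------------------------------------------------------------------
# EDF dialect

_EDF_DIGITAL_MAX = 32767
_EDF_DIGITAL_MIN = -32767


def _edf_field(value: object, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        # shorten floats to fit the fixed-width ascii field
        if isinstance(value, float):
            s = f"{value:.{max(width - 8, 1)}g}"[:width]
        else:
            s = s[:width]
    return s.ljust(width).encode("ascii")


def _events_sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".events.tsv")


def _write_edf(rec: Recording, path: Path) -> None:
    """Write a plain 16-bit EDF file.

    Uses 1-second data records when the sample count divides evenly by the
    (integer) sampling rate, otherwise one-sample records; either way the
    sample stream round-trips without padding.
    """
    n_ch, n_samp = rec.data.shape
    fs_int = int(round(rec.fs))
    if abs(rec.fs - fs_int) < 1e-9 and n_samp % fs_int == 0 and n_samp > 0:
        spr, n_records, record_dur = fs_int, n_samp // fs_int, 1.0
    else:
        spr, n_records, record_dur = 1, n_samp, 1.0 / rec.fs

    # physical/digital scaling per channel
    pmins = rec.data.min(axis=1)
    pmaxs = rec.data.max(axis=1)
    flat = pmaxs - pmins <= 0
    pmins[flat] -= 1.0  # avoid zero physical span
    pmaxs[flat] += 1.0

    now = datetime(2000, 1, 1)
    header = b""
    header += _edf_field("0", 8)
    header += _edf_field("X X X X", 80)
    header += _edf_field("Startdate X X X X", 80)
    header += _edf_field(now.strftime("%d.%m.%y"), 8)
    header += _edf_field(now.strftime("%H.%M.%S"), 8)
    header += _edf_field(256 * (1 + n_ch), 8)
    header += _edf_field("", 44)
    header += _edf_field(n_records, 8)
    header += _edf_field(f"{record_dur:.6g}", 8)
    header += _edf_field(n_ch, 4)
    for lab in rec.channel_labels:
        header += _edf_field(f"EEG {lab}", 16)
    header += b"".join(_edf_field("", 80) for _ in range(n_ch))
    header += b"".join(_edf_field("uV", 8) for _ in range(n_ch))
    header += b"".join(_edf_field(f"{p:.6g}", 8) for p in pmins)
    header += b"".join(_edf_field(f"{p:.6g}", 8) for p in pmaxs)
    header += b"".join(_edf_field(_EDF_DIGITAL_MIN, 8) for _ in range(n_ch))
    header += b"".join(_edf_field(_EDF_DIGITAL_MAX, 8) for _ in range(n_ch))
    header += b"".join(_edf_field("", 80) for _ in range(n_ch))
    header += b"".join(_edf_field(spr, 8) for _ in range(n_ch))
    header += b"".join(_edf_field("", 32) for _ in range(n_ch))

    scale = (pmaxs - pmins) / (_EDF_DIGITAL_MAX - _EDF_DIGITAL_MIN)
    digital = np.rint((rec.data - pmins[:, None]) / scale[:, None] + _EDF_DIGITAL_MIN)
    digital = np.clip(digital, _EDF_DIGITAL_MIN, _EDF_DIGITAL_MAX).astype("<i2")
    # record-major layout: for each record, each signal's spr samples in turn
    body = (
        digital.reshape(n_ch, n_records, spr)
        .transpose(1, 0, 2)
        .tobytes()
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(body)

    if rec.events:
        lines = ["onset_sample\tlabel"]
        lines += [f"{ev.onset_sample}\t{ev.label}" for ev in rec.events]
        _events_sidecar_path(path).write_text("\n".join(lines) + "\n")


def _read_edf(path: Path, label_map: Mapping[str, str] | None) -> Recording:
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types on malformed files
        raise ValueError(f"could not parse EDF file {path}: {exc}") from exc
    data = raw.get_data() * 1e6  # mne returns volts for EEG channels
    labels = [lab.removeprefix("EEG ").strip() for lab in raw.ch_names]
    fs = float(raw.info["sfreq"])

    events: list[Event] = []
    sidecar = _events_sidecar_path(path)
    if sidecar.exists():
        events = _read_events_tsv(sidecar, label_map)
    elif len(raw.annotations):
        for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
            events.append(Event(int(round(onset * fs)), _map_label(desc, label_map)))
    return Recording(data=data, fs=fs, channel_labels=labels, events=events)


def _read_events_tsv(path: Path, label_map: Mapping[str, str] | None) -> list[Event]:
    events: list[Event] = []
    lines = path.read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if lineno == 1 and line.startswith("onset_sample"):
            continue
        if not line.strip():
            continue
        onset_s, _, lab = line.partition("\t")
        try:
            onset = int(onset_s)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: unparseable onset_sample {onset_s!r}") from exc
        events.append(Event(onset, _map_label(lab.strip(), label_map)))
    return events


def _map_label(raw_label: str, label_map: Mapping[str, str] | None) -> str:
    label = (label_map or {}).get(raw_label, raw_label)
    if label not in TASK_LABELS:
        raise ValueError(
            f"unknown event label {raw_label!r}; permitted labels: {TASK_LABELS} "
            "(pass label_map to translate)"
        )
    return label


# ---------------------------------------------------------------------------
# public API


def read_recording(
    path: str | Path,
    format: str = "edf",
    label_map: Mapping[str, str] | None = None,
) -> Recording:
    """Read a :class:`Recording` from ``path``.

    Parameters
    ----------
    path
        File to read.
    format
        ``"edf"`` or ``"matrix"``.
    label_map
        Optional translation from on-disk event descriptions to the permitted
        labels (``rest``, ``grasp``, ``elbow``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "edf":
        return _read_edf(path, label_map)
    if format == "matrix":
        return _read_matrix(path, label_map)
    raise ValueError(f"unknown format {format!r}; expected 'edf' or 'matrix'")


def write_recording(rec: Recording, path: str | Path, format: str = "edf") -> None:
    """Write ``rec`` so that :func:`read_recording` recovers it.

    Sampling rate, channel labels and event onsets round-trip exactly; sample
    values round-trip exactly for ``matrix`` and to within 16-bit quantization
    of each channel's physical range for ``edf``.
    """
    if not np.all(np.isfinite(rec.data)):
        raise ValueError("Recording.data contains non-finite samples; refusing to write")
    path = Path(path)
    if format == "edf":
        _write_edf(rec, path)
    elif format == "matrix":
        _write_matrix(rec, path)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'edf' or 'matrix'")


def extract_epochs(
    rec: Recording,
    classes: Sequence[str],
    epoch_duration: float,
    offset: float = 0.0,
) -> EpochSet:
    """Cut one fixed-length trial per selected event.

    ``classes`` selects which event labels become trials and fixes the integer
    encoding: label code = position in ``classes``.  Each trial is the
    half-open window ``[onset + offset, onset + offset + epoch_duration)`` in
    samples (offset 0 starts at the cue).
    """
    classes = list(classes)
    n_samp = int(round(epoch_duration * rec.fs))
    off = int(round(offset * rec.fs))
    picks = [(i, ev) for i, ev in enumerate(rec.events) if ev.label in classes]
    trials = np.empty((len(picks), rec.n_channels, n_samp))
    labels = np.empty(len(picks), dtype=int)
    for row, (i, ev) in enumerate(picks):
        start = ev.onset_sample + off
        stop = start + n_samp
        if start < 0 or stop > rec.n_samples:
            raise ValueError(
                f"event {i} ({ev.label!r} at sample {ev.onset_sample}): window "
                f"[{start}, {stop}) outside recording of {rec.n_samples} samples"
            )
        trials[row] = rec.data[:, start:stop]
        labels[row] = classes.index(ev.label)
    return EpochSet(
        data=trials,
        labels=labels,
        fs=rec.fs,
        channel_labels=list(rec.channel_labels),
        class_names=classes,
    )
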