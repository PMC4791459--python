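"""Simulate a synthetic motor-imagery recording and locate the class contrast.

Generates one subject with event-related desynchronization on C3/C4, writes
and re-reads it as EDF, and prints the per-channel variance contrast between
imagined-grasp and rest epochs.
"""

import tempfile
from pathlib import Path

from motorimagery import (
    SimSpec,
    channel_variation,
    extract_epochs,
    read_recording,
    simulate_recording,
    write_recording,
)

rec = simulate_recording(SimSpec(n_trials=15, seed=1))
print(f"recording: {rec.n_channels} channels x {rec.n_samples} samples "
      f"at {rec.fs:g} Hz, {len(rec.events)} trial events")

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "subject.edf"
    write_recording(rec, path, format="edf")
    rec = read_recording(path, format="edf")
print(f"EDF round trip: {path.name} -> {rec.n_channels} channels, "
      f"{len(rec.events)} events preserved")

grasp = extract_epochs(rec, ("grasp",), 3.0)
rest = extract_epochs(rec, ("rest",), 3.0)
profile = channel_variation(rest, grasp)
print("\nper-channel variance (uV^2): rest vs grasp, largest contrasts first")
print(profile.sort_values("abs_difference", ascending=False).head(5).round(1))
print("\nThe contrast concentrates on C3/C4: rhythm power drops during "
      "imagined grasping over sensorimotor cortex.")
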