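import numpy as np
import pytest

from motorimagery import SegmentSet, SimSpec, extract_epochs, segment, simulate_recording


@pytest.fixture(scope="session")
def strong_recording():
    """A synthetic subject with the default (strong) sensorimotor contrast."""
    return simulate_recording(SimSpec(n_trials=12, seed=7))


@pytest.fixture(scope="session")
def strong_segments(strong_recording):
    epochs = extract_epochs(strong_recording, ("rest", "grasp"), 3.0)
    return segment(epochs, 0.25)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_noise_segments(
    rng,
    n_per_class=20,
    n_channels=4,
    n_samples=250,
    fs=1000.0,
    scale_by_class=None,
):
    """White-noise SegmentSet (one segment per trial), optional per-class scaling
    of channel 0."""
    n = 2 * n_per_class
    data = rng.standard_normal((n, n_channels, n_samples))
    labels = np.repeat([0, 1], n_per_class)
    if scale_by_class is not None:
        for cls, s in enumerate(scale_by_class):
            data[labels == cls, 0, :] *= s
    return SegmentSet(
        data=data,
        labels=labels,
        parent_trial=np.arange(n),
        fs=fs,
        channel_labels=[f"ch{i}" for i in range(n_channels)],
        class_names=("rest", "grasp"),
    )
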