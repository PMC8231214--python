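import numpy as np
import pytest

from collarcnn.data_io import BehaviourLabel, LabelledTrace
from collarcnn.preprocessing import Window, WindowSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_trace(rng):
    """60 s labelled trace at 10 Hz with a mid-trace label change."""
    n = 600
    ts = np.arange(n) / 10.0
    accel = rng.standard_normal((n, 3))
    labels = np.where(np.arange(n) < 350, BehaviourLabel.EATING, BehaviourLabel.OTHER)
    return LabelledTrace("steerA", ts, accel, labels)


def make_windowset(
    n_per_animal_class: int,
    animals,
    length: int = 50,
    seed: int = 0,
    amplitude_by_class=(0.2, 1.0, 3.0),
    freq_by_class=(0.5, 1.2, 3.0),
) -> WindowSet:
    """Synthetic windows with class-specific frequency and amplitude so a
    small CNN can separate them; used by the training-level tests."""
    rng = np.random.default_rng(seed)
    t = np.arange(length) / 10.0
    windows = []
    for animal in animals:
        for cls in range(3):
            for _ in range(n_per_animal_class):
                phase = rng.uniform(0, 2 * np.pi, size=(3, 1))
                base = amplitude_by_class[cls] * np.sin(
                    2 * np.pi * freq_by_class[cls] * t[None, :] + phase
                )
                data = base + 0.05 * rng.standard_normal((3, length))
                windows.append(
                    Window(data=data, label=cls, animal_id=animal, start_time=0.0)
                )
    return WindowSet(windows, window_seconds=length / 10.0)
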