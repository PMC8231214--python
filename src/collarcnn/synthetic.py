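"""Synthetic herd generator.

Emulates the statistical structure of neck-collar accelerometry that the
classifier relies on, so the full pipeline (differencing, windowing,
training, pruning, deployment accounting) is exercisable without field data:

* behaviour is a semi-Markov chain of bouts lasting minutes, not a
  per-sample chain — real rumination/eating bouts persist;
* RUMINATION is a rhythmic chewing oscillation interrupted by a ~2 s
  regurgitation pause every 40–60 s (the contraction cycle);
* EATING is a chewing oscillation at higher amplitude plus broadband
  head-motion bursts (tossing, pulling feed);
* OTHER is near-stationary posture with sporadic movement spikes;
* each axis carries a slowly drifting offset (random walk) standing in for
  gravity leakage as the collar rotates around the neck, plus white noise.

The generator makes no claim of biomechanical fidelity; it reproduces the
separability structure (narrowband vs broadband vs quiet, with overlapping
amplitudes between eating and rumination) that the method assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import SAMPLING_RATE_HZ, BehaviourLabel, LabelledTrace

__all__ = ["SynthConfig", "generate_herd", "make_split_fixture", "stationary_fractions"]

_N_STATES = 3

#: fixed per-state axis coupling (x, y, z): rumination loads the neck axes,
#: eating the head axis; purely a device-geometry convention.
_AXIS_WEIGHTS = {
    BehaviourLabel.RUMINATION: np.array([0.35, 1.0, 0.6]),
    BehaviourLabel.EATING: np.array([1.0, 0.7, 0.5]),
    BehaviourLabel.OTHER: np.array([1.0, 1.0, 1.0]),
}


def _default_transitions() -> np.ndarray:
    # uniform over the other two states; zero diagonal (bouts are maximal)
    m = np.full((_N_STATES, _N_STATES), 0.5)
    np.fill_diagonal(m, 0.0)
    return m


@dataclass
class SynthConfig:
    """Herd-generation parameters.

    Defaults are the package's canonical study conditions: an 18-animal herd,
    4 h per animal, bout dwell means of 10/8/12 min for rumination, eating
    and other, chewing at 1.2 Hz, and a rumination contraction pause drawn
    uniformly from 40–60 s intervals. The dwell means and trace length are
    chosen together so every animal cycles through every state several times
    (field bouts are longer, but field traces are also two orders of
    magnitude longer); amplitudes overlap between eating and rumination so
    the classes are learnable but not trivially separable.
    """

    n_animals: int = 18
    hours_per_animal: float = 4.0
    seed: int = 0
    transition_matrix: np.ndarray = field(default_factory=_default_transitions)
    dwell_means_min: tuple[float, float, float] = (10.0, 8.0, 12.0)
    min_dwell_s: float = 60.0
    rumination_cycle_s: tuple[float, float] = (40.0, 60.0)
    rumination_pause_s: float = 2.0
    chew_freq_hz: float = 1.2
    state_amplitudes: tuple[float, float, float] = (0.5, 0.9, 0.15)
    gravity_drift_scale: float = 0.002
    noise_sd: float = 0.05
    initial_state: int | None = None
    sampling_rate: float = SAMPLING_RATE_HZ

    def validate(self) -> None:
        m = np.asarray(self.transition_matrix, dtype=float)
        if m.shape != (_N_STATES, _N_STATES):
            raise ValueError("transition_matrix must be 3x3")
        if not np.allclose(m.sum(axis=1), 1.0):
            raise ValueError("transition_matrix rows must sum to 1")
        if np.any(np.diag(m) != 0):
            raise ValueError("transition_matrix diagonal must be zero (bouts are maximal)")
        if np.any(m < 0):
            raise ValueError("transition probabilities must be non-negative")
        if any(d <= 0 for d in self.dwell_means_min):
            raise ValueError("dwell means must be positive")
        if min(self.state_amplitudes) < 0 or self.noise_sd < 0 or self.gravity_drift_scale < 0:
            raise ValueError("amplitudes, noise and drift scales must be >= 0")
        if self.n_animals <= 0 or self.hours_per_animal <= 0:
            raise ValueError("herd must have at least one animal and positive duration")


def stationary_fractions(
    transition_matrix: np.ndarray, dwell_means_min: tuple[float, float, float]
) -> np.ndarray:
    """Dwell-weighted stationary distribution of the bout chain.

    The fraction of *time* in state i is pi_i * d_i / sum_j pi_j * d_j where
    pi is the stationary distribution of the embedded bout chain and d the
    mean dwell. This is the closed form the label-fraction tests check
    against.
    """
    m = np.asarray(transition_matrix, dtype=float)
    eigvals, eigvecs = np.linalg.eig(m.T)
    k = int(np.argmin(np.abs(eigvals - 1.0)))
    pi = np.real(eigvecs[:, k])
    pi = pi / pi.sum()
    weighted = pi * np.asarray(dwell_means_min, dtype=float)
    return weighted / weighted.sum()


def _simulate_states(
    config: SynthConfig, n_samples: int, rng: np.random.Generator
) -> tuple[np.ndarray, list[tuple[int, int, int]]]:
    """Semi-Markov state path: returns per-sample labels and bout list
    (state, start index, end index)."""
    fs = config.sampling_rate
    dwell_s = np.asarray(config.dwell_means_min, dtype=float) * 60.0
    if config.initial_state is not None:
        state = int(config.initial_state)
    else:
        pi = stationary_fractions(config.transition_matrix, config.dwell_means_min)
        state = int(rng.choice(_N_STATES, p=pi))
    labels = np.empty(n_samples, dtype=np.int64)
    bouts: list[tuple[int, int, int]] = []
    pos = 0
    while pos < n_samples:
        # shifted exponential: floor + Exp(mean - floor) so the bout mean is
        # exactly dwell_s while respecting the one-minute minimum
        mean, floor = dwell_s[state], config.min_dwell_s
        dur_s = floor + rng.exponential(max(mean - floor, 1e-9))
        dur = max(1, int(round(dur_s * fs)))
        end = min(pos + dur, n_samples)
        labels[pos:end] = state
        bouts.append((state, pos, end))
        pos = end
        state = int(rng.choice(_N_STATES, p=config.transition_matrix[state]))
    return labels, bouts


def _rumination_gate(n: int, fs: float, config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """1/0 gate that switches the chew oscillation off for ~2 s at each
    regurgitation pause; pause spacing drawn uniformly from the cycle range."""
    gate = np.ones(n)
    lo, hi = config.rumination_cycle_s
    t = rng.uniform(lo, hi)
    pause = int(round(config.rumination_pause_s * fs))
    while t * fs < n:
        start = int(round(t * fs))
        gate[start : start + pause] = 0.0
        t += rng.uniform(lo, hi)
    return gate


def _bout_signal(
    state: int, n: int, config: SynthConfig, rng: np.random.Generator
) -> np.ndarray:
    """(n, 3) motion signal for one bout, before drift and sensor noise."""
    fs = config.sampling_rate
    t = np.arange(n) / fs
    amp = config.state_amplitudes[state]
    out = np.zeros((n, 3))
    w = _AXIS_WEIGHTS[BehaviourLabel(state)]
    if state == BehaviourLabel.RUMINATION:
        phase = rng.uniform(0, 2 * np.pi, size=3)
        envelope = 1.0 + 0.2 * np.sin(2 * np.pi * 0.05 * t + rng.uniform(0, 2 * np.pi))
        gate = _rumination_gate(n, fs, config, rng)
        carrier = np.sin(2 * np.pi * config.chew_freq_hz * t[:, None] + phase)
        out = amp * w * (envelope * gate)[:, None] * carrier
    elif state == BehaviourLabel.EATING:
        phase = rng.uniform(0, 2 * np.pi, size=3)
        freq = config.chew_freq_hz * rng.uniform(0.9, 1.15)
        carrier = np.sin(2 * np.pi * freq * t[:, None] + phase)
        out = 0.6 * amp * w * carrier
        # broadband head-motion bursts: ~1 s of wideband noise every ~5 s
        pos = rng.exponential(5.0)
        while pos * fs < n:
            start = int(pos * fs)
            dur = int(rng.uniform(0.5, 1.5) * fs)
            seg = slice(start, min(start + dur, n))
            k = seg.stop - seg.start
            out[seg] += amp * w * rng.standard_normal((k, 3))
            pos += rng.exponential(5.0)
    else:  # OTHER: constant posture, sporadic movement spikes
        out += amp * rng.standard_normal(3)  # per-bout posture offset
        pos = rng.exponential(30.0)
        while pos * fs < n:
            start = int(pos * fs)
            out[start] += 6.0 * amp * w * rng.standard_normal(3)
            pos += rng.exponential(30.0)
    return out


def _simulate_animal(config: SynthConfig, animal_id: str, seed: int) -> LabelledTrace:
    rng = np.random.default_rng(seed)
    fs = config.sampling_rate
    n = int(round(config.hours_per_animal * 3600 * fs))
    labels, bouts = _simulate_states(config, n, rng)
    accel = np.zeros((n, 3))
    for state, start, end in bouts:
        accel[start:end] = _bout_signal(state, end - start, config, rng)
    # gravity leakage: independent per-axis random walk (collar rotation)
    if config.gravity_drift_scale > 0:
        accel += np.cumsum(
            config.gravity_drift_scale * rng.standard_normal((n, 3)), axis=0
        )
    if config.noise_sd > 0:
        accel += config.noise_sd * rng.standard_normal((n, 3))
    timestamps = np.arange(n) / fs
    return LabelledTrace(
        animal_id=animal_id,
        timestamps=timestamps,
        accel=accel,
        labels=labels,
        sampling_rate=fs,
    )


def generate_herd(config: SynthConfig) -> list[LabelledTrace]:
    """Generate ``config.n_animals`` labelled traces.

    Per-animal sub-seeds are ``config.seed + index`` so a herd can be
    extended without perturbing earlier animals; the whole herd is
    reproducible from the config alone.
    """
    config.validate()
    return [
        _simulate_animal(config, f"steer{i:02d}", config.seed + i)
        for i in range(config.n_animals)
    ]


def make_split_fixture(
    config: SynthConfig, n_test_animals: int
) -> tuple[list[LabelledTrace], list[LabelledTrace]]:
    """Generate a herd and hold out ``n_test_animals`` complete animals.

    Mirrors the study protocol of reserving whole animal traces for the test
    set; the train/validation and test animal sets are disjoint by
    construction.
    """
    if n_test_animals >= config.n_animals:
        raise ValueError(
            f"n_test_animals ({n_test_animals}) must be < n_animals ({config.n_animals})"
        )
    if n_test_animals < 0:
        raise ValueError("n_test_animals must be >= 0")
    herd = generate_herd(config)
    rng = np.random.default_rng(config.seed + 10_000)
    test_idx = set(rng.choice(len(herd), size=n_test_animals, replace=False).tolist())
    train = [t for i, t in enumerate(herd) if i not in test_idx]
    test = [t for i, t in enumerate(herd) if i in test_idx]
    return train, test
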