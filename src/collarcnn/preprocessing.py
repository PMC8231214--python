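"""Differencing, windowing, class/animal balancing and grouped folds.

The first-order difference Ds[t] = s[t] - s[t-1] removes the slowly varying
gravity component introduced by collar rotation, leaving motion-induced
acceleration. Differenced traces are cut into contiguous, non-overlapping
fixed-length windows, each labelled by majority vote; training sets are
balanced by undersampling so every animal contributes the same number of
windows per class; cross-validation folds partition *animals*, never
windows, so no animal's data can appear on both sides of a split.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .data_io import BehaviourLabel, LabelledTrace

__all__ = [
    "Window",
    "WindowSet",
    "FoldPlan",
    "BalanceError",
    "diff_trace",
    "segment_windows",
    "majority_label",
    "balance_windows",
    "make_folds",
]


class BalanceError(ValueError):
    """A (animal, class) cell required for balancing is empty."""


@dataclass
class Window:
    """One fixed-length differenced window: ``data`` is (3, L) float32."""

    data: np.ndarray
    label: int
    animal_id: str
    start_time: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 2 or self.data.shape[0] != 3 or self.data.shape[1] == 0:
            raise ValueError(f"window data must be (3, L), L>0; got {self.data.shape}")


@dataclass
class WindowSet:
    """A labelled collection of equal-length windows."""

    windows: list[Window]
    window_seconds: float

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def animal_ids(self) -> list[str]:
        return sorted({w.animal_id for w in self.windows})

    def counts(self) -> dict[tuple[str, int], int]:
        """Window count per (animal_id, label) cell."""
        return dict(Counter((w.animal_id, int(w.label)) for w in self.windows))

    def subset_animals(self, animal_ids) -> "WindowSet":
        wanted = set(animal_ids)
        return WindowSet(
            [w for w in self.windows if w.animal_id in wanted], self.window_seconds
        )

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Stack into (N, 3, L) float32 inputs and (N,) int64 targets."""
        if not self.windows:
            length = 0
            return (
                np.empty((0, 3, length), dtype=np.float32),
                np.empty((0,), dtype=np.int64),
            )
        x = np.stack([w.data for w in self.windows]).astype(np.float32)
        y = np.array([w.label for w in self.windows], dtype=np.int64)
        return x, y

    def extend(self, other: "WindowSet") -> "WindowSet":
        if other.window_seconds != self.window_seconds:
            raise ValueError("cannot mix window lengths in one WindowSet")
        return WindowSet(self.windows + other.windows, self.window_seconds)


@dataclass
class FoldPlan:
    """k disjoint animal-id sets forming a partition for grouped CV."""

    folds: list[list[str]]
    seed: int

    @property
    def k(self) -> int:
        return len(self.folds)

    def __post_init__(self) -> None:
        flat = [a for fold in self.folds for a in fold]
        if len(flat) != len(set(flat)):
            raise ValueError("folds overlap: an animal appears in more than one fold")
        sizes = [len(f) for f in self.folds]
        if sizes and max(sizes) - min(sizes) > 1:
            raise ValueError(f"fold sizes must differ by at most 1; got {sizes}")

    @property
    def animal_ids(self) -> list[str]:
        return sorted(a for fold in self.folds for a in fold)


def diff_trace(trace: LabelledTrace) -> LabelledTrace:
    """First-order difference per axis; output is one sample shorter.

    Labels and timestamps align to the *later* sample of each pair, so a
    label at index t in the output describes the interval ending at t.
    """
    if len(trace) < 2:
        raise ValueError("differencing needs at least 2 samples")
    accel = np.diff(trace.accel, axis=0)
    labels = trace.labels[1:] if trace.labels is not None else None
    return LabelledTrace(
        animal_id=trace.animal_id,
        timestamps=trace.timestamps[1:],
        accel=accel,
        labels=labels,
        sampling_rate=trace.sampling_rate,
    )


def majority_label(labels: np.ndarray) -> int:
    """Most frequent label in a block; ties break by enum declaration order
    (RUMINATION before EATING before OTHER)."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label block")
    counts = np.bincount(labels, minlength=len(BehaviourLabel))
    # argmax returns the first (lowest-code) maximum: exactly the tie rule
    return int(np.argmax(counts))


def segment_windows(trace: LabelledTrace, window_seconds: float) -> WindowSet:
    """Cut a differenced, labelled trace into contiguous non-overlapping
    windows of ``window_seconds * sampling_rate`` samples.

    The trailing remainder is dropped. A trace shorter than one window
    yields an empty WindowSet with a warning (not an error), so ragged herds
    do not abort a run.
    """
    if trace.labels is None:
        raise ValueError("segmentation requires a labelled trace")
    if window_seconds <= 0:
        raise ValueError("window_seconds must be positive")
    length = int(round(window_seconds * trace.sampling_rate))
    n = len(trace)
    n_windows = n // length
    if n_windows == 0:
        warnings.warn(
            f"trace {trace.animal_id!r} shorter than one {window_seconds} s window",
            stacklevel=2,
        )
        return WindowSet([], window_seconds)
    windows = []
    for i in range(n_windows):
        sl = slice(i * length, (i + 1) * length)
        windows.append(
            Window(
                data=trace.accel[sl].T,
                label=majority_label(trace.labels[sl]),
                animal_id=trace.animal_id,
                start_time=float(trace.timestamps[sl.start]),
            )
        )
    return WindowSet(windows, window_seconds)


def balance_windows(
    ws: WindowSet,
    seed: int,
    classes: tuple[int, ...] = tuple(int(c) for c in BehaviourLabel),
) -> WindowSet:
    """Undersample so every animal contributes the same count per class.

    The common count is the minimum over all (animal, class) cells; windows
    are drawn without replacement with a seeded generator, so the result is
    deterministic. An animal missing one of the required classes entirely
    cannot be balanced and raises :class:`BalanceError` naming it.
    """
    animals = ws.animal_ids
    counts = ws.counts()
    for animal in animals:
        for cls in classes:
            if counts.get((animal, cls), 0) == 0:
                raise BalanceError(
                    f"animal {animal!r} has no windows of class "
                    f"{BehaviourLabel(cls).name}; cannot balance"
                )
    target = min(counts[(a, c)] for a in animals for c in classes)
    rng = np.random.default_rng(seed)
    kept: list[Window] = []
    for animal in animals:
        for cls in classes:
            cell = [
                w for w in ws.windows if w.animal_id == animal and int(w.label) == cls
            ]
            idx = rng.choice(len(cell), size=target, replace=False)
            kept.extend(cell[i] for i in sorted(idx.tolist()))
    return WindowSet(kept, ws.window_seconds)


def make_folds(animal_ids, k: int = 5, seed: int = 0) -> FoldPlan:
    """Shuffle animal ids with ``seed`` and slice contiguously into ``k``
    folds of near-equal size (differing by at most one animal)."""
    ids = list(animal_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("animal ids must be unique")
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(ids) < k:
        raise ValueError(f"need at least k={k} animals; got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    shuffled = [ids[i] for i in order]
    folds = [part.tolist() for part in np.array_split(np.array(shuffled, dtype=object), k)]
    return FoldPlan(folds=[[str(a) for a in f] for f in folds], seed=seed)
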