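"""Collar / halter CSV input-output and timestamp merging.

Field data arrive as two independent 10 Hz streams per animal: the collar's
3-axis acceleration (x, y, z) and the halter's behaviour label derived from
muzzle pressure. Both devices carry their own real-time clock, so the two
grids never agree bit-exactly; merging is nearest-neighbour within half a
sampling interval. The merged per-animal stream is the unit every later
stage (differencing, windowing, training) consumes.
"""

from __future__ import annotations

import enum
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "BehaviourLabel",
    "LabelledTrace",
    "FormatError",
    "AlignmentError",
    "read_collar_csv",
    "read_halter_csv",
    "merge_by_timestamp",
    "write_trace_csv",
    "write_dataset",
    "read_dataset",
]

#: nominal collar/halter sampling rate, Hz
SAMPLING_RATE_HZ = 10.0

#: nearest-neighbour merge tolerance: half the 10 Hz sampling interval, seconds
MERGE_TOLERANCE_S = 0.05


class FormatError(ValueError):
    """A CSV file does not have the expected columns or cell types."""


class AlignmentError(ValueError):
    """Timestamps are unusable: non-monotonic, duplicated, or disjoint streams."""


class BehaviourLabel(enum.IntEnum):
    """The three behaviour states.

    Declaration order is load-bearing: majority-vote ties inside a window are
    broken in favour of the earlier member (RUMINATION > EATING > OTHER).
    """

    RUMINATION = 0
    EATING = 1
    OTHER = 2


@dataclass
class LabelledTrace:
    """One animal's 10 Hz 3-axis acceleration stream, optionally labelled.

    Parameters
    ----------
    animal_id : str
        Opaque identifier (stable across files).
    timestamps : ndarray, shape (n,)
        Epoch seconds, strictly increasing.
    accel : ndarray, shape (n, 3)
        Raw (x, y, z) acceleration samples.
    labels : ndarray of int, shape (n,), optional
        Per-sample behaviour codes (``BehaviourLabel`` values).
    sampling_rate : float
        Nominal rate in Hz; 10 for the collar hardware.
    """

    animal_id: str
    timestamps: np.ndarray
    accel: np.ndarray
    labels: np.ndarray | None = None
    sampling_rate: float = SAMPLING_RATE_HZ

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        if self.accel.ndim != 2 or self.accel.shape[1] != 3:
            raise FormatError(
                f"accel must be (n, 3); got shape {self.accel.shape}"
            )
        if self.timestamps.shape[0] != self.accel.shape[0]:
            raise FormatError("timestamps and accel lengths differ")
        if self.timestamps.size > 1:
            dt = np.diff(self.timestamps)
            if np.any(dt == 0):
                raise AlignmentError(
                    f"duplicated timestamp(s) in trace {self.animal_id!r}"
                )
            if np.any(dt < 0):
                raise AlignmentError(
                    f"timestamps not strictly increasing in trace {self.animal_id!r}"
                )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape[0] != self.timestamps.shape[0]:
                raise FormatError("labels and timestamps lengths differ")

    def __len__(self) -> int:
        return int(self.timestamps.shape[0])

    @property
    def is_labelled(self) -> bool:
        return self.labels is not None

    def equals(self, other: "LabelledTrace") -> bool:
        """Exact equality on id/timestamps/labels, float-close on acceleration."""
        if self.animal_id != other.animal_id or len(self) != len(other):
            return False
        if not np.array_equal(self.timestamps, other.timestamps):
            return False
        if (self.labels is None) != (other.labels is None):
            return False
        if self.labels is not None and not np.array_equal(self.labels, other.labels):
            return False
        return np.allclose(self.accel, other.accel, rtol=0, atol=1e-12)


_DEFAULT_COLUMNS = {"timestamp": "timestamp", "x": "x", "y": "y", "z": "z"}
_LABEL_COLUMN = "label"


def _normalise_timestamps(col: pd.Series, path: str | os.PathLike) -> np.ndarray:
    """Accept epoch seconds or ISO-8601 strings; return epoch seconds."""
    if pd.api.types.is_numeric_dtype(col):
        return col.to_numpy(dtype=float)
    try:
        parsed = pd.to_datetime(col, format="ISO8601", utc=True)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: unparseable timestamps ({exc})") from exc
    return parsed.astype("int64").to_numpy() / 1e9


def _parse_labels(col: pd.Series, path: str | os.PathLike) -> np.ndarray:
    if pd.api.types.is_numeric_dtype(col):
        values = col.to_numpy(dtype=np.int64)
        if not np.isin(values, [int(m) for m in BehaviourLabel]).all():
            raise FormatError(f"{path}: label codes outside {{0,1,2}}")
        return values
    try:
        return np.array(
            [BehaviourLabel[str(v).strip().upper()] for v in col], dtype=np.int64
        )
    except KeyError as exc:
        raise FormatError(f"{path}: unknown behaviour label {exc}") from exc


def read_collar_csv(
    path: str | os.PathLike,
    column_map: Mapping[str, str] | None = None,
    animal_id: str | None = None,
) -> LabelledTrace:
    """Read one collar CSV into a :class:`LabelledTrace`.

    The file must have a header row. ``column_map`` maps the logical names
    ``timestamp``/``x``/``y``/``z`` (and optionally ``label``) to the file's
    column names; the deposited-data layout varies, hence the indirection.
    Rows are sorted by timestamp; duplicated timestamps raise
    :class:`AlignmentError` (the differencing step needs a well-defined grid).
    """
    mapping = dict(_DEFAULT_COLUMNS)
    if column_map:
        mapping.update(column_map)
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as exc:
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc

    missing = [mapping[k] for k in ("timestamp", "x", "y", "z") if mapping[k] not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}; found {list(frame.columns)}")

    ts = _normalise_timestamps(frame[mapping["timestamp"]], path)
    axes = []
    for axis in ("x", "y", "z"):
        col = frame[mapping[axis]]
        numeric = pd.to_numeric(col, errors="coerce")
        bad = numeric.isna() & col.notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"{path}: non-numeric acceleration in column {mapping[axis]!r}, row {row}"
            )
        axes.append(numeric.to_numpy(dtype=float))
    accel = np.column_stack(axes)

    labels = None
    label_col = mapping.get("label", _LABEL_COLUMN)
    if label_col in frame.columns:
        labels = _parse_labels(frame[label_col], path)

    order = np.argsort(ts, kind="stable")
    ts, accel = ts[order], accel[order]
    if labels is not None:
        labels = labels[order]
    if animal_id is None:
        animal_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    return LabelledTrace(animal_id=animal_id, timestamps=ts, accel=accel, labels=labels)


def read_halter_csv(
    path: str | os.PathLike,
    column_map: Mapping[str, str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Read a halter ground-truth CSV; returns (timestamps, label codes)."""
    mapping = {"timestamp": "timestamp", "label": _LABEL_COLUMN}
    if column_map:
        mapping.update(column_map)
    try:
        frame = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    for key in ("timestamp", "label"):
        if mapping[key] not in frame.columns:
            raise FormatError(f"{path}: missing column {mapping[key]!r}")
    ts = _normalise_timestamps(frame[mapping["timestamp"]], path)
    labels = _parse_labels(frame[mapping["label"]], path)
    order = np.argsort(ts, kind="stable")
    return ts[order], labels[order]


def merge_by_timestamp(
    collar: LabelledTrace,
    halter: tuple[np.ndarray, np.ndarray],
    tolerance_s: float = MERGE_TOLERANCE_S,
) -> tuple[LabelledTrace, int]:
    """Attach halter labels to collar samples by nearest timestamp.

    Each collar sample takes the label of the nearest halter sample within
    ``tolerance_s`` (default: half the 10 Hz interval — the two devices keep
    independent clocks). Collar samples with no match are dropped.

    Returns
    -------
    (merged, n_dropped)
        The labelled trace and the count of collar samples dropped.

    Raises
    ------
    AlignmentError
        If no collar sample matches any halter sample.
    """
    h_ts = np.asarray(halter[0], dtype=float)
    h_labels = np.asarray(halter[1], dtype=np.int64)
    if h_ts.size == 0 or len(collar) == 0:
        raise AlignmentError("empty collar or halter stream")
    order = np.argsort(h_ts, kind="stable")
    h_ts, h_labels = h_ts[order], h_labels[order]

    idx = np.searchsorted(h_ts, collar.timestamps)
    left = np.clip(idx - 1, 0, h_ts.size - 1)
    right = np.clip(idx, 0, h_ts.size - 1)
    d_left = np.abs(collar.timestamps - h_ts[left])
    d_right = np.abs(collar.timestamps - h_ts[right])
    nearest = np.where(d_left <= d_right, left, right)
    dist = np.minimum(d_left, d_right)
    matched = dist <= tolerance_s

    n_dropped = int((~matched).sum())
    if matched.sum() == 0:
        raise AlignmentError(
            f"no halter label within {tolerance_s} s of any collar sample "
            f"(trace {collar.animal_id!r})"
        )
    merged = LabelledTrace(
        animal_id=collar.animal_id,
        timestamps=collar.timestamps[matched],
        accel=collar.accel[matched],
        labels=h_labels[nearest[matched]],
        sampling_rate=collar.sampling_rate,
    )
    return merged, n_dropped


# ---------------------------------------------------------------------------
# dataset persistence: per-animal CSVs plus a YAML manifest


def write_trace_csv(trace: LabelledTrace, path: str | os.PathLike) -> None:
    data = {
        "timestamp": trace.timestamps,
        "x": trace.accel[:, 0],
        "y": trace.accel[:, 1],
        "z": trace.accel[:, 2],
    }
    if trace.labels is not None:
        data["label"] = [BehaviourLabel(v).name for v in trace.labels]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def write_dataset(
    traces: Iterable[LabelledTrace],
    directory: str | os.PathLike,
    trial_id: str = "synthetic",
) -> str:
    """Write per-animal CSVs and a YAML manifest; returns the manifest path."""
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    entries = []
    for trace in traces:
        fname = f"{trace.animal_id}.csv"
        write_trace_csv(trace, os.path.join(directory, fname))
        entries.append({"animal_id": trace.animal_id, "file": fname})
    manifest = {
        "trial_id": trial_id,
        "sampling_rate_hz": SAMPLING_RATE_HZ,
        "animals": entries,
    }
    manifest_path = os.path.join(directory, "manifest.yaml")
    with open(manifest_path, "w") as handle:
        yaml.safe_dump(manifest, handle, sort_keys=False)
    return manifest_path


def read_dataset(manifest_path: str | os.PathLike) -> list[LabelledTrace]:
    """Read a dataset back from its YAML manifest."""
    with open(manifest_path) as handle:
        manifest = yaml.safe_load(handle)
    if not isinstance(manifest, dict) or "animals" not in manifest:
        raise FormatError(f"{manifest_path}: not a dataset manifest")
    base = os.path.dirname(os.fspath(manifest_path))
    traces = []
    for entry in manifest["animals"]:
        traces.append(
            read_collar_csv(
                os.path.join(base, entry["file"]), animal_id=entry["animal_id"]
            )
        )
    return traces
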