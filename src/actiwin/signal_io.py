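"""Reading and writing labeled tri-axial acceleration recordings.

Two on-disk dialects are supported:

* the PAMAP2 protocol dialect — whitespace-separated ``.dat`` files with 54
  numeric columns per row, one row per 100 Hz sample, ``NaN`` marking wireless
  dropouts;
* a generic long-format CSV dialect with a header row naming a timestamp
  column, an activity-label column and three acceleration columns per sensor.

Both produce the same in-memory :class:`Recording`, which downstream modules
(windowing, feature extraction) consume.  Label handling — the activity-code
vocabulary and the transient/break code — and the missing-data policy live
here so the rest of the pipeline can assume clean, labeled streams.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, FormatError, SchemaError

# --------------------------------------------------------------------------
# Activity vocabulary
# --------------------------------------------------------------------------

#: Code used for breaks / transitions between scripted activities.
TRANSIENT_CODE = 0

#: The 12 recognized activities, keyed by the dataset's integer codes.
DEFAULT_ACTIVITY_MAP: dict[int, str] = {
    1: "lying",
    2: "sitting",
    3: "standing",
    4: "walking",
    5: "running",
    6: "cycling",
    7: "nordic_walking",
    12: "ascending_stairs",
    13: "descending_stairs",
    16: "vacuum_cleaning",
    17: "ironing",
    24: "rope_jumping",
}

#: Short display labels in the conventional A1..A12 order.
ACTIVITY_SHORT_LABELS: dict[int, str] = {
    code: f"A{i + 1}" for i, code in enumerate(DEFAULT_ACTIVITY_MAP)
}

#: Supported sensor placements, in canonical order.
PLACEMENTS = ("wrist", "chest", "ankle")

# --------------------------------------------------------------------------
# PAMAP2 column layout
# --------------------------------------------------------------------------
# Each protocol row has 54 whitespace-separated columns:
#   col 0        timestamp (s)
#   col 1        activity code
#   col 2        heart rate (bpm; ignored here)
#   cols 3..19   hand-worn IMU   (17 columns)
#   cols 20..36  chest IMU       (17 columns)
#   cols 37..53  ankle IMU       (17 columns)
# Within each 17-column IMU block:
#   [0]      temperature
#   [1:4]    +/-16 g tri-axial accelerometer  <- the only channels used here
#   [4:7]    +/-6 g accelerometer (saturates during vigorous activity)
#   [7:10]   gyroscope, [10:13] magnetometer, [13:17] orientation quaternion
PAMAP2_N_COLUMNS = 54
PAMAP2_TIMESTAMP_COL = 0
PAMAP2_ACTIVITY_COL = 1
_PAMAP2_IMU_STARTS = {"wrist": 3, "chest": 20, "ankle": 37}
_PAMAP2_ACC16_OFFSET = 1  # offset of the +/-16 g accelerometer inside a block

#: placement -> (x, y, z) absolute column indices of the +/-16 g accelerometer.
PAMAP2_ACCEL_COLUMNS: dict[str, tuple[int, int, int]] = {
    p: tuple(start + _PAMAP2_ACC16_OFFSET + i for i in range(3))
    for p, start in _PAMAP2_IMU_STARTS.items()
}


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass
class SensorStream:
    """Tri-axial acceleration from one body-worn sensor, in m/s^2.

    Missing samples (wireless dropouts) are represented as ``NaN``.
    """

    placement: str
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        self.z = np.asarray(self.z, dtype=np.float64)
        if not (len(self.x) == len(self.y) == len(self.z)):
            raise DomainError(f"axes of sensor {self.placement!r} differ in length")

    def __len__(self) -> int:
        return len(self.x)

    def as_array(self) -> np.ndarray:
        """Return an (n, 3) array with columns x, y, z."""
        return np.column_stack([self.x, self.y, self.z])

    def n_missing(self) -> int:
        """Number of samples missing in at least one axis."""
        return int(np.isnan(self.as_array()).any(axis=1).sum())


@dataclass
class Recording:
    """A labeled multi-sensor acceleration time series at a fixed rate.

    ``sensors`` is an ordered mapping from placement label ("wrist", "chest",
    "ankle") to :class:`SensorStream`; ``labels`` holds one activity code per
    sample, aligned with ``timestamps`` (seconds, strictly increasing).
    """

    subject_id: str
    sampling_rate: float
    sensors: dict[str, SensorStream]
    labels: np.ndarray
    timestamps: np.ndarray
    activity_map: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_ACTIVITY_MAP))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.timestamps = np.asarray(self.timestamps, dtype=np.float64)
        if self.sampling_rate <= 0:
            raise DomainError("sampling_rate must be positive")
        n = len(self.labels)
        if len(self.timestamps) != n:
            raise DomainError("labels and timestamps differ in length")
        for stream in self.sensors.values():
            if len(stream) != n:
                raise DomainError(
                    f"sensor {stream.placement!r} length {len(stream)} != label length {n}"
                )
        if n > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise DomainError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.labels)

    def activity_name(self, code: int) -> str:
        if code == TRANSIENT_CODE:
            return "TRANSIENT"
        return self.activity_map.get(int(code), f"unknown_{code}")


@dataclass(frozen=True)
class Segment:
    """A maximal run of identical activity code, as a half-open index range."""

    code: int
    start: int
    stop: int
    is_transient: bool

    def __len__(self) -> int:
        return self.stop - self.start


# --------------------------------------------------------------------------
# Readers / writers
# --------------------------------------------------------------------------


def read_pamap2(
    path,
    placements: tuple[str, ...] = PLACEMENTS,
    subject_id: str | None = None,
    sampling_rate: float = 100.0,
    activity_map: dict[int, str] | None = None,
) -> Recording:
    """Read a PAMAP2 protocol ``.dat`` file into a :class:`Recording`.

    Only the +/-16 g accelerometer channels of the requested IMUs are kept
    (the +/-6 g accelerometer saturates during vigorous activities and the
    remaining channels are outside this pipeline's scope).  The PAMAP2
    "hand" IMU is exposed under the placement label ``"wrist"``.

    ``NaN`` dropout markers are preserved; rows carrying the transient code
    are retained and flagged by :func:`contiguous_segments`.
    """
    for p in placements:
        if p not in PAMAP2_ACCEL_COLUMNS:
            raise SchemaError(f"unknown placement {p!r}; expected one of {PLACEMENTS}")
    try:
        df = pd.read_csv(path, sep=r"\s+", header=None, dtype=np.float64)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    except pd.errors.ParserError as exc:
        # pandas names the offending line for over-wide rows
        raise FormatError(f"{path}: malformed row ({exc})") from None
    except ValueError as exc:
        raise FormatError(f"{path}: not a numeric whitespace-separated table ({exc})") from None
    if df.shape[1] != PAMAP2_N_COLUMNS:
        raise FormatError(
            f"{path}: expected {PAMAP2_N_COLUMNS} columns, found {df.shape[1]} (line 1)"
        )
    raw = df.to_numpy()
    timestamps = raw[:, PAMAP2_TIMESTAMP_COL]
    label_col = raw[:, PAMAP2_ACTIVITY_COL]
    if np.isnan(label_col).any():
        bad = int(np.flatnonzero(np.isnan(label_col))[0]) + 1
        raise FormatError(f"{path}: malformed row (non-numeric or missing activity) at line {bad}")
    sensors: dict[str, SensorStream] = {}
    for p in placements:
        cx, cy, cz = PAMAP2_ACCEL_COLUMNS[p]
        sensors[p] = SensorStream(p, raw[:, cx], raw[:, cy], raw[:, cz])
    return Recording(
        subject_id=subject_id or str(path),
        sampling_rate=sampling_rate,
        sensors=sensors,
        labels=label_col.astype(np.int64),
        timestamps=timestamps,
        activity_map=dict(activity_map or DEFAULT_ACTIVITY_MAP),
    )


#: Default header names of the generic CSV dialect: ``timestamp``,
#: ``activity`` and ``<placement>_x|_y|_z`` per sensor.
def default_csv_schema(placements: tuple[str, ...] = PLACEMENTS) -> dict:
    return {
        "timestamp": "timestamp",
        "label": "activity",
        "sensors": {p: (f"{p}_x", f"{p}_y", f"{p}_z") for p in placements},
    }


def read_csv_recording(
    path,
    schema: dict | None = None,
    subject_id: str | None = None,
    sampling_rate: float = 100.0,
    activity_map: dict[int, str] | None = None,
) -> Recording:
    """Read the generic CSV dialect into a :class:`Recording`.

    ``schema`` maps logical roles to column names::

        {"timestamp": "timestamp", "label": "activity",
         "sensors": {"wrist": ("wrist_x", "wrist_y", "wrist_z"), ...}}
    """
    schema = schema or default_csv_schema()
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    needed = [schema["timestamp"], schema["label"]]
    for cols in schema["sensors"].values():
        needed.extend(cols)
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: schema maps absent column(s) {missing}")
    sensors = {
        p: SensorStream(p, df[cx].to_numpy(), df[cy].to_numpy(), df[cz].to_numpy())
        for p, (cx, cy, cz) in schema["sensors"].items()
    }
    return Recording(
        subject_id=subject_id or str(path),
        sampling_rate=sampling_rate,
        sensors=sensors,
        labels=df[schema["label"]].to_numpy(dtype=np.int64),
        timestamps=df[schema["timestamp"]].to_numpy(dtype=np.float64),
        activity_map=dict(activity_map or DEFAULT_ACTIVITY_MAP),
    )


def write_csv_recording(rec: Recording, path, schema: dict | None = None) -> None:
    """Write a :class:`Recording` in the generic CSV dialect (round-trip safe)."""
    schema = schema or default_csv_schema(tuple(rec.sensors))
    data = {schema["timestamp"]: rec.timestamps, schema["label"]: rec.labels}
    for p, (cx, cy, cz) in schema["sensors"].items():
        stream = rec.sensors[p]
        data[cx], data[cy], data[cz] = stream.x, stream.y, stream.z
    # full repr precision so float samples survive the text round trip
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


# --------------------------------------------------------------------------
# Segmentation of the label stream and missing-data policy
# --------------------------------------------------------------------------


def contiguous_segments(rec: Recording) -> list[Segment]:
    """Maximal runs of identical activity code as half-open index ranges.

    The returned segments are disjoint, ordered and cover every sample;
    runs of the transient/break code are flagged ``is_transient`` so the
    windowing stage can exclude them.
    """
    labels = rec.labels
    if len(labels) == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    stops = np.concatenate([change, [len(labels)]])
    return [
        Segment(int(labels[a]), int(a), int(b), bool(labels[a] == TRANSIENT_CODE))
        for a, b in zip(starts, stops)
    ]


def interpolate_missing(rec: Recording, max_gap_s: float = 0.1) -> Recording:
    """Fill short dropout gaps by linear interpolation within activity segments.

    Gaps longer than ``max_gap_s`` (default 0.1 s, i.e. 10 samples at 100 Hz)
    are left as ``NaN``; windows overlapping them are later dropped by the
    windowing stage's missing-fraction policy.  Interpolation never crosses an
    activity boundary.
    """
    max_gap = int(round(max_gap_s * rec.sampling_rate))
    segments = contiguous_segments(rec)
    new_sensors: dict[str, SensorStream] = {}
    for p, stream in rec.sensors.items():
        axes = []
        for series in (stream.x, stream.y, stream.z):
            out = series.copy()
            for seg in segments:
                _fill_gaps_inplace(out[seg.start : seg.stop], max_gap)
            axes.append(out)
        new_sensors[p] = SensorStream(p, *axes)
    return Recording(
        rec.subject_id, rec.sampling_rate, new_sensors, rec.labels, rec.timestamps,
        dict(rec.activity_map),
    )


def _fill_gaps_inplace(series: np.ndarray, max_gap: int) -> None:
    """Linearly interpolate interior NaN runs of length <= max_gap (view-modifying)."""
    isnan = np.isnan(series)
    if not isnan.any() or isnan.all() or max_gap <= 0:
        return
    idx = np.arange(len(series))
    # identify NaN runs
    edges = np.diff(isnan.astype(np.int8))
    run_starts = list(np.flatnonzero(edges == 1) + 1)
    run_stops = list(np.flatnonzero(edges == -1) + 1)
    if isnan[0]:
        run_starts.insert(0, 0)
    if isnan[-1]:
        run_stops.append(len(series))
    for a, b in zip(run_starts, run_stops):
        if b - a > max_gap:
            continue
        if a == 0 or b == len(series):
            continue  # no anchor on one side; leave for the window-drop policy
        series[a:b] = np.interp(idx[a:b], [a - 1, b], [series[a - 1], series[b]])


def validate_placements(placements) -> tuple[str, ...]:
    """Normalize and validate a user-supplied sensor list (fail before compute)."""
    placements = tuple(placements)
    unknown = [p for p in placements if p not in PLACEMENTS]
    if unknown:
        raise SchemaError(f"unknown sensor placement(s) {unknown}; expected subset of {PLACEMENTS}")
    if len(set(placements)) != len(placements):
        warnings.warn("duplicate placements collapsed", stacklevel=2)
        placements = tuple(dict.fromkeys(placements))
    return placements
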