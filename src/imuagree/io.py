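"""Reading and writing sensor recordings, trial manifests and result tables.

One canonical CSV dialect is used for every per-trial recording: a header
row followed by one row per sample at a fixed rate (60 Hz by default),
with columns

    ``time``                               seconds from trial start
    ``quat_w, quat_x, quat_y, quat_z``     unit orientation quaternion
    ``freeacc_z, freeacc_x, freeacc_y``    free (gravity-removed) acceleration, m/s^2
    ``direction``                          optional +1/-1 walking-direction flag

Acceleration axes are stored in (z, x, y) order, the order in which
per-axis results are reported downstream.  All floats are printed with 17
significant digits so a write/read round trip is lossless.
"""

from __future__ import annotations

import enum
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Device",
    "Location",
    "Side",
    "Activity",
    "SensorRecording",
    "TrialEntry",
    "TrialManifest",
    "RecordingFormatError",
    "RecordingParseError",
    "RecordingIntegrityError",
    "read_recording",
    "write_recording",
    "write_long_table",
    "read_long_table",
    "RANGE_TABLE_COLUMNS",
    "AXES",
]

#: Axis storage and reporting order.
AXES = ("z", "x", "y")

QUAT_COLUMNS = ("quat_w", "quat_x", "quat_y", "quat_z")
ACC_COLUMNS = ("freeacc_z", "freeacc_x", "freeacc_y")

#: Fixed column order of the long-format range table.
RANGE_TABLE_COLUMNS = (
    "participant_id",
    "device",
    "session",
    "activity",
    "location",
    "axis",
    "quantity",
    "range_value",
    "n_cycles_used",
)


class Device(str, enum.Enum):
    TEST = "test"
    CRITERION = "criterion"


class Location(str, enum.Enum):
    SACRUM = "sacrum"
    THIGH = "thigh"
    SHANK = "shank"


class Side(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"
    NONE = "none"


class Activity(str, enum.Enum):
    SQUAT = "squat"
    JUMP = "jump"
    WALK = "walk"
    STAIR_ASCENT = "stair_ascent"
    STAIR_DESCENT = "stair_descent"


class RecordingFormatError(ValueError):
    """The file does not follow the documented CSV dialect."""


class RecordingParseError(ValueError):
    """A sample value could not be interpreted (non-finite / non-numeric)."""


class RecordingIntegrityError(ValueError):
    """The file parses but violates a physical invariant (quaternion norm)."""


@dataclass
class SensorRecording:
    """One device x location x session x activity stream.

    ``quat`` is an (N, 4) array in (w, x, y, z) order; ``free_acc`` is an
    (N, 3) array in (z, x, y) axis order.  ``walk_direction`` holds a
    per-sample +1/-1 flag and is present exactly for walking trials.
    """

    participant_id: str
    device: Device
    location: Location
    session: int
    activity: Activity
    quat: np.ndarray
    free_acc: np.ndarray
    sample_rate: float = 60.0
    side: Side = Side.NONE
    walk_direction: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.device = Device(self.device)
        self.location = Location(self.location)
        self.activity = Activity(self.activity)
        self.side = Side(self.side)
        self.quat = np.asarray(self.quat, dtype=float)
        self.free_acc = np.asarray(self.free_acc, dtype=float)
        if self.quat.ndim != 2 or self.quat.shape[1] != 4:
            raise ValueError("quat must be an (N, 4) array in (w, x, y, z) order")
        if self.free_acc.ndim != 2 or self.free_acc.shape[1] != 3:
            raise ValueError("free_acc must be an (N, 3) array in (z, x, y) order")
        if len(self.quat) != len(self.free_acc):
            raise ValueError("quat and free_acc must have equal length")
        if len(self.quat) < 2:
            raise ValueError("recording must contain at least 2 samples")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not (np.isfinite(self.quat).all() and np.isfinite(self.free_acc).all()):
            raise ValueError("recording contains non-finite values")
        norms = np.linalg.norm(self.quat, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise RecordingIntegrityError(
                f"quaternion norm deviates from 1 by up to {np.abs(norms - 1).max():.3g}"
            )
        if self.activity is Activity.WALK:
            if self.walk_direction is None:
                raise ValueError("walking trials require walk_direction flags")
            self.walk_direction = np.asarray(self.walk_direction, dtype=float)
            if len(self.walk_direction) != len(self.quat):
                raise ValueError("walk_direction length mismatch")
            if not np.all(np.isin(self.walk_direction, (-1.0, 1.0))):
                raise ValueError("walk_direction values must be +1 or -1")
        elif self.walk_direction is not None:
            raise ValueError("walk_direction is only valid for walking trials")

    def __len__(self) -> int:
        return len(self.quat)

    @property
    def n_samples(self) -> int:
        return len(self.quat)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.quat)) / self.sample_rate


def read_recording(path: str | os.PathLike, meta: Mapping[str, object]) -> SensorRecording:
    """Read one recording CSV written in the canonical dialect.

    ``meta`` supplies the key fields (participant_id, device, location,
    session, activity, optionally side and sample_rate) that the file
    itself does not carry.  Quaternions whose norm deviates from 1 by at
    most 1e-3 are renormalized; larger deviations raise
    :class:`RecordingIntegrityError`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise RecordingFormatError(f"cannot parse {path}: {exc}") from exc

    needed = list(QUAT_COLUMNS) + list(ACC_COLUMNS)
    for col in needed:
        if col not in df.columns:
            raise RecordingFormatError(f"missing column {col!r} in {path}")

    values = df[needed].to_numpy(dtype=float)
    bad = ~np.isfinite(values)
    if bad.any():
        row = int(np.argwhere(bad)[0, 0])
        raise RecordingParseError(f"non-finite value at data row {row} in {path}")

    quat = values[:, :4]
    acc = values[:, 4:]
    norms = np.linalg.norm(quat, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-3):
        raise RecordingIntegrityError(
            f"quaternion norm off unit by {np.abs(norms - 1).max():.3g} in {path}"
        )
    quat = quat / norms[:, None]

    meta = dict(meta)
    walk_direction = None
    if Activity(meta["activity"]) is Activity.WALK:
        if "direction" in df.columns:
            walk_direction = df["direction"].to_numpy(dtype=float)
        elif "walk_direction" in meta and meta["walk_direction"] is not None:
            walk_direction = np.asarray(meta["walk_direction"], dtype=float)
        else:
            raise RecordingFormatError(
                f"walking trial {path} has no direction column and no manifest flags"
            )
    meta.pop("walk_direction", None)

    return SensorRecording(
        quat=quat, free_acc=acc, walk_direction=walk_direction, **meta
    )


def write_recording(rec: SensorRecording, path: str | os.PathLike) -> Path:
    """Write a recording to the canonical CSV dialect (lossless to 1e-9)."""
    path = Path(path)
    data = {"time": rec.times}
    for i, col in enumerate(QUAT_COLUMNS):
        data[col] = rec.quat[:, i]
    for i, col in enumerate(ACC_COLUMNS):
        data[col] = rec.free_acc[:, i]
    if rec.walk_direction is not None:
        data["direction"] = rec.walk_direction
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")
    return path


def write_long_table(rows: Iterable[Mapping] | pd.DataFrame, path: str | os.PathLike) -> Path:
    """Write a long-format range table with the fixed column order."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    if len(df) == 0:
        df = pd.DataFrame(columns=list(RANGE_TABLE_COLUMNS))
    missing = [c for c in RANGE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"range table rows missing columns: {missing}")
    df = df[list(RANGE_TABLE_COLUMNS)]
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_long_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in RANGE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"range table file missing columns: {missing}")
    return df


@dataclass
class TrialEntry:
    """One participant x session x activity trial with its per-stream files.

    ``files`` maps (device, location) to a recording path.  For walking
    trials ``direction_spans`` lists (start_index, end_index, flag) spans;
    samples outside every span default to +1.
    """

    participant_id: str
    session: int
    activity: Activity
    files: dict[tuple[Device, Location], Path]
    direction_spans: list[tuple[int, int, int]] | None = None

    def __post_init__(self) -> None:
        self.activity = Activity(self.activity)
        self.files = {
            (Device(d), Location(l)): Path(p) for (d, l), p in self.files.items()
        }

    def direction_flags(self, n_samples: int) -> np.ndarray | None:
        if self.activity is not Activity.WALK:
            return None
        flags = np.ones(n_samples)
        for start, end, flag in self.direction_spans or []:
            flags[start:end] = flag
        return flags


@dataclass
class TrialManifest:
    """Enumeration of every trial file of a study, serializable to YAML."""

    entries: list[TrialEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple] = set()
        for e in self.entries:
            for (dev, loc) in e.files:
                key = (e.participant_id, e.session, e.activity, dev, loc)
                if key in seen:
                    raise ValueError(f"duplicate manifest key {key}")
                seen.add(key)

    def validate_files(self) -> None:
        for e in self.entries:
            for p in e.files.values():
                if not Path(p).exists():
                    raise FileNotFoundError(f"manifest references missing file {p}")

    def to_yaml(self, path: str | os.PathLike) -> Path:
        doc = []
        for e in self.entries:
            doc.append(
                {
                    "participant_id": e.participant_id,
                    "session": int(e.session),
                    "activity": e.activity.value,
                    "files": {
                        f"{dev.value}/{loc.value}": str(p)
                        for (dev, loc), p in e.files.items()
                    },
                    "direction_spans": (
                        [list(map(int, s)) for s in e.direction_spans]
                        if e.direction_spans is not None
                        else None
                    ),
                }
            )
        path = Path(path)
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "TrialManifest":
        doc = yaml.safe_load(Path(path).read_text())
        entries = []
        for item in doc or []:
            files = {}
            for key, p in item["files"].items():
                dev, loc = key.split("/")
                files[(Device(dev), Location(loc))] = Path(p)
            spans = item.get("direction_spans")
            entries.append(
                TrialEntry(
                    participant_id=str(item["participant_id"]),
                    session=int(item["session"]),
                    activity=Activity(item["activity"]),
                    files=files,
                    direction_spans=(
                        [tuple(s) for s in spans] if spans is not None else None
                    ),
                )
            )
        return cls(entries=entries)
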