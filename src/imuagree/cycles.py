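"""Movement-cycle detection, segmentation, time-normalization and range outcomes.

A movement cycle is delimited on the thigh-orientation x stream: each
dominant trough (local minimum with sufficient prominence, separated from
its neighbours by a minimum period) is flanked by the nearest preceding
and succeeding local maxima, which define cycle start and end.  Cycles
truncated at the signal edges are dropped, and the first and last complete
cycles are discarded before analysis.  Every retained segment is linearly
interpolated onto a 101-point grid (0-100% of the cycle) so cycles of
different durations are comparable; the per-cycle outcome is the signal
range (max minus min), averaged per participant before any cohort average.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _signal
from scipy.interpolate import CubicSpline

from .io import RANGE_TABLE_COLUMNS

__all__ = [
    "CycleBoundaries",
    "MovementCycle",
    "N_GRID",
    "detect_cycles",
    "discard_end_cycles",
    "segment_and_normalize",
    "cycle_range",
    "euclidean_norm",
    "aggregate_ranges",
    "cohort_mean_ranges",
]

#: Number of points of the time-normalized cycle grid (0..100%).
N_GRID = 101


@dataclass
class CycleBoundaries:
    """Ordered (start, trough, end) sample-index triples on the thigh stream."""

    triples: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_end = -1
        for s, t, e in self.triples:
            if not (s < t < e):
                raise ValueError(f"boundary triple ({s}, {t}, {e}) is not increasing")
            if s < prev_end:  # sharing a boundary sample (s == prev_end) is fine
                raise ValueError("cycle boundaries overlap")
            prev_end = e

    def __len__(self) -> int:
        return len(self.triples)

    def __iter__(self):
        return iter(self.triples)


@dataclass
class MovementCycle:
    """One time-normalized cycle of one signal (101 samples, 0-100%)."""

    values: np.ndarray
    location: str = ""
    axis: str = ""
    quantity: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_GRID,):
            raise ValueError(f"cycle must hold exactly {N_GRID} samples")
        if not np.isfinite(self.values).all():
            raise ValueError("cycle contains non-finite values")

    @property
    def signal_id(self) -> tuple[str, str, str]:
        return (self.location, self.axis, self.quantity)


def detect_cycles(
    thigh_ori_x: np.ndarray,
    sample_rate: float = 60.0,
    *,
    min_period: float = 0.5,
    prominence_floor: float | None = None,
    prominence_frac: float = 0.25,
) -> CycleBoundaries:
    """Detect movement cycles from the (filtered) thigh-orientation x stream.

    Troughs are local minima with prominence at least ``prominence_floor``
    (default: ``prominence_frac`` of the stream's own peak-to-peak range)
    and at least ``min_period`` seconds apart.  Each trough is flanked by
    the nearest local maxima on either side; troughs without both flanks
    (edge-truncated cycles) are omitted.  A signal with no qualifying
    trough yields empty boundaries, not an error.
    """
    x = np.asarray(thigh_ori_x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("signal contains non-finite values")
    if min_period <= 0:
        raise ValueError("min_period must be positive")
    amp = float(x.max() - x.min())
    if amp == 0.0:
        return CycleBoundaries([])
    if prominence_floor is None:
        prominence_floor = prominence_frac * amp
    distance = max(1, int(round(min_period * sample_rate)))
    troughs, _ = _signal.find_peaks(-x, prominence=prominence_floor, distance=distance)
    maxima, _ = _signal.find_peaks(x)
    triples = []
    for t in troughs:
        before = maxima[maxima < t]
        after = maxima[maxima > t]
        if len(before) == 0 or len(after) == 0:
            continue  # truncated at a signal edge
        triples.append((int(before[-1]), int(t), int(after[0])))
    return CycleBoundaries(triples)


def discard_end_cycles(b: CycleBoundaries) -> CycleBoundaries:
    """Drop the first and last complete cycle (transition artefacts)."""
    if len(b) <= 2:
        if len(b) > 0:
            warnings.warn(
                f"only {len(b)} cycles detected; none survive end-discard",
                stacklevel=2,
            )
        return CycleBoundaries([])
    return CycleBoundaries(b.triples[1:-1])


def segment_and_normalize(
    x: np.ndarray,
    b: CycleBoundaries,
    *,
    kind: str = "linear",
    location: str = "",
    axis: str = "",
    quantity: str = "",
    units: str = "",
) -> list[MovementCycle]:
    """Cut a signal at cycle boundaries and resample each segment to 101 points.

    The grid includes both endpoints (0% and 100%).  ``kind`` selects
    linear (default) or cubic-spline interpolation.
    """
    x = np.asarray(x, dtype=float)
    cycles = []
    for s, _t, e in b:
        if s < 0 or e >= len(x):
            raise ValueError(f"boundary ({s}, {e}) outside signal of length {len(x)}")
        seg = x[s : e + 1]
        src = np.linspace(0.0, 1.0, len(seg))
        dst = np.linspace(0.0, 1.0, N_GRID)
        if kind == "linear":
            vals = np.interp(dst, src, seg)
        elif kind == "cubic":
            vals = CubicSpline(src, seg)(dst)
        else:
            raise ValueError(f"unknown interpolation kind {kind!r}")
        cycles.append(
            MovementCycle(vals, location=location, axis=axis, quantity=quantity, units=units)
        )
    return cycles


def cycle_range(c: MovementCycle) -> float:
    """Range outcome of one cycle: maximum value minus minimum value."""
    return float(c.values.max() - c.values.min())


def euclidean_norm(
    cz: MovementCycle, cx: MovementCycle, cy: MovementCycle
) -> MovementCycle:
    """Samplewise Euclidean norm sqrt(z^2 + x^2 + y^2) of an acceleration triplet.

    The three inputs must be the z, x and y axis cycles of the same
    location/quantity segment.
    """
    if not (cz.location == cx.location == cy.location) or not (
        cz.quantity == cx.quantity == cy.quantity
    ):
        raise ValueError("axis cycles come from different signals")
    if (cz.axis, cx.axis, cy.axis) != ("z", "x", "y"):
        raise ValueError(f"expected axes (z, x, y), got {(cz.axis, cx.axis, cy.axis)}")
    vals = np.sqrt(cz.values**2 + cx.values**2 + cy.values**2)
    return MovementCycle(
        vals, location=cz.location, axis="norm", quantity="acc_norm", units=cz.units
    )


def aggregate_ranges(
    trial_cycles: Iterable[tuple[dict, Sequence[MovementCycle]]],
) -> pd.DataFrame:
    """Aggregate per-cycle ranges into a long-format range table.

    ``trial_cycles`` yields (metadata, cycles) pairs where metadata carries
    participant_id / device / session / activity / location / axis /
    quantity.  Each row of the result is that participant's mean of the
    per-cycle ranges together with the number of cycles used; streams with
    zero retained cycles are omitted with a warning.
    """
    rows = []
    for meta, cycles in trial_cycles:
        if len(cycles) == 0:
            warnings.warn(f"no retained cycles for {meta}; row omitted", stacklevel=2)
            continue
        ranges = [cycle_range(c) for c in cycles]
        row = dict(meta)
        row["range_value"] = float(np.mean(ranges))
        row["n_cycles_used"] = len(ranges)
        rows.append(row)
    if not rows:
        return pd.DataFrame(columns=list(RANGE_TABLE_COLUMNS))
    return pd.DataFrame(rows)[list(RANGE_TABLE_COLUMNS)]


def cohort_mean_ranges(range_table: pd.DataFrame) -> pd.DataFrame:
    """Cohort summaries: mean over participants of the participant means.

    Participant means enter with equal weight regardless of how many
    cycles each contributed (never pooled over cycles).
    """
    keys = ["device", "session", "activity", "location", "axis", "quantity"]
    out = (
        range_table.groupby(keys, as_index=False)
        .agg(mean_range=("range_value", "mean"), sd_range=("range_value", "std"),
             n_participants=("participant_id", "nunique"))
    )
    return out
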