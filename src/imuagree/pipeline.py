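"""End-to-end orchestration: recordings -> cycles -> range table -> reports.

The processing chain per trial and device mirrors the standard wearable
workflow: quaternions are converted to intrinsic z-x-y Euler angles, all
streams are low-pass filtered (6 Hz, second order, zero phase), walking
accelerations are direction-inverted, cycles are detected on that
device's own thigh-orientation x stream, the first and last complete
cycles are discarded, every stream is segmented with those boundaries
and time-normalized to 101 points, and per-cycle ranges are averaged per
participant.  Test and criterion cycles are paired by cycle index.

Reports are tidy DataFrames; the case grid per quantity is
3 locations x 3 axes x 5 activities = 45 cases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .cycles import (
    CycleBoundaries,
    MovementCycle,
    aggregate_ranges,
    cycle_range,
    detect_cycles,
    discard_end_cycles,
    euclidean_norm,
    segment_and_normalize,
)
from .io import Activity, Device, Location, SensorRecording, TrialManifest, read_recording
from .reliability import IntraclassCorrelation, classification_summary
from .signal_prep import invert_for_direction, lowpass_filter, quat_to_euler_zxy
from .validity import BlandAltman, LinearFit, classify_r2

__all__ = [
    "RunConfig",
    "StudyResult",
    "ValidityReport",
    "ReliabilityReport",
    "load_recordings",
    "process_trial",
    "process_study",
    "run_validity",
    "run_reliability",
]

log = logging.getLogger("imuagree")

_AXES = ("z", "x", "y")


@dataclass
class RunConfig:
    """Tunable settings of one pipeline run (documented defaults)."""

    cutoff_hz: float = 6.0
    filter_order: int = 2
    zero_phase: bool = True
    filter_before_euler: bool = False
    min_period_s: float = 0.5
    prominence_frac: float = 0.25
    interp_kind: str = "linear"
    lfm_mode: str = "concatenated"
    icc_form: str = "single"
    seed: int = 0
    out_dir: str | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> Path:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
        return Path(path)


@dataclass
class StudyResult:
    """Processed study: normalized cycles plus the long-format range table."""

    cycles: dict[tuple, list[MovementCycle]]
    range_table: pd.DataFrame
    cycle_log: pd.DataFrame


def load_recordings(manifest: TrialManifest) -> dict[tuple, SensorRecording]:
    """Read every file of a manifest into memory.

    Keys are (participant_id, session, device, location).  Walking-trial
    direction flags come from the file's own ``direction`` column or,
    failing that, from the manifest's annotation spans.
    """
    out: dict[tuple, SensorRecording] = {}
    for entry in manifest.entries:
        for (device, location), path in entry.files.items():
            meta = {
                "participant_id": entry.participant_id,
                "session": entry.session,
                "activity": entry.activity,
                "device": device,
                "location": location,
            }
            if entry.activity is Activity.WALK and entry.direction_spans is not None:
                n = len(pd.read_csv(path, usecols=[0]))
                meta["walk_direction"] = entry.direction_flags(n)
            out[(entry.participant_id, entry.session, device, location)] = read_recording(
                path, meta
            )
    return out


def _prepared_streams(rec: SensorRecording, config: RunConfig) -> dict[tuple[str, str], np.ndarray]:
    """Filtered per-axis streams of one recording, keyed (quantity, axis)."""
    fs = rec.sample_rate

    def lp(x: np.ndarray) -> np.ndarray:
        return lowpass_filter(
            x, fs, cutoff=config.cutoff_hz, order=config.filter_order,
            zero_phase=config.zero_phase,
        )

    if config.filter_before_euler:
        quat = np.column_stack([lp(rec.quat[:, i]) for i in range(4)])
        quat /= np.linalg.norm(quat, axis=1, keepdims=True)
        euler = quat_to_euler_zxy(quat, fs)
        ori = {"z": euler.z, "x": euler.x, "y": euler.y}
    else:
        euler = quat_to_euler_zxy(rec.quat, fs)
        ori = {a: lp(euler.axis(a)) for a in _AXES}

    acc = {a: lp(rec.free_acc[:, i]) for i, a in enumerate(_AXES)}
    if rec.activity is Activity.WALK:
        for a in ("x", "y"):
            acc[a] = invert_for_direction(acc[a], rec.walk_direction)

    streams = {("ori", a): ori[a] for a in _AXES}
    streams.update({("acc", a): acc[a] for a in _AXES})
    return streams


def process_trial(
    recordings: Mapping[tuple[Device, Location], SensorRecording],
    config: RunConfig | None = None,
) -> tuple[dict[tuple, list[MovementCycle]], list[dict]]:
    """Process all streams of one participant x session x activity trial.

    Each device segments with its own thigh-orientation boundaries.
    Returns cycles keyed (device, location, quantity, axis) — including
    the acceleration Euclidean norm under ("acc_norm", "norm") — and a
    per-device cycle-count log.
    """
    config = config or RunConfig()
    recordings = {(Device(d), Location(l)): r for (d, l), r in recordings.items()}
    devices = sorted({d for d, _ in recordings}, key=lambda d: d.value)
    cycles: dict[tuple, list[MovementCycle]] = {}
    logrows: list[dict] = []

    for device in devices:
        thigh = recordings.get((device, Location.THIGH))
        if thigh is None:
            log.warning("device %s has no thigh recording; skipped", device.value)
            continue
        thigh_streams = _prepared_streams(thigh, config)
        bounds = detect_cycles(
            thigh_streams[("ori", "x")],
            thigh.sample_rate,
            min_period=config.min_period_s,
            prominence_frac=config.prominence_frac,
        )
        kept = discard_end_cycles(bounds)
        logrows.append(
            {
                "participant_id": thigh.participant_id,
                "session": thigh.session,
                "activity": thigh.activity.value,
                "device": device.value,
                "n_troughs": len(bounds),
                "n_cycles_used": len(kept),
            }
        )
        for (dev, loc), rec in recordings.items():
            if dev is not device:
                continue
            streams = (
                thigh_streams if loc is Location.THIGH else _prepared_streams(rec, config)
            )
            for (qty, axis), x in streams.items():
                cycles[(device, loc, qty, axis)] = segment_and_normalize(
                    x,
                    kept,
                    kind=config.interp_kind,
                    location=loc.value,
                    axis=axis,
                    quantity=qty,
                    units="m/s^2" if qty == "acc" else "deg",
                )
            acc_triplets = [cycles[(device, loc, "acc", a)] for a in _AXES]
            cycles[(device, loc, "acc_norm", "norm")] = [
                euclidean_norm(cz, cx, cy) for cz, cx, cy in zip(*acc_triplets)
            ]
    return cycles, logrows


def process_study(
    recordings,
    config: RunConfig | None = None,
) -> StudyResult:
    """Process a whole study of recordings (a mapping's values or an iterable).

    Trials are grouped by each recording's own participant, session and
    activity metadata, so recordings from several activities can be
    processed together.
    """
    config = config or RunConfig()
    if isinstance(recordings, Mapping):
        recordings = recordings.values()
    trials: dict[tuple, dict] = {}
    for rec in recordings:
        key = (rec.participant_id, rec.session, rec.activity)
        inner = trials.setdefault(key, {})
        if (rec.device, rec.location) in inner:
            raise ValueError(
                f"duplicate recording for {key} {rec.device.value}/{rec.location.value}"
            )
        inner[(rec.device, rec.location)] = rec

    all_cycles: dict[tuple, list[MovementCycle]] = {}
    rows = []
    logrows = []
    for (pid, session, activity), trial_recs in sorted(
        trials.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2].value)
    ):
        tcycles, tlog = process_trial(trial_recs, config)
        logrows.extend(tlog)
        for (device, location, qty, axis), cyc in tcycles.items():
            all_cycles[
                (pid, session, device, activity, location, qty, axis)
            ] = cyc
            rows.append(
                (
                    {
                        "participant_id": pid,
                        "device": device.value,
                        "session": session,
                        "activity": activity.value,
                        "location": location.value,
                        "axis": axis,
                        "quantity": qty,
                    },
                    cyc,
                )
            )
    range_table = aggregate_ranges(rows)
    return StudyResult(
        cycles=all_cycles,
        range_table=range_table,
        cycle_log=pd.DataFrame(logrows),
    )


@dataclass
class ValidityReport:
    """Concurrent-validity outputs: per-case LFM and Bland-Altman tables."""

    lfm_cases: pd.DataFrame
    lfm_participants: pd.DataFrame
    bland_altman: pd.DataFrame
    proportions: dict[str, pd.DataFrame]
    skipped: list[tuple] = field(default_factory=list)

    def summary(self) -> str:
        lines = ["Concurrent validity (test vs criterion, session 1)", ""]
        for qty, props in self.proportions.items():
            lines.append(f"{qty} classification over {int(props['count'].sum())} cases:")
            for _, r in props.iterrows():
                lines.append(f"  {r['class']:<13} {r['count']:>3}  ({r['percent']}%)")
        if self.skipped:
            lines.append(f"skipped cases: {len(self.skipped)}")
        return "\n".join(lines)


def run_validity(
    study: StudyResult,
    config: RunConfig | None = None,
    *,
    session: int = 1,
    quantities: Sequence[str] = ("acc", "ori"),
) -> ValidityReport:
    """Per-case concurrent validity of the test device in one session.

    For every (activity, location, axis, quantity) case the LFM is fitted
    per participant on index-paired concatenated cycles and summarized as
    mean and SD across participants; range values feed a Bland-Altman
    analysis across participants.  Cases lacking a device pair are
    skipped and reported.
    """
    config = config or RunConfig()
    cyc = study.cycles
    case_index: dict[tuple, dict[str, tuple]] = {}
    for (pid, sess, device, activity, location, qty, axis), cycles in cyc.items():
        if sess != session or qty not in quantities:
            continue
        case = (activity, location, qty, axis)
        case_index.setdefault(case, {}).setdefault(pid, {})[device] = cycles

    if not case_index:
        raise ValueError("no paired-device cases in this session")

    lfm_part_rows = []
    lfm_case_rows = []
    ba_rows = []
    skipped = []
    rt = study.range_table
    for case in sorted(case_index, key=lambda c: (c[0].value, c[1].value, c[2], c[3])):
        activity, location, qty, axis = case
        per_part = []
        for pid, by_device in sorted(case_index[case].items()):
            if Device.TEST not in by_device or Device.CRITERION not in by_device:
                skipped.append((pid,) + case)
                continue
            tcyc, ccyc = by_device[Device.TEST], by_device[Device.CRITERION]
            if min(len(tcyc), len(ccyc)) == 0:
                skipped.append((pid,) + case)
                continue
            if config.lfm_mode == "mean_cycle":
                k = min(len(tcyc), len(ccyc))
                model = LinearFit(
                    np.mean([c.values for c in tcyc[:k]], axis=0),
                    np.mean([c.values for c in ccyc[:k]], axis=0),
                )
            else:
                model = LinearFit.from_cycles(tcyc, ccyc)
            res = model.fit()
            per_part.append((pid, res))
            lfm_part_rows.append(
                {
                    "activity": activity.value,
                    "location": location.value,
                    "quantity": qty,
                    "axis": axis,
                    "participant_id": pid,
                    "alpha1": res.alpha1,
                    "alpha0": res.alpha0,
                    "r2": res.r2,
                }
            )
        if not per_part:
            skipped.append(("<all>",) + case)
            continue
        a1 = np.array([r.alpha1 for _, r in per_part])
        a0 = np.array([r.alpha0 for _, r in per_part])
        r2 = np.array([r.r2 for _, r in per_part])
        mean_r2 = float(r2.mean())
        lfm_case_rows.append(
            {
                "activity": activity.value,
                "location": location.value,
                "quantity": qty,
                "axis": axis,
                "n_participants": len(per_part),
                "alpha1_mean": float(a1.mean()),
                "alpha1_sd": float(a1.std(ddof=1)) if len(a1) > 1 else 0.0,
                "alpha0_mean": float(a0.mean()),
                "alpha0_sd": float(a0.std(ddof=1)) if len(a0) > 1 else 0.0,
                "r2_mean": mean_r2,
                "r2_sd": float(r2.std(ddof=1)) if len(r2) > 1 else 0.0,
                "class": classify_r2(min(mean_r2, 1.0)),
            }
        )
        # Bland-Altman on participant-mean range values for this case
        sub = rt[
            (rt["activity"] == activity.value)
            & (rt["location"] == location.value)
            & (rt["quantity"] == qty)
            & (rt["axis"] == axis)
            & (rt["session"] == session)
        ]
        wide = sub.pivot_table(
            index="participant_id", columns="device", values="range_value"
        ).dropna()
        if len(wide) >= 2 and {"test", "criterion"} <= set(wide.columns):
            ba = BlandAltman(wide["test"].to_numpy(), wide["criterion"].to_numpy()).fit()
            ba_rows.append(
                {
                    "activity": activity.value,
                    "location": location.value,
                    "quantity": qty,
                    "axis": axis,
                    "n": ba.n,
                    "mean_diff": ba.mean_diff,
                    "sd_diff": ba.sd_diff,
                    "loa_lower": ba.loa_lower,
                    "loa_upper": ba.loa_upper,
                    "ci95_lower": ba.ci95_mean_diff[0],
                    "ci95_upper": ba.ci95_mean_diff[1],
                }
            )

    lfm_cases = pd.DataFrame(lfm_case_rows)
    if lfm_cases.empty:
        raise ValueError("all cases skipped: no participant had a device pair")
    proportions = {
        qty: classification_summary(list(lfm_cases[lfm_cases["quantity"] == qty]["class"]))
        for qty in quantities
        if (lfm_cases["quantity"] == qty).any()
    }
    return ValidityReport(
        lfm_cases=lfm_cases,
        lfm_participants=pd.DataFrame(lfm_part_rows),
        bland_altman=pd.DataFrame(ba_rows),
        proportions=proportions,
        skipped=skipped,
    )


@dataclass
class ReliabilityReport:
    """Test-retest outputs: per-case ICC/SEM table and class proportions."""

    cases: pd.DataFrame
    proportions: dict[str, pd.DataFrame]
    session_pair: tuple[int, int]
    excluded: list[tuple] = field(default_factory=list)

    def summary(self) -> str:
        s1, s2 = self.session_pair
        lines = [f"Test-retest reliability (sessions {s1} vs {s2})", ""]
        for qty, props in self.proportions.items():
            lines.append(f"{qty} classification over {int(props['count'].sum())} cases:")
            for _, r in props.iterrows():
                lines.append(f"  {r['class']:<13} {r['count']:>3}  ({r['percent']}%)")
        return "\n".join(lines)


def run_reliability(
    range_table: pd.DataFrame,
    session_pair: tuple[int, int] = (1, 2),
    config: RunConfig | None = None,
    *,
    device: str = "test",
    quantities: Sequence[str] = ("acc", "ori"),
) -> ReliabilityReport:
    """Per-case ICC, SEM and classification for one session pair.

    Participants present in only one of the two sessions are excluded
    case-wise and reported.
    """
    config = config or RunConfig()
    s1, s2 = session_pair
    rt = range_table
    sub = rt[(rt["device"] == device) & (rt["session"].isin([s1, s2]))]
    if sub.empty:
        raise ValueError(f"no rows for device {device!r} in sessions {session_pair}")
    rows = []
    excluded = []
    keys = ["activity", "location", "quantity", "axis"]
    for case, grp in sub[sub["quantity"].isin(quantities)].groupby(keys):
        wide = grp.pivot_table(
            index="participant_id", columns="session", values="range_value"
        )
        complete = wide.dropna()
        excluded.extend((pid,) + tuple(case) for pid in wide.index.difference(complete.index))
        if len(complete) < 2 or complete.shape[1] < 2:
            continue
        res = IntraclassCorrelation(
            complete[[s1, s2]].to_numpy(), form=config.icc_form
        ).fit()
        rows.append(
            dict(
                zip(keys, case),
                n_participants=res.n_subjects,
                icc=res.icc,
                ci95_lower=res.ci95[0],
                ci95_upper=res.ci95[1],
                sem=res.sem,
                sd_used=res.sd_used,
                **{"class": res.classification},
            )
        )
    cases = pd.DataFrame(rows)
    if cases.empty:
        raise ValueError("no complete cases for this session pair")
    proportions = {
        qty: classification_summary(list(cases[cases["quantity"] == qty]["class"]))
        for qty in quantities
        if (cases["quantity"] == qty).any()
    }
    return ReliabilityReport(
        cases=cases, proportions=proportions, session_pair=(s1, s2), excluded=excluded
    )
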