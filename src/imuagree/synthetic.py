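"""Synthetic dual-sensor motion cohorts with known ground truth.

The generator emulates the structure of a wearable-sensor validity and
reliability study: cyclic functional activities (squats, jumps, walking,
stair ascent/descent) recorded at 60 Hz as orientation plus free
acceleration at three body locations (sacrum, thigh, shank), viewed
through two devices whose differences (gain, offset, additive noise,
mounting misalignment, time lag) are injected with known values, and
repeated over sessions with participant- and session-level variance
components.  Because every distortion parameter is known, downstream
validity statistics can be checked by parameter recovery and reliability
statistics by the identity ICC = sigma_b^2 / (sigma_b^2 + sigma_w^2).

Waveforms are sums of one to three harmonics phase-locked to the cycle,
chosen so the thigh-orientation x stream has exactly one dominant trough
per cycle flanked by maxima (the cycle-detection landmark).  Jumps add an
exponentially decaying high-frequency burst at landing; walking reverses
direction at the midpoint and carries per-sample direction flags.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .io import (
    Activity,
    Device,
    Location,
    SensorRecording,
    TrialEntry,
    TrialManifest,
    write_recording,
)
from .signal_prep import euler_zxy_to_quat

__all__ = [
    "MotionTruth",
    "SensorDistortion",
    "CohortSpec",
    "IDENTITY_DISTORTION",
    "generate_motion_truth",
    "render_sensor_view",
    "generate_cohort",
    "simulate_range_matrix",
    "DEFAULT_CYCLE_PERIODS",
]

#: Default cycle durations per activity, seconds (squat repetitions are slow
#: and deliberate; jumps and strides are faster).
DEFAULT_CYCLE_PERIODS = {
    Activity.SQUAT: 3.0,
    Activity.JUMP: 1.6,
    Activity.WALK: 1.1,
    Activity.STAIR_ASCENT: 1.4,
    Activity.STAIR_DESCENT: 1.3,
}

#: Reference thigh-orientation amplitude (degrees) that cohort variance
#: components are expressed against.
_REF_AMPLITUDE = 20.0

# Harmonic recipes: (location, quantity, axis) -> (offset, [(harmonic, amp, phase)]).
# Amplitudes in degrees (ori) or m/s^2 (acc); every axis is non-degenerate.
# The thigh ori-x entry is overridden per activity with the dominant cosine
# that carries the cycle landmark.
_BASE_RECIPE = {
    ("sacrum", "ori", "z"): (2.0, [(1, 4.0, 0.3), (2, 1.5, 1.1)]),
    ("sacrum", "ori", "x"): (-5.0, [(1, 6.0, 0.0), (2, 2.0, 0.7)]),
    ("sacrum", "ori", "y"): (1.0, [(1, 3.5, 1.9), (3, 1.0, 0.4)]),
    ("thigh", "ori", "z"): (3.0, [(1, 5.0, 0.9), (2, 2.0, 2.1)]),
    ("thigh", "ori", "y"): (-2.0, [(1, 6.0, 2.5), (2, 2.5, 0.2)]),
    ("shank", "ori", "z"): (1.0, [(1, 5.5, 1.4), (2, 1.5, 2.8)]),
    ("shank", "ori", "x"): (-8.0, [(1, 14.0, 0.1), (2, 4.0, 1.5)]),
    ("shank", "ori", "y"): (0.5, [(1, 4.5, 0.8), (3, 1.2, 2.2)]),
    ("sacrum", "acc", "z"): (0.0, [(1, 2.5, 0.5), (2, 1.0, 1.7)]),
    ("sacrum", "acc", "x"): (0.0, [(1, 1.8, 1.2), (2, 0.8, 0.3)]),
    ("sacrum", "acc", "y"): (0.0, [(1, 1.5, 2.0), (3, 0.5, 1.0)]),
    ("thigh", "acc", "z"): (0.0, [(1, 3.0, 0.2), (2, 1.2, 2.4)]),
    ("thigh", "acc", "x"): (0.0, [(1, 2.2, 1.6), (2, 1.0, 0.9)]),
    ("thigh", "acc", "y"): (0.0, [(1, 1.8, 0.6), (3, 0.7, 1.8)]),
    ("shank", "acc", "z"): (0.0, [(1, 3.5, 1.0), (2, 1.5, 0.1)]),
    ("shank", "acc", "x"): (0.0, [(1, 2.8, 2.2), (2, 1.1, 1.3)]),
    ("shank", "acc", "y"): (0.0, [(1, 2.0, 0.4), (3, 0.9, 2.6)]),
}

#: Dominant thigh-orientation x amplitude (degrees) per activity; deep squats
#: flex the thigh most, walking least.
_THIGH_X_AMPLITUDE = {
    Activity.SQUAT: 35.0,
    Activity.JUMP: 25.0,
    Activity.WALK: 18.0,
    Activity.STAIR_ASCENT: 28.0,
    Activity.STAIR_DESCENT: 26.0,
}

#: Per-activity scaling of the acceleration recipes (jumps are the most
#: dynamic, squats the least).
_ACC_SCALE = {
    Activity.SQUAT: 0.8,
    Activity.JUMP: 2.5,
    Activity.WALK: 1.5,
    Activity.STAIR_ASCENT: 1.3,
    Activity.STAIR_DESCENT: 1.4,
}


@dataclass
class MotionTruth:
    """Ground-truth multi-location signals for one trial of one activity."""

    activity: Activity
    sample_rate: float
    cycle_period: float
    n_cycles: int
    times: np.ndarray
    signals: dict[tuple[str, str, str], np.ndarray]
    walk_direction: np.ndarray | None = None
    trough_prominence_floor: float = 5.0

    def signal(self, location: str, quantity: str, axis: str) -> np.ndarray:
        return self.signals[(location, quantity, axis)]

    @property
    def locations(self) -> tuple[str, ...]:
        return tuple(sorted({loc for loc, _, _ in self.signals}))


@dataclass
class SensorDistortion:
    """Known device imperfections applied when rendering a sensor view.

    ``noise_sd_overrides`` may target individual streams, keyed
    (quantity, axis) such as ("acc", "y"), overriding the global
    ``noise_sd`` there.
    """

    gain: float = 1.0
    offset: float = 0.0
    noise_sd: float = 0.0
    misalignment_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    time_lag: int = 0
    noise_sd_overrides: Mapping[tuple[str, str], float] | None = None

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if any(abs(m) > 30.0 for m in self.misalignment_deg):
            raise ValueError("misalignment limited to +/-30 degrees")

    def stream_noise_sd(self, quantity: str, axis: str) -> float:
        if self.noise_sd_overrides is not None:
            return float(self.noise_sd_overrides.get((quantity, axis), self.noise_sd))
        return self.noise_sd


IDENTITY_DISTORTION = SensorDistortion()


@dataclass
class CohortSpec:
    """Variance-component design of a simulated multi-session cohort.

    ``sigma2_between`` and ``sigma2_within`` are the between-participant
    and within-participant (between-session) variances of the outcome
    amplitude, in squrade signal units; the implied true reliability is
    ICC = sigma2_between / (sigma2_between + sigma2_within).
    ``placement_sd_deg`` is the SD of the per-session sensor-mounting
    rotation, either one value for all sessions or a mapping
    session -> SD.
    """

    n_participants: int
    sigma2_between: float = 1.0
    sigma2_within: float = 0.25
    placement_sd_deg: float | Mapping[int, float] = 0.0
    seed: int = 0
    n_sessions: int = 3

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        if self.sigma2_between < 0 or self.sigma2_within < 0:
            raise ValueError("variance components must be non-negative")

    @property
    def icc_true(self) -> float:
        tot = self.sigma2_between + self.sigma2_within
        return self.sigma2_between / tot if tot > 0 else 0.0

    def placement_sd(self, session: int) -> float:
        if isinstance(self.placement_sd_deg, Mapping):
            return float(self.placement_sd_deg.get(session, 0.0))
        return float(self.placement_sd_deg)


def _harmonics(phase: np.ndarray, recipe, scale: float) -> np.ndarray:
    offset, terms = recipe
    out = np.full_like(phase, offset)
    for k, amp, ph in terms:
        out += scale * amp * np.sin(k * phase + ph)
    return out


def generate_motion_truth(
    activity: Activity | str,
    n_cycles: int = 8,
    cycle_period: float | None = None,
    *,
    amplitude_scale: float = 1.0,
    sample_rate: float = 60.0,
    cycle_jitter: float = 0.02,
    seed: int = 0,
    locations: Sequence[str] = ("sacrum", "thigh", "shank"),
) -> MotionTruth:
    """Generate ground-truth signals for one trial.

    The trial spans ``n_cycles`` cycles plus half a cycle of lead-in/out
    so every cycle's flanking maxima lie strictly inside the record.
    ``cycle_jitter`` modulates each cycle's amplitude by a small
    multiplicative N(1, jitter^2) factor (smoothly interpolated), the
    kind of repetition-to-repetition variability real movement shows.
    Deterministic given ``seed``.
    """
    activity = Activity(activity)
    if n_cycles < 3:
        raise ValueError("need at least 3 cycles (end cycles are discarded)")
    if cycle_period is None:
        cycle_period = DEFAULT_CYCLE_PERIODS[activity]
    if cycle_period <= 0:
        raise ValueError("cycle_period must be positive")
    if amplitude_scale == 0.0:
        raise ValueError("zero amplitude produces no detectable cycles")
    if "thigh" not in locations:
        raise ValueError("the thigh stream is required for cycle detection")

    rng = np.random.default_rng(seed)
    T = float(cycle_period)
    duration = n_cycles * T + T / 2
    n_samples = int(round(duration * sample_rate)) + 1
    t = np.arange(n_samples) / sample_rate
    # phase 0 at the first interior maximum (t = T/4); troughs at phase pi + 2*pi*k
    phase = 2 * np.pi * (t - T / 4) / T

    # smooth per-cycle amplitude modulation envelope
    trough_times = T * 3 / 4 + T * np.arange(n_cycles)
    per_cycle = 1.0 + cycle_jitter * rng.standard_normal(n_cycles)
    anchor_t = np.concatenate([[0.0], trough_times, [duration]])
    anchor_v = np.concatenate([[per_cycle[0]], per_cycle, [per_cycle[-1]]])
    envelope = np.interp(t, anchor_t, anchor_v)

    acc_scale = _ACC_SCALE[activity] * amplitude_scale
    ori_scale = amplitude_scale
    signals: dict[tuple[str, str, str], np.ndarray] = {}
    for (loc, qty, axis), recipe in _BASE_RECIPE.items():
        if loc not in locations:
            continue
        scale = acc_scale if qty == "acc" else ori_scale
        offset, _ = recipe
        base = _harmonics(phase, recipe, scale)
        signals[(loc, qty, axis)] = offset + (base - offset) * envelope

    # dominant thigh-flexion waveform carrying the cycle landmark
    if "thigh" in locations:
        amp_x = _THIGH_X_AMPLITUDE[activity] * amplitude_scale
        base = -10.0 + amp_x / 2.0 * np.cos(phase) + 0.08 * amp_x * np.sin(2 * phase + 0.4)
        signals[("thigh", "ori", "x")] = -10.0 + (base + 10.0) * envelope

    walk_direction = None
    if activity is Activity.JUMP:
        # landing impact: decaying high-frequency burst shortly after mid-cycle
        f_hf, tau = 16.0, 0.06
        burst = np.zeros_like(t)
        for k in range(n_cycles):
            t_land = T / 4 + k * T + 0.6 * T
            dt = t - t_land
            m = dt >= 0
            burst[m] += np.exp(-dt[m] / tau) * np.sin(2 * np.pi * f_hf * dt[m])
        for loc in locations:
            for axis, w in (("z", 6.0), ("x", 3.0), ("y", 2.0)):
                signals[(loc, "acc", axis)] = (
                    signals[(loc, "acc", axis)] + w * amplitude_scale * burst
                )
    elif activity is Activity.WALK:
        # direction reversal at the trial midpoint: the as-recorded x/y
        # accelerations flip sign for the return direction
        walk_direction = np.ones(n_samples)
        walk_direction[t >= duration / 2] = -1.0
        for loc in locations:
            for axis in ("x", "y"):
                key = (loc, "acc", axis)
                signals[key] = signals[key] * walk_direction

    amp_x = _THIGH_X_AMPLITUDE[activity] * abs(amplitude_scale)
    return MotionTruth(
        activity=activity,
        sample_rate=sample_rate,
        cycle_period=T,
        n_cycles=n_cycles,
        times=t,
        signals=signals,
        walk_direction=walk_direction,
        trough_prominence_floor=0.25 * amp_x,
    )


def _lag(x: np.ndarray, lag: int) -> np.ndarray:
    if lag == 0:
        return x
    if abs(lag) >= len(x):
        raise ValueError("time lag exceeds signal length")
    out = np.empty_like(x)
    if lag > 0:
        out[lag:] = x[:-lag]
        out[:lag] = x[0]
    else:
        out[:lag] = x[-lag:]
        out[lag:] = x[-1]
    return out


def render_sensor_view(
    truth: MotionTruth,
    location: str | Location,
    dist: SensorDistortion,
    *,
    participant_id: str = "P01",
    device: Device | str = Device.TEST,
    session: int = 1,
    seed: int = 0,
) -> SensorRecording:
    """Render one device's recording of one location from ground truth.

    Each scalar stream becomes ``gain * lagged(signal) + offset + noise``;
    orientation noise and distortion are applied in Euler space (degrees)
    before quaternion conversion, and the mounting misalignment is
    composed as an additional fixed body-frame rotation.  Accelerations
    are additionally rotated by the misalignment.  Deterministic given
    ``seed``.
    """
    location = Location(location).value
    rng = np.random.default_rng(seed)
    n = len(truth.times)

    def distorted(key) -> np.ndarray:
        x = _lag(truth.signals[key], dist.time_lag)
        sd = dist.stream_noise_sd(key[1], key[2])
        return dist.gain * x + dist.offset + rng.normal(0.0, sd, n)

    ez = distorted((location, "ori", "z"))
    ex = distorted((location, "ori", "x"))
    ey = distorted((location, "ori", "y"))
    rot = Rotation.from_euler("ZXY", np.column_stack([ez, ex, ey]), degrees=True)
    if any(m != 0.0 for m in dist.misalignment_deg):
        mis = Rotation.from_euler("ZXY", dist.misalignment_deg, degrees=True)
        rot = rot * mis  # fixed mounting offset in the body frame
    quat = rot.as_quat(scalar_first=True)

    acc = np.column_stack(
        [distorted((location, "acc", a)) for a in ("z", "x", "y")]
    )
    if any(m != 0.0 for m in dist.misalignment_deg):
        mis_m = Rotation.from_euler("ZXY", dist.misalignment_deg, degrees=True).as_matrix()
        # acc stored (z, x, y); rotate in (x, y, z) then restore order
        xyz = acc[:, [1, 2, 0]] @ mis_m.T
        acc = xyz[:, [2, 0, 1]]

    return SensorRecording(
        participant_id=participant_id,
        device=Device(device),
        location=Location(location),
        session=session,
        activity=truth.activity,
        quat=quat,
        free_acc=acc,
        sample_rate=truth.sample_rate,
        walk_direction=None if truth.walk_direction is None else truth.walk_direction.copy(),
    )


def generate_cohort(
    spec: CohortSpec,
    activity: Activity | str,
    distortions: Mapping[Device | str, SensorDistortion] | None = None,
    *,
    n_cycles: int = 8,
    criterion_sessions: Sequence[int] = (1,),
    locations: Sequence[str] = ("sacrum", "thigh", "shank"),
    out_dir: str | Path | None = None,
) -> tuple[TrialManifest, dict]:
    """Simulate a multi-session cohort; optionally write recordings to disk.

    Per participant a random effect b_i ~ N(0, sigma2_between) and per
    session an independent w_ij ~ N(0, sigma2_within) perturb the outcome
    amplitude (expressed against a 20-degree reference amplitude, so
    ranges stay linear in b + w and the implied ICC is exactly
    sigma_b^2 / (sigma_b^2 + sigma_w^2)).  The test device is rendered in
    every session with an additional per-session mounting rotation of SD
    ``placement_sd_deg``; the criterion device only in
    ``criterion_sessions``.  Participant seeds derive as seed +
    participant index, so cohorts are reproducible and extensible.

    Returns the manifest and a dict
    ``(participant_id, session, device, location) -> SensorRecording``.
    If ``out_dir`` is given, recordings are also written as CSV and the
    manifest references those files.
    """
    activity = Activity(activity)
    if distortions is None:
        distortions = {}
    distortions = {Device(d): v for d, v in distortions.items()}
    sb = math.sqrt(spec.sigma2_between)
    sw = math.sqrt(spec.sigma2_within)

    recordings: dict[tuple, SensorRecording] = {}
    entries: dict[tuple, dict] = {}
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    for i in range(spec.n_participants):
        pid = f"P{i + 1:03d}"
        prng = np.random.default_rng(spec.seed + i)
        b_i = sb * prng.standard_normal()
        # repetition-jitter pattern is a participant trait: reusing the
        # truth seed across sessions keeps the between/within variance
        # decomposition exactly sigma_b^2 / (sigma_b^2 + sigma_w^2)
        truth_seed = int(prng.integers(2**31))
        for session in range(1, spec.n_sessions + 1):
            w_ij = sw * prng.standard_normal()
            scale = (_REF_AMPLITUDE + b_i + w_ij) / _REF_AMPLITUDE
            if scale <= 0.05:
                scale = 0.05  # guard: amplitudes stay positive and detectable
            truth = generate_motion_truth(
                activity,
                n_cycles=n_cycles,
                amplitude_scale=scale,
                seed=truth_seed,
                locations=locations,
            )
            placement_sd = spec.placement_sd(session)
            placement = tuple(
                float(a) for a in prng.normal(0.0, placement_sd, 3)
            ) if placement_sd > 0 else (0.0, 0.0, 0.0)
            devices = [Device.TEST] + (
                [Device.CRITERION] if session in criterion_sessions else []
            )
            for device in devices:
                base = distortions.get(device, IDENTITY_DISTORTION)
                if device is Device.TEST and placement != (0.0, 0.0, 0.0):
                    mis = tuple(
                        max(-30.0, min(30.0, m + p))
                        for m, p in zip(base.misalignment_deg, placement)
                    )
                    dist = replace(base, misalignment_deg=mis)
                else:
                    dist = base
                for loc in locations:
                    rec = render_sensor_view(
                        truth,
                        loc,
                        dist,
                        participant_id=pid,
                        device=device,
                        session=session,
                        seed=int(prng.integers(2**31)),
                    )
                    key = (pid, session, device, Location(loc))
                    recordings[key] = rec
                    tkey = (pid, session)
                    entry = entries.setdefault(
                        tkey,
                        {
                            "participant_id": pid,
                            "session": session,
                            "activity": activity,
                            "files": {},
                            "spans": None,
                        },
                    )
                    if truth.walk_direction is not None and entry["spans"] is None:
                        flip = int(np.argmax(truth.walk_direction < 0))
                        entry["spans"] = [(flip, len(truth.walk_direction), -1)]
                    if out_path is not None:
                        fname = f"{pid}_s{session}_{device.value}_{loc}_{activity.value}.csv"
                        fpath = out_path / fname
                        if fpath.exists():
                            raise FileExistsError(f"conflicting output path {fpath}")
                        write_recording(rec, fpath)
                        entry["files"][(device, Location(loc))] = fpath
                    else:
                        entry["files"][(device, Location(loc))] = Path(
                            f"<memory>/{pid}/{session}/{device.value}/{loc}"
                        )

    manifest = TrialManifest(
        entries=[
            TrialEntry(
                participant_id=e["participant_id"],
                session=e["session"],
                activity=e["activity"],
                files=e["files"],
                direction_spans=e["spans"],
            )
            for e in entries.values()
        ]
    )
    return manifest, recordings


def simulate_range_matrix(
    n_subjects: int,
    k_sessions: int,
    sigma2_between: float,
    sigma2_within: float,
    *,
    mean: float = 10.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw an outcome matrix y_ij = mean + b_i + w_ij from the cohort model.

    This is the variance-components model that :func:`generate_cohort`
    embeds in the waveform amplitudes, sampled directly at the outcome
    level; its population ICC (consistency) is
    sigma2_between / (sigma2_between + sigma2_within).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    b = rng.normal(0.0, math.sqrt(sigma2_between), size=(n_subjects, 1))
    w = rng.normal(0.0, math.sqrt(sigma2_within), size=(n_subjects, k_sessions))
    return mean + b + w
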