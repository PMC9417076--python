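"""Stream conditioning: quaternion -> Euler conversion, low-pass filtering,
walking-direction inversion.

Orientations are decomposed with the intrinsic z-x-y rotation sequence and
reported in degrees; the middle (x) angle is confined to (-90, 90) degrees
by construction, the outer angles are unwrapped so adjacent samples never
jump by an artificial 360 degrees.  Filtering is a 6 Hz second-order
Butterworth applied forward and backward (zero phase): phase lag would
shift the test waveform against the criterion waveform and bias every
downstream agreement statistic, so the zero-phase variant is the default.
The effective amplitude response of the dual pass is the square of the
single-pass magnitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal
from scipy.spatial.transform import Rotation

__all__ = [
    "EulerSeries",
    "GimbalWarning",
    "quat_to_euler_zxy",
    "euler_zxy_to_quat",
    "lowpass_filter",
    "invert_for_direction",
]


class GimbalWarning(UserWarning):
    """The middle Euler angle is numerically at gimbal lock (|x| ~ 90 deg)."""


@dataclass
class EulerSeries:
    """Per-sample intrinsic z-x-y Euler angles, in degrees."""

    z: np.ndarray
    x: np.ndarray
    y: np.ndarray
    sample_rate: float = 60.0

    def __len__(self) -> int:
        return len(self.z)

    def axis(self, name: str) -> np.ndarray:
        return {"z": self.z, "x": self.x, "y": self.y}[name]


def quat_to_euler_zxy(
    quat: np.ndarray,
    sample_rate: float = 60.0,
    *,
    unwrap: bool = True,
    norm_tol: float = 1e-6,
) -> EulerSeries:
    """Decompose unit quaternions (w, x, y, z) into intrinsic z-x-y Euler angles.

    Parameters
    ----------
    quat
        (N, 4) array of quaternions in scalar-first order.
    unwrap
        Unwrap the outer (z, y) angle streams with a 360-degree period so
        filtering never sees a wrap discontinuity.  The middle angle lives
        in (-90, 90) and needs no unwrapping.

    Raises a :class:`ValueError` for quaternions off the unit sphere by
    more than ``norm_tol`` and emits :class:`GimbalWarning` when the
    middle angle comes within 1e-6 degrees of +/-90 (values are still
    returned).
    """
    quat = np.asarray(quat, dtype=float)
    if quat.ndim != 2 or quat.shape[1] != 4:
        raise ValueError("quat must be an (N, 4) array")
    norms = np.linalg.norm(quat, axis=1)
    if np.any(np.abs(norms - 1.0) > norm_tol):
        raise ValueError(
            f"non-unit quaternion (norm off by {np.abs(norms - 1).max():.3g})"
        )
    rot = Rotation.from_quat(quat / norms[:, None], scalar_first=True)
    zxy = rot.as_euler("ZXY", degrees=True)
    z, x, y = zxy[:, 0], zxy[:, 1], zxy[:, 2]
    if np.any(np.abs(np.abs(x) - 90.0) < 1e-6):
        warnings.warn(
            "middle z-x-y angle at gimbal lock; outer angles are degenerate",
            GimbalWarning,
            stacklevel=2,
        )
    if unwrap:
        z = np.unwrap(z, period=360.0)
        y = np.unwrap(y, period=360.0)
    return EulerSeries(z=z, x=x, y=y, sample_rate=sample_rate)


def euler_zxy_to_quat(z: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Recompose intrinsic z-x-y Euler angles (degrees) into (w,x,y,z) quaternions."""
    angles = np.column_stack([z, x, y])
    return Rotation.from_euler("ZXY", angles, degrees=True).as_quat(scalar_first=True)


def lowpass_filter(
    x: np.ndarray,
    sample_rate: float,
    cutoff: float = 6.0,
    order: int = 2,
    *,
    zero_phase: bool = True,
) -> np.ndarray:
    """Low-pass Butterworth filter, zero-phase (forward-backward) by default.

    DC gain is exactly 1; the output has the length of the input.  The
    single-pass variant (``zero_phase=False``) is exposed for comparison
    but introduces phase lag.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    if not np.isfinite(x).all():
        raise ValueError("signal contains non-finite values")
    if cutoff >= sample_rate / 2:
        raise ValueError(f"cutoff {cutoff} Hz is at or above Nyquist ({sample_rate / 2} Hz)")
    if len(x) <= 6 * order:
        raise ValueError(f"signal too short to filter (need > {6 * order} samples)")
    b, a = _signal.butter(order, cutoff, btype="low", fs=sample_rate)
    if zero_phase:
        return _signal.filtfilt(b, a, x)
    return _signal.lfilter(b, a, x)


def invert_for_direction(x: np.ndarray, flags: np.ndarray) -> np.ndarray:
    """Multiply a signal samplewise by +1/-1 direction flags.

    Used on the x and y acceleration axes of walking trials so strides
    walked in the return direction contribute with consistent sign.
    """
    x = np.asarray(x, dtype=float)
    flags = np.asarray(flags, dtype=float)
    if flags.shape != x.shape:
        raise ValueError("direction flags must match signal length")
    if not np.all(np.isin(flags, (-1.0, 1.0))):
        raise ValueError("direction flags must be +1 or -1")
    return x * flags
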