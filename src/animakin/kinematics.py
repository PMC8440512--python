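"""Smooth differentiation and kinematic/spatial feature extraction.

Speed, acceleration magnitude and jerk magnitude are the first, second and
third derivatives of the raw centroid positions.  Naive frame differencing
amplifies sensor noise multiplicatively with each differentiation step, so
every step uses a smooth differential filter: an antisymmetric FIR kernel
that is exact on low-order polynomials and attenuates high-frequency noise.
The default kernel is the Savitzky-Golay first-derivative kernel of window
11 and polynomial order 3 (coefficients from ``scipy.signal.savgol_coeffs``).

Derivatives are computed per frame (pixels/frame) and converted to physical
units (mm/s, mm/s^2, mm/s^3) using the frame rate and the pixel pitch of the
capture device.  The default pitch, 0.2475 mm/px, is the WACOM Cintiq 22HD
active width (475.2 mm) over its 1920 px horizontal resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_coeffs

from .trajectory_model import AnimationRecording

__all__ = [
    "PX_TO_MM_DEFAULT",
    "DifferentiatorSpec",
    "KinematicProfile",
    "smooth_differentiate",
    "compute_kinematics",
    "simultaneous_movement",
    "relative_distance",
    "mean_rotation",
    "circular_diff_deg",
]

#: WACOM Cintiq 22HD: 475.2 mm active width / 1920 px.
PX_TO_MM_DEFAULT = 0.2475


@dataclass(frozen=True)
class DifferentiatorSpec:
    """An antisymmetric FIR differentiation kernel.

    ``kernel[i]`` multiplies the sample at offset ``i - half_width``; the
    convention is that of a derivative with respect to the sample index, so
    the result is in signal-units per sample and must be divided by ``dt``
    for a time derivative.  Antisymmetry guarantees exact zero output on
    constants; a consistent kernel is exact on linear (and here cubic)
    signals in the interior.
    """

    kernel: np.ndarray = field(
        default_factory=lambda: -savgol_coeffs(11, 3, deriv=1)
    )
    half_width: int = 5

    def __post_init__(self) -> None:
        k = np.asarray(self.kernel, dtype=float)
        object.__setattr__(self, "kernel", k)
        if k.size != 2 * self.half_width + 1:
            raise ValueError("kernel length must be 2*half_width + 1")
        if not np.allclose(k, -k[::-1], atol=1e-12):
            raise ValueError("kernel must be antisymmetric")
        # antisymmetry implies zero sum; assert the moment condition too
        offsets = np.arange(-self.half_width, self.half_width + 1)
        if not np.isclose(k @ offsets, 1.0, atol=1e-10):
            raise ValueError("kernel first moment must be 1 (unit derivative gain)")


def smooth_differentiate(
    signal, dt: float, spec: DifferentiatorSpec | None = None
) -> np.ndarray:
    """Derivative estimate of ``signal`` sampled at spacing ``dt``.

    Same length as the input; edges are handled by replicating the first and
    last samples (so edge derivative estimates are biased toward zero, which
    is benign for mean kinematics of long recordings).
    """
    spec = spec or DifferentiatorSpec()
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    if x.size <= spec.kernel.size:
        raise ValueError(
            f"signal length {x.size} must exceed kernel length {spec.kernel.size}"
        )
    if dt <= 0:
        raise ValueError("dt must be positive")
    # subtracting a reference level changes nothing mathematically (the
    # antisymmetric kernel annihilates constants) but makes the output
    # exactly zero on constant input and better conditioned on large offsets
    x = x - x[0]
    padded = np.pad(x, spec.half_width, mode="edge")
    # np.convolve flips the kernel; pre-flip so kernel[i] hits offset i-h
    return np.convolve(padded, spec.kernel[::-1], mode="valid") / dt


def circular_diff_deg(angles_deg: np.ndarray) -> np.ndarray:
    """Successive minimal signed angular differences, in degrees in (-180, 180]."""
    d = np.diff(np.asarray(angles_deg, dtype=float))
    return (d + 180.0) % 360.0 - 180.0


@dataclass(frozen=True)
class KinematicProfile:
    """Per-frame and summary kinematics of one recording.

    Per-frame arrays are in physical units (mm/s, mm/s^2, mm/s^3), one row
    per frame, columns red/blue.  Summary means are taken over frames first,
    then averaged across the two triangles.
    """

    animation_id: str
    speed: np.ndarray  # (n, 2) mm/s
    acceleration_mag: np.ndarray  # (n, 2) mm/s^2
    jerk_mag: np.ndarray  # (n, 2) mm/s^3
    speed_px_per_frame: np.ndarray  # (n, 2) raw units, used by Eq-4 style ops
    mean_speed: float
    mean_acceleration: float
    mean_jerk: float
    simultaneous_movement: float
    relative_distance: float
    mean_rotation: float


def _velocity_components(
    xy: np.ndarray, spec: DifferentiatorSpec
) -> tuple[np.ndarray, np.ndarray]:
    # derivatives per frame index (dt = 1 frame)
    vx = smooth_differentiate(xy[:, 0], 1.0, spec)
    vy = smooth_differentiate(xy[:, 1], 1.0, spec)
    return vx, vy


def simultaneous_movement(
    rec: AnimationRecording,
    speed_threshold_px_per_frame: float = 0.01,
    spec: DifferentiatorSpec | None = None,
) -> float:
    """Proportion of frames in which both triangles move.

    A triangle counts as moving when its raw speed exceeds the threshold
    (0.01, applied in pixels/frame before any unit conversion).
    """
    spec = spec or DifferentiatorSpec()
    speeds = []
    for xy in (rec.red_xy, rec.blue_xy):
        vx, vy = _velocity_components(xy, spec)
        speeds.append(np.hypot(vx, vy))
    both = (speeds[0] > speed_threshold_px_per_frame) & (
        speeds[1] > speed_threshold_px_per_frame
    )
    return float(np.mean(both))


def relative_distance(
    rec: AnimationRecording, px_to_mm: float = PX_TO_MM_DEFAULT
) -> float:
    """Mean Euclidean distance between the two centroids, in mm."""
    d = np.hypot(
        rec.red_xy[:, 0] - rec.blue_xy[:, 0], rec.red_xy[:, 1] - rec.blue_xy[:, 1]
    )
    return float(np.mean(d) * px_to_mm)


def mean_rotation(rec: AnimationRecording, movement_weighted: bool = False) -> float:
    """Average per-frame rotation of the triangles about their own axes.

    For each triangle, the mean absolute minimal circular difference of
    successive rotation angles (degrees/frame); the result averages the red
    and blue values.  ``movement_weighted=True`` instead weights each
    triangle's value by its proportion of moving frames (displacement > 0)
    before averaging.
    """
    vals = []
    weights = []
    for xy, rot in ((rec.red_xy, rec.red_rot), (rec.blue_xy, rec.blue_rot)):
        vals.append(float(np.mean(np.abs(circular_diff_deg(rot)))))
        moving = np.hypot(*np.diff(xy, axis=0).T) > 0
        weights.append(float(np.mean(moving)))
    if movement_weighted:
        wsum = weights[0] + weights[1]
        if wsum == 0:
            return 0.0
        return (weights[0] * vals[0] + weights[1] * vals[1]) / wsum
    return (vals[0] + vals[1]) / 2.0


def compute_kinematics(
    rec: AnimationRecording,
    spec: DifferentiatorSpec | None = None,
    px_to_mm: float = PX_TO_MM_DEFAULT,
) -> KinematicProfile:
    """Full kinematic and spatial profile of one recording.

    Speed is the Euclidean norm of the filtered (dx, dy) per frame;
    acceleration and jerk magnitudes come from successive filtered
    differentiation of the velocity components followed by the norm.
    Raw per-frame units are converted to mm/s^k via
    ``frame_rate_hz**k * px_to_mm``.
    """
    spec = spec or DifferentiatorSpec()
    if px_to_mm <= 0:
        raise ValueError("px_to_mm must be positive")
    fr = rec.frame_rate_hz
    n = rec.n_frames
    speed = np.empty((n, 2))
    acc = np.empty((n, 2))
    jerk = np.empty((n, 2))
    speed_raw = np.empty((n, 2))
    for col, xy in enumerate((rec.red_xy, rec.blue_xy)):
        vx, vy = _velocity_components(xy, spec)
        ax = smooth_differentiate(vx, 1.0, spec)
        ay = smooth_differentiate(vy, 1.0, spec)
        jx = smooth_differentiate(ax, 1.0, spec)
        jy = smooth_differentiate(ay, 1.0, spec)
        speed_raw[:, col] = np.hypot(vx, vy)
        speed[:, col] = speed_raw[:, col] * fr * px_to_mm
        acc[:, col] = np.hypot(ax, ay) * fr**2 * px_to_mm
        jerk[:, col] = np.hypot(jx, jy) * fr**3 * px_to_mm
    return KinematicProfile(
        animation_id=rec.animation_id,
        speed=speed,
        acceleration_mag=acc,
        jerk_mag=jerk,
        speed_px_per_frame=speed_raw,
        mean_speed=float(speed.mean(axis=0).mean()),
        mean_acceleration=float(acc.mean(axis=0).mean()),
        mean_jerk=float(jerk.mean(axis=0).mean()),
        simultaneous_movement=simultaneous_movement(rec, spec=spec),
        relative_distance=relative_distance(rec, px_to_mm=px_to_mm),
        mean_rotation=mean_rotation(rec),
    )
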