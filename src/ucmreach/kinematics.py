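"""End-effector kinematics: movement bounds, velocity metrics, curvature,
accuracy errors and time normalization.

Positions are millimetres, time in seconds (100 Hz sampling by default).
No smoothing is applied by default — the optional ``lowpass`` helper exists
for noisy recordings but is off everywhere unless asked for.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .errors import DetectionFailureError, InsufficientDataError, InvalidInputError

__all__ = [
    "TipTrajectory",
    "MovementBounds",
    "KinematicSummary",
    "SPEED_THRESHOLD_MM_S",
    "RADIUS_THRESHOLD_MM",
    "tangential_velocity",
    "detect_bounds",
    "phase_times",
    "curvature",
    "accuracy_errors",
    "time_normalize",
    "lowpass",
]

#: Movement onset/offset speed threshold, mm/s.
SPEED_THRESHOLD_MM_S = 25.0
#: Radius around the start point / target used with the speed threshold, mm.
RADIUS_THRESHOLD_MM = 10.0
#: Number of points of a time-normalized series (1%..100% of movement time).
N_NORMALIZED = 100


@dataclass(frozen=True)
class TipTrajectory:
    """Uniformly sampled 3-D tip path: ``time`` (s), ``position`` (N x 3, mm)."""

    time: np.ndarray
    position: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        p = np.asarray(self.position, dtype=float)
        if t.ndim != 1 or t.size < 3:
            raise InvalidInputError("time must be 1-D with at least 3 samples")
        if p.shape != (t.size, 3):
            raise InvalidInputError(
                f"position must be (n_samples, 3) = ({t.size}, 3), got {p.shape}"
            )
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(p))):
            raise InvalidInputError("trajectory contains non-finite values")
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError("time must be strictly increasing")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "position", p)

    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        dts = np.diff(self.time)
        return bool(np.all(np.abs(dts - dts.mean()) <= rtol * dts.mean()))


@dataclass(frozen=True)
class MovementBounds:
    """Sample indices of movement start and end, plus the elapsed time."""

    start_index: int
    end_index: int
    movement_time: float

    def __post_init__(self) -> None:
        if not self.start_index < self.end_index:
            raise InvalidInputError("start_index must precede end_index")


@dataclass(frozen=True)
class KinematicSummary:
    """Per-trial endpoint metrics.

    ``peak_velocity`` is in m/s (the conventional reporting unit); times in
    seconds; curvatures and the error in millimetres.
    """

    peak_velocity: float
    acceleration_time: float
    deceleration_time: float
    horizontal_curvature: float
    vertical_curvature: float
    absolute_error: float
    movement_time: float

    def to_dict(self) -> dict:
        return {
            "peak_velocity_m_s": self.peak_velocity,
            "acceleration_time_s": self.acceleration_time,
            "deceleration_time_s": self.deceleration_time,
            "horizontal_curvature_mm": self.horizontal_curvature,
            "vertical_curvature_mm": self.vertical_curvature,
            "absolute_error_mm": self.absolute_error,
            "movement_time_s": self.movement_time,
        }


def tangential_velocity(traj: TipTrajectory) -> np.ndarray:
    """Speed along the 3-D path, mm/s.

    The per-axis derivatives are taken by central differences in the
    interior and one-sided differences at the ends; the tangential velocity
    is the Euclidean norm of the derivative vector — the square root of the
    sum of the squared per-axis derivatives.
    """
    if not traj.is_uniform():
        raise InvalidInputError("tangential_velocity requires uniform sampling")
    deriv = np.gradient(traj.position, traj.time, axis=0)
    return np.linalg.norm(deriv, axis=1)


def detect_bounds(
    traj: TipTrajectory,
    velocity: np.ndarray,
    start_point,
    target_point,
    speed_threshold: float = SPEED_THRESHOLD_MM_S,
    radius: float = RADIUS_THRESHOLD_MM,
) -> MovementBounds:
    """Locate movement start and end by the speed-plus-radius criteria.

    Start: first sample whose tangential velocity exceeds ``speed_threshold``
    *and* which lies more than ``radius`` from the start point.  End: first
    subsequent sample whose velocity is below the threshold *and* which lies
    within ``radius`` of the target.  Both predicates are strict and must
    hold simultaneously.
    """
    start_point = np.asarray(start_point, dtype=float)
    target_point = np.asarray(target_point, dtype=float)
    velocity = np.asarray(velocity, dtype=float)
    if velocity.shape != (traj.n_samples,):
        raise InvalidInputError("velocity must have one value per trajectory sample")

    d_start = np.linalg.norm(traj.position - start_point, axis=1)
    d_target = np.linalg.norm(traj.position - target_point, axis=1)

    started = (velocity > speed_threshold) & (d_start > radius)
    start_candidates = np.flatnonzero(started)
    if start_candidates.size == 0:
        raise DetectionFailureError("start")
    start = int(start_candidates[0])

    ended = (velocity < speed_threshold) & (d_target < radius)
    end_candidates = np.flatnonzero(ended[start + 1 :])
    if end_candidates.size == 0:
        raise DetectionFailureError("end")
    end = start + 1 + int(end_candidates[0])

    return MovementBounds(start, end, float(traj.time[end] - traj.time[start]))


def phase_times(
    velocity: np.ndarray, bounds: MovementBounds, time: np.ndarray
) -> tuple[float, float]:
    """(acceleration_time, deceleration_time) split at peak velocity.

    The split is at the index of maximum tangential velocity within the
    movement bounds; ties go to the earliest maximum.
    """
    seg = np.asarray(velocity, dtype=float)[bounds.start_index : bounds.end_index + 1]
    peak = bounds.start_index + int(np.argmax(seg))
    acc = float(time[peak] - time[bounds.start_index])
    dec = float(time[bounds.end_index] - time[peak])
    return acc, dec


def curvature(
    traj: TipTrajectory,
    bounds: MovementBounds,
    start_point,
    target_point,
    plane: str,
) -> float:
    """Maximum in-plane deviation (mm) from the start->target chord.

    ``plane="horizontal"`` projects path and chord onto the transversal
    (x-y) plane; ``plane="vertical"`` onto the sagittal (x-z) plane.  The
    result is the unsigned maximum perpendicular distance over the
    in-bounds samples.
    """
    start_point = np.asarray(start_point, dtype=float)
    target_point = np.asarray(target_point, dtype=float)
    if np.allclose(start_point, target_point):
        raise InvalidInputError("start and target points coincide")
    if plane == "horizontal":
        axes = (0, 1)
    elif plane == "vertical":
        axes = (0, 2)
    else:
        raise InvalidInputError(f"plane must be 'horizontal' or 'vertical', got {plane!r}")

    pts = traj.position[bounds.start_index : bounds.end_index + 1][:, axes]
    a = start_point[list(axes)]
    b = target_point[list(axes)]
    chord = b - a
    length = np.linalg.norm(chord)
    if length < 1e-12:
        raise InvalidInputError("projected chord is degenerate in the requested plane")
    rel = pts - a
    # 2-D cross product magnitude / chord length = perpendicular distance.
    dist = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0]) / length
    return float(dist.max())


def accuracy_errors(endpoints, target_point) -> tuple[float, float]:
    """(absolute_error, variable_error) over a condition's endpoints, mm.

    Per trial the absolute error is the Euclidean distance from the tip at
    movement end to the target centre.  The condition's absolute error is
    the mean over trials; the variable error is the (n-1) standard
    deviation of the per-trial absolute errors.
    """
    pts = np.asarray(endpoints, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise InvalidInputError(f"endpoints must be (n_trials, 3), got {pts.shape}")
    if pts.shape[0] < 2:
        raise InsufficientDataError("need at least 2 endpoints for accuracy errors")
    errors = np.linalg.norm(pts - np.asarray(target_point, dtype=float), axis=1)
    return float(errors.mean()), float(errors.std(ddof=1))


def time_normalize(
    series, time: np.ndarray, bounds: MovementBounds, n_points: int = N_NORMALIZED
) -> np.ndarray:
    """Linearly resample the in-bounds part of ``series`` onto ``n_points``.

    Point ``k`` (k = 1..n_points) sits at fraction ``k / n_points`` of the
    movement time measured from the start sample, so the last point
    coincides with the end-of-movement sample and the first point is the
    "1 %" instant.
    """
    arr = np.asarray(series, dtype=float)
    time = np.asarray(time, dtype=float)
    if arr.shape[0] != time.size:
        raise InvalidInputError("series and time must have equal length")
    lo, hi = bounds.start_index, bounds.end_index
    if hi - lo + 1 < 2:
        raise InsufficientDataError("need at least 2 in-bounds samples to normalize")
    t_seg = time[lo : hi + 1]
    seg = arr[lo : hi + 1]
    fractions = np.arange(1, n_points + 1) / n_points
    grid = t_seg[0] + fractions * (t_seg[-1] - t_seg[0])
    if seg.ndim == 1:
        return np.interp(grid, t_seg, seg)
    out = np.empty((n_points,) + seg.shape[1:])
    flat = seg.reshape(seg.shape[0], -1)
    for j in range(flat.shape[1]):
        out.reshape(n_points, -1)[:, j] = np.interp(grid, t_seg, flat[:, j])
    return out


def lowpass(values: np.ndarray, sample_rate: float, cutoff_hz: float = 10.0) -> np.ndarray:
    """Optional zero-phase 2nd-order Butterworth low-pass (off by default)."""
    b, a = butter(2, cutoff_hz / (sample_rate / 2.0))
    return filtfilt(b, a, np.asarray(values, dtype=float), axis=0)
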