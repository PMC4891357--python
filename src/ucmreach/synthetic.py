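"""Synthetic trial-ensemble generator emulating the study design.

The experiment this package analyses had participants make 25 point-to-
point reaches (start and target 30 cm apart on a table) in 8 conditions:
four end-effector lengths (index finger, or a rod of 10/20/30 cm taped to
the finger) crossed with two seatings — either the chair was displaced away
from the target by exactly the rod length (so the tip amplitude and arm
postures stay comparable) or it was not (so longer rods need smaller joint
excursions).  Motion capture ran at 100 Hz.

The generator reproduces that design around a deterministic reference
movement: a straight minimum-jerk tip path tracked through damped
least-squares inverse kinematics.  Trial-to-trial variability is injected
in *joint space*, split between the Jacobian null space (goal-equivalent,
per-dimension std ``sigma_gev``) and its orthogonal complement
(non-goal-equivalent, std ``sigma_ngev``), which makes the ground-truth UCM
variances analytic: GEV = sigma_gev**2 and NGEV = sigma_ngev**2 at the
injection instant, up to the linearisation error of forward kinematics.
Deviations are temporally smooth (Gaussian-kernel-filtered white noise) so
velocity-threshold bounds detection still works on perturbed trials.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve1d

from .arm_model import (
    ArmGeometry,
    N_JOINTS,
    compute_jacobian,
    forward_kinematics,
    subspace_bases,
    validate_config,
)
from .errors import ConvergenceError, InvalidInputError, ReachabilityError
from .kinematics import TipTrajectory

__all__ = [
    "ConditionSpec",
    "VariabilityModel",
    "TrialEnsemble",
    "ReferenceMovement",
    "prepare_reference",
    "sample_ensemble",
    "ROD_LENGTHS_MM",
    "START_TARGET_DISTANCE_MM",
    "DEFAULT_START_POINT",
    "study_design",
    "minimum_jerk_path",
    "reference_joint_trajectory",
    "solve_posture",
    "generate_condition_dataset",
    "joint_path_length",
]

#: The study's four end-effector extensions, mm.
ROD_LENGTHS_MM = (0.0, 100.0, 200.0, 300.0)
#: Start and target are 30 cm apart.
START_TARGET_DISTANCE_MM = 300.0
#: Start point in the shoulder-centred frame for non-displaced conditions
#: (mm): 21.5 cm ahead of the shoulder, 30 cm below it (table height).
#: Keeps every condition's target comfortably inside the workspace (at most
#: ~87 % of chain length) and gives elbow flexion ~118 deg at the start and
#: ~64 deg at the target for the index-finger condition.
DEFAULT_START_POINT = (215.0, 0.0, -300.0)

#: Comfortable seated start posture used to seed inverse kinematics:
#: upper arm forward-down next to the body, elbow flexed roughly 110 deg.
_IK_SEED_POSTURE = np.array([0.0, 0.9, 0.0, -1.9, 0.0, 0.0, 0.0, 0.0, 0.0])


@dataclass(frozen=True)
class ConditionSpec:
    """One experimental condition: end-effector length, seating, task layout.

    ``displaced`` moves the shoulder ``rod_length`` farther from the target
    along -x, which in this shoulder-centred frame shifts both start and
    target by +``rod_length`` along x.  Movement time and the stationary
    hold phases around the reach are generator choices (the reference
    movement is symmetric minimum-jerk); defaults give a 0.7 s reach with
    a 0.80 m/s peak, inside the envelope reported for 30 cm seated reaches.
    """

    rod_length: float
    displaced: bool
    start_point: tuple[float, float, float]
    target_point: tuple[float, float, float]
    n_trials: int = 25
    sample_rate: float = 100.0
    movement_time: float = 0.7
    pre_hold: float = 0.3
    post_hold: float = 0.6

    def __post_init__(self) -> None:
        if self.rod_length < 0:
            raise InvalidInputError("rod_length must be >= 0")
        if self.n_trials < 1:
            raise InvalidInputError("n_trials must be >= 1")
        if self.movement_time <= 0 or self.sample_rate <= 0:
            raise InvalidInputError("movement_time and sample_rate must be > 0")
        if self.amplitude < 1e-9:
            raise InvalidInputError("start and target points must be distinct")

    @property
    def amplitude(self) -> float:
        return float(
            np.linalg.norm(np.subtract(self.target_point, self.start_point))
        )

    @property
    def name(self) -> str:
        placement = "displaced" if self.displaced else "not_displaced"
        return f"rod{int(round(self.rod_length / 10.0))}cm_{placement}"

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "rod_length_mm": self.rod_length,
            "displaced": self.displaced,
            "start_point_mm": list(self.start_point),
            "target_point_mm": list(self.target_point),
            "n_trials": self.n_trials,
            "sample_rate_hz": self.sample_rate,
            "movement_time_s": self.movement_time,
            "pre_hold_s": self.pre_hold,
            "post_hold_s": self.post_hold,
        }


@dataclass(frozen=True)
class VariabilityModel:
    """Joint-space trial-to-trial variability parameters.

    ``sigma_gev`` / ``sigma_ngev`` are the per-dimension standard
    deviations (rad) of the deviations injected into the Jacobian null
    space and its orthogonal complement; the defaults, 2 deg and 0.5 deg,
    give the 4:1 goal-equivalent dominance typical of stabilised pointing.
    ``temporal_smoothness`` is the correlation time (s) of the
    Gaussian-kernel noise process — 0.25 s models slow postural drift
    rather than sample-to-sample jitter.
    """

    sigma_gev: float = float(np.deg2rad(2.0))
    sigma_ngev: float = float(np.deg2rad(0.5))
    temporal_smoothness: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_gev < 0 or self.sigma_ngev < 0:
            raise InvalidInputError("noise standard deviations must be >= 0")
        if self.temporal_smoothness < 0:
            raise InvalidInputError("temporal_smoothness must be >= 0")

    def to_dict(self) -> dict:
        return {
            "sigma_gev_rad": self.sigma_gev,
            "sigma_ngev_rad": self.sigma_ngev,
            "temporal_smoothness_s": self.temporal_smoothness,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class TrialEnsemble:
    """All trials of one condition: joint angles and tip paths over time.

    ``angles`` has shape ``(n_trials, n_samples, 9)`` (rad), ``tips``
    ``(n_trials, n_samples, 3)`` (mm); the noiseless reference trajectory
    is kept alongside.
    """

    condition: ConditionSpec
    geometry: ArmGeometry
    model: VariabilityModel | None
    time: np.ndarray
    reference_angles: np.ndarray
    reference_tip: np.ndarray
    angles: np.ndarray
    tips: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.angles.shape[0]

    @property
    def n_samples(self) -> int:
        return self.time.size

    def trial_trajectory(self, i: int) -> TipTrajectory:
        return TipTrajectory(self.time, self.tips[i])


def study_design(
    n_trials: int = 25,
    start_point=DEFAULT_START_POINT,
    **overrides,
) -> list[ConditionSpec]:
    """The 8-condition design: 4 rod lengths x displaced/not, 25 trials each.

    Start and target sit 30 cm apart along +x in a horizontal plane 30 cm
    below the shoulder; displaced conditions shift both points away from
    the shoulder by the rod length.
    """
    start = np.asarray(start_point, dtype=float)
    conditions = []
    for displaced in (False, True):
        for rod in ROD_LENGTHS_MM:
            shift = np.array([rod if displaced else 0.0, 0.0, 0.0])
            s = tuple(float(v) for v in start + shift)
            t = tuple(float(v) for v in np.add(s, (START_TARGET_DISTANCE_MM, 0.0, 0.0)))
            conditions.append(
                ConditionSpec(
                    rod_length=rod,
                    displaced=displaced,
                    start_point=tuple(s),
                    target_point=tuple(t),
                    n_trials=n_trials,
                    **overrides,
                )
            )
    return conditions


def minimum_jerk_path(
    start,
    target,
    movement_time: float,
    sample_rate: float = 100.0,
    pre_hold: float = 0.3,
    post_hold: float = 0.6,
) -> TipTrajectory:
    """Straight-line reach with the quintic minimum-jerk time profile.

    The normalised profile is ``s(tau) = 10 tau^3 - 15 tau^4 + 6 tau^5``,
    the standard smoothness-optimal shape for point-to-point reaching; its
    peak speed is ``1.875 * amplitude / movement_time`` at the midpoint.
    Stationary holds of ``pre_hold`` / ``post_hold`` seconds flank the
    movement so that threshold-based bounds detection has sub-threshold
    data on both sides.
    """
    start = np.asarray(start, dtype=float)
    target = np.asarray(target, dtype=float)
    if movement_time <= 0 or sample_rate <= 0:
        raise InvalidInputError("movement_time and sample_rate must be > 0")
    if np.linalg.norm(target - start) < 1e-9:
        raise InvalidInputError("start and target must be distinct")
    dt = 1.0 / sample_rate
    n_pre = int(round(pre_hold * sample_rate))
    n_move = int(round(movement_time * sample_rate))
    n_post = int(round(post_hold * sample_rate))
    if n_move < 2:
        raise InvalidInputError("movement_time too short for the sample rate")
    n_total = n_pre + n_move + n_post + 1
    time = np.arange(n_total) * dt
    tau = np.clip((time - n_pre * dt) / (n_move * dt), 0.0, 1.0)
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    position = start[None, :] + s[:, None] * (target - start)[None, :]
    return TipTrajectory(time, position)


def _ik_solve(
    q0: np.ndarray,
    target: np.ndarray,
    geometry: ArmGeometry,
    damping: float,
    max_iter: int,
    tol: float,
    step_limit: float = 0.3,
) -> tuple[np.ndarray, float]:
    """Damped least-squares iteration toward one tip target."""
    q = q0.copy()
    eye3 = np.eye(3)
    residual = np.inf
    for _ in range(max_iter):
        tip = forward_kinematics(q, geometry)
        r = target - tip
        residual = float(np.linalg.norm(r))
        if residual < tol:
            return q, residual
        jac = compute_jacobian(q, geometry)
        dq = jac.T @ np.linalg.solve(jac @ jac.T + damping**2 * eye3, r)
        norm = float(np.linalg.norm(dq))
        if norm > step_limit:
            dq *= step_limit / norm
        q = q + dq
    # final check after the last update
    residual = float(np.linalg.norm(target - forward_kinematics(q, geometry)))
    if residual < tol:
        return q, residual
    raise ConvergenceError(
        f"inverse kinematics did not converge (residual {residual:.4g} mm)"
    )


def solve_posture(
    target,
    geometry: ArmGeometry,
    initial_config=None,
    damping: float = 0.01,
    max_iter: int = 500,
    tol: float = 0.01,
) -> np.ndarray:
    """Find a joint configuration placing the tip at ``target`` (mm).

    Seeds the damped least-squares iteration from a comfortable flexed
    posture (or ``initial_config``); used to establish the start posture of
    each condition.
    """
    target = np.asarray(target, dtype=float)
    if np.linalg.norm(target) >= geometry.total_length:
        raise ReachabilityError(
            f"target at {np.linalg.norm(target):.1f} mm exceeds the "
            f"{geometry.total_length:.1f} mm chain"
        )
    q0 = _IK_SEED_POSTURE if initial_config is None else validate_config(initial_config)
    q, _ = _ik_solve(q0, target, geometry, damping, max_iter, tol)
    return q


def reference_joint_trajectory(
    tip_path: TipTrajectory,
    geometry: ArmGeometry,
    initial_config,
    damping: float = 0.01,
    max_iter: int = 200,
    tol: float = 0.01,
) -> np.ndarray:
    """Joint-angle trajectory tracking a tip path, ``(n_samples, 9)`` rad.

    Damped least-squares inverse kinematics warm-started sample to sample
    from ``initial_config``; deterministic given its inputs.  Each sample
    converges to a tip residual below ``tol`` mm or raises
    :class:`~ucmreach.errors.ConvergenceError`; a sample outside the
    reachable workspace raises :class:`~ucmreach.errors.ReachabilityError`
    naming the sample.
    """
    q = validate_config(initial_config).astype(float)
    out = np.empty((tip_path.n_samples, N_JOINTS))
    reach = geometry.total_length
    for i, target in enumerate(tip_path.position):
        if np.linalg.norm(target) >= reach:
            raise ReachabilityError(
                f"tip sample {i} at {np.linalg.norm(target):.1f} mm exceeds "
                f"the {reach:.1f} mm chain"
            )
        try:
            q, _ = _ik_solve(q, target, geometry, damping, max_iter, tol)
        except ConvergenceError as exc:
            raise ConvergenceError(f"sample {i}: {exc}") from None
        out[i] = q
    return out


def _smooth_noise(
    rng: np.random.Generator,
    shape: tuple[int, ...],
    sigma: float,
    correlation_time: float,
    sample_rate: float,
) -> np.ndarray:
    """Zero-mean Gaussian process, instantaneous std ``sigma``, smoothed
    along axis -2 by a Gaussian kernel of width ``correlation_time``.

    The filtered process is rescaled by the exact theoretical factor
    (1/sqrt(sum k^2) for a sum-normalised kernel), not an empirical one,
    so the injected instantaneous variance is exactly ``sigma**2`` in
    expectation at every sample.
    """
    if sigma == 0.0:
        return np.zeros(shape)
    width = correlation_time * sample_rate  # in samples
    if width < 1e-9:
        return sigma * rng.standard_normal(shape)
    radius = max(1, int(np.ceil(4 * width)))
    x = np.arange(-radius, radius + 1)
    kernel = np.exp(-0.5 * (x / width) ** 2)
    kernel /= kernel.sum()
    scale = sigma / np.sqrt(np.sum(kernel**2))
    n = shape[-2]
    padded_shape = shape[:-2] + (n + 2 * radius,) + shape[-1:]
    white = rng.standard_normal(padded_shape)
    smoothed = convolve1d(white, kernel, axis=-2, mode="constant")
    return scale * smoothed[..., radius : radius + n, :]


@dataclass(frozen=True)
class ReferenceMovement:
    """Deterministic per-condition reference: tip path, joint trajectory
    and the instantaneous null/orthogonal projection matrices."""

    condition: ConditionSpec
    geometry: ArmGeometry
    time: np.ndarray
    tip: np.ndarray  # (n_samples, 3)
    angles: np.ndarray  # (n_samples, 9)
    p_null: np.ndarray  # (n_samples, 9, 9)
    p_orth: np.ndarray  # (n_samples, 9, 9)


def prepare_reference(
    condition: ConditionSpec, geometry: ArmGeometry = ArmGeometry()
) -> ReferenceMovement:
    """Build a condition's noiseless reference movement once.

    Minimum-jerk tip path, damped least-squares joint trajectory, and the
    Jacobian subspace projectors at every sample.  Replicate ensembles of
    the same condition can share this (the expensive part of simulation).
    """
    geometry = geometry.with_rod(condition.rod_length)
    tip_path = minimum_jerk_path(
        condition.start_point,
        condition.target_point,
        condition.movement_time,
        condition.sample_rate,
        condition.pre_hold,
        condition.post_hold,
    )
    q_start = solve_posture(condition.start_point, geometry)
    ref = reference_joint_trajectory(tip_path, geometry, q_start)
    n = tip_path.n_samples

    jacs = compute_jacobian(ref, geometry)  # (n, 3, 9)
    p_null = np.empty((n, N_JOINTS, N_JOINTS))
    p_orth = np.empty((n, N_JOINTS, N_JOINTS))
    for i in range(n):
        bases = subspace_bases(jacs[i])
        p_null[i] = bases.null_basis @ bases.null_basis.T
        p_orth[i] = bases.orth_basis @ bases.orth_basis.T
    return ReferenceMovement(
        condition=condition,
        geometry=geometry,
        time=tip_path.time,
        tip=tip_path.position,
        angles=ref,
        p_null=p_null,
        p_orth=p_orth,
    )


def sample_ensemble(
    reference: ReferenceMovement,
    model: VariabilityModel = VariabilityModel(),
    rng: np.random.Generator | None = None,
) -> TrialEnsemble:
    """Draw one trial ensemble around a prepared reference movement.

    Per trial and time sample, a smooth zero-mean joint-space deviation is
    added to the reference trajectory: the projection of one smooth 9-D
    process onto the instantaneous Jacobian null space (std ``sigma_gev``
    per dimension) plus the projection of an independent process onto the
    orthogonal complement (std ``sigma_ngev``).  Projection matrices are
    continuous in time (unlike raw SVD bases), so the deviations stay
    smooth.  Tip paths are recomputed through forward kinematics, making
    the tip-level consequences of the joint-space noise fully nonlinear.
    """
    condition = reference.condition
    geometry = reference.geometry
    ref = reference.angles
    p_null, p_orth = reference.p_null, reference.p_orth
    n = reference.time.size
    if rng is None:
        rng = np.random.default_rng(model.seed)
    shape = (condition.n_trials, n, N_JOINTS)
    w_gev = _smooth_noise(
        rng, shape, model.sigma_gev, model.temporal_smoothness, condition.sample_rate
    )
    w_ngev = _smooth_noise(
        rng, shape, model.sigma_ngev, model.temporal_smoothness, condition.sample_rate
    )
    deviations = np.einsum("nij,tnj->tni", p_null, w_gev) + np.einsum(
        "nij,tnj->tni", p_orth, w_ngev
    )
    # Emulate the study's physical constraints on the deviations:
    # the start posture is clamped (tip on the start dot, elbow on its
    # placer), so variability ramps in over the first half of the reach;
    # and each trial comes to rest on its own landing spot and holds it
    # until the end-of-trial signal, so the deviation freezes at the
    # movement-end sample.  At the movement end (the 100% instant) the
    # envelope is 1 and the instant-wise injected variance is exactly the
    # model's sigma**2 per subspace dimension.
    n_pre = int(round(condition.pre_hold * condition.sample_rate))
    n_move = int(round(condition.movement_time * condition.sample_rate))
    i_end = n_pre + n_move
    tau = np.clip((np.arange(n) - n_pre) / (0.5 * n_move), 0.0, 1.0)
    envelope = tau * tau * (3.0 - 2.0 * tau)  # smoothstep 0 -> 1
    deviations *= envelope[None, :, None]
    if i_end < n:
        deviations[:, i_end:, :] = deviations[:, i_end : i_end + 1, :]
    angles = ref[None, :, :] + deviations
    tips = forward_kinematics(angles, geometry)
    return TrialEnsemble(
        condition=condition,
        geometry=geometry,
        model=model,
        time=reference.time,
        reference_angles=ref,
        reference_tip=reference.tip,
        angles=angles,
        tips=tips,
    )


def generate_condition_dataset(
    condition: ConditionSpec,
    geometry: ArmGeometry = ArmGeometry(),
    model: VariabilityModel = VariabilityModel(),
    rng: np.random.Generator | None = None,
) -> TrialEnsemble:
    """Simulate one condition's trial ensemble (reference + noise).

    Convenience wrapper around :func:`prepare_reference` and
    :func:`sample_ensemble`; the arm geometry's rod length is overridden
    by the condition's.
    """
    return sample_ensemble(prepare_reference(condition, geometry), model, rng)


def joint_path_length(angles: np.ndarray) -> float:
    """Total joint-space path length sum(||q_{t+1} - q_t||), rad."""
    q = np.asarray(angles, dtype=float)
    return float(np.sum(np.linalg.norm(np.diff(q, axis=0), axis=1)))
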