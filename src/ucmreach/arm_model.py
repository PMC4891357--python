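"""Kinematic model of the 9-degree-of-freedom arm-plus-rod chain.

The chain runs shoulder -> elbow -> wrist -> finger base (metacarpophalangeal
joint) -> fingertip, optionally extended by a rigid rod taped collinear with
the distal finger segment.  Nine joint angles drive it, in the canonical
order used everywhere in this package (:data:`JOINT_NAMES`):

0. shoulder plane of elevation
1. shoulder elevation
2. shoulder axial (endo/exo) rotation
3. elbow flexion-extension
4. forearm pronation-supination
5. wrist abduction-adduction
6. wrist flexion-extension
7. finger abduction-adduction
8. finger flexion-extension

Conventions (the package's own; biomechanical guidelines leave the rotation
sequences to the implementer):

* Lab frame: origin at the shoulder centre, +x horizontal from the
  participant toward the target, +y to the participant's left, +z up.
* Zero posture: the whole chain straightened along +x, rod collinear.
* Shoulder: intrinsic Z (plane of elevation) * Y (elevation) * X (axial
  rotation) stack.  Elbow flexion and forearm pronation are successive
  single-axis rotations about the local y and x axes; wrist and finger are
  each abduction (local z) followed by flexion (local y).

Angles are radians internally; lengths are millimetres.  All kinematic
functions broadcast over leading axes, so a whole trajectory of shape
``(n_samples, 9)`` is evaluated in one call.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "JOINT_NAMES",
    "N_JOINTS",
    "N_TASK_DIMS",
    "ArmGeometry",
    "SubspaceBases",
    "forward_kinematics",
    "compute_jacobian",
    "subspace_bases",
    "validate_config",
]

JOINT_NAMES: tuple[str, ...] = (
    "shoulder_plane_of_elevation",
    "shoulder_elevation",
    "shoulder_rotation",
    "elbow_flexion",
    "forearm_pronation",
    "wrist_abduction",
    "wrist_flexion",
    "finger_abduction",
    "finger_flexion",
)
N_JOINTS = 9
N_TASK_DIMS = 3


@dataclass(frozen=True)
class ArmGeometry:
    """Segment lengths of the arm-plus-rod chain, millimetres.

    ``rod_length`` is 0 for index-finger pointing; the study's rods are
    100, 200 and 300 mm, but any non-negative length is accepted.
    """

    upper_arm_length: float = 300.0
    forearm_length: float = 250.0
    hand_length: float = 80.0
    finger_length: float = 70.0
    rod_length: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "upper_arm_length",
            "forearm_length",
            "hand_length",
            "finger_length",
            "rod_length",
        ):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise InvalidInputError(f"{name} must be finite and >= 0, got {value!r}")

    @property
    def total_length(self) -> float:
        """Tip distance from the shoulder at the straightened zero posture."""
        return (
            self.upper_arm_length
            + self.forearm_length
            + self.hand_length
            + self.finger_length
            + self.rod_length
        )

    def with_rod(self, rod_length: float) -> "ArmGeometry":
        """Same arm with a different rod attached."""
        return ArmGeometry(
            self.upper_arm_length,
            self.forearm_length,
            self.hand_length,
            self.finger_length,
            rod_length,
        )


def validate_config(config) -> np.ndarray:
    """Coerce to a float array with trailing axis of 9 finite joint angles."""
    arr = np.asarray(config, dtype=float)
    if arr.shape[-1:] != (N_JOINTS,):
        raise InvalidInputError(
            f"joint configuration must have {N_JOINTS} angles on the last axis, "
            f"got shape {arr.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("joint configuration contains non-finite angles")
    return arr


def _rot_x(a: np.ndarray) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    out = np.zeros(a.shape + (3, 3))
    out[..., 0, 0] = 1.0
    out[..., 1, 1] = c
    out[..., 1, 2] = -s
    out[..., 2, 1] = s
    out[..., 2, 2] = c
    return out


def _rot_y(a: np.ndarray) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    out = np.zeros(a.shape + (3, 3))
    out[..., 1, 1] = 1.0
    out[..., 0, 0] = c
    out[..., 0, 2] = s
    out[..., 2, 0] = -s
    out[..., 2, 2] = c
    return out


def _rot_z(a: np.ndarray) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    out = np.zeros(a.shape + (3, 3))
    out[..., 2, 2] = 1.0
    out[..., 0, 0] = c
    out[..., 0, 1] = -s
    out[..., 1, 0] = s
    out[..., 1, 1] = c
    return out


def forward_kinematics(config, geometry: ArmGeometry) -> np.ndarray:
    """Cartesian tip position (mm) of the rod tip (fingertip when no rod).

    Parameters
    ----------
    config
        Array-like of shape ``(..., 9)`` of joint angles in radians, in
        :data:`JOINT_NAMES` order.
    geometry
        Segment lengths.

    Returns
    -------
    ndarray of shape ``(..., 3)`` — tip position in the shoulder-centred
    lab frame.
    """
    q = validate_config(config)
    # Shoulder orientation: intrinsic Z * Y * X.
    r = _rot_z(q[..., 0]) @ _rot_y(q[..., 1]) @ _rot_x(q[..., 2])
    # Segments point along the local +x axis, so R @ [L,0,0] = L * R[:, 0].
    tip = geometry.upper_arm_length * r[..., :, 0]
    r = r @ _rot_y(q[..., 3]) @ _rot_x(q[..., 4])
    tip = tip + geometry.forearm_length * r[..., :, 0]
    r = r @ _rot_z(q[..., 5]) @ _rot_y(q[..., 6])
    tip = tip + geometry.hand_length * r[..., :, 0]
    r = r @ _rot_z(q[..., 7]) @ _rot_y(q[..., 8])
    tip = tip + (geometry.finger_length + geometry.rod_length) * r[..., :, 0]
    return tip


def compute_jacobian(config, geometry: ArmGeometry, step: float = 1e-6) -> np.ndarray:
    """Jacobian of tip position w.r.t. the joint angles, mm/rad.

    Central finite differences on :func:`forward_kinematics` with step
    ``step`` radians.  Broadcasts: ``(..., 9)`` configurations give a
    ``(..., 3, 9)`` stack of Jacobians.
    """
    q = validate_config(config)
    eye = np.eye(N_JOINTS)
    # (..., 9 probes, 9 angles)
    plus = q[..., None, :] + step * eye
    minus = q[..., None, :] - step * eye
    fp = forward_kinematics(plus, geometry)  # (..., 9, 3)
    fm = forward_kinematics(minus, geometry)
    jac = (fp - fm) / (2.0 * step)  # (..., 9, 3): d tip / d angle_j
    return np.swapaxes(jac, -1, -2)  # (..., 3, 9)


@dataclass(frozen=True)
class SubspaceBases:
    """Orthonormal bases of the Jacobian's null space and row space.

    ``null_basis`` (9 x k, k = 9 - rank(J)) spans the joint-angle changes
    that leave the tip fixed to first order — the uncontrolled manifold's
    tangent space.  ``orth_basis`` (9 x rank) spans its orthogonal
    complement, the directions that do move the tip.  ``singular`` flags a
    rank-deficient Jacobian (rank < 3, e.g. a fully stretched posture); the
    bases then have the actual dimensions and the caller decides.
    """

    null_basis: np.ndarray
    orth_basis: np.ndarray
    singular: bool = False
    rank: int = field(default=N_TASK_DIMS)

    @property
    def n_null(self) -> int:
        return self.null_basis.shape[1]

    @property
    def n_orth(self) -> int:
        return self.orth_basis.shape[1]


def subspace_bases(jacobian, rcond: float = 1e-10) -> SubspaceBases:
    """Split joint space into null(J) and its orthogonal complement.

    Uses the singular-value decomposition of ``jacobian``; singular values
    below ``rcond`` times the largest are treated as zero.  At a generic
    posture the null space has dimension 6 and the complement dimension 3.
    """
    j = np.asarray(jacobian, dtype=float)
    if j.shape != (N_TASK_DIMS, N_JOINTS):
        raise InvalidInputError(
            f"Jacobian must be {N_TASK_DIMS}x{N_JOINTS}, got {j.shape}"
        )
    if not np.all(np.isfinite(j)):
        raise InvalidInputError("Jacobian contains non-finite entries")
    _, s, vt = np.linalg.svd(j, full_matrices=True)
    if s.size and s[0] > 0:
        rank = int(np.sum(s > rcond * s[0]))
    else:
        rank = 0
    orth = vt[:rank].T
    null = vt[rank:].T
    return SubspaceBases(
        null_basis=null,
        orth_basis=orth,
        singular=rank < N_TASK_DIMS,
        rank=rank,
    )
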