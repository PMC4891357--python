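"""Uncontrolled-manifold (UCM) variance decomposition.

Across repeated reaches, the 9 joint angles at a given movement instant
vary from trial to trial.  Because the arm is redundant (9 joint angles, a
3-D tip position), part of that variability lies along the uncontrolled
manifold — joint-angle combinations that leave the tip where it is — and
part lies orthogonal to it.  With ``C`` the across-trials joint-angle
covariance matrix and ``J`` the tip Jacobian at the mean configuration:

    NGEV = trace(orth(J^T)^T @ C @ orth(J^T)) / d          (d = 3)
    GEV  = trace(null(J)^T  @ C @ null(J))  / (n - d)      (n = 9)
    V_Ratio = GEV / NGEV

GEV (goal-equivalent variability) is variance per null-space dimension;
NGEV (non-goal-equivalent variability) is variance per orthogonal
dimension; both in rad².  V_Ratio > 1 — equivalently log(V_Ratio) > 0 —
means joint-angle covariation stabilises the tip position.  Because the
raw quantities are strongly right-skewed across participants and
conditions, downstream statistics use the natural-log transforms.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .arm_model import N_JOINTS, N_TASK_DIMS, SubspaceBases, validate_config
from .errors import InsufficientDataError, InvalidInputError

__all__ = [
    "UCMResult",
    "joint_covariance",
    "ucm_decompose",
    "ucm_decompose_oracle",
    "log_transform",
]

# Negative projected variances larger than this magnitude indicate a
# genuinely non-PSD covariance rather than round-off.
_NEGATIVITY_TOL = 1e-12


@dataclass(frozen=True)
class UCMResult:
    """GEV, NGEV and their ratio at one movement instant.

    ``undefined`` lists the fields that could not be computed (e.g. the
    logs when a variance is zero); they are NaN rather than +/-inf so that
    aggregation never silently propagates non-finite values.
    """

    gev: float
    ngev: float
    v_ratio: float
    gev_log: float
    ngev_log: float
    v_ratio_log: float
    n_joint_dims: int = N_JOINTS
    n_task_dims: int = N_TASK_DIMS
    singular: bool = False
    undefined: tuple[str, ...] = field(default_factory=tuple)

    @property
    def stabilized(self) -> bool:
        """True when GEV > NGEV, i.e. log(V_Ratio) > 0."""
        return self.gev > self.ngev

    def to_dict(self) -> dict:
        return {
            "gev": self.gev,
            "ngev": self.ngev,
            "v_ratio": self.v_ratio,
            "gev_log": self.gev_log,
            "ngev_log": self.ngev_log,
            "v_ratio_log": self.v_ratio_log,
            "n_joint_dims": self.n_joint_dims,
            "n_task_dims": self.n_task_dims,
            "singular": self.singular,
            "undefined": list(self.undefined),
            "stabilized": self.stabilized,
        }


def joint_covariance(ensemble) -> np.ndarray:
    """Unbiased 9x9 covariance of joint configurations across trials.

    ``ensemble`` is array-like of shape ``(n_trials, 9)``: one joint
    configuration per trial, all taken at the same movement instant.
    Divides by ``n_trials - 1``.  The data are shifted by the first trial
    before centring — covariance is translation invariant, and the shift
    makes an ensemble of identical configurations yield an exact zero
    matrix instead of cancellation round-off.
    """
    configs = validate_config(ensemble)
    if configs.ndim != 2:
        raise InvalidInputError(
            f"ensemble must be 2-D (n_trials, {N_JOINTS}), got shape {configs.shape}"
        )
    if configs.shape[0] < 2:
        raise InsufficientDataError(
            f"need at least 2 trials for a covariance, got {configs.shape[0]}"
        )
    return np.cov(configs - configs[0], rowvar=False, ddof=1)


def _check_covariance(cov) -> np.ndarray:
    c = np.asarray(cov, dtype=float)
    if c.shape != (N_JOINTS, N_JOINTS):
        raise InvalidInputError(f"covariance must be {N_JOINTS}x{N_JOINTS}, got {c.shape}")
    if not np.all(np.isfinite(c)):
        raise InvalidInputError("covariance contains non-finite entries")
    if not np.allclose(c, c.T, atol=1e-12, rtol=0.0):
        raise InvalidInputError("covariance is not symmetric within 1e-12")
    return c


def _clip_variance(value: float, label: str) -> float:
    if value < 0.0:
        if value < -_NEGATIVITY_TOL:
            raise InvalidInputError(
                f"{label} = {value!r} is negative beyond round-off; "
                "covariance is not positive semi-definite"
            )
        warnings.warn(
            f"{label} = {value:.3e} is negative within round-off; clipping to 0",
            RuntimeWarning,
            stacklevel=3,
        )
        return 0.0
    return value


def _assemble(gev: float, ngev: float, singular: bool) -> UCMResult:
    undefined: list[str] = []

    gev_log = log_transform(gev)
    if gev_log is None:
        undefined.append("gev_log")
    ngev_log = log_transform(ngev)
    if ngev_log is None:
        undefined.append("ngev_log")

    if ngev > 0.0:
        v_ratio = gev / ngev
        v_ratio_log = log_transform(v_ratio)
        if v_ratio_log is None:
            undefined.append("v_ratio_log")
    else:
        v_ratio = math.nan
        v_ratio_log = None
        undefined += ["v_ratio", "v_ratio_log"]

    nan = math.nan
    return UCMResult(
        gev=gev,
        ngev=ngev,
        v_ratio=v_ratio,
        gev_log=nan if gev_log is None else gev_log,
        ngev_log=nan if ngev_log is None else ngev_log,
        v_ratio_log=nan if v_ratio_log is None else v_ratio_log,
        singular=singular,
        undefined=tuple(undefined),
    )


def ucm_decompose(cov, bases: SubspaceBases) -> UCMResult:
    """Decompose a joint-angle covariance into GEV and NGEV.

    ``bases`` must come from the Jacobian at the mean configuration of the
    same ensemble that produced ``cov``.  The conservation identity
    ``d * NGEV + (n - d) * GEV = trace(C)`` holds exactly (to round-off)
    because the two bases together span the full joint space.
    """
    c = _check_covariance(cov)
    null_b, orth_b = bases.null_basis, bases.orth_basis
    if null_b.shape[0] != N_JOINTS or orth_b.shape[0] != N_JOINTS:
        raise InvalidInputError("subspace bases do not match the 9-D joint space")
    n_null = null_b.shape[1]
    n_orth = orth_b.shape[1]
    if n_null == 0 or n_orth == 0:
        raise InvalidInputError("degenerate bases: empty null or orthogonal subspace")
    gev = _clip_variance(float(np.trace(null_b.T @ c @ null_b)) / n_null, "GEV")
    ngev = _clip_variance(float(np.trace(orth_b.T @ c @ orth_b)) / n_orth, "NGEV")
    return _assemble(gev, ngev, bases.singular)


def ucm_decompose_oracle(ensemble, bases: SubspaceBases) -> UCMResult:
    """Brute-force UCM decomposition by explicit per-trial projection.

    Projects each trial's deviation from the ensemble mean onto each basis,
    averages the squared projection norms over trials (dividing by
    ``n_trials - 1``) and normalises by subspace dimension.  Algebraically
    identical to :func:`ucm_decompose` applied to
    :func:`joint_covariance`; kept as an independent verification path.
    """
    configs = validate_config(ensemble)
    if configs.ndim != 2:
        raise InvalidInputError(
            f"ensemble must be 2-D (n_trials, {N_JOINTS}), got shape {configs.shape}"
        )
    n_trials = configs.shape[0]
    if n_trials < 2:
        raise InsufficientDataError(f"need at least 2 trials, got {n_trials}")
    shifted = configs - configs[0]  # translation invariant, exact at zero spread
    dev = shifted - shifted.mean(axis=0)
    proj_null = dev @ bases.null_basis  # (n_trials, n_null)
    proj_orth = dev @ bases.orth_basis
    gev = float(np.sum(proj_null**2)) / (n_trials - 1) / bases.n_null
    ngev = float(np.sum(proj_orth**2)) / (n_trials - 1) / bases.n_orth
    return _assemble(gev, ngev, bases.singular)


def log_transform(value: float):
    """Natural log of a positive scalar; ``None`` when undefined.

    The study's skew correction.  A non-positive input is not an error at
    this level — the caller records the corresponding result field as
    undefined instead of propagating -inf.
    """
    if value is None or not np.isfinite(value) or value <= 0.0:
        return None
    return math.log(value)
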