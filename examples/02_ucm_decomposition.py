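"""GEV/NGEV decomposition of across-trials joint-angle variability.

Constructs a 25-trial ensemble of joint configurations whose spread is
four times larger (in std) along the manifold than orthogonal to it, then
decomposes the across-trials covariance with the trace formulas and
verifies the result against the explicit per-trial projection oracle.
"""
import numpy as np

from ucmreach import (
    ArmGeometry,
    compute_jacobian,
    joint_covariance,
    subspace_bases,
    ucm_decompose,
    ucm_decompose_oracle,
)

rng = np.random.default_rng(42)
geometry = ArmGeometry()
mean_posture = np.deg2rad([5.0, 50.0, -10.0, -70.0, 10.0, 0.0, -10.0, 0.0, 5.0])

bases = subspace_bases(compute_jacobian(mean_posture, geometry))
sigma_gev, sigma_ngev = np.deg2rad(2.0), np.deg2rad(0.5)  # 4:1 std ratio
trials = (
    mean_posture
    + (sigma_gev * rng.standard_normal((25, 6))) @ bases.null_basis.T
    + (sigma_ngev * rng.standard_normal((25, 3))) @ bases.orth_basis.T
)

res = ucm_decompose(joint_covariance(trials), bases)
oracle = ucm_decompose_oracle(trials, bases)

print(f"GEV  = {res.gev:.3e} rad^2/dim (injected {sigma_gev**2:.3e})")
print(f"NGEV = {res.ngev:.3e} rad^2/dim (injected {sigma_ngev**2:.3e})")
print(f"V_Ratio = {res.v_ratio:.2f}, log(V_Ratio) = {res.v_ratio_log:.2f}")
print(f"oracle agreement: |dGEV| = {abs(res.gev - oracle.gev):.2e}")
print(f"stabilized (GEV > NGEV): {res.stabilized}")
# log(V_Ratio) > 0 is the stabilisation signature: the joint configuration
# varies mostly along directions that do not move the tip.
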