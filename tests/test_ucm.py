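"""UCM variance decomposition: covariance, trace formulas, oracle, logs."""
import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ucmreach import (
    compute_jacobian,
    joint_covariance,
    log_transform,
    subspace_bases,
    ucm_decompose,
    ucm_decompose_oracle,
)
from ucmreach.errors import InsufficientDataError, InvalidInputError

from conftest import random_posture


def random_psd(rng, scale=1e-4):
    a = rng.standard_normal((9, 9))
    c = a @ a.T * scale / 9.0
    return (c + c.T) / 2.0


@pytest.fixture()
def bases(geometry, rng):
    return subspace_bases(compute_jacobian(random_posture(rng), geometry))


class TestJointCovariance:
    def test_identical_trials_give_zero(self):
        config = np.linspace(0.0, 0.8, 9)
        cov = joint_covariance([config, config])
        np.testing.assert_allclose(cov, np.zeros((9, 9)), atol=1e-15)

    def test_large_sample_diagonal(self, rng):
        # law of large numbers: iid per-joint draws, sigma = 0.02
        mean = np.linspace(-0.5, 0.5, 9)
        trials = mean + 0.02 * rng.standard_normal((10000, 9))
        cov = joint_covariance(trials)
        np.testing.assert_allclose(np.diag(cov), 4e-4, rtol=0.05)

    def test_offset_invariance(self, rng):
        trials = rng.standard_normal((30, 9)) * 0.01
        shifted = trials + np.full(9, 0.7)
        np.testing.assert_allclose(
            joint_covariance(trials), joint_covariance(shifted), atol=1e-15
        )

    def test_single_trial_rejected(self):
        with pytest.raises(InsufficientDataError):
            joint_covariance(np.zeros((1, 9)))


class TestDecompose:
    def test_isotropic_covariance(self, bases):
        res = ucm_decompose(1e-4 * np.eye(9), bases)
        assert res.gev == pytest.approx(1e-4, rel=1e-12)
        assert res.ngev == pytest.approx(1e-4, rel=1e-12)
        assert res.v_ratio == pytest.approx(1.0, rel=1e-12)
        assert res.v_ratio_log == pytest.approx(0.0, abs=1e-12)

    def test_variability_confined_to_manifold(self, bases):
        sigma2 = 1e-4
        cov = bases.null_basis @ (sigma2 * np.eye(6)) @ bases.null_basis.T
        # NGEV may land a hair below zero in floating point and get
        # clipped to 0 (with a RuntimeWarning)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = ucm_decompose(cov, bases)
        assert res.gev == pytest.approx(sigma2, rel=1e-10)
        assert res.ngev == pytest.approx(0.0, abs=1e-16)
        # NGEV is zero up to round-off: the ratio is either flagged
        # undefined (exact zero) or astronomically large
        if "v_ratio" in res.undefined:
            assert math.isnan(res.v_ratio)
        else:
            assert res.v_ratio > 1e12

    def test_conservation(self, bases, rng):
        cov = random_psd(rng)
        res = ucm_decompose(cov, bases)
        total = 3 * res.ngev + 6 * res.gev
        assert total == pytest.approx(np.trace(cov), rel=1e-10)

    def test_rotation_invariance_of_bases(self, bases, rng):
        from ucmreach.arm_model import SubspaceBases

        cov = random_psd(rng)
        qn, _ = np.linalg.qr(rng.standard_normal((6, 6)))
        qo, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        remixed = SubspaceBases(
            null_basis=bases.null_basis @ qn, orth_basis=bases.orth_basis @ qo
        )
        a, b = ucm_decompose(cov, bases), ucm_decompose(cov, remixed)
        assert a.gev == pytest.approx(b.gev, rel=1e-10)
        assert a.ngev == pytest.approx(b.ngev, rel=1e-10)

    def test_stabilized_flag_tracks_gev_vs_ngev(self, bases):
        res = ucm_decompose(1e-4 * np.eye(9), bases)
        assert res.stabilized == (res.gev > res.ngev)
        cov = (
            bases.null_basis @ (1e-4 * np.eye(6)) @ bases.null_basis.T
            + bases.orth_basis @ (1e-6 * np.eye(3)) @ bases.orth_basis.T
        )
        assert ucm_decompose(cov, bases).stabilized

    def test_dimension_mismatch_rejected(self, bases):
        with pytest.raises(InvalidInputError):
            ucm_decompose(np.eye(8), bases)


class TestOracleEquivalence:
    def test_trace_formula_equals_explicit_projection(self, geometry, rng):
        for _ in range(100):
            bases = subspace_bases(
                compute_jacobian(random_posture(rng), geometry)
            )
            n_trials = int(rng.integers(5, 51))
            ensemble = random_posture(rng) + 0.02 * rng.standard_normal(
                (n_trials, 9)
            )
            direct = ucm_decompose(joint_covariance(ensemble), bases)
            oracle = ucm_decompose_oracle(ensemble, bases)
            assert direct.gev == pytest.approx(oracle.gev, rel=1e-10)
            assert direct.ngev == pytest.approx(oracle.ngev, rel=1e-10)

    def test_single_direction_hand_computation(self, bases, rng):
        # deviations of magnitude m along one null-basis column, alternating
        # sign so the mean deviation is zero: every trial contributes m^2 to
        # the null-space projection sum, GEV = n m^2 / (n - 1) / 6.
        m = 0.05
        v = bases.null_basis[:, 2]
        n = 10
        signs = np.array([1.0, -1.0] * (n // 2))
        ensemble = np.zeros((n, 9)) + signs[:, None] * m * v[None, :]
        res = ucm_decompose_oracle(ensemble, bases)
        assert res.gev == pytest.approx(n * m**2 / (n - 1) / 6.0, rel=1e-10)
        assert res.ngev == pytest.approx(0.0, abs=1e-20)

    def test_zero_deviations(self, bases):
        ensemble = np.tile(np.linspace(0, 1, 9), (5, 1))
        res = ucm_decompose_oracle(ensemble, bases)
        assert res.gev == 0.0 and res.ngev == 0.0


class TestLogTransform:
    @pytest.mark.parametrize(
        "value,expected", [(1.0, 0.0), (math.e, 1.0), (10.0, math.log(10.0))]
    )
    def test_natural_log(self, value, expected):
        assert log_transform(value) == pytest.approx(expected, abs=1e-12)

    def test_ratio_of_ten(self, bases):
        cov = (
            bases.null_basis @ (1e-3 * np.eye(6)) @ bases.null_basis.T
            + bases.orth_basis @ (1e-4 * np.eye(3)) @ bases.orth_basis.T
        )
        res = ucm_decompose(cov, bases)
        assert res.v_ratio_log == pytest.approx(math.log(10.0), rel=1e-9)

    def test_nonpositive_is_undefined(self):
        assert log_transform(0.0) is None
        assert log_transform(-1.0) is None


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_conservation_property(geometry, seed):
    """d*NGEV + (n-d)*GEV = trace(C) for random PSD covariances/postures."""
    rng = np.random.default_rng(seed)
    bases = subspace_bases(compute_jacobian(random_posture(rng), geometry))
    cov = random_psd(rng, scale=10 ** rng.uniform(-6, -2))
    res = ucm_decompose(cov, bases)
    assert 3 * res.ngev + 6 * res.gev == pytest.approx(np.trace(cov), rel=1e-10)
    assert res.gev >= 0 and res.ngev >= 0
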