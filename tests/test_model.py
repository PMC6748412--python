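"""State-space construction and discretization."""

import math

import numpy as np
import pytest
from scipy.integrate import quad_vec
from scipy.linalg import expm

import ipcsway as ip
from ipcsway.model import SingularSwitchingLine


class TestPhysicalConstants:
    def test_default_inertia_is_point_mass(self):
        c = ip.PhysicalConstants(mass=70.0, com_height=0.9)
        assert c.inertia == pytest.approx(70.0 * 0.9 ** 2)

    @pytest.mark.parametrize("kw", [{"mass": 0.0}, {"com_height": -1.0},
                                    {"gravity": 0.0}, {"inertia": -5.0}])
    def test_rejects_non_positive(self, kw):
        with pytest.raises(ValueError):
            ip.PhysicalConstants(**kw)


class TestAlphaFromA:
    def test_known_values(self):
        # the switching line makes angle pi/2 - a*pi with the x-axis
        assert ip.alpha_from_a(0.25) == pytest.approx(1.0)
        assert ip.alpha_from_a(0.5) == pytest.approx(0.0, abs=1e-12)
        assert ip.alpha_from_a(0.75) == pytest.approx(-1.0)
        assert ip.alpha_from_a(0.62) == pytest.approx(
            math.tan(math.pi / 2 - 0.62 * math.pi))

    def test_monotone_decreasing(self):
        grid = np.linspace(0.05, 0.95, 50)
        vals = [ip.alpha_from_a(a) for a in grid]
        assert all(x > y for x, y in zip(vals, vals[1:]))

    def test_active_fraction_matches_a(self):
        # a is the fraction of the phase plane satisfying the activation
        # side condition (Monte Carlo over directions, r = 0)
        rng = np.random.default_rng(0)
        phi = rng.uniform(0, 2 * np.pi, 200_000)
        p, v = np.cos(phi), np.sin(phi)
        for a in (0.25, 0.5, 0.62, 0.8):
            alpha = ip.alpha_from_a(a)
            frac = np.mean(p * (v - alpha * p) > 0)
            assert frac == pytest.approx(a, abs=0.01)

    @pytest.mark.parametrize("a", [0.0, 1.0])
    def test_singular_endpoints(self, a):
        with pytest.raises(SingularSwitchingLine):
            ip.alpha_from_a(a)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            ip.alpha_from_a(1.5)


def _params(**kw):
    base = dict(K=0.8, B=4.0, P=0.25, D=10.0, a=0.62, r=0.4, tau=0.2,
                sigma_w=0.2, eps=1e-4)
    base.update(kw)
    return ip.IPCParameters(**base)


class TestBuildModel:
    def test_matrix_layout(self, constants):
        m = ip.build_model(_params(), constants)
        c = constants.mgh / constants.inertia
        assert m.A[0, 0] == 0.0 and m.A[0, 1] == 1.0
        assert m.A[1, 0] == pytest.approx(c * 0.2)
        assert m.A[1, 1] == pytest.approx(-4.0 / constants.inertia)
        assert np.all(m.A_tau[0] == 0.0)
        assert m.A_tau[1, 0] == pytest.approx(-c * 0.25)
        assert m.A_tau[1, 1] == pytest.approx(-10.0 / constants.inertia)
        assert np.all(m.H == [[1.0, 0.0]])
        assert m.R[0, 0] == pytest.approx(1e-4)
        # acceleration-level process noise
        assert m.Q[1, 1] == pytest.approx(0.2 ** 2)

    def test_full_passive_cancellation(self, constants):
        m = ip.build_model(_params(K=1.0, B=0.0, P=0.0, D=0.0), constants)
        assert np.allclose(m.A, [[0.0, 1.0], [0.0, 0.0]])

    def test_sde_variant_zeroes_delayed_matrix(self, constants):
        m = ip.build_model(_params(), constants, ip.ModelVariant.SDE)
        assert np.all(m.A_tau == 0.0)

    def test_gravity_residual_scaling(self):
        c = ip.PhysicalConstants(mass=70.0, com_height=0.9)
        m = ip.build_model(_params(K=0.8), c)
        assert m.A[1, 0] == pytest.approx(9.81 * 0.2 / 0.9)

    def test_unit_invariance(self):
        # only ratios like mgh/I and B/I enter the drift, so scaling mass
        # (and hence inertia) leaves A and A_tau unchanged when B, D scale
        c1 = ip.PhysicalConstants(mass=60.0, com_height=1.0)
        c2 = ip.PhysicalConstants(mass=120.0, com_height=1.0)
        m1 = ip.build_model(_params(), c1)
        m2 = ip.build_model(_params(B=8.0, D=20.0), c2)
        assert np.allclose(m1.A, m2.A)
        assert np.allclose(m1.A_tau, m2.A_tau)


class TestDiscretize:
    def test_invalid_dt(self, constants):
        m = ip.build_model(_params(), constants)
        with pytest.raises(ValueError):
            ip.discretize(m, True, 0.0)

    def test_semigroup(self, constants):
        m = ip.build_model(_params(), constants)
        d1 = ip.discretize(m, True, 0.005)
        d2 = ip.discretize(m, True, 0.01)
        assert np.allclose(d1.Ad @ d1.Ad, d2.Ad, atol=1e-13)

    def test_small_dt_limits(self, constants):
        m = ip.build_model(_params(), constants)
        d = ip.discretize(m, True, 1e-9)
        assert np.allclose(d.Ad, np.eye(2), atol=1e-8)
        # Qd ~ Q dt in the small-interval limit
        assert d.Qd[1, 1] == pytest.approx(0.2 ** 2 * 1e-9, rel=1e-6)
        assert abs(d.Qd[0, 0]) < 1e-25

    def test_qd_against_quadrature(self, constants):
        m = ip.build_model(_params(sigma_w=1.7, B=25.0), constants)
        d = ip.discretize(m, True, 0.05)
        ref, _ = quad_vec(
            lambda s: expm(m.A * s) @ m.Q @ expm(m.A * s).T, 0.0, 0.05,
            epsabs=1e-14)
        assert np.allclose(d.Qd, ref, rtol=1e-9, atol=1e-16)

    def test_qd_constant_integrand(self, constants):
        m = ip.build_model(_params(K=1.0, B=0.0, P=0.0, D=0.0,
                                   sigma_w=0.5), constants)
        # A has a nilpotent structure here but Qd at tiny dt ~ Q dt
        d = ip.discretize(m, False, 1e-8)
        assert d.Qd[1, 1] == pytest.approx(m.Q[1, 1] * 1e-8, rel=1e-6)

    def test_inversion_free_matches_explicit_inverse(self, constants):
        m = ip.build_model(_params(K=0.8, B=30.0), constants)
        d = ip.discretize(m, True, 0.01)
        ref = np.linalg.inv(m.A) @ (d.Ad - np.eye(2)) @ m.A_tau
        assert np.allclose(d.Atau_d, ref, atol=1e-10)

    def test_singular_stiffness_is_legal(self, constants):
        # K = 1 makes A singular; the block-exponential construction must
        # still produce a finite delayed input matrix
        m = ip.build_model(_params(K=1.0, B=0.0), constants)
        d = ip.discretize(m, True, 0.01)
        assert np.all(np.isfinite(d.Atau_d))
        assert np.any(d.Atau_d != 0.0)

    def test_inactive_zeroes_delayed_input(self, constants):
        m = ip.build_model(_params(), constants)
        d = ip.discretize(m, False, 0.01)
        assert np.all(d.Atau_d == 0.0)

    def test_qd_symmetric_psd_random_draws(self, constants):
        rng = np.random.default_rng(3)
        for _ in range(20):
            m = ip.build_model(
                _params(K=rng.uniform(0, 1), B=rng.uniform(-100, 100),
                        sigma_w=rng.uniform(0, 3)), constants)
            d = ip.discretize(m, True, rng.uniform(1e-4, 0.1))
            assert np.allclose(d.Qd, d.Qd.T)
            assert np.all(np.linalg.eigvalsh(d.Qd) > -1e-15)

    def test_kernel_matches_scipy_path(self, constants):
        from ipcsway import _kernels
        m = ip.build_model(_params(B=12.0, D=55.0, sigma_w=0.9), constants)
        d = ip.discretize(m, True, 0.01)
        out = _kernels.discretize_scalar(
            m.A[1, 0], m.A[1, 1], m.A_tau[1, 0], m.A_tau[1, 1],
            m.Q[1, 1], 0.01)
        assert np.allclose(out[:4], d.Ad.ravel(), atol=1e-12)
        assert np.allclose(out[4:8], d.Atau_d.ravel(), atol=1e-12)
        assert out[8] == pytest.approx(d.Qd[0, 0], abs=1e-18)
        assert out[10] == pytest.approx(d.Qd[1, 1], abs=1e-14)
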