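"""Delayed switching filter: oracles, reductions, cross-implementation."""

import math

import numpy as np
import pytest
from scipy.linalg import expm

import ipcsway as ip
from ipcsway.kalman import (DelayBuffer, GaussianState, correct,
                            extrapolate_initial, lagged_state, predict)


def _params(**kw):
    base = dict(K=0.8, B=4.0, P=0.25, D=10.0, a=0.62, r=0.4, tau=0.2,
                sigma_w=0.2, eps=1e-4)
    base.update(kw)
    return ip.IPCParameters(**base)


class TestLaggedState:
    def _buffer(self, values):
        buf = DelayBuffer()
        for v in values:
            buf.append(v)
        return buf

    def test_integer_lag(self):
        buf = self._buffer([[i, 0.0] for i in range(6)])
        assert lagged_state(buf, 5, 3.0)[0] == 2.0

    def test_default_interpolation_is_midpoint(self):
        buf = self._buffer([[0.0, 0.0]] * 3 + [[1.0, 0.0], [2.0, 0.0],
                                               [3.0, 0.0]])
        # lam = 2.5 between entries at i-2 (value 1.0) and i-3 (value 0.0)
        assert lagged_state(buf, 5, 2.5)[0] == pytest.approx(0.5)

    def test_compat_mode_extrapolates(self):
        buf = self._buffer([[0.0, 0.0]] * 3 + [[1.0, 0.0], [2.0, 0.0],
                                               [3.0, 0.0]])
        assert lagged_state(buf, 5, 2.5, compat=True)[0] == pytest.approx(1.5)

    def test_zero_lag_returns_entry(self):
        buf = self._buffer([[1.0, 2.0], [3.0, 4.0]])
        assert np.array_equal(lagged_state(buf, 1, 0.0), [3.0, 4.0])

    def test_empty_buffer(self):
        with pytest.raises(IndexError):
            lagged_state(DelayBuffer(), 0, 1.0)


class TestExtrapolateInitial:
    def test_at_the_delay(self):
        nu = ip.TrialNuisance(x0=1.0, xdot0=2.0, xddot0=5.0)
        out = extrapolate_initial(nu, t=0.2, tau=0.2)
        assert np.allclose(out, [1.0, 2.0])

    def test_linear_case(self):
        nu = ip.TrialNuisance(x0=1.0, xdot0=2.0, xddot0=0.0)
        out = extrapolate_initial(nu, t=0.0, tau=0.2)
        assert np.allclose(out, [1.0 - 0.4, 2.0])

    def test_quadratic_no_half_factor(self):
        # the quadratic coefficient multiplies (t - tau)^2 directly
        nu = ip.TrialNuisance(x0=1.0, xdot0=2.0, xddot0=10.0)
        out = extrapolate_initial(nu, t=0.0, tau=0.2)
        assert out[0] == pytest.approx(1.0 - 0.4 + 10.0 * 0.04)
        assert out[1] == pytest.approx(2.0 + 2.0 * 10.0 * (-0.2))


class TestCorrect:
    def test_zero_covariance_keeps_prior(self, constants):
        m = ip.build_model(_params(), constants)
        st = GaussianState([0.3, 0.1], np.zeros((2, 2)))
        post, inc = correct(st, 0.5, m, mu=0.0)
        assert np.allclose(post.mean, st.mean)
        e = 0.5 - 0.3
        assert inc == pytest.approx(math.log(2 * math.pi * 1e-4)
                                    + e * e / 1e-4)

    def test_conjugate_gaussian_oracle(self, constants):
        # scalar observation of the position: posterior must match the
        # closed-form normal-normal update
        m = ip.build_model(_params(eps=0.04), constants)
        st = GaussianState([0.2, 0.0], np.diag([0.25, 1.0]))
        post, _ = correct(st, 1.0, m, mu=0.0)
        prec = 1 / 0.25 + 1 / 0.04
        mean = (0.2 / 0.25 + 1.0 / 0.04) / prec
        assert post.mean[0] == pytest.approx(mean)
        assert post.cov[0, 0] == pytest.approx(1 / prec)

    def test_huge_noise_zero_gain(self, constants):
        m = ip.build_model(_params(eps=1e12), constants)
        st = GaussianState([0.2, 0.1], np.eye(2) * 1e-3)
        post, _ = correct(st, 5.0, m, mu=0.0)
        assert np.allclose(post.mean, st.mean, atol=1e-9)


def _textbook_kf(y, dt, A, Qc, eps, x0, xd0, mu, p0):
    """Independent dense-matrix Kalman filter (no delay, no switching)."""
    F = expm(A * dt)
    VL = np.zeros((4, 4))
    VL[:2, :2] = -A * dt
    VL[:2, 2:] = Qc * dt
    VL[2:, 2:] = A.T * dt
    E = expm(VL)
    Qd = E[2:, 2:].T @ E[:2, 2:]
    H = np.array([[1.0, 0.0]])
    x = np.array([x0, xd0])
    P = np.eye(2) * p0
    m2 = 0.0
    for obs in y:
        S = float((H @ P @ H.T)[0, 0]) + eps
        e = float(obs) - float((H @ x)[0]) - mu
        m2 += math.log(2 * math.pi * S) + e * e / S
        K = (P @ H.T / S).ravel()
        x = x + K * e
        P = P - np.outer(K, H @ P)
        x = F @ x
        P = F @ P @ F.T + Qd
    return m2


class TestSDEReduction:
    def test_matches_textbook_filter(self, constants):
        """With no delayed terms the whole machinery is a plain Kalman
        filter; agreement to 1e-8 on a 500-point series."""
        p = _params(K=1.2, B=30.0, P=0.0, D=0.0, sigma_w=3.0, eps=2e-4)
        traj = ip.simulate(p, constants, duration=5.0, fine_dt=1e-4, seed=3)
        series = ip.observe(ip.downsample(traj, 100.0), p.eps, mu=0.1,
                            seed=4)
        nu = ip.TrialNuisance(x0=0.0, xdot0=0.0, mu=0.1)
        got = ip.minus2_loglik(series, p, nu, constants,
                               ip.ModelVariant.SDE, p0=1e4)
        m = ip.build_model(p, constants, ip.ModelVariant.SDE)
        ref = _textbook_kf(series.values, series.dt, m.A, m.Q, p.eps,
                           0.0, 0.0, 0.1, 1e4)
        assert got == pytest.approx(ref, abs=1e-8)


class TestPythonKernelAgreement:
    def test_stepwise_ops_reproduce_kernel_likelihood(self, constants):
        """The slow path assembled from predict/correct/lagged_state/
        extrapolate_initial reproduces the numba likelihood exactly."""
        p = _params()
        traj = ip.simulate(p, constants, duration=3.0, fine_dt=1e-4,
                           x0=1.0, noiseless=True)
        series = ip.downsample(traj, 100.0)
        nu = ip.TrialNuisance(x0=1.0, xdot0=0.0, xddot0=0.0, mu=0.0)
        p0 = 1e6
        m = ip.build_model(p, constants, ip.ModelVariant.ISDDE)
        lam = p.tau / series.dt
        buf = DelayBuffer()
        state = GaussianState([nu.x0, nu.xdot0], np.eye(2) * p0)
        m2 = 0.0

        def lag_at(j):
            t = j * series.dt
            if t <= p.tau + 1e-12:
                return extrapolate_initial(nu, t, p.tau)
            # the buffer clamps lookups beyond its newest entry
            return lagged_state(buf, j, lam)

        n = len(series)
        for i in range(n):
            state, inc = correct(state, series.values[i], m, nu.mu)
            m2 += inc
            buf.append(state.mean)
            if i == n - 1:
                break
            u = lag_at(i)
            v = lag_at(i + 1)
            state = predict(state, u, v, m, series.dt)
        got = ip.minus2_loglik(series, p, nu, constants,
                               ip.ModelVariant.ISDDE, p0=p0)
        assert got == pytest.approx(m2, rel=1e-10)


class TestMinus2Loglik:
    def test_noiseless_truth_has_tiny_innovations(self, asai, constants,
                                                  noiseless_asai_100hz):
        res = ip.filter_series(noiseless_asai_100hz,
                               asai.replace(sigma_w=0.06, eps=1e-10),
                               ip.TrialNuisance(x0=1.0), constants)
        assert not res.diverged
        assert np.abs(res.innovations[3:]).max() < 1e-4
        assert res.n_traversals > 0

    def test_divergent_parameters_penalized(self, constants,
                                            noiseless_asai_100hz):
        bad = _params(K=0.0, B=-900.0, P=0.0, D=0.0, sigma_w=0.0, eps=0.0)
        val = ip.minus2_loglik(noiseless_asai_100hz, bad,
                               ip.TrialNuisance(x0=1.0), constants)
        assert val >= ip.DIVERGED

    def test_truth_beats_perturbations(self, asai, constants):
        """The objective ranks the data-generating parameters above
        random structural perturbations in nearly all draws."""
        rng = np.random.default_rng(17)
        wins = 0
        n_draws = 60
        traj = ip.simulate(asai, constants, duration=10.0, fine_dt=1e-4,
                           seed=rng)
        series = ip.observe(ip.downsample(traj, 100.0), asai.eps, 0.0,
                            seed=rng)
        nu = ip.TrialNuisance()
        base = ip.minus2_loglik(series, asai, nu, constants)
        for _ in range(n_draws):
            pert = asai.replace(
                K=min(max(asai.K * rng.uniform(0.7, 1.3), 0.0), 1.0),
                P=asai.P * rng.uniform(0.5, 1.5),
                a=min(max(asai.a + rng.uniform(-0.1, 0.1), 0.01), 0.99),
                r=asai.r * rng.uniform(0.5, 1.5),
                tau=min(max(asai.tau + rng.uniform(-0.04, 0.04), 0.15),
                        0.25))
            wins += base < ip.minus2_loglik(series, pert, nu, constants)
        assert wins >= 0.95 * n_draws

    def test_multi_trial_additivity(self, asai, constants, noisy_trials):
        nus = [ip.TrialNuisance() for _ in noisy_trials]
        total = ip.multi_trial_minus2ll(list(zip(noisy_trials, nus)), asai,
                                        constants)
        parts = sum(ip.minus2_loglik(t, asai, nu, constants)
                    for t, nu in zip(noisy_trials, nus))
        assert total == pytest.approx(parts, rel=1e-12)
        one = ip.multi_trial_minus2ll([(noisy_trials[0], nus[0])], asai,
                                      constants)
        assert one == pytest.approx(
            ip.minus2_loglik(noisy_trials[0], asai, nus[0], constants))

    def test_duplicated_trial_doubles(self, asai, constants, noisy_trials):
        pair = [(noisy_trials[0], ip.TrialNuisance())] * 2
        assert ip.multi_trial_minus2ll(pair, asai, constants) == \
            pytest.approx(2 * ip.multi_trial_minus2ll(pair[:1], asai,
                                                      constants))

    def test_mismatched_rates_rejected(self, asai, constants, noisy_trials):
        other = ip.Trajectory(values=noisy_trials[0].values[:100], dt=0.02)
        with pytest.raises(ValueError):
            ip.multi_trial_minus2ll(
                [(noisy_trials[0], ip.TrialNuisance()),
                 (other, ip.TrialNuisance())], asai, constants)

    def test_empty_trials_rejected(self, asai, constants):
        with pytest.raises(ValueError):
            ip.multi_trial_minus2ll([], asai, constants)
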