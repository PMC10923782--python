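"""Baseline predictors: linear regression and ODE + hybrid Kalman filter."""

import numpy as np
import pytest
import scipy.linalg

from optoctrl.baselines import (KalmanBelief, LinearForecaster,
                                OdeKalmanForecaster, OdeParams, kalman_step,
                                ode_predict)
from optoctrl.datastore import ForecastSample, random_walk_stimulation


def _samples_from_linear_map(rng, n, P, H, noise=0.0):
    """Samples whose future is an exact linear map of (past, stims)."""
    W = rng.normal(0, 0.1, (8 * P + H, H))
    b = rng.normal(0, 0.1, H)
    samples = []
    for _ in range(n):
        past = rng.random((8, P))
        stims = rng.integers(0, 2, H).astype(float)
        x = np.concatenate([past.ravel(), stims])
        y = x @ W + b + noise * rng.standard_normal(H)
        samples.append(ForecastSample(past=past, future_stims=stims,
                                      future_fluo=y))
    return samples, W, b


class TestLinearForecaster:
    def test_exact_recovery_of_linear_map(self):
        rng = np.random.default_rng(0)
        samples, W, b = _samples_from_linear_map(rng, 600, 36, 12)
        model = LinearForecaster(horizon=12, p_fix=36, alpha=0.0).fit(samples)
        np.testing.assert_allclose(model.coef_, W, rtol=1e-6, atol=1e-8)
        np.testing.assert_allclose(model.intercept_, b, rtol=1e-6, atol=1e-8)

    def test_all_zero_inputs_predict_bias(self):
        rng = np.random.default_rng(1)
        samples, _, _ = _samples_from_linear_map(rng, 400, 36, 12)
        model = LinearForecaster(horizon=12).fit(samples)
        zero = ForecastSample(past=np.zeros((8, 36)),
                              future_stims=np.zeros(12),
                              future_fluo=np.zeros(12))
        np.testing.assert_allclose(model.predict_samples([zero])[0],
                                   model.intercept_, atol=1e-9)

    def test_longer_pasts_truncated_to_window(self):
        rng = np.random.default_rng(2)
        samples, _, _ = _samples_from_linear_map(rng, 200, 36, 12)
        model = LinearForecaster(horizon=12).fit(samples)
        s = samples[0]
        padded = ForecastSample(
            past=np.concatenate([rng.random((8, 20)), s.past], axis=1),
            future_stims=s.future_stims, future_fluo=s.future_fluo)
        np.testing.assert_allclose(model.predict_samples([padded])[0],
                                   model.predict_samples([s])[0], atol=1e-9)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            LinearForecaster().fit([])


PARAMS = OdeParams(k_a=0.2, k_d=0.2, beta=0.02, gamma=0.03,
                   q_a=1e-4, q_p=1e-4, r=1e-3)


class TestOdePredict:
    def test_steady_state_under_constant_green(self):
        belief = KalmanBelief(mean=[0.0, 0.0], cov=np.zeros((2, 2)))
        horizon = int(10.0 / min(PARAMS.k_d, PARAMS.gamma) / 5.0) + 20
        pred = ode_predict(belief, PARAMS, np.ones(horizon))
        p_ss = PARAMS.beta * PARAMS.k_a / (PARAMS.gamma * PARAMS.k_d)
        assert pred[-1] == pytest.approx(p_ss, rel=0.01)

    def test_exponential_decay_under_red(self):
        p0 = 0.8
        belief = KalmanBelief(mean=[0.0, p0], cov=np.zeros((2, 2)))
        pred = ode_predict(belief, PARAMS, np.zeros(24))
        t = 5.0 * np.arange(1, 25)
        np.testing.assert_allclose(pred, p0 * np.exp(-PARAMS.gamma * t),
                                   rtol=1e-6)

    def test_zero_length_horizon(self):
        belief = KalmanBelief(mean=[0.0, 0.5], cov=np.zeros((2, 2)))
        assert ode_predict(belief, PARAMS, np.zeros(0)).size == 0

    def test_negative_params_rejected(self):
        with pytest.raises(ValueError):
            OdeParams(k_a=-1.0, k_d=0.1, beta=0.01, gamma=0.01)


def _textbook_discrete_kf(m, P, Phi, drift, Qd, r, y):
    """Independent reference: standard discrete-time Kalman filter cycle."""
    m = Phi @ m + drift
    P = Phi @ P @ Phi.T + Qd
    H = np.array([[0.0, 1.0]])
    S = (H @ P @ H.T)[0, 0] + r
    K = (P @ H.T)[:, 0] / S
    m = m + K * (y - m[1])
    P = (np.eye(2) - np.outer(K, H[0])) @ P
    return m, P


def _vanloan_reference(params, u, dt=5.0):
    """Matched discretization computed independently (matrix exponential)."""
    A = np.array([[-params.k_d, 0.0], [params.beta, -params.gamma]])
    b = np.array([params.k_a * u, 0.0])
    M = np.zeros((3, 3))
    M[:2, :2], M[:2, 2] = A, b
    E = scipy.linalg.expm(M * dt)
    Q = np.diag([params.q_a, params.q_p])
    V = np.block([[-A, Q], [np.zeros((2, 2)), A.T]])
    Ev = scipy.linalg.expm(V * dt)
    return E[:2, :2], E[:2, 2], Ev[2:, 2:].T @ Ev[:2, 2:]


class TestKalmanStep:
    def test_uninformative_measurement_keeps_prior(self):
        params = OdeParams(k_a=0.2, k_d=0.2, beta=0.02, gamma=0.03,
                           q_a=1e-4, q_p=1e-4, r=1e12)
        belief = KalmanBelief(mean=[0.2, 0.4], cov=np.eye(2) * 0.01)
        Phi, drift, Qd = _vanloan_reference(params, 1.0)
        prior_mean = Phi @ belief.mean + drift
        post = kalman_step(belief, params, 1, 0.9)
        np.testing.assert_allclose(post.mean, prior_mean, atol=1e-9)

    def test_missing_measurement_skips_update(self):
        belief = KalmanBelief(mean=[0.2, 0.4], cov=np.eye(2) * 0.01)
        a = kalman_step(belief, PARAMS, 1, None)
        b = kalman_step(belief, PARAMS, 1, float("nan"))
        np.testing.assert_allclose(a.mean, b.mean)

    def test_noise_free_filter_tracks_exact_plant(self):
        # q -> 0, exact init: the posterior mean follows the true trajectory
        params = OdeParams(k_a=0.2, k_d=0.2, beta=0.02, gamma=0.03,
                           q_a=0.0, q_p=0.0, r=1e-3)
        truth = KalmanBelief(mean=[0.0, 0.3], cov=np.zeros((2, 2)))
        belief = KalmanBelief(mean=[0.0, 0.3], cov=np.zeros((2, 2)))
        stims = random_walk_stimulation(100, rng_seed=0)
        state = truth.mean.copy()
        for u in stims:
            Phi, drift, _ = _vanloan_reference(params, float(u))
            state = Phi @ state + drift
            belief = kalman_step(belief, params, int(u), state[1])
            np.testing.assert_allclose(belief.mean, state, atol=1e-8)

    def test_matches_textbook_discrete_filter(self):
        # 100 random steps: hybrid filter == discrete KF on the matched system
        rng = np.random.default_rng(0)
        belief = KalmanBelief(mean=[0.1, 0.2], cov=np.eye(2) * 0.05)
        m_ref, P_ref = belief.mean.copy(), belief.cov.copy()
        mats = {u: _vanloan_reference(PARAMS, u) for u in (0.0, 1.0)}
        for _ in range(100):
            u = int(rng.integers(0, 2))
            y = float(rng.random())
            belief = kalman_step(belief, PARAMS, u, y)
            Phi, drift, Qd = mats[float(u)]
            m_ref, P_ref = _textbook_discrete_kf(m_ref, P_ref, Phi, drift,
                                                 Qd, PARAMS.r, y)
            np.testing.assert_allclose(belief.mean, m_ref, atol=1e-8)
            np.testing.assert_allclose(belief.cov, P_ref, atol=1e-8)

    def test_covariance_propagation_matches_ode_integration(self):
        # independent oracle: numerically integrate dP/dt = AP + PA' + Q
        from scipy.integrate import solve_ivp
        P0 = np.array([[0.04, 0.01], [0.01, 0.09]])
        A = np.array([[-PARAMS.k_d, 0.0], [PARAMS.beta, -PARAMS.gamma]])
        Q = np.diag([PARAMS.q_a, PARAMS.q_p])

        def rhs(_, y):
            P = y.reshape(2, 2)
            return (A @ P + P @ A.T + Q).ravel()

        sol = solve_ivp(rhs, (0.0, 5.0), P0.ravel(), rtol=1e-11, atol=1e-13)
        params_noupdate = OdeParams(k_a=PARAMS.k_a, k_d=PARAMS.k_d,
                                    beta=PARAMS.beta, gamma=PARAMS.gamma,
                                    q_a=PARAMS.q_a, q_p=PARAMS.q_p, r=1e12)
        out = kalman_step(KalmanBelief(mean=[0.0, 0.0], cov=P0),
                          params_noupdate, 1, None)
        np.testing.assert_allclose(out.cov, sol.y[:, -1].reshape(2, 2),
                                   atol=1e-8)

    def test_covariance_stays_symmetric_psd_long_run(self):
        rng = np.random.default_rng(1)
        belief = KalmanBelief(mean=[0.0, 0.1], cov=np.eye(2) * 0.01)
        for _ in range(10_000):
            u = int(rng.integers(0, 2))
            y = float(rng.random())
            belief = kalman_step(belief, PARAMS, u, y)
            assert np.allclose(belief.cov, belief.cov.T, atol=1e-12)
            assert np.linalg.eigvalsh(belief.cov).min() >= -1e-12


class TestFitOde:
    def _ode_corpus(self, params, n_cells=20, T=192, seed=0):
        rng = np.random.default_rng(seed)
        corpus = []
        for _ in range(n_cells):
            u = random_walk_stimulation(T, rng)
            belief = KalmanBelief(mean=[0.0, 0.0], cov=np.zeros((2, 2)))
            p = ode_predict(belief, params, u) + params.offset
            arr = np.zeros((8, T))
            arr[0] = u
            arr[1] = np.concatenate([[params.offset], p[:-1]])
            corpus.append(arr)
        return corpus

    def test_self_consistency_recovery(self):
        true = OdeParams(k_a=0.2, k_d=0.2, beta=0.02, gamma=0.03, offset=0.05)
        corpus = self._ode_corpus(true)
        fit = OdeKalmanForecaster(horizon=12, n_fit_cells=20).fit(corpus)
        assert fit.params_.k_d == pytest.approx(true.k_d, rel=0.05)
        assert fit.params_.beta == pytest.approx(true.beta, rel=0.05)
        assert fit.params_.gamma == pytest.approx(true.gamma, rel=0.05)
        assert fit.params_.offset == pytest.approx(true.offset, abs=0.01)

    def test_gamma_matches_off_step_decay(self):
        true = OdeParams(k_a=0.2, k_d=0.2, beta=0.02, gamma=0.03)
        corpus = self._ode_corpus(true, seed=3)
        fit = OdeKalmanForecaster(horizon=12, n_fit_cells=20).fit(corpus)
        # independent estimate: exponential decay rate of an off step
        belief = KalmanBelief(mean=[0.0, 0.5], cov=np.zeros((2, 2)))
        decay = ode_predict(belief, true, np.zeros(12))
        observed = -np.log(decay[1] / decay[0]) / 5.0
        assert fit.params_.gamma == pytest.approx(observed, rel=0.05)

    def test_single_population_parameter_set(self, ode_model):
        assert isinstance(ode_model.params_, OdeParams)
        assert ode_model.params_.k_d > 0 and ode_model.params_.gamma > 0


def test_persistence_predicts_last_observed(persistence_model):
    past = np.zeros((8, 40))
    past[1, -1] = 0.42
    sample = ForecastSample(past=past, future_stims=np.zeros(12),
                            future_fluo=np.zeros(12))
    np.testing.assert_allclose(
        persistence_model.predict_samples([sample])[0], 0.42)
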