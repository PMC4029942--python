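"""Unit and property tests for the filter core and matrix builders."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vitalkf import kalman
from vitalkf.kalman import (
    FilterState,
    Measurement,
    ModelMatrices,
    SingularInnovationError,
    build_measurement_matrix,
    build_measurement_noise,
    build_process_noise,
    build_transition,
    predict,
    step,
    update,
)

DT = 1.0 / 95.0


def naive_kalman_step(x, P, A, Q, H, R, z):
    """Dense-algebra reference: explicit inverse, no factorizations."""
    xp = A @ x
    Pp = A @ P @ A.T + Q
    S = H @ Pp @ H.T + R
    K = Pp @ H.T @ np.linalg.inv(S)
    xn = xp + K @ (z - H @ xp)
    Pn = (np.eye(x.size) - K @ H) @ Pp
    return xn, Pn, K


def random_instance(rng):
    x = rng.normal(size=7)
    M = rng.normal(size=(7, 7))
    P = M @ M.T + np.eye(7)
    A = build_transition(rng.uniform(0, 12), rng.uniform(0, 4), DT)
    Q = build_process_noise(
        rng.uniform(0, 12), rng.uniform(0, 4), rng.uniform(0.1, 5, 3)
    )
    H = build_measurement_matrix(rng.uniform(0, 10, 3), rng.uniform(0, 10, 3))
    R = build_measurement_noise(rng.uniform(0.5, 5, 3))
    z = rng.normal(size=3)
    return x, P, A, Q, H, R, z


class TestBuilders:
    def test_transition_zero_frequencies_are_pure_integrators(self):
        A = build_transition(0.0, 0.0, DT)
        for i in (0, 2):
            assert np.allclose(A[i : i + 2, i : i + 2], [[1, DT], [0, 1]])
        assert np.allclose(A[4:, 4:], np.eye(3))

    def test_transition_subject1_entries(self):
        omega_f, omega_s = 2 * np.pi * 1.3, 2 * np.pi * 0.3
        A = build_transition(omega_f, omega_s, DT)
        assert A[1, 0] == pytest.approx(-(omega_f**2) * DT)
        assert A[0, 1] == pytest.approx(DT)
        assert A[3, 2] == pytest.approx(-(omega_s**2) * DT)
        # off-block entries all zero
        mask = np.zeros((7, 7), dtype=bool)
        mask[:2, :2] = mask[2:4, 2:4] = mask[4:, 4:] = True
        assert np.all(A[~mask] == 0)

    @given(omega=st.floats(0, 20), dt=st.floats(1e-4, 0.1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_oscillator_block_determinant(self, omega, dt):
        A = build_transition(omega, 0.0, dt)
        det = np.linalg.det(A[:2, :2])
        assert det == pytest.approx(1 + omega**2 * dt**2, rel=1e-9)

    def test_transition_rejects_bad_dt(self):
        with pytest.raises(ValueError):
            build_transition(1.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            build_transition(1.0, 1.0, np.nan)
        with pytest.raises(ValueError):
            build_transition(-1.0, 1.0, DT)

    def test_process_noise_diagonal_structure(self):
        omega_f, omega_s = 2 * np.pi * 1.3, 2 * np.pi * 0.3
        Q = build_process_noise(omega_f, omega_s, (989.0, 159.2, 1057.7))
        expected = np.diag(
            [1, omega_f**2, 1, omega_s**2, 989.0**2, 159.2**2, 1057.7**2]
        )
        assert np.allclose(Q, expected)
        assert np.allclose(
            build_process_noise(0, 0, (0, 0, 0)), np.diag([1, 0, 1, 0, 0, 0, 0])
        )

    def test_process_noise_frequency_scaling(self):
        base = build_process_noise(3.0, 1.0, (1, 1, 1))
        doubled = build_process_noise(6.0, 1.0, (1, 1, 1))
        assert doubled[1, 1] == pytest.approx(4 * base[1, 1])
        doubled[1, 1] = base[1, 1]
        assert np.allclose(doubled, base)

    def test_measurement_noise(self):
        assert np.allclose(build_measurement_noise((1, 1, 1)), np.eye(3))
        R = build_measurement_noise((53.6, 11.2, 64.2))
        assert np.allclose(np.diag(R), [53.6**2, 11.2**2, 64.2**2])
        with pytest.raises(ValueError):
            build_measurement_noise((-1, 1, 1))

    def test_measurement_matrix_structure(self):
        H = build_measurement_matrix((1, 1, 1), (1, 1, 1))
        assert np.allclose(H[:, 4:], np.eye(3))
        H = build_measurement_matrix((5, 6, 7), (8, 9, 10))
        # velocity states unobserved; offset block fixed to identity
        assert np.all(H[:, 1] == 0) and np.all(H[:, 3] == 0)
        assert np.allclose(H[:, 0], [5, 6, 7])
        assert np.allclose(H[:, 2], [8, 9, 10])
        assert np.allclose(H[:, 4:], np.eye(3))


class TestPredictUpdate:
    def test_identity_predict_is_noop(self):
        state = FilterState(np.arange(7.0), np.eye(7), k=0, dt=DT)
        out = predict(state, np.eye(7), np.zeros((7, 7)))
        assert np.allclose(out.x_hat, state.x_hat)
        assert np.allclose(out.P, state.P)

    def test_predict_velocity_coupling(self):
        omega_f = 2 * np.pi * 1.3
        A = build_transition(omega_f, 0.0, DT)
        state = FilterState(np.eye(7)[0], np.zeros((7, 7)), k=0, dt=DT)
        out = predict(state, A, np.zeros((7, 7)))
        expected = np.zeros(7)
        expected[0], expected[1] = 1.0, -(omega_f**2) * DT
        assert np.allclose(out.x_hat, expected)

    def test_predict_zero_state_covariance_becomes_q(self):
        state = FilterState(np.zeros(7), np.zeros((7, 7)), k=0, dt=DT)
        out = predict(state, np.eye(7), 2.5 * np.eye(7))
        assert np.allclose(out.P, 2.5 * np.eye(7))

    def test_zero_innovation_leaves_state_unchanged(self):
        rng = np.random.default_rng(0)
        x, P, A, Q, H, R, _ = random_instance(rng)
        state = FilterState(x, P, k=0, dt=DT)
        out, K = update(state, H @ x, H, R)
        assert np.allclose(out.x_hat, x)
        assert np.allclose(out.P, (np.eye(7) - K @ H) @ P)

    def test_scalar_reduction_gain_half(self):
        # 1-state/1-sensor textbook case P=1, H=1, R=1 -> K = 0.5,
        # embedded in the 7-state filter via an isolated offset channel
        P = np.zeros((7, 7))
        P[4, 4] = 1.0
        state = FilterState(np.zeros(7), P, k=0, dt=DT)
        H = build_measurement_matrix((0, 0, 0), (0, 0, 0))
        R = np.eye(3)
        out, K = update(state, np.array([1.0, 0, 0]), H, R)
        assert K[4, 0] == pytest.approx(0.5)
        assert out.x_hat[4] == pytest.approx(0.5)

    def test_zero_measurement_noise_trusts_measurement(self):
        rng = np.random.default_rng(1)
        x, P, A, Q, H, _, z = random_instance(rng)
        state = FilterState(x, P, k=0, dt=DT)
        out, _ = update(state, z, H, np.zeros((3, 3)))
        assert np.allclose(H @ out.x_hat, z, atol=1e-8)

    def test_matches_naive_dense_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            x, P, A, Q, H, R, z = random_instance(rng)
            state = FilterState(x, P, k=0, dt=DT)
            out = step(state, z, ModelMatrices(A=A, Q=Q, R=R, H=H))
            x_ref, P_ref, _ = naive_kalman_step(x, P, A, Q, H, R, z)
            assert np.allclose(out.x_hat, x_ref, rtol=1e-10, atol=1e-12)
            assert np.allclose(out.P, 0.5 * (P_ref + P_ref.T), rtol=1e-10, atol=1e-12)

    def test_covariance_symmetric_psd_after_steps(self):
        rng = np.random.default_rng(3)
        x, P, A, Q, H, R, _ = random_instance(rng)
        state = FilterState(x, P, k=0, dt=DT)
        mats = ModelMatrices(A=A, Q=Q, R=R, H=H)
        for _ in range(200):
            state = step(state, rng.normal(size=3), mats)
        assert np.allclose(state.P, state.P.T, rtol=1e-9)
        eigs = np.linalg.eigvalsh(state.P)
        assert eigs.min() >= -1e-9 * np.trace(state.P)

    def test_huge_measurement_noise_freezes_estimate(self):
        # Q = 0, R enormous: the gain collapses and measurements are ignored
        rng = np.random.default_rng(4)
        x, P, A, Q, H, _, z = random_instance(rng)
        state = FilterState(x, P, k=0, dt=DT)
        R = 1e14 * np.eye(3)
        out, K = update(state, z, H, R)
        assert np.abs(K).max() < 1e-6
        assert np.allclose(out.x_hat, x, atol=1e-4)

    def test_singular_innovation_raises_with_diagnostic(self):
        state = FilterState(np.zeros(7), np.zeros((7, 7)), k=0, dt=DT)
        H = build_measurement_matrix((0, 0, 0), (0, 0, 0))
        with pytest.raises(SingularInnovationError) as exc:
            update(state, np.zeros(3), H, np.zeros((3, 3)))
        assert exc.value.smallest_sv == 0.0

    def test_step_increments_index_and_composes(self):
        rng = np.random.default_rng(5)
        x, P, A, Q, H, R, _ = random_instance(rng)
        mats = ModelMatrices(A=A, Q=Q, R=R, H=H)
        z1, z2 = rng.normal(size=3), rng.normal(size=3)
        s0 = FilterState(x, P, k=0, dt=DT)
        s2 = step(step(s0, z1, mats), z2, mats)
        assert s2.k == 2
        # manual composition of predict + update twice
        ref = s0
        for z in (z1, z2):
            ref = predict(ref, A, Q)
            ref, _ = update(ref, z, H, R)
        assert np.allclose(s2.x_hat, ref.x_hat)
        assert np.allclose(s2.P, ref.P)

    def test_offsets_converge_to_constant_measurement(self):
        # offsets-only observation with a constant measurement: the offset
        # states must converge to the measured values (steady-state filter)
        z = np.array([3.0, -2.0, 5.0])
        H = build_measurement_matrix((0, 0, 0), (0, 0, 0))
        Q = build_process_noise(0, 0, (0.5, 0.5, 0.5))
        R = build_measurement_noise((1, 1, 1))
        mats = ModelMatrices(A=np.eye(7), Q=Q, R=R, H=H)
        state = FilterState(np.zeros(7), 10 * np.eye(7), k=0, dt=DT)
        for _ in range(300):
            state = step(state, z, mats)
        assert np.allclose(state.x_hat[4:], z, atol=1e-6)

    def test_measurement_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            Measurement(z=np.array([1.0, np.nan, 0.0]), t=0.0)
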