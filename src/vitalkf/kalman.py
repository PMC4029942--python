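"""Time-varying Kalman filter core for cardiorespiratory signal separation.

The hidden state holds two damped-free harmonic oscillators and three
random-walk offsets:

    x = (X_f, V_f, X_s, V_s, C1, C2, C3)

where (X_f, V_f) track the fast cardiac oscillation at angular frequency
``omega_f``, (X_s, V_s) track the slow respiratory oscillation at
``omega_s``, and C1..C3 are the per-sensor baseline offsets.  The three
sensor channels observe weighted sums of X_f, X_s and their own offset.

Everything in this module is agnostic to *how* the model parameters are
obtained: constructors take plain frequencies and standard deviations, so
the same recursion serves both the adaptive filter (parameters re-estimated
online) and the non-adaptive baseline (parameters frozen at initialization).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "N_STATES",
    "N_SENSORS",
    "FilterState",
    "ModelMatrices",
    "Measurement",
    "build_transition",
    "build_process_noise",
    "build_measurement_noise",
    "build_measurement_matrix",
    "predict",
    "update",
    "step",
]

N_STATES = 7
N_SENSORS = 3

#: relative condition-number threshold above which the innovation
#: covariance is declared numerically singular; the respiration
#: measurement gain is the squared respiration std and routinely reaches
#: 1e7-1e8 in sensor amplitude units, so condition numbers of 1e11-1e14
#: are normal operation here and the guard only catches genuine rank
#: deficiency near the double-precision limit
_COND_LIMIT = 1e15


class SingularInnovationError(np.linalg.LinAlgError):
    """Innovation covariance is numerically singular.

    Carries the smallest singular value for diagnostics.
    """

    def __init__(self, smallest_sv: float):
        self.smallest_sv = smallest_sv
        super().__init__(
            f"innovation covariance numerically singular "
            f"(smallest singular value {smallest_sv:.3e})"
        )


@dataclass
class FilterState:
    """State estimate, its error covariance and the discrete time index."""

    x_hat: np.ndarray  # (7,) state estimate, sensor amplitude units
    P: np.ndarray      # (7, 7) estimation-error covariance
    k: int             # sample index, non-negative
    dt: float          # sampling interval [s], constant over a run

    def __post_init__(self) -> None:
        self.x_hat = np.asarray(self.x_hat, dtype=float).reshape(N_STATES)
        self.P = np.asarray(self.P, dtype=float).reshape(N_STATES, N_STATES)
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.k < 0:
            raise ValueError(f"sample index must be non-negative, got {self.k}")


@dataclass
class ModelMatrices:
    """The model matrices consumed by one filter step.

    ``K`` holds the Kalman gain of the most recent correction; it is
    overwritten by :func:`update` and is ``None`` before the first step.
    """

    A: np.ndarray             # (7, 7) state transition
    Q: np.ndarray             # (7, 7) process-noise covariance
    R: np.ndarray             # (3, 3) measurement-noise covariance
    H: np.ndarray             # (3, 7) measurement matrix
    K: np.ndarray | None = field(default=None)  # (7, 3) last Kalman gain


@dataclass
class Measurement:
    """One raw 3-sensor sample at time ``t`` seconds."""

    z: np.ndarray
    t: float

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float).reshape(N_SENSORS)
        if not np.all(np.isfinite(self.z)):
            raise ValueError(f"non-finite measurement at t={self.t}: {self.z}")


def _check_rate(name: str, value: float) -> float:
    value = float(value)
    if not np.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be finite and non-negative, got {value}")
    return value


def build_transition(omega_f: float, omega_s: float, dt: float) -> np.ndarray:
    """Assemble the 7x7 state-transition matrix.

    Each oscillator occupies a 2x2 block ``[[1, dt], [-omega^2*dt, 1]]``
    (forward-Euler discretisation of a harmonic oscillator); the offset
    block is the identity, i.e. offsets evolve as random walks.

    Parameters
    ----------
    omega_f, omega_s
        Cardiac and respiratory angular frequencies [rad/s], >= 0.
    dt
        Sampling interval [s], > 0.
    """
    omega_f = _check_rate("omega_f", omega_f)
    omega_s = _check_rate("omega_s", omega_s)
    dt = float(dt)
    if not np.isfinite(dt) or dt <= 0:
        raise ValueError(f"dt must be finite and positive, got {dt}")
    A = np.eye(N_STATES)
    A[0, 1] = dt
    A[1, 0] = -(omega_f**2) * dt
    A[2, 3] = dt
    A[3, 2] = -(omega_s**2) * dt
    return A


def build_process_noise(
    omega_f: float, omega_s: float, sigma_trend: np.ndarray
) -> np.ndarray:
    """Assemble the diagonal 7x7 process-noise covariance.

    Diagonal: ``(1, omega_f^2, 1, omega_s^2, s1^2, s2^2, s3^2)`` with
    ``s_i`` the per-sensor trend standard deviations.  The velocity-state
    entries scale with the squared angular frequency because a faster
    oscillation produces proportionally larger derivative amplitudes; the
    position entries carry unit weight.
    """
    omega_f = _check_rate("omega_f", omega_f)
    omega_s = _check_rate("omega_s", omega_s)
    sigma_trend = np.asarray(sigma_trend, dtype=float).reshape(N_SENSORS)
    if np.any(sigma_trend < 0) or not np.all(np.isfinite(sigma_trend)):
        raise ValueError(f"sigma_trend must be non-negative, got {sigma_trend}")
    return np.diag(
        np.concatenate(([1.0, omega_f**2, 1.0, omega_s**2], sigma_trend**2))
    )


def build_measurement_noise(sigma_noise: np.ndarray) -> np.ndarray:
    """Diagonal 3x3 measurement-noise covariance from per-sensor noise std."""
    sigma_noise = np.asarray(sigma_noise, dtype=float).reshape(N_SENSORS)
    if np.any(sigma_noise < 0) or not np.all(np.isfinite(sigma_noise)):
        raise ValueError(f"sigma_noise must be non-negative, got {sigma_noise}")
    return np.diag(sigma_noise**2)


def build_measurement_matrix(h_f: np.ndarray, h_s: np.ndarray) -> np.ndarray:
    """Assemble the 3x7 measurement matrix.

    Row i reads ``(h_f[i], 0, h_s[i], 0, e_i)``: sensor i sees the cardiac
    position state with gain ``h_f[i]``, the respiratory position state with
    gain ``h_s[i]``, and exactly its own offset (the offset block is the
    3x3 identity and is never adapted).  Velocity states are unobserved.
    """
    h_f = np.asarray(h_f, dtype=float).reshape(N_SENSORS)
    h_s = np.asarray(h_s, dtype=float).reshape(N_SENSORS)
    for name, h in (("h_f", h_f), ("h_s", h_s)):
        if np.any(h < 0) or not np.all(np.isfinite(h)):
            raise ValueError(f"{name} must be finite and non-negative, got {h}")
    H = np.zeros((N_SENSORS, N_STATES))
    H[:, 0] = h_f
    H[:, 2] = h_s
    H[:, 4:] = np.eye(N_SENSORS)
    return H


def _symmetrize(P: np.ndarray) -> np.ndarray:
    # guards against drift of the covariance away from symmetry over
    # ~15,000 steps per run
    return 0.5 * (P + P.T)


def predict(state: FilterState, A: np.ndarray, Q: np.ndarray) -> FilterState:
    """Time update: propagate state and covariance one step forward.

    ``x- = A x``, ``P- = A P A^T + Q``.  Does not advance ``k``; use
    :func:`step` for the full predict/update cycle.
    """
    A = np.asarray(A, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if A.shape != (N_STATES, N_STATES) or Q.shape != (N_STATES, N_STATES):
        raise ValueError(f"expected 7x7 A and Q, got {A.shape} and {Q.shape}")
    x_pred = A @ state.x_hat
    P_pred = _symmetrize(A @ state.P @ A.T + Q)
    return replace(state, x_hat=x_pred, P=P_pred)


def update(
    state: FilterState, z: Measurement | np.ndarray, H: np.ndarray, R: np.ndarray
) -> tuple[FilterState, np.ndarray]:
    """Measurement update: blend the prediction with a new sample.

    Computes the Kalman gain ``K = P- H^T (H P- H^T + R)^-1`` via a linear
    solve, corrects the state with the innovation ``z - H x-`` and updates
    the covariance as ``P = (I - K H) P-`` (re-symmetrized).

    Returns
    -------
    (state, K)
        The corrected state and the gain used.

    Raises
    ------
    SingularInnovationError
        If the innovation covariance is numerically singular.
    """
    zv = z.z if isinstance(z, Measurement) else np.asarray(z, dtype=float)
    H = np.asarray(H, dtype=float)
    R = np.asarray(R, dtype=float)
    if H.shape != (N_SENSORS, N_STATES) or R.shape != (N_SENSORS, N_SENSORS):
        raise ValueError(f"expected 3x7 H and 3x3 R, got {H.shape} and {R.shape}")

    P_pred = state.P
    PHt = P_pred @ H.T
    S = H @ PHt + R
    # S is symmetric, so its singular values are the |eigenvalues|
    sv = np.sort(np.abs(np.linalg.eigvalsh(S)))[::-1]
    if sv[0] == 0 or sv[-1] == 0 or sv[0] / sv[-1] > _COND_LIMIT:
        raise SingularInnovationError(float(sv[-1]))
    # K = PHt S^-1 solved as S^T K^T = PHt^T (S symmetric)
    K = np.linalg.solve(S, PHt.T).T

    innovation = zv - H @ state.x_hat
    x_new = state.x_hat + K @ innovation
    P_new = _symmetrize((np.eye(N_STATES) - K @ H) @ P_pred)
    return replace(state, x_hat=x_new, P=P_new), K


def step(
    state: FilterState, z: Measurement | np.ndarray, matrices: ModelMatrices
) -> FilterState:
    """One full predict + update cycle; advances the sample index.

    Stores the Kalman gain of this step in ``matrices.K``.
    """
    pred = predict(state, matrices.A, matrices.Q)
    corrected, K = update(pred, z, matrices.H, matrices.R)
    matrices.K = K
    return replace(corrected, k=state.k + 1)
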