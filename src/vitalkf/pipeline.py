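"""End-to-end filter runs, evaluation metrics and the reference estimator.

``run`` drives the full per-sample loop: adaptation tick (when enabled),
model-matrix rebuild, Kalman predict/correct, and rate estimation on the
separated oscillator states with frequency feedback into the transition
matrix.  With ``adaptive=False`` every matrix stays at its initialization
values — the non-adaptive baseline.

Evaluation compares the online rate estimates against a spectrum-based
estimator applied to the noise-free reference channels (flow for
respiration, PPG for heart), and measures how well the offset states track
the raw sensor baselines.  The first 22.5 s (warm-up: buffers filling,
filter settling) are excluded from every metric.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import kalman
from .adaptation import AdaptationState, adaptation_tick
from .config import FilterConfig
from .kalman import FilterState, Measurement, ModelMatrices, N_SENSORS, N_STATES
from .rates import RateEstimator

__all__ = [
    "RunResult",
    "run",
    "spectrum_reference_rate",
    "evaluate_rates",
    "evaluate_offsets",
]

logger = logging.getLogger(__name__)

STATE_COLUMNS = ("Xf", "Vf", "Xs", "Vs", "C1", "C2", "C3")


@dataclass
class RunResult:
    """Per-sample filter output plus provenance."""

    t: np.ndarray              # (n,) time [s]
    states: np.ndarray         # (n, 7) state trajectory
    heart_rate_bpm: np.ndarray  # (n,)
    resp_rate_permin: np.ndarray  # (n,)
    config: FilterConfig
    config_hash: str
    input_digest: str
    #: filled when ``run(..., check_covariance_every=n)`` is used:
    #: worst relative asymmetry and most negative eigenvalue (relative to
    #: trace) of the error covariance over the checked steps
    covariance_report: dict | None = None
    #: per-decimation-instant record of the parameters the filter
    #: consumed (adaptive runs with ``record_params=True``): keys ``t``,
    #: ``sigma_noise``, ``sigma_resp``, ``sigma_heart``, ``sigma_trend``,
    #: ``h_f``, ``h_s``, ``omega_f``, ``omega_s``
    param_trace: dict | None = None

    @property
    def offsets(self) -> np.ndarray:
        """(n, 3) estimated per-sensor offsets C1..C3."""
        return self.states[:, 4:7]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.states, columns=list(STATE_COLUMNS))
        frame.insert(0, "time", self.t)
        frame["hr_bpm"] = self.heart_rate_bpm
        frame["rr_permin"] = self.resp_rate_permin
        return frame


def _initial_state(z0: np.ndarray, config: FilterConfig) -> FilterState:
    """Oscillator states start at zero; offsets at the first raw sample.

    P0 is diagonal: oscillator entries a configurable multiple of the
    matching process-noise entries, offset entries the squared initial
    trend std.
    """
    x0 = np.zeros(N_STATES)
    x0[4:] = z0
    omega_f0 = 2 * np.pi * config.f_f0
    omega_s0 = 2 * np.pi * config.f_s0
    q_diag = np.array([1.0, omega_f0**2, 1.0, omega_s0**2])
    p_diag = np.concatenate(
        (
            config.p0_oscillator_factor * q_diag,
            np.asarray(config.sigma_trend0, dtype=float) ** 2,
        )
    )
    return FilterState(x_hat=x0, P=np.diag(p_diag), k=0, dt=config.dt)


def run(
    signals: np.ndarray | pd.DataFrame,
    config: FilterConfig,
    check_covariance_every: int | None = None,
    record_params: bool = False,
) -> RunResult:
    """Filter a 3-channel recording sample-by-sample.

    Parameters
    ----------
    signals
        (n, 3) array, or a DataFrame with columns ``s1, s2, s3`` (extra
        columns such as ``time``/``flow``/``ppg`` are ignored).
    config
        Filter configuration; ``config.adaptive`` selects the adaptive
        filter or the frozen-parameter baseline.
    check_covariance_every
        If given, verify the symmetry and positive semidefiniteness of
        the error covariance every that many steps and attach the worst
        values seen to ``RunResult.covariance_report``.
    record_params
        Record every model parameter the filter consumed at each
        estimation instant (adaptive runs only); see
        ``RunResult.param_trace``.
    """
    if isinstance(signals, pd.DataFrame):
        raw = signals[["s1", "s2", "s3"]].to_numpy(dtype=float)
    else:
        raw = np.asarray(signals, dtype=float)
        if raw.ndim != 2 or raw.shape[1] != N_SENSORS:
            raise ValueError(f"signals must be (n, 3), got {raw.shape}")
    bad = np.flatnonzero(~np.all(np.isfinite(raw), axis=1))
    if bad.size:
        raise ValueError(f"non-finite sample at index {bad[0]}")
    n = raw.shape[0]
    if n < config.warmup_samples:
        raise ValueError(
            f"need at least the {config.warmup_s} s warm-up "
            f"({config.warmup_samples} samples), got {n}"
        )

    digest = hashlib.sha256(np.ascontiguousarray(raw).tobytes()).hexdigest()[:16]
    dt = config.dt
    state = _initial_state(raw[0], config)
    adapt = AdaptationState(config) if config.adaptive else None

    heart_est = RateEstimator(
        fs=config.fs,
        buffer_s=config.heart_rate_buffer_s,
        f0=config.f_f0,
        band=config.heart_band_hz,
        cutoff_hz=config.heart_rate_cutoff_hz,
        cadence=config.cadence,
        min_sep_frac=config.heart_min_sep_frac,
        prominence_frac=config.peak_prominence_frac,
        warmup_samples=config.warmup_samples,
    )
    resp_est = RateEstimator(
        fs=config.fs,
        buffer_s=config.resp_rate_buffer_s,
        f0=config.f_s0,
        band=config.resp_band_hz,
        cutoff_hz=config.resp_rate_cutoff_hz,
        cadence=config.cadence,
        min_sep_frac=config.resp_min_sep_frac,
        prominence_frac=config.resp_peak_prominence_frac,
        warmup_samples=config.warmup_samples,
    )

    omega_f0 = 2 * np.pi * config.f_f0
    omega_s0 = 2 * np.pi * config.f_s0
    matrices = ModelMatrices(
        A=kalman.build_transition(omega_f0, omega_s0, dt),
        Q=kalman.build_process_noise(omega_f0, omega_s0, config.sigma_trend0),
        R=kalman.build_measurement_noise(config.sigma_noise0),
        H=kalman.build_measurement_matrix(
            *_init_h(config),
        ),
    )

    states = np.empty((n, N_STATES))
    hr = np.empty(n)
    rr = np.empty(n)
    warmup_n = config.warmup_samples
    max_asym = 0.0
    min_rel_eig = np.inf
    trace: dict[str, list] | None = (
        {k: [] for k in ("t", "sigma_noise", "sigma_resp", "sigma_heart",
                         "sigma_trend", "h_f", "h_s", "omega_f", "omega_s")}
        if record_params and adapt is not None
        else None
    )

    for k in range(n):
        z = raw[k]
        if adapt is not None:
            params = adaptation_tick(adapt, z, config)
            # feed the estimated rates back only once the filter is settled
            if k >= warmup_n:
                omega_f = 2 * np.pi * heart_est.rate_hat
                omega_s = 2 * np.pi * resp_est.rate_hat
            else:
                omega_f, omega_s = omega_f0, omega_s0
            # parameters change only at decimation instants, so rebuilding
            # the matrices every sample would mostly recreate identical
            # arrays; rebuild on the estimation cadence (and through the
            # warm-up boundary, where the frequencies switch source)
            if k % config.cadence == 0 or k == warmup_n:
                matrices.A = kalman.build_transition(omega_f, omega_s, dt)
                matrices.Q = kalman.build_process_noise(
                    omega_f, omega_s, params.sigma_trend
                )
                matrices.R = kalman.build_measurement_noise(params.sigma_noise)
                matrices.H = kalman.build_measurement_matrix(params.h_f, params.h_s)
                if trace is not None:
                    trace["t"].append(k * dt)
                    trace["sigma_noise"].append(params.sigma_noise.copy())
                    trace["sigma_resp"].append(params.sigma_resp.copy())
                    trace["sigma_heart"].append(params.sigma_heart.copy())
                    trace["sigma_trend"].append(params.sigma_trend.copy())
                    trace["h_f"].append(params.h_f.copy())
                    trace["h_s"].append(params.h_s.copy())
                    trace["omega_f"].append(omega_f)
                    trace["omega_s"].append(omega_s)
        state = kalman.step(state, Measurement(z=z, t=k * dt), matrices)
        if check_covariance_every and k % check_covariance_every == 0:
            P = state.P
            denom = float(np.abs(P).max()) or 1.0
            max_asym = max(max_asym, float(np.abs(P - P.T).max()) / denom)
            min_rel_eig = min(
                min_rel_eig,
                float(np.linalg.eigvalsh(P)[0]) / float(np.trace(P)),
            )
        states[k] = state.x_hat
        hr[k] = heart_est.tick(state.x_hat[0]) * 60.0
        rr[k] = resp_est.tick(state.x_hat[2]) * 60.0

    return RunResult(
        t=np.arange(n) * dt,
        states=states,
        heart_rate_bpm=hr,
        resp_rate_permin=rr,
        config=config,
        config_hash=config.config_hash(),
        input_digest=digest,
        covariance_report=(
            {"max_asymmetry": max_asym, "min_relative_eigenvalue": min_rel_eig}
            if check_covariance_every
            else None
        ),
        param_trace=(
            {k: np.asarray(v) for k, v in trace.items()}
            if trace is not None
            else None
        ),
    )


def _init_h(config: FilterConfig) -> tuple[np.ndarray, np.ndarray]:
    """Measurement gains implied by the initialization std values."""
    sigma_heart = np.asarray(config.sigma_heart0, dtype=float)
    sigma_noise = np.asarray(config.sigma_noise0, dtype=float)
    sigma_resp = np.asarray(config.sigma_resp0, dtype=float)
    h_f = (sigma_heart / sigma_noise) ** 2 * np.asarray(config.scal_f)
    h_s = sigma_resp**2 * np.asarray(config.scal_s)
    return h_f, h_s


def spectrum_reference_rate(
    reference: np.ndarray,
    fs: float,
    band: tuple[float, float],
    window_s: float = 30.0,
    hop_s: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Offline spectrum-based rate estimate over a sliding window.

    For each Hann-windowed segment the dominant in-band DFT magnitude bin
    is refined by three-point parabolic interpolation.  Timestamps are the
    window centers.  Serves as the high-resolution evaluation reference,
    not the online path.

    Returns
    -------
    (times, rates_hz); windows with no in-band content yield NaN.
    """
    reference = np.asarray(reference, dtype=float)
    nwin = round(window_s * fs)
    lo, hi = band
    if nwin + 0.5 < 4 * fs / lo:
        raise ValueError(
            f"window of {window_s} s holds fewer than 4 periods at {lo} Hz"
        )
    hop = max(1, round(hop_s * fs))
    taper = np.hanning(nwin)
    freqs = np.fft.rfftfreq(nwin, 1.0 / fs)
    in_band = (freqs >= lo) & (freqs <= hi)

    times, rates = [], []
    for start in range(0, reference.size - nwin + 1, hop):
        seg = reference[start : start + nwin]
        seg = seg - seg.mean()
        mag = np.abs(np.fft.rfft(seg * taper))
        if not np.any(mag[in_band] > 0):
            times.append((start + nwin / 2) / fs)
            rates.append(np.nan)
            continue
        band_idx = np.flatnonzero(in_band)
        j = band_idx[np.argmax(mag[in_band])]
        f = freqs[j]
        if 0 < j < mag.size - 1:
            a, b, c = mag[j - 1], mag[j], mag[j + 1]
            denom = a - 2 * b + c
            if denom != 0:
                delta = 0.5 * (a - c) / denom
                f += np.clip(delta, -0.5, 0.5) * (fs / nwin)
        times.append((start + nwin / 2) / fs)
        rates.append(f)
    return np.asarray(times), np.asarray(rates)


def _aligned(
    t_est: np.ndarray,
    estimated: np.ndarray,
    t_ref: np.ndarray,
    reference: np.ndarray,
    warmup_s: float,
) -> tuple[np.ndarray, np.ndarray]:
    t_est = np.asarray(t_est, dtype=float)
    estimated = np.asarray(estimated, dtype=float)
    t_ref = np.asarray(t_ref, dtype=float)
    reference = np.asarray(reference, dtype=float)
    ok = ~np.isnan(reference)
    t_ref, reference = t_ref[ok], reference[ok]
    keep = (t_est >= warmup_s) & (t_est >= t_ref.min()) & (t_est <= t_ref.max())
    if not np.any(keep):
        raise ValueError("no overlap between estimate and reference after warm-up")
    ref_on_est = np.interp(t_est[keep], t_ref, reference)
    return estimated[keep], ref_on_est


def evaluate_rates(
    t_est: np.ndarray,
    estimated: np.ndarray,
    t_ref: np.ndarray,
    reference: np.ndarray,
    warmup_s: float = 22.5,
) -> tuple[float, float]:
    """Mean and std of (estimate − reference), warm-up excluded.

    Units follow the inputs (bpm for heart, min⁻¹ for respiration); the
    reference is linearly interpolated onto the estimate's time base.
    """
    est, ref = _aligned(t_est, estimated, t_ref, reference, warmup_s)
    err = est - ref
    return float(np.mean(err)), float(np.std(err))


def evaluate_offsets(
    offsets: np.ndarray,
    raw: np.ndarray,
    t: np.ndarray,
    warmup_s: float = 22.5,
) -> list[tuple[float, float]]:
    """Per-sensor mean and std of (raw − estimated offset), warm-up excluded.

    A large mean indicates the offset state failed to separate the
    baseline from the physiological signal.
    """
    offsets = np.asarray(offsets, dtype=float)
    raw = np.asarray(raw, dtype=float)
    t = np.asarray(t, dtype=float)
    keep = t >= warmup_s
    if not np.any(keep):
        raise ValueError("no samples after warm-up")
    residual = raw[keep] - offsets[keep]
    return [
        (float(np.mean(residual[:, i])), float(np.std(residual[:, i])))
        for i in range(N_SENSORS)
    ]
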