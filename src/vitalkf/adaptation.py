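"""Online estimation of the time-varying filter parameters.

The adaptive filter re-estimates, from the raw sensor stream itself, every
quantity its model matrices depend on:

* per-sensor measurement-noise std  — from the first difference of a short
  (0.5 s) window; differencing suppresses the slow physiological content
  and, for white noise, doubles the variance (hence the default
  divisor sqrt(2));
* per-sensor respiration std        — plain std of a long (20 s) window,
  which is dominated by the respiratory oscillation;
* per-sensor trend std              — fixed at 10% of the respiration std
  (trend variance = 1% of respiratory variance);
* per-sensor heart std              — std of the short window divided by a
  configurable divisor (default 2: the short window holds heart plus
  noise plus local respiratory slope, and halving approximates the
  cardiac share);
* the measurement-matrix gains      — h_f = (sigma_heart/sigma_noise)^2 *
  scal_f and h_s = sigma_resp^2 * scal_s.

Estimates are recomputed only every ``cadence``-th sample (every 10th at
95 Hz, an effective 9.5 Hz) and lowpass-smoothed by first-order Butterworth
filters running at that decimated rate; in between, the last values are
held so the filter still sees a parameter set at every sample.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .buffers import FirstOrderSmoother, RingBuffer
from .config import FilterConfig
from .kalman import N_SENSORS

__all__ = [
    "ScalingVectors",
    "AdaptedParams",
    "AdaptationState",
    "estimate_noise_std",
    "estimate_resp_std",
    "estimate_trend_std",
    "estimate_heart_std",
    "compute_h_entries",
    "adaptation_tick",
]

logger = logging.getLogger(__name__)

#: trend std as a fraction of the respiration std (trend variance is
#: defined as 1% of respiratory variance)
TREND_FRACTION = 0.1


@dataclass(frozen=True)
class ScalingVectors:
    """Per-sensor scaling of the heart and respiration measurement gains."""

    scal_f: tuple[float, float, float] = (1.0, 0.1, 0.1)
    scal_s: tuple[float, float, float] = (0.1, 1.0, 1.0)

    def __post_init__(self) -> None:
        for name in ("scal_f", "scal_s"):
            v = getattr(self, name)
            if len(v) != N_SENSORS or any(not (0 < x <= 1) for x in v):
                raise ValueError(f"{name} entries must lie in (0, 1], got {v}")


@dataclass
class AdaptedParams:
    """Smoothed parameter set emitted for the model-matrix builders."""

    sigma_noise: np.ndarray  # (3,)
    sigma_resp: np.ndarray   # (3,)
    sigma_heart: np.ndarray  # (3,)
    sigma_trend: np.ndarray  # (3,)
    h_f: np.ndarray          # (3,)
    h_s: np.ndarray          # (3,)


def estimate_noise_std(segment: np.ndarray, divisor: float = math.sqrt(2.0)) -> float:
    """Measurement-noise std from a differentiated short segment.

    ``std(diff(segment)) / divisor``; the default divisor sqrt(2) undoes
    the variance doubling that first-differencing applies to white noise.
    Returns NaN (caller holds its previous estimate) if the segment is too
    short to difference.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.size < 2:
        logger.warning("noise-std segment of length %d (<2); holding", segment.size)
        return float("nan")
    return float(np.std(np.diff(segment)) / divisor)


def estimate_resp_std(long_segment: np.ndarray) -> float:
    """Respiration std: plain std of the 20 s long-term segment."""
    return float(np.std(np.asarray(long_segment, dtype=float)))


def estimate_trend_std(sigma_resp: float) -> float:
    """Trend std from the respiration std (trend variance = 1% of resp variance)."""
    if sigma_resp < 0:
        raise ValueError(f"sigma_resp must be >= 0, got {sigma_resp}")
    return TREND_FRACTION * sigma_resp


def estimate_heart_std(segment: np.ndarray, divisor: float = 2.0) -> float:
    """Heart std from the short segment: ``std(segment) / divisor``."""
    segment = np.asarray(segment, dtype=float)
    if segment.size < 2:
        logger.warning("heart-std segment of length %d (<2); holding", segment.size)
        return float("nan")
    return float(np.std(segment) / divisor)


def compute_h_entries(
    sigma_heart: np.ndarray,
    sigma_noise: np.ndarray,
    sigma_resp: np.ndarray,
    scal: ScalingVectors,
    noise_floor_factor: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """Measurement-matrix gains from the current std estimates.

    ``h_f[i] = (sigma_heart[i] / sigma_noise[i])^2 * scal_f[i]`` and
    ``h_s[i] = sigma_resp[i]^2 * scal_s[i]``.  A vanishing noise estimate
    is floored at ``noise_floor_factor * sigma_resp[i]`` (with a tiny
    absolute fallback) to keep the ratio finite on noiseless input.
    """
    sigma_heart = np.asarray(sigma_heart, dtype=float)
    sigma_noise = np.asarray(sigma_noise, dtype=float).copy()
    sigma_resp = np.asarray(sigma_resp, dtype=float)
    floor = np.maximum(noise_floor_factor * sigma_resp, 1e-30)
    low = sigma_noise < floor
    if np.any(low):
        logger.warning(
            "noise std %s below floor %s; flooring", sigma_noise[low], floor[low]
        )
        sigma_noise[low] = floor[low]
    h_f = (sigma_heart / sigma_noise) ** 2 * np.asarray(scal.scal_f)
    h_s = sigma_resp**2 * np.asarray(scal.scal_s)
    return h_f, h_s


@dataclass
class AdaptationState:
    """Rolling buffers, smoothers and the currently held parameter set."""

    config: FilterConfig
    short_buffers: list[RingBuffer] = field(init=False)
    long_buffers: list[RingBuffer] = field(init=False)
    smoothers: dict[str, list[FirstOrderSmoother]] = field(init=False)
    cadence_counter: int = field(init=False, default=0)
    params: AdaptedParams = field(init=False)

    def __post_init__(self) -> None:
        cfg = self.config
        self.short_buffers = [
            RingBuffer(cfg.short_window_len) for _ in range(N_SENSORS)
        ]
        self.long_buffers = [
            RingBuffer(cfg.long_window_len) for _ in range(N_SENSORS)
        ]
        rate = cfg.estimation_rate_hz
        init = {
            "noise": cfg.sigma_noise0,
            "resp": cfg.sigma_resp0,
            "heart": cfg.sigma_heart0,
        }
        self.smoothers = {
            name: [
                FirstOrderSmoother(cfg.estimate_cutoff_hz, rate, x0=v)
                for v in values
            ]
            for name, values in init.items()
        }
        self.params = self._params_from_current()

    def _smoothed(self, name: str) -> np.ndarray:
        return np.array([s.value for s in self.smoothers[name]])

    def _params_from_current(self) -> AdaptedParams:
        cfg = self.config
        sigma_noise = self._smoothed("noise")
        sigma_resp = self._smoothed("resp")
        sigma_heart = self._smoothed("heart")
        sigma_trend = np.array([estimate_trend_std(s) for s in sigma_resp])
        h_f, h_s = compute_h_entries(
            sigma_heart,
            sigma_noise,
            sigma_resp,
            ScalingVectors(cfg.scal_f, cfg.scal_s),
            cfg.noise_floor_factor,
        )
        return AdaptedParams(
            sigma_noise=sigma_noise,
            sigma_resp=sigma_resp,
            sigma_heart=sigma_heart,
            sigma_trend=sigma_trend,
            h_f=h_f,
            h_s=h_s,
        )


def adaptation_tick(
    state: AdaptationState, z: np.ndarray, config: FilterConfig | None = None
) -> AdaptedParams:
    """Ingest one raw 3-sensor sample; emit the current parameter set.

    Buffers are updated every call.  Every ``cadence``-th call the raw std
    estimates are recomputed and pushed through their smoothers; on all
    other calls the previous parameter set is held.  Long-window estimates
    (respiration, hence trend) keep their initialization values until the
    20 s buffer has filled; the short-window estimates (noise, heart)
    likewise until the 0.5 s buffer has filled.

    Returns a reference to the state's current :class:`AdaptedParams`.
    """
    cfg = config or state.config
    z = np.asarray(z, dtype=float).reshape(N_SENSORS)
    for i in range(N_SENSORS):
        state.short_buffers[i].push(z[i])
        state.long_buffers[i].push(z[i])

    state.cadence_counter += 1
    if state.cadence_counter % cfg.cadence != 0:
        return state.params

    for i in range(N_SENSORS):
        if state.short_buffers[i].full:
            short = state.short_buffers[i].view()
            raw_noise = estimate_noise_std(short, cfg.noise_diff_divisor)
            raw_heart = estimate_heart_std(short, cfg.heart_std_divisor)
            if not math.isnan(raw_noise):
                state.smoothers["noise"][i](raw_noise)
            if not math.isnan(raw_heart):
                state.smoothers["heart"][i](raw_heart)
        if state.long_buffers[i].full:
            raw_resp = estimate_resp_std(state.long_buffers[i].view())
            state.smoothers["resp"][i](raw_resp)

    state.params = state._params_from_current()
    return state.params
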