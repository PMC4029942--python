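"""Synthetic multi-sensor cardiorespiratory sessions with known ground truth.

Emulates the signal structure of non-contact (magnetic-induction style)
thoracic sensors: each of three channels carries

* a very large, slowly drifting offset (random walk on a constant level),
* a dominant respiratory oscillation with higher harmonics (breathing is
  not sinusoidal, and the 2nd/3rd harmonics can overlap the cardiac band),
* a much smaller cardiac oscillation,
* additive white Gaussian noise.

Sensor 1 is cardiac-dominant (largest heart-to-respiration amplitude
ratio), as for a sensor placed directly over the heart.  Noise-free flow
and PPG reference channels are generated phase-locked to the respiratory
and cardiac components.  Every generated series is reproducible from the
spec and its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .kalman import N_SENSORS

__all__ = ["SessionSpec", "SessionTruth", "SyntheticSession", "generate", "preset"]

RateTrack = Callable[[np.ndarray], np.ndarray]
"""Maps a time vector [s] to instantaneous rate (bpm or breaths/min)."""


def constant_track(value: float) -> RateTrack:
    return lambda t: np.full_like(np.asarray(t, dtype=float), float(value))


def step_track(value_before: float, value_after: float, t_step: float) -> RateTrack:
    def track(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.where(t < t_step, float(value_before), float(value_after))

    return track


@dataclass
class SessionSpec:
    """Full parameterization of one synthetic session.

    Rates are given as tracks (functions of time); amplitudes, offsets,
    drifts and noise levels per sensor, in arbitrary sensor amplitude
    units.  ``resp_harmonics`` lists (order, relative amplitude) pairs
    added on top of the respiratory fundamental.
    """

    duration_s: float = 120.0
    fs: float = 95.0
    heart_rate_track: RateTrack = field(default_factory=lambda: constant_track(78.0))
    resp_rate_track: RateTrack = field(default_factory=lambda: constant_track(18.0))
    offset_level: tuple[float, ...] = (50000.0, 20000.0, 40000.0)
    # per-sample random-walk steps sized so the baseline wanders by a
    # noticeable fraction of the respiratory amplitude within a minute —
    # the large, time-varying offset these sensors are known for
    drift_sigma: tuple[float, ...] = (40.0, 5.0, 6.0)
    # respiration couples ~10x more strongly into sensor 1 (directly over
    # the thorax center) than into sensors 2-3, mirroring the amplitude
    # spread seen on real sensor arrays of this kind; sensor 1 also has
    # the largest heart-to-respiration ratio
    resp_amplitude: tuple[float, ...] = (10000.0, 1000.0, 1000.0)
    heart_amplitude: tuple[float, ...] = (2000.0, 60.0, 90.0)
    noise_sigma: tuple[float, ...] = (50.0, 12.0, 15.0)
    resp_harmonics: Sequence[tuple[int, float]] = ((2, 0.3), (3, 0.1))
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.duration_s <= 0:
            problems.append(f"duration_s must be > 0, got {self.duration_s}")
        if self.fs <= 0:
            problems.append(f"fs must be > 0, got {self.fs}")
        for name in (
            "offset_level",
            "drift_sigma",
            "resp_amplitude",
            "heart_amplitude",
            "noise_sigma",
        ):
            v = getattr(self, name)
            if len(v) != N_SENSORS:
                problems.append(f"{name} must have {N_SENSORS} entries, got {len(v)}")
            elif name != "offset_level" and any(x < 0 for x in v):
                problems.append(f"{name} entries must be >= 0, got {v}")
        for order, rel in self.resp_harmonics:
            if order < 2 or rel < 0:
                problems.append(
                    f"harmonic (order={order}, rel={rel}) invalid: "
                    "order >= 2 and rel >= 0 required"
                )
        if problems:
            raise ValueError("invalid session spec: " + "; ".join(problems))

    def summary(self) -> dict:
        """JSON-serializable description (rate tracks sampled at t=0)."""
        return {
            "duration_s": self.duration_s,
            "fs": self.fs,
            "heart_rate_bpm_t0": float(self.heart_rate_track(np.zeros(1))[0]),
            "resp_rate_permin_t0": float(self.resp_rate_track(np.zeros(1))[0]),
            "offset_level": list(self.offset_level),
            "drift_sigma": list(self.drift_sigma),
            "resp_amplitude": list(self.resp_amplitude),
            "heart_amplitude": list(self.heart_amplitude),
            "noise_sigma": list(self.noise_sigma),
            "resp_harmonics": [list(h) for h in self.resp_harmonics],
            "seed": self.seed,
        }


@dataclass
class SessionTruth:
    """Ground truth stored alongside the generated channels."""

    heart_rate_bpm: np.ndarray   # (n,) true instantaneous heart rate
    resp_rate_permin: np.ndarray  # (n,) true respiration rate
    sigma_noise: np.ndarray      # (3,) exact generator noise std
    sigma_resp: np.ndarray       # (3,) std of the respiratory component
    sigma_heart: np.ndarray      # (3,) std of the cardiac component
    offset_track: np.ndarray     # (n, 3) offset level + drift
    resp_component: np.ndarray   # (n, 3) noise-free respiratory component
    heart_component: np.ndarray  # (n, 3) noise-free cardiac component
    resp_phase: np.ndarray       # (n,) respiratory fundamental phase [rad]
    heart_phase: np.ndarray      # (n,) cardiac phase [rad]


@dataclass
class SyntheticSession:
    """Generated sensor and reference channels plus ground truth."""

    t: np.ndarray         # (n,) time [s]
    sensors: np.ndarray   # (n, 3)
    flow_ref: np.ndarray  # (n,) noise-free respiration reference
    ppg_ref: np.ndarray   # (n,) noise-free cardiac reference
    truth: SessionTruth
    spec: SessionSpec

    @property
    def fs(self) -> float:
        return self.spec.fs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.t,
                "s1": self.sensors[:, 0],
                "s2": self.sensors[:, 1],
                "s3": self.sensors[:, 2],
                "flow": self.flow_ref,
                "ppg": self.ppg_ref,
            }
        )

    def write_csv(self, path: str | Path) -> None:
        """Write channels as CSV plus a JSON sidecar with spec and truth."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        sidecar = {
            "spec": self.spec.summary(),
            "truth_summary": {
                "sigma_noise": self.truth.sigma_noise.tolist(),
                "sigma_resp": self.truth.sigma_resp.tolist(),
                "sigma_heart": self.truth.sigma_heart.tolist(),
                "mean_heart_rate_bpm": float(np.mean(self.truth.heart_rate_bpm)),
                "mean_resp_rate_permin": float(np.mean(self.truth.resp_rate_permin)),
            },
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2)
        )


def generate(spec: SessionSpec) -> SyntheticSession:
    """Generate one session from a spec; identical spec + seed → identical data.

    Phases are obtained by cumulative trapezoidal integration of the rate
    tracks, so they stay continuous through rate changes.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = round(spec.duration_s * spec.fs)
    t = np.arange(n) / spec.fs

    f_f = spec.heart_rate_track(t) / 60.0   # Hz
    f_s = spec.resp_rate_track(t) / 60.0
    phase_f = 2 * np.pi * cumulative_trapezoid(f_f, t, initial=0.0)
    phase_s = 2 * np.pi * cumulative_trapezoid(f_s, t, initial=0.0)

    resp_wave = np.sin(phase_s)
    for order, rel in spec.resp_harmonics:
        resp_wave = resp_wave + rel * np.sin(order * phase_s)
    heart_wave = np.sin(phase_f)

    offset = np.empty((n, N_SENSORS))
    sensors = np.empty((n, N_SENSORS))
    resp_comp = np.empty((n, N_SENSORS))
    heart_comp = np.empty((n, N_SENSORS))
    for i in range(N_SENSORS):
        drift = np.cumsum(rng.normal(0.0, spec.drift_sigma[i], n))
        offset[:, i] = spec.offset_level[i] + drift
        resp_comp[:, i] = spec.resp_amplitude[i] * resp_wave
        heart_comp[:, i] = spec.heart_amplitude[i] * heart_wave
        noise = rng.normal(0.0, spec.noise_sigma[i], n)
        sensors[:, i] = offset[:, i] + resp_comp[:, i] + heart_comp[:, i] + noise

    truth = SessionTruth(
        heart_rate_bpm=f_f * 60.0,
        resp_rate_permin=f_s * 60.0,
        sigma_noise=np.array(spec.noise_sigma, dtype=float),
        sigma_resp=resp_comp.std(axis=0),
        sigma_heart=heart_comp.std(axis=0),
        offset_track=offset,
        resp_component=resp_comp,
        heart_component=heart_comp,
        resp_phase=phase_s,
        heart_phase=phase_f,
    )
    return SyntheticSession(
        t=t,
        sensors=sensors,
        flow_ref=np.sin(phase_s),
        ppg_ref=np.sin(phase_f),
        truth=truth,
        spec=spec,
    )


_PRESETS: dict[str, Callable[[], SessionSpec]] = {
    # rates follow the best-case initialization of the two study subjects
    "subject1_like": lambda: SessionSpec(
        heart_rate_track=constant_track(78.0),   # 1.3 Hz
        resp_rate_track=constant_track(18.0),    # 0.3 Hz
    ),
    "subject2_like": lambda: SessionSpec(
        heart_rate_track=constant_track(102.0),  # 1.7 Hz
        resp_rate_track=constant_track(12.0),    # 0.2 Hz
        offset_level=(30000.0, 25000.0, 45000.0),
        drift_sigma=(12.0, 2.0, 2.0),
        resp_amplitude=(3000.0, 300.0, 300.0),
        heart_amplitude=(600.0, 20.0, 27.0),
        noise_sigma=(15.0, 4.0, 5.0),
    ),
    # cardiac frequency exactly twice the respiratory frequency: the 2nd
    # respiratory harmonic lands on the heart band
    "worst_case": lambda: SessionSpec(
        heart_rate_track=constant_track(42.0),   # 0.70 Hz
        resp_rate_track=constant_track(21.0),    # 0.35 Hz
    ),
    # sinusoidal session with noise well above the differenced
    # physiological slope: the regime in which the short-window noise
    # estimator is identifiable, used to validate the variance estimators
    # against known ground truth (mirrors validating the estimation laws
    # on simulated sinusoidal signals before use on recordings)
    "estimator_validation": lambda: SessionSpec(
        heart_rate_track=constant_track(60.0),
        resp_rate_track=constant_track(12.0),
        offset_level=(30000.0, 30000.0, 30000.0),
        drift_sigma=(1.0, 1.0, 1.0),
        resp_amplitude=(1800.0, 1800.0, 1800.0),
        heart_amplitude=(400.0, 20.0, 20.0),
        noise_sigma=(50.0, 50.0, 50.0),
        resp_harmonics=(),
    ),
}


def preset(name: str, seed: int = 0, duration_s: float | None = None) -> SessionSpec:
    """Named session spec: ``subject1_like``, ``subject2_like``, ``worst_case``."""
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; valid presets: {sorted(_PRESETS)}")
    spec = _PRESETS[name]()
    spec.seed = seed
    if duration_s is not None:
        spec.duration_s = duration_s
    return spec
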