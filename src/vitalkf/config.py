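"""Filter configuration and the published initialization presets.

A :class:`FilterConfig` bundles everything a run needs: the initialization
standard deviations for noise, heart, respiration and trend on each of the
three sensors, the starting heart/respiration frequencies, the per-sensor
scaling vectors, buffer lengths, smoother cutoffs, the estimation cadence
and the warm-up span.

Four named presets are shipped:

``SE1`` / ``SE2``
    "Sensor Estimation" settings: variances estimated offline from the
    whole recording of each of two subjects — the best case.
``DS``
    Default settings meant to work adequately in most cases.
``BS``
    Bad settings: deliberately misconfigured (huge noise variance, tiny
    signal variances), the worst case a user could dial in.
"""

from __future__ import annotations

import hashlib
import json
import math
from typing import Literal, Tuple

from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = ["FilterConfig", "PRESETS", "load_preset"]

Vec3 = Tuple[float, float, float]


class FilterConfig(BaseModel):
    """Complete parameterization of one filter run."""

    adaptive: bool = True
    fs: float = Field(default=95.0, gt=0, description="sampling rate [Hz]")

    # initial model frequencies
    f_f0: float = Field(default=1.3, gt=0, description="initial heart rate [Hz]")
    f_s0: float = Field(default=0.3, gt=0, description="initial respiration rate [Hz]")

    # initialization standard deviations, one entry per sensor
    sigma_trend0: Vec3 = (989.0, 159.2, 1057.7)
    sigma_noise0: Vec3 = (53.6, 11.2, 64.2)
    sigma_heart0: Vec3 = (1112.1, 195.8, 1605.8)
    sigma_resp0: Vec3 = (10195.7, 1114.4, 8498.0)

    # per-sensor scaling of the heart / respiration measurement gains;
    # sensor 1 sits over the heart, sensors 2-3 carry mostly respiration
    scal_f: Vec3 = (1.0, 0.1, 0.1)
    scal_s: Vec3 = (0.1, 1.0, 1.0)

    # rolling-window lengths [s]
    short_window_s: float = Field(default=0.5, gt=0)
    long_window_s: float = Field(default=20.0, gt=0)
    heart_rate_buffer_s: float = Field(default=10.0, gt=0)
    resp_rate_buffer_s: float = Field(default=20.0, gt=0)

    # smoothing cutoffs [Hz]; heart rate and all variance estimates share
    # 0.1 Hz, the slower respiration rate uses 0.05 Hz
    estimate_cutoff_hz: float = Field(default=0.1, gt=0)
    heart_rate_cutoff_hz: float = Field(default=0.1, gt=0)
    resp_rate_cutoff_hz: float = Field(default=0.05, gt=0)

    # every ``cadence``-th sample the estimates are recomputed; in between
    # the last values are held
    cadence: int = Field(default=10, ge=1)
    warmup_s: float = Field(default=22.5, ge=0)

    # estimator divisors (see adaptation module)
    noise_diff_divisor: float = Field(default=math.sqrt(2.0), gt=0)
    heart_std_divisor: float = Field(default=2.0, gt=0)
    noise_floor_factor: float = Field(default=1e-12, gt=0)

    # plausibility clamps for the rate feedback [Hz]
    heart_band_hz: Tuple[float, float] = (0.6, 3.0)
    resp_band_hz: Tuple[float, float] = (0.05, 0.8)

    # minimum extrema separation as a fraction of the current period
    heart_min_sep_frac: float = Field(default=0.4, gt=0, lt=1)
    resp_min_sep_frac: float = Field(default=0.5, gt=0, lt=1)
    # extrema prominence floor as a fraction of the buffer std; the
    # respiratory state is dominated by its source, so a stricter floor
    # is safe there and suppresses cardiac ripple riding the crests
    peak_prominence_frac: float = Field(default=0.35, ge=0)
    resp_peak_prominence_frac: float = Field(default=0.6, ge=0)

    # P0: oscillator entries = factor * matching Q0 diagonal,
    # offset entries = sigma_trend0^2
    p0_oscillator_factor: float = Field(default=10.0, gt=0)

    @field_validator(
        "sigma_trend0", "sigma_noise0", "sigma_heart0", "sigma_resp0"
    )
    @classmethod
    def _positive_sigmas(cls, v: Vec3) -> Vec3:
        if any(x <= 0 for x in v):
            raise ValueError(f"all sigma entries must be > 0, got {v}")
        return v

    @field_validator("scal_f", "scal_s")
    @classmethod
    def _scal_in_unit_interval(cls, v: Vec3) -> Vec3:
        if any(not (0 < x <= 1) for x in v):
            raise ValueError(f"scaling entries must lie in (0, 1], got {v}")
        return v

    @model_validator(mode="after")
    def _bands_ordered(self) -> "FilterConfig":
        for name in ("heart_band_hz", "resp_band_hz"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi):
                raise ValueError(f"{name} must satisfy 0 < low < high, got {(lo, hi)}")
        return self

    # -- derived quantities ------------------------------------------------

    @property
    def dt(self) -> float:
        return 1.0 / self.fs

    @property
    def short_window_len(self) -> int:
        return round(self.short_window_s * self.fs)

    @property
    def long_window_len(self) -> int:
        return round(self.long_window_s * self.fs)

    @property
    def heart_rate_buffer_len(self) -> int:
        return round(self.heart_rate_buffer_s * self.fs)

    @property
    def resp_rate_buffer_len(self) -> int:
        return round(self.resp_rate_buffer_s * self.fs)

    @property
    def warmup_samples(self) -> int:
        return round(self.warmup_s * self.fs)

    @property
    def estimation_rate_hz(self) -> float:
        """Effective rate at which estimates are recomputed [Hz]."""
        return self.fs / self.cadence

    def config_hash(self) -> str:
        """Stable digest of the configuration, for provenance records."""
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


_SE_COMMON = dict(scal_f=(1.0, 0.1, 0.1), scal_s=(0.1, 1.0, 1.0))

PRESETS: dict[str, dict] = {
    "SE1": dict(
        f_f0=1.3,
        f_s0=0.3,
        sigma_trend0=(989.0, 159.2, 1057.7),
        sigma_noise0=(53.6, 11.2, 64.2),
        sigma_heart0=(1112.1, 195.8, 1605.8),
        sigma_resp0=(10195.7, 1114.4, 8498.0),
        **_SE_COMMON,
    ),
    "SE2": dict(
        f_f0=1.7,
        f_s0=0.2,
        sigma_trend0=(54.1, 819.9, 1801.5),
        sigma_noise0=(6.7, 12.2, 15.6),
        sigma_heart0=(70.1, 198.8, 454.8),
        sigma_resp0=(191.2, 4137.1, 5846.5),
        **_SE_COMMON,
    ),
    "DS": dict(
        f_f0=1.5,
        f_s0=0.1,
        sigma_trend0=(100.0, 100.0, 100.0),
        sigma_noise0=(10.0, 10.0, 10.0),
        sigma_heart0=(100.0, 100.0, 100.0),
        sigma_resp0=(10000.0, 10000.0, 10000.0),
        **_SE_COMMON,
    ),
    "BS": dict(
        f_f0=1.0,
        f_s0=0.1,
        sigma_trend0=(1.0, 1.0, 1.0),
        sigma_noise0=(1000.0, 1000.0, 1000.0),
        sigma_heart0=(1.0, 1.0, 1.0),
        sigma_resp0=(1.0, 1.0, 1.0),
        **_SE_COMMON,
    ),
}


def load_preset(
    name: Literal["SE1", "SE2", "DS", "BS"], **overrides
) -> FilterConfig:
    """Build a :class:`FilterConfig` from a named preset.

    Keyword overrides (e.g. ``adaptive=False``) are applied on top.
    """
    if name not in PRESETS:
        raise KeyError(
            f"unknown preset {name!r}; valid presets: {sorted(PRESETS)}"
        )
    return FilterConfig(**{**PRESETS[name], **overrides})
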