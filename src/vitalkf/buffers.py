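"""Fixed-capacity ring buffers and streaming first-order smoothers."""

from __future__ import annotations

import numpy as np
from scipy import signal

__all__ = ["RingBuffer", "FirstOrderSmoother"]


class RingBuffer:
    """Fixed-capacity rolling window over a scalar stream.

    ``view()`` returns the stored samples in arrival order; until the
    buffer has filled, only the samples seen so far are returned.
    """

    def __init__(self, capacity: int):
        if capacity < 1:
            raise ValueError(f"capacity must be >= 1, got {capacity}")
        self.capacity = int(capacity)
        self._data = np.zeros(self.capacity)
        self._idx = 0
        self._count = 0

    def push(self, value: float) -> None:
        self._data[self._idx] = value
        self._idx = (self._idx + 1) % self.capacity
        if self._count < self.capacity:
            self._count += 1

    @property
    def full(self) -> bool:
        return self._count == self.capacity

    def __len__(self) -> int:
        return self._count

    def view(self) -> np.ndarray:
        """Samples in arrival order (copy)."""
        if self._count < self.capacity:
            return self._data[: self._count].copy()
        return np.concatenate((self._data[self._idx :], self._data[: self._idx]))


class FirstOrderSmoother:
    """Streaming first-order Butterworth lowpass with DC gain 1.

    Designed for a given cutoff at a given update rate; processes one
    value per call.  The internal state is initialized so that a constant
    input equal to ``x0`` passes through unchanged from the first call,
    suppressing startup transients.
    """

    def __init__(self, cutoff_hz: float, rate_hz: float, x0: float = 0.0):
        if not 0 < cutoff_hz < rate_hz / 2:
            raise ValueError(
                f"cutoff must lie in (0, rate/2) = (0, {rate_hz / 2}), "
                f"got {cutoff_hz}"
            )
        self.cutoff_hz = float(cutoff_hz)
        self.rate_hz = float(rate_hz)
        self._b, self._a = signal.butter(1, cutoff_hz, fs=rate_hz)
        self._zi_unit = signal.lfilter_zi(self._b, self._a)
        self._z = self._zi_unit * x0
        self._y = float(x0)

    def reset(self, x0: float) -> None:
        self._z = self._zi_unit * x0
        self._y = float(x0)

    @property
    def value(self) -> float:
        """Most recent output."""
        return self._y

    def __call__(self, x: float) -> float:
        y, self._z = signal.lfilter(self._b, self._a, [x], zi=self._z)
        self._y = float(y[0])
        return self._y
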