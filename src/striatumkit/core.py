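"""Shared containers for time series and matched-filter templates."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Trace", "Template"]


@dataclass
class Trace:
    """Uniformly sampled time series (fluorescence, ΔF/F₀ or voltage).

    Parameters
    ----------
    t0 : float
        Time of the first sample, in seconds.
    dt : float
        Sampling interval, in seconds.
    values : ndarray
        Sample values; units depend on the signal (ΔF/F₀ is unitless,
        voltage is in mV, current in pA).
    """

    t0: float
    dt: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("values must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.values.size)

    @property
    def duration(self) -> float:
        return self.dt * self.values.size

    def index_at(self, t: float) -> int:
        """Index of the sample at or immediately before time ``t``."""
        return int(np.floor((t - self.t0) / self.dt + 1e-9))


@dataclass
class Template:
    """Matched-filter waveform for event detection.

    ``self_dot`` is the dot product of the template with itself -- the
    score of a perfect fit, against which detection thresholds are set.
    """

    dt: float
    values: np.ndarray
    self_dot: float = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.values.size < 1:
            raise ValueError("template must have at least one sample")
        self.self_dot = float(self.values @ self.values)
        if self.self_dot <= 0:
            raise ValueError("template must have positive energy")

    @property
    def duration(self) -> float:
        return self.dt * self.values.size

    def resampled(self, dt: float) -> "Template":
        """Template interpolated onto a new sampling interval."""
        if np.isclose(dt, self.dt):
            return self
        t_old = self.dt * np.arange(self.values.size)
        t_new = np.arange(0.0, t_old[-1] + 0.5 * dt, dt)
        return Template(dt=dt, values=np.interp(t_new, t_old, self.values))
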