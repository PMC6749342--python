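"""Uniformly sampled scalar time series.

The universal carrier for segment elevation angles (rad), adaptive-oscillator
residuals, and anything else that flows through the detection pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TimeSeries"]


@dataclass
class TimeSeries:
    """A uniformly sampled signal.

    Parameters
    ----------
    values
        Sample values (typically radians for elevation angles).
    fs_hz
        Sampling rate in samples per second; must be positive.
    t0_s
        Absolute time of the first sample, seconds.
    channel
        Free-form label, e.g. ``"shank"``, ``"foot"``, ``"error"``.
    """

    values: np.ndarray
    fs_hz: float
    t0_s: float = 0.0
    channel: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("TimeSeries.values must be one-dimensional")
        if not np.isfinite(self.fs_hz) or self.fs_hz <= 0:
            raise ValueError(f"fs_hz must be a positive finite number, got {self.fs_hz}")
        if self.values.size and not np.all(np.isfinite(self.values)):
            bad = int(np.flatnonzero(~np.isfinite(self.values))[0])
            raise ValueError(f"non-finite sample at index {bad}")

    @property
    def n(self) -> int:
        return int(self.values.size)

    def __len__(self) -> int:
        return self.n

    @property
    def dt_s(self) -> float:
        return 1.0 / self.fs_hz

    @property
    def duration_s(self) -> float:
        return self.n / self.fs_hz

    def time(self) -> np.ndarray:
        """Sample times in seconds, starting at ``t0_s``."""
        return self.t0_s + np.arange(self.n) / self.fs_hz

    def slice_samples(self, start: int, stop: int) -> "TimeSeries":
        """Sub-series covering sample indices ``[start, stop)``."""
        if not (0 <= start <= stop <= self.n):
            raise ValueError(f"slice [{start}, {stop}) out of range for n={self.n}")
        return TimeSeries(
            self.values[start:stop].copy(),
            self.fs_hz,
            t0_s=self.t0_s + start / self.fs_hz,
            channel=self.channel,
        )
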