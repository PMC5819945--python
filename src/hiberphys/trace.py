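"""Regularly sampled temperature series and grid alignment.

A :class:`TemperatureTrace` is the common container for the three logger
streams handled by this package: nest temperature (T_nest, 1-min nominal
interval), ambient temperature (T_a, 30-min nominal interval) and implanted
body temperature (T_b, 1-min nominal interval, 0.5 °C resolution).
Timestamps are minutes since the start of the recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VALID_SOURCES = ("nest", "ambient", "body")


@dataclass(frozen=True)
class TemperatureTrace:
    """A regularly sampled temperature series.

    Parameters
    ----------
    timestamps : ndarray
        Minutes since the start of the recording, strictly increasing.
    values : ndarray
        Temperatures in °C, finite.
    source : str
        One of ``nest``, ``ambient``, ``body``.
    sampling_interval : float
        Nominal sampling interval in minutes.
    """

    timestamps: np.ndarray
    values: np.ndarray
    source: str
    sampling_interval: float = field(default=1.0)

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        vs = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "values", vs)
        if ts.ndim != 1 or vs.ndim != 1 or ts.shape != vs.shape:
            raise ValueError("timestamps and values must be 1-d arrays of equal length")
        if ts.size < 2:
            raise ValueError("a trace needs at least two samples")
        if np.any(np.diff(ts) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(vs)):
            raise ValueError("temperature values must be finite")
        if self.source not in VALID_SOURCES:
            raise ValueError(f"source must be one of {VALID_SOURCES}, got {self.source!r}")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")

    @property
    def n(self) -> int:
        return self.timestamps.size

    @property
    def span(self) -> tuple[float, float]:
        return float(self.timestamps[0]), float(self.timestamps[-1])


def align_ambient(ambient: TemperatureTrace, target_grid: np.ndarray) -> TemperatureTrace:
    """Linearly interpolate an ambient trace onto a (finer) target grid.

    Bridges the 30-min ambient grid to the 1-min nest grid so that the
    difference T_nest − T_a is defined sample by sample.  Extrapolation is
    refused: the ambient record must cover the requested span.
    """
    grid = np.asarray(target_grid, dtype=float)
    lo, hi = ambient.span
    if grid[0] < lo or grid[-1] > hi:
        raise ValueError(
            "ambient trace spans [%g, %g] min but target grid requires [%g, %g] min"
            % (lo, hi, grid[0], grid[-1])
        )
    vals = np.interp(grid, ambient.timestamps, ambient.values)
    step = float(np.median(np.diff(grid))) if grid.size > 1 else ambient.sampling_interval
    return TemperatureTrace(grid, vals, source="ambient", sampling_interval=step)
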