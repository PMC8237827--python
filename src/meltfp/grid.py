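"""Uniform temperature grids for high-resolution melt acquisition.

HRM instruments ramp in fixed increments; every curve in one run shares a
single grid. The default grid (55–95 °C at 0.1 °C) matches a standard
post-PCR melt program.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TemperatureGrid", "DEFAULT_GRID"]


@dataclass(frozen=True)
class TemperatureGrid:
    """An inclusive uniform temperature grid ``start, start+step, ..., stop``.

    Parameters
    ----------
    start, stop : float
        Grid endpoints in °C, ``start < stop``.
    step : float
        Increment in °C, must divide ``stop - start`` evenly.
    """

    start: float = 55.0
    stop: float = 95.0
    step: float = 0.1

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError(f"grid step must be > 0, got {self.step}")
        if self.start >= self.stop:
            raise ValueError(
                f"grid start must be below stop, got [{self.start}, {self.stop}]"
            )
        n = (self.stop - self.start) / self.step
        if abs(n - round(n)) > 1e-6:
            raise ValueError(
                f"(stop - start)/step = {n} is not an integer count"
            )

    @property
    def n_points(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1

    def temperatures(self) -> np.ndarray:
        """Grid temperatures as a float array (length ``n_points``)."""
        return self.start + self.step * np.arange(self.n_points)

    def contains(self, t: float, strict: bool = False) -> bool:
        """Whether ``t`` lies on the grid span (strictly inside if ``strict``)."""
        if strict:
            return self.start < t < self.stop
        return self.start <= t <= self.stop

    @classmethod
    def from_temperatures(cls, temps: np.ndarray, rtol: float = 1e-6) -> "TemperatureGrid":
        """Infer the grid from an observed temperature vector.

        Raises ``ValueError`` if the vector is not uniformly spaced.
        """
        temps = np.asarray(temps, dtype=float)
        if temps.ndim != 1 or temps.size < 2:
            raise ValueError("need a 1-D temperature vector with >= 2 points")
        diffs = np.diff(temps)
        step = float(np.median(diffs))
        if step <= 0 or not np.allclose(diffs, step, rtol=rtol, atol=step * 1e-3):
            raise ValueError("temperature vector is not a uniform ascending grid")
        return cls(start=float(temps[0]), stop=float(temps[-1]), step=step)


#: The instrument default: 55–95 °C in 0.1 °C increments (401 points).
DEFAULT_GRID = TemperatureGrid()
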