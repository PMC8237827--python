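"""Raw melt curve → melting fingerprint.

The processing chain mirrors what HRM analysis software does after a melt
run:

1. **Normalization** — fluorescence is rescaled by an affine map so that the
   mean over a pre-melt window is 1 and the mean over a post-melt window is
   0, removing well-to-well baseline and gain differences.
2. **Derivative** — the negative derivative −dF/dT is estimated with a
   Savitzky–Golay smoothing-differentiation filter; each resolvable duplex
   population appears as a peak.
3. **Peak calling** — local maxima passing prominence / height / separation
   filters become melting peaks; the peak apex temperature (Tm) is refined
   below the grid resolution by 3-point parabolic interpolation.

The ordered list of peaks for one primer is the *melting fingerprint*, the
unit of comparison for species identification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks, peak_widths, savgol_filter

from .grid import TemperatureGrid

__all__ = [
    "MeltCurve",
    "NormalizedCurve",
    "DerivativeCurve",
    "MeltPeak",
    "MeltFingerprint",
    "ProcessingConfig",
    "DegenerateCurveError",
    "normalize_curve",
    "derivative_curve",
    "call_peaks",
    "extract_fingerprint",
]


class DegenerateCurveError(ValueError):
    """Raised when a curve has no dynamic range between the melt regions."""


@dataclass(frozen=True)
class MeltCurve:
    """Raw fluorescence F versus temperature T for one well and one primer."""

    id: str
    primer: str
    temperatures: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "fluorescence", f)
        if t.shape != f.shape or t.ndim != 1:
            raise ValueError(f"curve {self.id!r}: temperature/fluorescence shape mismatch")
        if t.size < 50:
            raise ValueError(f"curve {self.id!r}: need >= 50 grid points, got {t.size}")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(f))):
            raise ValueError(f"curve {self.id!r}: non-finite values")

    @property
    def grid(self) -> TemperatureGrid:
        return TemperatureGrid.from_temperatures(self.temperatures)


@dataclass(frozen=True)
class NormalizedCurve:
    """Dimensionless melt curve: pre-melt region ≈ 1, post-melt region ≈ 0."""

    id: str
    primer: str
    temperatures: np.ndarray
    values: np.ndarray


@dataclass(frozen=True)
class DerivativeCurve:
    """−d(normalized F)/dT on the interior of the grid, per °C."""

    id: str
    primer: str
    temperatures: np.ndarray
    values: np.ndarray

    @property
    def step(self) -> float:
        return float(self.temperatures[1] - self.temperatures[0])


@dataclass(frozen=True)
class MeltPeak:
    """One melting peak: apex temperature (Tm) and shape descriptors."""

    tm: float
    height: float
    prominence: float
    width: float


@dataclass(frozen=True)
class MeltFingerprint:
    """Ordered melting peaks for one primer on one sample.

    A fingerprint with zero peaks is kept but flagged invalid — it cannot be
    classified.
    """

    primer: str
    peaks: tuple[MeltPeak, ...]
    source_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks", tuple(self.peaks))
        tms = [p.tm for p in self.peaks]
        if any(b <= a for a, b in zip(tms, tms[1:])):
            raise ValueError("fingerprint peaks must be strictly increasing in tm")

    @property
    def valid(self) -> bool:
        return len(self.peaks) > 0

    @property
    def tms(self) -> tuple[float, ...]:
        return tuple(p.tm for p in self.peaks)


@dataclass(frozen=True)
class ProcessingConfig:
    """Tunable parameters of the extraction chain.

    ``pre_region``/``post_region`` default to the first/last 2 °C of the
    grid. ``min_prominence`` is a fraction of the derivative maximum;
    ``min_height`` is absolute (per °C); ``min_separation`` is in °C.
    """

    pre_region: Optional[tuple[float, float]] = None
    post_region: Optional[tuple[float, float]] = None
    smooth_window: float = 1.3
    min_prominence: float = 0.05
    min_height: float = 0.02
    min_separation: float = 0.8


def _region_mask(temps: np.ndarray, region: tuple[float, float]) -> np.ndarray:
    lo, hi = region
    if lo >= hi:
        raise ValueError(f"region {region} is empty")
    if lo < temps[0] - 1e-9 or hi > temps[-1] + 1e-9:
        raise ValueError(f"region {region} lies outside the grid "
                         f"[{temps[0]:.4g}, {temps[-1]:.4g}]")
    mask = (temps >= lo - 1e-9) & (temps <= hi + 1e-9)
    if int(mask.sum()) < 5:
        raise ValueError(f"region {region} covers fewer than 5 grid points")
    return mask


def normalize_curve(
    curve: MeltCurve | NormalizedCurve,
    pre_region: Optional[tuple[float, float]] = None,
    post_region: Optional[tuple[float, float]] = None,
) -> NormalizedCurve:
    """Affine pre/post-melt normalization.

    The line through (mean pre-melt level → 1) and (mean post-melt level → 0)
    maps the whole curve; the operation is idempotent.
    """
    temps = np.asarray(curve.temperatures, dtype=float)
    values = np.asarray(
        curve.fluorescence if isinstance(curve, MeltCurve) else curve.values,
        dtype=float,
    )
    if pre_region is None:
        pre_region = (float(temps[0]), float(temps[0]) + 2.0)
    if post_region is None:
        post_region = (float(temps[-1]) - 2.0, float(temps[-1]))
    if pre_region[1] > post_region[0]:
        raise ValueError(
            f"pre-melt region {pre_region} must lie entirely below the "
            f"post-melt region {post_region}"
        )
    pre = _region_mask(temps, pre_region)
    post = _region_mask(temps, post_region)
    pre_mean = float(values[pre].mean())
    post_mean = float(values[post].mean())
    scale = pre_mean - post_mean
    if abs(scale) <= 1e-9 * max(1.0, abs(pre_mean), abs(post_mean)):
        raise DegenerateCurveError(
            f"degenerate curve {curve.id!r}: pre-melt mean equals post-melt mean"
        )
    return NormalizedCurve(
        id=curve.id,
        primer=curve.primer,
        temperatures=temps,
        values=(values - post_mean) / scale,
    )


def derivative_curve(nc: NormalizedCurve, smooth_window: float = 1.3) -> DerivativeCurve:
    """−dF/dT via a Savitzky–Golay first-derivative filter (order 3).

    ``smooth_window`` is in °C; it is converted to an odd number of grid
    points. The half-window at each end is trimmed, so the result lives on
    the interior of the grid.
    """
    temps = np.asarray(nc.temperatures, dtype=float)
    step = float(temps[1] - temps[0])
    w = int(round(smooth_window / step))
    if w < 3:
        raise ValueError(f"smooth_window {smooth_window} °C is below 3 grid steps")
    if w % 2 == 0:
        w += 1
    w = max(w, 5)  # polyorder 3 needs > 4 points
    if temps.size < w:
        raise ValueError(f"curve shorter ({temps.size}) than smoothing window ({w})")
    d = -savgol_filter(np.asarray(nc.values, dtype=float), w, polyorder=3,
                       deriv=1, delta=step)
    half = w // 2
    return DerivativeCurve(
        id=nc.id, primer=nc.primer,
        temperatures=temps[half:-half], values=d[half:-half],
    )


def _parabolic_refine(t: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-grid apex by fitting a parabola through the 3 points around i."""
    if i == 0 or i == len(y) - 1:
        return float(t[i]), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:  # not locally concave; keep the grid point
        return float(t[i]), float(y[i])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    step = float(t[1] - t[0])
    return float(t[i] + delta * step), float(y1 - 0.25 * (y0 - y2) * delta)


def call_peaks(
    dc: DerivativeCurve,
    min_prominence: float = 0.05,
    min_separation: float = 0.8,
    min_height: float = 0.02,
) -> MeltFingerprint:
    """Call melting peaks on a derivative curve.

    ``min_prominence`` is relative to the derivative maximum. Plateau maxima
    are reported at their leftmost grid point. Returns a (possibly empty)
    fingerprint; an empty one is flagged invalid rather than raising.
    """
    if min(min_prominence, min_separation, min_height) < 0:
        raise ValueError("peak-calling thresholds must be >= 0")
    t, y = dc.temperatures, np.asarray(dc.values, dtype=float)
    step = dc.step
    vmax = float(y.max(initial=0.0))
    if vmax <= 0:
        return MeltFingerprint(primer=dc.primer, peaks=(), source_id=dc.id)
    prom = max(min_prominence * vmax, 1e-12)
    distance = max(int(round(min_separation / step)), 1)
    idx, props = find_peaks(
        y, height=min_height, prominence=prom, distance=distance,
        plateau_size=(1, None),
    )
    if idx.size == 0:
        return MeltFingerprint(primer=dc.primer, peaks=(), source_id=dc.id)
    # leftmost grid point of a flat apex
    apex = props["left_edges"]
    widths = peak_widths(y, idx, rel_height=0.5)[0] * step
    peaks = []
    for k, i in enumerate(apex):
        if props["plateau_sizes"][k] > 1:   # flat apex: keep leftmost point
            tm, height = float(t[int(i)]), float(y[int(i)])
        else:
            tm, height = _parabolic_refine(t, y, int(i))
        prominence = min(float(props["prominences"][k]), height)
        peaks.append(MeltPeak(tm=tm, height=height,
                              prominence=prominence, width=float(widths[k])))
    peaks.sort(key=lambda p: p.tm)
    return MeltFingerprint(primer=dc.primer, peaks=tuple(peaks), source_id=dc.id)


def extract_fingerprint(
    curve: MeltCurve, config: ProcessingConfig = ProcessingConfig()
) -> MeltFingerprint:
    """Normalize → differentiate → call peaks, with one config object."""
    nc = normalize_curve(curve, config.pre_region, config.post_region)
    dc = derivative_curve(nc, config.smooth_window)
    return call_peaks(
        dc,
        min_prominence=config.min_prominence,
        min_separation=config.min_separation,
        min_height=config.min_height,
    )
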