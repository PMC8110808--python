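"""Spatial stiffness heatmaps and the 5-15 kPa morphogenetic band.

Sparse AFM measurements (x, y in mm; stiffness in kPa) are interpolated
piecewise-linearly on their Delaunay triangulation into a calibrated pixel
grid.  Area metrics count valid pixels: the wound area softer than a
threshold (the "under 15 kPa" measure) and the area inside the 5-15 kPa
competence band where hair placodes can form.  Soft area is related to
follicle yield by ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import QhullError

__all__ = [
    "StiffnessSample",
    "StiffnessGrid",
    "BandSpec",
    "RegressionResult",
    "interpolate_grid",
    "area_below",
    "competence_band_area",
    "regress_area_count",
]


@dataclass(frozen=True)
class StiffnessSample:
    x: float  # mm
    y: float  # mm
    stiffness: float  # kPa

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("sample coordinates must be finite")
        if not (self.stiffness > 0):
            raise ValueError("stiffness must be positive")


@dataclass(frozen=True)
class StiffnessGrid:
    """Interpolated stiffness field with spatial calibration.

    ``values[i, j]`` is the stiffness (kPa) at the pixel center
    ``(origin[0] + j * pixel_size, origin[1] + i * pixel_size)``; rows run
    along +y.  ``valid_mask`` flags pixels inside the interpolation hull.
    """

    values: np.ndarray
    origin: tuple[float, float]
    pixel_size: float
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        if not (self.pixel_size > 0):
            raise ValueError("pixel_size must be positive")
        if self.values.shape != self.valid_mask.shape:
            raise ValueError("values and valid_mask shapes differ")

    @property
    def x_coords(self) -> np.ndarray:
        return self.origin[0] + np.arange(self.values.shape[1]) * self.pixel_size

    @property
    def y_coords(self) -> np.ndarray:
        return self.origin[1] + np.arange(self.values.shape[0]) * self.pixel_size

    @property
    def valid_area(self) -> float:
        return float(self.valid_mask.sum()) * self.pixel_size ** 2


@dataclass(frozen=True)
class BandSpec:
    """Stiffness competence band, default the 5-15 kPa placode window."""

    low: float = 5.0
    high: float = 15.0

    def __post_init__(self) -> None:
        if not (0 <= self.low < self.high):
            raise ValueError("band requires 0 <= low < high")


@dataclass(frozen=True)
class RegressionResult:
    slope: float  # follicles per mm^2
    intercept: float  # follicles
    r_squared: float
    n: int
    stderr: float  # standard error of the slope

    def slope_ci95(self) -> tuple[float, float]:
        t = stats.t.ppf(0.975, self.n - 2)
        return (self.slope - t * self.stderr, self.slope + t * self.stderr)


def _as_xyz(samples) -> np.ndarray:
    if isinstance(samples, pd.DataFrame):
        return samples[["x_mm", "y_mm", "stiffness_kPa"]].to_numpy(float)
    return np.array([(s.x, s.y, s.stiffness) for s in samples], dtype=float)


def interpolate_grid(samples, pixel_size: float = 0.02) -> StiffnessGrid:
    """Delaunay piecewise-linear interpolation of sparse samples.

    ``samples`` is a sequence of :class:`StiffnessSample` or a DataFrame
    with columns ``x_mm, y_mm, stiffness_kPa``.  The grid covers the
    samples' bounding box; pixels outside the convex hull are masked.
    Exact duplicates are deduplicated; duplicate coordinates carrying
    conflicting stiffness raise.
    """
    if not (pixel_size > 0):
        raise ValueError("pixel_size must be positive")
    xyz = _as_xyz(samples)
    if xyz.shape[0] < 3:
        raise ValueError("need at least 3 samples to triangulate")
    # resolve duplicates
    seen: dict[tuple[float, float], float] = {}
    for x, y, z in xyz:
        key = (x, y)
        if key in seen and not np.isclose(seen[key], z):
            raise ValueError(f"conflicting duplicate sample at ({x:g}, {y:g}) mm")
        seen[key] = z
    pts = np.array([(x, y) for x, y in seen])
    z = np.array(list(seen.values()))
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 distinct samples")
    try:
        interp = LinearNDInterpolator(pts, z)
    except QhullError as err:
        raise ValueError("samples are collinear: cannot triangulate") from err
    if interp.tri.simplices.size == 0:  # pragma: no cover - qhull catches first
        raise ValueError("samples are collinear: cannot triangulate")

    x0, y0 = pts.min(axis=0)
    x1, y1 = pts.max(axis=0)
    nx = int(np.floor((x1 - x0) / pixel_size)) + 1
    ny = int(np.floor((y1 - y0) / pixel_size)) + 1
    xs = x0 + np.arange(nx) * pixel_size
    ys = y0 + np.arange(ny) * pixel_size
    X, Y = np.meshgrid(xs, ys)
    vals = interp(X, Y)
    mask = np.isfinite(vals)
    return StiffnessGrid(values=np.where(mask, vals, np.nan),
                         origin=(float(x0), float(y0)),
                         pixel_size=float(pixel_size), valid_mask=mask)


def area_below(grid: StiffnessGrid, threshold: float) -> float:
    """Area (mm^2) of valid pixels strictly softer than ``threshold`` kPa."""
    if not (threshold > 0):
        raise ValueError("threshold must be positive")
    sel = grid.valid_mask & (grid.values < threshold)
    return float(sel.sum()) * grid.pixel_size ** 2


def competence_band_area(grid: StiffnessGrid,
                         band: BandSpec = BandSpec()) -> tuple[np.ndarray, float]:
    """Mask and area of valid pixels inside the closed band [low, high]."""
    mask = grid.valid_mask & (grid.values >= band.low) & (grid.values <= band.high)
    return mask, float(mask.sum()) * grid.pixel_size ** 2


def regress_area_count(pairs) -> RegressionResult:
    """OLS of follicle count on soft area.

    ``pairs`` is a DataFrame with columns ``area_mm2, follicles`` or any
    (n, 2) array-like.  Requires >= 3 wounds and non-degenerate areas.
    """
    if isinstance(pairs, pd.DataFrame):
        x = pairs["area_mm2"].to_numpy(float)
        y = pairs["follicles"].to_numpy(float)
    else:
        arr = np.asarray(pairs, dtype=float)
        x, y = arr[:, 0], arr[:, 1]
    if x.size < 3:
        raise ValueError("regression needs at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate regression: all areas identical")
    if np.ptp(y) == 0:
        # flat response: zero slope and, by convention, zero explained variance
        return RegressionResult(slope=0.0, intercept=float(y[0]),
                                r_squared=0.0, n=int(x.size), stderr=0.0)
    res = stats.linregress(x, y)
    return RegressionResult(slope=float(res.slope),
                            intercept=float(res.intercept),
                            r_squared=float(res.rvalue ** 2),
                            n=int(x.size), stderr=float(res.stderr))
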