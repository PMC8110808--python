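"""Hertz spherical-indentation model and force-curve fitting.

AFM indentation of soft tissue with a spherical probe follows the Hertz
contact law

    F(h) = E / (1 - nu^2) * (4 sqrt(R) / 3) * h^(3/2)

where ``h`` is the indentation depth beyond the contact point, ``E`` the
sample Young's modulus (Pa), ``nu`` its Poisson ratio and ``R`` the probe
radius (m).  Fitting a measured force-indentation curve to this law yields
the local tissue stiffness.  All fitting is done in SI units; kPa is a
reporting convenience.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "ForceCurve",
    "HertzFit",
    "BatchSummary",
    "NoContactError",
    "hertz_force",
    "fit_hertz",
    "batch_fit",
]

#: Maximum indentation force used during acquisition; points above it are
#: excluded from the fit window.
DEFAULT_FORCE_WINDOW = 5e-9  # N


class NoContactError(ValueError):
    """Raised when a force curve carries no usable contact signal."""


@dataclass(frozen=True)
class ForceCurve:
    """One AFM indentation record.

    Parameters
    ----------
    indentation
        Probe displacement into the sample, metres, non-decreasing.
    force
        Cantilever force, newtons, same length as ``indentation``.
    R
        Probe (bead) radius in metres.
    nu
        Sample Poisson ratio; incompressible soft tissue uses 0.5.
    position
        Optional (x_mm, y_mm) location of the measurement in the wound.
    """

    indentation: np.ndarray
    force: np.ndarray
    R: float = 2.5e-6
    nu: float = 0.5
    position: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        h = np.asarray(self.indentation, dtype=float)
        f = np.asarray(self.force, dtype=float)
        object.__setattr__(self, "indentation", h)
        object.__setattr__(self, "force", f)
        if h.ndim != 1 or f.ndim != 1 or h.size != f.size:
            raise ValueError("indentation and force must be 1-D and equal length")
        if h.size < 10:
            raise ValueError("force curve needs at least 10 points")
        if np.any(np.diff(h) < 0):
            raise ValueError("indentation must be non-decreasing")
        if not (self.R > 0):
            raise ValueError("R must be positive")
        if not (0 <= self.nu < 1):
            raise ValueError("nu must lie in [0, 1)")

    def __len__(self) -> int:
        return self.indentation.size


@dataclass(frozen=True)
class HertzFit:
    """Result of fitting one curve: modulus, contact point, diagnostics."""

    E: float  # Pa
    h0: float  # m
    rss: float  # N^2
    n_used: int
    converged: bool

    @property
    def E_kPa(self) -> float:
        return self.E / 1e3


@dataclass(frozen=True)
class BatchSummary:
    mean_kPa: float
    sem_kPa: float
    n: int
    n_failed: int


def hertz_force(h, E: float, R: float, nu: float = 0.5):
    """Hertz force (N) at indentation depth ``h`` (m), elementwise.

    Raises for negative depths or the singular ``nu = 1``.
    """
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("indentation depth h must be non-negative")
    if not (E > 0):
        raise ValueError("E must be positive")
    if not (R > 0):
        raise ValueError("R must be positive")
    if not (0 <= nu < 1):
        raise ValueError("nu must lie in [0, 1); nu = 1 is singular")
    k = hertz_prefactor(E, R, nu)
    out = k * h ** 1.5
    return out if out.ndim else float(out)


def hertz_prefactor(E: float, R: float, nu: float) -> float:
    """Stiffness prefactor k such that F = k * h^(3/2)."""
    return E / (1.0 - nu ** 2) * 4.0 * np.sqrt(R) / 3.0


def modulus_from_prefactor(k: float, R: float, nu: float) -> float:
    return k * 3.0 * (1.0 - nu ** 2) / (4.0 * np.sqrt(R))


def _profiled_fit(h: np.ndarray, f: np.ndarray, h0: float,
                  f_max: float) -> tuple[float, float, int]:
    """Best prefactor and RSS for a fixed contact point.

    The pre-contact baseline (median force at depths <= h0) is subtracted
    before fitting; the window keeps post-contact points with baseline-
    corrected force <= f_max.  Returns (k, rss, n_used); k < 0 is possible
    for pathological data and handled by the caller.
    """
    pre = f[h <= h0]
    baseline = float(np.median(pre)) if pre.size else 0.0
    fc = f - baseline
    sel = (h > h0) & (fc <= f_max)
    n = int(sel.sum())
    if n < 2:
        return 0.0, np.inf, n
    g = (h[sel] - h0) ** 1.5
    denom = float(g @ g)
    if denom == 0.0:
        return 0.0, np.inf, n
    k = float(fc[sel] @ g) / denom
    r = fc[sel] - k * g
    return k, float(r @ r), n


def fit_hertz(curve: ForceCurve, f_max: float = DEFAULT_FORCE_WINDOW,
              n_h0_grid: int = 60) -> HertzFit:
    """Fit (E, h0) to a force curve by least squares on F = k (h-h0)^{3/2}.

    The contact point is found by a coarse grid search (robust against the
    shallow 3/2-power residual landscape) followed by bounded scalar
    refinement; the modulus follows in closed form from the profiled
    linear subproblem.  Only points at or below ``f_max`` (default 5 nN,
    the acquisition trigger force) enter the fit.

    Raises
    ------
    NoContactError
        If the curve is flat (no force rise above the noise floor) or force
        does not increase across the fit window.
    """
    h = curve.indentation
    f = curve.force
    span = float(f.max() - f.min())
    noise = float(np.median(np.abs(f - np.median(f)))) * 1.4826
    if span <= 0 or span < 5 * noise and span < 1e-12:
        raise NoContactError("force curve is flat: no contact detected")
    # force must, on the whole, rise with depth
    half = h.size // 2
    if np.median(f[half:]) <= np.median(f[:half]):
        raise NoContactError("force does not increase with indentation")

    h_lo, h_hi = float(h[0]), float(h[0] + 0.8 * (h[-1] - h[0]))
    grid = np.linspace(h_lo, h_hi, n_h0_grid)
    rss_grid = np.array([_profiled_fit(h, f, h0, f_max)[1] for h0 in grid])
    if not np.isfinite(rss_grid).any():
        return HertzFit(E=np.nan, h0=np.nan, rss=np.inf, n_used=0, converged=False)
    i = int(np.nanargmin(rss_grid))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]

    def objective(h0: float) -> float:
        return _profiled_fit(h, f, h0, f_max)[1]

    try:
        res = optimize.minimize_scalar(
            objective, bounds=(lo, hi), method="bounded",
            options={"xatol": max((hi - lo) * 1e-9, 1e-16)})
        candidates = [float(res.x), float(grid[i]), float(lo), float(hi)]
    except Exception:
        candidates = [float(grid[i]), float(lo), float(hi)]
    h0_hat = min(candidates, key=objective)
    k, rss, n_used = _profiled_fit(h, f, h0_hat, f_max)
    if not np.isfinite(rss) or k <= 0:
        return HertzFit(E=np.nan, h0=h0_hat, rss=np.inf, n_used=n_used,
                        converged=False)
    E = modulus_from_prefactor(k, curve.R, curve.nu)
    return HertzFit(E=E, h0=h0_hat, rss=rss, n_used=n_used, converged=True)


def batch_fit(curves: Sequence[ForceCurve],
              f_max: float = DEFAULT_FORCE_WINDOW) -> tuple[list[HertzFit], BatchSummary]:
    """Fit every curve; summarise mean +/- SEM (kPa) over converged fits."""
    if len(curves) == 0:
        raise ValueError("batch_fit needs at least one curve")
    fits: list[HertzFit] = []
    for c in curves:
        try:
            fits.append(fit_hertz(c, f_max=f_max))
        except NoContactError:
            fits.append(HertzFit(E=np.nan, h0=np.nan, rss=np.inf, n_used=0,
                                 converged=False))
    ok = [ft.E_kPa for ft in fits if ft.converged]
    if not ok:
        raise ValueError("no curve produced a converged Hertz fit")
    arr = np.array(ok)
    sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
    summary = BatchSummary(mean_kPa=float(arr.mean()), sem_kPa=sem,
                           n=arr.size, n_failed=len(fits) - arr.size)
    return fits, summary
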