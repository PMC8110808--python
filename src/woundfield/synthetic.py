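"""Synthetic data generators for the whole analysis chain.

Three generators, one per downstream stage:

* noisy Hertz-shaped AFM force curves (``gen_force_curve``),
* radially structured wound stiffness landscapes with sparse AFM-style
  sampling (``gen_stiffness_landscape``), and
* linear soft-area -> follicle-count datasets (``gen_follicle_dataset``).

Landscape presets encode the measured wound regimes: laboratory-mouse
wounds with a soft center (~10.5 kPa) and stiff margin (~28 kPa) at
post-wound day 14, spiny-mouse wounds that are uniformly soft (center
below 5 kPa, margin below 15 kPa), Blebbistatin-softened wounds, and a
ring-shaped soft annulus.  All generators are deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
import pandas as pd

from .hertz import ForceCurve, hertz_prefactor

__all__ = [
    "CurveGenConfig",
    "LandscapeConfig",
    "FollicleModelConfig",
    "LANDSCAPE_PRESETS",
    "gen_force_curve",
    "gen_stiffness_landscape",
    "gen_follicle_dataset",
    "landscape_field",
]

# Regression slopes (follicles per mm^2 of wound bed softer than 15 kPa)
# for the control/Blebbistatin group and the Twist1-perturbed group.
SLOPE_CONTROL = 12.812
SLOPE_PERTURBED = 1.6828


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"{name}: {msg}")


@dataclass(frozen=True)
class CurveGenConfig:
    """Parameters of one synthetic Hertz force curve.

    ``E_true`` is the ground-truth Young's modulus (Pa); ``R`` the probe
    radius (m, default 2.5 um bead); ``h0`` the contact-point offset (m);
    ``h_max`` the deepest indentation (m); ``noise_sd`` additive Gaussian
    force noise (N) and ``noise_fraction`` optional multiplicative noise
    (fraction of the instantaneous force).
    """

    E_true: float = 10.5e3
    R: float = 2.5e-6
    nu: float = 0.5
    h0: float = 0.0
    h_max: float = 5e-7
    n_points: int = 200
    noise_sd: float = 0.0
    noise_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.E_true > 0, "E_true", "must be > 0")
        _require(self.R > 0, "R", "must be > 0")
        _require(0 <= self.nu < 1, "nu", "must lie in [0, 1)")
        _require(self.h0 >= 0, "h0", "must be >= 0")
        _require(self.h_max > self.h0, "h_max", "must exceed h0")
        _require(self.n_points >= 10, "n_points", "must be >= 10")
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        _require(self.noise_fraction >= 0, "noise_fraction", "must be >= 0")

    @classmethod
    def for_max_force(cls, E_true: float, f_max: float = 5e-9,
                      overshoot: float = 1.2, **kw) -> "CurveGenConfig":
        """Configure ``h_max`` so the curve tops out near the trigger force.

        Mirrors acquisition, where the ramp stops at ~5 nN: the deepest
        point reaches ``overshoot * f_max``.
        """
        cfg = cls(E_true=E_true, h_max=1.0, **{k: v for k, v in kw.items()
                                               if k != "h_max"})
        k = hertz_prefactor(E_true, cfg.R, cfg.nu)
        depth = (overshoot * f_max / k) ** (2.0 / 3.0)
        return replace(cfg, h_max=cfg.h0 + depth)


def gen_force_curve(config: CurveGenConfig) -> ForceCurve:
    """Noisy Hertz curve: zero force before contact, power law after."""
    rng = np.random.default_rng(config.seed)
    h = np.linspace(0.0, config.h_max, config.n_points)
    k = hertz_prefactor(config.E_true, config.R, config.nu)
    depth = np.clip(h - config.h0, 0.0, None)
    f = k * depth ** 1.5
    if config.noise_fraction > 0:
        f = f * (1.0 + config.noise_fraction * rng.standard_normal(f.size))
    if config.noise_sd > 0:
        f = f + config.noise_sd * rng.standard_normal(f.size)
    return ForceCurve(indentation=h, force=f, R=config.R, nu=config.nu)


# ---------------------------------------------------------------------------
# Stiffness landscapes
# ---------------------------------------------------------------------------

#: Preset wound profiles: (center kPa, margin kPa, halfwidth mm, transition mm).
#: Laboratory PWD14 uses the measured 10.5 / 28.0 kPa pair; spiny PWD14 keeps
#: the whole bed below 15 kPa with a sub-5 kPa center.  PWD21 and Blebbistatin
#: presets are qualitative (stiffening over time / global softening).
LANDSCAPE_PRESETS: dict[str, dict] = {
    "lab_pwd14": dict(center_stiffness=10.5, margin_stiffness=28.0,
                      wound_halfwidth=5.0, transition_width=1.5),
    "lab_pwd21": dict(center_stiffness=18.0, margin_stiffness=35.0,
                      wound_halfwidth=5.0, transition_width=1.5),
    "lab_bleb": dict(center_stiffness=7.0, margin_stiffness=20.0,
                     wound_halfwidth=5.0, transition_width=2.0),
    "spiny_pwd14": dict(center_stiffness=3.0, margin_stiffness=12.0,
                        wound_halfwidth=7.5, transition_width=2.0),
    "spiny_pwd21": dict(center_stiffness=6.0, margin_stiffness=14.0,
                        wound_halfwidth=7.5, transition_width=2.0),
    "ring": dict(center_stiffness=8.0, margin_stiffness=25.0,
                 wound_halfwidth=5.0, transition_width=2.0),
    "uniform": dict(center_stiffness=10.0, margin_stiffness=10.0,
                    wound_halfwidth=5.0, transition_width=1.5),
}


@dataclass(frozen=True)
class LandscapeConfig:
    """Radial wound-stiffness landscape (kPa over mm coordinates)."""

    profile: str = "lab_pwd14"
    wound_halfwidth: float = 5.0
    center_stiffness: float = 10.5
    margin_stiffness: float = 28.0
    transition_width: float = 1.5
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.profile not in LANDSCAPE_PRESETS:
            raise ValueError(
                f"unknown profile {self.profile!r}; valid profiles: "
                + ", ".join(sorted(LANDSCAPE_PRESETS)))
        _require(self.wound_halfwidth > 0, "wound_halfwidth", "must be > 0")
        _require(self.center_stiffness > 0, "center_stiffness", "must be > 0")
        _require(self.margin_stiffness > 0, "margin_stiffness", "must be > 0")
        _require(self.transition_width > 0, "transition_width", "must be > 0")
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")

    @classmethod
    def preset(cls, profile: str, noise_sd: float = 0.0,
               seed: int = 0) -> "LandscapeConfig":
        if profile not in LANDSCAPE_PRESETS:
            raise ValueError(
                f"unknown profile {profile!r}; valid profiles: "
                + ", ".join(sorted(LANDSCAPE_PRESETS)))
        return cls(profile=profile, noise_sd=noise_sd, seed=seed,
                   **LANDSCAPE_PRESETS[profile])


def _smoothstep(t: np.ndarray) -> np.ndarray:
    """Cosine smoothstep: 0 for t<=0, 1 for t>=1, C1 in between."""
    t = np.clip(t, 0.0, 1.0)
    return 0.5 - 0.5 * np.cos(np.pi * t)


def landscape_field(config: LandscapeConfig) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
    """Continuous noiseless stiffness field K(x, y) in kPa (x, y in mm)."""
    c = config.center_stiffness
    m = config.margin_stiffness
    hw = config.wound_halfwidth
    tw = config.transition_width

    if config.profile == "uniform":
        def field(x, y):
            r = np.hypot(np.asarray(x, float), np.asarray(y, float))
            return np.full_like(r, c)
    elif config.profile == "ring":
        # stiff plateau with a soft Gaussian annulus at 0.7 * halfwidth
        r0 = 0.7 * hw

        def field(x, y):
            r = np.hypot(np.asarray(x, float), np.asarray(y, float))
            return m - (m - c) * np.exp(-(((r - r0) / tw) ** 2))
    else:
        def field(x, y):
            r = np.hypot(np.asarray(x, float), np.asarray(y, float))
            return c + (m - c) * _smoothstep((r - (hw - tw / 2.0)) / tw)
    return field


def _sample_layout(hw: float) -> np.ndarray:
    """AFM-style layout: cross transect through the center plus margin ring.

    Seven stations per arm out to 1.4x the wound halfwidth (the traverse
    "across the wound") and twelve points on the margin ring.
    """
    rs = np.linspace(0.2, 1.4, 7) * hw
    pts = [(0.0, 0.0)]
    for r in rs:
        pts += [(r, 0.0), (-r, 0.0), (0.0, r), (0.0, -r)]
    ring_r = 1.4 * hw
    ang = np.linspace(0, 2 * np.pi, 13)[:-1] + np.pi / 12
    pts += [(ring_r * np.cos(a), ring_r * np.sin(a)) for a in ang]
    return np.array(pts)


def gen_stiffness_landscape(config: LandscapeConfig):
    """Continuous field plus noisy sparse samples on the AFM layout.

    Returns ``(field, samples)`` where ``field(x, y)`` evaluates the
    noiseless stiffness (kPa) and ``samples`` is a DataFrame with columns
    ``x_mm, y_mm, stiffness_kPa``.  Sampled stiffness is floored at
    0.1 kPa so noise cannot produce non-physical values.
    """
    field = landscape_field(config)
    pts = _sample_layout(config.wound_halfwidth)
    rng = np.random.default_rng(config.seed)
    z = field(pts[:, 0], pts[:, 1])
    if config.noise_sd > 0:
        z = z + config.noise_sd * rng.standard_normal(z.size)
    z = np.clip(z, 0.1, None)
    samples = pd.DataFrame({"x_mm": pts[:, 0], "y_mm": pts[:, 1],
                            "stiffness_kPa": z})
    return field, samples


# ---------------------------------------------------------------------------
# Soft area -> follicle counts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FollicleModelConfig:
    """Linear soft-area -> follicle-count model with Gaussian count noise."""

    slope: float = SLOPE_CONTROL
    intercept: float = 0.0
    noise_sd: float = 0.0
    n_wounds: int = 20
    area_range: tuple[float, float] = (0.5, 4.0)
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_wounds >= 3, "n_wounds",
                 "regression needs >= 3 wounds")
        _require(self.area_range[0] < self.area_range[1], "area_range",
                 "min must be < max")
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")


def gen_follicle_dataset(config: FollicleModelConfig) -> pd.DataFrame:
    """Table of (area_mm2, follicles).

    With noise, counts are floored at 0 and rounded to whole follicles;
    the noiseless table is left exactly on the line so it satisfies the
    generating model identically.
    """
    rng = np.random.default_rng(config.seed)
    areas = np.linspace(*config.area_range, config.n_wounds)
    counts = config.slope * areas + config.intercept
    if config.noise_sd > 0:
        counts = counts + config.noise_sd * rng.standard_normal(counts.size)
        counts = np.round(np.clip(counts, 0.0, None))
    return pd.DataFrame({"area_mm2": areas, "follicles": counts})
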