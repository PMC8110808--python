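"""End-to-end scenario runs: generate -> fit -> map -> simulate -> classify.

A scenario bundles a wound-stiffness landscape preset with the Turing-model
defaults and runs the full chain, persisting each stage's artifact and a
JSON + text report.  The packaged demos reproduce the observed competence
topologies: laboratory wounds pattern centrally, spiny-mouse wounds
peripherally, and a ring landscape yields a concentric competent annulus.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import io as wio
from .hertz import batch_fit
from .patterns import classify_topology, detect_spots
from .stiffness_map import BandSpec, competence_band_area, area_below, \
    interpolate_grid, regress_area_count
from .synthetic import (CurveGenConfig, FollicleModelConfig, LandscapeConfig,
                        gen_follicle_dataset, gen_force_curve,
                        gen_stiffness_landscape)
from .turing import (TuringParams, explicit_dt_bound,
                     simulate_from_measured_stiffness)

__all__ = ["RunConfig", "run_scenario", "validate_config", "SCENARIOS"]

log = logging.getLogger("woundfield")

SCENARIOS = {
    "lab": "lab_pwd14",
    "spiny": "spiny_pwd14",
    "bleb": "lab_bleb",
    "ring": "ring",
    "custom": None,
}


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration of one pipeline run."""

    scenario: str = "lab"
    landscape: LandscapeConfig = field(
        default_factory=lambda: LandscapeConfig.preset("lab_pwd14"))
    turing: TuringParams = field(default_factory=TuringParams)
    band: BandSpec = field(default_factory=BandSpec)
    follicles: FollicleModelConfig = field(default_factory=FollicleModelConfig)
    n_curves_per_site: int = 5
    curve_noise_fraction: float = 0.02
    landscape_noise_sd: float = 0.3
    pixel_size_mm: float = 0.05
    min_spot_area: int = 2
    master_seed: int = 0
    output_dir: str = "woundfield_run"


def _seeds(master: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(master).generate_state(n)]


def scenario_config(scenario: str, master_seed: int = 0,
                    output_dir: str | None = None, **overrides) -> RunConfig:
    """Resolve a scenario preset into a full RunConfig."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; valid scenarios: "
                         + ", ".join(sorted(SCENARIOS)))
    profile = SCENARIOS[scenario]
    cfg = RunConfig(scenario=scenario, master_seed=master_seed,
                    output_dir=output_dir or f"woundfield_{scenario}",
                    **overrides)
    if profile is not None and "landscape" not in overrides:
        seed_land = _seeds(master_seed, 4)[0]
        cfg = replace(cfg, landscape=LandscapeConfig.preset(
            profile, noise_sd=cfg.landscape_noise_sd, seed=seed_land))
    return cfg


def validate_config(path) -> RunConfig:
    """Load a JSON (or YAML) run config, fill defaults, report violations.

    The document mirrors RunConfig: top-level scalars plus optional
    ``landscape``, ``turing``, ``band`` and ``follicles`` sections.
    Raises ValueError listing each offending field path.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as err:
        raise IOError(f"cannot read config {path}: {err}") from err
    try:
        if path.suffix in (".yaml", ".yml"):
            import yaml
            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
    except Exception as err:
        raise IOError(f"cannot parse config {path}: {err}") from err
    if not isinstance(raw, dict):
        raise IOError(f"config {path} must contain a mapping")

    errors: list[str] = []
    scenario = raw.get("scenario", "lab")
    if scenario not in SCENARIOS:
        errors.append(f"scenario: unknown {scenario!r}; valid: "
                      + ", ".join(sorted(SCENARIOS)))

    def build(cls, section, name):
        data = raw.get(section, {})
        if not isinstance(data, dict):
            errors.append(f"{section}: must be an object")
            return None
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - allowed
        for u in sorted(unknown):
            errors.append(f"{section}.{u}: unknown field")
        try:
            return cls(**{k: v for k, v in data.items() if k in allowed})
        except (TypeError, ValueError) as err:
            errors.append(f"{section}: {err}")
            return None

    landscape = build(LandscapeConfig, "landscape", "landscape")
    turing = build(TuringParams, "turing", "turing")
    band = build(BandSpec, "band", "band")
    follicles = build(FollicleModelConfig, "follicles", "follicles")
    if turing is not None and turing.scheme == "explicit" \
            and turing.dt > explicit_dt_bound(turing):
        errors.append(f"turing.dt: {turing.dt:g} violates stability bound "
                      f"{explicit_dt_bound(turing):g}")
    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))

    kw = {}
    for key in ("n_curves_per_site", "curve_noise_fraction",
                "landscape_noise_sd", "pixel_size_mm", "min_spot_area",
                "master_seed", "output_dir"):
        if key in raw:
            kw[key] = raw[key]
    cfg = scenario_config(scenario, **kw) if scenario in SCENARIOS else None
    if landscape is not None and "landscape" in raw:
        cfg = replace(cfg, landscape=landscape)
    if turing is not None and "turing" in raw:
        cfg = replace(cfg, turing=turing)
    if band is not None and "band" in raw:
        cfg = replace(cfg, band=band)
    if follicles is not None and "follicles" in raw:
        cfg = replace(cfg, follicles=follicles)
    return cfg


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(wio.config_to_dict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_scenario(cfg: RunConfig) -> dict:
    """Execute every stage, persist artifacts, return the run report."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _seeds(cfg.master_seed, 8)
    report: dict = {"scenario": cfg.scenario,
                    "config_hash": _config_hash(cfg),
                    "master_seed": cfg.master_seed,
                    "stages": {}}
    t0 = time.time()

    def stage(name):
        log.info("stage %s ...", name)
        return time.time()

    try:
        # 1. synthetic landscape + AFM sampling
        t = stage("landscape")
        field_fn, samples = gen_stiffness_landscape(cfg.landscape)
        wio.write_samples_csv(samples, out / "samples.csv", cfg.landscape)
        report["stages"]["landscape"] = {
            "profile": cfg.landscape.profile, "n_samples": len(samples),
            "elapsed_s": round(time.time() - t, 2)}

        # 2. force curves at wound center and margin + Hertz fits
        t = stage("afm_fits")
        fits_summary = {}
        for k, (site, E_kPa) in enumerate(
                (("center", cfg.landscape.center_stiffness),
                 ("margin", cfg.landscape.margin_stiffness))):
            curves = []
            for i, seed in enumerate(_seeds(seeds[1] + k,
                                            cfg.n_curves_per_site)):
                cc = CurveGenConfig.for_max_force(
                    E_true=E_kPa * 1e3, seed=seed,
                    noise_fraction=cfg.curve_noise_fraction)
                curve = gen_force_curve(cc)
                curves.append(curve)
                wio.write_curve_csv(curve, out / f"curve_{site}_{i}.csv", cc)
            _, summary = batch_fit(curves)
            fits_summary[site] = {"mean_kPa": summary.mean_kPa,
                                  "sem_kPa": summary.sem_kPa,
                                  "n": summary.n,
                                  "true_kPa": E_kPa}
        report["stages"]["afm_fits"] = {**fits_summary,
                                        "elapsed_s": round(time.time() - t, 2)}

        # 3. stiffness heatmap + areas
        t = stage("stiffness_map")
        grid = interpolate_grid(samples, pixel_size=cfg.pixel_size_mm)
        wio.write_grid(grid, out / "stiffness_grid")
        _, band_area = competence_band_area(grid, cfg.band)
        soft_area = area_below(grid, cfg.band.high)
        report["stages"]["stiffness_map"] = {
            "soft_area_mm2": soft_area, "band_area_mm2": band_area,
            "valid_area_mm2": grid.valid_area,
            "elapsed_s": round(time.time() - t, 2)}

        # 4. soft-area -> follicle regression
        t = stage("regression")
        follicles = replace(cfg.follicles, seed=seeds[2])
        table = gen_follicle_dataset(follicles)
        wio.write_samples_csv(table, out / "follicles.csv", follicles)
        reg = regress_area_count(table)
        report["stages"]["regression"] = {
            "slope": reg.slope, "intercept": reg.intercept,
            "r_squared": reg.r_squared, "n": reg.n,
            "true_slope": follicles.slope,
            "elapsed_s": round(time.time() - t, 2)}

        # 5. stiffness-driven Turing simulation
        t = stage("simulation")
        state = simulate_from_measured_stiffness(grid, cfg.turing,
                                                 seed=seeds[3])
        wio.write_field_csv(state.u, out / "u.csv")
        wio.write_field_csv(state.E, out / "E.csv")
        report["stages"]["simulation"] = {
            "t_final": state.t, "converged": state.converged,
            "residual": state.residual, "u_max": float(state.u.max()),
            "E_max": float(state.E.max()),
            "elapsed_s": round(time.time() - t, 2)}

        # 6. spot detection + topology
        t = stage("topology")
        spots = detect_spots(state.u, threshold=cfg.turing.u_threshold,
                             min_area=cfg.min_spot_area,
                             half_width=cfg.turing.half_width)
        wio.write_spots_csv(spots, out / "spots.csv")
        topo = classify_topology(spots, sigma=cfg.turing.sigma)
        report["stages"]["topology"] = {
            "label": topo.label, "n_spots": spots.n_spots,
            "central_density": topo.central_density,
            "peripheral_density": topo.peripheral_density,
            "ratio": topo.ratio,
            "radial_counts": topo.radial_counts.tolist(),
            "elapsed_s": round(time.time() - t, 2)}
    except Exception as err:
        done = list(report["stages"])
        stage_name = ["landscape", "afm_fits", "stiffness_map", "regression",
                      "simulation", "topology"][len(done)] \
            if len(done) < 6 else "unknown"
        raise RuntimeError(f"stage '{stage_name}' failed: {err}") from err

    report["topology_label"] = report["stages"]["topology"]["label"]
    report["total_elapsed_s"] = round(time.time() - t0, 2)
    (out / "report.json").write_text(json.dumps(report, indent=2))
    (out / "report.txt").write_text(_format_report(report))
    return report


def _format_report(report: dict) -> str:
    lines = [f"woundfield scenario: {report['scenario']}",
             f"config hash: {report['config_hash']}",
             f"master seed: {report['master_seed']}", ""]
    fits = report["stages"]["afm_fits"]
    for site in ("center", "margin"):
        s = fits[site]
        lines.append(f"AFM {site}: {s['mean_kPa']:.2f} +/- {s['sem_kPa']:.2f} "
                     f"kPa (n={s['n']}, true {s['true_kPa']:.1f})")
    sm = report["stages"]["stiffness_map"]
    lines.append(f"area below {15.0:.0f} kPa: {sm['soft_area_mm2']:.2f} mm^2; "
                 f"5-15 kPa band: {sm['band_area_mm2']:.2f} mm^2")
    rg = report["stages"]["regression"]
    lines.append(f"regression: slope {rg['slope']:.3f} follicles/mm^2 "
                 f"(true {rg['true_slope']:.3f}), R^2 {rg['r_squared']:.3f}")
    tp = report["stages"]["topology"]
    lines.append(f"spots: {tp['n_spots']}; topology: {tp['label']} "
                 f"(central/peripheral density ratio {tp['ratio']:.2f})")
    return "\n".join(lines) + "\n"
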