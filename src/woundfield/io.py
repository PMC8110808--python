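"""Plain-text readers and writers for the pipeline's artifacts.

Every writer emits a JSON sidecar (``<file>.meta.json``) recording the
generating configuration and seed so artifacts are self-describing.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .hertz import ForceCurve
from .stiffness_map import StiffnessGrid

__all__ = [
    "write_sidecar",
    "write_curve_csv",
    "read_curve_csv",
    "write_samples_csv",
    "read_samples_csv",
    "write_grid",
    "read_grid",
    "write_field_csv",
    "read_field_csv",
    "write_spots_csv",
    "config_to_dict",
]


def config_to_dict(config) -> dict:
    if dataclasses.is_dataclass(config):
        return dataclasses.asdict(config)
    return dict(config)


def write_sidecar(path: Path, config=None, seed=None, **extra) -> None:
    meta = dict(extra)
    if config is not None:
        meta["config"] = config_to_dict(config)
    if seed is not None:
        meta["seed"] = int(seed)
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2,
                                                         default=_jsonable))
    return None


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_curve_csv(curve: ForceCurve, path, config=None) -> None:
    path = Path(path)
    pd.DataFrame({"indentation_m": curve.indentation,
                  "force_N": curve.force}).to_csv(path, index=False)
    write_sidecar(path, config=config, R=curve.R, nu=curve.nu,
                  position=curve.position)


def read_curve_csv(path, R: float = 2.5e-6, nu: float = 0.5) -> ForceCurve:
    path = Path(path)
    df = pd.read_csv(path)
    meta_path = Path(str(path) + ".meta.json")
    position = None
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        R = meta.get("R", R)
        nu = meta.get("nu", nu)
        position = meta.get("position")
        if position is not None:
            position = tuple(position)
    return ForceCurve(indentation=df["indentation_m"].to_numpy(),
                      force=df["force_N"].to_numpy(), R=R, nu=nu,
                      position=position)


def write_samples_csv(samples: pd.DataFrame, path, config=None) -> None:
    path = Path(path)
    samples.to_csv(path, index=False)
    write_sidecar(path, config=config)


def read_samples_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"x_mm", "y_mm", "stiffness_kPa"}
    if not required.issubset(df.columns):
        raise ValueError(f"samples CSV must have columns {sorted(required)}")
    return df


def write_grid(grid: StiffnessGrid, path_base) -> None:
    """Grid as CSV matrix plus JSON header (origin, pixel size)."""
    base = Path(path_base)
    np.savetxt(base.with_suffix(".csv"), grid.values, delimiter=",", fmt="%.6g")
    header = {"origin_mm": list(grid.origin), "pixel_size_mm": grid.pixel_size,
              "shape": list(grid.values.shape)}
    base.with_suffix(".json").write_text(json.dumps(header, indent=2))


def read_grid(path_base) -> StiffnessGrid:
    base = Path(path_base)
    values = np.loadtxt(base.with_suffix(".csv"), delimiter=",", ndmin=2)
    header = json.loads(base.with_suffix(".json").read_text())
    mask = np.isfinite(values)
    return StiffnessGrid(values=values, origin=tuple(header["origin_mm"]),
                         pixel_size=float(header["pixel_size_mm"]),
                         valid_mask=mask)


def write_field_csv(field: np.ndarray, path) -> None:
    np.savetxt(path, field, delimiter=",", fmt="%.8g")


def read_field_csv(path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",", ndmin=2)


def write_spots_csv(spots, path) -> None:
    pd.DataFrame({
        "id": np.arange(1, spots.n_spots + 1),
        "x": spots.centroids[:, 0] if spots.n_spots else [],
        "y": spots.centroids[:, 1] if spots.n_spots else [],
        "area_px": spots.areas,
    }).to_csv(path, index=False)
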