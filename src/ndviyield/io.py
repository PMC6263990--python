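"""File formats: ESRI ASCII grid rasters, long-format CSVs, YAML configs.

Single-band rasters (crop mask, county map, yield maps) are written as
ESRI ASCII grids (.asc) — a plain-text raster format with an affine
georeference header that any GIS reads. The synthetic scenes carry a
synthetic affine transform: 30 m cells anchored at an arbitrary origin.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import (CropParamPriors, CropPrior, SceneBundle, SceneConfig,
                        default_priors)
from .yield_model import NODATA

__all__ = [
    "write_ascii_grid", "read_ascii_grid", "export_scene",
    "load_run_config", "dump_run_config", "read_observations", "write_params_table",
]

# synthetic affine: 30 m cells, arbitrary UTM-like origin
CELLSIZE_M = 30.0
X_ORIGIN = 400_000.0
Y_ORIGIN = 4_500_000.0


def write_ascii_grid(path, grid: np.ndarray, nodata: float = NODATA) -> None:
    grid = np.asarray(grid)
    if grid.ndim != 2:
        raise ValueError("raster must be 2-D")
    h, w = grid.shape
    header = (
        f"ncols {w}\nnrows {h}\nxllcorner {X_ORIGIN}\nyllcorner {Y_ORIGIN}\n"
        f"cellsize {CELLSIZE_M}\nNODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, grid, fmt="%.6g")


def read_ascii_grid(path) -> tuple[np.ndarray, dict]:
    meta = {}
    with open(path) as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            meta[key.lower()] = float(value)
        grid = np.loadtxt(fh)
    grid = np.atleast_2d(grid)
    return grid, meta


def export_scene(scene: SceneBundle, out_dir) -> dict[str, Path]:
    """Write a scene's maps and tables; returns {artifact name: path}."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "crop_mask": out / "crop_mask.asc",
        "county_map": out / "county_map.asc",
        "true_yield": out / "true_yield.asc",
        "observations": out / "observations.csv",
        "county_truth": out / "county_truth.csv",
        "true_params": out / "true_params.csv",
    }
    write_ascii_grid(paths["crop_mask"], scene.crop_mask, nodata=-1)
    write_ascii_grid(paths["county_map"], scene.county_map, nodata=-1)
    write_ascii_grid(paths["true_yield"], scene.true_yield_map())
    scene.observations.to_csv(paths["observations"], index=False)
    scene.county_truth.to_csv(paths["county_truth"], index=False)
    scene.params.to_csv(paths["true_params"], index=False)
    return paths


def read_observations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"pixel_id", "row", "col", "crop", "doy", "ndvi"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"observation CSV missing columns {sorted(missing)}")
    return df


def write_params_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def _prior_from_dict(d: dict) -> CropPrior:
    kwargs = dict(d)
    for key in ("a_range", "b_range", "d_range", "k_range", "growth_window"):
        kwargs[key] = tuple(kwargs[key])
    return CropPrior(**kwargs)


def load_run_config(path) -> tuple[SceneConfig, CropParamPriors, dict]:
    """Read a YAML run config: scene block, optional priors, extras.

    Returns (scene config, priors, remaining top-level keys).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    scene_kwargs = dict(raw.pop("scene", {}))
    if "window" in scene_kwargs:
        scene_kwargs["window"] = tuple(scene_kwargs["window"])
    config = SceneConfig(**scene_kwargs)
    priors_raw = raw.pop("priors", None)
    if priors_raw is None:
        priors = default_priors()
    else:
        priors = CropParamPriors(
            maize=_prior_from_dict(priors_raw["maize"]),
            sunflower=_prior_from_dict(priors_raw["sunflower"]),
        )
    return config, priors, raw


def dump_run_config(path, config: SceneConfig, priors: CropParamPriors,
                    extras: dict | None = None) -> None:
    doc = dict(extras or {})
    doc["scene"] = dataclasses.asdict(config)
    doc["scene"]["window"] = list(config.window)
    doc["priors"] = {
        crop: {k: (list(v) if isinstance(v, tuple) else v)
               for k, v in dataclasses.asdict(getattr(priors, crop)).items()}
        for crop in ("maize", "sunflower")
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
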