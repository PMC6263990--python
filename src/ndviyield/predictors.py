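"""Predictor layouts for the eight yield-estimation models.

Each of the eight models per crop takes a fixed, ordered predictor vector
built from the fitted NDVI curve:

=====  ==========================================================
model  predictors (maize grid; sunflower N-grids start at N_160)
=====  ==========================================================
1      N_120 ... N_260, 5-day step
2      N_120 ... N_260, 10-day step
3      model 2 + t_inf_1, t_inf_2, t_max
4      model 3 + d, k
5      N_120 ... N_210, 10-day step  (pre-harvest series only)
6      model 5 + t_inf_1
7      N_inf_1, N_inf_2, N_max, t_inf_1, t_inf_2, t_max
8      model 7 + d, k
=====  ==========================================================

``N_t`` is the fitted curve evaluated at DOY ``t`` (daily reconstruction),
not a raw acquisition: raw observation days do not align to the fixed grid.
Model 5's truncation at DOY 210 (50 days before harvest) is what makes
pre-harvest forecasting testable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curve import CurveParams, evaluate_curve
from .phenology import PhenoFeatures

__all__ = ["ModelSpec", "PredictorVector", "build_spec", "build_vector", "build_table",
           "MODEL_IDS", "CROPS"]

MODEL_IDS = (1, 2, 3, 4, 5, 6, 7, 8)
CROPS = ("maize", "sunflower")

# Growth windows (DOY): maize 120-260, sunflower 160-260; both peak near 220.
GROWTH_START = {"maize": 120, "sunflower": 160}
GROWTH_END = 260
PREHARVEST_END = 210  # models 5-6 use the series up to 50 days before harvest

_PHENO_TIMES = ("t_inf_1", "t_inf_2", "t_max")
_PHENO_NDVI = ("N_inf_1", "N_inf_2", "N_max")
_NDVI_NAME = re.compile(r"^N_(\d+)$")


@dataclass(frozen=True)
class ModelSpec:
    """Ordered predictor layout for one (model id, crop) pair."""

    model_id: int
    crop: str
    names: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.names)


@dataclass(frozen=True)
class PredictorVector:
    """One pixel's predictor values, ordered to match its ModelSpec."""

    pixel_id: int
    model_id: int
    crop: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("predictor values must be finite")
        object.__setattr__(self, "values", v)


def _ndvi_grid(crop: str, step: int, end: int) -> tuple[str, ...]:
    return tuple(f"N_{t}" for t in range(GROWTH_START[crop], end + 1, step))


def build_spec(model_id: int, crop: str) -> ModelSpec:
    """Return the ordered predictor names for a (model id, crop) pair."""
    if crop not in CROPS:
        raise ValueError(f"unknown crop {crop!r}; expected one of {CROPS}")
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model id {model_id}; expected 1-8")

    if model_id == 1:
        names = _ndvi_grid(crop, 5, GROWTH_END)
    elif model_id == 2:
        names = _ndvi_grid(crop, 10, GROWTH_END)
    elif model_id == 3:
        names = _ndvi_grid(crop, 10, GROWTH_END) + _PHENO_TIMES
    elif model_id == 4:
        names = _ndvi_grid(crop, 10, GROWTH_END) + _PHENO_TIMES + ("d", "k")
    elif model_id == 5:
        names = _ndvi_grid(crop, 10, PREHARVEST_END)
    elif model_id == 6:
        names = _ndvi_grid(crop, 10, PREHARVEST_END) + ("t_inf_1",)
    elif model_id == 7:
        names = _PHENO_NDVI + _PHENO_TIMES
    else:
        names = _PHENO_NDVI + _PHENO_TIMES + ("d", "k")
    return ModelSpec(model_id=model_id, crop=crop, names=names)


def _value_for(name: str, params: CurveParams, features: PhenoFeatures) -> float:
    m = _NDVI_NAME.match(name)
    if m:
        return float(evaluate_curve(params, float(m.group(1))))
    if name == "d":
        return params.d
    if name == "k":
        return params.k
    if name in _PHENO_TIMES:
        return getattr(features, name)
    if name in _PHENO_NDVI:
        return getattr(features, "ndvi" + name[1:])
    raise KeyError(f"unknown predictor name {name!r}")


def build_vector(spec: ModelSpec, params: CurveParams, features: PhenoFeatures,
                 pixel_id: int = 0) -> PredictorVector:
    """Assemble one pixel's predictor vector from its fitted curve."""
    if not params.converged:
        raise ValueError(f"pixel {pixel_id}: curve fit did not converge; pixel excluded")
    values = np.array([_value_for(n, params, features) for n in spec.names])
    return PredictorVector(pixel_id=pixel_id, model_id=spec.model_id, crop=spec.crop,
                           values=values)


def build_table(spec: ModelSpec, params_by_pixel: dict[int, CurveParams],
                features_by_pixel: dict[int, PhenoFeatures]) -> pd.DataFrame:
    """Predictor table (one row per pixel, columns in spec order).

    Pixels with non-converged fits are silently absent from the inputs by
    contract (the fitting stage drops and logs them).
    """
    rows = {}
    for pid, params in params_by_pixel.items():
        vec = build_vector(spec, params, features_by_pixel[pid], pixel_id=pid)
        rows[pid] = vec.values
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(spec.names))
    df.index.name = "pixel_id"
    return df.sort_index()
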