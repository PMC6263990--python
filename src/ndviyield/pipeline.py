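"""End-to-end orchestration: simulate -> fit -> predictors -> train -> map
-> aggregate -> evaluate, with a manifest for reproducibility.

A run processes one synthetic district over ``n_years`` seasons. Per year
the observation stack is curve-fitted once per pixel (failed fits are
dropped and logged, never imputed), predictor tables are built per
(crop, model id), forests are calibrated on the sampling-point pixels and
applied to every crop pixel, and pixel yields are aggregated to county
production. Validation compares estimated against true county production
(p = 1 in the adjusted R^2, as for a univariate validation regression) and
ranks models by multi-year mean RMSE with RE as tie-break.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from .curve import CurveFitError, CurveParams, fit_curve, NdviSeries, _evaluate
from .evaluation import MetricSet, aggregate_production, metrics, rank_models
from .phenology import extract_phenology
from .predictors import ModelSpec, build_spec, _NDVI_NAME
from .synthetic import (CROP_CODES, CropParamPriors, SceneBundle, SceneConfig,
                        make_calibration_set, scene_for_year)
from .yield_model import RfConfig, calibrate, predict_map
from . import io as nio

__all__ = ["RunConfig", "run_all", "fit_pixels", "predictor_table", "PARAM_COLUMNS"]

log = logging.getLogger("ndviyield")

PARAM_COLUMNS = ["pixel_id", "row", "col", "crop", "a", "b", "c", "d", "k",
                 "rss", "converged", "t_inf_1", "t_inf_2", "t_max",
                 "ndvi_inf_1", "ndvi_inf_2", "ndvi_max"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one reproducible pipeline run."""

    scene: SceneConfig
    priors: CropParamPriors | None = None
    crops: tuple[str, ...] = ("maize", "sunflower")
    model_ids: tuple[int, ...] = (2, 5, 7, 8)
    rf: RfConfig = field(default_factory=RfConfig)
    points_per_crop: dict = field(
        default_factory=lambda: {"maize": 34, "sunflower": 54}
    )
    pixels_per_point: int = 8
    re_denominator: str = "estimated"
    out_dir: str = "runs/default"

    def __post_init__(self) -> None:
        if not self.model_ids:
            raise ValueError("model_ids must not be empty")
        if not self.crops:
            raise ValueError("crops must not be empty")
        bad = [m for m in self.model_ids if m not in range(1, 9)]
        if bad:
            raise ValueError(f"unknown model ids {bad}")


def fit_pixels(observations: pd.DataFrame) -> tuple[pd.DataFrame, list[int]]:
    """Fit the seasonal curve for every pixel in a long observation table.

    Returns (params table, dropped pixel ids). A pixel is dropped when its
    series is degenerate, too short, or the fit fails to converge.
    """
    rows, dropped = [], []
    for pid, obs in observations.groupby("pixel_id", sort=True):
        obs = obs.sort_values("doy")
        try:
            params = fit_curve(NdviSeries(pixel_id=int(pid),
                                          t=obs["doy"].to_numpy(dtype=float),
                                          ndvi=obs["ndvi"].to_numpy(dtype=float)))
            feats = extract_phenology(params)
        except (CurveFitError, ValueError) as exc:
            log.warning("pixel %s dropped: %s", pid, exc)
            dropped.append(int(pid))
            continue
        first = obs.iloc[0]
        rows.append({
            "pixel_id": int(pid), "row": int(first["row"]), "col": int(first["col"]),
            "crop": first["crop"], "a": params.a, "b": params.b, "c": params.c,
            "d": params.d, "k": params.k, "rss": params.rss,
            "converged": params.converged, **feats.as_dict(),
            "ndvi_inf_1": feats.ndvi_inf_1, "ndvi_inf_2": feats.ndvi_inf_2,
            "ndvi_max": feats.ndvi_max,
        })
    df = pd.DataFrame(rows, columns=PARAM_COLUMNS)
    return df, dropped


def predictor_table(params_df: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Predictor table for one model spec from a fitted-params table.

    Vectorised over pixels: fixed-DOY NDVI columns are the fitted curve
    evaluated on the model grid; phenology/shape columns are copied.
    """
    sel = params_df[params_df["crop"] == spec.crop]
    out = pd.DataFrame(index=sel["pixel_id"].to_numpy())
    out.index.name = "pixel_id"
    a, b = sel["a"].to_numpy()[:, None], sel["b"].to_numpy()[:, None]
    c, d = sel["c"].to_numpy()[:, None], sel["d"].to_numpy()[:, None]
    k = sel["k"].to_numpy()[:, None]
    for name in spec.names:
        m = _NDVI_NAME.match(name)
        if m:
            out[name] = _evaluate(float(m.group(1)), a, b, c, d, k).ravel()
        elif name in ("d", "k"):
            out[name] = sel[name].to_numpy()
        elif name.startswith("t_"):
            out[name] = sel[name].to_numpy()
        else:  # N_inf_1 / N_inf_2 / N_max
            out[name] = sel["ndvi" + name[1:]].to_numpy()
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns the run manifest (also written)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    t_start = time.time()

    config_doc = json.dumps(dataclasses.asdict(cfg.scene), sort_keys=True, default=list)
    config_hash = hashlib.sha256(config_doc.encode()).hexdigest()

    yearly: dict[str, dict[int, list[MetricSet]]] = {c: {m: [] for m in cfg.model_ids}
                                                    for c in cfg.crops}
    production_rows = []
    calibration_rows = []

    for year in range(cfg.scene.n_years):
        ydir = out / f"year_{year}"
        ydir.mkdir(parents=True, exist_ok=True)
        t0 = time.time()
        scene = scene_for_year(cfg.scene, year, cfg.priors)
        for name, path in nio.export_scene(scene, ydir / "scene").items():
            artifacts[f"year{year}/scene/{name}"] = _sha256(path)
        log.info("stage=simulate year=%d crop_pixels=%d elapsed=%.1fs",
                 year, len(scene.params), time.time() - t0)

        t0 = time.time()
        params_df, dropped = fit_pixels(scene.observations)
        params_path = ydir / "params.csv"
        params_df.to_csv(params_path, index=False)
        artifacts[f"year{year}/params"] = _sha256(params_path)
        log.info("stage=fit year=%d fitted=%d dropped=%d elapsed=%.1fs",
                 year, len(params_df), len(dropped), time.time() - t0)

        cal = make_calibration_set(scene, cfg.points_per_crop, cfg.pixels_per_point)
        truth_by_pixel = scene.params.set_index("pixel_id")

        for crop in cfg.crops:
            code = CROP_CODES[crop]
            cal_ids = cal.loc[cal["crop"] == crop, "pixel_id"]
            cal_ids = cal_ids[cal_ids.isin(params_df["pixel_id"])]
            y_cal = truth_by_pixel.loc[cal_ids, "yield_t_ha"].to_numpy()
            for model_id in cfg.model_ids:
                spec = build_spec(model_id, crop)
                X_all = predictor_table(params_df, spec)
                tag = f"year{year}/{crop}/model{model_id}"
                x_path = ydir / f"X_{crop}_model{model_id}.csv"
                X_all.to_csv(x_path)
                artifacts[f"{tag}/predictors"] = _sha256(x_path)

                t0 = time.time()
                model = calibrate(X_all.loc[cal_ids], y_cal, cfg.rf,
                                  crop=crop, model_id=model_id)
                m_path = ydir / f"model_{crop}_{model_id}.joblib"
                joblib.dump(model, m_path)
                artifacts[f"{tag}/model"] = _sha256(m_path)

                train_pred = model.predict(X_all.loc[cal_ids])
                cal_metrics = metrics(y_cal, train_pred, p=len(spec),
                                      denominator=cfg.re_denominator)
                calibration_rows.append({
                    "year": year, "crop": crop, "model_id": model_id,
                    "n": cal_metrics.n, "p": cal_metrics.p,
                    "rmse": cal_metrics.rmse, "re": cal_metrics.re,
                    "r2": cal_metrics.r2, "adj_r2": cal_metrics.adj_r2,
                })

                yield_map = predict_map(model, X_all, scene.crop_mask, code,
                                        params_df.set_index("pixel_id")[["row", "col"]],
                                        strict=False)
                map_path = ydir / f"yield_{crop}_model{model_id}.asc"
                nio.write_ascii_grid(map_path, yield_map)
                artifacts[f"{tag}/yield_map"] = _sha256(map_path)
                log.info("stage=train_map year=%d crop=%s model=%d elapsed=%.1fs",
                         year, crop, model_id, time.time() - t0)

                est = aggregate_production(yield_map, scene.crop_mask,
                                           scene.county_map, cfg.scene.pixel_area_ha,
                                           crop_labels={code: crop})
                truth = scene.county_truth.query("crop == @crop")
                merged = est.merge(truth, on=["county", "crop"],
                                   suffixes=("_est", "_true"))
                for _, r in merged.iterrows():
                    production_rows.append({
                        "year": year, "crop": crop, "model_id": model_id,
                        "county": r["county"],
                        "county_name": scene.county_names[r["county"]],
                        "estimated_kt": r["production_t_est"] / 1000.0,
                        "true_kt": r["production_t_true"] / 1000.0,
                        "estimated_mean_yield_t_ha": r["mean_yield_t_ha_est"],
                        "true_mean_yield_t_ha": r["mean_yield_t_ha_true"],
                    })
                county_metrics = metrics(
                    merged["production_t_true"] / 1000.0,
                    merged["production_t_est"] / 1000.0,
                    p=1, denominator=cfg.re_denominator,
                )
                yearly[crop][model_id].append(county_metrics)

    production = pd.DataFrame(production_rows)
    production.to_csv(out / "county_production.csv", index=False)
    artifacts["county_production"] = _sha256(out / "county_production.csv")

    calibration = pd.DataFrame(calibration_rows)
    calibration.to_csv(out / "calibration_metrics.csv", index=False)
    artifacts["calibration_metrics"] = _sha256(out / "calibration_metrics.csv")

    rank_frames = []
    for crop in cfg.crops:
        ranked = rank_models(yearly[crop])
        ranked.insert(0, "crop", crop)
        rank_frames.append(ranked)
    ranking = pd.concat(rank_frames, ignore_index=True)
    ranking.to_csv(out / "model_ranking.csv", index=False)
    artifacts["model_ranking"] = _sha256(out / "model_ranking.csv")

    manifest = {
        "config_hash": config_hash,
        "seed": cfg.scene.seed,
        "rf_seed": cfg.rf.seed,
        "n_years": cfg.scene.n_years,
        "crops": list(cfg.crops),
        "model_ids": list(cfg.model_ids),
        "artifacts": artifacts,
        "wall_time_s": round(time.time() - t_start, 2),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
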