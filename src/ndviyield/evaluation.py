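"""Accuracy metrics, county-level production aggregation and model ranking.

Given observed values ``S_i`` and estimates ``P_i`` (i = 1..N):

* ``RMSE = sqrt( (1/N) * sum (S_i - P_i)^2 )`` in the data's units;
* ``RE   = (1/N) * sum |P_i - S_i| / P_i * 100`` — note the denominator is
  the *estimate*; a ``denominator="observed"`` switch gives the more common
  normalisation by ``S_i``;
* ``R^2`` is the squared Pearson correlation of S and P (symmetric in its
  arguments, unlike the regression sum-of-squares form);
* adjusted ``R^2 = 1 - (1 - R^2) (N - 1)/(N - p - 1)`` with ``p`` the
  predictor count (``p = 1`` for validation against a univariate
  regression of estimated on statistical production).

County production is the pixel-area-weighted sum of per-pixel yields over
one crop within one county: ``production (t) = area_ha * sum yields (t/ha)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .yield_model import NODATA

__all__ = ["MetricSet", "metrics", "relative_error", "aggregate_production",
           "rank_models"]


@dataclass(frozen=True)
class MetricSet:
    """RMSE, relative error (%), R^2 and adjusted R^2 for one comparison."""

    rmse: float
    re: float
    r2: float
    adj_r2: float
    n: int
    p: int


def relative_error(S, P, denominator: str = "estimated") -> float:
    """Mean absolute relative deviation in percent.

    ``denominator="estimated"`` divides each |P_i - S_i| by P_i (the
    literal printed form); ``"observed"`` divides by S_i.
    """
    S = np.asarray(S, dtype=float).reshape(-1)
    P = np.asarray(P, dtype=float).reshape(-1)
    if S.shape != P.shape:
        raise ValueError("S and P must have equal length")
    if denominator not in ("estimated", "observed"):
        raise ValueError("denominator must be 'estimated' or 'observed'")
    den = P if denominator == "estimated" else S
    if np.any(den == 0):
        raise ValueError("relative error undefined: zero denominator value")
    return float(np.mean(np.abs(P - S) / np.abs(den)) * 100.0)


def metrics(S, P, p: int = 1, denominator: str = "estimated") -> MetricSet:
    """Accuracy metrics between observed ``S`` and estimated ``P`` values.

    ``p`` is the predictor count used by the adjusted R^2 penalty.
    ``denominator`` selects the RE normalisation: ``"estimated"`` divides
    each absolute deviation by P_i; ``"observed"`` by S_i.
    """
    S = np.asarray(S, dtype=float).reshape(-1)
    P = np.asarray(P, dtype=float).reshape(-1)
    if S.shape != P.shape:
        raise ValueError("S and P must have equal length")
    n = len(S)
    if n < 2:
        raise ValueError("need at least 2 value pairs")
    rmse = float(np.sqrt(np.mean((S - P) ** 2)))
    re = relative_error(S, P, denominator=denominator)

    sd_s, sd_p = S.std(), P.std()
    if sd_s == 0 or sd_p == 0:
        raise ValueError("R^2 undefined for zero-variance input")
    cov = np.mean((S - S.mean()) * (P - P.mean()))
    r2 = float((cov / (sd_s * sd_p)) ** 2)
    # guard against correlation rounding marginally above 1
    r2 = min(r2, 1.0)

    if n - p - 1 <= 0:
        raise ValueError(f"adjusted R^2 undefined for n={n}, p={p}")
    adj_r2 = float(1.0 - (1.0 - r2) * (n - 1) / (n - p - 1))
    return MetricSet(rmse=rmse, re=re, r2=r2, adj_r2=adj_r2, n=n, p=p)


def aggregate_production(yield_map: np.ndarray, crop_mask: np.ndarray,
                         county_map: np.ndarray, pixel_area_ha: float,
                         crop_labels: dict[int, str] | None = None) -> pd.DataFrame:
    """Sum per-pixel yields into county production per crop.

    Returns one row per (county, crop) present in the masks with columns
    ``county``, ``crop``, ``n_pixels``, ``mean_yield_t_ha``, ``production_t``
    and ``production_kt``. Pixels whose yield equals the no-data sentinel
    are excluded (dropped fits).
    """
    if not (yield_map.shape == crop_mask.shape == county_map.shape):
        raise ValueError("yield map, crop mask and county map must share one grid")
    valid = yield_map != NODATA
    rows = []
    for county in np.unique(county_map):
        in_county = county_map == county
        for code in np.unique(crop_mask[in_county & valid]):
            if code == 0:
                continue  # non-crop background
            sel = in_county & valid & (crop_mask == code)
            n_pix = int(sel.sum())
            if n_pix == 0:
                continue
            total = float(yield_map[sel].sum()) * pixel_area_ha
            crop = crop_labels.get(int(code), str(code)) if crop_labels else str(code)
            rows.append({
                "county": int(county),
                "crop": crop,
                "n_pixels": n_pix,
                "mean_yield_t_ha": total / (n_pix * pixel_area_ha),
                "production_t": total,
                "production_kt": total / 1000.0,
            })
    return pd.DataFrame(rows, columns=["county", "crop", "n_pixels",
                                       "mean_yield_t_ha", "production_t",
                                       "production_kt"])


def rank_models(yearly_metrics: dict[int, list[MetricSet]]) -> pd.DataFrame:
    """Rank models by multi-year mean RMSE, ties broken by mean RE.

    ``yearly_metrics`` maps model id -> one MetricSet per year. Returns a
    DataFrame sorted best-first with columns ``model_id``, ``mean_rmse``,
    ``mean_re``, ``n_years`` and ``rank`` (1 = best).
    """
    if not yearly_metrics:
        raise ValueError("no models to rank")
    rows = []
    for model_id, per_year in yearly_metrics.items():
        if not per_year:
            raise ValueError(f"model {model_id} has no yearly metrics")
        rows.append({
            "model_id": model_id,
            "mean_rmse": float(np.mean([m.rmse for m in per_year])),
            "mean_re": float(np.mean([m.re for m in per_year])),
            "n_years": len(per_year),
        })
    df = pd.DataFrame(rows).sort_values(
        ["mean_rmse", "mean_re", "model_id"], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
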