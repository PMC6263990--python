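"""Per-crop random-forest yield regression at pixel scale.

The yield at pixel (i, j) in year k is modelled as ``Y[i,j,k] = F(x[i,j,k])``
where ``x`` is one of the eight predictor layouts and ``F`` a random-forest
regression (mean of trees). Forest hyper-parameters follow the conventions
of the randomForest R/Matlab packages: ``ntree = 500`` trees, ``mtry``
(features tried per split) defaulting to one third of the predictor count,
and terminal ``nodesize = 1``.

One forest is trained per (crop, model id); training and prediction are
joined on predictor *names*, never on column position, so a permuted
predictor table can never be silently misaligned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.utils.validation import check_is_fitted

__all__ = ["RfConfig", "RandomForestYieldRegressor", "calibrate", "predict_map", "NODATA"]

NODATA = -9999.0


@dataclass(frozen=True)
class RfConfig:
    """Random-forest hyper-parameters (randomForest-style conventions)."""

    ntree: int = 500
    mtry: int | None = None  # None -> floor(p/3), min 1
    nodesize: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if self.nodesize < 1:
            raise ValueError("nodesize must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1 when given")

    def resolved_mtry(self, p: int) -> int:
        m = self.mtry if self.mtry is not None else max(1, p // 3)
        if m > p:
            raise ValueError(f"mtry={m} exceeds predictor count p={p}")
        return m


class RandomForestYieldRegressor(RegressorMixin, BaseEstimator):
    """Random-forest pixel-yield regressor with name-based feature joins.

    scikit-learn estimator wrapping :class:`RandomForestRegressor` with the
    mtry = p/3 regression convention. ``fit`` expects a DataFrame whose
    columns are predictor names; ``predict`` reorders any DataFrame to the
    training layout by name and rejects missing or unknown predictors.

    Parameters mirror :class:`RfConfig`; ``crop`` and ``model_id`` are
    carried as metadata for provenance only.

    Attributes
    ----------
    forest_ : RandomForestRegressor
        The fitted ensemble.
    feature_names_ : list of str
        Training predictor order; the join key for prediction.
    n_train_ : int
        Number of training pixels.
    """

    def __init__(self, ntree: int = 500, mtry: int | None = None, nodesize: int = 1,
                 seed: int = 0, crop: str | None = None, model_id: int | None = None):
        self.ntree = ntree
        self.mtry = mtry
        self.nodesize = nodesize
        self.seed = seed
        self.crop = crop
        self.model_id = model_id

    def _align(self, X: pd.DataFrame) -> pd.DataFrame:
        missing = set(self.feature_names_) - set(X.columns)
        if missing:
            raise ValueError(f"predictor table is missing {sorted(missing)}")
        return X[self.feature_names_]

    def fit(self, X: pd.DataFrame, y):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X))
            X.columns = [str(c) for c in X.columns]
        y = np.asarray(y, dtype=float).reshape(-1)
        if len(X) != len(y):
            raise ValueError(f"X has {len(X)} rows but y has {len(y)} values")
        if X.isna().any().any() or not np.all(np.isfinite(y)):
            raise ValueError("missing values in predictors or yields")
        cfg = RfConfig(ntree=self.ntree, mtry=self.mtry, nodesize=self.nodesize,
                       seed=self.seed)
        self.feature_names_ = [str(c) for c in X.columns]
        p = len(self.feature_names_)
        self.forest_ = RandomForestRegressor(
            n_estimators=cfg.ntree,
            max_features=cfg.resolved_mtry(p),
            min_samples_leaf=cfg.nodesize,
            random_state=cfg.seed,
            n_jobs=1,
        )
        self.forest_.fit(X.to_numpy(dtype=float), y)
        self.n_train_ = len(y)
        self.y_train_range_ = (float(y.min()), float(y.max()))
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "forest_")
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X))
            X.columns = [str(c) for c in X.columns]
        X = self._align(X)
        if len(X) == 0:
            return np.empty(0)
        return self.forest_.predict(X.to_numpy(dtype=float))


def calibrate(X: pd.DataFrame, y, cfg: RfConfig | None = None,
              crop: str | None = None, model_id: int | None = None,
              min_rows: int = 50) -> RandomForestYieldRegressor:
    """Train a per-crop yield forest on pixel-level measured yields.

    Requires at least ``min_rows`` calibration pixels — five-parameter curve
    pixels are plentiful, and small samples make forest variance dominate.
    """
    cfg = cfg or RfConfig()
    if len(X) < min_rows:
        raise ValueError(f"calibration needs >= {min_rows} pixels, got {len(X)}")
    model = RandomForestYieldRegressor(
        ntree=cfg.ntree, mtry=cfg.mtry, nodesize=cfg.nodesize, seed=cfg.seed,
        crop=crop, model_id=model_id,
    )
    return model.fit(X, y)


def predict_map(model: RandomForestYieldRegressor, X: pd.DataFrame,
                crop_mask: np.ndarray, crop_code: int,
                positions: pd.DataFrame, strict: bool = True) -> np.ndarray:
    """Predict a per-pixel yield map (t/ha) for one crop.

    Parameters
    ----------
    X : DataFrame
        Predictor table indexed by pixel id, covering every masked pixel.
    crop_mask : 2-D int array
        Per-pixel crop labels.
    crop_code : int
        Label value selecting this model's crop in ``crop_mask``.
    positions : DataFrame
        ``row``/``col`` per pixel id (index aligned with ``X``).
    strict : bool
        When True, every masked pixel must have predictors; when False,
        uncovered pixels (e.g. dropped curve fits) stay ``NODATA``.

    Returns a float array shaped like ``crop_mask`` with ``NODATA`` outside
    the crop and at uncovered pixels.
    """
    out = np.full(crop_mask.shape, NODATA, dtype=float)
    if not (crop_mask == crop_code).any():
        return out
    pos = positions.loc[X.index]
    if strict:
        covered = np.zeros(crop_mask.shape, dtype=bool)
        covered[pos["row"].to_numpy(), pos["col"].to_numpy()] = True
        n_missing = int(((crop_mask == crop_code) & ~covered).sum())
        if n_missing:
            raise ValueError(f"{n_missing} masked pixels lack predictors")
    keep = crop_mask[pos["row"].to_numpy(), pos["col"].to_numpy()] == crop_code
    if not keep.any():
        return out
    Xc, posc = X.loc[keep], pos.loc[keep]
    yhat = model.predict(Xc)
    out[posc["row"].to_numpy(), posc["col"].to_numpy()] = yhat
    return out
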