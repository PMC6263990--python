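"""Random-forest yield regression: conventions, contracts, recovery."""

import numpy as np
import pandas as pd
import pytest

from ndviyield import (NODATA, RandomForestYieldRegressor, RfConfig, SceneConfig,
                       build_spec, calibrate, generate_scene, predict_map,
                       predictor_table)
from ndviyield.pipeline import PARAM_COLUMNS
from ndviyield.phenology import extract_phenology
from ndviyield.curve import CurveParams


def toy_data(n=120, p=5, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, p)),
                     columns=[f"x{i}" for i in range(p)])
    y = X["x0"] * 2.0 + rng.normal(scale=0.1, size=n) + 10.0
    return X, y


def params_table_from_truth(scene, crop):
    """Fitted-params-shaped table built from generator truth (exact fits)."""
    sub = scene.params[scene.params["crop"] == crop]
    rows = []
    for _, r in sub.iterrows():
        p = CurveParams(r["a"], r["b"], r["c"], r["d"], r["k"])
        feats = extract_phenology(p)
        rows.append({"pixel_id": int(r["pixel_id"]), "row": int(r["row"]),
                     "col": int(r["col"]), "crop": crop,
                     "a": p.a, "b": p.b, "c": p.c, "d": p.d, "k": p.k,
                     "rss": 0.0, "converged": True, **feats.as_dict(),
                     "ndvi_inf_1": feats.ndvi_inf_1,
                     "ndvi_inf_2": feats.ndvi_inf_2,
                     "ndvi_max": feats.ndvi_max})
    return pd.DataFrame(rows, columns=PARAM_COLUMNS)


class TestConfig:
    def test_mtry_default_one_third(self):
        assert RfConfig().resolved_mtry(15) == 5
        assert RfConfig().resolved_mtry(2) == 1  # floor(p/3) clipped up to 1
        assert RfConfig(mtry=4).resolved_mtry(10) == 4

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            RfConfig(ntree=0)
        with pytest.raises(ValueError):
            RfConfig(nodesize=0)
        with pytest.raises(ValueError):
            RfConfig(mtry=9).resolved_mtry(5)


class TestContracts:
    def test_constant_response_predicts_constant(self):
        X, _ = toy_data()
        model = calibrate(X, np.full(len(X), 10.0))
        assert np.allclose(model.predict(X), 10.0)

    def test_seeded_determinism(self):
        X, y = toy_data()
        p1 = calibrate(X, y, RfConfig(seed=3)).predict(X)
        p2 = calibrate(X, y, RfConfig(seed=3)).predict(X)
        np.testing.assert_array_equal(p1, p2)

    def test_prediction_joins_by_name_not_position(self):
        X, y = toy_data()
        model = calibrate(X, y)
        shuffled = X[list(reversed(X.columns))]
        np.testing.assert_array_equal(model.predict(X), model.predict(shuffled))

    def test_missing_predictor_rejected(self):
        X, y = toy_data()
        model = calibrate(X, y)
        with pytest.raises(ValueError, match="missing"):
            model.predict(X.drop(columns=["x0"]))

    def test_predictions_bounded_by_training_range(self):
        X, y = toy_data()
        model = calibrate(X, y)
        far = X * 10.0  # extrapolation cannot escape the mean-of-trees range
        pred = model.predict(far)
        assert pred.min() >= y.min() and pred.max() <= y.max()

    def test_duplicating_rows_is_stable(self):
        # duplicating every training row must not move held-out predictions
        # beyond the order of the forest's own Monte-Carlo noise (oracle:
        # refit on identical data with a different seed); in-sample
        # predictions are excluded because duplication doubles the bootstrap
        # inclusion rate and legitimately sharpens the in-sample fit
        X, y = toy_data()
        rng = np.random.default_rng(10)
        X_new = pd.DataFrame(rng.normal(size=(200, X.shape[1])), columns=X.columns)
        base = calibrate(X, y, RfConfig(seed=1)).predict(X_new)
        reseeded = calibrate(X, y, RfConfig(seed=2)).predict(X_new)
        doubled = calibrate(pd.concat([X, X], ignore_index=True),
                            np.concatenate([y, y]), RfConfig(seed=1)).predict(X_new)
        mc_noise = np.sqrt(np.mean((base - reseeded) ** 2))
        dup_shift = np.sqrt(np.mean((base - doubled) ** 2))
        assert dup_shift <= 2.0 * mc_noise
        assert dup_shift <= 0.1 * np.std(y)

    def test_row_mismatch_and_small_sample_rejected(self):
        X, y = toy_data()
        with pytest.raises(ValueError, match="rows"):
            calibrate(X, y[:-5])
        with pytest.raises(ValueError, match=">= 50"):
            calibrate(X.iloc[:10], y[:10])


class TestMapPrediction:
    def test_empty_mask_gives_empty_map(self):
        X, y = toy_data()
        model = calibrate(X, y)
        mask = np.zeros((4, 4), dtype=int)
        pos = pd.DataFrame({"row": [], "col": []})
        out = predict_map(model, X.iloc[:0], mask, crop_code=1, positions=pos)
        assert (out == NODATA).all()

    def test_uncovered_pixels_rejected_when_strict(self):
        X, y = toy_data(n=60)
        model = calibrate(X, y)
        mask = np.ones((8, 8), dtype=int)
        pos = pd.DataFrame({"row": np.arange(60) // 8, "col": np.arange(60) % 8},
                           index=X.index)
        with pytest.raises(ValueError, match="lack predictors"):
            predict_map(model, X, mask, crop_code=1, positions=pos)


@pytest.fixture(scope="module")
def big_noiseless(noiseless_yield_priors):
    # ~10k maize pixels; predictors from the generating curves
    scene = generate_scene(SceneConfig(height=160, width=160, seed=17),
                           noiseless_yield_priors)
    params_df = params_table_from_truth(scene, "maize")
    X = predictor_table(params_df, build_spec(2, "maize"))
    y = scene.params.set_index("pixel_id").loc[X.index, "yield_t_ha"]
    return X, y


class TestRecovery:
    def test_held_out_pixels_mostly_within_one_tonne(self, big_noiseless):
        X, y = big_noiseless
        rng = np.random.default_rng(0)
        idx = rng.permutation(len(X))
        train, test = idx[:5000], idx[5000:10000]
        model = calibrate(X.iloc[train], y.iloc[train].to_numpy(), RfConfig(seed=1))
        err = model.predict(X.iloc[test]) - y.iloc[test].to_numpy()
        assert (np.abs(err) <= 1.0).mean() >= 0.90

    def test_more_trees_do_not_hurt(self, big_noiseless):
        X, y = big_noiseless
        rng = np.random.default_rng(1)
        idx = rng.permutation(len(X))[:3000]
        train, test = idx[:2000], idx[2000:]
        rmse = {}
        for ntree in (50, 500):
            model = calibrate(X.iloc[train], y.iloc[train].to_numpy(),
                              RfConfig(ntree=ntree, seed=5))
            err = model.predict(X.iloc[test]) - y.iloc[test].to_numpy()
            rmse[ntree] = float(np.sqrt(np.mean(err ** 2)))
        assert rmse[500] <= rmse[50] * 1.05  # growth never hurts beyond noise
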