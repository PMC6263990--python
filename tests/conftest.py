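import dataclasses

import numpy as np
import pytest

from ndviyield import (SceneConfig, default_priors, fit_pixels, generate_scene,
                       make_calibration_set)


@pytest.fixture(scope="session")
def clean_scene():
    """Small scene with no cloud dropout and no NDVI noise."""
    return generate_scene(SceneConfig(height=24, width=24, seed=3,
                                      cloud_dropout=0.0, noise_sd=0.0))


@pytest.fixture(scope="session")
def small_scene():
    """Small scene under the default observation model."""
    return generate_scene(SceneConfig(height=40, width=40, seed=5))


@pytest.fixture(scope="session")
def noiseless_yield_priors():
    """Default priors with the yield-link noise switched off for both crops."""
    pri = default_priors()
    return dataclasses.replace(
        pri,
        maize=dataclasses.replace(pri.maize, yield_sd=0.0),
        sunflower=dataclasses.replace(pri.sunflower, yield_sd=0.0),
    )


@pytest.fixture(scope="session")
def calibration_run(noiseless_yield_priors):
    """Default-size scene with noise-free yields, survey-style calibration set
    and fitted curves for the calibration + a held-out maize sample.

    Shared by the model-recovery tests and the acceptance checks (curve
    fitting dominates the cost, so it is done once per session).
    """
    scene = generate_scene(SceneConfig(seed=11), noiseless_yield_priors)
    cal = make_calibration_set(scene, {"maize": 34, "sunflower": 54})
    maize = scene.params[scene.params["crop"] == "maize"].set_index("pixel_id")
    cal_ids = cal.loc[cal["crop"] == "maize", "pixel_id"].to_numpy()
    rng = np.random.default_rng(2)
    held_out = rng.choice(maize.index.difference(cal_ids).to_numpy(), 500,
                          replace=False)
    wanted = np.concatenate([cal_ids, held_out])
    obs = scene.observations[scene.observations["pixel_id"].isin(wanted)]
    params_df, dropped = fit_pixels(obs)
    return {
        "scene": scene, "cal": cal, "maize": maize, "cal_ids": cal_ids,
        "held_out": held_out, "params_df": params_df, "dropped": dropped,
    }
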