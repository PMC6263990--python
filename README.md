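# ndviyield

Pixel-scale estimation of maize and sunflower yields in an irrigation
district from sparse satellite NDVI time series.

Regional crop-yield estimates are usually calibrated at administrative
level, which hides within-district variability and suffers from mixed
pixels at coarse resolution. This package implements the alternative:
calibrate machine-learning yield models directly against ground-measured
yields attached to individual 30 m pixels, using the full seasonal NDVI
trajectory of each pixel, then validate by summing predicted pixel yields
into county production. It is written for agricultural remote-sensing
researchers who want a tested, reproducible pipeline they can point at
their own imagery and survey data — and it ships a synthetic-scene
generator so every stage is testable without any external data.

## Method

1. **Seasonal curve fitting.** Each pixel's irregular (DOY, NDVI)
   observations are fitted by bounded least squares with the five-parameter
   asymmetric logistic curve

   ```
   NDVI(t) = a + (b/k) (1+n)^(-(k+1)/k) n (k+1)^((k+1)/k),
   n       = exp[(t + d ln k - c)/d],
   ```

   which peaks at `t = c` with value `a + b`; `d` is the time scale (days)
   and `k` the asymmetry (`k = 1` is symmetric).

2. **Phenological characteristics.** Closed forms give the three
   characteristic points: the peak (`t_max = c`, `NDVI_max = a + b`) and
   the two inflections — maximum growth and maximum withering rate — at
   `n± = (k/2)[(k+3) ± sqrt((k+3)² − 4)]`, `t = c − d ln k + d ln n±`.
   Both are cross-checked against an independent numerical
   optimisation/root-finding oracle to below 1e−6 days.

3. **Predictor layouts.** Eight fixed layouts per crop combine the
   reconstructed daily NDVI on 5- or 10-day grids (maize DOY 120–260,
   sunflower 160–260; models 5–6 stop at DOY 210, 50 days before harvest)
   with the phenological characteristics and the shape parameters `d, k`.

4. **Random-forest yield regression.** One forest per (crop, layout),
   `ntree = 500`, `mtry = ⌊p/3⌋`, `nodesize = 1`, trained on
   survey pixels (34 maize points and 54 sunflower points × 8 pixels =
   272 / 432 calibration pixels) and applied to every crop pixel.

5. **Evaluation.** RMSE, relative error `RE = mean(|P−S|/P)·100`
   (normalised by the estimate, as printed in the source formulation, with
   an `observed` switch), squared-Pearson `R²`, and adjusted `R²`
   penalised by predictor count; county production is pixel area × sum of
   pixel yields, and models are ranked by multi-year mean RMSE with RE as
   tie-break.

## Worked example

```python
import numpy as np
from ndviyield import (SceneConfig, generate_scene, make_calibration_set,
                       fit_pixels, build_spec, predictor_table, calibrate,
                       RfConfig, metrics)

scene = generate_scene(SceneConfig(seed=1))          # 100x100 district
cal = make_calibration_set(scene, {"maize": 34, "sunflower": 54})
print(cal.groupby("crop").size())
# crop
# maize        272
# sunflower    432

ids = cal.loc[cal.crop == "maize", "pixel_id"]
obs = scene.observations[scene.observations.pixel_id.isin(ids)]
params, dropped = fit_pixels(obs)                    # 272 curve fits
spec = build_spec(2, "maize")                        # N_120..N_260, 10-day
X = predictor_table(params, spec)
y = scene.params.set_index("pixel_id").loc[X.index, "yield_t_ha"]
model = calibrate(X, y.to_numpy(), RfConfig(seed=1))
m = metrics(y, model.predict(X), p=len(spec))
print(f"training R2 = {m.r2:.3f}, RMSE = {m.rmse:.2f} t/ha")
# training R2 = 0.994, RMSE = 0.20 t/ha
```

The calibration counts reproduce the survey design (8 pixels per sampling
point), and the training R² sits above the 0.80–0.90 range expected for
pixel-level calibration because the synthetic yields carry only 0.3 t/ha
of link noise.

The same pipeline runs from the shell:

```bash
ndviyield simulate --seed 1 --out-dir scene/
ndviyield fit --observations scene/observations.csv --out params.csv
ndviyield predictors --params params.csv --model 5 --crop maize --out X.csv
ndviyield benchmark --seed 1 --out-dir runs/bench   # full end-to-end run
```

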