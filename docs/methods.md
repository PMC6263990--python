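# Methods

## The model

A crop pixel's seasonal NDVI trajectory is modelled by the five-parameter
asymmetric logistic curve

```
f(t) = a + (b/k) (1+n)^(-(k+1)/k) n (k+1)^((k+1)/k),   n = exp[(t + d ln k - c)/d]
```

with `t` the day of year (DOY). The parameterisation is deliberately
interpretable: at `t = c`, `n = k` and the peak term equals one, so the
curve attains its maximum `a + b` exactly at `c`. `a` is the off-season
baseline (bare soil / residue), `b` the seasonal amplitude, `d` the
green-up/senescence time scale in days, and `k` a dimensionless asymmetry
(`k = 1` gives a symmetric bell; `k > 1` slows the senescence limb).

Differentiating twice in `ln n` shows the inflection points satisfy
`n² − k(k+3) n + k² = 0`, hence

```
n± = (k/2) [(k+3) ± sqrt((k+3)² − 4)],     t± = c − d ln k + d ln n± .
```

`t−` is the time of maximum growth rate, `t+` of maximum withering rate;
their curve values plus the peak give the six phenological features. The
closed forms are cross-checked in the test suite and acceptance script
against an independent numerical oracle (`numeric_phenology`): Brent
root-finding on a complex-step first derivative and a central difference
of it for the second derivative. Complex-step differentiation is used
because the curve is locally flat near its stationary/inflection points
and plain finite differences of function values only localise the roots to
~1e−5 days; the oracle agrees with the closed forms to better than 1e−8
days over `k ∈ [0.3, 5]`, `d ∈ [5, 20]`.

## Curve fitting

Least squares with box constraints (trust-region reflective,
`scipy.optimize.least_squares`): `a ∈ [−0.5, 0.5]`, `b ∈ (0, 1.5]`,
`c` within the observation window ±30 days, `d ∈ [2, 60]` days,
`k ∈ [0.05, 20]`. The loss is plain (unweighted) residual sum of squares.
Initialisation exploits the parameterisation: `a₀ = min NDVI`,
`b₀ = range`, `c₀ = DOY of the maximum`, `d₀ = span/6`, `k₀ = 1`, with
restarts from `k₀ ∈ {0.5, 2}` and the best (lowest-RSS) solution kept.
The curve is evaluated in log space (`z = ln n` is linear in `t`), so the
far tails neither overflow nor underflow.

A fit requires at least 8 observations spanning at least 60 days — five
parameters need meaningful over-determination, and 8 matches the survey
granularity of 8 pixels per sampling point. Degenerate (constant) series
and non-converged fits raise a flagged failure; the pipeline drops and
logs such pixels and never imputes them.

## Predictor layouts

Eight fixed layouts per crop (maize NDVI grids start at DOY 120, sunflower
at 160; both end at 260, or at 210 for the pre-harvest layouts 5–6):
5-day grid (1), 10-day grid (2), grid + phenological times (3), + shape
parameters `d, k` (4), pre-harvest grid (5), + `t_inf_1` (6), the six
phenological features alone (7), + `d, k` (8). Grid NDVI values are taken
from the fitted curve's daily reconstruction, not from raw acquisitions:
raw observation days are irregular and do not align to a fixed grid.
Layout name order is fixed and all joins downstream are by name.
Phenological times in layouts 3–4 are not clipped to the growth window;
fits whose inflections stray outside it keep their analytic values.

## Yield regression

`RandomForestRegressor` with the randomForest-package conventions:
`ntree = 500`, `mtry = ⌊p/3⌋` (minimum 1), `nodesize = 1`, fixed seed.
One forest per (crop, layout). Predictions are means of trees, hence
bounded by the training yield range. Hyper-parameters are exposed but not
tuned — the point of the eight layouts is predictor comparison at fixed
learner settings.

## Metrics, aggregation, ranking

`RE = mean(|P − S|/P)·100` divides by the *estimate* `P`. That is the
literal printed form of the formulation this package follows; because
normalising by the observation is the more common convention, a
`denominator="observed"` switch is provided and the default is the printed
form. `R²` is the squared Pearson correlation (symmetric in S and P);
adjusted `R² = 1 − (1−R²)(N−1)/(N−p−1)` uses the layout's predictor count
during calibration and `p = 1` for county validation (univariate
regression of estimated on statistical production). County production is
`pixel area (0.09 ha) × Σ pixel yields`; conservation under any county
partition refinement is exact up to float accumulation. Models are ranked
by multi-year mean RMSE, ties broken by mean RE; the tie-break is a design
choice (the two are reported jointly wherever the method is discussed, but
no formal rule exists).

## Synthetic scenes

The generator emulates the data structure of a 30 m / 2-day-revisit
optical constellation over an arid irrigation district:

* **Geometry** — default 100×100 pixels of 0.09 ha, four rectangular
  counties, i.i.d. per-pixel crop labels (maize 0.40, sunflower 0.40,
  other 0.05, rest non-crop — the two major crops cover ~80% of cropland
  in the emulated district).
* **Curves** — per-pixel parameters drawn from per-crop priors: maize
  `a ~ U(0.08, 0.16)`, `b ~ U(0.55, 0.80)`, `c ~ N(220, 5)` DOY,
  `d ~ U(12, 18)` d, `k ~ U(0.8, 2.0)`; sunflower `b ~ U(0.40, 0.65)`,
  `c ~ N(220, 4)`, `d ~ U(9, 14)`, `k` as maize. These place maize's
  appreciable NDVI inside DOY 120–260 and sunflower's inside 160–260 with
  both peaking near 220.
* **Observations** — nominal acquisitions every 2 days over DOY 90–290
  (101 per season), each independently lost with probability 0.6 (heavy
  cloud screening; the true per-pixel gap statistics of the emulated
  archive are unknown, so the rate is a config knob), additive Gaussian
  NDVI noise σ = 0.02, clipped to [−0.2, 1.0]. Every crop pixel must
  retain ≥ 8 acquisitions; short pixels redraw their dropout pattern a
  bounded number of times, then the scene errors out.
* **Yields** — linear in `NDVI_max`, season length `t_inf_2 − t_inf_1`,
  and the curve's DOY-integral over the growth window, plus Gaussian noise
  (0.30 t/ha maize, 0.15 sunflower). Coefficients were calibrated once
  against the prior feature distributions so that scene yields reproduce
  the published two-year survey statistics (maize mean/SD ≈ 11.5/2.25
  t/ha, sunflower ≈ 3.64/0.95). With yield noise zero, yield is an exact
  deterministic function of the pixel's phenology, which is what makes
  forest-recovery tests sharp.
* **Survey** — sampling points on a jittered uniform grid over each
  crop's extent, 8 nearest same-crop pixels per point; 34 maize + 54
  sunflower points give the 272/432 calibration pixels of the emulated
  ground campaign.

What the generator does **not** emulate: spatial autocorrelation of crop
parcels (labels are i.i.d.), mixed pixels, spatially or temporally
correlated cloud masks, atmospheric residuals or view-angle effects in
NDVI, inter-annual meteorological trends, and classification error in the
crop mask. Passing tests therefore demonstrate the pipeline's correctness
and its statistical behaviour under the assumed observation model, not
performance on real imagery — in particular, county-validation accuracy on
real data is also limited by crop-map errors that do not exist here.

## Problem sizes and numerical choices

Tests and the acceptance script run scenes between 24×24 and 160×160
pixels, curve-fit a few hundred to ~1300 series (≈10 ms each), and use
500-tree forests on up to 5000 training pixels; these sizes were chosen to
exercise every code path at comfortable statistical power while keeping a
full run in tens of seconds. Multi-year runs derive per-year seeds via
`SeedSequence(seed, year)`. All scene, survey, noise and forest
randomness flows from explicit seeds; reruns are bit-identical, and the
pipeline manifest records SHA-256 checksums of every artifact to prove it.

Raster outputs use the ESRI ASCII grid format (plain text, affine header)
with a synthetic 30 m georeference; tables are CSV; configs are YAML.
Trained forests are persisted with joblib at run time.

## Known limitations

* The RE definition (denominator = estimate) inflates percentages when
  estimates are small; use the `observed` switch for comparisons with
  other studies.
* Curve fitting is per-pixel and embarrassingly parallel but implemented
  serially; very large scenes are CPU-bound in `fit_pixels`.
* The generator's Bernoulli dropout understates the burstiness of real
  cloud gaps; long consecutive gaps are rarer here than in practice, so
  real-data fit failure rates will exceed the synthetic ones.
* Layouts 1–6 presume the growth windows above; transferring to another
  region requires re-specifying them.
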