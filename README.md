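# wheatcast

County-level winter wheat yield estimation from multisource
remote-sensing time series, built around a CNN-BiLSTM regressor with
Gaussian-process Bayesian hyperparameter optimization — plus a synthetic
scene generator with a *known* yield-generating process, so every stage
of the pipeline can be validated end to end without satellite archives.

**Who it is for.** Agricultural remote-sensing researchers who estimate
crop yields from fused satellite and climate time series (vegetation
indices, solar-induced chlorophyll fluorescence, reanalysis climate) and
want a tested, CPU-friendly reference implementation of the full chain:
preprocessing, the deep regressor, hyperparameter search, and the
standard evaluation protocols (feature-combination comparison, stepwise
early-season prediction, drought-year leave-one-year-out validation,
cross-region accuracy tables).

## The model

Each county-year is a (T × F) matrix: T = 31 eight-day composites from
sowing (early October, day 0) to harvest (day 248), and F features drawn
from EVI, LAI, SIF and six climate variables (T2m, Tmn, Tmx, Pre, U10m,
V10m), reduced to cropland-masked county means.

The regressor is

    input (T × F) → 1-D conv over time (ReLU) → max pool
                  → BiLSTM → [h⃗_T , h⃖_1] → dense → dense → ŷ

with the canonical LSTM gates

    f_t = σ(W_f·[h_{t−1}, x_t] + b_f)        i_t = σ(W_i·[h_{t−1}, x_t] + b_i)
    C̃_t = tanh(W_C·[h_{t−1}, x_t] + b_C)     C_t = f_t ∘ C_{t−1} + i_t ∘ C̃_t
    o_t = σ(W_o·[h_{t−1}, x_t] + b_o)        h_t = o_t ∘ tanh(C_t)

trained with Adam on z-scored yields, early-stopped on an internal
validation split.  Forward *and* backward passes are implemented in
NumPy; the vectorized layer is tested against a per-step reference
implementation of the gate equations, and the analytic gradients against
finite differences.

Hyperparameters (filter/unit counts, learning rate, batch size) are
tuned by from-scratch Bayesian optimization: an exact Matérn-5/2 GP
surrogate and Expected Improvement, `EI = (best − μ)Φ(z) + σφ(z)`,
maximized over seeded candidates (10 random initial points + 50
iterations).

Accuracy is reported as R², RMSE (kg/ha), MRE (%) and — for cross-region
tables — the accuracy ratio EY/OY × 100.

## Worked example

```python
import numpy as np
from wheatcast import (SceneConfig, simulate_county_dataset, build_samples,
                       FEATURE_ORDER, BCBLConfig)
from wheatcast.experiments import FEATURE_COMBOS, train_eval_deep

# a 40-county x 10-year synthetic scene with one drought year whose
# yield penalty is routed through SIF
cfg = SceneConfig(n_years=10, n_counties=40, grid_rows=32, grid_cols=32,
                  drought_years=(0,), drought_severity=0.7, seed=1)
data = simulate_county_dataset(cfg)
samples = build_samples(data.county_series, data.yields, FEATURE_ORDER)

sub = samples.select_features(FEATURE_COMBOS["TS+Climate+SIF"])
report, res, norm = train_eval_deep(sub, "BCBL",
                                    BCBLConfig(max_epochs=100, patience=12),
                                    seed=0)
print(res.summary())
print(f"held-out R2 = {report.r2:.3f}, RMSE = {report.rmse:.1f} kg/ha, "
      f"MRE = {report.mre:.2f}% (n = {report.n})")
```

prints

```
Sequence Yield Regression Results
==========================================================
Front end:              conv_bilstm
Architecture:           conv(32x3) -> pool(2) -> BiLSTM(32) -> dense(32,16) -> 1
No. observations:       320
No. parameters:         20161
Epochs run:             58 (max 100, patience 12)
Final train MSE (z):    0.1953
Best val MSE (z):       0.1314
Train R^2:              0.8435
Target mean/sd (kg/ha): 6609.9 / 831.7
==========================================================
held-out R2 = 0.829, RMSE = 329.5 kg/ha, MRE = 3.95% (n = 80)
```

The scene's noise-free yields give an oracle R² of 0.87, so a held-out
R² of 0.83 means the model has extracted nearly all the extractable
signal; the 330 kg/ha RMSE sits just above the scene's 300 kg/ha yield
noise floor.  On this generator, adding SIF to the EVI/LAI pair raises
held-out R² by ≈ 0.25, and in the drought year (where stress attenuates
SIF and depresses yields) the TS+Climate+SIF model beats TS+Climate by
≈ 170 kg/ha RMSE under leave-one-year-out validation — the qualitative
patterns the pipeline is designed to detect.

A thin CLI wraps the same library
(`wheatcast simulate|train|tune|evaluate|stepwise|drought ...` with a
YAML config); see `wheatcast --help`.

## Layout

- `wheatcast.scene` — synthetic scene generator (phenology, climate,
  SPEI, counties, yields with recorded noise-free truth)
- `wheatcast.preprocess` — SG smoothing, MVC compositing, climate
  aggregation, bilinear resampling, zonal means, normalization, SPEI
  classes, sample assembly
- `wheatcast.model` — `CNNBiLSTMYield` / `LSTMYield` model classes,
  `fit()` → results with `summary()`, reference gate equations
- `wheatcast.bayesopt` — GP + Expected Improvement optimizer
- `wheatcast.evaluation` — metrics, splits, the cross-region reference
  table
- `wheatcast.experiments` — feature-combination, stepwise, drought and
  cross-region drivers; tree baselines
- `wheatcast.cli` / `wheatcast.io` — command line and file round-trips

See `docs/methods.md` for the modelling assumptions, parameter defaults
and limitations.
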