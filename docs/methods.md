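# Methods

`wheatcast` estimates county-level winter wheat yields from multisource
remote-sensing time series with a CNN-BiLSTM regressor, tuned by
Gaussian-process Bayesian optimization, and validates the whole chain on
synthetic scenes whose yield-generating process is known exactly.  This
note records the models, the defaults and why, and what the synthetic
experiments do and do not demonstrate.

## The estimation problem

The unit of analysis is a county-year.  Its predictors are a (T × F)
matrix of 8-day composite means over the county's cropland: vegetation
indices (EVI, LAI), solar-induced chlorophyll fluorescence (SIF), and six
reanalysis-style climate variables (T2m, Tmn, Tmx, Pre, U10m, V10m).
Time runs over one growing season — day 0 is sowing in early October,
harvest is day 248, so T = 31 eight-day composites.  The target is the
official county yield in kg/ha.

## Preparation chain

- **Savitzky–Golay smoothing** (window 9, order 2) of EVI/LAI series,
  pixelwise.  An order-2 SG filter reproduces any quadratic exactly, so
  phenological peaks are preserved while composite-level noise is damped.
  Edge handling fits the polynomial to the nearest full window and
  evaluates it at the edge position (scipy's `mode="interp"`), keeping
  the output length equal to the input length without padding artifacts.
- **Maximum-value compositing (MVC)** of 4-day SIF frames into 8-day
  windows `[start, start+8)`: the per-pixel maximum suppresses cloud and
  atmospheric contamination, which biases retrievals low.  Nodata cells
  are ignored unless the whole window is nodata.
- **8-day aggregated averaging** of daily climate grids, aligned to the
  vegetation composite windows.  The arithmetic mean is applied to all
  six variables, precipitation included.  Averaging (rather than
  summing) precipitation is physically debatable but keeps all channels
  on a per-day scale; only relative temporal structure reaches the model.
- **Bilinear resampling** on cell-center coordinates for grids that
  arrive at a different resolution.
- **Zonal means**: per county and composite, the mean over pixels that
  are both inside the county and cropland-masked.  Counties with no
  masked pixels raise an error rather than disappearing silently.
- **Min-max normalization to [0, 1]** per feature.  Statistics are
  learned on the training split only and frozen for every later use
  (test sets, stepwise truncations, cross-region transfer); out-of-range
  values clip.  This prevents information leaking from evaluation data
  into the scaling.
- **SPEI drought classes**: ND (> −0.5), MD1 (−0.5 ≥ SPEI > −1),
  MD2 (−1 ≥ SPEI > −1.5), SD (−1.5 ≥ SPEI > −2), ED (≤ −2); boundaries
  belong to the more severe class.

## The CNN-BiLSTM regressor

Architecture: 1-D convolution along the composite axis (features as
channels, 'same' length, ReLU) → temporal max pooling (size 2) → a
bidirectional LSTM → the 2H concatenation of each direction's final
state → two dense layers (ReLU) → linear scalar output.  The baseline is
a single unidirectional LSTM with the same dense head.

The LSTM cell follows the standard gate equations — forget, input and
output gates through logistic sigmoids of `W·[h_{t−1}, x_t] + b`, a tanh
candidate state, `C_t = f∘C_{t−1} + i∘C̃`, `h_t = o∘tanh(C_t)`.  A
per-step reference implementation of these equations lives in
`wheatcast.model`; the vectorized batched layer used in training is
tested against it to 1e-5, and the full network's analytic gradients are
verified against central finite differences.

Training choices (paper-silent points decided here):

- ReLU for conv and dense layers, linear output — the standard choice
  for regression heads.
- Max pooling of size 2.
- The dense head consumes the final state of each BiLSTM direction
  (forward at t = T−1; backward at t = 0 of the re-aligned output, i.e.
  the state that has consumed the whole sequence).  This is the usual
  `Bidirectional(..., return_sequences=False)` semantics; summarizing
  with the temporal mean was rejected for simplicity.
- Targets are z-scored on the training samples for optimization and
  de-standardized to kg/ha for every reported number.  Constant targets
  degrade gracefully to "predict the constant".
- Optimizer: Adam at learning rate 1e-3, mini-batches of 32 with seeded
  shuffling.  1e-3 converges more stably than larger steps for these
  layer sizes; the Bayesian search space brackets it (1e-4 to 1e-2).
- Early stopping on an internal 20% validation split, patience 10
  (tests and the acceptance runs use patience 12), at most 100 epochs;
  the parameters at the best validation loss are kept.
- Forget-gate biases initialize at 1 so early epochs do not flush the
  cell state; other weights are Glorot-uniform from a seeded generator.
  Training is bit-reproducible given a seed on a fixed platform; exact
  floating-point reproducibility across BLAS builds is not promised.

Default sizes (conv 32×3, BiLSTM 32, dense 32/16) are modest
CPU-friendly values inside the search ranges below.

## Bayesian hyperparameter optimization

A from-scratch minimizer for expensive objectives: an exact GP surrogate
with a Matérn-5/2 kernel on z-scored objective values (jitter 1e-6;
length-scale by marginal-likelihood grid search), and Expected
Improvement for minimization, `EI = (best − μ)Φ(z) + σφ(z)` with
`z = (best − μ)/σ`.  The acquisition is maximized over 2048 seeded
uniform candidates in the unit cube — candidate sampling rather than
gradient ascent, because integer-valued dimensions (filter counts, unit
counts) make gradients ill-defined.  Integer parameters decode by
rounding, learning rates decode on a log scale.

The loop evaluates 10 random configurations, then 50 iterations of
fit–propose–evaluate (history length exactly 60; failed trials are
recorded with a penalty value and the loop continues).  An optional
convergence stop (EI < 1e-6 for 5 consecutive iterations) is off by
default so the history length stays predictable.  The tuning objective
is validation RMSE on an inner 20% split.  Default search ranges:
conv filters [16, 128], kernel [2, 5], BiLSTM units [16, 128], dense
[8, 64]², learning rate log-[1e-4, 1e-2], batch size [16, 64].

## Evaluation protocols

- R² about the mean observed yield; RMSE in kg/ha; MRE as the mean
  *absolute* relative error in percent (without the absolute value,
  over- and under-estimates cancel and the statistic stops being an
  error magnitude).
- Accuracy ratio EY/OY × 100 per county-year for cross-region tables,
  reported to 2 decimals; values above 100 are overestimates.
- Splits: seeded uniform 80/20 for the deep models (unstratified — the
  split protocol is recorded in run manifests); 5-fold CV averaged for
  the tree baselines (RF, XGBoost on flattened (T·F) vectors);
  leave-one-year-out for temporal generalization and drought-year
  validation.
- Stepwise early-season analysis retrains the model (fixed
  hyperparameters, fixed test split, fresh weights) on progressively
  longer input windows [0, t).  Hyperparameters are not re-tuned per
  truncation: re-tuning would multiply cost by T and confound the
  trajectory with search noise.

## The synthetic scene generator

The generator emulates the statistical structure the analysis assumes,
not radiative transfer or crop physiology:

- **Counties**: Voronoi partition around seed pixels drawn without
  replacement (every county keeps at least one pixel); Bernoulli
  cropland mask (default fraction 0.6).
- **Phenology**: per-pixel EVI follows a double-logistic curve
  `base + amp·[σ(r₁(t−t₁)) − σ(r₂(t−t₂))]` with green-up near day 140
  and senescence near day 215 — a winter-wheat shape with growth paused
  over winter.  County-year random effects perturb the amplitude
  (relative sd 0.20) and the inflection days (sd 5 d).  LAI is the
  monotone surrogate `6·EVI^1.2` clipped to [0, 7]; only relative
  structure matters downstream.  SIF is `1.2·EVI·L(t)` with a seasonal
  light term, emitted at 4-day cadence so the MVC step is exercised for
  real.  Independent Gaussian noise (sd 0.02) is added to each variable.
- **Climate**: sinusoidal seasonal cycles (coldest mid-January) plus
  noise and a per-year anomaly; `Tmn ≤ T2m ≤ Tmx` enforced pointwise,
  precipitation rectified at zero.
- **Drought years** multiply SIF by a severity factor (default 0.7)
  inside a spring stress window (composites 19–28, roughly early March
  to early May) and push in-window monthly SPEI into the configured
  drought band; other months draw SPEI ~ N(0.2, 0.3).
- **Yields**: `b₀ + b₁·ΣSIF_critical + b₂·ΣEVI_season + b₃·GDD −
  b₄·heat_exceedance − b₅·max(0, −mean SPEI) + ε`, with county-mean
  integrals, GDD = Σ max(T2m − 0, 0), heat exceedance above 28 °C on
  Tmx, and ε ~ N(0, 300 kg/ha).  Defaults (b₀ = 1500, b₁ = 700,
  b₂ = 200, b₃ = 0.5, b₄ = 10, b₅ = 800) were chosen analytically so
  that typical yields sit near 6500 kg/ha, the deterministic signal sd
  is roughly 700 kg/ha, and the best achievable ("oracle") R² is about
  0.85 — the regime the validation experiments are designed for.  The
  noise-free yield is recorded beside the noisy one, so oracle skill is
  measurable, and an independent brute-force scan over pixels and
  windows reproduces it exactly in the tests.

Because the drought penalty is routed through SIF, models that see SIF
can explain drought-year yields that TS+Climate models cannot — the
mechanism behind the drought-validation experiment.

What passing these experiments shows: the pipeline wiring, the training
machinery, the protocols, and the qualitative orderings (SIF adds skill;
SIF helps most in drought years; accuracy accumulates through the
critical window) behave as designed.  What it does not show: performance
on real MODIS/reanalysis archives, whose spatial autocorrelation, sensor
artifacts, cloud contamination and management-driven yield variation the
generator does not emulate.  Absolute error levels on synthetic scenes
(RMSE near the 300 kg/ha noise floor) are not forecasts of real-data
error.

## Problem sizes

The default synthetic scale is 93 counties × 10 years (930 samples) on a
64×64 grid.  The test suite and the acceptance script use a 40-county ×
10-year scene (400 samples, 32×32 grid) for model-skill statistics and a
12-county × 4-year miniature for protocol checks; medians over 5 seeds
are reported.  These sizes were chosen so a complete run stays
comfortable on a single CPU while keeping the statistics stable.

## Known limitations

- No spatial autocorrelation within counties beyond shared phenology
  parameters; no cross-county teleconnections.
- The grid is unit-spaced with no geographic projection; bilinear
  resampling is provided but the generator emits all variables on a
  common grid.
- The yield process is linear in its integrals; real yield formation is
  not, and the deep models' margin over linear-ish baselines is
  correspondingly small on synthetic scenes.
- Precipitation and wind enter the feature set but not the synthetic
  yield process (beyond SPEI), so they act as realistic distractors.
- Training determinism is per-platform; different BLAS builds may
  produce slightly different trained weights.
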