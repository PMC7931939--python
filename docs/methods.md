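# Methods

This note records the modeling assumptions, parameter choices, and numerical
conventions behind `medcast`, and what the synthetic benchmark does and does
not demonstrate.

## Data model and evaluation

The unit of analysis is a gap-free daily series of average per-patient
expenditure, `value_t = total_spent_t / patient_count_t` (USD per patient per
day). Days with zero refills are rejected rather than imputed: the quotient
is undefined there, and the reader assumes every day has at least one refill.

Models are scored on *weekly blocks*: consecutive 7-day windows counted from
the series start, each the sum of its 7 daily values. Blocks are not
calendar-aware, and trailing days that do not fill a block are dropped (a
1,306-day training window therefore yields exactly 186 blocks and a 259-day
test window 37). Metrics are weekly RMSE and the coefficient of
determination R² = 1 − SS_res/SS_tot. R² may be negative and is reported
as-is; it is undefined for a constant actual series, which is an error in
the strict scorer (`evaluate`, `score_weekly`) and reported as NaN with an
RMSE-only objective by the lenient pipeline scorer (`score_weekly_safe`),
so that degenerate simulations (zero innovation noise) still produce a
report.

Calibration uses the joint objective `RMSE/10 + (1 − R²)`. The RMSE term is
computed on the standardized weekly scale whenever a scaler is available:
after the [−1, +1] rescaling both terms vary on a comparable O(1) range,
which is the point of the 1/10 factor. Reported RMSEs are always on the
original USD scale (R² is invariant under the affine rescaling, so only the
objective's RMSE term changes).

Standardization maps the *training* minimum and maximum onto [−1, +1]; test
values may legitimately fall outside that interval. Fitting the scaler on
training data only avoids look-ahead leakage.

Stationarity is decided by the augmented Dickey–Fuller test (statsmodels,
AIC lag selection) at α = 0.05, searching d ∈ {0, 1, 2}: the recommended d
is the smallest at which the unit-root null is rejected. A constant series
is treated as trivially stationary. Note the test has its nominal size: on
a truly integrated series the null is falsely rejected in roughly 5% of
samples, so occasionally an integrated simulation is modeled at d = 0. This
is a property of the test, not a defect of the generator, and it is why the
regime-identification properties in the test suite are asserted across
seeds at a 95% rate rather than pointwise.

## Walk-forward protocol

All forecasters predict one step ahead. During the test period each actual
value is appended to the conditioning history after its prediction is made,
and fitted parameters are *frozen* — only the history grows. Re-estimating
parameters at each of the 259 test steps, for each of 30 runs, would
multiply the cost by four orders of magnitude for no change in the
protocol's logic; freezing is the package's design choice and is applied
uniformly to all models.

Predictions cross scales deterministically: a model operating on the
differenced standardized scale has its prediction added to the previous
day's (actual) standardized value, then unscaled to USD. A consequence used
as a test oracle: a model that always predicts a zero difference reduces
exactly to the persistence baseline.

In-sample (training-period) one-step predictions align day-for-day with the
training series. The first `lag + d` days have no preceding window; they are
filled with the actual values. This zero-error placeholder touches at most a
handful of days out of 1,306 and keeps the weekly blocking and the ensemble's
sample count aligned with the full training period.

## Component forecasters

**Persistence** needs no parameters and is the baseline every other model
must beat.

**ARIMA** is estimated by statsmodels' state-space ARIMA (conditional
likelihood handling and differencing internal to the model). The (p, q)
order is chosen by grid search over [0, 5] × [0, 5] at the ADF-determined d,
scoring each candidate's in-sample one-step predictions with the weekly
objective; non-convergent cells are skipped with a warning, and ties are
broken by smallest p + q, then smallest p (parsimony). A hand-written
one-step predictor implementing the model equation directly
(`arima_predict_one`, conditional residual recursion) exists alongside the
statsmodels path and is cross-checked against it on pure-AR models in the
tests; keeping both routes separate preserves an independent oracle.

**MLP and LSTM** are self-contained numpy implementations: explicit forward
and backward passes, mean-squared-error loss, Adam at learning rate 1e−3
(β₁ = 0.9, β₂ = 0.999). The MLP applies ReLU on hidden layers and a linear
output unit. The LSTM uses standard gated memory cells with sigmoid
input/forget/output gates; ReLU serves as the cell-input and cell-output
activation (the convention used when a ReLU activation is requested on a
recurrent layer), the forget-gate bias is initialized to 1, and a single
linear unit reads the final hidden state. Initialization is Glorot-uniform
from a per-trainer seeded generator; every source of randomness
(initialization, mini-batch shuffling, dropout masks) flows from that one
generator, so training is bit-for-bit reproducible from the seed.

Training regimes: mini-batches are presented chronologically unless
`shuffle` is on (reshuffled each epoch). Dropout is the inverted variant at
rate 0.20 — *node* dropout masks hidden-layer outputs (both nets), and
*recurrent* dropout masks the previous hidden state on the recurrent path
(LSTM only); recurrent-layer masks are drawn once per batch and shared
across time steps. When the rate is zero no masks are drawn at all, which
makes a zero-rate dropout run consume the identical random stream as a plain
run — the degenerate-equivalence property the tests assert bitwise. The lag
is 2 on the modeling scale for both nets (so a d = 1 series consumes 3
original days per window).

The repeated-run protocol reruns a stochastic trainer n times (default 30)
with seeds `seed_base + k`; the run with the lowest *training* objective is
"best" and supplies the predictions used downstream, while cross-run
mean/sd of the test metrics support model comparison. Deterministic
forecasters are trained once and replicated, since every run would be
identical.

## Genetic algorithm

The GA searches the 4 × 5 × 4 × 7 = 560-point grid of (hidden layers,
neurons, batch size, epochs). Chromosomes are tuples of grid indices, so
every individual the operators emit decodes to a legal architecture.
Operators follow the stated rates — per-gene mutation 0.20 (resampling from
the gene's grid), single-point crossover 0.80 — with tournament selection of
size 3, elitism of 1, and population 20. Population size and selection
scheme are the package's own defaults: the space is small and discrete, and
tournament selection is standard and parameter-light. Stopping combines the
two stated rules: run at least 100 generations, then stop at the first 20
consecutive generations without improvement. Fitness values are cached so
each unique chromosome is evaluated once; inside the GA a stochastic trainer
is evaluated with a single seeded run (the repeated-run protocol applies
after the GA picks the winner).

## Ensemble

Weights over the ARIMA/MLP/LSTM best-run *training* predictions start at
1/N and are updated once per training day by
`w_i ← w_i · exp(−η · l_it)` with `l_it = (f_it − y_t)²`, then renormalized.
Persistence is not a component. Two numerical conventions matter:

- **Sign of the exponent.** The update must *down*-weight large errors;
  the implementation uses `exp(−η·l)`, consistent with the
  exponential-weights literature and with the observable behavior that the
  worst component's weight collapses toward zero as η grows.
- **Loss scale.** Squared errors are computed on the standardized daily
  scale by default (`loss_scale` equivalent: pass the scaler), keeping
  η·Σl at a magnitude where the exponential is well-behaved; the original
  USD scale is available by omitting the scaler. Internally weights are
  carried in log space, so the sequential update telescopes exactly to the
  closed form `w_i ∝ exp(−η Σₜ l_it)` and cannot underflow even at large
  η·Σl. The closed form doubles as the independent oracle in the tests
  (agreement to 1e−9).

η is calibrated over {0.0, 0.1, …, 1.0} by the weekly objective of the
combined training predictions; ties prefer the smallest η. Weights are
frozen after training; there is no online updating during the test period.
The test-period ensemble forecast is the pointwise convex combination of the
component test predictions.

## Synthetic data

The generator emulates the two regimes the pipeline must distinguish, with
defaults chosen once to resemble realistic per-patient expenditures:

| parameter | default | meaning |
|---|---|---|
| `n_days` | 1,565 | canonical span; splits 1,306 train / 259 test |
| `ar`, `ma` | (0.6, −0.2), (0.3,) | ARMA structure of the noise |
| `base_level` | 40 USD/patient/day | weekly blocks ≈ 280 USD, hundreds-of-USD scale |
| `innovation_sd` | 4 USD | daily innovation |
| `drift`, `walk_sd` | 0.02, 1.2 USD/day | integrated regime only |
| `refill_rate` | 500 patients/day | for emitting totals/counts |

The stationary regime is `base_level` + ARMA noise; the integrated regime
adds a drifting random walk. Values are truncated at zero after noise
addition (expenditures are nonnegative) — a deliberate deviation from a pure
ARMA law, negligible at the default signal-to-noise ratio. ARMA noise is
simulated by direct recursion with a 200+-step burn-in.

What passing tests on this generator do **not** show: real expenditure
series have calendar structure (weekday/holiday effects), heavy-tailed and
heteroskedastic innovations, occasional level shifts from price changes, and
missing or zero-refill days. None of these are emulated, so the benchmark
demonstrates the *machinery* (preprocessing, training regimes, order
selection, weighting) rather than clinical forecast accuracy.

## Problem sizes used in the shipped runs

The test suite and the acceptance script favor demonstration-scale settings
chosen to exercise every code path at full fidelity while completing
quickly: repeated runs use n = 3 (the protocol is identical for n = 30, only
the minimum is taken over fewer draws), neural demonstrations use fixed
small architectures (1–2 layers, 8 neurons, 64 epochs) instead of a full GA
sweep, and AR-recovery/GA-optimality properties use 20–50 seeds. The GA's
search behavior is validated against exhaustive enumeration of its 560-point
space on cheap synthetic fitness surfaces, which isolates the search
dynamics from network training noise.

## Known limitations

- Walk-forward freezes parameters; slow drift in the data-generating process
  during the test period is absorbed only through the growing history, not
  through re-estimation.
- The ADF-based choice of d inherits the test's size and power; borderline
  series can be mis-differenced (see above), and d > 2 is not searched.
- The grid-searched ARIMA order minimizes the in-sample weekly objective,
  which measures low-frequency fit; it is not an information criterion and
  can prefer a compact misspecified model whose weekly aggregates track
  better.
- The ensemble weights are a single probability vector per series; there is
  no time-varying or state-dependent weighting.
- Neural training is plain Adam without early stopping or regularization
  beyond dropout; epoch counts from the grid are trusted as given.
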