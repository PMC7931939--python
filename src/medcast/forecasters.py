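"""Component forecasters and their one-step-ahead walk-forward evaluation.

Four forecasters share one contract: fit on the training portion of a daily
expenditure series, then predict the test period one step at a time with
walk-forward validation — after each prediction the *actual* value joins the
conditioning history (fitted parameters are frozen; only the history grows).
Predictions always come back on the original USD scale: each forecaster
carries a preprocessing recipe (differencing order ``d``, an optional
[-1, +1] scaler fitted on training data, and the lag window length) and
inverts it internally.

* persistence — the naive baseline, next value = last observed value;
* ARIMA(p, d, q) — linear model estimated with statsmodels, with the
  (p, q) order chosen by grid search over [0, 5] x [0, 5] on the training
  objective;
* MLP — feed-forward net on lag windows (ReLU hidden layers, linear out);
* LSTM — stacked recurrent net consuming the lag window as a sequence.

The neural trainers support the shuffle x dropout regimes (mini-batch
shuffling on/off; node dropout for both nets, recurrent-connection dropout
for the LSTM, at rate 0.20) and the best-of-n-runs protocol: a stochastic
trainer is rerun ``n_runs`` times (seeds ``seed_base + k``) and the run
minimizing the training objective supplies the predictions handed to the
ensemble, while cross-run mean/sd metrics support model comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from statsmodels.tsa.arima.model import ARIMA as _SMARIMA

from ._nn import LSTMNet, MLPNet, mlp_forward  # noqa: F401  (re-exported)
from .series import (
    DailySeries,
    ScalerParams,
    SupervisedSet,
    difference,
    make_supervised,
    score_weekly,
    score_weekly_safe,
)

__all__ = [
    "HIDDEN_LAYERS_GRID",
    "NEURONS_GRID",
    "BATCH_SIZE_GRID",
    "EPOCHS_GRID",
    "ArimaOrder",
    "ArimaModel",
    "NeuralSpec",
    "Recipe",
    "Forecaster",
    "PersistenceForecaster",
    "ArimaForecaster",
    "NeuralForecaster",
    "RunSet",
    "persistence_predict",
    "arima_predict_one",
    "grid_search_arima",
    "fit_arima",
    "fit_persistence",
    "train_mlp",
    "train_lstm",
    "fit_mlp",
    "fit_lstm",
    "prepare_supervised",
    "walk_forward",
    "run_repeated",
    "mlp_forward",
]

# Hyperparameter grids searched for the neural forecasters.
HIDDEN_LAYERS_GRID = (1, 2, 3, 4)
NEURONS_GRID = (4, 8, 16, 32, 64)
BATCH_SIZE_GRID = (5, 10, 15, 20)
EPOCHS_GRID = (8, 16, 32, 64, 128, 256, 512)


def _values(series) -> np.ndarray:
    if isinstance(series, DailySeries):
        return series.values
    return np.asarray(series, dtype=float)


# ---------------------------------------------------------------------------
# persistence


def persistence_predict(history) -> float:
    """Next value = last observed value (the baseline forecaster)."""
    history = _values(history)
    if len(history) == 0:
        raise ValueError("persistence needs at least one observed value")
    return float(history[-1])


# ---------------------------------------------------------------------------
# ARIMA


@dataclass(frozen=True)
class ArimaOrder:
    """(p, d, q): autoregressive order, differencing degree, moving-average order."""

    p: int
    d: int
    q: int

    def __post_init__(self) -> None:
        if not (0 <= self.p <= 5 and 0 <= self.q <= 5):
            raise ValueError("p and q must lie in [0, 5]")
        if self.d not in (0, 1, 2):
            raise ValueError("d must be 0, 1, or 2")


@dataclass(frozen=True)
class ArimaModel:
    """Explicit ARIMA coefficient bundle for hand-computable one-step forecasts.

    The model equation on the (d-times differenced) series y' is
    ``y'_t = c + sum_i phi_i y'_{t-i} + sum_j theta_j e_{t-j} + e_t``.
    """

    order: ArimaOrder
    constant: float = 0.0
    ar_coefficients: tuple[float, ...] = ()
    ma_coefficients: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if len(self.ar_coefficients) != self.order.p:
            raise ValueError("ar_coefficients must have length p")
        if len(self.ma_coefficients) != self.order.q:
            raise ValueError("ma_coefficients must have length q")


def arima_predict_one(model: ArimaModel, history) -> float:
    """One-step forecast from the model equation, conditional on the history.

    ``history`` is the differenced series y'.  Residuals are reconstructed
    recursively (zero before enough history exists — the conditional
    convention) and the forecast step's own innovation is set to zero.
    """
    y = _values(history)
    p, q = model.order.p, model.order.q
    if len(y) < max(p, q):
        raise ValueError(f"history of length {len(y)} too short for p={p}, q={q}")
    phi = np.asarray(model.ar_coefficients)
    theta = np.asarray(model.ma_coefficients)
    resid = np.zeros(len(y))
    for t in range(p, len(y)):
        pred = model.constant + float(phi @ y[t - 1 :: -1][:p]) if p else model.constant
        if q:
            past = resid[max(t - q, 0) : t][::-1]
            pred += float(theta[: len(past)] @ past)
        resid[t] = y[t] - pred
    nxt = model.constant
    if p:
        nxt += float(phi @ y[::-1][:p])
    if q:
        past = resid[::-1][:q]
        nxt += float(theta[: len(past)] @ past)
    return float(nxt)


# ---------------------------------------------------------------------------
# recipes and the forecaster contract


@dataclass(frozen=True)
class Recipe:
    """Preprocessing applied before modeling and inverted after prediction.

    The modeling scale is the [-1, +1]-standardized series differenced ``d``
    times; ``lag`` model-scale values form a prediction window (consuming
    ``lag + d`` original days).
    """

    d: int = 0
    scaler: ScalerParams | None = None
    lag: int = 1


class Forecaster:
    """Fitted one-step-ahead forecaster with frozen parameters.

    Subclasses implement :meth:`predict_window` on the modeling scale; the
    base class handles walk-forward evaluation and scale inversion.
    """

    kind: str = "base"

    def __init__(self, recipe: Recipe):
        self.recipe = recipe

    # -- modeling-scale prediction ------------------------------------
    def predict_window(self, window: np.ndarray) -> float:
        raise NotImplementedError

    # -- USD-scale machinery ------------------------------------------
    def _to_model_scale(self, usd: np.ndarray) -> np.ndarray:
        scaled = self.recipe.scaler.scale(usd) if self.recipe.scaler else usd
        return difference(scaled, self.recipe.d) if self.recipe.d else scaled

    def predict_next(self, history_usd) -> float:
        """Predict the next day's USD value from a USD history."""
        r = self.recipe
        usd = _values(history_usd)
        need = r.lag + r.d
        if len(usd) < need:
            raise ValueError(f"need at least {need} days of history")
        tail = usd[-need:]
        scaled = r.scaler.scale(tail) if r.scaler else tail
        pred = self.predict_window(difference(scaled, r.d) if r.d else scaled)
        for k in range(r.d, 0, -1):  # undo differencing, innermost first
            pred = pred + difference(scaled, k - 1)[-1]
        return float(r.scaler.unscale(pred)) if r.scaler else float(pred)

    def walk_forward(self, train, test) -> np.ndarray:
        """One-step-ahead predictions over the test period, USD scale.

        After each step the actual test value is appended to the history;
        parameters are not re-estimated.
        """
        history = list(_values(train))
        preds = np.empty(len(_values(test)))
        for t, actual in enumerate(_values(test)):
            preds[t] = self.predict_next(np.asarray(history))
            history.append(actual)
        return preds

    def train_predictions(self, train) -> np.ndarray:
        """In-sample one-step-ahead predictions on the training days, USD scale.

        The first ``lag + d`` days have no preceding window; they are filled
        with the actual values so the output aligns day-for-day with the
        training series (documented zero-error placeholder).
        """
        usd = _values(train)
        burn = self.recipe.lag + self.recipe.d
        preds = usd.copy()
        for t in range(burn, len(usd)):
            preds[t] = self.predict_next(usd[:t])
        return preds


class PersistenceForecaster(Forecaster):
    kind = "persistence"

    def __init__(self) -> None:
        super().__init__(Recipe(d=0, scaler=None, lag=1))

    def predict_window(self, window: np.ndarray) -> float:
        return float(window[-1])


def fit_persistence(train=None) -> PersistenceForecaster:
    """The baseline needs no fitting; accepts train data for API symmetry."""
    return PersistenceForecaster()


class ArimaForecaster(Forecaster):
    """statsmodels-estimated ARIMA with frozen parameters.

    Differencing is handled inside the state-space model (the order's ``d``),
    so the modeling input is the standardized, undifferenced series and
    walk-forward prediction re-filters the grown history with ``apply``.
    """

    kind = "arima"

    def __init__(self, order: ArimaOrder, results, scaler: ScalerParams | None):
        super().__init__(Recipe(d=0, scaler=scaler, lag=max(order.p + order.d, order.q, 1)))
        self.order = order
        self._results = results

    def predict_window(self, window: np.ndarray) -> float:  # pragma: no cover
        raise NotImplementedError("ArimaForecaster predicts via the filtered history")

    def _scaled(self, usd: np.ndarray) -> np.ndarray:
        return self.recipe.scaler.scale(usd) if self.recipe.scaler else usd

    def _unscale(self, x: np.ndarray) -> np.ndarray:
        return self.recipe.scaler.unscale(x) if self.recipe.scaler else np.asarray(x)

    def predict_next(self, history_usd) -> float:
        refiltered = self._results.apply(self._scaled(_values(history_usd)))
        return float(self._unscale(refiltered.forecast(1))[0])

    def walk_forward(self, train, test) -> np.ndarray:
        train_v, test_v = _values(train), _values(test)
        if len(test_v) == 0:
            return np.empty(0)
        full = self._scaled(np.concatenate([train_v, test_v]))
        refiltered = self._results.apply(full)
        preds = refiltered.predict(start=len(train_v), end=len(full) - 1)
        return self._unscale(np.asarray(preds))

    def train_predictions(self, train) -> np.ndarray:
        usd = _values(train)
        refiltered = self._results.apply(self._scaled(usd))
        preds = self._unscale(np.asarray(refiltered.predict(start=0, end=len(usd) - 1)))
        burn = self.order.d  # differenced levels are undefined for the first d days
        preds[:burn] = usd[:burn]
        return preds


def fit_arima(train, order: ArimaOrder, scaler: ScalerParams | None = None) -> ArimaForecaster:
    """Estimate an ARIMA of the given order on the (standardized) training series."""
    usd = _values(train)
    endog = scaler.scale(usd) if scaler else usd
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results = _SMARIMA(endog, order=(order.p, order.d, order.q)).fit()
    return ArimaForecaster(order, results, scaler)


def grid_search_arima(
    train,
    d: int,
    p_max: int = 5,
    q_max: int = 5,
    scaler: ScalerParams | None = None,
) -> ArimaOrder:
    """Choose (p, q) minimizing the weekly training objective at fixed d.

    All (p_max+1) x (q_max+1) candidates are fit; non-convergent fits are
    skipped with a warning.  Ties are broken by smallest p + q, then
    smallest p (parsimony).
    """
    usd = _values(train)
    best: tuple[float, int, int, ArimaOrder] | None = None
    for p in range(p_max + 1):
        for q in range(q_max + 1):
            order = ArimaOrder(p, d, q)
            try:
                fc = fit_arima(usd, order, scaler)
                preds = fc.train_predictions(usd)
                report = score_weekly(preds, usd, scaler)
                if not np.isfinite(report.objective):
                    raise ValueError("non-finite objective")
            except Exception as exc:  # noqa: BLE001 — skip non-convergent cells
                warnings.warn(f"ARIMA({p},{d},{q}) skipped: {exc}", stacklevel=2)
                continue
            key = (round(report.objective, 12), p + q, p)
            if best is None or key < best[:3]:
                best = (*key, order)
    if best is None:
        raise RuntimeError("no ARIMA candidate converged on this series")
    return best[3]


# ---------------------------------------------------------------------------
# neural forecasters


@dataclass(frozen=True)
class NeuralSpec:
    """Hyperparameter bundle for the neural trainers.

    Architecture values must come from the search grids; ``dropout_mode``
    ``recurrent`` is only valid for the LSTM.
    """

    hidden_layers: int = 1
    neurons_per_layer: int = 8
    batch_size: int = 10
    epochs: int = 64
    lag: int = 2
    shuffle: bool = False
    dropout_mode: str = "none"
    dropout_rate: float = 0.20

    def __post_init__(self) -> None:
        checks = (
            (self.hidden_layers, HIDDEN_LAYERS_GRID, "hidden_layers"),
            (self.neurons_per_layer, NEURONS_GRID, "neurons_per_layer"),
            (self.batch_size, BATCH_SIZE_GRID, "batch_size"),
            (self.epochs, EPOCHS_GRID, "epochs"),
        )
        for value, grid, name in checks:
            if value not in grid:
                raise ValueError(f"{name}={value} not in grid {grid}")
        if self.lag < 1:
            raise ValueError("lag must be >= 1")
        if self.dropout_mode not in ("none", "node", "recurrent"):
            raise ValueError(f"unknown dropout_mode {self.dropout_mode!r}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")

    @property
    def effective_dropout(self) -> float:
        return self.dropout_rate if self.dropout_mode != "none" else 0.0


def train_mlp(supervised: SupervisedSet, spec: NeuralSpec, seed: int) -> MLPNet:
    """Backprop-train an MLP on the supervised lag windows (modeling scale)."""
    if spec.dropout_mode == "recurrent":
        raise ValueError("recurrent dropout is undefined for the feed-forward MLP")
    net = MLPNet(spec.lag, spec.hidden_layers, spec.neurons_per_layer, seed)
    return net.fit(
        supervised.inputs,
        supervised.targets,
        epochs=spec.epochs,
        batch_size=spec.batch_size,
        shuffle=spec.shuffle,
        dropout_rate=spec.effective_dropout,
    )


def train_lstm(supervised: SupervisedSet, spec: NeuralSpec, seed: int) -> LSTMNet:
    """Train a stacked LSTM consuming each lag window as a length-lag sequence."""
    net = LSTMNet(spec.lag, spec.hidden_layers, spec.neurons_per_layer, seed)
    return net.fit(
        supervised.inputs,
        supervised.targets,
        epochs=spec.epochs,
        batch_size=spec.batch_size,
        shuffle=spec.shuffle,
        dropout_rate=spec.effective_dropout,
        dropout_mode=spec.dropout_mode if spec.effective_dropout > 0 else "none",
    )


class NeuralForecaster(Forecaster):
    def __init__(self, kind: str, net, recipe: Recipe):
        super().__init__(recipe)
        self.kind = kind
        self.net = net

    def predict_window(self, window: np.ndarray) -> float:
        return float(self.net.predict(np.asarray(window)[None, :])[0])


def prepare_supervised(train, d: int, lag: int, scaler: ScalerParams | None) -> SupervisedSet:
    """Standardize, difference d times, and slide the lag window."""
    usd = _values(train)
    scaled = scaler.scale(usd) if scaler else usd
    model_scale = difference(scaled, d) if d else scaled
    return make_supervised(model_scale, lag)


def fit_mlp(train, spec: NeuralSpec, seed: int, d: int = 0,
            scaler: ScalerParams | None = None) -> NeuralForecaster:
    supervised = prepare_supervised(train, d, spec.lag, scaler)
    return NeuralForecaster("mlp", train_mlp(supervised, spec, seed),
                            Recipe(d, scaler, spec.lag))


def fit_lstm(train, spec: NeuralSpec, seed: int, d: int = 0,
             scaler: ScalerParams | None = None) -> NeuralForecaster:
    supervised = prepare_supervised(train, d, spec.lag, scaler)
    return NeuralForecaster("lstm", train_lstm(supervised, spec, seed),
                            Recipe(d, scaler, spec.lag))


# ---------------------------------------------------------------------------
# walk-forward + repeated runs


def walk_forward(forecaster: Forecaster, train, test) -> np.ndarray:
    """One-step-ahead walk-forward test predictions on the USD scale."""
    return forecaster.walk_forward(train, test)


@dataclass(frozen=True)
class RunSet:
    """Outcome of the repeated-run protocol for one forecaster.

    The run minimizing the training objective is "best"; its predictions
    feed the ensemble, while the cross-run mean/sd of test RMSE and R^2
    support model comparison.
    """

    kind: str
    train_predictions: np.ndarray  # (n_runs, n_train) USD
    test_predictions: np.ndarray  # (n_runs, horizon) USD
    train_objectives: np.ndarray  # (n_runs,)
    test_rmse: np.ndarray
    test_r_squared: np.ndarray
    best_run: int
    seed_base: int = 0

    @property
    def best_train_predictions(self) -> np.ndarray:
        return self.train_predictions[self.best_run]

    @property
    def best_test_predictions(self) -> np.ndarray:
        return self.test_predictions[self.best_run]

    def summary(self) -> dict:
        return {
            "kind": self.kind,
            "best_run": int(self.best_run),
            "best_test_rmse": float(self.test_rmse[self.best_run]),
            "best_test_r2": float(self.test_r_squared[self.best_run]),
            "mean_test_rmse": float(self.test_rmse.mean()),
            "sd_test_rmse": float(self.test_rmse.std(ddof=1)) if len(self.test_rmse) > 1 else 0.0,
            "mean_test_r2": float(self.test_r_squared.mean()),
            "seed_base": int(self.seed_base),
        }


def run_repeated(
    trainer,
    train,
    test,
    n_runs: int = 30,
    seed_base: int = 0,
    deterministic: bool = False,
) -> RunSet:
    """Run a trainer ``n_runs`` times (seeds ``seed_base + k``) and collect runs.

    ``trainer(seed) -> Forecaster`` must be bound to the training data.
    Deterministic forecasters (persistence, ARIMA) are trained once and the
    single run replicated, since every run would be identical.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    train_v, test_v = _values(train), _values(test)

    def one_run(seed: int):
        fc = trainer(seed)
        tr = fc.train_predictions(train_v)
        te = fc.walk_forward(train_v, test_v)
        obj = score_weekly_safe(tr, train_v, fc.recipe.scaler).objective
        rep = score_weekly_safe(te, test_v, fc.recipe.scaler)
        return fc.kind, tr, te, obj, rep.rmse, rep.r_squared

    runs = [one_run(seed_base)]
    if not deterministic:
        runs += [one_run(seed_base + k) for k in range(1, n_runs)]
    else:
        runs *= n_runs
    kind = runs[0][0]
    train_preds = np.stack([r[1] for r in runs])
    test_preds = np.stack([r[2] for r in runs])
    objectives = np.array([r[3] for r in runs])
    best = int(np.argmin(objectives))
    return RunSet(
        kind=kind,
        train_predictions=train_preds,
        test_predictions=test_preds,
        train_objectives=objectives,
        test_rmse=np.array([r[4] for r in runs]),
        test_r_squared=np.array([r[5] for r in runs]),
        best_run=best,
        seed_base=seed_base,
    )
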