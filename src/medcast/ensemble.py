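"""Dynamically weighted forecast combination via normalized exponential weights.

Given N component forecasters' best one-step-ahead predictions on the
training period, weights start uniform at 1/N and, for each training day t,
every model's weight is multiplied by ``exp(-eta * l_it)`` — where
``l_it = (f_it - y_t)^2`` is the model's squared error that day — and the
weights are renormalized to sum to one.  After the last training sample the
weights are frozen and the test-period ensemble forecast is the convex
combination ``sum_i w_i f_it``.

The learning rate eta is calibrated on the training period over the grid
{0.0, 0.1, ..., 1.0} (11 values) by the weekly objective
``RMSE/10 + (1 - R^2)``; ties prefer the smallest eta.

Internally weights are carried in log space: the sequential update then
telescopes exactly to ``w_i ∝ exp(-eta * sum_t l_it)``, immune to underflow
for large ``eta * sum l``.  Squared-error losses are computed on the
standardized daily scale by default (``loss_scale="standardized"``) so the
exponent stays O(1); the original USD scale is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import ScalerParams, score_weekly

__all__ = [
    "DEFAULT_ETA_GRID",
    "ComponentPredictions",
    "EnsembleWeights",
    "squared_error_loss",
    "update_weights_one_step",
    "train_ensemble_weights",
    "calibrate_eta",
    "ensemble_predict",
]

DEFAULT_ETA_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.0, 1.01, 0.1), 1))


@dataclass(frozen=True)
class ComponentPredictions:
    """Time-aligned component predictions and actuals (original USD scale).

    ``predictions`` has one row per model (N x T); ``actuals`` has length T.
    """

    model_names: tuple[str, ...]
    predictions: np.ndarray
    actuals: np.ndarray

    def __post_init__(self) -> None:
        preds = np.atleast_2d(np.asarray(self.predictions, dtype=float))
        actuals = np.asarray(self.actuals, dtype=float)
        if preds.shape != (len(self.model_names), len(actuals)):
            raise ValueError("predictions must be (n_models, n_samples)")
        if not (np.all(np.isfinite(preds)) and np.all(np.isfinite(actuals))):
            raise ValueError("predictions and actuals must be finite")
        object.__setattr__(self, "model_names", tuple(self.model_names))
        object.__setattr__(self, "predictions", preds)
        object.__setattr__(self, "actuals", actuals)

    @property
    def n_models(self) -> int:
        return len(self.model_names)


@dataclass(frozen=True)
class EnsembleWeights:
    """Nonnegative per-model weights summing to one, with the eta used."""

    model_names: tuple[str, ...]
    weights: np.ndarray
    eta: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if len(w) != len(self.model_names):
            raise ValueError("one weight per model required")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be nonnegative and sum to 1")
        object.__setattr__(self, "model_names", tuple(self.model_names))
        object.__setattr__(self, "weights", w)

    def as_dict(self) -> dict[str, float]:
        return {name: float(w) for name, w in zip(self.model_names, self.weights)}


def squared_error_loss(prediction, actual):
    """Per-sample squared error (f - y)^2."""
    return (np.asarray(prediction, dtype=float) - np.asarray(actual, dtype=float)) ** 2


def update_weights_one_step(weights, predictions_t, actual_t, eta: float) -> np.ndarray:
    """One multiplicative update: w_i <- w_i * exp(-eta * l_it), renormalized.

    eta = 0 leaves the weights unchanged; a common loss across models
    cancels in the renormalization.
    """
    w = np.asarray(weights, dtype=float)
    if eta < 0:
        raise ValueError("eta must be nonnegative")
    losses = squared_error_loss(np.asarray(predictions_t, dtype=float), actual_t)
    with np.errstate(divide="ignore"):
        log_w = np.log(w) - eta * losses
    log_w -= log_w.max()  # safe renormalization
    updated = np.exp(log_w)
    total = updated.sum()
    if total == 0.0 or not np.isfinite(total):
        raise FloatingPointError(
            "all weights underflowed to zero; rescale the losses (e.g. use the "
            "standardized loss scale) or lower eta"
        )
    return updated / total


def _losses(components: ComponentPredictions, scaler: ScalerParams | None) -> np.ndarray:
    preds, actuals = components.predictions, components.actuals
    if scaler is not None:
        preds = scaler.scale(preds)
        actuals = scaler.scale(actuals)
    return squared_error_loss(preds, actuals[None, :])


def train_ensemble_weights(
    components: ComponentPredictions,
    eta: float,
    scaler: ScalerParams | None = None,
) -> EnsembleWeights:
    """Sequentially apply the weight update over all training samples.

    Starting from uniform 1/N, the t-loop runs in log space, which agrees
    with the sequential update exactly: the final weights satisfy
    ``w_i ∝ exp(-eta * sum_t l_it)``.  When ``scaler`` is given, losses are
    computed on the standardized scale.
    """
    losses = _losses(components, scaler)
    log_w = np.full(components.n_models, -np.log(components.n_models))
    for t in range(losses.shape[1]):
        log_w = log_w - eta * losses[:, t]
        log_w -= log_w.max()  # renormalization, deferred to log space
    w = np.exp(log_w)
    return EnsembleWeights(components.model_names, w / w.sum(), float(eta))


def ensemble_predict(weights: EnsembleWeights, component_predictions) -> np.ndarray:
    """Pointwise convex combination sum_i w_i f_it of component predictions."""
    preds = np.atleast_2d(np.asarray(component_predictions, dtype=float))
    if preds.shape[0] != len(weights.weights):
        raise ValueError("one prediction row per model required")
    return weights.weights @ preds


def calibrate_eta(
    components: ComponentPredictions,
    eta_grid=DEFAULT_ETA_GRID,
    scaler: ScalerParams | None = None,
) -> EnsembleWeights:
    """Pick the eta (and its trained weights) minimizing the weekly objective
    of the combined training predictions; ties go to the smallest eta.

    The weekly objective scores the USD-scale combination (with the
    standardized RMSE term when a scaler is given), matching how component
    models are themselves calibrated.
    """
    grid = tuple(eta_grid)
    if not grid:
        raise ValueError("eta grid must be nonempty")
    best: tuple[float, float, EnsembleWeights] | None = None
    for eta in grid:
        weights = train_ensemble_weights(components, eta, scaler)
        combined = ensemble_predict(weights, components.predictions)
        objective = score_weekly(combined, components.actuals, scaler).objective
        if best is None or (objective, eta) < best[:2]:
            best = (objective, eta, weights)
    return best[2]
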