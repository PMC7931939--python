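"""Component forecasters: hand-worked predictions, walk-forward semantics,
training reproducibility, and order selection."""

import warnings

import numpy as np
import pytest

from medcast.forecasters import (
    ArimaModel,
    ArimaOrder,
    NeuralSpec,
    PersistenceForecaster,
    Recipe,
    arima_predict_one,
    fit_arima,
    fit_lstm,
    fit_mlp,
    fit_persistence,
    grid_search_arima,
    mlp_forward,
    persistence_predict,
    run_repeated,
    train_lstm,
    train_mlp,
    walk_forward,
)
from medcast.series import ScalerParams, make_supervised, score_weekly


class TestPersistence:
    def test_predicts_last_value(self):
        assert persistence_predict([4.0, 9.0]) == 9.0

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError):
            persistence_predict([])

    def test_walk_forward_is_shift_by_one(self):
        preds = walk_forward(fit_persistence(), [1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        np.testing.assert_allclose(preds, [3.0, 4.0, 5.0])

    def test_constant_series_gives_zero_error(self):
        preds = walk_forward(fit_persistence(), np.full(20, 5.0), np.full(14, 5.0))
        np.testing.assert_allclose(preds, 5.0)

    def test_zero_horizon_gives_empty_predictions(self):
        assert len(walk_forward(fit_persistence(), [1.0, 2.0], [])) == 0


class TestArimaPredictOne:
    def test_unit_ar1_reduces_to_persistence(self):
        model = ArimaModel(ArimaOrder(1, 0, 0), ar_coefficients=(1.0,))
        assert arima_predict_one(model, [4.0, 9.0]) == 9.0

    def test_constant_model_ignores_history(self):
        model = ArimaModel(ArimaOrder(0, 0, 0), constant=5.0)
        assert arima_predict_one(model, [1.0, 2.0, 3.0]) == 5.0

    def test_hand_evaluated_ar2(self):
        model = ArimaModel(ArimaOrder(2, 0, 0), constant=1.0, ar_coefficients=(0.5, 0.25))
        assert arima_predict_one(model, [7.0, 2.0, 4.0]) == pytest.approx(3.5)

    def test_insufficient_history_rejected(self):
        model = ArimaModel(ArimaOrder(2, 0, 0), ar_coefficients=(0.5, 0.25))
        with pytest.raises(ValueError):
            arima_predict_one(model, [1.0])

    def test_agrees_with_statsmodels_on_pure_ar(self):
        """Cross-check: on a pure AR model the hand recursion and the
        statsmodels filter give the same next-step forecast."""
        rng = np.random.default_rng(3)
        y = np.zeros(300)
        e = rng.normal(size=300)
        for t in range(2, 300):
            y[t] = 0.6 * y[t - 1] - 0.3 * y[t - 2] + e[t]
        fitted = fit_arima(y, ArimaOrder(2, 0, 0))
        res = fitted._results
        phi = tuple(res.arparams)
        const = float(res.params[0]) * (1.0 - sum(phi))  # mean form -> intercept form
        model = ArimaModel(ArimaOrder(2, 0, 0), constant=const, ar_coefficients=phi)
        mine = arima_predict_one(model, y)
        theirs = float(res.forecast(1)[0])
        assert mine == pytest.approx(theirs, rel=1e-6)


class TestArimaOrderSelection:
    def test_grid_search_on_ar2_matches_exhaustive_objective(self):
        """Grid search returns the exhaustive-minimum objective; the
        true-order fit can do no better than ~5% relative."""
        rng = np.random.default_rng(0)
        n = 800
        y = np.zeros(n)
        e = rng.normal(size=n)
        for t in range(2, n):
            y[t] = 0.6 * y[t - 1] - 0.3 * y[t - 2] + e[t]
        y = y + 50.0
        order = grid_search_arima(y, d=0)
        selected = score_weekly(fit_arima(y, order).train_predictions(y), y).objective
        true_order = score_weekly(
            fit_arima(y, ArimaOrder(2, 0, 0)).train_predictions(y), y
        ).objective
        assert selected <= true_order * 1.05

    def test_white_noise_selects_minimal_order(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=700) + 50.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            order = grid_search_arima(y, d=0)
        assert order.p + order.q <= 1

    def test_arma21_recovery_invariant(self):
        """On ARMA(2,1) at n=1,300 the selected p is within +-1 of the truth
        and the daily one-step RMSE is within 10% of the innovation sd."""
        rng = np.random.default_rng(0)
        n = 1300
        y = np.zeros(n)
        e = rng.normal(size=n)
        for t in range(2, n):
            y[t] = 0.6 * y[t - 1] - 0.3 * y[t - 2] + e[t] + 0.4 * e[t - 1]
        y = y + 50.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            order = grid_search_arima(y, d=0, p_max=3, q_max=3)
        assert abs(order.p - 2) <= 1
        preds = fit_arima(y, order).train_predictions(y)
        rmse_daily = np.sqrt(np.mean((preds[10:] - y[10:]) ** 2))
        assert rmse_daily == pytest.approx(1.0, rel=0.10)


class TestMlpForward:
    def test_zero_weights_give_output_bias(self):
        weights = [np.zeros((2, 3)), np.zeros((3, 1))]
        biases = [np.zeros(3), np.array([4.5])]
        assert mlp_forward([7.0, -2.0], weights, biases) == 4.5

    def test_negative_preactivation_is_clipped(self):
        weights = [np.array([[1.0], [1.0]]), np.array([[2.0]])]
        biases = [np.array([-10.0]), np.array([3.0])]
        # ReLU(2 + 3 - 10) = 0, so only the output bias remains
        assert mlp_forward([2.0, 3.0], weights, biases) == 3.0

    def test_positive_preactivation_passes_through(self):
        weights = [np.array([[1.0], [1.0]]), np.array([[2.0]])]
        biases = [np.array([0.0]), np.array([0.0])]
        assert mlp_forward([2.0, 3.0], weights, biases) == pytest.approx(10.0)


class TestNeuralTraining:
    def test_same_seed_same_parameters(self, linear_recurrence):
        supervised, _ = linear_recurrence
        spec = NeuralSpec(hidden_layers=2, neurons_per_layer=8, epochs=8,
                          batch_size=10, shuffle=True, lag=2)
        a = train_mlp(supervised, spec, seed=3)
        b = train_mlp(supervised, spec, seed=3)
        assert all(np.array_equal(x, y) for x, y in zip(a.parameters, b.parameters))
        la = train_lstm(supervised, spec, seed=3)
        lb = train_lstm(supervised, spec, seed=3)
        assert all(np.array_equal(x, y) for x, y in zip(la.parameters, lb.parameters))

    def test_mlp_learns_noiseless_recurrence(self, linear_recurrence):
        supervised, y = linear_recurrence
        spec = NeuralSpec(hidden_layers=1, neurons_per_layer=8, epochs=256,
                          batch_size=10, shuffle=True, lag=2)
        net = train_mlp(supervised, spec, seed=1)
        rmse = np.sqrt(np.mean((net.predict(supervised.inputs) - supervised.targets) ** 2))
        assert rmse < 0.01 * np.ptp(y)

    def test_lstm_learns_noiseless_recurrence(self, linear_recurrence):
        supervised, y = linear_recurrence
        spec = NeuralSpec(hidden_layers=1, neurons_per_layer=8, epochs=128,
                          batch_size=10, shuffle=True, lag=2)
        net = train_lstm(supervised, spec, seed=1)
        rmse = np.sqrt(np.mean((net.predict(supervised.inputs) - supervised.targets) ** 2))
        assert rmse < 0.02 * np.ptp(y)

    def test_zero_rate_dropout_matches_plain_trainer_bitwise(self, linear_recurrence):
        supervised, _ = linear_recurrence
        base = dict(hidden_layers=2, neurons_per_layer=8, epochs=8, batch_size=10,
                    shuffle=False, lag=2)
        plain = NeuralSpec(dropout_mode="none", **base)
        zero_node = NeuralSpec(dropout_mode="node", dropout_rate=0.0, **base)
        a = train_mlp(supervised, plain, seed=9)
        b = train_mlp(supervised, zero_node, seed=9)
        assert all(np.array_equal(x, y) for x, y in zip(a.parameters, b.parameters))
        zero_rec = NeuralSpec(dropout_mode="recurrent", dropout_rate=0.0, **base)
        la = train_lstm(supervised, plain, seed=9)
        lb = train_lstm(supervised, zero_rec, seed=9)
        assert all(np.array_equal(x, y) for x, y in zip(la.parameters, lb.parameters))

    def test_dropout_regimes_train_and_predict_finite(self, linear_recurrence):
        supervised, _ = linear_recurrence
        for mode, trainer in (("node", train_mlp), ("node", train_lstm),
                              ("recurrent", train_lstm)):
            spec = NeuralSpec(hidden_layers=2, neurons_per_layer=4, epochs=8,
                              batch_size=10, shuffle=True, lag=2, dropout_mode=mode)
            net = trainer(supervised, spec, seed=0)
            assert np.all(np.isfinite(net.predict(supervised.inputs)))

    def test_recurrent_dropout_rejected_for_mlp(self, linear_recurrence):
        supervised, _ = linear_recurrence
        spec = NeuralSpec(dropout_mode="recurrent", lag=2)
        with pytest.raises(ValueError, match="recurrent"):
            train_mlp(supervised, spec, seed=0)

    def test_spec_grid_membership_enforced(self):
        with pytest.raises(ValueError, match="neurons"):
            NeuralSpec(neurons_per_layer=7)


class TestGradients:
    """Backprop checked against central finite differences."""

    @pytest.mark.parametrize("net_kind", ["mlp", "lstm"])
    def test_analytic_gradients_match_numeric(self, net_kind):
        from medcast._nn import LSTMNet, MLPNet

        rng = np.random.default_rng(2)
        X = rng.normal(size=(6, 3))
        y = rng.normal(size=6)
        net = MLPNet(3, 2, 4, seed=0) if net_kind == "mlp" else LSTMNet(3, 2, 4, seed=0)
        # nudge all parameters off zero so no ReLU preactivation sits exactly
        # at the kink, where the subgradient and a central difference differ
        for p in net.parameters:
            p += rng.normal(scale=0.05, size=p.shape)
        if net_kind == "mlp":
            grads = net._forward_backward(X, y, 0.0)
        else:
            grads = net._forward_backward(X, y, 0.0, "none")
        eps = 1e-6

        def loss():
            return np.mean((net.predict(X) - y) ** 2)

        for p, g in zip(net.parameters, grads):
            for _ in range(min(p.size, 4)):
                idx = tuple(rng.integers(s) for s in p.shape)
                orig = p[idx]
                p[idx] = orig + eps
                lp = loss()
                p[idx] = orig - eps
                lm = loss()
                p[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                assert g[idx] == pytest.approx(numeric, rel=1e-3, abs=1e-7)


class TestWalkForward:
    def test_predictions_have_horizon_length_and_are_finite(self, stationary_series):
        train, test = stationary_series.split(1306)
        scaler = ScalerParams.fit(train.values)
        spec = NeuralSpec(epochs=8, batch_size=20, lag=2)
        for forecaster in (
            fit_persistence(),
            fit_arima(train.values, ArimaOrder(1, 0, 0), scaler),
            fit_mlp(train.values[:200], spec, seed=0, scaler=scaler),
        ):
            preds = walk_forward(forecaster, train.values[:200], test.values[:30])
            assert preds.shape == (30,)
            assert np.all(np.isfinite(preds))

    def test_zero_differenced_prediction_reduces_to_persistence(self):
        """Under d=1 preprocessing each inverted prediction adds the model's
        differenced forecast to the previous actual, so a model that always
        predicts a zero difference is the persistence baseline."""

        class ZeroDiff(PersistenceForecaster):
            def __init__(self):
                super().__init__()
                self.recipe = Recipe(d=1, scaler=None, lag=1)

            def predict_window(self, window):
                return 0.0

        train = np.array([3.0, 5.0, 4.0, 6.0])
        test = np.array([7.0, 5.5, 8.0])
        np.testing.assert_allclose(
            ZeroDiff().walk_forward(train, test),
            walk_forward(fit_persistence(), train, test),
        )

    def test_persistence_equals_unit_ar1_walk_forward(self):
        """Persistence and ARIMA(1,0,0) with phi=1, c=0 agree exactly."""
        rng = np.random.default_rng(5)
        train = rng.normal(size=40)
        test = rng.normal(size=10)
        model = ArimaModel(ArimaOrder(1, 0, 0), ar_coefficients=(1.0,))
        history = list(train)
        preds = []
        for actual in test:
            preds.append(arima_predict_one(model, np.asarray(history)))
            history.append(actual)
        np.testing.assert_allclose(preds, walk_forward(fit_persistence(), train, test))


class TestRunRepeated:
    def test_deterministic_forecaster_has_zero_cross_run_variance(self, stationary_series):
        train, test = stationary_series.split(1306)
        runset = run_repeated(lambda seed: fit_persistence(), train.values[:100],
                              test.values[:30], n_runs=5, deterministic=True)
        assert runset.test_rmse.std() == 0.0
        assert np.array_equal(runset.test_predictions[0], runset.test_predictions[4])

    def test_single_run_is_best_run(self, stationary_series):
        train, test = stationary_series.split(1306)
        runset = run_repeated(lambda seed: fit_persistence(), train.values[:100],
                              test.values[:30], n_runs=1, deterministic=True)
        assert runset.best_run == 0

    def test_best_run_objective_is_minimum(self, stationary_series):
        train, test = stationary_series.split(1306)
        scaler = ScalerParams.fit(train.values[:150])
        spec = NeuralSpec(epochs=8, batch_size=20, lag=2, shuffle=True)
        runset = run_repeated(
            lambda seed: fit_mlp(train.values[:150], spec, seed, scaler=scaler),
            train.values[:150], test.values[:30], n_runs=3, seed_base=2,
        )
        assert runset.train_objectives[runset.best_run] == runset.train_objectives.min()
        assert runset.train_objectives[runset.best_run] <= runset.train_objectives.mean()
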