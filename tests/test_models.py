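"""Model forward passes, gradients, fitting and hyperparameter selection."""

import math

import numpy as np
import pytest

from medadhere.estimators import (
    DEFAULT_L2_GRID,
    LinearModelParams,
    LSTMAdherenceClassifier,
    LogisticAdherenceClassifier,
    MLPAdherenceClassifier,
    RidgeAdherenceClassifier,
    SimpleRNNAdherenceClassifier,
    SplitScheme,
    logistic_predict,
    ridge_fit,
    select_hyperparameters,
)
from medadhere.nn import (
    LSTMNet,
    MLPNet,
    SimpleRNNNet,
    TrainingConfig,
    TrainingDivergence,
    fit_network,
    lstm_forward,
    mlp_forward,
    onehot,
    simple_rnn_forward,
)
from medadhere.evaluation import roc_auc

from conftest import grad_check


def _sig(z):
    return 1.0 / (1.0 + math.exp(-z))


class TestLogisticPredict:
    def test_zero_coefficients_give_half(self):
        p = LinearModelParams(0.0, np.zeros(3), "logistic")
        assert logistic_predict(p, np.zeros(3)) == 0.5

    def test_saturates_to_one(self):
        p = LinearModelParams(50.0, np.array([50.0]), "logistic")
        assert logistic_predict(p, np.array([1.0])) == pytest.approx(1.0)

    def test_hand_case(self):
        # b0=1, b1=2, x=0.5 -> p = 1/(1+e^-2)
        p = LinearModelParams(1.0, np.array([2.0]), "logistic")
        assert logistic_predict(p, np.array([0.5])) == \
            pytest.approx(1.0 / (1.0 + math.exp(-2.0)))

    def test_width_mismatch(self):
        p = LinearModelParams(0.0, np.zeros(2), "logistic")
        with pytest.raises(ValueError, match="width mismatch"):
            logistic_predict(p, np.zeros(3))


class TestRidge:
    def test_l2_zero_equals_least_squares_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 5))
        y = (rng.random(40) < 0.5).astype(int)
        t = np.where(y > 0, 1.0, -1.0)
        params = ridge_fit(X, y, l2_grid=[0.0], cv=2)
        # oracle: ordinary least squares with an intercept column
        A = np.column_stack([np.ones(len(t)), X])
        beta, *_ = np.linalg.lstsq(A, t, rcond=None)
        assert params.intercept == pytest.approx(beta[0], abs=1e-8)
        np.testing.assert_allclose(params.coef, beta[1:], atol=1e-8)

    def test_large_l2_shrinks_coefficients(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 4))
        y = (X[:, 0] > 0).astype(int)
        small = ridge_fit(X, y, l2_grid=[1e-6], cv=2)
        big = ridge_fit(X, y, l2_grid=[1e6], cv=2)
        assert np.linalg.norm(big.coef) < 1e-3 * np.linalg.norm(small.coef)

    def test_collinear_features_fit_with_penalty(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        X = np.column_stack([x, x])  # exact duplicate
        y = (x > 0).astype(int)
        params = ridge_fit(X, y, l2_grid=[1e-2], cv=2)
        assert np.all(np.isfinite(params.coef))
        with pytest.raises(np.linalg.LinAlgError):
            ridge_fit(X, y, l2_grid=[0.0], cv=2)

    def test_estimator_decision_value_ranks_classes(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(300, 6))
        y = (X[:, 0] + 0.3 * rng.normal(size=300) > 0).astype(int)
        est = RidgeAdherenceClassifier().fit(X, y)
        assert est.l2_ in DEFAULT_L2_GRID
        assert roc_auc(est.decision_function(X), y) > 0.9
        assert (est.predict(X) == y).mean() > 0.85

    def test_empty_or_negative_grid_rejected(self):
        with pytest.raises(ValueError):
            ridge_fit(np.eye(3), np.array([0, 1, 0]), l2_grid=[])
        with pytest.raises(ValueError):
            ridge_fit(np.eye(3), np.array([0, 1, 0]), l2_grid=[-1.0])


class TestForwardPasses:
    def test_mlp_zero_weights_give_half_half(self):
        net = MLPNet(3, hidden=(4, 4))
        params = {k: np.zeros_like(v)
                  for k, v in net.init_params(np.random.default_rng(0)).items()}
        out = mlp_forward(net, params, np.array([1.0, -2.0, 3.0]))
        np.testing.assert_allclose(out, [0.5, 0.5])

    def test_mlp_hand_case_single_units(self):
        # 1-feature, 1-unit hidden layers, sigmoid activations
        net = MLPNet(1, hidden=(1, 1), activation="sigmoid", dropout=(0, 0))
        params = {
            "W1": np.array([[2.0]]), "b1": np.array([0.5]),
            "W2": np.array([[-1.0]]), "b2": np.array([0.25]),
            "W3": np.array([[1.5], [-0.5]]), "b3": np.array([0.1, -0.1]),
        }
        x = 0.8
        h1 = _sig(2.0 * x + 0.5)
        h2 = _sig(-1.0 * h1 + 0.25)
        z = (1.5 * h2 + 0.1, -0.5 * h2 - 0.1)
        e = (math.exp(z[0]), math.exp(z[1]))
        expect = (e[0] / sum(e), e[1] / sum(e))
        out = mlp_forward(net, params, np.array([x]))
        np.testing.assert_allclose(out, expect, atol=1e-12)

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(5)
        for net, shape in ((MLPNet(6), (10, 6)),
                           (SimpleRNNNet(4), (10, 8, 4)),
                           (LSTMNet(4), (10, 8, 4))):
            params = net.init_params(rng)
            out = net.forward(params, rng.normal(size=shape))
            assert np.all(out >= 0)
            np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-9)

    def test_rnn_length_one_equals_feedforward(self):
        rng = np.random.default_rng(6)
        net = SimpleRNNNet(3, hidden=2)
        params = net.init_params(rng)
        x = rng.normal(size=3)
        out = simple_rnn_forward(net, params, x[None, :])
        h = 1.0 / (1.0 + np.exp(-(params["Whx"] @ x + params["bh"])))
        z = params["Wyh"] @ h + params["by"]
        e = np.exp(z - z.max())
        np.testing.assert_allclose(out, e / e.sum(), atol=1e-12)

    def test_rnn_zero_recurrence_depends_only_on_last_input(self):
        rng = np.random.default_rng(7)
        net = SimpleRNNNet(3, hidden=2)
        params = net.init_params(rng)
        params["Whh"] = np.zeros_like(params["Whh"])
        seq_a = rng.normal(size=(5, 3))
        seq_b = rng.normal(size=(5, 3))
        seq_b[-1] = seq_a[-1]
        np.testing.assert_allclose(
            simple_rnn_forward(net, params, seq_a),
            simple_rnn_forward(net, params, seq_b), atol=1e-12)

    def test_rnn_hand_case_two_steps_one_unit(self):
        net = SimpleRNNNet(1, hidden=1)
        params = {"Whx": np.array([[0.5]]), "Whh": np.array([[0.25]]),
                  "bh": np.array([0.1]),
                  "Wyh": np.array([[1.0], [-1.0]]), "by": np.array([0.0, 0.0])}
        x1, x2 = 1.0, -0.5
        h1 = _sig(0.5 * x1 + 0.1)
        h2 = _sig(0.5 * x2 + 0.25 * h1 + 0.1)
        z = (h2, -h2)
        e = (math.exp(z[0]), math.exp(z[1]))
        out = simple_rnn_forward(net, params,
                                 np.array([[x1], [x2]]))
        np.testing.assert_allclose(out, (e[0] / sum(e), e[1] / sum(e)),
                                   atol=1e-12)

    def test_empty_sequence_rejected(self):
        net = SimpleRNNNet(2)
        params = net.init_params(np.random.default_rng(0))
        with pytest.raises(ValueError):
            simple_rnn_forward(net, params, np.empty((0, 2)))
        lnet = LSTMNet(2)
        lparams = lnet.init_params(np.random.default_rng(0))
        with pytest.raises(ValueError):
            lstm_forward(lnet, lparams, np.empty((0, 2)))


class TestLSTMGating:
    def _params(self, net, fill=0.0):
        rng = np.random.default_rng(0)
        return {k: np.full_like(v, fill)
                for k, v in net.init_params(rng).items()}

    def test_forget_zero_and_no_input_keeps_state_at_zero(self):
        net = LSTMNet(1, hidden=1)
        params = self._params(net)
        params["bf"][:] = -50.0  # forget gate saturated at 0
        params["bi"][:] = -50.0  # input gate closed: g*i = 0
        cache, h = net._scan(params, np.ones((1, 5, 1)))
        for step in cache:
            np.testing.assert_allclose(step["s"], 0.0, atol=1e-20)

    def test_forget_one_input_zero_preserves_initial_state(self):
        # constant-error-carousel limit: s stays at s(0) = 0
        net = LSTMNet(1, hidden=1)
        params = self._params(net)
        params["bf"][:] = 50.0   # forget gate saturated at 1
        params["bi"][:] = -50.0  # input gate 0
        cache, _ = net._scan(params, np.random.default_rng(1).normal(size=(1, 6, 1)))
        for step in cache:
            np.testing.assert_allclose(step["s"], 0.0, atol=1e-20)

    def test_hand_case_all_weights_half(self):
        net = LSTMNet(1, hidden=1)
        params = self._params(net, fill=0.5)
        x1, x2 = 1.0, -1.0
        h = s = 0.0
        for x in (x1, x2):
            g = math.tanh(0.5 * x + 0.5 * h + 0.5)
            i = _sig(0.5 * x + 0.5 * h + 0.5)
            f = _sig(0.5 * x + 0.5 * h + 0.5)
            o = _sig(0.5 * x + 0.5 * h + 0.5)
            s = g * i + s * f
            h = math.tanh(s) * o
        z = (0.5 * h + 0.5, 0.5 * h + 0.5)
        expect = (0.5, 0.5)  # equal logits by symmetric output weights
        assert math.isclose(z[0], z[1])
        out = lstm_forward(net, params, np.array([[x1], [x2]]))
        np.testing.assert_allclose(out, expect, atol=1e-12)
        # and the hidden state itself matches the manual unrolling
        cache, hT = net._scan(params, np.array([[[x1], [x2]]]))
        assert hT[0, 0] == pytest.approx(h, abs=1e-12)
        assert cache[-1]["s"][0, 0] == pytest.approx(s, abs=1e-12)


class TestGradients:
    """Analytic gradients vs central finite differences (<= 1e-4 relative)."""

    @pytest.mark.parametrize("maker,shape", [
        (lambda rng: MLPNet(3, hidden=(4, 2), activation="tanh",
                            dropout=(0, 0)), (6, 3)),
        (lambda rng: MLPNet(2, hidden=(3, 3), activation="sigmoid",
                            dropout=(0, 0)), (5, 2)),
        (lambda rng: SimpleRNNNet(2, hidden=3), (4, 5, 2)),
        (lambda rng: SimpleRNNNet(3, hidden=1, activation="tanh"), (4, 3, 3)),
        (lambda rng: LSTMNet(2, hidden=2), (4, 5, 2)),
        (lambda rng: LSTMNet(3, hidden=4), (3, 4, 3)),
    ])
    def test_gradcheck(self, maker, shape):
        rng = np.random.default_rng(12)
        net = maker(rng)
        params = net.init_params(rng)
        X = rng.normal(size=shape)
        y = rng.integers(0, 2, size=shape[0])
        Y = onehot(y)
        l2 = 1e-3 if net.l2_keys else 0.0
        err = grad_check(
            lambda p: net.loss_and_grads(p, X, Y, l2=l2), params)
        assert err <= 1e-4


class TestTraining:
    def _toy(self, n=400, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 4))
        y = (X[:, 0] - X[:, 1] > 0).astype(int)
        return X, y

    def test_separable_toy_reaches_high_accuracy(self):
        X, y = self._toy()
        est = MLPAdherenceClassifier(hidden=(16, 16), dropout=(0, 0),
                                     batch_size=64, epochs=60, seed=0)
        est.fit(X, y)
        assert (est.predict(X) == y).mean() > 0.97
        # loss decreases over the first epochs
        assert est.history_["loss"][5] < est.history_["loss"][0]

    def test_same_seed_identical_loss_curve(self):
        X, y = self._toy()
        kw = dict(hidden=(8, 8), dropout=(0.2, 0.2), batch_size=64,
                  epochs=10, seed=5)
        a = MLPAdherenceClassifier(**kw).fit(X, y)
        b = MLPAdherenceClassifier(**kw).fit(X, y)
        assert a.history_["loss"] == b.history_["loss"]
        np.testing.assert_array_equal(a.params_["W1"], b.params_["W1"])

    def test_shuffled_labels_give_chance_auc(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(600, 3, 4))
        y = (X[:, -1, 0] > 0).astype(int)
        y_shuffled = rng.permutation(y)
        tr, val = np.arange(0, 450), np.arange(450, 600)
        est = LSTMAdherenceClassifier(units=3, batch_size=64, epochs=20,
                                      seed=0)
        est.fit(X[tr], y_shuffled[tr])
        auc = roc_auc(est.decision_function(X[val]), y_shuffled[val])
        assert abs(auc - 0.5) < 0.07

    def test_divergence_raises(self):
        X, y = self._toy(100)
        X[0, 0] = np.nan  # propagates to a non-finite loss
        net = MLPNet(4, hidden=(4, 4), dropout=(0, 0))
        cfg = TrainingConfig(batch_size=100, epochs=3, seed=0)
        with pytest.raises(TrainingDivergence):
            fit_network(net, X, y, cfg)

    def test_recurrent_models_are_order_sensitive(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(200, 6, 3))
        # label depends on the trend of the first feature
        y = (X[:, -1, 0] - X[:, 0, 0] > 0).astype(int)
        est = LSTMAdherenceClassifier(units=4, batch_size=32, epochs=30,
                                      seed=1).fit(X, y)
        seq = X[:5]
        flipped = seq[:, ::-1, :].copy()
        assert not np.allclose(est.decision_function(seq),
                               est.decision_function(flipped))

    def test_mlp_on_aggregated_input_is_permutation_invariant(self):
        rng = np.random.default_rng(10)
        seq = rng.normal(size=(5, 6, 3))
        est = MLPAdherenceClassifier(hidden=(8, 8), dropout=(0, 0),
                                     batch_size=16, epochs=5, seed=0)
        est.fit(seq.mean(axis=1), rng.integers(0, 2, size=5))
        perm = seq[:, rng.permutation(6), :]
        np.testing.assert_allclose(est.decision_function(seq.mean(axis=1)),
                                   est.decision_function(perm.mean(axis=1)))


class TestSplitScheme:
    def test_partition_and_proportions(self):
        scheme = SplitScheme(test_fraction=0.1, n_folds=5)
        splits = scheme.split(1000, seed=3)
        test = set(splits["test"])
        assert len(test) == 100
        for train, val in splits["folds"]:
            assert not test & set(train)
            assert not test & set(val)
            assert not set(train) & set(val)
            assert len(train) + len(val) == 900
            # 90/10 proportions within the non-test portion
            assert len(val) == 90
        vals = [set(v) for _, v in splits["folds"]]
        assert all(not a & b for i, a in enumerate(vals)
                   for b in vals[i + 1:])


class TestSelectHyperparameters:
    def _factory(self, config):
        return MLPAdherenceClassifier(hidden=config["hidden"],
                                      dropout=(0, 0), batch_size=64,
                                      epochs=15, seed=0)

    def test_single_entry_grid_returned(self):
        X, y = TestTraining()._toy(200)
        best, table = select_hyperparameters(
            self._factory, [{"hidden": (4, 4)}], X, y, seed=0)
        assert best == {"hidden": (4, 4)}
        assert len(table) == 1

    def test_broken_config_excluded(self):
        X, y = TestTraining()._toy(200)
        best, table = select_hyperparameters(
            self._factory, [{"hidden": (0, 0)}, {"hidden": (8, 8)}],
            X, y, seed=0)
        assert best == {"hidden": (8, 8)}
        assert table[0]["mean_loss"] == np.inf

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            select_hyperparameters(self._factory, [], np.eye(2),
                                   np.array([0, 1]))

    def test_dominant_config_wins(self):
        X, y = TestTraining()._toy(300)

        def factory(config):
            if config["model"] == "good":
                return LogisticAdherenceClassifier()
            return RidgeAdherenceClassifier(l2_grid=[1e6])  # crushed coefs
        best, table = select_hyperparameters(
            factory, [{"model": "bad"}, {"model": "good"}], X, y, seed=0)
        assert best == {"model": "good"}
        # dominance fold by fold
        bad, good = table[0]["fold_losses"], table[1]["fold_losses"]
        assert all(g < b for g, b in zip(good, bad))
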