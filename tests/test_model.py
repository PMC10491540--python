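import numpy as np
import pytest

import pubtriage as pt


def oracle_forward(layers, x):
    """Straight-line re-implementation of the affine/ReLU/sigmoid chain."""
    a = np.asarray(x, dtype=float)
    for W, b, act in layers:
        z = W.T @ a + b
        a = np.maximum(0.0, z) if act == "relu" else 1.0 / (1.0 + np.exp(-z))
    return float(a[0])


def toy_model():
    """1 hidden ReLU unit W=(1,-2), b=0.5; sigmoid output w=3, b=0."""
    return pt.MLPModel(
        layers=[
            pt.LayerParams(np.array([[1.0], [-2.0]]), np.array([0.5]), "relu"),
            pt.LayerParams(np.array([[3.0]]), np.array([0.0]), "sigmoid"),
        ],
        input_dim=2,
    )


def separable_data(n=400, dim=10, seed=0):
    """One signal feature per class, everything else random noise."""
    rng = np.random.default_rng(seed)
    y = np.array([1.0, 0.0] * (n // 2))
    X = (rng.random((n, dim)) < 0.3).astype(float)
    X[:, 0] = y
    X[:, 1] = 1.0 - y
    return X, y


class TestForward:
    def test_all_zero_weights_give_sigmoid_of_zero(self):
        model = pt.MLPModel(
            layers=[
                pt.LayerParams(np.zeros((3, 2)), np.zeros(2), "relu"),
                pt.LayerParams(np.zeros((2, 1)), np.zeros(1), "sigmoid"),
            ],
            input_dim=3,
        )
        assert pt.forward(model, np.ones(3)) == 0.5

    def test_hand_computed_two_input_toy_network(self):
        model = toy_model()
        # x=(1,1): pre-act -0.5 -> ReLU 0 -> sigmoid(0) = 0.5
        assert pt.forward(model, np.array([1.0, 1.0])) == 0.5
        # x=(1,0): ReLU(1.5) -> sigmoid(4.5) ~= 0.9891
        assert pt.forward(model, np.array([1.0, 0.0])) == pytest.approx(0.98901, abs=1e-4)

    def test_agrees_with_straight_line_oracle_on_random_models(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            dims = [int(rng.integers(1, 6)) for _ in range(int(rng.integers(1, 4)))]
            dims = [int(rng.integers(2, 7))] + dims + [1]
            layers, chain = [], []
            for i in range(len(dims) - 1):
                act = "sigmoid" if i == len(dims) - 2 else "relu"
                W = rng.normal(size=(dims[i], dims[i + 1]))
                b = rng.normal(size=dims[i + 1])
                layers.append(pt.LayerParams(W, b, act))
                chain.append((W, b, act))
            model = pt.MLPModel(layers=layers, input_dim=dims[0])
            x = rng.normal(size=dims[0])
            assert pt.forward(model, x) == pytest.approx(oracle_forward(chain, x), abs=1e-12)

    def test_dimension_mismatch_is_an_error(self):
        with pytest.raises(pt.ConfigError, match="shape"):
            pt.forward(toy_model(), np.ones(3))

    def test_output_stays_in_unit_interval(self):
        rng = np.random.default_rng(9)
        model = pt.build_mlp(6, hidden_units=8, hidden_layers=2, seed=0)
        for _ in range(100):
            p = pt.forward(model, rng.normal(scale=50, size=6))
            assert 0.0 <= p <= 1.0


class TestMseLoss:
    @pytest.mark.parametrize(
        "y_hat,y,expected",
        [(0.7, 0.7, 0.0), (0.8, 1.0, 0.04), ([0.5, 0.5], [1.0, 0.0], 0.25)],
    )
    def test_squared_error_and_batch_mean(self, y_hat, y, expected):
        assert pt.mse_loss(y_hat, y) == pytest.approx(expected)


class TestTrain:
    def test_zero_epochs_leaves_model_unchanged_with_empty_history(self):
        X, y = separable_data(n=20)
        model = pt.build_mlp(10, hidden_units=4, seed=1)
        before = [layer.W.copy() for layer in model.layers]
        trained, history = pt.train(model, X, y, pt.TrainConfig(epochs=0, seed=1))
        assert history == []
        for W0, layer in zip(before, trained.layers):
            assert np.array_equal(W0, layer.W)

    def test_backprop_matches_central_finite_differences(self):
        from pubtriage.model import _backward_batch, _forward_batch

        rng = np.random.default_rng(17)
        model = pt.build_mlp(4, hidden_units=5, hidden_layers=1, seed=2)
        eps = 1e-6
        for _ in range(100):
            X = rng.normal(size=(3, 4))
            y = rng.integers(0, 2, size=3).astype(float)
            grads, _ = _backward_batch(model, X, y)
            for layer, (gW, gb) in zip(model.layers, grads):
                for arr, grad in ((layer.W, gW), (layer.b, gb)):
                    flat = arr.ravel()
                    idx = rng.integers(flat.size)
                    orig = flat[idx]
                    flat[idx] = orig + eps
                    up = pt.mse_loss(_forward_batch(model, X), y)
                    flat[idx] = orig - eps
                    down = pt.mse_loss(_forward_batch(model, X), y)
                    flat[idx] = orig
                    numeric = (up - down) / (2 * eps)
                    assert grad.ravel()[idx] == pytest.approx(numeric, abs=1e-5)

    def test_separable_corpus_reaches_training_accuracy(self):
        X, y = separable_data(n=400, seed=5)
        model = pt.build_mlp(10, seed=5)
        _, history = pt.train(model, X, y, pt.TrainConfig(seed=5))
        assert history[-1]["accuracy"] >= 0.95
        assert history[-1]["loss"] < history[0]["loss"]

    def test_training_is_bit_reproducible_under_a_seed(self):
        X, y = separable_data(n=60, seed=6)
        runs = []
        for _ in range(2):
            model = pt.build_mlp(10, hidden_units=8, seed=6)
            pt.train(model, X, y, pt.TrainConfig(epochs=5, seed=6))
            runs.append(model)
        for la, lb in zip(runs[0].layers, runs[1].layers):
            assert np.array_equal(la.W, lb.W)
            assert np.array_equal(la.b, lb.b)
        assert runs[0].version == runs[1].version

    def test_empty_training_set_is_an_error(self):
        model = pt.build_mlp(4, seed=0)
        with pytest.raises(pt.ConfigError, match="empty"):
            pt.train(model, np.zeros((0, 4)), np.zeros(0), pt.TrainConfig())


class TestAccuracyAndEvaluate:
    def test_printed_test_confusion_matrix_gives_0942(self):
        cm = pt.ConfusionMatrix(tp=183, fp=13, fn=10, tn=193)
        assert round(pt.accuracy(cm), 3) == 0.942

    @pytest.mark.parametrize(
        "cm,expected",
        [
            (pt.ConfusionMatrix(tp=5, tn=5, fp=0, fn=0), 1.0),
            (pt.ConfusionMatrix(tp=0, tn=0, fp=5, fn=5), 0.0),
        ],
    )
    def test_degenerate_matrices(self, cm, expected):
        assert pt.accuracy(cm) == expected

    def test_empty_matrix_is_an_error(self):
        with pytest.raises(pt.ConfigError):
            pt.accuracy(pt.ConfusionMatrix(tp=0, tn=0, fp=0, fn=0))

    def test_confusion_matrix_matches_manual_count_on_hand_built_set(self):
        model = toy_model()
        # outputs: (1,0)->0.989, (0,1)->0.5, (1,1)->0.5, (0,0)->sigmoid(1.5)=0.817
        X = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0], [0.0, 0.0]])
        y = np.array([1.0, 0.0, 0.0, 1.0])
        cm, metrics, per_sample = pt.evaluate(model, X, y)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (2, 2, 0, 0)
        assert metrics.accuracy == 0.5
        assert len(per_sample) == 4
        assert per_sample[0][0] == 1.0
        assert per_sample[0][1] == pytest.approx(0.98901, abs=1e-4)

    def test_perfectly_separable_toy_pair_scores_one(self):
        # model fires hard on feature 0 (relevant) and is silenced by feature 1
        model = pt.MLPModel(
            layers=[
                pt.LayerParams(np.array([[10.0], [-10.0]]), np.array([0.0]), "relu"),
                pt.LayerParams(np.array([[2.0]]), np.array([-10.0]), "sigmoid"),
            ],
            input_dim=2,
        )
        X = np.array([[1.0, 0.0], [0.0, 1.0]] * 10)
        y = np.array([1.0, 0.0] * 10)
        cm, metrics, per_sample = pt.evaluate(model, X, y)
        assert metrics.accuracy == 1.0
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (10, 10, 0, 0)
        assert len(per_sample) == 20


class TestCrossValidate:
    def test_kfold_returns_per_fold_metrics(self):
        X, y = separable_data(n=400, seed=9)
        folds = [np.arange(i, 400, 5) for i in range(5)]
        results = pt.cross_validate(X, y, folds, pt.TrainConfig(seed=9))
        assert len(results) == 5
        assert all(0.0 <= m.accuracy <= 1.0 for m in results)
        assert np.mean([m.accuracy for m in results]) >= 0.9
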