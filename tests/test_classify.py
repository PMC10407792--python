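import numpy as np
import pytest
from sklearn.neighbors import KNeighborsRegressor

from soyphen.classify import (
    BPNetwork,
    GRNN,
    LSSVM,
    TraitMatrix,
    evaluate_model,
    regression_metrics,
    train_test_split,
)
from soyphen.synth import make_trait_dataset


@pytest.fixture
def dataset():
    return make_trait_dataset(n_per_class=50, seed=0)


class TestTrainTestSplit:
    def test_reproducible_8_2(self, rng):
        data = TraitMatrix(rng.normal(size=(10, 6)), np.r_[[1] * 5, [2] * 5])
        tr1, te1 = train_test_split(data, 0.8, seed=1)
        tr2, te2 = train_test_split(data, 0.8, seed=1)
        assert len(tr1) == 8 and len(te1) == 2
        np.testing.assert_array_equal(tr1.X, tr2.X)
        np.testing.assert_array_equal(te1.y, te2.y)

    def test_partition_property(self, dataset):
        tr, te = train_test_split(dataset, 0.8, seed=3)
        rows = np.vstack([tr.X, te.X])
        # every original row appears exactly once across the two halves
        key = lambda X: {tuple(r) for r in X}
        assert key(rows) == key(dataset.X)
        assert len(tr) + len(te) == len(dataset)

    def test_stratified_balanced_classes(self):
        data = make_trait_dataset(n_per_class=100, seed=1)
        tr, te = train_test_split(data, 0.8, seed=0)
        for lab in (1, 2, 3):
            assert abs(np.sum(tr.y == lab) - 80) <= 1
            assert abs(np.sum(te.y == lab) - 20) <= 1

    def test_tiny_class_rejected(self):
        data = TraitMatrix(np.zeros((3, 6)), np.array([1, 1, 2]))
        with pytest.raises(ValueError):
            train_test_split(data, 0.8, seed=0)


class TestGRNN:
    def test_single_training_sample(self):
        model = GRNN(spread=1.0).fit([[0.0] * 6], [2.0])
        pred = model.predict(np.random.default_rng(0).normal(size=(5, 6)))
        np.testing.assert_allclose(pred, 2.0)

    def test_symmetric_midpoint(self):
        X = np.array([[-1.0], [1.0]])
        model = GRNN(spread=0.7, standardize=False).fit(X, [0.0, 2.0])
        assert abs(model.predict([[0.0]])[0] - 1.0) < 1e-12

    def test_small_spread_matches_1nn(self, rng):
        X = rng.normal(size=(200, 6))
        y = rng.normal(size=200)
        model = GRNN(spread=1e-3).fit(X, y)
        q = rng.normal(size=(50, 6))
        nn = KNeighborsRegressor(n_neighbors=1).fit(model.X_, y)
        qs = (q - model.mean_) / model.sd_
        np.testing.assert_allclose(model.predict(q), nn.predict(qs), atol=1e-9)

    def test_predictions_convex_in_labels(self, rng):
        X = rng.normal(size=(100, 6))
        y = rng.uniform(1, 3, 100)
        model = GRNN(spread=0.5).fit(X, y)
        pred = model.predict(rng.normal(size=(200, 6)) * 3)
        assert pred.min() >= y.min() - 1e-9
        assert pred.max() <= y.max() + 1e-9

    def test_loo_spread_deterministic(self, dataset):
        m1 = GRNN().fit(dataset.X, dataset.y)
        m2 = GRNN().fit(dataset.X, dataset.y)
        assert m1.spread_ == m2.spread_

    def test_sklearn_params_protocol(self):
        model = GRNN(spread=2.0)
        assert model.get_params()["spread"] == 2.0
        model.set_params(spread=1.0)
        assert model.spread == 1.0


class TestLSSVM:
    def test_two_point_signs(self):
        model = LSSVM(gamma=100.0, kernel_width=1.0, standardize=False).fit(
            [[-1.0], [1.0]], [-1.0, 1.0]
        )
        pred = model.predict([[-1.0], [1.0]])
        assert pred[0] < 0 < pred[1]

    def test_xor_with_rbf(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1.0]])
        y = np.array([-1.0, 1.0, 1.0, -1.0])
        model = LSSVM(gamma=1000.0, kernel_width=0.5, standardize=False).fit(X, y)
        assert np.all(np.sign(model.predict(X)) == y)

    def test_system_residual(self, dataset):
        model = LSSVM().fit(dataset.X, dataset.y)
        assert model.residual_ <= 1e-8

    def test_multiclass_one_vs_rest(self, dataset):
        model = LSSVM(gamma=50.0).fit(dataset.X, dataset.y)
        labels = model.predict_label(dataset.X)
        assert set(labels) <= {1, 2, 3}
        assert np.mean(labels == dataset.y) > 0.9


class TestBPNetwork:
    def test_untrained_depends_only_on_seed(self, rng):
        X = rng.normal(size=(10, 6))
        y = rng.normal(size=10)
        p1 = BPNetwork(epochs=0, seed=5).fit(X, y).predict(X)
        p2 = BPNetwork(epochs=0, seed=5).fit(X, y).predict(X)
        p3 = BPNetwork(epochs=0, seed=6).fit(X, y).predict(X)
        np.testing.assert_array_equal(p1, p2)
        assert not np.allclose(p1, p3)

    def test_gradient_matches_finite_differences(self):
        X = np.array(
            [[0.1, 0.2, 0.3, 0.4, 0.5, 0.6],
             [0.5, 0.1, 0.9, 0.2, 0.3, 0.4],
             [0.9, 0.8, 0.1, 0.6, 0.2, 0.1]]
        )
        y = np.array([1.0, 2.0, 3.0])
        model = BPNetwork(hidden=4, epochs=0, seed=1).fit(X, y)
        grads = model.gradients(X, y)
        eps = 1e-6
        for name in ("W1", "b1", "W2"):
            arr = getattr(model, name + "_")
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = arr[idx]
                arr[idx] = orig + eps
                lp = model.loss(X, y)
                arr[idx] = orig - eps
                lm = model.loss(X, y)
                arr[idx] = orig
                fd = (lp - lm) / (2 * eps)
                assert abs(fd - grads[name][idx]) < 1e-5

    def test_learns_and_function(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1.0]])
        y = np.array([0.0, 0.0, 0.0, 1.0])
        model = BPNetwork(hidden=4, lr=0.5, epochs=5000, seed=0,
                          standardize=False).fit(X, y)
        assert model.loss(X, y) < 0.05

    def test_loss_curve_trends_down(self, dataset):
        model = BPNetwork(hidden=6, lr=0.05, epochs=400, seed=0).fit(
            dataset.X, dataset.y
        )
        first = np.mean(model.loss_curve_[:20])
        last = np.mean(model.loss_curve_[-20:])
        assert last < first


class TestRegressionMetrics:
    def test_perfect_fit(self):
        rep = regression_metrics([1.0, 2, 3], [1.0, 2, 3], [1.0, 2], [1.0, 2])
        assert rep.mape == 0 and rep.rmse == 0 and rep.r2 == 1
        assert rep.rc == 1 and rep.rp == 1

    def test_hand_computed_example(self):
        rep = regression_metrics([1.0, 2, 3], [1.0, 2, 6])
        assert abs(rep.rmse - np.sqrt(3)) < 1e-12
        assert abs(rep.mape - 100.0 / 3) < 1e-9
        assert abs(rep.r2 - (-3.5)) < 1e-12

    def test_rmse_shift_invariant(self, rng):
        y = rng.normal(size=40)
        p = y + rng.normal(size=40) * 0.3
        r1 = regression_metrics(y + 5, p + 5)
        r2 = regression_metrics(y - 2 + 1e-9, p - 2 + 1e-9)
        assert abs(r1.rmse - r2.rmse) < 1e-9

    def test_zero_variance_warns_nan(self):
        with pytest.warns(UserWarning):
            rep = regression_metrics([2.0, 2.0], [1.0, 3.0])
        assert np.isnan(rep.r2)

    def test_zero_target_rejected(self):
        with pytest.raises(ValueError):
            regression_metrics([0.0, 1.0], [1.0, 1.0])


class TestProtocol:
    def test_grnn_separable_dataset(self):
        data = make_trait_dataset(seed=0)  # defaults: 3 x 149, >=3 sd apart
        report, acc = evaluate_model(GRNN(), data, 0.8, seed=0)
        assert acc >= 0.90
        assert report.rp > 0.9

    def test_chance_level_at_zero_separation(self):
        data = make_trait_dataset(class_shifts=(1.0, 1.0, 1.0), seed=0)
        _, acc = evaluate_model(GRNN(), data, 0.8, seed=0)
        assert acc < 0.5

    def test_whole_protocol_bit_reproducible(self):
        data = make_trait_dataset(seed=4)
        r1, a1 = evaluate_model(GRNN(), data, 0.8, seed=2)
        r2, a2 = evaluate_model(GRNN(), data, 0.8, seed=2)
        assert a1 == a2
        assert r1 == r2
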