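"""Elastic-net NN: penalty arithmetic, forward pass, training, tuning."""

import numpy as np
import pytest

from oudiverge import (
    CONSERVED,
    DIVERGED,
    NeuralNetClassifier,
    NeuralNetRegressor,
    PriorSpec,
    cross_val_loss,
    elastic_net_penalty,
    generate_dataset,
    train_nn,
    tune_nn,
)
from oudiverge.neural import default_lambda_grid


class TestElasticNetPenalty:
    @pytest.mark.parametrize(
        "lam,gamma,weights,expected",
        [
            (0.0, 0.5, [np.array([1.0, -2.0])], 0.0),
            (1.0, 1.0, [np.array([1.0, -2.0])], 3.0),  # pure L1
            (0.5, 0.0, [np.array([1.0, -2.0])], 2.5),  # pure L2
            (2.0, 0.5, [np.array([1.0]), np.array([-1.0])], 4.0),
        ],
    )
    def test_arithmetic(self, lam, gamma, weights, expected):
        assert elastic_net_penalty(weights, lam, gamma) == pytest.approx(expected)

    def test_monotone_in_lambda(self):
        w = [np.array([0.3, -1.2, 4.0])]
        lams = np.linspace(0, 2, 9)
        vals = [elastic_net_penalty(w, lam, 0.4) for lam in lams]
        assert np.all(np.diff(vals) >= 0)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            elastic_net_penalty([np.ones(2)], -1.0, 0.5)
        with pytest.raises(ValueError):
            elastic_net_penalty([np.ones(2)], 1.0, 1.5)


def _toy_separable(n=200, seed=0, m=6):
    """Conserved pairs near a shared optimum; diverged offset by +5 in e2."""
    rng = np.random.default_rng(seed)
    base = rng.uniform(0, 5, size=(n, m))
    noise = lambda: rng.normal(0, 0.1, size=(n, m))
    X_cons = np.empty((n, 2 * m))
    X_cons[:, 0::2] = base + noise()
    X_cons[:, 1::2] = base + noise()
    X_div = np.empty((n, 2 * m))
    base2 = rng.uniform(0, 5, size=(n, m))
    X_div[:, 0::2] = base2 + noise()
    X_div[:, 1::2] = base2 + 5.0 + noise()
    X = np.vstack([X_cons, X_div])
    y = np.array([CONSERVED] * n + [DIVERGED] * n)
    order = rng.permutation(len(y))
    return X[order], y[order]


class TestForwardPass:
    def test_zero_weights_give_uniform_probabilities(self):
        clf = NeuralNetClassifier(hidden_layers=0, epochs=1, batch_size=4,
                                  random_state=0)
        X, y = _toy_separable(10)
        clf.fit(X, y)
        clf.coefs_ = [np.zeros_like(w) for w in clf.coefs_]
        clf.intercepts_ = [np.zeros_like(b) for b in clf.intercepts_]
        proba = clf.predict_proba(X[:3])
        assert np.allclose(proba, 0.5)
        # exact tie resolves to the conserved (null) class
        assert set(clf.predict(X[:3])) == {CONSERVED}

    def test_hand_computed_single_hidden_layer(self):
        # 2 inputs -> 1 hidden-layer net with hand-set weights; compare
        # against explicit arithmetic including the ReLU cutoff
        clf = NeuralNetClassifier(hidden_layers=1, first_width=2, epochs=1,
                                  batch_size=2, random_state=0)
        X = np.array([[1.0, -1.0], [0.5, 2.0]])
        clf.fit(X, np.array([CONSERVED, DIVERGED]))
        clf.coefs_ = [
            np.array([[1.0, -1.0], [2.0, 0.5]], dtype=np.float32),
            np.array([[0.5, -0.5], [1.0, 2.0]], dtype=np.float32),
        ]
        clf.intercepts_ = [
            np.array([0.1, -0.2], dtype=np.float32),
            np.array([0.0, 0.3], dtype=np.float32),
        ]
        x = np.array([1.0, -1.0])
        h = np.maximum(x @ clf.coefs_[0] + clf.intercepts_[0], 0.0)
        logits = h @ clf.coefs_[1] + clf.intercepts_[1]
        expect = np.exp(logits) / np.exp(logits).sum()
        assert np.allclose(clf.predict_proba(x)[0], expect, atol=1e-6)
        # the second hidden unit has negative pre-activation for this input
        assert h[1] == 0.0

    def test_probabilities_sum_to_one(self):
        X, y = _toy_separable(50, seed=3)
        clf = NeuralNetClassifier(hidden_layers=2, first_width=16, epochs=5,
                                  batch_size=32, random_state=1).fit(X, y)
        proba = clf.predict_proba(X)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_shape_mismatch_rejected(self):
        X, y = _toy_separable(20)
        clf = NeuralNetClassifier(hidden_layers=0, epochs=1, random_state=0).fit(X, y)
        with pytest.raises(ValueError):
            clf.predict(X[:, :5])


class TestTraining:
    def test_separable_toy_reaches_perfect_accuracy(self):
        X, y = _toy_separable(150, seed=1)
        Xt, yt = _toy_separable(80, seed=2)
        clf = NeuralNetClassifier(hidden_layers=1, first_width=32, epochs=60,
                                  batch_size=64, random_state=0).fit(X, y)
        assert np.mean(clf.predict(Xt) == yt) == 1.0

    def test_no_signal_training_stays_at_chance(self):
        # force theta2 == theta1 in both classes: labels carry no information
        rng = np.random.default_rng(0)
        data = generate_dataset(PriorSpec(m=2), 300, 300, 1)
        X = data.features.copy()
        y = data.labels
        cons = y == CONSERVED
        X[~cons] = X[cons][: np.sum(~cons)]  # diverged rows get conserved data
        clf = NeuralNetClassifier(hidden_layers=1, first_width=32, epochs=30,
                                  batch_size=100, random_state=0).fit(X, y)
        test = generate_dataset(PriorSpec(m=2), 200, 0, 2)
        acc = np.mean(clf.predict(test.features) == CONSERVED)
        assert 0.2 < acc < 0.8  # no systematic signal either way

    def test_seeded_training_is_reproducible(self):
        X, y = _toy_separable(100, seed=4)
        a = NeuralNetClassifier(hidden_layers=1, first_width=8, epochs=10,
                                batch_size=50, random_state=5).fit(X, y)
        b = NeuralNetClassifier(hidden_layers=1, first_width=8, epochs=10,
                                batch_size=50, random_state=5).fit(X, y)
        for wa, wb in zip(a.coefs_, b.coefs_):
            assert np.array_equal(wa, wb)

    def test_linear_limit_matches_logistic_regression(self):
        # L=0, lambda=0 is plain multinomial logistic regression: decisions
        # must agree with the sklearn fit on an easy 2-feature problem
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(7)
        X = np.vstack([rng.normal(0, 1, (300, 2)), rng.normal(2.2, 1, (300, 2))])
        y = np.array([CONSERVED] * 300 + [DIVERGED] * 300)
        nn = NeuralNetClassifier(hidden_layers=0, lam=0.0, epochs=4000,
                                 batch_size=600, learning_rate=1e-2,
                                 random_state=0).fit(X, y)
        lr = LogisticRegression(C=np.inf).fit(X, y)
        grid = np.random.default_rng(8).uniform(-3, 5, size=(1000, 2))
        agreement = np.mean(nn.predict(grid) == lr.predict(grid))
        assert agreement >= 0.99

    def test_divergent_training_raises(self):
        X, y = _toy_separable(50, seed=6)
        reg = NeuralNetRegressor(hidden_layers=1, first_width=8, epochs=50,
                                 batch_size=50, learning_rate=1e12, random_state=0)
        with np.errstate(all="ignore"), pytest.raises(FloatingPointError):
            reg.fit(X * 1e3, X * 1e3)

    def test_invalid_depth_rejected(self):
        X, y = _toy_separable(10)
        with pytest.raises(ValueError):
            NeuralNetClassifier(hidden_layers=7).fit(X, y)


class TestRegressor:
    def test_output_dimension_matches_target(self):
        data = generate_dataset(PriorSpec(m=6), 100, 100, 3)
        reg = train_nn(data, "regress", random_state=0, hidden_layers=1,
                       first_width=16, epochs=5, batch_size=100)
        pred = reg.predict(data.features[:7])
        assert pred.shape == (7, 12)

    def test_linear_limit_matches_least_squares(self):
        from sklearn.linear_model import LinearRegression

        rng = np.random.default_rng(9)
        X = rng.normal(0, 1, (400, 3))
        Y = X @ np.array([[1.0, -2.0], [0.5, 0.0], [0.0, 1.5]]) + 0.3
        nn = NeuralNetRegressor(hidden_layers=0, lam=0.0, epochs=2500,
                                batch_size=400, learning_rate=1e-2,
                                random_state=0).fit(X, Y)
        ls = LinearRegression().fit(X, Y)
        assert np.allclose(nn.predict(X), ls.predict(X), atol=0.02)


class TestTuning:
    def test_single_point_grid_returned_with_its_loss(self):
        data = generate_dataset(PriorSpec(m=2), 100, 100, 4)
        cfg, loss, model = tune_nn(
            data, "classify", hidden_layer_grid=(1,), lambda_grid=[1e-6],
            gamma_grid=(0.5,), random_state=0, epochs=3, batch_size=80,
            first_width=8,
        )
        assert cfg == {"hidden_layers": 1, "lam": 1e-6, "gamma_mix": 0.5}
        assert np.isfinite(loss)
        assert model is not None and model.hidden_layers == 1

    def test_empty_grid_rejected(self):
        data = generate_dataset(PriorSpec(m=2), 50, 50, 4)
        with pytest.raises(ValueError):
            tune_nn(data, hidden_layer_grid=(), random_state=0)

    def test_default_lambda_grid_spans_stated_log_range(self):
        grid = default_lambda_grid()
        assert len(grid) == 25
        assert grid[0] == pytest.approx(1e-12)
        assert grid[-1] == pytest.approx(1e-3)
        assert np.allclose(np.diff(np.log10(grid)), np.diff(np.log10(grid))[0])

    def test_cross_val_loss_penalty_flag(self):
        data = generate_dataset(PriorSpec(m=2), 100, 100, 5)
        kwargs = dict(hidden_layers=1, first_width=8, epochs=3, batch_size=80,
                      lam=1e-2, gamma_mix=1.0, random_state=0)
        plain = cross_val_loss(data, "classify", **kwargs)
        penalized = cross_val_loss(data, "classify", include_penalty=True, **kwargs)
        assert penalized > plain > 0
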