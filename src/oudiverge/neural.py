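"""Elastic-net-regularized dense feed-forward neural networks.

The network takes the 2m-long interleaved log-expression vector of an
ortholog pair and either classifies it (softmax over K=2 classes,
cross-entropy loss) or jointly regresses all K=2m expression optima
(linear output, mean squared error).  Hidden layers use ReLU; the first
hidden layer has 256 units and each subsequent layer halves the width,
so L hidden layers give widths 256, 128, 64, ...  With L=0 the model
reduces to logistic (classification) or ordinary linear (regression)
regression on the features.

Training minimizes

    J(W) = mean loss + lambda * sum over non-bias weights of
           [(1 - gamma) * w^2 + gamma * |w|]

with the Adam optimizer on seeded mini-batches.  gamma=1 is pure L1
(sparse, feature-selecting), gamma=0 pure L2.  Biases are never
penalized.  Everything is plain NumPy with manual backpropagation, in
float32 for speed; training is exactly reproducible for a fixed
``random_state``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.model_selection import StratifiedKFold

from .simulate import LabeledDataset

__all__ = [
    "NeuralNetClassifier",
    "NeuralNetRegressor",
    "elastic_net_penalty",
    "train_nn",
    "cross_val_loss",
    "tune_nn",
    "default_lambda_grid",
]

_ADAM_EPS = 1e-8


def elastic_net_penalty(weights, lam: float, gamma_mix: float) -> float:
    """Elastic-net penalty over a collection of (non-bias) weight arrays.

    lam * sum[(1 - gamma) w^2 + gamma |w|], summed over every entry of
    every array in ``weights``.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if not 0.0 <= gamma_mix <= 1.0:
        raise ValueError("gamma_mix must lie in [0, 1]")
    if lam == 0.0:
        return 0.0
    total = 0.0
    for w in weights:
        w = np.asarray(w, dtype=float)
        total += (1.0 - gamma_mix) * np.sum(w * w) + gamma_mix * np.sum(np.abs(w))
    return float(lam * total)


def _hidden_widths(hidden_layers: int, first_width: int) -> list[int]:
    return [first_width // 2**i for i in range(hidden_layers)]


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    np.exp(z, out=z)
    z /= z.sum(axis=1, keepdims=True)
    return z


class _ElasticNetNN(BaseEstimator):
    """Shared fit machinery; subclasses set the output head and loss."""

    _is_classifier = False

    def __init__(
        self,
        hidden_layers=2,
        first_width=256,
        lam=0.0,
        gamma_mix=1.0,
        learning_rate=1e-3,
        beta1=0.9,
        beta2=0.999,
        batch_size=5000,
        epochs=500,
        random_state=None,
    ):
        self.hidden_layers = hidden_layers
        self.first_width = first_width
        self.lam = lam
        self.gamma_mix = gamma_mix
        self.learning_rate = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.batch_size = batch_size
        self.epochs = epochs
        self.random_state = random_state

    # -- forward / backward ------------------------------------------------

    def _forward(self, X):
        """Return (list of post-activation layer inputs, output logits)."""
        acts = [X]
        a = X
        n_hidden = len(self.coefs_) - 1
        for i in range(n_hidden):
            a = a @ self.coefs_[i] + self.intercepts_[i]
            np.maximum(a, 0.0, out=a)
            acts.append(a)
        logits = a @ self.coefs_[-1] + self.intercepts_[-1]
        return acts, logits

    def _penalty_grad(self, w):
        return self.lam * (
            2.0 * (1.0 - self.gamma_mix) * w + self.gamma_mix * np.sign(w)
        )

    def fit(self, X, y):
        if self.hidden_layers not in (0, 1, 2, 3):
            raise ValueError("hidden_layers must be in {0, 1, 2, 3}")
        if not 0.0 <= self.gamma_mix <= 1.0:
            raise ValueError("gamma_mix must lie in [0, 1]")
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 2 or len(X) == 0:
            raise ValueError("X must be a non-empty 2D array")
        Y = self._encode_targets(y)
        n, p = X.shape
        k_out = Y.shape[1]

        rng = np.random.default_rng(self.random_state)
        sizes = [p, *_hidden_widths(self.hidden_layers, self.first_width), k_out]
        self.coefs_, self.intercepts_ = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            self.coefs_.append(
                rng.uniform(-limit, limit, (fan_in, fan_out)).astype(np.float32)
            )
            self.intercepts_.append(np.zeros(fan_out, dtype=np.float32))

        params = self.coefs_ + self.intercepts_
        m1 = [np.zeros_like(w) for w in params]
        m2 = [np.zeros_like(w) for w in params]
        step = 0
        batch = min(self.batch_size, n)
        self.loss_curve_ = []

        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, n, batch):
                idx = order[start : start + batch]
                xb, yb = X[idx], Y[idx]
                grads, loss = self._backward(xb, yb)
                epoch_loss += loss
                n_batches += 1
                step += 1
                # Adam with bias correction
                c1 = 1.0 - self.beta1**step
                c2 = 1.0 - self.beta2**step
                for w, g, v1, v2 in zip(params, grads, m1, m2):
                    v1 *= self.beta1
                    v1 += (1.0 - self.beta1) * g
                    v2 *= self.beta2
                    v2 += (1.0 - self.beta2) * g * g
                    w -= self.learning_rate * (v1 / c1) / (np.sqrt(v2 / c2) + _ADAM_EPS)
            self.loss_curve_.append(epoch_loss / n_batches)
            if not np.isfinite(self.loss_curve_[-1]):
                raise FloatingPointError("training diverged: non-finite loss")
        self.n_features_in_ = p
        return self

    def _backward(self, xb, yb):
        acts, logits = self._forward(xb)
        delta, loss = self._output_grad(logits, yb)
        grads_w, grads_b = [], []
        for i in range(len(self.coefs_) - 1, -1, -1):
            gw = acts[i].T @ delta
            gw += self._penalty_grad(self.coefs_[i])
            gb = delta.sum(axis=0)
            grads_w.append(gw)
            grads_b.append(gb)
            if i > 0:
                delta = delta @ self.coefs_[i].T
                delta[acts[i] <= 0.0] = 0.0
        grads_w.reverse()
        grads_b.reverse()
        loss += elastic_net_penalty(self.coefs_, self.lam, self.gamma_mix)
        return grads_w + grads_b, loss

    def _raw_output(self, X):
        X = np.asarray(X, dtype=np.float32)
        squeeze = X.ndim == 1
        if squeeze:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        _, logits = self._forward(X)
        return logits[0] if squeeze else logits


class NeuralNetClassifier(_ElasticNetNN, ClassifierMixin):
    """Softmax-output NN classifying ortholog pairs as conserved/diverged.

    ``predict_proba`` returns class probabilities ordered by ``classes_``;
    an exact probability tie resolves to the conserved (null-like) class.
    """

    _is_classifier = True

    def _encode_targets(self, y):
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("exactly two classes required")
        codes = (y == self.classes_[1]).astype(int)
        onehot = np.zeros((len(y), 2), dtype=np.float32)
        onehot[np.arange(len(y)), codes] = 1.0
        return onehot

    def _output_grad(self, logits, yb):
        probs = _softmax(logits.astype(np.float64))
        n = len(yb)
        loss = -np.mean(np.sum(yb * np.log(np.clip(probs, 1e-12, None)), axis=1))
        delta = ((probs - yb) / n).astype(np.float32)
        return delta, float(loss)

    def predict_proba(self, X):
        logits = self._raw_output(X).astype(np.float64)
        return _softmax(np.atleast_2d(logits))

    def predict(self, X):
        proba = self.predict_proba(X)
        # strict inequality: an exact tie falls back to the first
        # (alphabetically "conserved") class
        return self.classes_[(proba[:, 1] > proba[:, 0]).astype(int)]

    def decision_scores(self, X):
        """Probability of the "diverged" class (for ROC sweeps)."""
        return self.predict_proba(X)[:, 1]


class NeuralNetRegressor(_ElasticNetNN, RegressorMixin):
    """Linear-output NN jointly regressing all 2m expression optima."""

    def _encode_targets(self, y):
        Y = np.asarray(y, dtype=np.float32)
        if Y.ndim == 1:
            Y = Y[:, None]
        return Y

    def _output_grad(self, logits, yb):
        n, k = yb.shape
        resid = logits - yb
        loss = float(np.mean(resid.astype(np.float64) ** 2))
        delta = (2.0 * resid / (n * k)).astype(np.float32)
        return delta, loss

    def predict(self, X):
        return self._raw_output(X).astype(np.float64)


# -- dataset-level helpers -------------------------------------------------


def _estimator_for(task, config, random_state):
    cls = NeuralNetClassifier if task == "classify" else NeuralNetRegressor
    return cls(random_state=random_state, **config)


def _targets_for(data: LabeledDataset, task):
    return data.labels if task == "classify" else data.optima()


def train_nn(data: LabeledDataset, task: str = "classify", random_state=None, **config):
    """Fit a NN of the given task on a labelled dataset.

    ``config`` forwards to the estimator (hidden_layers, lam, gamma_mix,
    epochs, ...).  Returns the fitted estimator.
    """
    if task not in ("classify", "regress"):
        raise ValueError("task must be 'classify' or 'regress'")
    est = _estimator_for(task, config, random_state)
    return est.fit(data.features, _targets_for(data, task))


def _validation_loss(est, X, Y, include_penalty=False):
    if est._is_classifier:
        probs = est.predict_proba(X)
        onehot = np.zeros_like(probs)
        onehot[np.arange(len(Y)), (Y == est.classes_[1]).astype(int)] = 1.0
        base = -np.mean(np.sum(onehot * np.log(np.clip(probs, 1e-12, None)), axis=1))
    else:
        base = float(np.mean((est.predict(X) - Y) ** 2))
    if include_penalty:
        # deep-learning-framework-style val_loss, regularizer losses folded in
        base += elastic_net_penalty(est.coefs_, est.lam, est.gamma_mix)
    return float(base)


def cross_val_loss(
    data: LabeledDataset,
    task: str = "classify",
    n_splits: int = 5,
    random_state=None,
    include_penalty: bool = False,
    **config,
):
    """Mean class-balanced k-fold validation loss of a NN configuration.

    Folds are stratified by class label (so each 80/20 split is balanced
    when the dataset is).  The reported loss is validation cross-entropy
    (classification) or MSE averaged over outputs (regression);
    ``include_penalty`` adds the elastic-net penalty of each fold's fitted
    weights, giving the regularized objective instead.
    """
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=random_state)
    X = data.features
    Y = _targets_for(data, task)
    losses = []
    for i, (tr, va) in enumerate(skf.split(X, data.labels)):
        seed = None if random_state is None else int(random_state) + i
        est = _estimator_for(task, config, seed)
        est.fit(X[tr], Y[tr])
        losses.append(_validation_loss(est, X[va], Y[va], include_penalty))
    return float(np.mean(losses))


def default_lambda_grid(n: int = 25) -> np.ndarray:
    """n shrinkage strengths log-uniform over log10(lambda) in [-12, -3]."""
    return 10.0 ** np.linspace(-12.0, -3.0, n)


def tune_nn(
    data: LabeledDataset,
    task: str = "classify",
    hidden_layer_grid=(0, 1, 2, 3),
    lambda_grid=None,
    gamma_grid=(0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
    n_splits: int = 5,
    random_state=None,
    refit: bool = True,
    **config,
):
    """Grid-search (L, lambda, gamma) by k-fold CV; optionally refit on all data.

    Returns (best_config_dict, best_cv_loss, fitted_model_or_None).
    """
    if lambda_grid is None:
        lambda_grid = default_lambda_grid()
    grid = [
        {"hidden_layers": int(L), "lam": float(lam), "gamma_mix": float(g)}
        for L in hidden_layer_grid
        for lam in lambda_grid
        for g in gamma_grid
    ]
    if not grid:
        raise ValueError("empty hyperparameter grid")
    best_cfg, best_loss = None, np.inf
    for cfg in grid:
        loss = cross_val_loss(
            data, task, n_splits=n_splits, random_state=random_state, **cfg, **config
        )
        if loss < best_loss:
            best_cfg, best_loss = cfg, loss
    model = None
    if refit:
        model = train_nn(data, task, random_state=random_state, **best_cfg, **config)
    return best_cfg, best_loss, model
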