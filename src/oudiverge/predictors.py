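"""Random-forest and support-vector architectures, tuning, and model IO.

Together with the neural networks in :mod:`oudiverge.neural`, these make up
the three predictor architectures.  Both tasks are supported: classification
of ortholog pairs into conserved/diverged, and regression of the 2m
expression optima.  The NN regresses all outputs jointly; the forest and
SVM fit one regressor per output.

The forest follows Breiman's algorithm: 500 unpruned trees, each grown on a
same-size bootstrap resample, with a random feature subset considered at
every split (sqrt(p) for classification, p/3 for regression), Gini impurity
(classification) or response variance (regression), and a minimum node size
of 10 / 5.  The SVM uses a radial-basis kernel K(x, x') = exp(-g ||x-x'||^2)
with kernel width g and box constraint C tuned by class-balanced 5-fold
cross-validation over a log-spaced grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC, SVR

from .simulate import CONSERVED, DIVERGED, LabeledDataset

__all__ = [
    "default_gamma_grid",
    "default_C_grid",
    "train_rf",
    "train_svm",
    "tune_svm",
    "MultiOutputRegressorBundle",
    "predict_labels",
    "predict_scores",
    "predict_optima",
    "save_model",
    "load_model",
]


def default_gamma_grid(n: int = 11) -> np.ndarray:
    """n RBF kernel widths log-uniform over [0.001, 5]."""
    return 10.0 ** np.linspace(np.log10(0.001), np.log10(5.0), n)


def default_C_grid(n: int = 5) -> np.ndarray:
    """n box-constraint values log-uniform over [0.01, 100]."""
    return 10.0 ** np.linspace(-2.0, 2.0, n)


@dataclass
class MultiOutputRegressorBundle:
    """One independently fitted regressor per output column."""

    estimators: list

    def predict(self, X):
        return np.column_stack([est.predict(X) for est in self.estimators])


def train_rf(
    data: LabeledDataset,
    task: str = "classify",
    n_trees: int = 500,
    random_state=None,
):
    """Fit the random-forest architecture on a labelled dataset."""
    if task == "classify":
        rf = RandomForestClassifier(
            n_estimators=n_trees,
            criterion="gini",
            max_features="sqrt",
            min_samples_split=10,
            bootstrap=True,
            random_state=random_state,
        )
        return rf.fit(data.features, data.labels)
    if task == "regress":
        targets = data.optima()
        ests = []
        for k in range(targets.shape[1]):
            rf = RandomForestRegressor(
                n_estimators=n_trees,
                criterion="squared_error",
                max_features=1.0 / 3.0,
                min_samples_split=5,
                bootstrap=True,
                random_state=None if random_state is None else random_state + k,
            )
            ests.append(rf.fit(data.features, targets[:, k]))
        return MultiOutputRegressorBundle(ests)
    raise ValueError("task must be 'classify' or 'regress'")


def train_svm(
    data: LabeledDataset,
    task: str = "classify",
    gamma: float = 1.0,
    C: float = 1.0,
    epsilon: float = 0.1,
    random_state=None,
):
    """Fit the RBF-kernel SVM at fixed hyperparameters."""
    if task == "classify":
        svm = SVC(kernel="rbf", gamma=gamma, C=C, random_state=random_state,
                  cache_size=500)
        return svm.fit(data.features, data.labels)
    if task == "regress":
        targets = data.optima()
        ests = []
        for k in range(targets.shape[1]):
            svr = SVR(kernel="rbf", gamma=gamma, C=C, epsilon=epsilon, cache_size=500)
            ests.append(svr.fit(data.features, targets[:, k]))
        return MultiOutputRegressorBundle(ests)
    raise ValueError("task must be 'classify' or 'regress'")


def tune_svm(
    data: LabeledDataset,
    task: str = "classify",
    gamma_grid=None,
    C_grid=None,
    n_splits: int = 5,
    subsample: int | None = 3000,
    random_state=None,
):
    """Grid-search (gamma, C) by class-balanced k-fold CV.

    Kernel-machine training is quadratic-plus in the sample count, so by
    default the grid is evaluated on a class-balanced random subsample of
    ``subsample`` observations; the winning pair is meant to be refit on
    the full set with :func:`train_svm`.  Returns
    (best_gamma, best_C, best_cv_accuracy_or_neg_mse).
    """
    gamma_grid = default_gamma_grid() if gamma_grid is None else np.asarray(gamma_grid)
    C_grid = default_C_grid() if C_grid is None else np.asarray(C_grid)
    if gamma_grid.size == 0 or C_grid.size == 0:
        raise ValueError("empty hyperparameter grid")

    rng = np.random.default_rng(random_state)
    idx = np.arange(len(data))
    if subsample is not None and subsample < len(data):
        parts = []
        for lab in (CONSERVED, DIVERGED):
            lab_idx = idx[data.labels == lab]
            take = min(len(lab_idx), subsample // 2)
            parts.append(rng.choice(lab_idx, size=take, replace=False))
        idx = np.concatenate(parts)
    X = data.features[idx]
    labels = data.labels[idx]
    targets = labels if task == "classify" else data.optima()[idx]

    skf = StratifiedKFold(n_splits=n_splits, shuffle=True,
                          random_state=None if random_state is None else int(random_state))
    folds = list(skf.split(X, labels))
    best = (None, None, -np.inf)
    for g in gamma_grid:
        for C in C_grid:
            scores = []
            for tr, va in folds:
                if task == "classify":
                    est = SVC(kernel="rbf", gamma=g, C=C, cache_size=500)
                    est.fit(X[tr], targets[tr])
                    scores.append(np.mean(est.predict(X[va]) == targets[va]))
                else:
                    mses = []
                    for k in range(targets.shape[1]):
                        est = SVR(kernel="rbf", gamma=g, C=C, cache_size=500)
                        est.fit(X[tr], targets[tr, k])
                        mses.append(np.mean((est.predict(X[va]) - targets[va, k]) ** 2))
                    scores.append(-np.mean(mses))
            mean_score = float(np.mean(scores))
            if mean_score > best[2]:
                best = (float(g), float(C), mean_score)
    return best


# -- architecture-agnostic prediction --------------------------------------


def predict_scores(model, X) -> np.ndarray:
    """Monotone "divergedness" score per observation.

    Probability of the diverged class for NN/RF; the signed decision value
    (distance to the separating hyperplane, diverged-positive) for the SVM.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if hasattr(model, "predict_proba"):
        proba = model.predict_proba(X)
        col = int(np.where(model.classes_ == DIVERGED)[0][0])
        return np.asarray(proba)[:, col]
    if hasattr(model, "decision_function"):
        dec = np.asarray(model.decision_function(X))
        # sklearn orients the decision function toward classes_[1]
        return dec if model.classes_[1] == DIVERGED else -dec
    raise TypeError(f"{type(model).__name__} exposes no classification score")


def predict_labels(model, X):
    """(labels, scores) for a fitted classifier of any architecture.

    Ties (probability exactly 0.5, or a decision value of exactly 0)
    resolve to the conserved class, which plays the role of the null
    hypothesis.
    """
    scores = predict_scores(model, X)
    threshold = 0.5 if hasattr(model, "predict_proba") else 0.0
    labels = np.where(scores > threshold, DIVERGED, CONSERVED)
    return labels, scores


def predict_optima(model, X) -> np.ndarray:
    """2m optimum estimates per observation, ordered (th1_1, th2_1, ...)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    out = np.asarray(model.predict(X), dtype=float)
    return out


# -- serialization ---------------------------------------------------------


def save_model(model, path) -> None:
    """Persist any fitted architecture to a single portable archive."""
    joblib.dump(model, Path(path))


def load_model(path):
    return joblib.load(Path(path))
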