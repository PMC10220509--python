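"""Benchmark metrics and experiment harness.

Conventions: "diverged" is the positive class, so power = diverged-class
true positive rate and the false positive rate is the fraction of conserved
pairs called diverged.  Confusion matrices are row-normalized with rows
ordered (conserved, diverged).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .baseline import DistanceThresholdClassifier
from .predictors import predict_labels
from .simulate import (
    CONSERVED,
    DIVERGED,
    LabeledDataset,
    PriorSpec,
    generate_dataset,
    regime_prior,
)

__all__ = [
    "accuracy",
    "confusion_rates",
    "roc_curve",
    "optima_error_summary",
    "regime_sweep",
    "DEFAULT_ALPHA_REGIMES",
    "DEFAULT_SIGMA2_REGIMES",
]

_CLASS_ORDER = (CONSERVED, DIVERGED)

DEFAULT_ALPHA_REGIMES = ((1.0, 10.0), (10.0, 100.0), (100.0, 1000.0))
DEFAULT_SIGMA2_REGIMES = (
    (0.01, 0.1),
    (0.1, 1.0),
    (1.0, 10.0),
    (10.0, 100.0),
    (100.0, 1000.0),
)


def accuracy(predicted, truth) -> float:
    """Fraction of exact label matches."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if len(predicted) != len(truth):
        raise ValueError("length mismatch")
    if len(truth) == 0:
        raise ValueError("empty input")
    return float(np.mean(predicted == truth))


def confusion_rates(predicted, truth) -> np.ndarray:
    """Row-normalized 2x2 confusion matrix, rows/cols (conserved, diverged)."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if len(truth) == 0:
        raise ValueError("empty input")
    mat = np.zeros((2, 2))
    for i, t in enumerate(_CLASS_ORDER):
        mask = truth == t
        if not mask.any():
            raise ValueError(f"class {t!r} absent from truth")
        for j, p in enumerate(_CLASS_ORDER):
            mat[i, j] = np.mean(predicted[mask] == p)
    return mat


def roc_curve(scores, truth):
    """ROC sweep of a diverged-positive score; returns (fpr, tpr, auc).

    Tied scores collapse into a single threshold step; the area is the
    trapezoid-rule integral, which equals the concordance probability
    with half credit for ties.
    """
    truth = np.asarray(truth)
    if len(set(truth.tolist())) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, _ = _sk_roc_curve(truth == DIVERGED, np.asarray(scores, dtype=float))
    return fpr, tpr, float(_sk_auc(fpr, tpr))


def optima_error_summary(estimates, truth, labels) -> pd.DataFrame:
    """Per-parameter, per-condition, per-class summary of optimum errors.

    ``estimates`` and ``truth`` are (N, 2m) arrays ordered
    (th1_1, th2_1, ..., th1_m, th2_m).  Returns a tidy frame with columns
    parameter ("theta1"/"theta2"), condition (1-based), label, median,
    iqr, and n.
    """
    estimates = np.asarray(estimates, dtype=float)
    truth = np.asarray(truth, dtype=float)
    labels = np.asarray(labels)
    if estimates.shape != truth.shape or len(labels) != len(estimates):
        raise ValueError("shape mismatch between estimates, truth, and labels")
    err = estimates - truth
    m = estimates.shape[1] // 2
    rows = []
    for lab in _CLASS_ORDER:
        mask = labels == lab
        for k in range(m):
            for j, name in enumerate(("theta1", "theta2")):
                e = err[mask, 2 * k + j]
                q1, med, q3 = np.percentile(e, [25, 50, 75])
                rows.append(
                    {
                        "parameter": name,
                        "condition": k + 1,
                        "label": lab,
                        "median": med,
                        "iqr": q3 - q1,
                        "n": int(mask.sum()),
                    }
                )
    return pd.DataFrame(rows)


def _evaluate_on(models: dict, data: LabeledDataset) -> list[dict]:
    rows = []
    for name, model in models.items():
        if isinstance(model, DistanceThresholdClassifier):
            labels = model.predict(data.features)
            scores = model.decision_scores(data.features)
        else:
            labels, scores = predict_labels(model, data.features)
        cm = confusion_rates(labels, data.labels)
        _, _, auc_val = roc_curve(scores, data.labels)
        rows.append(
            {
                "method": name,
                "accuracy": accuracy(labels, data.labels),
                "power": cm[1, 1],
                "fpr": cm[0, 1],
                "conserved_rate": cm[0, 0],
                "diverged_rate": cm[1, 1],
                "auc": auc_val,
            }
        )
    return rows


def regime_sweep(
    models: dict,
    alpha_regimes=DEFAULT_ALPHA_REGIMES,
    sigma2_regimes=DEFAULT_SIGMA2_REGIMES,
    n_per_regime: int = 2000,
    base_prior: PriorSpec | None = None,
    random_state=None,
) -> pd.DataFrame:
    """Accuracy/power/AUC of trained models across restricted (alpha, sigma2) regimes.

    Models stay fixed (trained under the full prior); only the test data are
    drawn from each restricted regime, sampling alpha and sigma2
    linear-uniformly within the regime's range.  ``n_per_regime`` is split
    evenly between the classes.
    """
    rng = np.random.default_rng(random_state)
    rows = []
    for a_range in alpha_regimes:
        for s_range in sigma2_regimes:
            prior = regime_prior(a_range, s_range, base_prior)
            data = generate_dataset(
                prior, n_per_regime // 2, n_per_regime - n_per_regime // 2, rng
            )
            for row in _evaluate_on(models, data):
                row.update(
                    {
                        "alpha_min": a_range[0],
                        "alpha_max": a_range[1],
                        "sigma2_min": s_range[0],
                        "sigma2_max": s_range[1],
                    }
                )
                rows.append(row)
    return pd.DataFrame(rows)


def benchmark_table(models: dict, data: LabeledDataset) -> pd.DataFrame:
    """One summary row per method on a fixed labelled test set."""
    return pd.DataFrame(_evaluate_on(models, data))
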