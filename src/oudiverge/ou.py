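"""Bivariate Ornstein-Uhlenbeck model of ortholog expression in two species.

Expression of a single-copy ortholog pair in one condition is modelled as an
OU process along the two-species phylogeny: expression is pulled toward an
optimum (theta1 in Species 1, theta2 in Species 2) with selection strength
alpha, and fluctuates by phenotypic drift with variance rate sigma2.
Species 1 is assumed to retain the ancestral optimum; the model asks whether
Species 2 shifted toward a different optimum.  Divergence time is absorbed
into alpha and sigma2 (unit branch length).

Under this model the pair (e1, e2) of log-expression values is bivariate
normal with

    E[e1] = theta1
    E[e2] = (1 - exp(-alpha)) * theta2 + exp(-alpha) * theta1
    Var[e1] = Var[e2] = sigma2 / (2 * alpha)
    Cov[e1, e2] = (sigma2 / (2 * alpha)) * exp(-2 * alpha)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import multivariate_normal

__all__ = [
    "OUParams",
    "expected_expression",
    "expression_covariance",
    "sample_expression_pair",
    "pair_log_density",
]

#: parameters this close to zero produce a numerically singular covariance
_PARAM_FLOOR = 1e-12


@dataclass(frozen=True)
class OUParams:
    """Per-condition evolutionary parameters of one ortholog pair.

    Parameters
    ----------
    theta1 : float
        Expression optimum of Species 1 (the ancestral optimum),
        log-expression units.
    theta2 : float
        Expression optimum of Species 2 (the potentially derived optimum).
    alpha : float
        Selection strength, per unit divergence time; must be positive.
    sigma2 : float
        Drift variance rate, squared log-expression units per unit time;
        must be positive.
    """

    theta1: float
    theta2: float
    alpha: float
    sigma2: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.theta1) and np.isfinite(self.theta2)):
            raise ValueError("theta1 and theta2 must be finite")
        if not np.isfinite(self.alpha) or self.alpha <= _PARAM_FLOOR:
            raise ValueError(f"alpha must exceed {_PARAM_FLOOR}, got {self.alpha}")
        if not np.isfinite(self.sigma2) or self.sigma2 <= _PARAM_FLOOR:
            raise ValueError(f"sigma2 must exceed {_PARAM_FLOOR}, got {self.sigma2}")


def expected_expression(params: OUParams) -> tuple[float, float]:
    """Stationary/relaxation means of (e1, e2).

    Species 1 keeps the ancestral optimum theta1; Species 2 relaxes from
    theta1 toward theta2 at rate alpha over the unit branch.
    """
    decay = np.exp(-params.alpha)
    mean1 = params.theta1
    mean2 = (1.0 - decay) * params.theta2 + decay * params.theta1
    return float(mean1), float(mean2)


def expression_covariance(params: OUParams) -> np.ndarray:
    """2x2 covariance of (e1, e2): Var = sigma2/(2 alpha), Cov = Var * exp(-2 alpha)."""
    var = params.sigma2 / (2.0 * params.alpha)
    cov = var * np.exp(-2.0 * params.alpha)
    return np.array([[var, cov], [cov, var]])


def sample_expression_pair(
    params: OUParams, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` i.i.d. (e1, e2) pairs; returns an (n, 2) array.

    Sampling goes through a Cholesky-style construction so the same rng
    state always yields the same draws.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mean1, mean2 = expected_expression(params)
    var = params.sigma2 / (2.0 * params.alpha)
    rho = np.exp(-2.0 * params.alpha)
    z = rng.standard_normal((n, 2))
    sd = np.sqrt(var)
    e1 = mean1 + sd * z[:, 0]
    e2 = mean2 + sd * (rho * z[:, 0] + np.sqrt(1.0 - rho * rho) * z[:, 1])
    return np.column_stack([e1, e2])


def pair_log_density(e, params: OUParams) -> float:
    """Log density of the bivariate normal expression model at ``e = (e1, e2)``."""
    mean = np.asarray(expected_expression(params))
    cov = expression_covariance(params)
    # correlation exp(-2 alpha) ~ 1 makes the covariance numerically singular
    if 1.0 - np.exp(-4.0 * params.alpha) < 1e-8:
        raise ValueError("degenerate model: covariance numerically singular")
    return float(multivariate_normal.logpdf(np.asarray(e, dtype=float), mean, cov))
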