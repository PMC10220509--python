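"""Simulation of labelled ortholog expression datasets under the OU model.

Each simulated ortholog pair carries a gene-level class label: "conserved"
(theta1 = theta2 in every condition) or "diverged" (theta1 != theta2 in
every condition).  All four OU parameters are drawn anew, independently,
for every condition of every pair, so a pair with m conditions consumes
4*m random parameters.  Features are interleaved per condition:
(e11, e21, e12, e22, ..., e1m, e2m).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .ou import OUParams, sample_expression_pair

__all__ = [
    "CONSERVED",
    "DIVERGED",
    "PriorSpec",
    "LabeledDataset",
    "draw_condition_params",
    "simulate_ortholog_pair",
    "generate_dataset",
    "regime_prior",
]

CONSERVED = "conserved"
DIVERGED = "diverged"
_LABELS = (CONSERVED, DIVERGED)


@dataclass(frozen=True)
class PriorSpec:
    """Prior over per-condition OU parameters.

    Defaults match the wide simulation regime used for training: optima
    uniform on [0, 5] log-expression units (the range of quantile-normalized
    log-FPKM in the motivating fly dataset), selection strength log10-uniform
    over [0, 3] and drift variance log10-uniform over [-2, 3], with m = 6
    conditions (tissues).

    ``alpha_sampling`` / ``sigma2_sampling`` select between "log10" (uniform
    on the log10 scale over ``*_range`` given as log10 endpoints) and
    "linear" (uniform on the natural scale over ``*_range`` endpoints).
    """

    theta_range: tuple[float, float] = (0.0, 5.0)
    alpha_range: tuple[float, float] = (0.0, 3.0)
    alpha_sampling: str = "log10"
    sigma2_range: tuple[float, float] = (-2.0, 3.0)
    sigma2_sampling: str = "log10"
    m: int = 6

    def __post_init__(self) -> None:
        for lo, hi in (self.theta_range, self.alpha_range, self.sigma2_range):
            if not lo < hi:
                raise ValueError("interval endpoints must be ordered")
        if self.alpha_sampling not in ("log10", "linear"):
            raise ValueError(f"unknown alpha_sampling {self.alpha_sampling!r}")
        if self.sigma2_sampling not in ("log10", "linear"):
            raise ValueError(f"unknown sigma2_sampling {self.sigma2_sampling!r}")
        if self.m < 1:
            raise ValueError("m must be >= 1")

    def linearized(self) -> "PriorSpec":
        """The same endpoint ranges sampled linearly instead of on log10 scale.

        A log10 range [a, b] becomes a linear-uniform range [10**a, 10**b];
        this is the "non-uniform prior" variant used for robustness testing.
        """
        out = self
        if self.alpha_sampling == "log10":
            out = replace(
                out,
                alpha_range=(10.0 ** self.alpha_range[0], 10.0 ** self.alpha_range[1]),
                alpha_sampling="linear",
            )
        if self.sigma2_sampling == "log10":
            out = replace(
                out,
                sigma2_range=(10.0 ** self.sigma2_range[0], 10.0 ** self.sigma2_range[1]),
                sigma2_sampling="linear",
            )
        return out


def _draw_scale(rng, sampling, rng_range, size):
    lo, hi = rng_range
    u = rng.uniform(lo, hi, size=size)
    return 10.0 ** u if sampling == "log10" else u


@dataclass
class LabeledDataset:
    """A labelled set of simulated (or imported) ortholog feature vectors.

    Attributes
    ----------
    features : (N, 2m) array, interleaved (e11, e21, ..., e1m, e2m).
    labels : (N,) array of "conserved"/"diverged" strings.
    params : (N, m, 4) array of the true per-condition (theta1, theta2,
        alpha, sigma2), or None for empirical data.
    prior : the PriorSpec the data were drawn from, or None.
    seed : the seed used, or None.
    """

    features: np.ndarray
    labels: np.ndarray
    params: np.ndarray | None = None
    prior: PriorSpec | None = None
    seed: int | None = None
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels must have equal length")
        if self.params is not None and len(self.params) != len(self.features):
            raise ValueError("params must align with features")
        if not self.gene_ids:
            self.gene_ids = [f"sim_{i}" for i in range(len(self.features))]

    def __len__(self) -> int:
        return len(self.features)

    @property
    def m(self) -> int:
        return self.features.shape[1] // 2

    @property
    def y(self) -> np.ndarray:
        """Integer labels: 0 = conserved, 1 = diverged."""
        return (self.labels == DIVERGED).astype(int)

    def optima(self) -> np.ndarray:
        """True optima as an (N, 2m) array ordered (th1_1, th2_1, ..., th1_m, th2_m)."""
        if self.params is None:
            raise ValueError("dataset carries no true parameters")
        return self.params[:, :, :2].reshape(len(self), -1)

    def class_counts(self) -> dict[str, int]:
        return {lab: int(np.sum(self.labels == lab)) for lab in _LABELS}

    def subset(self, index) -> "LabeledDataset":
        """A view-copy restricted to the given row index."""
        index = np.asarray(index)
        return LabeledDataset(
            features=self.features[index],
            labels=self.labels[index],
            params=None if self.params is None else self.params[index],
            prior=self.prior,
            seed=self.seed,
            gene_ids=[self.gene_ids[i] for i in np.atleast_1d(index)],
        )

    def balanced_head(self, n_per_class: int) -> "LabeledDataset":
        """The first ``n_per_class`` rows of each class, original order."""
        keep = []
        for lab in _LABELS:
            keep.extend(np.flatnonzero(self.labels == lab)[:n_per_class])
        return self.subset(np.sort(np.asarray(keep)))

    # -- serialization -----------------------------------------------------

    def to_tsv(self, path) -> None:
        """Write the dataset (and sidecar provenance JSON) as plain text."""
        path = Path(path)
        m = self.m
        cols = {"gene_id": self.gene_ids, "label": self.labels}
        for k in range(m):
            cols[f"e1_c{k + 1}"] = self.features[:, 2 * k]
            cols[f"e2_c{k + 1}"] = self.features[:, 2 * k + 1]
        if self.params is not None:
            for k in range(m):
                for j, name in enumerate(("theta1", "theta2", "alpha", "sigma2")):
                    cols[f"{name}_c{k + 1}"] = self.params[:, k, j]
        pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
        if self.prior is not None:
            meta = {"prior": self.prior.__dict__, "seed": self.seed}
            path.with_suffix(path.suffix + ".json").write_text(
                json.dumps(meta, default=list, indent=1)
            )

    @classmethod
    def from_tsv(cls, path) -> "LabeledDataset":
        df = pd.read_csv(path, sep="\t")
        m = sum(c.startswith("e1_c") for c in df.columns)
        feat = np.empty((len(df), 2 * m))
        for k in range(m):
            feat[:, 2 * k] = df[f"e1_c{k + 1}"]
            feat[:, 2 * k + 1] = df[f"e2_c{k + 1}"]
        params = None
        if f"theta1_c1" in df.columns:
            params = np.empty((len(df), m, 4))
            for k in range(m):
                for j, name in enumerate(("theta1", "theta2", "alpha", "sigma2")):
                    params[:, k, j] = df[f"{name}_c{k + 1}"]
        return cls(
            features=feat,
            labels=df["label"].to_numpy(),
            params=params,
            gene_ids=df["gene_id"].astype(str).tolist(),
        )


def draw_condition_params(
    prior: PriorSpec, label: str, rng: np.random.Generator
) -> OUParams:
    """Draw one condition's OU parameters for the given class label.

    Conserved forces theta2 == theta1 exactly; diverged draws theta2
    independently (equality has probability zero).
    """
    if label not in _LABELS:
        raise ValueError(f"unknown label {label!r}")
    th1 = rng.uniform(*prior.theta_range)
    th2 = th1 if label == CONSERVED else rng.uniform(*prior.theta_range)
    alpha = float(_draw_scale(rng, prior.alpha_sampling, prior.alpha_range, None))
    sigma2 = float(_draw_scale(rng, prior.sigma2_sampling, prior.sigma2_range, None))
    return OUParams(theta1=th1, theta2=th2, alpha=alpha, sigma2=sigma2)


def simulate_ortholog_pair(
    prior: PriorSpec, label: str, rng: np.random.Generator
) -> tuple[np.ndarray, list[OUParams]]:
    """Simulate one ortholog pair: a length-2m feature vector plus true params."""
    params = [draw_condition_params(prior, label, rng) for _ in range(prior.m)]
    x = np.empty(2 * prior.m)
    for k, p in enumerate(params):
        e = sample_expression_pair(p, 1, rng)[0]
        x[2 * k] = e[0]
        x[2 * k + 1] = e[1]
    return x, params


def _simulate_block(prior: PriorSpec, label: str, n: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized simulation of n pairs of one class; returns (features, params)."""
    m = prior.m
    th1 = rng.uniform(*prior.theta_range, size=(n, m))
    if label == CONSERVED:
        th2 = th1.copy()
    else:
        th2 = rng.uniform(*prior.theta_range, size=(n, m))
    alpha = _draw_scale(rng, prior.alpha_sampling, prior.alpha_range, (n, m))
    sigma2 = _draw_scale(rng, prior.sigma2_sampling, prior.sigma2_range, (n, m))

    decay = np.exp(-alpha)
    mean1 = th1
    mean2 = (1.0 - decay) * th2 + decay * th1
    var = sigma2 / (2.0 * alpha)
    rho = np.exp(-2.0 * alpha)
    sd = np.sqrt(var)
    z = rng.standard_normal((n, m, 2))
    e1 = mean1 + sd * z[:, :, 0]
    e2 = mean2 + sd * (rho * z[:, :, 0] + np.sqrt(1.0 - rho**2) * z[:, :, 1])

    feat = np.empty((n, 2 * m))
    feat[:, 0::2] = e1
    feat[:, 1::2] = e2
    params = np.stack([th1, th2, alpha, sigma2], axis=-1)
    return feat, params


def generate_dataset(
    prior: PriorSpec,
    n_conserved: int,
    n_diverged: int,
    rng: np.random.Generator | int,
) -> LabeledDataset:
    """Generate a labelled dataset with the given class counts.

    The two class blocks are simulated and then shuffled (seeded), so
    mini-batch consumers see mixed classes.
    """
    if n_conserved < 0 or n_diverged < 0:
        raise ValueError("class counts must be nonnegative")
    if n_conserved + n_diverged == 0:
        raise ValueError("cannot generate an empty dataset")
    seed = None
    if isinstance(rng, (int, np.integer)):
        seed = int(rng)
        rng = np.random.default_rng(seed)

    feat_c, par_c = _simulate_block(prior, CONSERVED, n_conserved, rng)
    feat_d, par_d = _simulate_block(prior, DIVERGED, n_diverged, rng)
    feat = np.vstack([feat_c, feat_d])
    params = np.vstack([par_c, par_d])
    labels = np.array([CONSERVED] * n_conserved + [DIVERGED] * n_diverged)

    order = rng.permutation(len(labels))
    return LabeledDataset(
        features=feat[order],
        labels=labels[order],
        params=params[order],
        prior=prior,
        seed=seed,
    )


def regime_prior(
    alpha_range: tuple[float, float],
    sigma2_range: tuple[float, float],
    base: PriorSpec | None = None,
) -> PriorSpec:
    """A prior restricted to linear-uniform alpha/sigma2 ranges, theta unchanged.

    Used for the restricted-parameter-regime sweeps (e.g. alpha in [100, 1000]
    crossed with sigma2 in [0.01, 0.1]).
    """
    base = base or PriorSpec()
    if not alpha_range[0] < alpha_range[1]:
        raise ValueError("inverted alpha range")
    if not sigma2_range[0] < sigma2_range[1]:
        raise ValueError("inverted sigma2 range")
    return replace(
        base,
        alpha_range=tuple(map(float, alpha_range)),
        alpha_sampling="linear",
        sigma2_range=tuple(map(float, sigma2_range)),
        sigma2_sampling="linear",
    )
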