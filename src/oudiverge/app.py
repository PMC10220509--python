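"""Empirical application pipeline: ortholog tables, filtering, prediction, tests.

Input tables are TSV files with one row per single-copy ortholog pair:
``gene_id``, then m log-scale (quantile-normalized) expression columns for
Species 1 (``sp1_<cond>``) and m for Species 2 (``sp2_<cond>``), in matching
condition order.  Species 1 must be the species carrying the ancestral state
(e.g. the gene on the ancestral chromosomal arm): the OU mean structure is
asymmetric, so swapping species changes the model's meaning.  The pipeline
assumes the values are already normalized and does not re-normalize.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import binomtest, fisher_exact

from .predictors import predict_labels, predict_optima

__all__ = [
    "OrthologTable",
    "read_ortholog_table",
    "write_ortholog_table",
    "filter_min_expression",
    "apply_model",
    "exact_binomial_two_tailed",
    "fisher_exact_two_tailed",
    "synthetic_ortholog_table",
]

DEFAULT_CONDITIONS = (
    "carcass",
    "female_head",
    "ovary",
    "male_head",
    "testis",
    "accessory_gland",
)


@dataclass
class OrthologTable:
    """Per-gene expression of ortholog pairs across m shared conditions."""

    gene_ids: list[str]
    conditions: list[str]
    sp1: np.ndarray  # (N, m) log-expression, ancestral-state species
    sp2: np.ndarray  # (N, m) log-expression, derived-state species
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.sp1 = np.asarray(self.sp1, dtype=float)
        self.sp2 = np.asarray(self.sp2, dtype=float)
        n, m = self.sp1.shape
        if self.sp2.shape != (n, m):
            raise ValueError("species expression blocks must have identical shape")
        if len(self.gene_ids) != n or len(self.conditions) != m:
            raise ValueError("gene_ids/conditions do not match expression shape")
        if len(set(self.gene_ids)) != n:
            raise ValueError("duplicate gene ids")
        if not (np.isfinite(self.sp1).all() and np.isfinite(self.sp2).all()):
            raise ValueError("expression values must be finite")

    def __len__(self) -> int:
        return len(self.gene_ids)

    @property
    def m(self) -> int:
        return len(self.conditions)

    def features(self) -> np.ndarray:
        """Interleaved (e1_c1, e2_c1, ..., e1_cm, e2_cm) feature matrix."""
        feat = np.empty((len(self), 2 * self.m))
        feat[:, 0::2] = self.sp1
        feat[:, 1::2] = self.sp2
        return feat


def read_ortholog_table(path) -> OrthologTable:
    """Parse a species-1-first TSV expression table.

    Condition order follows the sp1_* column order; the sp2_* columns must
    name the same conditions (any order is accepted but must be complete).
    """
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ValueError("missing gene_id column")
    sp1_cols = [c for c in df.columns if c.startswith("sp1_")]
    sp2_cols = [c for c in df.columns if c.startswith("sp2_")]
    conds = [c[4:] for c in sp1_cols]
    if sorted(conds) != sorted(c[4:] for c in sp2_cols):
        raise ValueError("species 1 and species 2 condition columns disagree")
    if not conds:
        raise ValueError("no expression columns found")
    sp2_ordered = [f"sp2_{c}" for c in conds]
    for col in sp1_cols + sp2_ordered:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"non-numeric values in column {col}")
    other = [c for c in df.columns if c not in {"gene_id", *sp1_cols, *sp2_cols}]
    return OrthologTable(
        gene_ids=df["gene_id"].astype(str).tolist(),
        conditions=conds,
        sp1=df[sp1_cols].to_numpy(),
        sp2=df[sp2_ordered].to_numpy(),
        metadata=df[other].copy() if other else None,
    )


def write_ortholog_table(table: OrthologTable, path) -> None:
    cols = {"gene_id": table.gene_ids}
    for j, c in enumerate(table.conditions):
        cols[f"sp1_{c}"] = table.sp1[:, j]
    for j, c in enumerate(table.conditions):
        cols[f"sp2_{c}"] = table.sp2[:, j]
    df = pd.DataFrame(cols)
    if table.metadata is not None:
        df = pd.concat([df, table.metadata.reset_index(drop=True)], axis=1)
    df.to_csv(path, sep="\t", index=False)


def filter_min_expression(table: OrthologTable, floor: float = 1.0) -> OrthologTable:
    """Drop genes whose expression is below ``floor`` in every condition of
    either species (the "quantile-normalized FPKM < 1 in all tissues" rule).
    Gene order is otherwise preserved; applying the filter twice is a no-op.
    """
    dead = (table.sp1 < floor).all(axis=1) | (table.sp2 < floor).all(axis=1)
    keep = ~dead
    return OrthologTable(
        gene_ids=[g for g, k in zip(table.gene_ids, keep) if k],
        conditions=list(table.conditions),
        sp1=table.sp1[keep],
        sp2=table.sp2[keep],
        metadata=None if table.metadata is None else table.metadata.loc[keep].reset_index(drop=True),
    )


def apply_model(classifier, regressor, table: OrthologTable, out_path=None) -> pd.DataFrame:
    """Predict class, score, and 2m optima for every gene in a table.

    Returns a frame with gene_id, label, score, then theta1_c*/theta2_c*
    estimate columns; optionally also written as TSV.
    """
    X = table.features()
    expected = getattr(classifier, "n_features_in_", X.shape[1])
    if X.shape[1] != expected:
        raise ValueError(
            f"table has {table.m} conditions but the model expects {expected // 2}"
        )
    labels, scores = predict_labels(classifier, X)
    out = {"gene_id": table.gene_ids, "label": labels, "score": scores}
    if regressor is not None:
        optima = predict_optima(regressor, X)
        for k in range(table.m):
            out[f"theta1_c{k + 1}"] = optima[:, 2 * k]
            out[f"theta2_c{k + 1}"] = optima[:, 2 * k + 1]
    df = pd.DataFrame(out)
    if out_path is not None:
        df.to_csv(Path(out_path), sep="\t", index=False, float_format="%.6g")
    return df


def exact_binomial_two_tailed(x: int, n: int, p: float) -> float:
    """Two-tailed exact binomial P-value (minimum-likelihood tail convention:
    sum of all outcome probabilities no larger than that of the observed x).
    """
    if not 0 <= x <= n:
        raise ValueError("need 0 <= x <= n")
    if not 0.0 < p < 1.0:
        raise ValueError("need 0 < p < 1")
    return float(binomtest(x, n, p, alternative="two-sided").pvalue)


def fisher_exact_two_tailed(counts) -> float:
    """Two-tailed Fisher exact P-value of a 2x2 nonnegative integer table."""
    counts = np.asarray(counts)
    if counts.shape != (2, 2) or (counts < 0).any():
        raise ValueError("counts must be a nonnegative 2x2 table")
    if counts.sum() == 0:
        raise ValueError("all-zero table")
    return float(fisher_exact(counts, alternative="two-sided")[1])


def synthetic_ortholog_table(
    n_conserved: int,
    n_diverged: int,
    rng,
    m: int = 6,
    conditions=DEFAULT_CONDITIONS,
    alpha_range=(100.0, 1000.0),
    sigma2_range=(0.01, 0.1),
    theta_range=(0.0, 5.0),
) -> tuple[OrthologTable, np.ndarray]:
    """A synthetic stand-in for a two-species tissue expression table.

    Emulates a 6-tissue log-FPKM table on the [0, 5] scale by simulating
    ortholog pairs from the OU model in a strong-signal regime (defaults:
    strong selection, weak drift).  Returns the table and the true labels.
    """
    from .simulate import generate_dataset, regime_prior, PriorSpec

    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    conditions = list(conditions)[:m]
    if len(conditions) < m:
        conditions += [f"cond{i}" for i in range(len(conditions), m)]
    prior = regime_prior(alpha_range, sigma2_range, PriorSpec(theta_range=theta_range, m=m))
    data = generate_dataset(prior, n_conserved, n_diverged, rng)
    table = OrthologTable(
        gene_ids=[f"gene_{i}" for i in range(len(data))],
        conditions=conditions,
        sp1=data.features[:, 0::2],
        sp2=data.features[:, 1::2],
    )
    return table, data.labels
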