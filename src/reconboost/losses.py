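"""Reconstruction-error functionals and their per-gene gradients.

Two loss families, one per baseline family.  For encoder/decoder baselines
the loss is a gene-weighted mean squared error whose gradient with respect to
the weights is the vector of per-gene MSEs, so the loss equals the inner
product ``<m, p>``.  For location-distribution baselines the loss penalises,
per gene, the expression variance within each reconstructed location plus
(optionally) the roughness of the location-mean profile along the 1-D grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .simplex_core import GeneWeights

__all__ = [
    "ExpressionMatrix",
    "LocationDistribution",
    "weighted_mse",
    "per_gene_mse",
    "spatial_variance_loss",
]


@dataclass
class ExpressionMatrix:
    """A genes x cells real expression matrix with identifiers.

    ``values[i, j]`` is the expression of gene ``i`` in cell ``j``.  When
    ``standardized`` is set, each non-constant gene row has mean 0 and
    variance 1 (population convention).
    """

    values: np.ndarray
    gene_ids: List[str] = field(default_factory=list)
    cell_ids: List[str] = field(default_factory=list)
    standardized: bool = False

    def __post_init__(self) -> None:
        X = np.asarray(self.values, dtype=float)
        if X.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if not np.all(np.isfinite(X)):
            raise ValueError("expression values must be finite (no NaN/Inf)")
        self.values = X
        if not self.gene_ids:
            self.gene_ids = [f"g{i}" for i in range(X.shape[0])]
        if not self.cell_ids:
            self.cell_ids = [f"c{j}" for j in range(X.shape[1])]
        if len(self.gene_ids) != X.shape[0]:
            raise ValueError("gene_ids length must equal the number of rows")
        if len(self.cell_ids) != X.shape[1]:
            raise ValueError("cell_ids length must equal the number of columns")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        if self.standardized:
            mu = X.mean(axis=1)
            var = X.var(axis=1)
            if np.any(np.abs(mu) > 1e-6):
                raise ValueError("standardized flag set but gene means != 0")
            nonconst = var > 1e-12
            if np.any(np.abs(var[nonconst] - 1.0) > 1e-3):
                raise ValueError("standardized flag set but gene variances != 1")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def reweighted(self, p: GeneWeights) -> np.ndarray:
        """The matrix ``diag(p) X`` consumed by the baseline algorithm."""
        if p.n != self.n_genes:
            raise ValueError("weight length must match gene count")
        return p.weights[:, None] * self.values


@dataclass
class LocationDistribution:
    """Per-location cell distributions ``mu_1..mu_h`` on a 1-D grid.

    ``mu[j, c]`` is the probability that location ``j`` assigns to cell ``c``;
    each row is a distribution over cells.
    """

    mu: np.ndarray

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        if mu.ndim != 2 or mu.shape[0] < 2:
            raise ValueError("mu must be an h x N matrix with h >= 2")
        if np.any(mu < 0) or not np.all(np.isfinite(mu)):
            raise ValueError("mu entries must be finite and non-negative")
        if np.any(np.abs(mu.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("each row of mu must sum to 1")
        self.mu = mu

    @property
    def h(self) -> int:
        return self.mu.shape[0]

    @property
    def n_cells(self) -> int:
        return self.mu.shape[1]


def _check_shapes(X: np.ndarray, Y: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise ValueError(f"shape mismatch: X {X.shape} vs Y {Y.shape}")
    return X, Y


def per_gene_mse(X: np.ndarray | ExpressionMatrix, Y: np.ndarray) -> np.ndarray:
    """Per-gene reconstruction error ``m[g] = (1/N) sum_j (X[g,j]-Y[g,j])^2``."""
    if isinstance(X, ExpressionMatrix):
        X = X.values
    X, Y = _check_shapes(X, Y)
    return np.mean((X - Y) ** 2, axis=1)


def weighted_mse(
    p: GeneWeights, X: np.ndarray | ExpressionMatrix, Y: np.ndarray
) -> float:
    """Gene-weighted MSE ``l(p, X, Y) = (1/N) sum_g p[g] sum_j (X-Y)^2``.

    Identically equal to ``<per_gene_mse(X, Y), p>``.
    """
    m = per_gene_mse(X, Y)
    if p.n != m.size:
        raise ValueError("weight length must match gene count")
    return float(np.dot(m, p.weights))


def _weighted_var(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Probability-weighted variance of each gene row under cell weights w."""
    mean = X @ w
    return ((X - mean[:, None]) ** 2) @ w


def spatial_variance_loss(
    p: GeneWeights,
    X: np.ndarray | ExpressionMatrix,
    mu: LocationDistribution,
    lambda_smooth: float = 0.0,
    variance_agg: str = "mean",
) -> Tuple[float, np.ndarray]:
    """Variance-based loss for location-distribution baselines.

    The per-gene term combines two penalties:

    * within-location variance — cells a location assigns mass to should
      express the gene similarly: ``agg_j Var_{mu_j}(X[g])`` with ``agg``
      either the mean (default, scale-independent of ``h``) or the printed
      sum over locations;
    * profile roughness — the empirical variance (over ``j = 2..h``) of the
      increments of the location-mean profile ``E_{mu_j}[X[g]]``, enforcing
      smooth change along the grid.

    ``lambda_smooth`` interpolates: ``(1 - lambda) * within + lambda *
    increment``.  Returns ``(loss, m)`` with ``loss = <m, p>``.
    """
    if isinstance(X, ExpressionMatrix):
        X = X.values
    X = np.asarray(X, dtype=float)
    if not (0.0 <= lambda_smooth <= 1.0):
        raise ValueError("lambda_smooth must lie in [0, 1]")
    if variance_agg not in ("mean", "sum"):
        raise ValueError("variance_agg must be 'mean' or 'sum'")
    if X.shape[1] != mu.n_cells:
        raise ValueError("cell count mismatch between X and mu")
    if p.n != X.shape[0]:
        raise ValueError("weight length must match gene count")
    h = mu.h
    if h < 2 and lambda_smooth > 0:
        raise ValueError("increment variance needs h >= 2 locations")

    within = np.zeros(X.shape[0])
    for j in range(h):
        within += _weighted_var(X, mu.mu[j])
    if variance_agg == "mean":
        within /= h

    profiles = X @ mu.mu.T  # genes x h location means
    if lambda_smooth > 0:
        incr = np.diff(profiles, axis=1)  # genes x (h-1)
        incr_var = incr.var(axis=1)  # population convention over h-1 diffs
    else:
        incr_var = np.zeros(X.shape[0])

    m = (1.0 - lambda_smooth) * within + lambda_smooth * incr_var
    return float(np.dot(m, p.weights)), m
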