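"""Synthetic single-cell data with known manifold-informative gene sets.

Each cell carries a latent location on one or two low-dimensional manifolds
(uniform on [0,1]^d or standard Gaussian in d dimensions, d in {1, 2}).  A
gene informative for a manifold is a random polynomial of total degree <= 3
of the cell's location on that manifold — i.i.d. standard-normal
coefficients over an orthonormal polynomial basis, so each degree carries
comparable variance — z-scored across cells.  Mixture benchmarks stack
two single-manifold blocks gene-wise — every cell then expresses genes tied
to two independent latent structures — and shuffle the gene order by a
recorded permutation.  Gaussian noise at scale ``beta`` replaces a
``beta`` fraction of each gene's variance with fresh standard-normal noise
while preserving zero mean and unit variance.

Everything is deterministic under a seed, and all sizes are free parameters
so the same generative recipes run at full scale or desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations_with_replacement
from typing import Dict, List, Optional

import numpy as np

from .losses import ExpressionMatrix

__all__ = [
    "ManifoldSpec",
    "SyntheticDataset",
    "sample_cell_locations",
    "generate_single_manifold_dataset",
    "mix_datasets",
    "add_noise",
    "make_benchmark",
    "BENCHMARK_RECIPES",
]

_RESAMPLE_CAP = 10  # retries for a degenerate (constant-expression) gene
_VAR_EPS = 1e-12


@dataclass(frozen=True)
class ManifoldSpec:
    """A latent cell-location distribution: family x dimension.

    ``uniform`` draws coordinates i.i.d. Unif([0,1]); ``gaussian`` draws
    standard normals.  ``dimension`` is 1 or 2.
    """

    family: str
    dimension: int

    def __post_init__(self) -> None:
        if self.family not in ("uniform", "gaussian"):
            raise ValueError("family must be 'uniform' or 'gaussian'")
        if self.dimension not in (1, 2):
            raise ValueError("dimension must be 1 or 2")

    def __str__(self) -> str:
        if self.family == "uniform":
            return "Unif([0,1])" + ("^2" if self.dimension == 2 else "")
        return "N(0,1)" if self.dimension == 1 else "N(0,I2)"


def _orthonormal_basis_1d(family: str, c: np.ndarray, degree: int) -> np.ndarray:
    """Orthonormal polynomial values of orders ``0..degree`` at points ``c``.

    Probabilists' Hermite polynomials (normalised by ``sqrt(e!)``) for the
    gaussian family, shifted Legendre polynomials (orthonormal on [0,1]) for
    the uniform family.  Shape: ``(degree+1, len(c))``.
    """
    out = np.empty((degree + 1, c.size))
    out[0] = 1.0
    if family == "gaussian":
        # He_{e+1}(c) = c He_e(c) - e He_{e-1}(c); norm sqrt(e!)
        he_prev, he = np.ones_like(c), c.copy()
        fact = 1.0
        for e in range(1, degree + 1):
            fact *= e
            out[e] = he / np.sqrt(fact)
            he_prev, he = he, c * he - e * he_prev
    else:
        # Legendre on [-1,1] at t = 2c-1, normalised by sqrt(2e+1)
        t = 2.0 * c - 1.0
        p_prev, p = np.ones_like(t), t.copy()
        for e in range(1, degree + 1):
            out[e] = p * np.sqrt(2 * e + 1)
            p_prev, p = p, ((2 * e + 1) * t * p - e * p_prev) / (e + 1)
    return out


@dataclass
class GenePolynomialProgram:
    """One block's gene programs: random polynomials of the latent location.

    Each gene is ``sum_m a_m B_m(c)`` over all product-basis polynomials of
    total degree <= the block degree, with i.i.d. standard-normal
    coefficients ``a_m``.  The basis is orthonormal under the manifold's
    sampling distribution, so every degree contributes comparably to a
    gene's variance and the block's nominal degree reflects genuine
    function complexity.
    """

    coefficients: np.ndarray
    exponents: np.ndarray  # basis terms x dimension: per-coordinate orders
    family: str = "gaussian"
    manifold_index: int = 0

    def evaluate(self, locations: np.ndarray) -> np.ndarray:
        """Raw (pre-z-score) expression: genes x cells."""
        degree = int(self.exponents.max()) if self.exponents.size else 0
        dim = locations.shape[1]
        basis_1d = [
            _orthonormal_basis_1d(self.family, locations[:, d], degree)
            for d in range(dim)
        ]
        # term values: cells x terms, product over coordinates
        design = np.ones((locations.shape[0], self.exponents.shape[0]))
        for d in range(dim):
            design *= basis_1d[d][self.exponents[:, d], :].T
        return self.coefficients @ design.T


@dataclass
class SyntheticDataset:
    """Expression plus the latent ground truth it was generated from.

    ``block_labels[g]`` indexes the manifold gene ``g`` depends on;
    ``recoverable_mask`` marks the block the baseline is expected to capture
    (set by :func:`make_benchmark`).  ``locations`` maps block index to the
    cells x dimension latent coordinate table.  ``gene_order_permutation``
    is the shuffle applied when stacking blocks (identity if unmixed).
    """

    X: ExpressionMatrix
    locations: Dict[int, np.ndarray]
    manifolds: Dict[int, ManifoldSpec]
    block_labels: np.ndarray
    beta: float = 0.0
    gene_order_permutation: Optional[np.ndarray] = None
    recoverable_mask: Optional[np.ndarray] = None
    programs: Dict[int, GenePolynomialProgram] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.block_labels = np.asarray(self.block_labels, dtype=int)
        if self.block_labels.size != self.X.n_genes:
            raise ValueError("block_labels length must equal gene count")
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError("beta must lie in [0, 1]")

    def block_mask(self, block: int) -> np.ndarray:
        return self.block_labels == block


def _monomial_exponents(dimension: int, degree: int) -> np.ndarray:
    """Exponent table for all monomials of total degree <= ``degree``."""
    rows = []
    for d in range(degree + 1):
        for combo in combinations_with_replacement(range(dimension), d):
            e = np.zeros(dimension, dtype=int)
            for v in combo:
                e[v] += 1
            rows.append(e)
    return np.array(rows, dtype=int)


def _zscore_rows(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    return (X - mu) / sd


def sample_cell_locations(
    spec: ManifoldSpec, N: int, seed: int
) -> np.ndarray:
    """Draw ``N`` i.i.d. cell locations from the manifold distribution."""
    if N < 1:
        raise ValueError("cell count must be >= 1")
    rng = np.random.default_rng(seed)
    if spec.family == "uniform":
        return rng.uniform(0.0, 1.0, size=(N, spec.dimension))
    return rng.standard_normal(size=(N, spec.dimension))


def generate_single_manifold_dataset(
    spec: ManifoldSpec,
    n_genes: int,
    degree: int,
    N: int,
    seed: int,
) -> SyntheticDataset:
    """One block: ``n_genes`` random degree-<=``degree`` polynomial programs.

    Coefficients are drawn i.i.d. N(0,1) over the orthonormal polynomial
    product basis up to the total degree (cross terms included in 2-D);
    each gene row is then z-scored across cells.  A gene whose raw expression is numerically constant is
    resampled (at most 10 times, then generation fails).
    """
    if degree not in (1, 2, 3):
        raise ValueError("degree must be in {1, 2, 3}")
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if N < 2:
        raise ValueError("need at least 2 cells to standardize")
    rng = np.random.default_rng(seed)
    locations = sample_cell_locations(spec, N, seed=int(rng.integers(2**31)))
    exponents = _monomial_exponents(spec.dimension, degree)
    coeffs = rng.standard_normal(size=(n_genes, exponents.shape[0]))
    program = GenePolynomialProgram(coeffs, exponents, family=spec.family)
    raw = program.evaluate(locations)
    for g in np.flatnonzero(raw.var(axis=1) < _VAR_EPS):
        for attempt in range(_RESAMPLE_CAP + 1):
            if attempt == _RESAMPLE_CAP:
                raise RuntimeError(
                    f"gene {g}: constant expression after {_RESAMPLE_CAP} resamples"
                )
            coeffs[g] = rng.standard_normal(exponents.shape[0])
            raw[g] = program.evaluate(locations)[g]
            if raw[g].var() >= _VAR_EPS:
                break
    X = ExpressionMatrix(_zscore_rows(raw), standardized=True)
    return SyntheticDataset(
        X=X,
        locations={0: locations},
        manifolds={0: spec},
        block_labels=np.zeros(n_genes, dtype=int),
        programs={0: program},
    )


def mix_datasets(
    d1: SyntheticDataset, d2: SyntheticDataset, seed: int
) -> SyntheticDataset:
    """Stack two single-manifold blocks gene-wise and shuffle gene order.

    The cells of the mixture carry both latent locations (one per block);
    block labels ride along through the recorded permutation, so the ground
    truth partition is always recoverable.
    """
    if d1.X.n_cells != d2.X.n_cells:
        raise ValueError("datasets must have the same number of cells")
    rng = np.random.default_rng(seed)
    stacked = np.vstack([d1.X.values, d2.X.values])
    labels = np.concatenate([d1.block_labels, d2.block_labels + 1])
    perm = rng.permutation(stacked.shape[0])
    X = ExpressionMatrix(stacked[perm], standardized=True)
    return SyntheticDataset(
        X=X,
        locations={0: d1.locations[0], 1: d2.locations[0]},
        manifolds={0: d1.manifolds[0], 1: d2.manifolds[0]},
        block_labels=labels[perm],
        gene_order_permutation=perm,
        programs={0: d1.programs.get(0), 1: d2.programs.get(0)},
    )


def add_noise(d: SyntheticDataset, beta: float, seed: int) -> SyntheticDataset:
    """Corrupt expression at noise scale ``beta`` in [0, 1].

    ``X_beta = sqrt(1-beta) X + sqrt(beta) Nbar`` with ``Nbar`` i.i.d.
    standard normal, row-standardised.  Square-root mixing weights keep the
    population variance of each gene at 1; the mixture rows are re-z-scored
    so the unit-variance invariant holds exactly at any finite cell count.
    ``beta = 0`` returns the data unchanged; ``beta = 1`` is pure noise.
    """
    if not (0.0 <= beta <= 1.0):
        raise ValueError("beta must lie in [0, 1]")
    if not d.X.standardized:
        raise ValueError("add_noise expects standardized expression")
    if beta == 0.0:
        return replace(d, beta=0.0)
    rng = np.random.default_rng(seed)
    noise = _zscore_rows(rng.standard_normal(size=d.X.values.shape))
    if beta == 1.0:
        mixed = noise
    else:
        mixed = _zscore_rows(
            np.sqrt(1.0 - beta) * d.X.values + np.sqrt(beta) * noise
        )
    X = ExpressionMatrix(
        mixed, gene_ids=list(d.X.gene_ids), cell_ids=list(d.X.cell_ids),
        standardized=True,
    )
    return replace(d, X=X, beta=beta)


#: benchmark recipes: (manifold, degree) per block; which block the baseline
#: is expected to capture (lower-dimensional manifold for D1/D3, lower
#: polynomial degree for D2/D4); and the autoencoder code dimension (the
#: minimum cell-manifold dimension of the mixture)
BENCHMARK_RECIPES: Dict[str, dict] = {
    "D1": {
        "blocks": [(ManifoldSpec("uniform", 2), 3), (ManifoldSpec("gaussian", 2), 3)],
        "recoverable_block": 0,
        "code_dim": 2,
        "description": "different cell-location distributions: "
        "Unif([0,1])^2 vs N(0,I2), degree-3 programs",
    },
    "D2": {
        "blocks": [(ManifoldSpec("gaussian", 1), 2), (ManifoldSpec("gaussian", 1), 3)],
        "recoverable_block": 0,
        "code_dim": 1,
        "description": "different program degrees on N(0,1): degree 2 vs 3",
    },
    "D3": {
        "blocks": [(ManifoldSpec("uniform", 2), 3), (ManifoldSpec("uniform", 1), 3)],
        "recoverable_block": 1,
        "code_dim": 1,
        "description": "different manifold dimensions: Unif([0,1])^2 vs "
        "Unif([0,1]), degree-3 programs",
    },
    "D4": {
        "blocks": [(ManifoldSpec("gaussian", 1), 2), (ManifoldSpec("gaussian", 2), 1)],
        "recoverable_block": 1,
        "code_dim": 1,
        "description": "different dimension and degree: N(0,1) degree 2 vs "
        "N(0,I2) degree 1",
    },
}


def make_benchmark(
    recipe: str,
    n_genes_per_block: int = 50,
    N: int = 20000,
    beta: float = 0.0,
    seed: int = 0,
) -> SyntheticDataset:
    """Build a two-manifold mixture benchmark (recipes D1-D4).

    Composes block generation, gene-wise stacking/shuffling and noise
    corruption, and records which block is the "recoverable" informative set
    the reconstruction baseline is expected to concentrate on.
    """
    if recipe not in BENCHMARK_RECIPES:
        raise ValueError(f"unknown recipe {recipe!r}; choose from D1-D4")
    cfg = BENCHMARK_RECIPES[recipe]
    ss = np.random.SeedSequence(seed)
    s_block1, s_block2, s_mix, s_noise = (
        int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(4)
    )
    (spec1, deg1), (spec2, deg2) = cfg["blocks"]
    b1 = generate_single_manifold_dataset(spec1, n_genes_per_block, deg1, N, s_block1)
    b2 = generate_single_manifold_dataset(spec2, n_genes_per_block, deg2, N, s_block2)
    mixed = mix_datasets(b1, b2, s_mix)
    noisy = add_noise(mixed, beta, s_noise)
    noisy.recoverable_mask = noisy.block_labels == cfg["recoverable_block"]
    return noisy
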