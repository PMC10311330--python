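"""Baseline reconstruction algorithms consumed by the boosting loop.

A *baseline* takes the gene-reweighted expression matrix ``diag(p) X`` and
returns either an encoder/decoder pair with its reconstruction (the
autoencoder family) or a distribution of cells over a 1-D grid of spatial
locations (the optimal-transport family).  The boosting driver treats the
baseline as a black box; anything matching :class:`BaselineFit` plugs in,
including external tools via :func:`adapter_external`.

Built-ins:

* :func:`fit_autoencoder` — a shallow tanh autoencoder (mirror architecture
  ``n -> width -> k -> width -> n``, linear output) trained with minibatch
  Adam; written directly in numpy.
* :func:`fit_ot_spatial` — a deliberately simplified spatial embedder that
  assigns cells to a 1-D grid by entropically regularised Gromov–Wasserstein
  matching between k-NN graph distances in expression space and grid
  distances.  It mirrors the structural-correspondence idea of
  optimal-transport tissue reconstruction at desk scale; it is not a
  reimplementation of any published tool.
"""

from __future__ import annotations

import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, List, Optional, Tuple

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path
from sklearn.neighbors import kneighbors_graph

from .losses import ExpressionMatrix, LocationDistribution

__all__ = [
    "FitError",
    "AdapterError",
    "BaselineFit",
    "AutoencoderSpec",
    "OTSpatialSpec",
    "fit_autoencoder",
    "fit_ot_spatial",
    "adapter_external",
    "location_mean_profiles",
]


class FitError(RuntimeError):
    """A baseline fit diverged or received degenerate input."""


class AdapterError(RuntimeError):
    """An external baseline produced output violating the contract."""


@dataclass
class BaselineFit:
    """Result of fitting a baseline reconstruction algorithm.

    Exactly one of the two families is populated: ``encoder``/``decoder``
    (with ``kind = "encoder_decoder"``) or ``mu`` (``kind =
    "location_distribution"``).  ``reconstruction`` always has the shape of
    the input matrix.
    """

    kind: str
    reconstruction: np.ndarray
    encoder: Optional[Callable[[np.ndarray], np.ndarray]] = None
    decoder: Optional[Callable[[np.ndarray], np.ndarray]] = None
    mu: Optional[LocationDistribution] = None
    code_dim: int = 1
    loss_history: List[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("encoder_decoder", "location_distribution"):
            raise ValueError(f"unknown baseline kind {self.kind!r}")
        self.reconstruction = np.asarray(self.reconstruction, dtype=float)
        has_ed = self.encoder is not None and self.decoder is not None
        has_mu = self.mu is not None
        if self.kind == "encoder_decoder" and (not has_ed or has_mu):
            raise ValueError("encoder_decoder fit must populate encoder/decoder only")
        if self.kind == "location_distribution" and (not has_mu or has_ed):
            raise ValueError("location_distribution fit must populate mu only")
        if self.code_dim < 1:
            raise ValueError("code_dim must be >= 1")


@dataclass
class AutoencoderSpec:
    """Architecture and training schedule of the shallow tanh autoencoder.

    Encoder ``n -> max_width -> code_dim``, decoder mirrored, tanh on every
    hidden layer (including the code), linear output.  ``code_dim`` should be
    the minimum dimension among the cell manifolds expected in the data.
    Trained with minibatch Adam on plain MSE; gene weighting enters through
    the input scaling ``diag(p) X``, not the objective.  The input's global
    scale is normalised away internally (training is scale-equivariant), so
    the learning rate keeps its meaning whatever the weight vector's overall
    magnitude; defaults are set so the network reaches a well-converged fit
    within the epoch budget on data of a few thousand cells.
    """

    code_dim: int = 1
    max_width: int = 64
    epochs: int = 70
    learning_rate: float = 3e-3
    batch_size: int = 32
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.code_dim < 1:
            raise ValueError("code_dim must be >= 1")
        if not (64 <= self.max_width <= 128):
            raise ValueError("max_width must lie in [64, 128]")
        if not (70 <= self.epochs <= 100):
            raise ValueError("epochs must lie in [70, 100]")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class OTSpatialSpec:
    """Parameters of the simplified optimal-transport spatial embedder.

    ``n_locations`` grid positions with unit spacing; ``entropic_reg`` is the
    Sinkhorn regularisation on the (max-normalised) cost tensors;
    ``n_neighbors`` sets the expression k-NN graph whose shortest-path
    distances define cell–cell structure.  ``structure_weight`` is reserved
    for interpolation with a reference atlas term, which this embedder does
    not implement; it must be 1.0.
    """

    n_locations: int = 10
    entropic_reg: float = 5e-2
    structure_weight: float = 1.0
    n_neighbors: int = 5
    max_iter: int = 50
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_locations < 2:
            raise ValueError("n_locations must be >= 2")
        if self.entropic_reg <= 0:
            raise ValueError("entropic_reg must be positive")
        if self.structure_weight != 1.0:
            raise ValueError(
                "structure_weight < 1 requires a reference atlas, "
                "which this embedder does not support"
            )
        if self.n_neighbors < 1 or self.max_iter < 1:
            raise ValueError("n_neighbors and max_iter must be >= 1")


# ---------------------------------------------------------------------------
# shallow tanh autoencoder (numpy + Adam)
# ---------------------------------------------------------------------------


def _glorot(rng: np.random.Generator, fan_out: int, fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_out, fan_in))


class _AdamState:
    def __init__(self, params: List[np.ndarray], lr: float) -> None:
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: List[np.ndarray], grads: List[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def fit_autoencoder(
    Xw: np.ndarray | ExpressionMatrix, spec: AutoencoderSpec
) -> BaselineFit:
    """Train the shallow tanh autoencoder on the reweighted matrix.

    Cells are the training samples (columns of ``Xw``).  Returns the fitted
    encoder/decoder as callables on ``n x B`` column blocks, the full
    reconstruction ``Y = decoder(encoder(Xw))``, and the per-epoch training
    loss history.  Fully deterministic under ``spec.seed``.
    """
    if isinstance(Xw, ExpressionMatrix):
        Xw = Xw.values
    Xw = np.asarray(Xw, dtype=float)
    if not np.all(np.isfinite(Xw)):
        raise ValueError("autoencoder input must be finite")
    n, N = Xw.shape
    if spec.code_dim >= n:
        raise ValueError("code_dim must be smaller than the gene count")
    if spec.seed is None:
        raise ValueError("fit_autoencoder requires an explicit seed")
    # scale-equivariant training: normalise the global input scale so the
    # optimiser operates in the unit-variance regime tanh nets are tuned
    # for; relative gene scales (the weighting) are untouched
    scale = float(np.sqrt(np.mean(Xw**2)))
    if scale <= 0:
        raise FitError("autoencoder input is identically zero")
    Xs = Xw / scale
    rng = np.random.default_rng(spec.seed)
    w, k = spec.max_width, spec.code_dim

    W1, b1 = _glorot(rng, w, n), np.zeros((w, 1))
    W2, b2 = _glorot(rng, k, w), np.zeros((k, 1))
    W3, b3 = _glorot(rng, w, k), np.zeros((w, 1))
    W4, b4 = _glorot(rng, n, w), np.zeros((n, 1))
    params = [W1, b1, W2, b2, W3, b3, W4, b4]
    adam = _AdamState(params, spec.learning_rate)

    def forward(A0: np.ndarray):
        A1 = np.tanh(W1 @ A0 + b1)
        A2 = np.tanh(W2 @ A1 + b2)
        A3 = np.tanh(W3 @ A2 + b3)
        Y = W4 @ A3 + b4
        return A1, A2, A3, Y

    loss_history: List[float] = []
    for _ in range(spec.epochs):
        order = rng.permutation(N)
        epoch_sse = 0.0
        for start in range(0, N, spec.batch_size):
            idx = order[start : start + spec.batch_size]
            A0 = Xs[:, idx]
            A1, A2, A3, Y = forward(A0)
            R = Y - A0
            epoch_sse += float(np.sum(R * R))
            dY = (2.0 / R.size) * R
            gW4 = dY @ A3.T
            gb4 = dY.sum(axis=1, keepdims=True)
            dA3 = (W4.T @ dY) * (1.0 - A3 * A3)
            gW3 = dA3 @ A2.T
            gb3 = dA3.sum(axis=1, keepdims=True)
            dA2 = (W3.T @ dA3) * (1.0 - A2 * A2)
            gW2 = dA2 @ A1.T
            gb2 = dA2.sum(axis=1, keepdims=True)
            dA1 = (W2.T @ dA2) * (1.0 - A1 * A1)
            gW1 = dA1 @ A0.T
            gb1 = dA1.sum(axis=1, keepdims=True)
            adam.step(params, [gW1, gb1, gW2, gb2, gW3, gb3, gW4, gb4])
        epoch_loss = epoch_sse * scale**2 / (n * N)  # on the input scale
        if not np.isfinite(epoch_loss):
            raise FitError("autoencoder training diverged (non-finite loss)")
        loss_history.append(epoch_loss)

    def encoder(x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[0] != n:
            x = x.T
        x = x / scale
        return np.tanh(W2 @ np.tanh(W1 @ x + b1) + b2)

    def decoder(z: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(np.asarray(z, dtype=float))
        if z.shape[0] != k:
            z = z.T
        return (W4 @ np.tanh(W3 @ z + b3) + b4) * scale

    return BaselineFit(
        kind="encoder_decoder",
        reconstruction=decoder(encoder(Xw)),
        encoder=encoder,
        decoder=decoder,
        code_dim=k,
        loss_history=loss_history,
    )


# ---------------------------------------------------------------------------
# simplified entropic Gromov–Wasserstein spatial embedder
# ---------------------------------------------------------------------------


def _knn_geodesics(Xw: np.ndarray, n_neighbors: int) -> np.ndarray:
    """Shortest-path distances on the symmetrised cell k-NN graph."""
    cells = Xw.T  # cells x genes
    k = min(n_neighbors, cells.shape[0] - 1)
    graph = kneighbors_graph(cells, n_neighbors=k, mode="distance")
    graph = graph.maximum(graph.T)
    D = shortest_path(csr_matrix(graph), method="D", directed=False)
    if np.isinf(D).any():
        # disconnected components: bridge with twice the graph diameter
        finite_max = D[np.isfinite(D)].max()
        warnings.warn("k-NN graph disconnected; bridging components")
        D[np.isinf(D)] = 2.0 * finite_max
    return D


def _sinkhorn(
    p: np.ndarray, q: np.ndarray, cost: np.ndarray, reg: float, n_iter: int = 200
) -> np.ndarray:
    K = np.exp(-(cost - cost.min()) / reg)
    u = np.ones_like(p)
    v = np.ones_like(q)
    for _ in range(n_iter):
        u = p / np.maximum(K @ v, 1e-300)
        v = q / np.maximum(K.T @ u, 1e-300)
    return u[:, None] * K * v[None, :]


def fit_ot_spatial(
    Xw: np.ndarray | ExpressionMatrix, spec: OTSpatialSpec
) -> BaselineFit:
    """Embed cells onto a 1-D grid by entropic Gromov–Wasserstein matching.

    Matches the cell k-NN geodesic distance matrix against the grid distance
    matrix ``|i - j|`` (both max-normalised, square loss, uniform marginals)
    by alternating Sinkhorn projections.  The transport plan's rows, each
    renormalised, give the per-location cell distributions ``mu_j``; the
    reconstruction assigns every cell the location-mean expression profile of
    its modal location.  A small seeded jitter on the initial plan breaks the
    left–right symmetry of the grid, so the recovered axis is defined up to a
    global flip.
    """
    if isinstance(Xw, ExpressionMatrix):
        Xw = Xw.values
    Xw = np.asarray(Xw, dtype=float)
    n, N = Xw.shape
    h = spec.n_locations
    if N < h:
        raise ValueError(f"need at least n_locations={h} cells, got {N}")
    if spec.seed is None:
        raise ValueError("fit_ot_spatial requires an explicit seed")

    C_cells = _knn_geodesics(Xw, spec.n_neighbors)
    if C_cells.max() <= 0:
        raise FitError("degenerate cell distance matrix (all zeros)")
    C_cells = C_cells / C_cells.max()
    grid = np.arange(h, dtype=float)
    C_grid = np.abs(grid[:, None] - grid[None, :])
    C_grid /= C_grid.max()

    p = np.full(h, 1.0 / h)
    q = np.full(N, 1.0 / N)
    rng = np.random.default_rng(spec.seed)
    T = np.outer(p, q) * (1.0 + 0.05 * rng.random((h, N)))
    T /= T.sum()
    # square-loss GW cost decomposition: const - 2 * C_grid @ T @ C_cells
    const = np.outer(C_grid**2 @ p, np.ones(N)) + np.outer(
        np.ones(h), C_cells**2 @ q
    )
    for _ in range(spec.max_iter):
        tens = const - 2.0 * C_grid @ T @ C_cells
        T_next = _sinkhorn(p, q, tens, spec.entropic_reg)
        if np.abs(T_next - T).max() < 1e-10:
            T = T_next
            break
        T = T_next

    mu = LocationDistribution(T / T.sum(axis=1, keepdims=True))
    profiles = location_mean_profiles(mu, Xw)
    modal = np.argmax(T, axis=0)  # each cell's most likely location
    Y = profiles[:, modal]
    return BaselineFit(
        kind="location_distribution",
        reconstruction=Y,
        mu=mu,
        code_dim=1,
    )


def location_mean_profiles(
    mu: LocationDistribution, X: np.ndarray | ExpressionMatrix
) -> np.ndarray:
    """Mean expression per location: ``profile[i, j] = E_{mu_j}[X[i]]``."""
    if isinstance(X, ExpressionMatrix):
        X = X.values
    X = np.asarray(X, dtype=float)
    if X.shape[1] != mu.n_cells:
        raise ValueError("cell count mismatch between X and mu")
    return X @ mu.mu.T


# ---------------------------------------------------------------------------
# external-baseline adapter
# ---------------------------------------------------------------------------


def _fit_from_matrix(result: np.ndarray, Xw: np.ndarray) -> BaselineFit:
    result = np.asarray(result, dtype=float)
    if result.ndim != 2:
        raise AdapterError(f"external baseline returned shape {result.shape}")
    if result.shape == Xw.shape:
        return BaselineFit(
            kind="encoder_decoder",
            reconstruction=result,
            encoder=lambda x: x,
            decoder=lambda z: z,
            code_dim=Xw.shape[0],
        )
    if result.shape[1] == Xw.shape[1] and result.shape[0] >= 2:
        rowsums = result.sum(axis=1, keepdims=True)
        if np.any(rowsums <= 0) or np.any(result < 0):
            raise AdapterError("location distribution rows must be non-negative")
        if np.any(np.abs(rowsums - 1.0) > 1e-9):
            warnings.warn("renormalizing unnormalized location-distribution rows")
            result = result / rowsums
        mu = LocationDistribution(result)
        profiles = location_mean_profiles(mu, Xw)
        modal = np.argmax(result, axis=0)
        return BaselineFit(
            kind="location_distribution",
            reconstruction=profiles[:, modal],
            mu=mu,
            code_dim=1,
        )
    raise AdapterError(
        f"external baseline output shape {result.shape} matches neither the "
        f"input shape {Xw.shape} nor an h x N location distribution"
    )


def adapter_external(
    cmd_or_callable, Xw: np.ndarray | ExpressionMatrix
) -> BaselineFit:
    """Wrap an arbitrary reconstruction tool as a baseline.

    ``cmd_or_callable`` is either an in-process callable taking the
    reweighted ``n x N`` matrix, or a shell command template containing
    ``{input}`` and ``{output}`` placeholders for Matrix Market file paths.
    The callable may return an ``(encoder, decoder)`` pair, a reconstruction
    matrix of the input shape, or an ``h x N`` location-distribution matrix
    (rows are renormalised with a warning if needed).
    """
    if isinstance(Xw, ExpressionMatrix):
        Xw = Xw.values
    Xw = np.asarray(Xw, dtype=float)

    if callable(cmd_or_callable):
        try:
            result = cmd_or_callable(Xw)
        except Exception as exc:  # surface with context, keep the cause
            raise AdapterError(f"external baseline raised: {exc}") from exc
        if isinstance(result, tuple) and len(result) == 2:
            encoder, decoder = result
            try:
                code = np.atleast_2d(np.asarray(encoder(Xw), dtype=float))
                Y = np.asarray(decoder(code), dtype=float)
            except Exception as exc:
                raise AdapterError(f"encoder/decoder pair failed: {exc}") from exc
            if Y.shape != Xw.shape:
                raise AdapterError(
                    f"decoder output shape {Y.shape} != input shape {Xw.shape}"
                )
            return BaselineFit(
                kind="encoder_decoder",
                reconstruction=Y,
                encoder=encoder,
                decoder=decoder,
                code_dim=int(code.shape[0]),
            )
        return _fit_from_matrix(result, Xw)

    if isinstance(cmd_or_callable, str):
        from scipy.io import mmread, mmwrite

        with tempfile.TemporaryDirectory() as tmp:
            inp = Path(tmp) / "input.mtx"
            out = Path(tmp) / "output.mtx"
            mmwrite(str(inp), np.asarray(Xw))
            cmd = cmd_or_callable.format(input=inp, output=out)
            proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
            if proc.returncode != 0:
                raise AdapterError(
                    f"external command failed (exit {proc.returncode}): "
                    f"{proc.stderr.strip()}"
                )
            if not out.exists():
                raise AdapterError("external command produced no output file")
            result = mmread(str(out))
            if hasattr(result, "toarray"):
                result = result.toarray()
            return _fit_from_matrix(np.asarray(result), Xw)

    raise AdapterError("baseline must be a callable or a shell command string")
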