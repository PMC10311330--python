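"""Gene-weight distributions and the multiplicative-weights update geometry.

The boosting loop maintains a probability distribution ``p`` over the ``n``
genes of an expression matrix.  Each round multiplies ``p`` entrywise by
``exp(-eta * m)`` (``m`` = per-gene reconstruction error), renormalises, and
projects the result back onto the capped simplex ``{p : p >= 0, sum p = 1,
max p <= c}`` so that no single gene can dominate the input given to the
baseline reconstruction algorithm.  This module implements that geometry:
weight construction, relative entropy, the closed-form multiplicative update,
the KL projection onto the capped simplex, and the final threshold
classification of genes as manifold-informative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SUM_TOL",
    "CAP_TOL",
    "WEIGHT_FLOOR",
    "GeneWeights",
    "ReweightConfig",
    "uniform_weights",
    "indicator_weights",
    "relative_entropy",
    "mwu_step",
    "project_capped",
    "classify_genes",
]

#: tolerance on |sum(p) - 1| for a valid distribution
SUM_TOL = 1e-9
#: tolerance on p[i] - cap for a valid capped distribution
CAP_TOL = 1e-12
#: numerical floor applied before logarithms / ratios; weights are never
#: zeroed so a down-weighted gene can always recover in later rounds
WEIGHT_FLOOR = 1e-300


@dataclass(frozen=True)
class GeneWeights:
    """A probability distribution over genes, optionally capped entrywise.

    Parameters
    ----------
    weights
        Length-``n`` vector of non-negative reals summing to 1.
    cap
        Optional entrywise upper bound ``c`` in ``(0, 1]``.  Feasibility
        requires ``c * n >= 1``.
    """

    weights: np.ndarray
    cap: Optional[float] = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or w.size < 1:
            raise ValueError("weights must be a non-empty 1-D vector")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > SUM_TOL:
            raise ValueError(f"weights must sum to 1 (got {w.sum()!r})")
        if self.cap is not None:
            if not (0.0 < self.cap <= 1.0):
                raise ValueError("cap must lie in (0, 1]")
            if self.cap * w.size < 1.0 - SUM_TOL:
                raise ValueError(
                    f"infeasible cap: cap*n = {self.cap * w.size} < 1"
                )
            if np.any(w > self.cap + CAP_TOL):
                raise ValueError("weights exceed the declared cap")
        w.flags.writeable = False
        object.__setattr__(self, "weights", w)

    @property
    def n(self) -> int:
        return int(self.weights.size)

    def marginal(self, mask: np.ndarray) -> float:
        """Total weight ``p_S`` on the gene subset given by a boolean mask."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != self.weights.shape:
            raise ValueError("mask length must match gene count")
        return float(self.weights[mask].sum())


@dataclass
class ReweightConfig:
    """Hyper-parameters of the iterative reweighting loop.

    Attributes
    ----------
    eta
        Multiplicative-update step size; gradients are max-normalised before
        the update so ``eta`` is scale-free (default 1.0).
    epsilon, s_size
        Together define the weight cap ``1 / (epsilon * s_size)``: no gene may
        carry more than that fraction of the total weight.  ``s_size`` is the
        assumed size of the manifold-informative gene subset; ``s_size=None``
        defaults to ``n // 2`` at run time.
    max_rounds
        Hard stop on the number of weight updates (default 10).
    loss_improvement_tol
        Stop early when the per-round loss improvement falls below this value;
        0 disables the criterion.
    entropy_tol
        Stop early when ``D(p_t, u_n)`` exceeds this value (weights have
        concentrated); 0 disables the criterion.
    gradient_scale
        ``"reweighted"``: per-gene errors are measured on the reweighted
        matrix ``diag(p) X`` the baseline actually consumed.  ``"original"``:
        inputs and reconstruction are rescaled by ``1/p[g]`` first, so errors
        are on the original expression scale.
    lambda_smooth
        Interpolation in ``[0, 1]`` between within-location variance and
        smoothness (increment-variance) penalties of the spatial loss.
    delta
        Classification threshold parameter: a gene is informative when its
        final weight exceeds ``(1 - delta) / n`` (default 0.2).
    """

    eta: float = 1.0
    epsilon: float = 0.5
    s_size: Optional[int] = None
    max_rounds: int = 10
    loss_improvement_tol: float = 0.0
    entropy_tol: float = 0.0
    seed: int = 0
    gradient_scale: str = "reweighted"
    lambda_smooth: float = 0.0
    delta: float = 0.2

    def __post_init__(self) -> None:
        if self.eta < 0:
            raise ValueError("eta must be non-negative")
        if not (0.0 < self.epsilon <= 1.0):
            raise ValueError("epsilon must lie in (0, 1]")
        if self.s_size is not None and self.s_size < 1:
            raise ValueError("s_size must be a positive integer")
        if self.max_rounds < 0:
            raise ValueError("max_rounds must be non-negative")
        if self.loss_improvement_tol < 0 or self.entropy_tol < 0:
            raise ValueError("termination tolerances must be non-negative")
        if self.gradient_scale not in ("reweighted", "original"):
            raise ValueError("gradient_scale must be 'reweighted' or 'original'")
        if not (0.0 <= self.lambda_smooth <= 1.0):
            raise ValueError("lambda_smooth must lie in [0, 1]")
        if not (0.0 < self.delta < 1.0):
            raise ValueError("delta must lie in (0, 1)")

    def cap_for(self, n: int) -> float:
        """Weight cap ``1 / (epsilon * |S|)`` for an ``n``-gene matrix.

        Clipped to 1 (a cap above 1 is vacuous on the simplex).  Raises if the
        cap is infeasible, i.e. ``cap * n < 1``.
        """
        s = self.s_size if self.s_size is not None else max(n // 2, 1)
        cap = min(1.0 / (self.epsilon * s), 1.0)
        if cap * n < 1.0 - SUM_TOL:
            raise ValueError(
                f"infeasible cap 1/(epsilon*|S|) = {cap} for n = {n} genes"
            )
        return cap


def uniform_weights(n: int) -> GeneWeights:
    """The uniform distribution ``u_n`` over ``n`` genes (cap unset)."""
    if n < 1:
        raise ValueError("gene count must be >= 1")
    return GeneWeights(np.full(n, 1.0 / n))


def indicator_weights(S: Sequence[int] | np.ndarray, n: int) -> GeneWeights:
    """The uniform distribution ``chi_S`` over a gene subset ``S``.

    ``S`` is either an index sequence or a length-``n`` boolean mask.
    """
    w = np.zeros(n)
    S = np.asarray(S)
    if S.dtype == bool:
        if S.size != n:
            raise ValueError("boolean mask length must equal gene count")
        idx = np.flatnonzero(S)
    else:
        idx = np.unique(S.astype(int))
        if idx.size and (idx.min() < 0 or idx.max() >= n):
            raise ValueError("gene indices out of range")
    if idx.size == 0:
        raise ValueError("gene subset S must be non-empty")
    w[idx] = 1.0 / idx.size
    return GeneWeights(w)


def relative_entropy(p: GeneWeights, q: GeneWeights) -> float:
    """Relative entropy ``D(p, q) = sum_i p_i ln(p_i / q_i)`` (nats).

    Uses the ``0 * ln(0/q) = 0`` convention.  Raises if ``q`` vanishes
    anywhere ``p`` has mass (the divergence would be infinite by definition;
    callers that want ``inf`` recorded handle that case themselves).
    """
    pw, qw = p.weights, q.weights
    if pw.size != qw.size:
        raise ValueError("p and q must have the same length")
    support = pw > 0
    if np.any(qw[support] <= 0):
        raise ValueError("q must be positive on the support of p")
    ps = pw[support]
    qs = qw[support]
    return float(np.sum(ps * np.log(ps / qs)))


def mwu_step(p: GeneWeights, m: np.ndarray, eta: float) -> GeneWeights:
    """One multiplicative-weights update ``p'[g] ∝ p[g] exp(-eta m[g])``.

    This is the closed-form minimiser of the linearised loss plus relative
    entropy proximity term ``eta <m, q> + D(q, p)`` over the simplex: genes
    with lower reconstruction error gain relative weight.  Computed in log
    space for numerical stability; the returned distribution carries no cap
    (projection is a separate step).
    """
    if eta < 0:
        raise ValueError("eta must be non-negative")
    m = np.asarray(m, dtype=float)
    if m.shape != p.weights.shape:
        raise ValueError("gradient length must match gene count")
    if np.any(m < 0) or not np.all(np.isfinite(m)):
        raise ValueError("gradient entries must be finite and non-negative")
    w = np.maximum(p.weights, WEIGHT_FLOOR)
    if p.weights.sum() <= 0:
        raise ValueError("p must have positive total mass")
    logw = np.log(w) - eta * m
    logw -= logw.max()
    out = np.exp(logw)
    out /= out.sum()
    return GeneWeights(out)


def project_capped(p: GeneWeights, cap: float) -> GeneWeights:
    """KL projection of ``p`` onto the capped simplex ``{q : q <= cap}``.

    Iterates the cap-and-rescale rule to a fixed point: entries above the cap
    are clipped to it and the remaining entries are rescaled pro rata to
    restore total mass 1.  A single pass can push a previously-uncapped entry
    over the cap, hence the iteration; the fixed point is the exact
    KL-closest capped distribution (entries below the cap keep their relative
    proportions).  Idempotent, and never increases the largest entry.
    """
    n = p.n
    if cap * n < 1.0 - SUM_TOL:
        raise ValueError(f"infeasible cap: cap*n = {cap * n} < 1")
    w = p.weights.copy()
    capped = np.zeros(n, dtype=bool)
    for _ in range(n + 1):
        over = (w > cap + CAP_TOL) & ~capped
        if not over.any():
            break
        capped |= over
        free = ~capped
        remaining = 1.0 - cap * capped.sum()
        free_mass = w[free].sum()
        w[capped] = cap
        if free.any():
            if free_mass <= 0:
                # degenerate: no mass left to rescale; spread evenly
                w[free] = remaining / free.sum() if remaining > 0 else 0.0
            else:
                w[free] *= remaining / free_mass
    return GeneWeights(np.clip(w, 0.0, cap), cap=min(cap, 1.0))


def classify_genes(p: GeneWeights, delta: float) -> np.ndarray:
    """Label genes as manifold-informative by thresholding their weight.

    Gene ``g`` is informative iff ``p[g] > (1 - delta)/n``, i.e. its final
    weight did not drop (much) below its uniform starting value ``1/n``.
    Strictly-greater comparison: a gene exactly at the threshold is not
    informative.
    """
    if not (0.0 < delta < 1.0):
        raise ValueError("delta must lie in (0, 1)")
    return p.weights > (1.0 - delta) / p.n
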