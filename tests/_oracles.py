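"""Independent numeric oracles shared by the unit and acceptance tests.

These deliberately avoid the package's own closed forms: the update and
projection oracles solve the defining optimisation problems with a
general-purpose constrained optimiser, and the AUC oracle counts
positive–negative pairs directly.
"""

import itertools

import numpy as np
from scipy.optimize import minimize


def mwu_oracle(p: np.ndarray, m: np.ndarray, eta: float) -> np.ndarray:
    """Numeric minimizer of eta*<m,q> + D(q,p) over the simplex."""

    def objective(q):
        q = np.maximum(q, 1e-12)
        return eta * np.dot(m, q) + np.sum(q * np.log(q / p))

    n = p.size
    res = minimize(
        objective,
        np.full(n, 1.0 / n),
        method="SLSQP",
        bounds=[(1e-12, 1.0)] * n,
        constraints=[{"type": "eq", "fun": lambda q: q.sum() - 1.0}],
        options={"maxiter": 500, "ftol": 1e-14},
    )
    assert res.success
    return res.x


def projection_oracle(p: np.ndarray, cap: float) -> np.ndarray:
    """KL-closest point of the capped simplex, by constrained optimization."""

    def objective(q):
        q = np.maximum(q, 1e-15)
        return np.sum(q * np.log(q / np.maximum(p, 1e-300)))

    n = p.size
    res = minimize(
        objective,
        np.full(n, 1.0 / n),
        method="SLSQP",
        bounds=[(1e-15, cap)] * n,
        constraints=[{"type": "eq", "fun": lambda q: q.sum() - 1.0}],
        options={"maxiter": 500, "ftol": 1e-14},
    )
    assert res.success
    return res.x


def auc_pair_counting(scores: np.ndarray, truth: np.ndarray) -> float:
    """Brute-force AUC: fraction of positive-negative pairs ranked correctly,
    ties counting one half."""
    pos = scores[truth]
    neg = scores[~truth]
    wins = ties = 0
    for a, b in itertools.product(pos, neg):
        if a > b:
            wins += 1
        elif a == b:
            ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))
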