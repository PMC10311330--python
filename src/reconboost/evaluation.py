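"""Metrics for weight trajectories, gene classification and reconstructions.

On synthetic data the ground-truth informative gene set ``S`` is known, so
the trajectory can be scored directly: the relative entropy ``D(chi_S, p_t)``
between the uniform distribution on ``S`` and the learned weights should
fall round over round, the final weights should rank ``S`` above its
complement (AUC), and thresholding the weights at ``(1-delta)/n`` should
recover ``S`` with high TPR and falling FPR.  Reconstruction quality is
scored by mutual information between the learned cell encoding and gene
expression, and by Pearson correlation of location-mean expression profiles.
The linear-fit labeller identifies genes whose mean expression varies
monotonically along a reconstructed 1-D tissue axis (zonated genes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from sklearn.metrics import roc_auc_score

from .driver import WeightTrajectory
from .losses import ExpressionMatrix
from .simplex_core import GeneWeights, indicator_weights, relative_entropy

__all__ = [
    "EvaluationReport",
    "entropy_trace",
    "auc_informative",
    "tpr_fpr",
    "mutual_information_blocks",
    "pearson_profiles",
    "label_zonated",
]


@dataclass
class EvaluationReport:
    """Bundle of trajectory-level and gene-level evaluation results."""

    relative_entropy_per_round: List[float] = field(default_factory=list)
    auc: Optional[float] = None
    tpr: Optional[float] = None
    fpr: Optional[float] = None
    mi_by_block: Dict[int, Tuple[float, float]] = field(default_factory=dict)
    pearson_by_gene: Optional[np.ndarray] = None
    labels: Optional[np.ndarray] = None

    def to_dict(self) -> Dict:
        return {
            "relative_entropy_per_round": list(self.relative_entropy_per_round),
            "auc": self.auc,
            "tpr": self.tpr,
            "fpr": self.fpr,
            "mi_by_block": {
                str(k): {"mean": v[0], "sd": v[1]} for k, v in self.mi_by_block.items()
            },
        }


def entropy_trace(
    traj: WeightTrajectory, truth_mask: np.ndarray
) -> List[float]:
    """Per-round relative entropy ``D(chi_S, p_t)`` to the ground truth.

    The divergence is taken truth-first (reference distribution ``chi_S``
    uniform on the true set ``S``); rounds where ``p_t`` has zero mass on
    some gene of ``S`` record ``inf``.  At round 0 the trace equals
    ``ln(n / |S|)`` exactly.
    """
    truth_mask = np.asarray(truth_mask, dtype=bool)
    if not truth_mask.any():
        raise ValueError("truth mask must select at least one gene")
    chi = indicator_weights(truth_mask, truth_mask.size)
    trace: List[float] = []
    for rec in traj.rounds:
        p = rec.weights
        if np.any(p.weights[truth_mask] <= 0):
            trace.append(float("inf"))
        else:
            trace.append(relative_entropy(chi, p))
    return trace


def auc_informative(p_final: GeneWeights, truth_mask: np.ndarray) -> float:
    """AUC of the final gene weight as a score for membership in ``S``.

    Midrank handling of tied weights; raises if the truth is single-class.
    """
    truth_mask = np.asarray(truth_mask, dtype=bool)
    if truth_mask.all() or not truth_mask.any():
        raise ValueError("AUC undefined: truth mask is single-class")
    return float(roc_auc_score(truth_mask, p_final.weights))


def tpr_fpr(
    mask_pred: np.ndarray, mask_true: np.ndarray
) -> Tuple[float, float]:
    """True- and false-positive rate of a predicted informative-gene mask."""
    pred = np.asarray(mask_pred, dtype=bool)
    true = np.asarray(mask_true, dtype=bool)
    if pred.shape != true.shape:
        raise ValueError("masks must have the same length")
    if true.all() or not true.any():
        raise ValueError("TPR/FPR undefined: truth mask is single-class")
    tpr = float((pred & true).sum() / true.sum())
    fpr = float((pred & ~true).sum() / (~true).sum())
    return tpr, fpr


def _equal_frequency_bins(x: np.ndarray, bins: int) -> np.ndarray:
    """Assign each value to one of ``bins`` equal-frequency bins via ranks."""
    order = np.argsort(x, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(x.size)
    return (ranks * bins) // x.size


def _histogram_mi(a: np.ndarray, b: np.ndarray, bins: int) -> float:
    """Plug-in MI (nats) of two vectors under equal-frequency binning."""
    ia = _equal_frequency_bins(a, bins)
    ib = _equal_frequency_bins(b, bins)
    joint = np.zeros((bins, bins))
    np.add.at(joint, (ia, ib), 1.0)
    joint /= joint.sum()
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    nz = joint > 0
    return float(
        np.sum(joint[nz] * np.log(joint[nz] / np.outer(pa, pb)[nz]))
    )


def mutual_information_blocks(
    encoding: np.ndarray,
    X: ExpressionMatrix | np.ndarray,
    truth_labels: np.ndarray,
    bins: int = 16,
) -> Dict[int, Tuple[float, float]]:
    """Mean +/- sd mutual information per gene block.

    Per gene, the plug-in histogram MI (natural log, equal-frequency bins on
    each marginal) between the first encoding coordinate of the cells and
    that gene's expression; aggregated as (mean, sd) within each block of
    ``truth_labels``.  A constant encoding yields MI 0 for every gene.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if isinstance(X, ExpressionMatrix):
        X = X.values
    X = np.asarray(X, dtype=float)
    encoding = np.atleast_2d(np.asarray(encoding, dtype=float))
    coord = encoding[0]
    if coord.size != X.shape[1]:
        raise ValueError("encoding length must equal cell count")
    labels = np.asarray(truth_labels).astype(int)
    if labels.size != X.shape[0]:
        raise ValueError("truth labels length must equal gene count")
    if np.ptp(coord) == 0:
        mi = np.zeros(X.shape[0])
    else:
        mi = np.array([_histogram_mi(coord, X[g], bins) for g in range(X.shape[0])])
    return {
        int(b): (float(mi[labels == b].mean()), float(mi[labels == b].std()))
        for b in np.unique(labels)
    }


def pearson_profiles(
    reconstructed: np.ndarray, reference: np.ndarray
) -> np.ndarray:
    """Per-gene Pearson correlation between two gene x location profiles.

    Genes with a zero-variance profile in either matrix get ``nan``.
    """
    A = np.asarray(reconstructed, dtype=float)
    B = np.asarray(reference, dtype=float)
    if A.shape != B.shape:
        raise ValueError("profile matrices must have the same shape")
    if A.shape[1] < 3:
        raise ValueError("need at least 3 locations")
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    denom = np.sqrt((Ac**2).sum(axis=1) * (Bc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Ac * Bc).sum(axis=1) / denom
    r[denom == 0] = np.nan
    return r


def label_zonated(
    profiles: np.ndarray,
    r2_min: float = 0.1,
    slope_min: float = 0.001,
) -> Tuple[np.ndarray, Dict[str, np.ndarray]]:
    """Label genes whose mean profile varies linearly along the 1-D axis.

    Ordinary least squares of each gene's location-mean profile against the
    integer grid ``0..h-1``.  A gene is labelled zonated when the fit is
    informative (coefficient of determination ``R^2 > r2_min``) and the trend
    is non-flat (``|slope| > slope_min``); the absolute slope makes the label
    invariant to the direction of the axis.  Returns the boolean labels and
    per-gene diagnostics (``r_squared``, ``slope``).
    """
    P = np.asarray(profiles, dtype=float)
    if P.ndim != 2 or P.shape[1] < 3:
        raise ValueError("profiles must be gene x location with >= 3 locations")
    h = P.shape[1]
    x = np.arange(h, dtype=float)
    xc = x - x.mean()
    Pc = P - P.mean(axis=1, keepdims=True)
    sxx = float((xc**2).sum())
    slope = (Pc @ xc) / sxx
    fitted = np.outer(slope, xc)
    ss_res = ((Pc - fitted) ** 2).sum(axis=1)
    ss_tot = (Pc**2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = 1.0 - ss_res / ss_tot
    r2[ss_tot == 0] = 0.0
    labels = (r2 > r2_min) & (np.abs(slope) > slope_min)
    return labels, {"r_squared": r2, "slope": slope}
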