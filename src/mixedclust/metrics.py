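"""Evaluation criteria: classification rate, information-gain rate, ANOVA F.

The classification rate (CR) scores a clustering against known classes under
the correctness-maximizing one-to-one cluster-to-class assignment, so it is
invariant to cluster relabeling and never overstates accuracy when the
number of clusters is wrong.  The information-gain rate (IGR) is the
entropy reduction achieved by the partition relative to the total class
entropy (base-2 logs); it equals 1 for pure clusters — including pure
over-splits, a known blind spot of purity-style criteria.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationReport",
    "classification_rate",
    "entropy_bits",
    "information_gain_rate",
    "anova_f",
]


@dataclass
class EvaluationReport:
    """CR and entropy-based purity of one clustering against true labels."""

    cr: float
    ig: float | None
    total_entropy: float
    igr: float | None
    matching: dict


def _confusion(true_labels, pred):
    true_labels = np.asarray(true_labels)
    pred = np.asarray(pred)
    if true_labels.shape != pred.shape or true_labels.ndim != 1:
        raise ValueError("label vectors must be equal-length 1-d arrays")
    classes, t = np.unique(true_labels, return_inverse=True)
    clusters, c = np.unique(pred, return_inverse=True)
    cm = np.zeros((len(classes), len(clusters)), dtype=np.int64)
    np.add.at(cm, (t, c), 1)
    return classes, clusters, cm


def classification_rate(true_labels, pred) -> tuple[float, dict]:
    """Fraction correctly assigned under the best one-to-one cluster↔class map.

    The map maximizes the matched count on the confusion matrix (Hungarian
    assignment); surplus clusters left unmatched contribute zero correct
    records.  Returns ``(cr, matching)`` with matching as cluster -> class.
    """
    classes, clusters, cm = _confusion(true_labels, pred)
    rows, cols = linear_sum_assignment(cm, maximize=True)
    correct = int(cm[rows, cols].sum())
    matching = {clusters[c]: classes[r] for r, c in zip(rows, cols)}
    return correct / cm.sum(), matching


def entropy_bits(labels) -> float:
    """Shannon entropy of a label vector in bits."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label vector")
    _, counts = np.unique(labels, return_counts=True)
    f = counts / counts.sum()
    return float(-(f * np.log2(f)).sum())


def information_gain_rate(true_labels, pred) -> EvaluationReport:
    """Entropy-based purity report of a clustering.

    weighted entropy = sum_k (n_k / n) * H(true labels within cluster k);
    IG = total entropy - weighted entropy; IGR = IG / total entropy.
    A single true class leaves IGR undefined (reported as None).
    """
    true_labels = np.asarray(true_labels)
    pred = np.asarray(pred)
    cr, matching = classification_rate(true_labels, pred)
    total = entropy_bits(true_labels)
    if total == 0.0:
        logger.warning("only one true class: information-gain rate undefined")
        return EvaluationReport(
            cr=cr, ig=None, total_entropy=0.0, igr=None, matching=matching
        )
    n = len(pred)
    weighted = 0.0
    for k in np.unique(pred):
        mask = pred == k
        weighted += mask.sum() / n * entropy_bits(true_labels[mask])
    ig = total - weighted
    return EvaluationReport(
        cr=cr, ig=ig, total_entropy=total, igr=ig / total, matching=matching
    )


def anova_f(Z: np.ndarray, membership) -> float:
    """Mean one-way ANOVA F statistic over continuous columns.

    Each column's F = between-group mean square / within-group mean square
    with the clusters as groups.  Fewer than two groups (or n <= K) gives 0;
    zero within-group variance with separated means gives +inf.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    membership = np.asarray(membership)
    groups, idx = np.unique(membership, return_inverse=True)
    K = len(groups)
    n = Z.shape[0]
    if K < 2 or n <= K:
        return 0.0
    grand = Z.mean(axis=0)
    counts = np.bincount(idx).astype(float)
    sums = np.zeros((K, Z.shape[1]))
    np.add.at(sums, idx, Z)
    means = sums / counts[:, None]
    ssb = (counts[:, None] * (means - grand) ** 2).sum(axis=0)
    ssw = ((Z - means[idx]) ** 2).sum(axis=0)
    msb = ssb / (K - 1)
    msw = ssw / (n - K)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(msw > 0, msb / np.where(msw > 0, msw, 1.0), np.where(msb > 0, np.inf, 0.0))
    return float(np.mean(f))
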