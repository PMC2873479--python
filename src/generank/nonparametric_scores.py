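"""Rank/combinatorial gene scores: TNoM, MDMR, and WEPO.

These punish disorder in the expression-sorted label sequence instead of
assuming a distribution; a smaller score marks a more informative gene.

* TNoM — the minimum number of samples any single threshold rule
  sign(a*x + b) misclassifies, minimized over the threshold b and both
  orientations (sign of a). Equal expression values can never be separated
  by a threshold, so cuts run only between distinct values.
* MDMR — the minimum number of adjacent transpositions turning the
  expression-sorted label sequence into a perfect split (all + first or all
  - first), i.e. the smaller of the two cross-class inversion counts.
  Tied expression values can be ordered arbitrarily, so tied cross-class
  pairs contribute no inversion (the minimum over tie permutations).
* WEPO — a z-score-weighted variant of the swap count: each wrong-order
  cross-class pair is punished by the gap between the two samples' robust
  z-scores (centering by the mean, scaling by the mean absolute deviation).
  This concrete punishment is this package's instantiation of the published
  idea of weighting rank swaps by z-score overlap.
"""

from __future__ import annotations

import numpy as np

from .core_data import EPS, ExpressionMatrix, GeneRanking


def robust_zscores(x: np.ndarray) -> tuple[np.ndarray, float]:
    """z = (x - mean) / MAD with MAD the mean absolute deviation about the mean.

    A gene with MAD <= eps (constant) gets an all-zero z vector.
    """
    x = np.asarray(x, dtype=float)
    mu = x.mean()
    mad = float(np.abs(x - mu).mean())
    if mad <= EPS:
        return np.zeros_like(x), mad
    return (x - mu) / mad, mad


def tnom_scores(X: ExpressionMatrix) -> GeneRanking:
    """Threshold number of misclassifications per gene (integer, lower better).

    Single sorted sweep over the <= s+1 distinct cut positions for both
    orientations; the score is bounded by min(m_pos, m_neg) because placing
    every sample on one side achieves that error count.
    """
    labels = X.require_labels()
    g, s = X.values.shape
    n_pos = int((labels == 1).sum())
    n_neg = s - n_pos

    order = np.argsort(X.values, axis=1, kind="stable")
    sorted_vals = np.take_along_axis(X.values, order, axis=1)
    lab_pos = (labels[order] == 1).astype(int)  # (g, s)

    # P[:, k] = number of positives among the first k sorted samples, k=0..s
    P = np.concatenate([np.zeros((g, 1), int), np.cumsum(lab_pos, axis=1)], axis=1)
    K = np.arange(s + 1)
    # orientation A: predict - below the cut, + above
    err_a = P + (n_neg - (K - P))
    # orientation B: predict + below the cut, - above
    err_b = (K - P) + (n_pos - P)
    err = np.minimum(err_a, err_b)

    # a threshold can only fall strictly between distinct values
    valid = np.ones((g, s + 1), dtype=bool)
    valid[:, 1:s] = sorted_vals[:, 1:] > sorted_vals[:, :-1]
    err = np.where(valid, err, s + 1)
    scores = err.min(axis=1).astype(float)
    return GeneRanking("tnom", scores, "lower_better", X.gene_ids)


def mdmr_scores(X: ExpressionMatrix) -> GeneRanking:
    """Minimum adjacent-swap distance to a perfect class split (lower better).

    Equals min over the two modal targets of the number of strictly
    wrong-order cross-class pairs; 0 iff some ordering of the samples splits
    the classes exactly.
    """
    labels = X.require_labels()
    pos = X.values[:, labels == 1]  # (g, m+)
    neg = X.values[:, labels == -1]  # (g, m-)
    # + first (low values): inversion when a - sample lies strictly below a +
    inv_pos_first = (neg[:, :, None] < pos[:, None, :]).sum(axis=(1, 2))
    inv_neg_first = (pos[:, None, :] < neg[:, :, None]).sum(axis=(1, 2))
    scores = np.minimum(inv_pos_first, inv_neg_first).astype(float)
    return GeneRanking("mdmr", scores, "lower_better", X.gene_ids)


def wepo_scores(X: ExpressionMatrix) -> GeneRanking:
    """Weighted punishment on overlap (real-valued, lower better).

    Per gene: robust z-scores, then the punishment is the smaller, over the
    two orientations, of the summed z-gaps of wrong-order cross-class pairs.
    Zero iff the classes are separable in z. MAD-zero genes score 0 and are
    flagged degenerate.
    """
    labels = X.require_labels()
    g = X.n_genes
    mu = X.values.mean(axis=1, keepdims=True)
    mad = np.abs(X.values - mu).mean(axis=1, keepdims=True)
    degenerate = mad[:, 0] <= EPS
    z = np.divide(X.values - mu, mad, out=np.zeros_like(X.values), where=mad > EPS)

    zp = z[:, labels == 1]
    zn = z[:, labels == -1]
    diff = zp[:, None, :] - zn[:, :, None]  # (g, m-, m+): z(+) - z(-)
    pun_pos_first = np.where(diff > 0, diff, 0.0).sum(axis=(1, 2))
    pun_neg_first = np.where(diff < 0, -diff, 0.0).sum(axis=(1, 2))
    scores = np.minimum(pun_pos_first, pun_neg_first)
    scores[degenerate] = 0.0
    return GeneRanking("wepo", scores, "lower_better", X.gene_ids, flags=degenerate)
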