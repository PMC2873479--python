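"""Parametric gene-ranking statistics: SNR, unpaired t, and the Fisher/LSD criterion.

All three compare class means against within-class spread; a larger score
marks a more informative gene. Denominators are floored at a tiny epsilon so
constant genes score finite values instead of crashing a whole-chip scan.
"""

from __future__ import annotations

import numpy as np

from .core_data import EPS, ExpressionMatrix, GeneRanking, class_stats


def snr_scores(X: ExpressionMatrix) -> GeneRanking:
    """Signal-to-noise ratio: F = |mu+ - mu-| / (sigma+ + sigma-).

    Class SDs use the population convention (ddof=0). A gene constant within
    both classes has a vanishing denominator; with equal class means it
    scores 0, otherwise |delta mu| / eps (large but finite).
    """
    st = class_stats(X, ddof=0)
    num = np.abs(st.mu_pos - st.mu_neg)
    den = np.maximum(st.sigma_pos + st.sigma_neg, EPS)
    scores = np.where(num <= EPS, 0.0, num / den)
    return GeneRanking("snr", scores, "higher_better", X.gene_ids)


def ttest_scores(X: ExpressionMatrix) -> GeneRanking:
    """Welch unpaired two-sample t, reported as |T|.

    |T| = |mu+ - mu-| / sqrt(sigma+^2/M+ + sigma-^2/M-) with sample SDs
    (ddof=1), so each class needs at least two samples.
    """
    st = class_stats(X, ddof=1)
    num = np.abs(st.mu_pos - st.mu_neg)
    var = st.sigma_pos**2 / st.m_pos + st.sigma_neg**2 / st.m_neg
    scores = np.where(num <= EPS, 0.0, num / np.sqrt(np.maximum(var, EPS)))
    return GeneRanking("ttest", scores, "higher_better", X.gene_ids)


def lsd_scores(X: ExpressionMatrix) -> GeneRanking:
    """Fisher criterion (least significant difference):
    F = (mu+ - mu-)^2 / (sigma+^2 + sigma-^2), population SDs."""
    st = class_stats(X, ddof=0)
    num = (st.mu_pos - st.mu_neg) ** 2
    den = np.maximum(st.sigma_pos**2 + st.sigma_neg**2, EPS)
    scores = np.where(num <= EPS, 0.0, num / den)
    return GeneRanking("lsd", scores, "higher_better", X.gene_ids)
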