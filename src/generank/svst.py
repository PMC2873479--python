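"""Support Vector Sampling Technique (SVST).

A linear soft-margin SVM is fit on all samples; only the support-vector
samples — those with positive dual coefficient alpha, which carry the
classification-relevant information — are retained, and genes are then
ranked by the signal-to-noise ratio computed on that reduced sample set.

Dual-coefficient geometry (linear kernel, penalty C):
  alpha_i = 0        sample lies strictly outside the margin (y f(x) > 1);
  0 < alpha_i < C    unbounded support vector, on the margin (y f(x) = 1);
  alpha_i = C        bounded support vector, inside or beyond the margin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .core_data import ClassDesignError, ExpressionMatrix, GeneRanking, normalize_genes
from .parametric_scores import snr_scores


@dataclass
class SvmModel:
    """A fitted linear soft-margin SVM in primal+dual form.

    ``gamma`` is recorded for config fidelity but is inert under the linear
    kernel. ``margins`` holds y_i * f(x_i) for every training sample.
    """

    alpha: np.ndarray  # per-sample dual coefficients, 0 <= alpha_i <= C
    w: np.ndarray  # weight vector over genes
    b: float
    C: float
    gamma: float
    labels: np.ndarray
    margins: np.ndarray

    def decision_function(self, values: np.ndarray) -> np.ndarray:
        """f(x) = w . x + b for samples given as columns of ``values``."""
        return self.w @ values + self.b


@dataclass
class SupportSampleSet:
    """Indices of retained support-vector samples with their alpha status."""

    indices: np.ndarray
    status: list[str]  # "unbounded" (0<alpha<C) or "bounded" (alpha=C)
    policy: str


def fit_linear_svm(X: ExpressionMatrix, C: float = 1.0, tol: float = 1e-7) -> SvmModel:
    """Solve the soft-margin dual on the samples (columns) of ``X``.

    The problem is convex so the fit is deterministic for fixed input. The
    solver tolerance is kept tight because downstream checks rely on KKT
    conditions holding to ~1e-4.
    """
    labels = X.require_labels()
    A = X.values.T  # samples x genes
    svc = SVC(kernel="linear", C=C, tol=tol)
    svc.fit(A, labels)
    alpha = np.zeros(X.n_samples)
    alpha[svc.support_] = np.abs(svc.dual_coef_[0])
    w = svc.coef_[0]
    b = float(svc.intercept_[0])
    margins = labels * (A @ w + b)
    return SvmModel(alpha=alpha, w=w, b=b, C=C, gamma=1.0 / X.n_genes,
                    labels=labels, margins=margins)


def select_support_samples(
    model: SvmModel, policy: str = "all_sv", tol: float | None = None
) -> SupportSampleSet:
    """Pick the retained samples by dual coefficient.

    ``all_sv`` keeps every alpha > tol; ``unbounded_only`` keeps only the
    on-margin samples with tol < alpha < C - tol. The default tolerance is
    1e-6 * C (numeric solvers leave dust on the bounds).
    """
    if tol is None:
        tol = 1e-6 * model.C
    if policy == "all_sv":
        mask = model.alpha > tol
    elif policy == "unbounded_only":
        mask = (model.alpha > tol) & (model.alpha < model.C - tol)
        if not mask.any():
            raise ClassDesignError(
                "no unbounded support vectors (all alpha at the C bound); "
                "retry with policy='all_sv'"
            )
    else:
        raise ValueError(f"unknown support policy {policy!r}")
    idx = np.flatnonzero(mask)
    status = [
        "unbounded" if model.alpha[i] < model.C - tol else "bounded" for i in idx
    ]
    return SupportSampleSet(indices=idx, status=status, policy=policy)


def svst_rank(
    X: ExpressionMatrix,
    C: float = 1.0,
    policy: str = "all_sv",
    *,
    normalize: bool = True,
    renormalize_subset: bool = False,
) -> tuple[GeneRanking, SupportSampleSet, SvmModel]:
    """Rank genes by SNR restricted to the support-vector samples.

    The matrix is gene-normalized before the fit (set ``normalize=False`` if
    already normalized). By default class statistics on the reduced sample
    set reuse the full-set normalization; ``renormalize_subset`` re-runs the
    per-gene z-normalization on the retained columns instead.
    """
    Xn = normalize_genes(X) if normalize else X
    model = fit_linear_svm(Xn, C=C)
    sel = select_support_samples(model, policy=policy)
    sub = Xn.subset_samples(sel.indices)
    if renormalize_subset:
        sub = normalize_genes(sub)
    if sub.labels is None or len(set(sub.labels.tolist())) < 2:
        raise ClassDesignError("support-vector sample set is single-class (degenerate fit)")
    ranking = snr_scores(sub)
    ranking.method = "svst"
    return ranking, sel, model
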