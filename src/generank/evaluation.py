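"""Repeated random 3-fold SVM benchmark of gene-selection methods.

For each of ``n_repeats`` independent repeats the samples are split into
``n_folds`` stratified folds; each fold serves once as the validation set.
Per training split, each method ranks the genes (inside the training folds
only under the default ``per_fold`` scope, guarding against the selection
bias of choosing genes on the full dataset), a linear SVM (C=1) is trained on
the top-k genes, and validation accuracy is recorded. Reports give the mean
accuracy and its min-max range per (method, k), rendered in the compact
".95(.88 to 1)" style.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .core_data import ExpressionMatrix, GeneRanking
from .nonparametric_scores import mdmr_scores, tnom_scores, wepo_scores
from .parametric_scores import lsd_scores, snr_scores, ttest_scores
from .rfgs import RfgsConfig, rfgs_rank
from .svst import svst_rank

# A ranking method takes a (labeled) training matrix and an integer seed;
# deterministic methods ignore the seed.
RankingMethod = Callable[[ExpressionMatrix, int], GeneRanking]

METHOD_NAMES = ("snr", "ttest", "lsd", "tnom", "mdmr", "wepo", "rfgs", "svst")


def get_method(name: str, **params) -> RankingMethod:
    """Look up a ranking method by tag, binding any method parameters.

    RFGS accepts ``n_groups``, ``n_cycles``, ``n_runs``; SVST accepts ``C``
    and ``policy``. The returned callable signature is (matrix, seed).
    """
    simple = {
        "snr": snr_scores,
        "ttest": ttest_scores,
        "lsd": lsd_scores,
        "tnom": tnom_scores,
        "mdmr": mdmr_scores,
        "wepo": wepo_scores,
    }
    if name in simple:
        fn = simple[name]
        return lambda X, seed: fn(X)
    if name == "rfgs":
        def run_rfgs(X: ExpressionMatrix, seed: int) -> GeneRanking:
            cfg = RfgsConfig(seed=seed, **params)
            if cfg.n_groups > X.n_genes:
                cfg.n_groups = X.n_genes
            return rfgs_rank(X, cfg)[1]
        return run_rfgs
    if name == "svst":
        return lambda X, seed: svst_rank(X, **params)[0]
    raise KeyError(
        f"unknown method {name!r}; registered methods: {', '.join(METHOD_NAMES)}"
    )


@dataclass
class CvConfig:
    n_folds: int = 3
    n_repeats: int = 100
    top_k_list: tuple[int, ...] = (25, 50, 75, 100, 125, 150)
    selection_scope: str = "per_fold"  # or "whole_dataset"
    seed: int = 0
    C: float = 1.0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")
        if self.selection_scope not in ("per_fold", "whole_dataset"):
            raise ValueError(f"unknown selection scope {self.selection_scope!r}")


@dataclass
class CvReport:
    """Per-top-k accuracy samples over repeats x folds for one method."""

    method: str
    accuracies: dict[int, np.ndarray]  # k -> (n_repeats, n_folds)
    warnings: list[str] = field(default_factory=list)

    def mean(self, k: int) -> float:
        return float(self.accuracies[k].mean())

    def min(self, k: int) -> float:
        return float(self.accuracies[k].min())

    def max(self, k: int) -> float:
        return float(self.accuracies[k].max())

    def summary(self) -> pd.DataFrame:
        rows = [
            {"method": self.method, "top_k": k, "mean": self.mean(k),
             "min": self.min(k), "max": self.max(k)}
            for k in sorted(self.accuracies)
        ]
        return pd.DataFrame(rows)


def random_kfold_indices(
    labels: np.ndarray, k: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Random class-stratified k-fold partition of sample indices.

    Within each class the indices are shuffled and dealt round-robin, so fold
    sizes differ by at most one overall and per class.
    """
    labels = np.asarray(labels)
    s = len(labels)
    if k > s:
        raise ValueError(f"cannot make {k} folds from {s} samples")
    folds: list[list[int]] = [[] for _ in range(k)]
    counter = 0
    for cls in (1, -1):
        idx = np.flatnonzero(labels == cls)
        for i in rng.permutation(idx):
            folds[counter % k].append(int(i))
            counter += 1
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def evaluate_method(
    X: ExpressionMatrix, method_name: str, cfg: CvConfig, **method_params
) -> CvReport:
    """Repeated random k-fold accuracy of a linear SVM on each top-k gene set.

    Every repeat draws fresh folds (and, for stochastic methods, a fresh
    method seed) from its own RNG stream, so repeats are independent and the
    whole report is reproducible from ``cfg.seed``.
    """
    labels = X.require_labels()
    method = get_method(method_name, **method_params)
    top_ks = tuple(cfg.top_k_list)
    if max(top_ks) > X.n_genes:
        raise ValueError("top_k exceeds the number of genes")
    acc = {k: np.zeros((cfg.n_repeats, cfg.n_folds)) for k in top_ks}
    warnings: list[str] = []

    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_repeats)
    for rep, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        folds = random_kfold_indices(labels, cfg.n_folds, rng)
        whole_ranking = None
        if cfg.selection_scope == "whole_dataset":
            whole_ranking = method(X, int(rng.integers(2**31)))
        for f, val_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(X.n_samples), val_idx)
            X_train = X.subset_samples(train_idx)
            if len(set(X_train.labels.tolist())) < 2:
                warnings.append(f"repeat {rep} fold {f}: single-class training set")
                continue
            if len(set(X.labels[val_idx].tolist())) < 2:
                warnings.append(f"repeat {rep} fold {f}: single-class validation fold")
            ranking = (
                whole_ranking
                if whole_ranking is not None
                else method(X_train, int(rng.integers(2**31)))
            )
            for k in top_ks:
                genes = ranking.top_indices(k)
                clf = SVC(kernel="linear", C=cfg.C)
                clf.fit(X_train.values[genes].T, X_train.labels)
                pred = clf.predict(X.values[np.ix_(genes, val_idx)].T)
                acc[k][rep, f] = float((pred == labels[val_idx]).mean())
    return CvReport(method=method_name, accuracies=acc, warnings=warnings)


def evaluate_methods(
    X: ExpressionMatrix,
    methods: list[str],
    cfg: CvConfig,
    method_params: dict[str, dict] | None = None,
) -> dict[str, CvReport]:
    method_params = method_params or {}
    return {
        m: evaluate_method(X, m, cfg, **method_params.get(m, {})) for m in methods
    }


# ---------------------------------------------------------------------------
# report rendering


def _fmt(v: float) -> str:
    """Compact accuracy: .95 style, 1 for a rounded 1.00."""
    r = round(v, 2)
    if abs(r - 1.0) < 1e-12:
        return "1"
    s = f"{r:.2f}"
    return s[1:] if s.startswith("0") else s


def format_cell(mean: float, lo: float, hi: float) -> str:
    return f"{_fmt(mean)}({_fmt(lo)} to {_fmt(hi)})"


def report_frame(reports: dict[str, CvReport]) -> pd.DataFrame:
    """Methods x top-k table of formatted mean(lo to hi) cells."""
    if not reports:
        raise ValueError("no reports to format")
    ks = sorted(next(iter(reports.values())).accuracies)
    data = {
        f"{k} genes": [
            format_cell(rep.mean(k), rep.min(k), rep.max(k))
            for rep in reports.values()
        ]
        for k in ks
    }
    return pd.DataFrame(data, index=list(reports))


def format_report(reports: dict[str, CvReport]) -> str:
    """Aligned-text rendering of the methods x top-k accuracy table."""
    df = report_frame(reports)
    return df.to_string(index_names=False)
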