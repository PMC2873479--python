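"""Random Forest Gene Selection (RFGS).

Genes are repeatedly partitioned into random groups; a decision-tree root is
found for each group (the gene whose best single threshold split minimizes
weighted Gini impurity — the root a CART tree grown on the group would pick);
each root earns one mark. Marks accumulate over N cycles per run and the
ranking averages per-gene marks over independent runs. Only the root matters,
so no tree is grown below it, and because the best-split impurity of a gene
does not depend on its group, it is precomputed once per dataset: a cycle
then reduces to a random partition plus a per-group argmin.

This borrows only the random-subset-plus-root idea from random forests:
there is no bagging of samples, no out-of-bag error, and no full trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_data import ExpressionMatrix, GeneRanking


@dataclass
class RfgsConfig:
    """Knobs of the root-voting procedure.

    Defaults follow the benchmark protocol this package reproduces:
    1000 groups, 100 cycles, 10 independent runs, top-25 report.
    """

    n_groups: int = 1000
    n_cycles: int = 100
    n_runs: int = 10
    seed: int = 0
    top_n: int = 25
    tie: str = "lowest"  # "lowest" gene index | "random" via the run RNG


@dataclass
class RfgsHitTable:
    """Per-gene root-selection counts per run plus run-level aggregates."""

    hits: np.ndarray  # (n_runs, g) integer counts
    mean_hits: np.ndarray  # (g,)
    top_n_membership: np.ndarray  # (g,) number of runs whose top-n contains the gene
    top_n: int


def partition_genes(g: int, m: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Randomly split gene indices {0..g-1} into m disjoint groups.

    A uniform random permutation is chunked; the first g % m groups take one
    extra gene so sizes differ by at most 1.
    """
    if not 1 <= m <= g:
        raise ValueError(f"need 1 <= n_groups <= n_genes, got {m} groups for {g} genes")
    perm = rng.permutation(g)
    return np.split(perm, _group_starts(g, m)[1:])


def _group_starts(g: int, m: int) -> np.ndarray:
    base, rem = divmod(g, m)
    sizes = np.full(m, base, dtype=int)
    sizes[:rem] += 1
    starts = np.zeros(m, dtype=int)
    starts[1:] = np.cumsum(sizes)[:-1]
    return starts


def best_split_impurity(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-gene minimum weighted Gini impurity over all threshold splits.

    Candidate thresholds sit midway between consecutive distinct sorted
    values. Orientation does not change a split's impurity, so only cut
    positions are enumerated. A constant gene has no valid split and is
    assigned the parent impurity, so it never beats a splittable gene.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    labels = np.asarray(labels)
    g, s = values.shape
    n_pos = int((labels == 1).sum())
    p_parent = n_pos / s
    parent = 1.0 - p_parent**2 - (1.0 - p_parent) ** 2

    order = np.argsort(values, axis=1, kind="stable")
    sv = np.take_along_axis(values, order, axis=1)
    lab_pos = (labels[order] == 1).astype(float)
    P = np.cumsum(lab_pos, axis=1)[:, :-1]  # positives among first k, k=1..s-1
    K = np.arange(1, s, dtype=float)

    pL = P / K
    pR = (n_pos - P) / (s - K)
    gini_left = 1.0 - pL**2 - (1.0 - pL) ** 2
    gini_right = 1.0 - pR**2 - (1.0 - pR) ** 2
    weighted = (K * gini_left + (s - K) * gini_right) / s

    valid = sv[:, 1:] > sv[:, :-1]
    weighted = np.where(valid, weighted, np.inf)
    best = weighted.min(axis=1) if s > 1 else np.full(g, np.inf)
    return np.where(np.isfinite(best), best, parent)


def root_gene(group: np.ndarray, X: ExpressionMatrix) -> int:
    """The group member a CART root split would choose (ties: lowest index)."""
    group = np.asarray(group, dtype=int)
    if group.size == 0:
        raise ValueError("empty gene group")
    labels = X.require_labels()
    imp = best_split_impurity(X.values[group], labels)
    winners = group[imp == imp.min()]
    return int(winners.min())


def rfgs_rank(X: ExpressionMatrix, cfg: RfgsConfig) -> tuple[RfgsHitTable, GeneRanking]:
    """Run the full root-voting procedure and rank genes by mean hit count.

    Per run a dedicated RNG stream is spawned from ``cfg.seed``, so runs are
    independent yet the whole procedure is reproducible. Per run the hit
    counts conserve exactly n_cycles * n_groups marks (one root per group per
    cycle). Ranking ties break by ascending gene index.
    """
    labels = X.require_labels()
    g = X.n_genes
    if not 1 <= cfg.n_groups <= g:
        raise ValueError(f"n_groups must be in [1, {g}], got {cfg.n_groups}")
    if cfg.tie not in ("lowest", "random"):
        raise ValueError(f"unknown tie policy {cfg.tie!r}")

    imp = best_split_impurity(X.values, labels)
    starts = _group_starts(g, cfg.n_groups)

    hits = np.zeros((cfg.n_runs, g), dtype=np.int64)
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_runs)
    for run, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        tie_key = rng.permutation(g) if cfg.tie == "random" else np.arange(g)
        # priority[i] = rank of gene i under (impurity, tie_key); the root of
        # a group is its minimum-priority member
        order = np.lexsort((tie_key, imp))
        priority = np.empty(g, dtype=np.int64)
        priority[order] = np.arange(g)
        gene_of_priority = order
        for _ in range(cfg.n_cycles):
            perm = rng.permutation(g)
            group_min = np.minimum.reduceat(priority[perm], starts)
            roots = gene_of_priority[group_min]
            hits[run, roots] += 1

    mean_hits = hits.mean(axis=0)
    membership = np.zeros(g, dtype=np.int64)
    for run in range(cfg.n_runs):
        run_rank = GeneRanking("rfgs_run", hits[run].astype(float), "higher_better", X.gene_ids)
        membership[run_rank.top_indices(cfg.top_n)] += 1

    table = RfgsHitTable(hits=hits, mean_hits=mean_hits,
                         top_n_membership=membership, top_n=cfg.top_n)
    ranking = GeneRanking("rfgs", mean_hits, "higher_better", X.gene_ids)
    return table, ranking
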