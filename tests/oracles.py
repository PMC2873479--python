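"""Independent brute-force oracles used to validate the fast implementations.

These deliberately use naive enumeration / graph search and share no code
with the package's sweep/vectorized implementations.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def tnom_brute(values, labels) -> int:
    """Minimum errors of any threshold rule sign(a*x + b): enumerate every
    candidate threshold (midpoints between distinct sorted values plus one
    below and one above everything) crossed with both orientations."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    distinct = np.unique(values)
    thresholds = [distinct[0] - 1.0]
    thresholds += [(a + b) / 2.0 for a, b in zip(distinct[:-1], distinct[1:])]
    thresholds += [distinct[-1] + 1.0]
    best = len(values)
    for thr in thresholds:
        for orient in (1, -1):
            pred = np.where(orient * (values - thr) > 0, 1, -1)
            best = min(best, int((pred != labels).sum()))
    return best


def mdmr_bfs(label_sequence) -> int:
    """Shortest adjacent-swap path from a label sequence to either modal
    target (all + first or all - first), by breadth-first search."""
    start = tuple(int(x) for x in label_sequence)
    n_pos = sum(1 for x in start if x == 1)
    n_neg = len(start) - n_pos
    targets = {
        tuple([1] * n_pos + [-1] * n_neg),
        tuple([-1] * n_neg + [1] * n_pos),
    }
    if start in targets:
        return 0
    seen = {start}
    queue = deque([(start, 0)])
    while queue:
        seq, d = queue.popleft()
        for i in range(len(seq) - 1):
            if seq[i] == seq[i + 1]:
                continue
            nxt = list(seq)
            nxt[i], nxt[i + 1] = nxt[i + 1], nxt[i]
            nxt = tuple(nxt)
            if nxt in targets:
                return d + 1
            if nxt not in seen:
                seen.add(nxt)
                queue.append((nxt, d + 1))
    raise AssertionError("unreachable: modal sequence always reachable")


def wepo_pairs(values, labels) -> float:
    """Loop-based wrong-order cross-class z-gap sum, min over orientations."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    mu = values.mean()
    mad = np.abs(values - mu).mean()
    if mad <= 1e-12:
        return 0.0
    z = (values - mu) / mad
    zp = z[labels == 1]
    zn = z[labels == -1]
    pun_pos_first = 0.0  # target: + samples below - samples
    pun_neg_first = 0.0
    for a in zp:
        for b in zn:
            if a > b:
                pun_pos_first += a - b
            elif b > a:
                pun_neg_first += b - a
    return min(pun_pos_first, pun_neg_first)


def _gini_of_split(labels_left, labels_right) -> float:
    total = len(labels_left) + len(labels_right)
    out = 0.0
    for part in (labels_left, labels_right):
        n = len(part)
        if n == 0:
            continue
        p = sum(1 for x in part if x == 1) / n
        out += (n / total) * (1.0 - p * p - (1.0 - p) * (1.0 - p))
    return out


def root_brute(group, values, labels) -> int:
    """Exhaustive (gene, cut, orientation) scan for the best CART root.

    Orientation does not change a split's impurity, so the scan enumerates
    every midpoint threshold of every gene; ties resolve to the lowest gene
    index. Unsplittable (constant) genes score the parent impurity.
    """
    labels = list(labels)
    n = len(labels)
    p = sum(1 for x in labels if x == 1) / n
    parent = 1.0 - p * p - (1.0 - p) * (1.0 - p)
    best_gene, best_imp = None, None
    for gi in sorted(int(i) for i in group):
        row = np.asarray(values[gi], dtype=float)
        distinct = np.unique(row)
        imp = parent
        for a, b in zip(distinct[:-1], distinct[1:]):
            thr = (a + b) / 2.0
            left = [labels[j] for j in range(n) if row[j] <= thr]
            right = [labels[j] for j in range(n) if row[j] > thr]
            imp = min(imp, _gini_of_split(left, right))
        if best_imp is None or imp < best_imp - 1e-15:
            best_gene, best_imp = gi, imp
    return best_gene
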