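"""Two-class expression simulator with planted differentially expressed genes.

Noise genes are i.i.d. Gaussian across all samples; each planted gene's
positive-class mean is shifted by delta standard deviations. Presets emulate
the shapes of the classic leukemia (7129 genes x 72 samples, 47/25 split) and
prostate (12600 genes x 52 tumor + 50 normal, tumor coded -1) benchmark
matrices so every scoring method is testable without external downloads.

Heavier-tailed Student-t noise and per-gene variance jitter are exposed for
robustness checks of the nonparametric scores; the generator makes no attempt
to model probe-level artifacts, batch effects or real microarray noise
spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_data import ExpressionMatrix


@dataclass
class SimSpec:
    """Recipe for one simulated matrix.

    ``planted`` lists (gene index, effect size delta in SD units,
    direction +1/-1): the positive class of that gene is shifted by
    direction * delta * noise_sd.
    """

    n_genes: int
    n_pos: int
    n_neg: int
    planted: tuple[tuple[int, float, int], ...] = ()
    noise_sd: float = 1.0
    baseline_mean: float = 0.0
    seed: int = 0
    noise: str = "gaussian"  # or "t" (Student-t, scaled to unit variance)
    t_df: float = 3.0
    var_jitter: float = 0.0  # lognormal sigma multiplying per-gene SD

    def __post_init__(self) -> None:
        idx = [p[0] for p in self.planted]
        if len(set(idx)) != len(idx):
            raise ValueError("planted gene indices must be unique")
        if any(not 0 <= i < self.n_genes for i in idx):
            raise ValueError("planted gene index out of range")
        if any(p[1] < 0 for p in self.planted):
            raise ValueError("effect sizes must be non-negative")


def simulate(spec: SimSpec) -> tuple[ExpressionMatrix, np.ndarray]:
    """Draw one matrix; returns it with labels attached plus the truth set.

    Columns are ordered positive class (+1) first, then negative (-1).
    Reproducible bit-for-bit from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    g, s = spec.n_genes, spec.n_pos + spec.n_neg
    if spec.noise == "gaussian":
        values = rng.normal(0.0, 1.0, size=(g, s))
    elif spec.noise == "t":
        scale = np.sqrt(spec.t_df / (spec.t_df - 2.0))
        values = rng.standard_t(spec.t_df, size=(g, s)) / scale
    else:
        raise ValueError(f"unknown noise model {spec.noise!r}")
    sd = np.full((g, 1), spec.noise_sd)
    if spec.var_jitter > 0:
        sd = sd * rng.lognormal(0.0, spec.var_jitter, size=(g, 1))
    values = spec.baseline_mean + sd * values
    for idx, delta, direction in spec.planted:
        values[idx, : spec.n_pos] += direction * delta * spec.noise_sd
    labels = np.concatenate([np.ones(spec.n_pos, int), -np.ones(spec.n_neg, int)])
    X = ExpressionMatrix(
        values=values,
        gene_ids=[f"G{i:05d}" for i in range(g)],
        sample_ids=[f"P{i:03d}" for i in range(spec.n_pos)]
        + [f"N{i:03d}" for i in range(spec.n_neg)],
        labels=labels,
    )
    truth = np.array(sorted(p[0] for p in spec.planted), dtype=int)
    return X, truth


def planted_spec(
    n_genes: int = 500,
    n_pos: int = 20,
    n_neg: int = 20,
    n_planted: int = 10,
    delta: float = 2.0,
    seed: int = 0,
    **kwargs,
) -> SimSpec:
    """Standard recovery protocol: n_planted genes at a common effect size,
    scattered at seed-determined indices with alternating shift direction."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9E3779B9]))
    idx = rng.choice(n_genes, size=n_planted, replace=False)
    planted = tuple(
        (int(i), float(delta), 1 if k % 2 == 0 else -1) for k, i in enumerate(idx)
    )
    return SimSpec(n_genes=n_genes, n_pos=n_pos, n_neg=n_neg, planted=planted,
                   seed=seed, **kwargs)


def _preset(n_genes: int, n_pos: int, n_neg: int, seed: int) -> tuple[ExpressionMatrix, np.ndarray]:
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5F3759DF]))
    idx = rng.choice(n_genes, size=30, replace=False)
    deltas = np.linspace(1.0, 3.0, 30)
    planted = tuple(
        (int(i), float(d), 1 if k % 2 == 0 else -1)
        for k, (i, d) in enumerate(zip(idx, deltas))
    )
    return simulate(SimSpec(n_genes=n_genes, n_pos=n_pos, n_neg=n_neg,
                            planted=planted, seed=seed))


def golub_like(seed: int = 0, n_pos: int = 47, n_neg: int = 25) -> tuple[ExpressionMatrix, np.ndarray]:
    """Leukemia-shaped preset: 7129 genes x 72 samples (default 47 ALL / 25 AML),
    30 planted genes with effect sizes spread over [1, 3]."""
    return _preset(7129, n_pos, n_neg, seed)


def singh_like(seed: int = 0) -> tuple[ExpressionMatrix, np.ndarray]:
    """Prostate-shaped preset: 12600 genes x 102 samples, 52 tumor coded -1
    and 50 normal coded +1, 30 planted genes with effect sizes over [1, 3]."""
    X, truth = _preset(12600, 50, 52, seed)
    # normal (+1) first, then tumor (-1); rename samples to match convention
    X.sample_ids = [f"NORMAL{i:03d}" for i in range(50)] + [
        f"TUMOR{i:03d}" for i in range(52)
    ]
    return X, truth
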