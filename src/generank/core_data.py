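"""Expression-matrix container, microarray file formats, and shared normalization.

The in-memory model is a genes x samples real matrix with unique gene and
sample identifiers and an optional binary label vector coded {+1, -1}.
Readers are provided for plain delimited text, GenePattern GCT (versioned
"#1.2" header) and RES (expression/call column pairs), and labels from
GenePattern CLS or a two-column sample/class file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

EPS = 1e-12


class FormatError(ValueError):
    """A file does not parse under the named dialect (header/body mismatch etc.)."""


class DuplicateGeneError(ValueError):
    """Duplicate gene identifiers found where uniqueness is required."""


class ClassDesignError(ValueError):
    """Labels do not describe a two-class design."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix with optional {+1, -1} labels.

    Rows are genes, columns are samples (the GCT/RES convention). ``labels``
    may be ``None`` for an unlabeled matrix; every scoring operation requires
    labels with both classes non-empty.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        g, s = self.values.shape
        if len(self.gene_ids) != g:
            raise ValueError(f"{g} rows but {len(self.gene_ids)} gene ids")
        if len(self.sample_ids) != s:
            raise ValueError(f"{s} columns but {len(self.sample_ids)} sample ids")
        dup = _duplicates(self.gene_ids)
        if dup:
            raise DuplicateGeneError(f"duplicate gene ids: {sorted(dup)}")
        if len(set(self.sample_ids)) != s:
            raise ValueError("sample ids are not unique")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (s,):
                raise ValueError(
                    f"{len(self.labels)} labels attached to a {s}-sample matrix"
                )
            if not np.all(np.isin(self.labels, (-1, 1))):
                raise ValueError("labels must be coded {+1, -1}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def require_labels(self) -> np.ndarray:
        if self.labels is None:
            raise ClassDesignError("operation requires class labels")
        if not ((self.labels == 1).any() and (self.labels == -1).any()):
            raise ClassDesignError("both classes must be non-empty")
        return self.labels

    def with_labels(self, labels: Sequence[int]) -> "ExpressionMatrix":
        """Return a copy with ``labels`` attached (length-checked)."""
        return replace(self, labels=np.asarray(labels, dtype=int))

    def subset_samples(self, indices: Sequence[int]) -> "ExpressionMatrix":
        """Column subset preserving gene ids; labels sliced if present."""
        idx = np.asarray(indices, dtype=int)
        return ExpressionMatrix(
            values=self.values[:, idx],
            gene_ids=list(self.gene_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
            labels=None if self.labels is None else self.labels[idx],
        )

    def subset_genes(self, indices: Sequence[int]) -> "ExpressionMatrix":
        idx = np.asarray(indices, dtype=int)
        return ExpressionMatrix(
            values=self.values[idx],
            gene_ids=[self.gene_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            labels=self.labels,
        )


@dataclass(frozen=True)
class ClassStats:
    """Per-gene class means/SDs and the class sample counts."""

    mu_pos: np.ndarray
    mu_neg: np.ndarray
    sigma_pos: np.ndarray
    sigma_neg: np.ndarray
    m_pos: int
    m_neg: int


@dataclass
class GeneRanking:
    """Per-gene scores plus the direction that marks an informative gene.

    ``order`` sorts genes best-first under ``direction`` with ties broken by
    ascending gene index (stable and deterministic).
    """

    method: str
    scores: np.ndarray
    direction: str  # "higher_better" | "lower_better"
    gene_ids: list[str]
    flags: np.ndarray | None = None  # e.g. degenerate-gene markers

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.direction not in ("higher_better", "lower_better"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if len(self.gene_ids) != len(self.scores):
            raise ValueError("scores and gene_ids length mismatch")

    @property
    def order(self) -> np.ndarray:
        key = -self.scores if self.direction == "higher_better" else self.scores
        return np.lexsort((np.arange(len(key)), key))

    def top(self, n: int) -> list[str]:
        return [self.gene_ids[i] for i in self.order[:n]]

    def top_indices(self, n: int) -> np.ndarray:
        return self.order[:n]

    def to_frame(self) -> pd.DataFrame:
        order = self.order
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(order) + 1),
                "gene_id": [self.gene_ids[i] for i in order],
                "score": self.scores[order],
                "method": self.method,
            }
        )


def write_ranking(ranking: GeneRanking, path: str | Path) -> None:
    ranking.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression I/O


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def _dedup_ids(ids: list[str], policy: str) -> list[str]:
    dup = _duplicates(ids)
    if not dup:
        return ids
    if policy == "error":
        raise DuplicateGeneError(
            f"duplicate gene ids: {sorted(dup)}; pass dedup='suffix' to disambiguate"
        )
    if policy == "suffix":
        counts: dict[str, int] = {}
        out = []
        for x in ids:
            k = counts.get(x, 0)
            out.append(x if k == 0 else f"{x}.{k}")
            counts[x] = k + 1
        return out
    raise ValueError(f"unknown dedup policy {policy!r}")


def read_expression(
    path: str | Path,
    format: str = "delimited",
    *,
    transpose: bool = False,
    dedup: str = "error",
) -> ExpressionMatrix:
    """Read an expression matrix (labels unset).

    ``format`` is one of ``delimited`` (TSV/CSV, first column = gene ids,
    header = sample ids), ``gct`` or ``res``. RES present/absent/marginal
    call columns are discarded. ``transpose`` applies to the delimited
    dialect only (samples-as-rows input).
    """
    path = Path(path)
    if format == "delimited":
        sep = _sniff_delimiter(path)
        df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
        if transpose:
            df = df.T
        gene_ids = _dedup_ids([str(i) for i in df.index], dedup)
        return ExpressionMatrix(df.to_numpy(float), gene_ids, [str(c) for c in df.columns])
    if format == "gct":
        return _read_gct(path, dedup)
    if format == "res":
        return _read_res(path, dedup)
    raise ValueError(f"unknown expression format {format!r}")


def _sniff_delimiter(path: Path) -> str:
    first = open(path).readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def _read_gct(path: Path, dedup: str) -> ExpressionMatrix:
    with open(path) as fh:
        version = fh.readline().strip()
        if not version.startswith("#1.2"):
            raise FormatError(f"{path}: expected '#1.2' GCT header, got {version!r}")
        try:
            n_genes, n_samples = (int(tok) for tok in fh.readline().split())
        except ValueError as exc:
            raise FormatError(f"{path}: malformed GCT dimension line") from exc
        df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    if df.shape[0] != n_genes or df.shape[1] - 2 != n_samples:
        raise FormatError(
            f"{path}: GCT header declares {n_genes}x{n_samples} but body is "
            f"{df.shape[0]}x{df.shape[1] - 2}"
        )
    gene_ids = _dedup_ids([str(x) for x in df.iloc[:, 0]], dedup)
    sample_ids = [str(c) for c in df.columns[2:]]
    return ExpressionMatrix(df.iloc[:, 2:].to_numpy(float), gene_ids, sample_ids)


def _read_res(path: Path, dedup: str) -> ExpressionMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        fh.readline()  # sample description line, unused
        try:
            n_genes = int(fh.readline().strip())
        except ValueError as exc:
            raise FormatError(f"{path}: malformed RES gene-count line") from exc
        body = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    # header: Description, Accession, then each sample id followed by an
    # empty column reserving space for its call flag
    sample_ids = [h for h in header[2:] if h != ""]
    if len(body) != n_genes:
        raise FormatError(f"{path}: RES declares {n_genes} genes but body has {len(body)}")
    gene_ids = _dedup_ids([row[1] for row in body], dedup)
    values = np.array(
        [[float(v) for v in row[2::2]] for row in body], dtype=float
    )
    if values.shape[1] != len(sample_ids):
        raise FormatError(f"{path}: RES value columns do not match sample header")
    return ExpressionMatrix(values, gene_ids, sample_ids)


def write_expression(X: ExpressionMatrix, path: str | Path, format: str = "gct") -> None:
    """Write the matrix as GCT, RES or plain TSV (labels are not written)."""
    path = Path(path)
    if format == "delimited":
        pd.DataFrame(X.values, index=X.gene_ids, columns=X.sample_ids).to_csv(
            path, sep="\t", index_label="gene_id"
        )
        return
    if format == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{X.n_genes}\t{X.n_samples}\n")
            fh.write("Name\tDescription\t" + "\t".join(X.sample_ids) + "\n")
            for i, gid in enumerate(X.gene_ids):
                row = "\t".join(repr(float(v)) for v in X.values[i])
                fh.write(f"{gid}\tna\t{row}\n")
        return
    if format == "res":
        with open(path, "w") as fh:
            fh.write("Description\tAccession\t" + "\t\t".join(X.sample_ids) + "\n")
            fh.write("\n")
            fh.write(f"{X.n_genes}\n")
            for i, gid in enumerate(X.gene_ids):
                cells = "\t".join(f"{float(v)!r}\tP" for v in X.values[i])
                fh.write(f"na\t{gid}\t{cells}\n")
        return
    raise ValueError(f"unknown expression format {format!r}")


# ---------------------------------------------------------------------------
# label I/O


@dataclass(frozen=True)
class LabelSet:
    """A {+1, -1} label vector plus the class-name mapping that produced it."""

    labels: np.ndarray
    mapping: dict[str, int]


def read_labels(
    path: str | Path,
    format: str = "cls",
    *,
    positive_class: str | None = None,
) -> LabelSet:
    """Read binary class labels from a CLS or two-column file.

    Exactly two classes are required. By default the first class name
    encountered maps to +1; pass ``positive_class`` to override (e.g. the
    normal-tissue convention where tumor samples are coded -1).
    """
    path = Path(path)
    if format == "cls":
        names, assignments = _read_cls(path)
    elif format == "two_column":
        df = pd.read_csv(path, sep=None, engine="python", header=None)
        if df.shape[1] != 2:
            raise FormatError(f"{path}: expected two columns (sample, class)")
        assignments = [str(x) for x in df.iloc[:, 1]]
        names = list(dict.fromkeys(assignments))
    else:
        raise ValueError(f"unknown label format {format!r}")
    distinct = list(dict.fromkeys(assignments))
    if len(distinct) != 2:
        raise ClassDesignError(
            f"{path}: two-class design required, found {len(distinct)} classes"
        )
    if positive_class is None:
        positive_class = names[0]
    if positive_class not in distinct:
        raise ClassDesignError(f"positive class {positive_class!r} not among {distinct}")
    mapping = {c: (1 if c == positive_class else -1) for c in distinct}
    labels = np.array([mapping[c] for c in assignments], dtype=int)
    return LabelSet(labels=labels, mapping=mapping)


def _read_cls(path: Path) -> tuple[list[str], list[str]]:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if len(lines) < 3:
        raise FormatError(f"{path}: CLS needs a count line, a '#' name line and labels")
    counts = lines[0].split()
    if len(counts) != 3:
        raise FormatError(f"{path}: malformed CLS count line {lines[0]!r}")
    n_samples, n_classes = int(counts[0]), int(counts[1])
    if not lines[1].startswith("#"):
        raise FormatError(f"{path}: second CLS line must start with '#'")
    names = lines[1][1:].split()
    if len(names) != n_classes:
        raise FormatError(f"{path}: CLS declares {n_classes} classes, names {names}")
    tokens = lines[2].split()
    if len(tokens) != n_samples:
        raise FormatError(
            f"{path}: CLS declares {n_samples} samples but {len(tokens)} labels"
        )
    # third line may use class names or 0-based indices
    if all(t in names for t in tokens):
        assignments = tokens
    else:
        try:
            assignments = [names[int(t)] for t in tokens]
        except (ValueError, IndexError) as exc:
            raise FormatError(f"{path}: CLS labels are neither names nor indices") from exc
    return names, assignments


def write_cls(labels: np.ndarray, path: str | Path, names: tuple[str, str] = ("POS", "NEG")) -> None:
    """Write a GenePattern CLS file; +1 maps to ``names[0]``."""
    labels = np.asarray(labels, dtype=int)
    with open(path, "w") as fh:
        fh.write(f"{len(labels)} 2 1\n")
        fh.write(f"# {names[0]} {names[1]}\n")
        fh.write(" ".join(names[0] if y == 1 else names[1] for y in labels) + "\n")


# ---------------------------------------------------------------------------
# normalization and class statistics


def normalize_genes(X: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene z-normalization: subtract the row mean, divide by the row SD.

    The SD is the population SD (ddof=0). Zero-variance rows map to all
    zeros rather than erroring, so constant probes survive a full-chip scan.
    Labels and identifiers are unchanged.
    """
    if X.n_samples < 2:
        raise ValueError("normalization requires at least 2 samples")
    mu = X.values.mean(axis=1, keepdims=True)
    sd = X.values.std(axis=1, ddof=0, keepdims=True)
    centered = X.values - mu
    out = np.divide(centered, sd, out=np.zeros_like(centered), where=sd > EPS)
    return replace(X, values=out)


def class_stats(X: ExpressionMatrix, ddof: int = 0) -> ClassStats:
    """Per-gene class means and SDs under the requested ddof convention."""
    labels = X.require_labels()
    pos = X.values[:, labels == 1]
    neg = X.values[:, labels == -1]
    m_pos, m_neg = pos.shape[1], neg.shape[1]
    if ddof == 1 and min(m_pos, m_neg) < 2:
        raise ClassDesignError("ddof=1 requires at least 2 samples per class")
    return ClassStats(
        mu_pos=pos.mean(axis=1),
        mu_neg=neg.mean(axis=1),
        sigma_pos=pos.std(axis=1, ddof=ddof),
        sigma_neg=neg.std(axis=1, ddof=ddof),
        m_pos=m_pos,
        m_neg=m_neg,
    )
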