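"""Readers, writers and normalization utilities for expression data.

Supported on-disk formats are deliberately plain text: tab-separated
expression matrices (genes in rows, samples in columns), tab-separated
sample metadata, GMT gene-set catalogs and two-column edge lists.
Gene identifiers are opaque, case-sensitive strings; no probe or symbol
mapping is performed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import networkx as nx

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ("sample_id", "group", "subset", "dose", "replicate")


class ExpressionIOError(ValueError):
    """Raised for malformed expression/metadata/GMT/edge-list inputs."""


@dataclass
class ExpressionMatrix:
    """A gene-by-sample matrix of (log2) expression values.

    Parameters
    ----------
    gene_ids:
        Row identifiers; unique, order defines row order.
    sample_ids:
        Column identifiers; unique, order defines column order.
    values:
        ``(n_genes, n_samples)`` float array; all entries must be finite.
    log_scale:
        Whether values are on a log2 scale.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    log_scale: bool = True

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dup = _first_duplicate(self.gene_ids)
            raise ExpressionIOError(f"duplicate gene id: {dup!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = _first_duplicate(self.sample_ids)
            raise ExpressionIOError(f"duplicate sample id: {dup!r}")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ExpressionIOError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ExpressionIOError("non-finite values in expression matrix")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene not in matrix: {gene_id!r}") from None

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_index(gene_id)]

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.gene_index(g) for g in gene_ids]
        return ExpressionMatrix(
            list(gene_ids), list(self.sample_ids), self.values[idx], self.log_scale
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        idx = []
        for s in sample_ids:
            if s not in pos:
                raise KeyError(f"sample not in matrix: {s!r}")
            idx.append(pos[s])
        return ExpressionMatrix(
            list(self.gene_ids), list(sample_ids), self.values[:, idx], self.log_scale
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    term_name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ExpressionIOError(f"empty gene set: {self.term_id!r}")
        if len(set(self.genes)) != len(self.genes):
            raise ExpressionIOError(f"duplicate members in set {self.term_id!r}")


@dataclass
class GeneSetCatalog:
    """Named gene sets plus an optional background universe size."""

    sets: dict[str, GeneSet] = field(default_factory=dict)
    background_size: int | None = None

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.term_id in self.sets:
            raise ExpressionIOError(f"duplicate term id: {gene_set.term_id!r}")
        self.sets[gene_set.term_id] = gene_set

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())


def _first_duplicate(items: Iterable[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""


def _fmt(v: float) -> str:
    # repr gives the shortest string that round-trips, so write->read->write
    # is byte-stable
    return repr(float(v))


# ---------------------------------------------------------------------------
# expression matrices


def read_expression_tsv(path: str | Path, log_scale: bool = True) -> ExpressionMatrix:
    """Read a gene-by-sample TSV (header row = sample ids, first column = gene ids).

    Any non-numeric value cell, ragged row or duplicate gene id is a hard
    error naming the offending line or id.
    """
    path = Path(path)
    raw = path.read_text(encoding="utf-8").splitlines()
    numbered = [
        (i, ln) for i, ln in enumerate(raw, 1) if ln != "" and not ln.startswith("#")
    ]
    if len(numbered) < 2:
        raise ExpressionIOError(f"{path}: no data rows")
    header = numbered[0][1].split("\t")
    sample_ids = header[1:]
    n_cols = len(header)
    gene_ids: list[str] = []
    seen: set[str] = set()
    rows: list[list[float]] = []
    for lineno, line in numbered[1:]:
        fields = line.split("\t")
        if len(fields) != n_cols:
            raise ExpressionIOError(
                f"{path}:{lineno}: ragged row ({len(fields)} fields, expected {n_cols})"
            )
        gid = fields[0]
        if gid in seen:
            raise ExpressionIOError(f"{path}:{lineno}: duplicate gene id: {gid!r}")
        seen.add(gid)
        try:
            row = [float(v) for v in fields[1:]]
        except ValueError:
            raise ExpressionIOError(
                f"{path}:{lineno}: non-numeric value in row {gid!r}"
            ) from None
        gene_ids.append(gid)
        rows.append(row)
    return ExpressionMatrix(gene_ids, sample_ids, np.array(rows, dtype=float), log_scale)


def write_expression_tsv(
    matrix: ExpressionMatrix, path: str | Path, header_comment: str | None = None
) -> None:
    path = Path(path)
    out: list[str] = []
    if header_comment:
        out.extend(f"# {ln}" for ln in header_comment.splitlines())
    out.append("\t".join(["gene_id", *matrix.sample_ids]))
    for gid, row in zip(matrix.gene_ids, matrix.values):
        out.append("\t".join([gid, *(_fmt(v) for v in row)]))
    path.write_text("\n".join(out) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# sample metadata


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    """Read sample metadata (columns sample_id, group, subset, dose, replicate)."""
    path = Path(path)
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, comment="#")
    missing = [c for c in ("sample_id", "group") if c not in meta.columns]
    if missing:
        raise ExpressionIOError(f"{path}: missing metadata columns: {missing}")
    for col in METADATA_COLUMNS:
        if col not in meta.columns:
            meta[col] = np.nan
    if meta["sample_id"].duplicated().any():
        dup = meta["sample_id"][meta["sample_id"].duplicated()].iloc[0]
        raise ExpressionIOError(f"{path}: duplicate sample id: {dup!r}")
    return meta[list(METADATA_COLUMNS)]


def write_metadata_tsv(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def check_metadata(meta: pd.DataFrame, matrix: ExpressionMatrix) -> None:
    unknown = set(meta["sample_id"]) - set(matrix.sample_ids)
    if unknown:
        raise ExpressionIOError(f"metadata samples not in matrix: {sorted(unknown)}")


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path: str | Path) -> GeneSetCatalog:
    """Read a GMT catalog (term, description, member genes per tab-separated line).

    Duplicate members within one line are dropped with a logged warning;
    duplicate term ids across lines are an error.
    """
    path = Path(path)
    catalog = GeneSetCatalog()
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ExpressionIOError(
                f"{path}:{lineno}: GMT line needs >= 3 fields, got {len(fields)}"
            )
        term_id, term_name, *members = fields
        unique = list(dict.fromkeys(m for m in members if m))
        if len(unique) < len([m for m in members if m]):
            logger.warning(
                "%s:%d: duplicate members in term %r deduplicated", path, lineno, term_id
            )
        if term_id in catalog.sets:
            raise ExpressionIOError(f"{path}:{lineno}: duplicate term id: {term_id!r}")
        catalog.add(GeneSet(term_id, term_name, tuple(unique)))
    if len(catalog) == 0:
        raise ExpressionIOError(f"{path}: no gene sets")
    return catalog


def write_gmt(catalog: GeneSetCatalog, path: str | Path) -> None:
    lines = [
        "\t".join([s.term_id, s.term_name, *s.genes]) for s in catalog
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# gene networks


def read_edge_list(path: str | Path) -> nx.Graph:
    """Read a two-column TSV of gene pairs into a simple undirected graph.

    Self-loops are dropped and duplicate edges collapsed, each with a
    logged warning.  An empty file yields an empty graph.
    """
    path = Path(path)
    graph: nx.Graph = nx.Graph()
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2 or not fields[0] or not fields[1]:
            raise ExpressionIOError(
                f"{path}:{lineno}: malformed edge line (need 2 non-empty fields)"
            )
        u, v = fields
        if u == v:
            logger.warning("%s:%d: self-loop %r dropped", path, lineno, u)
            continue
        if graph.has_edge(u, v):
            logger.warning("%s:%d: duplicate edge %r-%r collapsed", path, lineno, u, v)
            continue
        graph.add_edge(u, v)
    return graph


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    lines = [f"{u}\t{v}" for u, v in sorted(tuple(sorted(e)) for e in graph.edges())]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


# ---------------------------------------------------------------------------
# normalization


def log2_transform(matrix: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """Apply ``v -> log2(v + offset)`` to a linear-scale matrix."""
    if matrix.log_scale:
        raise ExpressionIOError("matrix is already log-scale")
    if offset < 0:
        raise ExpressionIOError("offset must be >= 0")
    if np.any(matrix.values < 0):
        raise ExpressionIOError("negative values cannot be log-transformed")
    if np.any(matrix.values + offset <= 0):
        raise ExpressionIOError("log2 of non-positive value; increase offset")
    return replace(matrix, values=np.log2(matrix.values + offset), log_scale=True)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize samples to the mean of the sorted value vectors.

    After normalization every sample shares the same sorted value vector
    (the column-wise mean of the input sorted vectors).  Ties within a
    sample receive the mean of the reference values their ranks span,
    which keeps the procedure deterministic and idempotent.
    """
    if matrix.n_samples < 2:
        raise ExpressionIOError("quantile normalization needs >= 2 samples")
    values = matrix.values
    n = matrix.n_genes
    reference = np.mean(np.sort(values, axis=0), axis=1)
    csum = np.concatenate([[0.0], np.cumsum(reference)])
    out = np.empty_like(values)
    for j in range(matrix.n_samples):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        ranks_min = np.empty(n, dtype=int)
        ranks_max = np.empty(n, dtype=int)
        sorted_col = col[order]
        # boundaries of tie groups in the sorted column
        start = 0
        for end in range(1, n + 1):
            if end == n or sorted_col[end] != sorted_col[start]:
                ranks_min[order[start:end]] = start + 1
                ranks_max[order[start:end]] = end
                start = end
        out[:, j] = (csum[ranks_max] - csum[ranks_min - 1]) / (
            ranks_max - ranks_min + 1
        )
    return replace(matrix, values=out)
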