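"""Gene-gene similarity matrices and hierarchical clustering.

Similarity is the Spearman rank correlation over samples; the
agglomerative tree is built on the distance ``d = 1 - rho`` (signed, so
anti-correlated genes are maximally distant) with average linkage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .io import ExpressionMatrix


@dataclass
class SimilarityMatrix:
    gene_ids: list[str]
    values: np.ndarray  # symmetric, unit diagonal, rho in [-1, 1]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.gene_ids)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("similarity matrix not symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.gene_ids)


@dataclass
class ClusterTree:
    """Average-linkage merge history plus a flat cut at ``k`` clusters."""

    gene_ids: list[str]
    linkage: np.ndarray  # scipy linkage matrix
    leaf_order: list[str]
    labels: dict[str, int]  # gene -> cluster label (1..k)
    k: int

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for g in self.gene_ids:
            out.setdefault(self.labels[g], []).append(g)
        return out


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation with average ranks for ties.

    A zero-variance vector yields rho 0 by convention (with a warning)
    rather than NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.ndim != 1 or x.size < 3:
        raise ValueError("vectors must be 1-D with length >= 3")
    rx = rankdata(x)
    ry = rankdata(y)
    sx = rx.std()
    sy = ry.std()
    if sx == 0.0 or sy == 0.0:
        warnings.warn("zero-variance vector in spearman_rho; returning 0.0")
        return 0.0
    rho = np.corrcoef(rx, ry)[0, 1]
    return float(np.clip(rho, -1.0, 1.0))


def similarity_matrix(
    matrix: ExpressionMatrix, gene_subset: list[str] | None = None
) -> SimilarityMatrix:
    """Pairwise Spearman rho over samples for the requested genes."""
    genes = list(gene_subset) if gene_subset is not None else list(matrix.gene_ids)
    for g in genes:
        if g not in matrix.gene_ids:
            raise KeyError(f"gene not in matrix: {g!r}")
    sub = matrix.subset_genes(genes)
    ranks = np.apply_along_axis(rankdata, 1, sub.values)
    sd = ranks.std(axis=1)
    degenerate = sd == 0.0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance gene(s); rho set to 0"
        )
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(norms > 0, centered / norms, 0.0)
    rho = np.clip(unit @ unit.T, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    rho[degenerate, :] = 0.0
    rho[:, degenerate] = 0.0
    # degenerate diagonal stays 0 only off-diagonal; keep self-similarity 1
    np.fill_diagonal(rho, 1.0)
    rho = (rho + rho.T) / 2.0
    return SimilarityMatrix(genes, rho)


def hierarchical_clusters(sim: SimilarityMatrix, k: int) -> ClusterTree:
    """Average-linkage agglomeration on ``d = 1 - rho``, cut at ``k`` clusters."""
    n = len(sim.gene_ids)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if n == 1:
        return ClusterTree(sim.gene_ids, np.empty((0, 4)), list(sim.gene_ids), {sim.gene_ids[0]: 1}, 1)
    dist = 1.0 - sim.values
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    condensed = squareform(dist, checks=False)
    linkage = hierarchy.linkage(condensed, method="average")
    flat = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    leaves = hierarchy.leaves_list(linkage)
    labels = {g: int(c) for g, c in zip(sim.gene_ids, flat)}
    leaf_order = [sim.gene_ids[i] for i in leaves]
    return ClusterTree(list(sim.gene_ids), linkage, leaf_order, labels, k)
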