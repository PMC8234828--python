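"""Seed-gene co-expression screen.

Every gene in the matrix is scored against one chosen seed gene with a
(mean-centered) cosine similarity; significance comes from a permutation
null built by shuffling the seed gene's sample order, and the resulting
p-values are Benjamini-Hochberg adjusted.  Genes passing the FDR
threshold are split by the sign of their similarity.

Centering each profile before the cosine makes the statistic identical
to the Pearson correlation; without centering, cosine similarity of
non-negative log intensities can never be negative, so centering is the
default.  The un-centered statistic is available via
``ScreenConfig(center_genes=False)``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

#: permutation counts at or below this enable exhaustive enumeration
EXHAUSTIVE_LIMIT = 5000

SIGN_POSITIVE = "positive"
SIGN_NEGATIVE = "negative"
SIGN_NS = "nonsignificant"


@dataclass
class ScreenConfig:
    """Configuration of a seed-gene screen.

    ``exhaustive=None`` enumerates all sample permutations whenever
    ``n_samples! <= EXHAUSTIVE_LIMIT`` and falls back to Monte-Carlo
    sampling (with replacement) otherwise; ``True``/``False`` force the
    choice.
    """

    seed_gene_id: str
    n_permutations: int = 1000
    fdr_threshold: float = 0.1
    center_genes: bool = True
    rng_seed: int = 0
    two_sided: bool = True
    exhaustive: bool | None = None

    def __post_init__(self) -> None:
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if not 0.0 < self.fdr_threshold < 1.0:
            raise ValueError("fdr_threshold must be in (0, 1)")


@dataclass
class ScreenResult:
    """Outcome of a seed-gene screen.

    ``table`` has one row per non-seed gene with columns
    ``gene_id, similarity, p_value, q_value, sign``, sorted by
    ``q_value`` then descending ``|similarity|`` with lexicographic
    tie-break on gene id.
    """

    seed_gene_id: str
    table: pd.DataFrame
    n_positive: int
    n_negative: int
    config: ScreenConfig

    def genes_with_sign(self, sign: str) -> list[str]:
        return self.table.loc[self.table["sign"] == sign, "gene_id"].tolist()


def centered_cosine(x: np.ndarray, y: np.ndarray) -> float:
    """Cosine similarity of two mean-centered sample vectors.

    Equals the Pearson correlation of ``x`` and ``y``.  Returns 0.0 by
    convention when either centered vector has zero norm.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.ndim != 1 or x.size < 3:
        raise ValueError("vectors must be 1-D with length >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.linalg.norm(xc)
    ny = np.linalg.norm(yc)
    if nx == 0.0 or ny == 0.0:
        return 0.0
    return float(np.clip(xc @ yc / (nx * ny), -1.0, 1.0))


def _unit_rows(values: np.ndarray, center: bool) -> np.ndarray:
    """Row-normalize to unit vectors; zero-variance rows become zero rows."""
    v = values - values.mean(axis=1, keepdims=True) if center else values.copy()
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(norms > 0, v / norms, 0.0)
    return v


def _permutation_indices(
    n_samples: int, config: ScreenConfig
) -> tuple[np.ndarray, bool]:
    """Return a (B, n_samples) array of sample orderings and an exhaustive flag."""
    total = math.factorial(n_samples)
    use_exhaustive = (
        config.exhaustive
        if config.exhaustive is not None
        else total <= EXHAUSTIVE_LIMIT
    )
    if use_exhaustive:
        if total > EXHAUSTIVE_LIMIT:
            raise ValueError(
                f"exhaustive enumeration of {total} permutations exceeds "
                f"limit {EXHAUSTIVE_LIMIT}"
            )
        perms = np.array(list(itertools.permutations(range(n_samples))), dtype=int)
        return perms, True
    rng = np.random.default_rng(config.rng_seed)
    perms = np.array(
        [rng.permutation(n_samples) for _ in range(config.n_permutations)], dtype=int
    )
    return perms, False


def permutation_pvalues(
    matrix: ExpressionMatrix, config: ScreenConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Observed similarities and permutation p-values against the seed gene.

    One shared permutation of the seed profile per iteration is scored
    against all genes, preserving the inter-gene correlation structure.
    Monte-Carlo p-values use the add-one estimate
    ``p = (1 + #{|T_b| >= |T_obs|}) / (1 + B)``; exhaustive p-values are
    exact proportions over all ``n!`` orderings (the identity ordering
    guarantees ``p >= 1/n!``).  Returns arrays aligned with
    ``matrix.gene_ids`` (the seed gene included, ``p = 1`` there).
    """
    if config.seed_gene_id not in matrix.gene_ids:
        raise KeyError(f"seed gene not in matrix: {config.seed_gene_id!r}")
    if matrix.n_samples < 4:
        raise ValueError("screen needs >= 4 samples")
    unit = _unit_rows(matrix.values, config.center_genes)
    seed_unit = unit[matrix.gene_index(config.seed_gene_id)]
    t_obs = unit @ seed_unit
    t_obs = np.clip(t_obs, -1.0, 1.0)

    perms, exhaustive = _permutation_indices(matrix.n_samples, config)
    b = perms.shape[0]
    # (genes x samples) @ (samples x B) -> null statistics per gene per draw
    t_null = unit @ seed_unit[perms].T
    tol = 1e-12
    if config.two_sided:
        exceed = np.abs(t_null) >= np.abs(t_obs)[:, None] - tol
    else:
        exceed = t_null >= t_obs[:, None] - tol
    counts = exceed.sum(axis=1)
    if exhaustive:
        p = counts / b
    else:
        p = (1.0 + counts) / (1.0 + b)
    # degenerate zero-variance genes: T = 0, p = 1 by convention
    zero = ~np.any(unit, axis=1)
    p[zero] = 1.0
    return t_obs, p


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``q_(i) = min_{j >= i} min(1, p_(j) * m / j)`` over the sorted
    p-values; the mapping is order-preserving.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a non-empty 1-D array")
    if np.any(~np.isfinite(p)) or np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def run_seed_screen(matrix: ExpressionMatrix, config: ScreenConfig) -> ScreenResult:
    """Run the full screen: similarity, permutation p, BH q, sign split.

    The seed gene is excluded from the result table (its self-similarity
    is trivially 1).
    """
    t_obs, p = permutation_pvalues(matrix, config)
    seed_idx = matrix.gene_index(config.seed_gene_id)
    keep = np.arange(matrix.n_genes) != seed_idx
    gene_ids = [g for i, g in enumerate(matrix.gene_ids) if keep[i]]
    t_obs, p = t_obs[keep], p[keep]
    q = bh_adjust(p)
    sign = np.where(
        (q < config.fdr_threshold) & (t_obs > 0),
        SIGN_POSITIVE,
        np.where((q < config.fdr_threshold) & (t_obs < 0), SIGN_NEGATIVE, SIGN_NS),
    )
    table = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "similarity": t_obs,
            "p_value": p,
            "q_value": q,
            "sign": sign,
        }
    )
    table = _sort_table(table).reset_index(drop=True)
    n_pos = int((table["sign"] == SIGN_POSITIVE).sum())
    n_neg = int((table["sign"] == SIGN_NEGATIVE).sum())
    return ScreenResult(config.seed_gene_id, table, n_pos, n_neg, config)


def _sort_table(table: pd.DataFrame) -> pd.DataFrame:
    tmp = table.assign(_abs=table["similarity"].abs())
    tmp = tmp.sort_values(
        by=["q_value", "_abs", "gene_id"], ascending=[True, False, True], kind="stable"
    )
    return tmp.drop(columns="_abs")
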