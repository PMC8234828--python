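"""Group contrasts and dose-response trend tests.

``welch_contrast`` is a deliberately plain per-gene Welch two-sample t
on log2 values (no variance moderation) — a documented stand-in for
moderated linear-model tests, adequate for synthetic-data validation.

``dose_trend`` tests for a monotone dose-response with the Spearman
correlation between expression and log10(dose), with significance from
permuting the sample-to-dose assignment.  (A Jonckheere-Terpstra test
would be a reasonable alternative; the rank-correlation permutation
test was chosen for its symmetry with the co-expression screen.)
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata, t as t_dist

from .io import ExpressionMatrix
from .screen import EXHAUSTIVE_LIMIT, bh_adjust


@dataclass
class DoseTrendConfig:
    n_permutations: int = 1000
    rng_seed: int = 0
    alpha: float = 0.05
    exhaustive: bool | None = None

    def __post_init__(self) -> None:
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


def welch_contrast(
    matrix: ExpressionMatrix,
    metadata: pd.DataFrame,
    group_pair: tuple[str, str],
) -> pd.DataFrame:
    """Per-gene Welch t-test between two groups.

    Returns columns ``gene_id, lfc, t, df, p_value, q_value, degenerate``
    where ``lfc`` is mean(group2) - mean(group1) on the log2 scale.
    Genes with zero variance in both groups get ``p = 1`` and are
    flagged degenerate.
    """
    g1, g2 = group_pair
    known = set(metadata["group"])
    for g in group_pair:
        if g not in known:
            raise ValueError(f"unknown group label: {g!r}")
    ids1 = metadata.loc[metadata["group"] == g1, "sample_id"].tolist()
    ids2 = metadata.loc[metadata["group"] == g2, "sample_id"].tolist()
    if len(ids1) < 2 or len(ids2) < 2:
        raise ValueError("each group needs >= 2 samples")
    x1 = matrix.subset_samples(ids1).values
    x2 = matrix.subset_samples(ids2).values
    n1, n2 = x1.shape[1], x2.shape[1]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)
    lfc = m2 - m1
    se2 = v1 / n1 + v2 / n2
    degenerate = se2 == 0.0
    ws_denom = (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_stat = np.where(degenerate, 0.0, lfc / np.sqrt(np.where(se2 > 0, se2, 1.0)))
        df = np.where(degenerate, 1.0, se2**2 / np.where(ws_denom > 0, ws_denom, 1.0))
    p = np.where(degenerate, 1.0, 2.0 * t_dist.sf(np.abs(t_stat), df))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    table = pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "lfc": lfc,
            "t": t_stat,
            "df": df,
            "p_value": p,
            "q_value": bh_adjust(p),
            "degenerate": degenerate,
        }
    )
    return table


def _trend_permutations(n: int, config: DoseTrendConfig) -> tuple[np.ndarray, bool]:
    total = math.factorial(n)
    use_exhaustive = (
        config.exhaustive if config.exhaustive is not None else total <= EXHAUSTIVE_LIMIT
    )
    if use_exhaustive:
        if total > EXHAUSTIVE_LIMIT:
            raise ValueError(
                f"exhaustive enumeration of {total} permutations exceeds "
                f"limit {EXHAUSTIVE_LIMIT}"
            )
        return np.array(list(itertools.permutations(range(n))), dtype=int), True
    rng = np.random.default_rng(config.rng_seed)
    return (
        np.array([rng.permutation(n) for _ in range(config.n_permutations)], dtype=int),
        False,
    )


def dose_trend(
    matrix: ExpressionMatrix,
    metadata: pd.DataFrame,
    config: DoseTrendConfig | None = None,
) -> pd.DataFrame:
    """Per-gene Spearman trend of expression against log10(dose).

    Significance comes from permuting the sample-to-dose assignment
    (shared permutations across genes; add-one two-sided p for
    Monte-Carlo, exact proportion when exhaustive).  Returns columns
    ``gene_id, rho, p_value, q_value, direction`` with direction
    ``down``/``up`` for genes significant at ``config.alpha`` and
    ``none`` otherwise.
    """
    if config is None:
        config = DoseTrendConfig()
    meta = metadata.set_index("sample_id").loc[matrix.sample_ids]
    doses = meta["dose"].to_numpy(dtype=float)
    if np.any(~np.isfinite(doses)):
        raise ValueError("all samples need a dose for a trend test")
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    if len(np.unique(doses)) < 3:
        raise ValueError("need >= 3 distinct dose levels")
    x = np.log10(doses)
    rx = rankdata(x)
    rx_c = rx - rx.mean()
    rx_unit = rx_c / np.linalg.norm(rx_c)

    ranks = np.apply_along_axis(rankdata, 1, matrix.values)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    degenerate = (norms == 0).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(norms > 0, centered / norms, 0.0)
    rho = np.clip(unit @ rx_unit, -1.0, 1.0)

    perms, exhaustive = _trend_permutations(matrix.n_samples, config)
    rho_null = unit @ rx_unit[perms].T
    tol = 1e-12
    counts = (np.abs(rho_null) >= np.abs(rho)[:, None] - tol).sum(axis=1)
    if exhaustive:
        p = counts / perms.shape[0]
    else:
        p = (1.0 + counts) / (1.0 + perms.shape[0])
    p[degenerate] = 1.0
    rho[degenerate] = 0.0
    q = bh_adjust(p)
    direction = np.where(
        (p < config.alpha) & (rho < 0),
        "down",
        np.where((p < config.alpha) & (rho > 0), "up", "none"),
    )
    return pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "rho": rho,
            "p_value": p,
            "q_value": q,
            "direction": direction,
        }
    )
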