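"""Transcriptomic-cohort handling: quantile normalization, quartile splits
and per-gene log fold-changes between extreme quartiles.

Public transcriptomic validation cohorts arrive as normalized expression
matrices rather than qPCR Ct tables; after quantile normalization the clock
math of :mod:`gamclock.clock` applies unchanged (the residual ratio
``sigma/a`` does not depend on the expression scale).  Subjects ranked by
chronological age or by the clock readout are split into extreme quartiles
and genes summarized by the difference of group means on the log2 scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "QuartileSplit",
    "quantile_normalize",
    "quartile_split",
    "group_logfc",
]


@dataclass
class QuartileSplit:
    """Extreme-quartile membership by a ranking variable (CA or the clock)."""

    q1: list       # lowest floor(n/4) subjects
    q4: list       # highest floor(n/4) subjects
    ranking_variable: str


def quantile_normalize(matrix: pd.DataFrame,
                       standardize: bool = False) -> pd.DataFrame:
    """Classic quantile normalization of a genes x samples matrix.

    Each column (sample) is forced onto the across-sample mean of the order
    statistics: rank k in every column maps to the mean of all columns' k-th
    smallest values.  Tied values receive the mean of their mapped values
    (average ranks), so the transform is idempotent.  ``standardize``
    additionally z-scores each row (gene) afterwards.
    """
    if matrix.size == 0:
        raise ValueError("empty matrix")
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    arr = matrix.to_numpy(dtype=float)
    mean_sorted = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        order = np.argsort(arr[:, j], kind="stable")
        col = np.empty(arr.shape[0])
        col[order] = mean_sorted
        # tied input values get the mean of their mapped order statistics
        ranks = sps.rankdata(arr[:, j], method="average")
        col = pd.Series(col).groupby(ranks).transform("mean").to_numpy()
        out[:, j] = col
    res = pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    if standardize:
        mu = res.mean(axis=1)
        sd = res.std(axis=1, ddof=0).replace(0, np.nan)
        res = res.sub(mu, axis=0).div(sd, axis=0)
    return res


def quartile_split(values: pd.Series,
                   ranking_variable: str = "ca") -> QuartileSplit:
    """Lowest and highest floor(n/4) subjects by the ranking variable.

    The sort is stable, so tied subjects keep their input order (documented
    tie-break).  Requires n >= 8 so each extreme quartile has >= 2 members.
    """
    n = len(values)
    if n < 8:
        raise ValueError("need at least 8 subjects for a quartile split")
    k = n // 4
    order = values.iloc[np.argsort(values.to_numpy(), kind="stable")]
    return QuartileSplit(q1=list(order.index[:k]), q4=list(order.index[-k:]),
                         ranking_variable=ranking_variable)


def group_logfc(matrix: pd.DataFrame, split: QuartileSplit,
                log2_transform: bool = False,
                offset: float = 1.0) -> pd.Series:
    """Per-gene log2 fold-change between extreme quartiles (Q4 minus Q1).

    ``matrix`` is samples x genes on the log2 scale; set ``log2_transform``
    to apply ``log2(x + offset)`` first for linear-scale input.  Positive
    values mean higher expression in the high-ranked (elderly) quartile.
    """
    if len(split.q1) == 0 or len(split.q4) == 0:
        raise ValueError("both quartile groups must be non-empty")
    m = matrix
    if log2_transform:
        m = np.log2(m + offset)
    return (m.loc[split.q4].mean(axis=0)
            - m.loc[split.q1].mean(axis=0)).rename("logfc")
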