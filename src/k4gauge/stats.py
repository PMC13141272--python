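"""Rank-test machinery shared by the transcriptome summaries.

The exact small-sample Mann-Whitney test enumerates the permutation null of
the U statistic conditional on the observed values (so ties are handled
exactly); larger samples fall back to the tie-corrected normal
approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

EXACT_MAX_N = 8  # enumerate when both groups are at most this size


@dataclass
class MannWhitneyResult:
    u: float
    p: float
    n1: int
    n2: int
    method: str  # "exact" | "asymptotic"


def u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for the first sample: #{x > y} pairs, counting ties as 1/2."""
    x = np.asarray(x, dtype=float)[:, None]
    y = np.asarray(y, dtype=float)[None, :]
    return float((x > y).sum() + 0.5 * (x == y).sum())


def mann_whitney(x, y, exact_max_n: int = EXACT_MAX_N) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    Exact permutation enumeration when both samples have at most
    ``exact_max_n`` observations, tie-corrected normal approximation
    otherwise.  The two-sided exact p is twice the smaller tail probability
    of U, capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("both samples must be non-empty")
    u_obs = u_statistic(x, y)

    if n <= exact_max_n and m <= exact_max_n:
        pooled = np.concatenate([x, y])
        gt = (pooled[:, None] > pooled[None, :]) + 0.5 * (pooled[:, None] == pooled[None, :])
        # G[i,j] + G[j,i] = 1 for i != j and G[i,i] = 1/2, so the within-subset
        # pair sum of any n-subset is the constant n^2/2: U(subset) reduces to
        # the subset's score sum minus that constant.
        scores = gt.sum(axis=1)
        const = n * n / 2.0
        us = np.fromiter((scores[list(c)].sum() - const
                          for c in combinations(range(n + m), n)),
                         dtype=float)
        eps = 1e-9
        lower = np.mean(us <= u_obs + eps)
        upper = np.mean(us >= u_obs - eps)
        p = min(1.0, 2.0 * min(lower, upper))
        return MannWhitneyResult(u=u_obs, p=float(p), n1=n, n2=m, method="exact")

    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return MannWhitneyResult(u=float(res.statistic), p=float(res.pvalue),
                             n1=n, n2=m, method="asymptotic")
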