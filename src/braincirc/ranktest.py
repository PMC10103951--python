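"""Shared two-sided Mann-Whitney U core.

Small samples (up to 16 pooled observations, which covers any pair of groups
of 8 or fewer each) are evaluated by exhaustive enumeration of
all group labelings of the pooled observations, with midranks for ties; the
two-sided p is the fraction of labelings whose U deviates from the null mean
n1*n2/2 at least as much as the observed U.  Larger samples use the normal
approximation with tie correction (scipy).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

EXACT_POOLED_LIMIT = 16


@dataclass(frozen=True)
class RankTestResult:
    statistic: float  # U for the first group
    pvalue: float
    method: str  # "exact" | "asymptotic"


def _u_from_ranks(rank_sum: float, n1: int) -> float:
    return rank_sum - n1 * (n1 + 1) / 2


def mann_whitney(a, b) -> RankTestResult:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    if n1 + n2 <= EXACT_POOLED_LIMIT:
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)  # midranks under ties
        u_obs = _u_from_ranks(ranks[:n1].sum(), n1)
        center = n1 * n2 / 2
        dev_obs = abs(u_obs - center)
        hits = total = 0
        for idx in combinations(range(n1 + n2), n1):
            u = _u_from_ranks(ranks[list(idx)].sum(), n1)
            total += 1
            if abs(u - center) >= dev_obs - 1e-12:
                hits += 1
        return RankTestResult(float(u_obs), hits / total, "exact")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return RankTestResult(float(res.statistic), float(res.pvalue), "asymptotic")
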