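"""Exact two-sided Mann–Whitney / Wilcoxon rank-sum test for small samples.

With five subjects per group the normal approximation is unreliable, so the
null distribution of the rank sum is obtained by complete enumeration of
all C(n+m, n) assignments of the pooled midranks to the first group.  Ties
are handled by midranks in both the observed statistic and the enumerated
null, so a fully tied sample gives p = 1 exactly.
"""

from __future__ import annotations

from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = ["rank_sum_test"]

_MAX_TOTAL = 20  # enumeration regime; C(20, 10) = 184 756 assignments


def rank_sum_test(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Exact two-sided rank-sum test.

    Returns ``(U, p)`` where ``U`` is the Mann–Whitney statistic of
    ``group_a`` (number of (a, b) pairs with a > b, ties counted half) and
    ``p`` the exact two-sided tail probability: the fraction of all equally
    likely rank assignments whose statistic is at least as far from the
    null mean n*m/2 as the observed one.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n, m = a.size, b.size
    if n == 0 or m == 0:
        raise ValueError("both groups must be non-empty")
    if n + m > _MAX_TOTAL:
        raise ValueError(
            f"exact enumeration supports at most {_MAX_TOTAL} observations"
        )
    ranks = rankdata(np.concatenate([a, b]))
    r_a = float(ranks[:n].sum())
    u_obs = r_a - n * (n + 1) / 2.0
    center = n * m / 2.0
    dist_obs = abs(u_obs - center)

    hits = 0
    offset = n * (n + 1) / 2.0
    for idx in combinations(range(n + m), n):
        u = ranks[list(idx)].sum() - offset
        if abs(u - center) >= dist_obs - 1e-12:
            hits += 1
    p = hits / comb(n + m, n)
    return u_obs, p
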