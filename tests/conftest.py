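"""Shared test helpers: independent brute-force oracles.

These oracles deliberately avoid the library code paths they check:
the Fisher oracle enumerates hypergeometric probabilities directly, and the
rank-sum oracle enumerates all group assignments.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pytest


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration over fixed margins.

    Sums hypergeometric probabilities of all tables with the observed margins
    whose probability is <= (1 + 1e-7) x P(observed).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    def prob(x: int) -> float:
        return comb(r1, x) * comb(r2, c1 - x) / denom
    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return min(1.0, sum(prob(x) for x in range(lo, hi + 1)
                        if prob(x) <= p_obs * (1.0 + 1e-7)))


def rank_sum_two_sided_permutation(a, b) -> float:
    """Two-sided rank-sum p by full enumeration of group assignments (no ties)."""
    pooled = np.concatenate([a, b])
    assert np.unique(pooled).size == pooled.size, "oracle assumes no ties"
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    m, n = len(a), len(b)
    mid = m * n / 2.0
    def ustat(group) -> float:
        w = sum(ranks[v] for v in group)
        return w - m * (m + 1) / 2.0
    u_obs = abs(ustat(a) - mid)
    count = total = 0
    for idx in combinations(range(m + n), m):
        group = pooled[list(idx)]
        total += 1
        if abs(ustat(group) - mid) >= u_obs - 1e-12:
            count += 1
    return count / total


@pytest.fixture
def fisher_oracle():
    return fisher_two_sided_enumeration


@pytest.fixture
def rank_sum_oracle():
    return rank_sum_two_sided_permutation
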