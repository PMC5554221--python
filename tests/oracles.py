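"""Independent brute-force oracles used across the test suite.

Each oracle recomputes a quantity from first principles (exhaustive
enumeration, exact combinatorics, closed forms) without touching the
implementation under test.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np


def brute_unanimity_support(states: dict[str, np.ndarray], members: tuple[str, ...]) -> float:
    """Fraction of samples where every member shares one nonzero state."""
    sub = np.array([states[t] for t in members])
    n = sub.shape[1]
    hits = 0
    for j in range(n):
        col = sub[:, j]
        if col[0] != 0 and (col == col[0]).all():
            hits += 1
    return hits / n


def brute_mine(states: dict[str, np.ndarray], min_support: float, max_size: int):
    """All TF sets (size <= max_size) with unanimity support >= min_support,
    ordered by (size, members)."""
    tfs = sorted(states)
    out = []
    for size in range(1, max_size + 1):
        for mem in combinations(tfs, size):
            sup = brute_unanimity_support(states, mem)
            if sup >= min_support:
                out.append((mem, sup))
    out.sort(key=lambda x: (len(x[0]), x[0]))
    return out


def brute_discrete_score(g: np.ndarray, a_states: np.ndarray, i_states: np.ndarray) -> float:
    """Mean |gene - sign(a - i)| / 2 evaluated sample by sample."""
    total = 0.0
    for j in range(g.size):
        p = np.sign(a_states[j] - i_states[j])
        total += abs(int(g[j]) - p)
    return total / (2.0 * g.size)


def hypergeom_tail_exact(overlap: int, universe: int, successes: int, draws: int) -> float:
    """P(X >= overlap) by exact integer combinatorics."""
    if overlap <= 0:
        return 1.0
    total = comb(universe, draws)
    num = sum(
        comb(successes, k) * comb(universe - successes, draws - k)
        for k in range(overlap, min(successes, draws) + 1)
    )
    return num / total


def order_stat_tail(r: float, k: int, n: int) -> float:
    """P(U_(k) <= r) for n iid uniforms, via the exact binomial sum
    sum_{j>=k} C(n, j) r^j (1-r)^(n-j) -- independent of any Beta CDF."""
    return float(sum(comb(n, j) * r**j * (1 - r) ** (n - j) for j in range(k, n + 1)))


def brute_rho(norm_ranks) -> float:
    """min over k of P(U_(k) <= r_(k)) from the binomial-sum tail."""
    r = sorted(norm_ranks)
    n = len(r)
    return min(order_stat_tail(r[k - 1], k, n) for k in range(1, n + 1))


def brute_segment(x: np.ndarray, k: int):
    """Exhaustive best k-segmentation of samples-by-dims matrix x:
    returns (cost, boundaries) minimizing within-segment squared deviation."""
    n = x.shape[0]

    def seg_cost(i, j):
        seg = x[i:j]
        return float(((seg - seg.mean(axis=0)) ** 2).sum())

    best = (np.inf, None)
    for cuts in combinations(range(1, n), k - 1):
        bounds = (0,) + cuts + (n,)
        c = sum(seg_cost(bounds[i], bounds[i + 1]) for i in range(k))
        if c < best[0] - 1e-12:
            best = (c, list(cuts))
    return best
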