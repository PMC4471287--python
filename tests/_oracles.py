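"""Independent reference implementations used to validate the package.

These oracles are deliberately naive (exhaustive enumeration, pairwise
linkage) and share no code with the implementations they check.
"""

from itertools import combinations

import numpy as np


def hypergeom_tail_by_enumeration(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by enumerating every size-n draw from an N-item urn with K
    successes. Only feasible for small N."""
    items = [1] * K + [0] * (N - K)
    total = 0
    hits = 0
    for draw in combinations(range(N), n):
        total += 1
        if sum(items[i] for i in draw) >= k:
            hits += 1
    return hits / total


def clusters_by_pairwise_linkage(positions, max_gap=50, min_sites=2):
    """Single-linkage clustering of 1-D positions: any two sites within
    max_gap of each other join the same component; components with fewer
    than min_sites sites are discarded. Returns sorted tuples of positions."""
    pos = sorted(positions)
    n = len(pos)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    for i in range(n):
        for j in range(i + 1, n):
            if abs(pos[j] - pos[i]) <= max_gap:
                union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(pos[i])
    out = [tuple(sorted(g)) for g in groups.values() if len(g) >= min_sites]
    return sorted(out)


def welch_statistic_by_formula(a, b):
    """Textbook Welch statistic and Welch-Satterthwaite df, written directly
    from the formula with python floats."""
    a = list(map(float, a))
    b = list(map(float, b))
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / se2**0.5
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, df


def monte_carlo_hypergeom_tail(rng: np.random.Generator, N, K, n, k, reps=100_000):
    """Empirical P(X >= k) from urn draws, with its standard error."""
    draws = rng.hypergeometric(K, N - K, n, size=reps)
    p_hat = float(np.mean(draws >= k))
    se = (p_hat * (1 - p_hat) / reps) ** 0.5
    return p_hat, se
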