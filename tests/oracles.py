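"""Independent brute-force oracles for the graph-metric tests.

Everything here is deliberately naive — triple-loop Floyd-Warshall,
exhaustive path enumeration with a length bound, explicit triangle loops —
and shares no code with the package implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np

REL_TIE_TOL = 1e-12


def floyd_warshall(weights: np.ndarray) -> np.ndarray:
    """Triple-loop all-pairs shortest path lengths on length = 1/weight."""
    n = weights.shape[0]
    d = np.full((n, n), math.inf)
    for i in range(n):
        d[i, i] = 0.0
    for i in range(n):
        for j in range(n):
            if weights[i, j] > 0:
                d[i, j] = 1.0 / weights[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def enumerate_shortest_paths(weights: np.ndarray, s: int, t: int, d_st: float):
    """All simple s-t paths whose length ties the shortest, by bounded DFS.

    Prefixes longer than d_st (plus a relative tie tolerance) are pruned;
    edge lengths are positive, so the bound is valid. Returns the list of
    tied shortest paths (as node tuples).
    """
    if not math.isfinite(d_st):
        return []
    bound = d_st * (1 + REL_TIE_TOL) + 1e-300
    n = weights.shape[0]
    paths = []
    stack = [(s, (s,), 0.0)]
    while stack:
        node, path, length = stack.pop()
        if node == t:
            if length >= d_st * (1 - REL_TIE_TOL) - 1e-300:
                paths.append(path)
            continue
        for nxt in range(n):
            if weights[node, nxt] > 0 and nxt not in path:
                new_len = length + 1.0 / weights[node, nxt]
                if new_len <= bound:
                    stack.append((nxt, path + (nxt,), new_len))
    return paths


def betweenness(weights: np.ndarray) -> np.ndarray:
    """Unnormalized betweenness via exhaustive tied-path enumeration."""
    n = weights.shape[0]
    d = floyd_warshall(weights)
    b = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = enumerate_shortest_paths(weights, s, t, d[s, t])
            if not paths:
                continue
            sigma = len(paths)
            for path in paths:
                for v in path[1:-1]:
                    b[v] += 1.0 / sigma
    return b


def onnela_clustering(weights: np.ndarray) -> np.ndarray:
    """Explicit loop over all (j, h) neighbor pairs."""
    n = weights.shape[0]
    wmax = weights.max()
    c = np.zeros(n)
    if wmax == 0:
        return c
    for i in range(n):
        k = int((weights[i] > 0).sum())
        if k < 2:
            continue
        total = 0.0
        for j in range(n):
            for h in range(n):
                if j == i or h == i or j == h:
                    continue
                total += (
                    (weights[i, j] / wmax)
                    * (weights[i, h] / wmax)
                    * (weights[j, h] / wmax)
                ) ** (1.0 / 3.0)
        c[i] = total / (k * (k - 1))
    return c


def global_efficiency(weights: np.ndarray) -> float:
    d = floyd_warshall(weights)
    n = d.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and math.isfinite(d[i, j]) and d[i, j] > 0:
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def regional_efficiency(weights: np.ndarray) -> np.ndarray:
    d = floyd_warshall(weights)
    n = d.shape[0]
    e = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j and math.isfinite(d[i, j]) and d[i, j] > 0:
                e[i] += 1.0 / d[i, j]
    return e / (n - 1)


def vulnerability(weights: np.ndarray) -> np.ndarray:
    n = weights.shape[0]
    e_full = global_efficiency(weights)
    out = np.zeros(n)
    for i in range(n):
        keep = [j for j in range(n) if j != i]
        sub = weights[np.ix_(keep, keep)]
        out[i] = e_full - global_efficiency(sub)
    return out


def exact_permutation_p(a, b, side: str) -> float:
    """Exact one-tailed permutation p by full enumeration of assignments."""
    import itertools

    pooled = list(a) + list(b)
    n_a = len(a)
    observed = np.mean(a) - np.mean(b)
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n_a):
        ga = [pooled[i] for i in comb]
        gb = [pooled[i] for i in range(len(pooled)) if i not in comb]
        diff = np.mean(ga) - np.mean(gb)
        total += 1
        if side == "greater" and diff >= observed:
            count += 1
        if side == "less" and diff <= observed:
            count += 1
    return count / total


def bh_stepup(p_values, q: float):
    """Hand execution of the Benjamini-Hochberg step-up rule."""
    p = sorted(p_values)
    m = len(p)
    k_star = 0
    for k in range(1, m + 1):
        if p[k - 1] <= k * q / m:
            k_star = k
    if k_star == 0:
        return [False] * m, 0.0
    thresh = p[k_star - 1]
    return [pv <= thresh for pv in p_values], thresh
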