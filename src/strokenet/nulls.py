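"""Matched random networks and normalized small-world quantities.

Surrogates preserve the number of nodes, the number of edges, and the exact
degree sequence by double-edge swaps on the binary topology; the original
multiset of edge weights is then randomly permuted onto the rewired edge
set. Total weight is preserved; the per-node strength sequence is not — the
null keeps topology-level structure matched while scrambling which
connections are strong.

Small-worldness sigma = gamma / lambda, where gamma = C / <C_rand> and
lambda = L / <L_rand> over an ensemble of (by default 100) such surrogates.
sigma > 1 is the small-world signature: clustering well above the matched
random level at a near-random path length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import ConnectivityMatrix
from .metrics import (
    _efficiency_from_distances,
    local_clustering,
    shortest_path_lengths,
)

log = logging.getLogger(__name__)


def _clustering_and_cpl(m: ConnectivityMatrix) -> tuple[float, float]:
    """Mean clustering and characteristic path length (1/E_glob) only —
    the two quantities the null ensemble needs; betweenness and
    vulnerability are skipped for speed."""
    c = float(local_clustering(m).mean())
    eglob = _efficiency_from_distances(shortest_path_lengths(m))
    return c, (1.0 / eglob if eglob > 0 else np.inf)


@dataclass
class SmallWorldResult:
    gamma: float
    lam: float
    sigma: float
    n_random: int
    c_rand_mean: float
    l_rand_mean: float
    #: per-surrogate values, for ensemble standard errors
    c_rand: np.ndarray = field(repr=False, default=None)
    l_rand: np.ndarray = field(repr=False, default=None)


def rewire_preserving_degree(
    m: ConnectivityMatrix, swaps_per_edge: int = 10, rng_seed: int | np.random.SeedSequence = 0
) -> ConnectivityMatrix:
    """Degree-preserving randomization by double-edge swaps.

    Picks two edges (a,b), (c,d) and rewires to (a,d), (c,b) when that
    creates no self-loop or duplicate edge; each accepted swap preserves
    every node's degree exactly. Runs ``swaps_per_edge * n_edges`` accepted
    swaps (a conventional mixing burn-in), with a bounded retry budget: on
    pathological graphs where the budget runs out, the partially randomized
    network is returned and the achieved swap count logged.

    The weight multiset is then permuted uniformly onto the new edge set.
    """
    rng = np.random.default_rng(rng_seed)
    ii, jj = np.nonzero(np.triu(m.weights, k=1))
    n_edges = len(ii)
    if n_edges < 2:
        raise ValueError("rewiring requires at least 2 edges")
    edges = np.stack([ii, jj], axis=1)
    present = set(map(tuple, edges))
    target = swaps_per_edge * n_edges
    max_tries = 100 * target
    done = tries = 0
    chunk = max(1024, 4 * target)
    pair_buf = rng.integers(0, n_edges, size=(chunk, 2))
    flip_buf = rng.integers(0, 2, size=chunk)
    buf_pos = 0
    while done < target and tries < max_tries:
        if buf_pos >= chunk:
            pair_buf = rng.integers(0, n_edges, size=(chunk, 2))
            flip_buf = rng.integers(0, 2, size=chunk)
            buf_pos = 0
        e1, e2 = pair_buf[buf_pos]
        flip = flip_buf[buf_pos]
        buf_pos += 1
        tries += 1
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        # randomize which endpoints pair up
        if flip:
            c, d = d, c
        if a == d or c == b or a == c or b == d:
            continue
        new1 = (min(a, d), max(a, d))
        new2 = (min(c, b), max(c, b))
        if new1 in present or new2 in present:
            continue
        present.discard((min(a, b), max(a, b)))
        present.discard(tuple(sorted((edges[e2][0], edges[e2][1]))))
        present.add(new1)
        present.add(new2)
        edges[e1] = new1
        edges[e2] = new2
        done += 1
    if done < target:
        log.warning("rewiring stopped early: %d of %d swaps achieved", done, target)
    weights = m.weights[ii, jj]
    perm = rng.permutation(n_edges)
    out = np.zeros_like(m.weights)
    out[edges[:, 0], edges[:, 1]] = weights[perm]
    out = out + out.T
    return ConnectivityMatrix(out, m.atlas)


def small_worldness(
    m: ConnectivityMatrix,
    n_random: int = 100,
    rng_seed: int | np.random.SeedSequence = 0,
    swaps_per_edge: int = 10,
) -> SmallWorldResult:
    """Normalized clustering, path length, and small-worldness.

    One master seed deterministically spawns per-surrogate seeds, so
    results are reproducible and the ensemble is order-independent.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    c_obs, l_obs = _clustering_and_cpl(m)
    if not np.isfinite(l_obs):
        raise ValueError("characteristic path length is infinite; graph too disconnected")
    seq = (
        rng_seed
        if isinstance(rng_seed, np.random.SeedSequence)
        else np.random.SeedSequence(rng_seed)
    )
    c_rand = np.empty(n_random)
    l_rand = np.empty(n_random)
    for k, child in enumerate(seq.spawn(n_random)):
        surrogate = rewire_preserving_degree(m, swaps_per_edge=swaps_per_edge, rng_seed=child)
        c_rand[k], l_rand[k] = _clustering_and_cpl(surrogate)
    c_mean = float(c_rand.mean())
    l_mean = float(l_rand.mean())
    if c_mean == 0 or l_mean == 0 or not np.isfinite(l_mean):
        raise ValueError("degenerate null: surrogate clustering or path length unusable")
    gamma = c_obs / c_mean
    lam = l_obs / l_mean
    return SmallWorldResult(
        gamma=gamma,
        lam=lam,
        sigma=gamma / lam,
        n_random=n_random,
        c_rand_mean=c_mean,
        l_rand_mean=l_mean,
        c_rand=c_rand,
        l_rand=l_rand,
    )
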