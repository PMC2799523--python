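"""Brute-force reference implementations used only to check the package.

These deliberately share no code with restgraph: clustering by explicit
triangle enumeration, geodesics by Floyd–Warshall, efficiencies by pair
enumeration, and BH-FDR by the literal step-up definition.
"""

from itertools import combinations

import numpy as np


def clustering_by_enumeration(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    c = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(1 for a, b in combinations(nbrs, 2) if adj[a, b])
        c[i] = links / (k * (k - 1) / 2)
    return c


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = np.where(adj, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def mean_path_length(adj: np.ndarray) -> float:
    """L over unordered pairs of the largest connected component."""
    d = floyd_warshall(adj)
    n = adj.shape[0]
    # largest component by reachability
    comps = []
    seen = set()
    for i in range(n):
        if i in seen:
            continue
        comp = {j for j in range(n) if np.isfinite(d[i, j])}
        seen |= comp
        comps.append(sorted(comp))
    comp = max(comps, key=len)
    if len(comp) < 2:
        return float("nan")
    vals = [d[i, j] for i, j in combinations(comp, 2)]
    return float(np.mean(vals))


def global_efficiency_by_pairs(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n < 2:
        return 0.0
    d = floyd_warshall(adj)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]) and d[i, j] > 0:
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def local_efficiency_by_pairs(adj: np.ndarray) -> float:
    n = adj.shape[0]
    vals = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        if len(nbrs) < 2:
            vals.append(0.0)
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        vals.append(global_efficiency_by_pairs(sub))
    return float(np.mean(vals))


def bh_stepup(p: np.ndarray, q: float) -> np.ndarray:
    """Literal Benjamini–Hochberg step-up: reject all i <= i*."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    below = [i for i in range(m) if sorted_p[i] <= (i + 1) / m * q]
    reject = np.zeros(m, dtype=bool)
    if below:
        reject[order[: max(below) + 1]] = True
    return reject
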