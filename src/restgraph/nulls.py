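"""Degree-preserving null models and small-world analysis.

Random reference networks are produced by Markov-chain double-edge
swaps (Maslov–Sneppen rewiring): pick two edges (a,b), (c,d) with four
distinct endpoints and (a,d), (c,b) absent, and replace them by
(a,d), (c,b).  This preserves every node's degree exactly while
randomizing topology.  Ensembles of rewired graphs supply the
normalized small-world indices γ = C/C_rand, λ = L/L_rand and
σ = γ/λ, and the efficiency comparisons that delimit the small-world
threshold regime.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix, ThresholdSpec, binarize
from .graph import BinaryGraph
from .metrics import (
    NetworkMetrics,
    clustering,
    global_efficiency,
    largest_component_size,
    local_efficiency,
    network_metrics,
    path_lengths,
)

logger = logging.getLogger(__name__)

try:  # compiled swap kernel; the pure-Python loop below is the reference
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "NullEnsembleSummary",
    "SmallWorldIndices",
    "RegimeResult",
    "maslov_rewire",
    "null_ensemble",
    "small_world_indices",
    "theoretical_random",
    "identify_regime",
    "sweep_metrics",
    "make_grid",
]


@dataclass(frozen=True)
class NullEnsembleSummary:
    n_random: int
    mean_C_rand: float
    mean_L_rand: float
    mean_Eglob_rand: float
    mean_Eloc_rand: float
    C_rand: np.ndarray
    L_rand: np.ndarray
    Eglob_rand: np.ndarray
    Eloc_rand: np.ndarray


@dataclass(frozen=True)
class SmallWorldIndices:
    gamma: float
    lam: float
    sigma: float


@dataclass(frozen=True)
class RegimeResult:
    """Outcome of the threshold sweep for the small-world regime.

    ``diagnostics`` holds one row per threshold: K, largest component,
    the ensemble efficiency means, and the per-criterion booleans.
    ``t_min``/``t_max`` bound the maximal contiguous run of in-regime
    thresholds (None when the regime is empty).
    """

    t_grid: np.ndarray
    t_min: float | None
    t_max: float | None
    k_min: float | None
    k_max: float | None
    diagnostics: pd.DataFrame

    @property
    def is_empty(self) -> bool:
        return self.t_min is None


def _swap_loop_python(
    adj: np.ndarray, edges: np.ndarray, n_swaps: int, max_tries: int, seed: int
) -> int:
    """Reference implementation of the double-edge-swap Markov chain."""
    rng = np.random.RandomState(seed)
    m = edges.shape[0]
    successes = 0
    tries = 0
    while successes < n_swaps and tries < max_tries:
        tries += 1
        e1 = rng.randint(m)
        e2 = rng.randint(m)
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if rng.randint(2) == 1:
            c, d = d, c
        # propose (a,b),(c,d) -> (a,d),(c,b)
        if a == c or a == d or b == c or b == d:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = adj[b, a] = False
        adj[c, d] = adj[d, c] = False
        adj[a, d] = adj[d, a] = True
        adj[c, b] = adj[b, c] = True
        edges[e1] = (a, d)
        edges[e2] = (c, b)
        successes += 1
    return successes


if _HAVE_NUMBA:

    @_njit(cache=False)
    def _swap_loop_compiled(adj, edges, n_swaps, max_tries, seed):  # pragma: no cover
        np.random.seed(seed)
        m = edges.shape[0]
        successes = 0
        tries = 0
        while successes < n_swaps and tries < max_tries:
            tries += 1
            e1 = np.random.randint(m)
            e2 = np.random.randint(m)
            if e1 == e2:
                continue
            a, b = edges[e1, 0], edges[e1, 1]
            c, d = edges[e2, 0], edges[e2, 1]
            if np.random.randint(2) == 1:
                c, d = d, c
            if a == c or a == d or b == c or b == d:
                continue
            if adj[a, d] or adj[c, b]:
                continue
            adj[a, b] = False
            adj[b, a] = False
            adj[c, d] = False
            adj[d, c] = False
            adj[a, d] = True
            adj[d, a] = True
            adj[c, b] = True
            adj[b, c] = True
            edges[e1, 0] = a
            edges[e1, 1] = d
            edges[e2, 0] = c
            edges[e2, 1] = b
            successes += 1
        return successes


def maslov_rewire(
    graph: BinaryGraph,
    n_swaps: int | None = None,
    seed: int | np.random.SeedSequence | None = None,
    max_tries_factor: int = 20,
) -> BinaryGraph:
    """Randomize a graph by degree-preserving double-edge swaps.

    *n_swaps* counts successful swaps (default 10× the edge count, a
    common convergence heuristic).  Proposals that would create a
    self-loop or a duplicate edge are rejected.  The procedure stops
    early after ``max_tries_factor``·n_swaps attempts — graphs with
    few legal swaps (e.g. near-complete ones) then come back only
    partially randomized, and a graph with no edges to swap is
    returned unchanged with a logged notice.

    The swap loop runs through a compiled kernel when numba is
    importable and otherwise through an identical pure-Python loop;
    results are deterministic per seed within either backend.
    """
    m = graph.n_edges
    if m < 2:
        logger.info("fewer than 2 edges; returning input unchanged")
        return graph
    if n_swaps is None:
        n_swaps = 10 * m
    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    scalar_seed = int(seq.generate_state(1)[0] % np.uint32(2**31))
    adj = np.array(graph.adjacency, dtype=bool)
    edges = graph.edge_array().astype(np.int64)
    loop = _swap_loop_compiled if _HAVE_NUMBA else _swap_loop_python
    successes = int(loop(adj, edges, n_swaps, max_tries_factor * n_swaps, scalar_seed))
    if successes == 0:
        logger.info("no legal swap found; returning input unchanged")
        return graph
    if successes < n_swaps:
        logger.debug("rewiring stalled after %d of %d swaps", successes, n_swaps)
    return BinaryGraph(adj, graph.labels)


def null_ensemble(
    graph: BinaryGraph,
    n_random: int = 100,
    seed: int | np.random.SeedSequence | None = None,
    n_swaps: int | None = None,
    measures: tuple[str, ...] = ("clustering", "paths", "efficiency"),
) -> NullEnsembleSummary:
    """Metrics over an ensemble of independently rewired realizations.

    *measures* limits which metric families are evaluated (skipping
    local efficiency is the main saving); unevaluated summaries are
    NaN.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = seq.spawn(n_random)
    c_vals = np.full(n_random, np.nan)
    l_vals = np.full(n_random, np.nan)
    eg_vals = np.full(n_random, np.nan)
    el_vals = np.full(n_random, np.nan)
    for i, child in enumerate(children):
        rand = maslov_rewire(graph, n_swaps=n_swaps, seed=child)
        if "clustering" in measures:
            _, c_vals[i] = clustering(rand)
        if "paths" in measures:
            # disconnection in a rewired realization is expected, not a
            # data problem worth a user-facing warning
            _, l_vals[i] = path_lengths(rand, on_disconnected="largest", warn=False)
        if "efficiency" in measures:
            eg_vals[i] = global_efficiency(rand)
            el_vals[i] = local_efficiency(rand)
    def _mean(vals: np.ndarray) -> float:
        return float(np.nanmean(vals)) if np.isfinite(vals).any() else float("nan")

    return NullEnsembleSummary(
        n_random=n_random,
        mean_C_rand=_mean(c_vals),
        mean_L_rand=_mean(l_vals),
        mean_Eglob_rand=_mean(eg_vals),
        mean_Eloc_rand=_mean(el_vals),
        C_rand=c_vals,
        L_rand=l_vals,
        Eglob_rand=eg_vals,
        Eloc_rand=el_vals,
    )


def small_world_indices(
    metrics: NetworkMetrics, nulls: NullEnsembleSummary
) -> SmallWorldIndices:
    """γ = C_net/C_rand, λ = L_net/L_rand, σ = γ/λ; σ > 1 is small-world."""
    if not nulls.mean_C_rand > 0 or not nulls.mean_L_rand > 0:
        raise ValueError("null ensemble means must be positive")
    gamma = metrics.C_net / nulls.mean_C_rand
    lam = metrics.L_net / nulls.mean_L_rand
    return SmallWorldIndices(gamma=gamma, lam=lam, sigma=gamma / lam)


def theoretical_random(K: float, N: int) -> tuple[float, float]:
    """Erdős–Rényi expectations C_rand = K/N and L_rand = ln N / ln K."""
    if K <= 1:
        raise ValueError("K must exceed 1")
    if N <= K:
        raise ValueError("N must exceed K")
    return K / N, float(np.log(N) / np.log(K))


def make_grid(start: float, stop: float, step: float) -> np.ndarray:
    """Inclusive grid: stop is kept when it falls within half a step."""
    return np.arange(start, stop + step / 2.0, step)


def identify_regime(
    z_matrix: ConnectivityMatrix,
    t_step: float = 0.005,
    n_random: int = 20,
    seed: int | None = None,
    k_min: float | None = None,
    n_swaps_factor: int = 10,
) -> RegimeResult:
    """Sweep |z| thresholds and delimit the small-world regime.

    A threshold T is in-regime iff the binarized graph (a) is fully
    connected, (b) stays sparse-but-dense-enough with mean degree
    K ≥ 2·ln(N) (≈ 9.0 for N = 90), and (c) has lower global and
    higher local efficiency than its degree-matched rewired ensemble
    (strict inequalities; ties fail).  The maximal contiguous run of
    in-regime thresholds gives [t_min, t_max] and the matching K range.
    """
    n = z_matrix.n_regions
    if k_min is None:
        k_min = 2.0 * np.log(n)
    zvals = np.abs(z_matrix.z)
    z_top = float(zvals[np.triu_indices(n, k=1)].max())
    t_grid = make_grid(t_step, max(z_top, t_step), t_step)
    seq = np.random.SeedSequence(seed)
    t_seeds = seq.spawn(len(t_grid))

    rows = []
    for t, t_seed in zip(t_grid, t_seeds):
        g = binarize(z_matrix, ThresholdSpec("z_value", float(t)))
        comp = largest_component_size(g)
        mean_k = 2.0 * g.n_edges / n
        row = dict(
            threshold=float(t),
            K=mean_k,
            largest_component=comp,
            connected=comp == n,
            dense_enough=mean_k >= k_min,
            E_glob=np.nan,
            E_loc=np.nan,
            Eglob_rand=np.nan,
            Eloc_rand=np.nan,
            efficiency_ok=False,
        )
        if row["connected"] and row["dense_enough"]:
            nulls = null_ensemble(
                g,
                n_random=n_random,
                seed=t_seed,
                n_swaps=n_swaps_factor * g.n_edges,
                measures=("efficiency",),
            )
            e_glob = global_efficiency(g)
            e_loc = local_efficiency(g)
            row.update(
                E_glob=e_glob,
                E_loc=e_loc,
                Eglob_rand=nulls.mean_Eglob_rand,
                Eloc_rand=nulls.mean_Eloc_rand,
                efficiency_ok=(e_glob < nulls.mean_Eglob_rand)
                and (e_loc > nulls.mean_Eloc_rand),
            )
        row["in_regime"] = row["connected"] and row["dense_enough"] and row["efficiency_ok"]
        rows.append(row)
    diagnostics = pd.DataFrame(rows)

    in_regime = diagnostics["in_regime"].to_numpy()
    if not in_regime.any():
        return RegimeResult(t_grid, None, None, None, None, diagnostics)
    # maximal contiguous run of True
    best_start = best_len = cur_start = cur_len = 0
    for i, flag in enumerate(in_regime):
        if flag:
            if cur_len == 0:
                cur_start = i
            cur_len += 1
            if cur_len > best_len:
                best_start, best_len = cur_start, cur_len
        else:
            cur_len = 0
    run = diagnostics.iloc[best_start : best_start + best_len]
    return RegimeResult(
        t_grid,
        float(run["threshold"].iloc[0]),
        float(run["threshold"].iloc[-1]),
        float(run["K"].min()),
        float(run["K"].max()),
        diagnostics,
    )


def sweep_metrics(
    matrices: list[ConnectivityMatrix],
    grid: np.ndarray,
    grid_mode: str = "threshold",
    n_random: int = 20,
    seed: int | None = None,
    matrix_ids: list[str] | None = None,
    with_nulls: bool = True,
) -> pd.DataFrame:
    """Topology metrics (and small-world indices) along a grid.

    *grid_mode* ``threshold`` treats the grid as |z| cuts; ``degree``
    as target mean degrees.  Returns a long-format frame with one row
    per (matrix, grid point).
    """
    if grid_mode not in ("threshold", "degree"):
        raise ValueError(f"unknown grid_mode {grid_mode!r}")
    if matrix_ids is None:
        matrix_ids = [
            m.tag if m.tag is not None else f"matrix-{i}" for i, m in enumerate(matrices)
        ]
    seq = np.random.SeedSequence(seed)
    rows = []
    for mat_id, matrix in zip(matrix_ids, matrices):
        for point in np.asarray(grid, dtype=float):
            mode = "z_value" if grid_mode == "threshold" else "target_mean_degree"
            g = binarize(matrix, ThresholdSpec(mode, float(point)))
            met = network_metrics(g)
            row = dict(
                matrix_id=mat_id,
                grid_mode=grid_mode,
                grid_value=float(point),
                K=met.K,
                C_net=met.C_net,
                L_net=met.L_net,
                E_glob=met.E_glob,
                E_loc=met.E_loc,
                n_edges=met.n_edges,
                largest_component=met.largest_component_size,
            )
            if with_nulls and g.n_edges >= 2:
                child = seq.spawn(1)[0]
                nulls = null_ensemble(
                    g, n_random=n_random, seed=child,
                    measures=("clustering", "paths"),
                )
                if nulls.mean_C_rand > 0 and nulls.mean_L_rand > 0 and np.isfinite(met.L_net):
                    idx = small_world_indices(met, nulls)
                    row.update(gamma=idx.gamma, lam=idx.lam, sigma=idx.sigma)
                else:
                    row.update(gamma=np.nan, lam=np.nan, sigma=np.nan)
            else:
                row.update(gamma=np.nan, lam=np.nan, sigma=np.nan)
            rows.append(row)
    return pd.DataFrame(rows)
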