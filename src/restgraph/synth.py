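"""Synthetic two-group cohort generator and benchmark graphs.

Everything downstream of raw image reconstruction is testable against
this module: it produces region-of-interest (ROI) time series for two
groups of subjects with a known, block-modular correlation structure,
planted group differences on chosen edges, serially correlated noise,
low-frequency drift, nuisance reference signals, and 6-parameter head
motion traces with a configurable number of excludable subjects.

The default configuration mirrors the study conditions the package is
designed around: 18 "patient" vs 27 "control" subjects, 210 time
points at TR = 2 s, 90 regions in six anatomical blocks, and ten
planted edge effects of |Δr| = 0.3 — increases inside the medial
temporal block, decreases within and between the frontal and
parietal-(pre)motor blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .graph import BinaryGraph
from .regions import FRONTAL, MEDIAL_TEMPORAL, PARIETAL_PREMOTOR, load_region_table

__all__ = [
    "CohortConfig",
    "PlantedEffect",
    "PlantedEffectMap",
    "SubjectRecord",
    "Cohort",
    "make_benchmark_graph",
    "default_planted_effects",
    "build_group_covariance",
    "nearest_correlation",
    "simulate_cohort",
    "backbone_correlation",
]


# ---------------------------------------------------------------------------
# benchmark graphs


def make_benchmark_graph(
    kind: str,
    n: int,
    k: int | None = None,
    p: float | None = None,
    seed: int | None = None,
) -> BinaryGraph:
    """Construct a deterministic benchmark graph.

    Supported kinds: ``ring_lattice`` (each node tied to k/2 neighbours
    on each side), ``watts_strogatz`` (lattice with each edge rewired
    with probability p), ``erdos_renyi``, ``complete``, ``path``,
    ``star``.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    if kind in ("ring_lattice", "watts_strogatz"):
        if k is None or k % 2 != 0 or k >= n or k <= 0:
            raise ValueError("k must be even, positive, and < n")
    if kind == "ring_lattice":
        g = nx.watts_strogatz_graph(n, k, 0.0)
    elif kind == "watts_strogatz":
        if p is None or not 0.0 <= p <= 1.0:
            raise ValueError("p must lie in [0, 1]")
        g = nx.watts_strogatz_graph(n, k, p, seed=seed)
    elif kind == "erdos_renyi":
        if p is None or not 0.0 <= p <= 1.0:
            raise ValueError("p must lie in [0, 1]")
        g = nx.gnp_random_graph(n, p, seed=seed)
    elif kind == "complete":
        g = nx.complete_graph(n)
    elif kind == "path":
        g = nx.path_graph(n)
    elif kind == "star":
        g = nx.star_graph(n - 1)
    else:
        raise ValueError(f"unknown benchmark graph kind {kind!r}")
    return BinaryGraph(nx.to_numpy_array(g, nodelist=range(n), dtype=bool))


# ---------------------------------------------------------------------------
# configuration and record types


@dataclass(frozen=True)
class PlantedEffect:
    """One planted group difference: r(i, j) shifted by delta_r in group b."""

    i: int
    j: int
    delta_r: float

    @property
    def sign(self) -> int:
        return 1 if self.delta_r > 0 else -1


@dataclass(frozen=True)
class CohortConfig:
    n_group_a: int = 27
    n_group_b: int = 18
    n_timepoints: int = 210
    tr_seconds: float = 2.0
    base_correlation_within_block: float = 0.35
    base_correlation_between_block: float = 0.10
    planted_effects: tuple[PlantedEffect, ...] | None = None
    ar_coefficient: float = 0.3
    drift_amplitude: float = 0.5
    nuisance_coupling: float = 0.2
    n_motion_violators: int = 0
    psd_tolerance: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_group_a <= 0 or self.n_group_b <= 0 or self.n_timepoints <= 0:
            raise ValueError("subject counts and n_timepoints must be positive")
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise ValueError("ar_coefficient must lie in [0, 1)")
        if self.n_motion_violators > self.n_group_a + self.n_group_b:
            raise ValueError("more motion violators than subjects")


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    group: str  # "a" or "b"
    timeseries: np.ndarray  # n_timepoints x 90
    motion: np.ndarray  # n_timepoints x 6 (mm, mm, mm, deg, deg, deg)
    nuisance: np.ndarray  # n_timepoints x 2 (ventricle, white matter)
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.timeseries.ndim != 2:
            raise ValueError("timeseries must be 2-D")
        if self.motion.shape != (self.timeseries.shape[0], 6):
            raise ValueError("motion must be n_timepoints x 6")
        if np.isnan(self.timeseries).any() or np.isnan(self.motion).any():
            raise ValueError("missing values are not allowed")


@dataclass(frozen=True)
class PlantedEffectMap:
    """Ground truth: planted edges plus both groups' target correlations."""

    effects: tuple[PlantedEffect, ...]
    target_a: np.ndarray
    target_b: np.ndarray

    def target(self, group: str) -> np.ndarray:
        if group == "a":
            return self.target_a
        if group == "b":
            return self.target_b
        raise ValueError(f"unknown group {group!r}")

    def edge_set(self) -> set[tuple[int, int]]:
        return {(min(e.i, e.j), max(e.i, e.j)) for e in self.effects}


@dataclass(frozen=True)
class Cohort:
    subjects: tuple[SubjectRecord, ...]
    truth: PlantedEffectMap
    violator_ids: tuple[str, ...]
    config: CohortConfig


# ---------------------------------------------------------------------------
# target covariance construction


def default_planted_effects(
    region_table: pd.DataFrame | None = None, delta_r: float = 0.3
) -> tuple[PlantedEffect, ...]:
    """Ten planted edges emulating the expected group-difference pattern.

    Five increases inside the medial temporal block, concentrated on
    the two hippocampi (three incident edges each) so that node-level
    total-connectivity (Γ) elevation is recoverable, not just the
    individual edges; five decreases within and between the frontal
    and parietal-(pre)motor blocks, concentrated on the left precuneus
    and right middle frontal gyrus.
    """
    table = load_region_table() if region_table is None else region_table
    idx = {abbr: i for i, abbr in enumerate(table["abbreviation"])}
    increases = [
        ("lHIP", "lAMYG"),
        ("lHIP", "lPHIP"),
        ("lHIP", "rHIP"),
        ("rHIP", "rAMYG"),
        ("rHIP", "rPHIP"),
    ]
    decreases = [
        ("lPCUN", "lPCC"),
        ("lPCUN", "lSFGmed"),
        ("lPCUN", "lIPG"),
        ("rMFG", "rSFG"),
        ("rMFG", "rIPG"),
    ]
    effects = [PlantedEffect(idx[a], idx[b], +delta_r) for a, b in increases]
    effects += [PlantedEffect(idx[a], idx[b], -delta_r) for a, b in decreases]
    lobe = table["lobe_group"]
    for eff, (a, b) in zip(effects[:5], increases):
        assert lobe[eff.i] == lobe[eff.j] == MEDIAL_TEMPORAL, (a, b)
    for eff in effects[5:]:
        assert {lobe[eff.i], lobe[eff.j]} <= {FRONTAL, PARIETAL_PREMOTOR}
    return tuple(effects)


def gamma_elevation_regions(
    region_table: pd.DataFrame | None = None,
    effects: tuple[PlantedEffect, ...] | None = None,
) -> np.ndarray:
    """Regions whose planted increases should elevate Γ (>= 2 incident)."""
    table = load_region_table() if region_table is None else region_table
    if effects is None:
        effects = default_planted_effects(table)
    counts = np.zeros(len(table), dtype=int)
    for e in effects:
        if e.delta_r > 0:
            counts[e.i] += 1
            counts[e.j] += 1
    return np.flatnonzero(counts >= 2)


def nearest_correlation(
    matrix: np.ndarray, eig_floor: float = 1e-8, max_shift: float | None = None
) -> np.ndarray:
    """Project a symmetric matrix to the nearest valid correlation matrix.

    Eigenvalues are clipped at *eig_floor*, the matrix is rebuilt and
    renormalized to unit diagonal.  If *max_shift* is given and any
    entry moves by more than that amount, a ``ValueError`` is raised:
    the requested structure was too far from positive semi-definite.
    """
    m = np.asarray(matrix, dtype=float)
    m = 0.5 * (m + m.T)
    vals, vecs = np.linalg.eigh(m)
    repaired = (vecs * np.clip(vals, eig_floor, None)) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    repaired = 0.5 * (repaired + repaired.T)
    if max_shift is not None:
        shift = np.max(np.abs(repaired - m))
        if shift > max_shift:
            raise ValueError(
                f"PSD repair moved an entry by {shift:.4f} > tolerance {max_shift}"
            )
    return repaired


def _block_base_matrix(table: pd.DataFrame, within: float, between: float) -> np.ndarray:
    lobe = table["lobe_group"].to_numpy()
    same_block = lobe[:, None] == lobe[None, :]
    base = np.where(same_block, within, between).astype(float)
    np.fill_diagonal(base, 1.0)
    return base


def build_group_covariance(
    region_table: pd.DataFrame | None = None,
    config: CohortConfig | None = None,
) -> PlantedEffectMap:
    """Build both groups' target correlation matrices.

    Group a carries the block-modular base structure; group b is
    identical except on the planted edges, where r is shifted by each
    effect's delta_r.  Both matrices are repaired to positive
    semi-definiteness (eigenvalue clipping) and the repair is rejected
    if it moves any entry by more than ``config.psd_tolerance``.
    """
    table = load_region_table() if region_table is None else region_table
    cfg = config if config is not None else CohortConfig()
    effects = (
        cfg.planted_effects
        if cfg.planted_effects is not None
        else default_planted_effects(table)
    )
    base = _block_base_matrix(
        table, cfg.base_correlation_within_block, cfg.base_correlation_between_block
    )
    shifted = base.copy()
    for eff in effects:
        if eff.i == eff.j:
            raise ValueError("planted effect on the diagonal")
        r_new = base[eff.i, eff.j] + eff.delta_r
        if abs(r_new) >= 1.0:
            raise ValueError(
                f"planted shift pushes |r| to {abs(r_new):.3f} >= 1 on edge "
                f"({eff.i}, {eff.j})"
            )
        shifted[eff.i, eff.j] = shifted[eff.j, eff.i] = r_new
    target_a = nearest_correlation(base, max_shift=cfg.psd_tolerance)
    target_b = nearest_correlation(shifted, max_shift=cfg.psd_tolerance)
    return PlantedEffectMap(tuple(effects), target_a, target_b)


def backbone_correlation(
    graph: BinaryGraph, r_edge: float = 0.4, r_gap: float = 0.05,
    psd_tolerance: float = 0.25,
) -> np.ndarray:
    """Correlation matrix whose strong entries follow a graph backbone.

    Useful for building cohorts with a prescribed topology (e.g. a
    small-world backbone).  The raw two-level matrix is usually not
    PSD, so a looser repair tolerance applies than for block models.
    """
    a = graph.adjacency
    m = np.where(a, r_edge, r_gap).astype(float)
    np.fill_diagonal(m, 1.0)
    return nearest_correlation(m, max_shift=psd_tolerance)


# ---------------------------------------------------------------------------
# time-series simulation


def _simulate_timeseries(
    rng: np.random.Generator, target: np.ndarray, cfg: CohortConfig
) -> np.ndarray:
    """AR(1) process with stationary cross-correlation equal to *target*."""
    n_t, n_r = cfg.n_timepoints, target.shape[0]
    chol = np.linalg.cholesky(target + 1e-10 * np.eye(n_r))
    innov = rng.standard_normal((n_t, n_r)) @ chol.T
    phi = cfg.ar_coefficient
    x = np.empty_like(innov)
    x[0] = innov[0]
    scale = np.sqrt(1.0 - phi * phi)
    for t in range(1, n_t):
        x[t] = phi * x[t - 1] + scale * innov[t]
    return x


def _drift(rng: np.random.Generator, cfg: CohortConfig, n_regions: int) -> np.ndarray:
    """Linear trend plus a 0.005 Hz sinusoid, per region."""
    if cfg.drift_amplitude == 0.0:
        return np.zeros((cfg.n_timepoints, n_regions))
    t = np.arange(cfg.n_timepoints) * cfg.tr_seconds
    ramp = (t - t.mean()) / max(t.max() - t.min(), 1e-12)
    slopes = rng.uniform(-1.0, 1.0, size=n_regions)
    phases = rng.uniform(0.0, 2 * np.pi, size=n_regions)
    amps = rng.uniform(0.5, 1.0, size=n_regions)
    sinus = np.sin(2 * np.pi * 0.005 * t[:, None] + phases[None, :]) * amps[None, :]
    return cfg.drift_amplitude * (ramp[:, None] * slopes[None, :] + sinus)


def _smooth_walk(rng: np.random.Generator, n: int, window: int = 11) -> np.ndarray:
    steps = rng.standard_normal(n + window)
    walk = np.cumsum(steps)
    kernel = np.ones(window) / window
    smoothed = np.convolve(walk, kernel, mode="valid")[:n]
    return smoothed - smoothed[0]


def _motion_trace(
    rng: np.random.Generator, n_t: int, violator: bool
) -> np.ndarray:
    """Six smooth random-walk axes, referenced to the first frame.

    Non-violators peak well below the 1 mm / 1 deg exclusion limits;
    a violator exceeds the limit on exactly one randomly chosen axis.
    """
    trace = np.empty((n_t, 6))
    peaks = rng.uniform(0.05, 0.5, size=6)
    hot_axis = int(rng.integers(6)) if violator else -1
    if violator:
        peaks[hot_axis] = rng.uniform(1.1, 1.6)
    for axis in range(6):
        walk = _smooth_walk(rng, n_t)
        top = np.max(np.abs(walk))
        trace[:, axis] = walk * (peaks[axis] / top if top > 0 else 0.0)
    return trace


def _nuisance_signals(rng: np.random.Generator, cfg: CohortConfig) -> np.ndarray:
    """Ventricle and white-matter reference signals (AR(1) noise)."""
    sig = np.empty((cfg.n_timepoints, 2))
    for col in range(2):
        eps = rng.standard_normal(cfg.n_timepoints)
        out = np.empty_like(eps)
        out[0] = eps[0]
        for t in range(1, cfg.n_timepoints):
            out[t] = 0.5 * out[t - 1] + eps[t] * np.sqrt(0.75)
        sig[:, col] = out
    return sig


def simulate_cohort(
    config: CohortConfig | None = None,
    region_table: pd.DataFrame | None = None,
) -> Cohort:
    """Simulate the full two-group cohort.

    Returns the subject records together with the ground-truth ledger
    (planted edges, target matrices, motion-violator ids).  The output
    is a pure function of the configuration: the same config (including
    seed) reproduces the cohort exactly.
    """
    cfg = config if config is not None else CohortConfig()
    table = load_region_table() if region_table is None else region_table
    truth = build_group_covariance(table, cfg)

    n_total = cfg.n_group_a + cfg.n_group_b
    root = np.random.SeedSequence(cfg.seed)
    assign_rng = np.random.default_rng(root.spawn(1)[0])
    violator_slots = set(
        assign_rng.choice(n_total, size=cfg.n_motion_violators, replace=False).tolist()
    )
    subject_seeds = root.spawn(n_total)

    subjects: list[SubjectRecord] = []
    violator_ids: list[str] = []
    for s in range(n_total):
        group = "a" if s < cfg.n_group_a else "b"
        rng = np.random.default_rng(subject_seeds[s])
        ts = _simulate_timeseries(rng, truth.target(group), cfg)
        ts += _drift(rng, cfg, ts.shape[1])
        nuis = _nuisance_signals(rng, cfg)
        ts += cfg.nuisance_coupling * nuis.sum(axis=1, keepdims=True)
        violator = s in violator_slots
        motion = _motion_trace(rng, cfg.n_timepoints, violator)
        if group == "b":  # the patient-like group carries clinical covariates
            covars = {
                "epilepsy_duration_years": round(float(rng.uniform(2.0, 30.0)), 1),
                "seizure_frequency_per_month": round(float(rng.uniform(1.0, 10.0)), 1),
            }
        else:
            covars = {}
        subject_id = f"sub-{s + 1:03d}"
        if violator:
            violator_ids.append(subject_id)
        subjects.append(
            SubjectRecord(subject_id, group, ts, motion, nuis, covars)
        )
    return Cohort(tuple(subjects), truth, tuple(violator_ids), cfg)
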