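"""Correlation matrices, Fisher-z inference, thresholding, and graph I/O.

Pearson correlation between every pair of ROI time series gives a
symmetric r matrix per subject; Fisher's r-to-z transform stabilises
its variance.  Under independence z·sqrt(L − 3) is approximately
standard normal (L = 200 frames gives d.f. = 197), which supplies
edge-wise p-values and the Bonferroni-corrected visualization
threshold.  Binarizing |z| (or a p-value, or a target mean degree)
produces the undirected graphs every topology metric operates on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .graph import BinaryGraph

__all__ = [
    "ConnectivityMatrix",
    "ThresholdSpec",
    "correlation_matrix",
    "fisher_z",
    "fisher_z_inverse",
    "group_mean_zmatrix",
    "edge_pvalue",
    "bonferroni_threshold",
    "binarize",
    "pair_count",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_pajek",
    "write_edgelist_tsv",
]


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric region-by-region correlation with its Fisher-z image."""

    r: np.ndarray
    n_samples: int
    labels: tuple[str, ...] | None = None
    tag: str | None = None

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValueError("r must be square")
        if not np.allclose(r, r.T, atol=1e-10):
            raise ValueError("r must be symmetric")
        if not np.allclose(np.diag(r), 1.0, atol=1e-10):
            raise ValueError("r must have unit diagonal")
        off = r[~np.eye(r.shape[0], dtype=bool)]
        if np.abs(off).max(initial=0.0) > 1.0:
            raise ValueError("off-diagonal |r| must be <= 1")
        if self.n_samples < 10:
            raise ValueError("n_samples must be >= 10")
        object.__setattr__(self, "r", r)

    @property
    def n_regions(self) -> int:
        return self.r.shape[0]

    @property
    def z(self) -> np.ndarray:
        """Fisher-z matrix; the diagonal is set to 0 and is not meaningful.

        Off-diagonal entries with |r| = 1 map to ±inf.
        """
        with np.errstate(divide="ignore"):
            z = np.arctanh(self.r - np.eye(self.n_regions))
        np.fill_diagonal(z, 0.0)
        return z


@dataclass(frozen=True)
class ThresholdSpec:
    """How to binarize a connectivity matrix.

    mode ``z_value``: edge iff |z| > value (value = T).
    mode ``p_value``: edge iff the edge p-value < value (value = alpha).
    mode ``target_mean_degree``: T chosen from the sorted |z| values so
    the mean degree is closest to value (= K) from below, ties broken
    toward the sparser graph.
    With ``use_absolute=False`` only positive correlations form edges.
    """

    mode: str
    value: float
    use_absolute: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("z_value", "p_value", "target_mean_degree"):
            raise ValueError(f"unknown threshold mode {self.mode!r}")
        if self.mode == "p_value" and not 0.0 < self.value < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.mode == "z_value" and self.value < 0.0:
            raise ValueError("z threshold must be non-negative")


def correlation_matrix(
    timeseries: np.ndarray,
    labels: tuple[str, ...] | None = None,
    tag: str | None = None,
) -> ConnectivityMatrix:
    """Pearson correlation of every pair of columns of an L x N matrix."""
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise ValueError("timeseries must be 2-D")
    if ts.shape[0] < 10:
        raise ValueError(f"need at least 10 time points, got {ts.shape[0]}")
    constant = np.flatnonzero(ts.max(axis=0) == ts.min(axis=0))
    if constant.size:
        name = labels[constant[0]] if labels else f"column {constant[0]}"
        raise ValueError(f"constant time series in region {name}; r undefined")
    r = np.corrcoef(ts, rowvar=False)
    r = np.clip(0.5 * (r + r.T), -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(r, n_samples=ts.shape[0], labels=labels, tag=tag)


def fisher_z(r):
    """Fisher r-to-z transform, z = atanh(r); requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("|r| must be < 1 for the Fisher transform")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def fisher_z_inverse(z):
    """Inverse Fisher transform, r = tanh(z)."""
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if out.ndim == 0 else out


def group_mean_zmatrix(matrices: list[ConnectivityMatrix], tag: str | None = None) -> ConnectivityMatrix:
    """Element-wise mean of the subjects' Fisher-z matrices.

    The returned matrix stores r = tanh(mean z) with the per-subject
    sample count (all subjects must share shape, labels, and L).
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    first = matrices[0]
    for m in matrices[1:]:
        if m.n_regions != first.n_regions:
            raise ValueError("matrices differ in shape")
        if m.labels != first.labels:
            raise ValueError("matrices differ in region order")
        if m.n_samples != first.n_samples:
            raise ValueError("matrices differ in sample count")
    mean_z = np.mean([m.z for m in matrices], axis=0)
    r = np.tanh(mean_z)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(r, n_samples=first.n_samples, labels=first.labels, tag=tag)


def edge_pvalue(z, n_samples: int, method: str = "normal"):
    """Two-sided p-value for a Fisher-z value under the null r = 0.

    ``normal`` (default): p = 2·(1 − Φ(|z|·sqrt(L − 3))), the Fisher
    approximation whose d.f. is L − 3 (197 for L = 200).  ``t``: the
    exact t transform of r with d.f. = L − 2.
    """
    if n_samples <= 3:
        raise ValueError("n_samples must exceed 3")
    z = np.asarray(z, dtype=float)
    if method == "normal":
        p = 2.0 * stats.norm.sf(np.abs(z) * np.sqrt(n_samples - 3))
    elif method == "t":
        r = np.tanh(z)
        t = np.abs(r) * np.sqrt((n_samples - 2) / (1.0 - r**2))
        p = 2.0 * stats.t.sf(t, df=n_samples - 2)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(p) if p.ndim == 0 else p


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test level alpha/m for m simultaneous tests."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / m


def pair_count(n: int) -> int:
    """Number of unique unordered pairs among n regions: n(n−1)/2."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return n * (n - 1) // 2


def _threshold_for_mean_degree(zvals: np.ndarray, k_target: float, n: int) -> float:
    """Largest |z| cut giving mean degree closest to k_target from below."""
    if not 0.0 < k_target < n - 1:
        raise ValueError(f"target mean degree must lie in (0, {n - 1})")
    m_target = int(np.floor(k_target * n / 2.0 + 1e-9))
    ranked = np.sort(zvals)[::-1]
    if m_target >= ranked.size:
        return 0.0
    # edge rule is strict (|z| > T): cutting at the (m_target+1)-th value
    # keeps at most m_target edges, ties dropping below the target (sparser).
    return float(ranked[m_target])


def binarize(matrix: ConnectivityMatrix, spec: ThresholdSpec) -> BinaryGraph:
    """Threshold a connectivity matrix into an undirected binary graph."""
    z = matrix.z
    strength = np.abs(z) if spec.use_absolute else z
    np.fill_diagonal(strength, -np.inf)
    if spec.mode == "z_value":
        adj = strength > spec.value
    elif spec.mode == "p_value":
        with np.errstate(invalid="ignore"):
            p = edge_pvalue(z, matrix.n_samples)
        adj = (p < spec.value) & np.isfinite(strength)
        if not spec.use_absolute:
            adj &= z > 0
    else:
        iu = np.triu_indices(matrix.n_regions, k=1)
        vals = strength[iu]
        t = _threshold_for_mean_degree(vals[np.isfinite(vals)], spec.value, matrix.n_regions)
        adj = strength > t
    adj = adj & adj.T
    np.fill_diagonal(adj, False)
    return BinaryGraph(adj, matrix.labels)


# ---------------------------------------------------------------------------
# I/O


def write_matrix_tsv(matrix: ConnectivityMatrix, path: str | Path) -> None:
    """Write r as TSV with abbreviation headers plus a JSON sidecar."""
    path = Path(path)
    labels = list(matrix.labels) if matrix.labels else [
        f"R{i:02d}" for i in range(matrix.n_regions)
    ]
    pd.DataFrame(matrix.r, index=labels, columns=labels).to_csv(path, sep="\t")
    sidecar = {
        "n_samples": matrix.n_samples,
        "tag": matrix.tag,
        "n_regions": matrix.n_regions,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_matrix_tsv(path: str | Path) -> ConnectivityMatrix:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return ConnectivityMatrix(
        frame.to_numpy(),
        n_samples=int(sidecar["n_samples"]),
        labels=tuple(frame.columns),
        tag=sidecar.get("tag"),
    )


def write_pajek(
    graph: BinaryGraph,
    path: str | Path,
    coordinates: np.ndarray | None = None,
) -> None:
    """Export a graph in Pajek .net format (1-based vertex numbering).

    *coordinates* is an optional (n, 3) array of node positions; they
    are normalized into [0, 1] as Pajek layouts expect.
    """
    n = graph.n_nodes
    labels = graph.labels or tuple(f"v{i + 1}" for i in range(n))
    lines = [f"*Vertices {n}"]
    if coordinates is not None:
        coords = np.asarray(coordinates, dtype=float)
        lo, hi = coords.min(axis=0), coords.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        norm = (coords - lo) / span
    for i in range(n):
        line = f'{i + 1} "{labels[i]}"'
        if coordinates is not None:
            line += " " + " ".join(f"{c:.4f}" for c in norm[i])
        lines.append(line)
    lines.append("*Edges")
    for i, j in graph.edge_array():
        lines.append(f"{i + 1} {j + 1}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_edgelist_tsv(graph: BinaryGraph, path: str | Path) -> None:
    labels = graph.labels or tuple(str(i) for i in range(graph.n_nodes))
    rows = [(labels[i], labels[j]) for i, j in graph.edge_array()]
    pd.DataFrame(rows, columns=["region_i", "region_j"]).to_csv(
        path, sep="\t", index=False
    )
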