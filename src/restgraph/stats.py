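"""Two-group inference on edges, node metrics, and sweep curves.

Edge-wise comparisons run a pooled-variance two-sample t-test on the
subject-level Fisher-z values of each of the 4005 region pairs, with
Benjamini–Hochberg FDR control across the family.  The same machinery
covers per-region metrics (degree, normalized Γ, clustering, ...) and
per-threshold topology curves.  Clinical correlations are plain
Pearson r with an uncorrected two-sided p (exploratory by design).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .connectivity import ConnectivityMatrix

__all__ = [
    "ClinicalCorrelationResult",
    "two_sample_t",
    "fdr_bh",
    "edgewise_compare",
    "nodewise_compare",
    "curvewise_compare",
    "clinical_correlation",
]


def two_sample_t(
    a: np.ndarray, b: np.ndarray, equal_var: bool = True
) -> tuple[float, float, float]:
    """Two-sample two-tailed t-test; returns (t, p, d.f.).

    Pooled-variance (Student) by default with d.f. = n_a + n_b − 2;
    Welch with ``equal_var=False``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        raise ValueError("zero pooled variance: t is undefined")
    result = sps.ttest_ind(a, b, equal_var=equal_var)
    if equal_var:
        df = a.size + b.size - 2.0
    else:
        sa, sb = va / a.size, vb / b.size
        df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    return float(result.statistic), float(result.pvalue), float(df)


def fdr_bh(
    p: np.ndarray, q_level: float = 0.05, method: str = "bh"
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up FDR control.

    Returns (reject mask, adjusted q-values) in the original order.
    ``method="by"`` applies the Benjamini–Yekutieli variant instead.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    sm_method = {"bh": "fdr_bh", "by": "fdr_by"}.get(method)
    if sm_method is None:
        raise ValueError(f"unknown FDR method {method!r}")
    reject, qvals, _, _ = multipletests(p, alpha=q_level, method=sm_method)
    return reject, qvals


def edgewise_compare(
    group_a: list[ConnectivityMatrix],
    group_b: list[ConnectivityMatrix],
    q_level: float = 0.05,
    p_premask: float | None = None,
    equal_var: bool = True,
) -> pd.DataFrame:
    """t-test every unordered region pair's Fisher-z across groups.

    Returns one row per pair (4005 for 90 regions) with per-group mean
    z, t, p, BH-adjusted q, the direction sign (+1 where group a's
    mean z exceeds group b's), and the rejection flag at *q_level*,
    sorted by q.  With *p_premask*, only pairs with p ≤ p_premask
    enter the FDR family (others are never rejected); the mask choice
    is recorded in ``frame.attrs``.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 subjects per group")
    n = group_a[0].n_regions
    labels = group_a[0].labels or tuple(f"R{i:02d}" for i in range(n))
    za = np.stack([m.z for m in group_a])  # subjects x n x n
    zb = np.stack([m.z for m in group_b])
    iu = np.triu_indices(n, k=1)
    a_vals = za[:, iu[0], iu[1]]
    b_vals = zb[:, iu[0], iu[1]]

    t, p, _ = _vectorized_pooled_t(a_vals, b_vals, equal_var=equal_var)
    if p_premask is not None:
        family = p <= p_premask
        reject = np.zeros(p.size, dtype=bool)
        q = np.ones(p.size)
        if family.any():
            reject[family], q[family] = fdr_bh(p[family], q_level)
    else:
        reject, q = fdr_bh(p, q_level)

    mean_a = a_vals.mean(axis=0)
    mean_b = b_vals.mean(axis=0)
    frame = pd.DataFrame(
        dict(
            region_i=[labels[i] for i in iu[0]],
            region_j=[labels[j] for j in iu[1]],
            i=iu[0],
            j=iu[1],
            mean_z_a=mean_a,
            mean_z_b=mean_b,
            t=t,
            p=p,
            q=q,
            direction=np.sign(mean_a - mean_b).astype(int),
            significant=reject,
        )
    )
    frame.attrs["q_level"] = q_level
    frame.attrs["p_premask"] = p_premask
    return frame.sort_values("q", kind="stable").reset_index(drop=True)


def _vectorized_pooled_t(
    a: np.ndarray, b: np.ndarray, equal_var: bool = True
) -> tuple[np.ndarray, np.ndarray, float]:
    """Column-wise two-sample t over (subjects x tests) arrays."""
    t, p = sps.ttest_ind(a, b, axis=0, equal_var=equal_var)
    df = a.shape[0] + b.shape[0] - 2.0
    return np.asarray(t), np.asarray(p), df


def nodewise_compare(
    group_a: np.ndarray,
    group_b: np.ndarray,
    metric: str,
    labels: tuple[str, ...] | None = None,
    q_level: float = 0.05,
    threshold_note: str | None = None,
) -> pd.DataFrame:
    """t-test a per-region metric across groups with FDR over regions.

    *group_a*/*group_b* are (subjects x regions) arrays of a metric
    computed at a common threshold; the threshold description is kept
    in ``frame.attrs``.
    """
    group_a = np.asarray(group_a, dtype=float)
    group_b = np.asarray(group_b, dtype=float)
    if group_a.ndim != 2 or group_b.ndim != 2 or group_a.shape[1] != group_b.shape[1]:
        raise ValueError("groups must be (subjects x regions) with equal regions")
    n = group_a.shape[1]
    if labels is None:
        labels = tuple(f"R{i:02d}" for i in range(n))
    t, p, _ = _vectorized_pooled_t(group_a, group_b)
    reject, q = fdr_bh(p, q_level)
    frame = pd.DataFrame(
        dict(
            region=list(labels),
            metric=metric,
            mean_a=group_a.mean(axis=0),
            mean_b=group_b.mean(axis=0),
            t=t,
            p=p,
            q=q,
            significant=reject,
        )
    )
    frame.attrs["q_level"] = q_level
    frame.attrs["threshold"] = threshold_note
    return frame


def curvewise_compare(
    group_a: np.ndarray,
    group_b: np.ndarray,
    grid: np.ndarray,
    metric: str = "metric",
    q_level: float = 0.05,
) -> pd.DataFrame:
    """t-test a per-subject metric curve at each grid point.

    *group_a*/*group_b* are (subjects x grid points) arrays sampled on
    the identical *grid*; FDR runs across grid points.
    """
    group_a = np.asarray(group_a, dtype=float)
    group_b = np.asarray(group_b, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if group_a.shape[1] != grid.size or group_b.shape[1] != grid.size:
        raise ValueError("curves do not share the given grid")
    t, p, _ = _vectorized_pooled_t(group_a, group_b)
    reject, q = fdr_bh(p, q_level)
    return pd.DataFrame(
        dict(
            grid_value=grid,
            metric=metric,
            mean_a=group_a.mean(axis=0),
            mean_b=group_b.mean(axis=0),
            t=t,
            p=p,
            q=q,
            significant=reject,
        )
    )


@dataclass(frozen=True)
class ClinicalCorrelationResult:
    metric: str
    covariate: str
    r: float
    p: float
    n: int


def clinical_correlation(
    metric_values: np.ndarray,
    covariate_values: np.ndarray,
    metric: str = "metric",
    covariate: str = "covariate",
) -> ClinicalCorrelationResult:
    """Pearson correlation between a topology metric and a clinical variable.

    Two-sided p from the t transform t = r·sqrt((n−2)/(1−r²));
    uncorrected, exploratory.
    """
    x = np.asarray(metric_values, dtype=float)
    y = np.asarray(covariate_values, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("zero variance in one of the variables")
    r, p = sps.pearsonr(x, y)
    return ClinicalCorrelationResult(metric, covariate, float(r), float(p), int(x.size))
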