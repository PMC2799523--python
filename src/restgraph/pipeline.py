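"""End-to-end pipeline: simulate → preprocess → connect → metrics →
nulls → compare → report.

Each stage reads and writes the package's TSV/JSON interchange files,
so stages are separately runnable (and separately testable) and
``run_pipeline`` is exactly the chained stages.  All randomness
derives from one master seed by documented splitting
(``stage_seed(master, index)``), so regenerating with the same config
reproduces every numeric output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import (
    ConnectivityMatrix,
    ThresholdSpec,
    binarize,
    bonferroni_threshold,
    correlation_matrix,
    group_mean_zmatrix,
    pair_count,
    read_matrix_tsv,
    write_matrix_tsv,
    write_pajek,
)
from .io import read_cohort, write_cohort
from .metrics import (
    clustering,
    degrees,
    fit_degree_distributions,
    hubs,
    n_to_1_connectivity,
    network_metrics,
)
from .nulls import identify_regime, null_ensemble, small_world_indices
from .preprocess import (
    PreprocessConfig,
    exclude_by_motion,
    preprocess_subject,
    summarize_head_motion,
)
from .regions import load_region_table
from .stats import clinical_correlation, edgewise_compare, nodewise_compare
from .synth import CohortConfig, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "stage_seed",
           "stage_simulate", "stage_preprocess", "stage_connect",
           "stage_metrics", "stage_nulls", "stage_compare", "stage_report"]

_STAGES = ("simulate", "preprocess", "connect", "metrics", "nulls", "compare")


def stage_seed(master: int, index: int) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    return int(np.random.SeedSequence([master, index]).generate_state(1)[0] % 2**31)


@dataclass
class RunConfig:
    outdir: str = "restgraph-run"
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    analysis_threshold: float = 0.18  # |z| cut for subject/group graphs (mid-regime)
    regime_t_step: float = 0.005
    regime_n_random: int = 20
    indices_n_random: int = 100
    q_level: float = 0.05
    p_premask: float | None = None
    bonferroni_alpha: float = 0.001

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        doc = dict(doc)
        if "cohort" in doc:
            doc["cohort"] = CohortConfig(**doc["cohort"])
        if "preprocess" in doc:
            doc["preprocess"] = PreprocessConfig(**doc["preprocess"])
        return cls(**doc)

    def to_dict(self) -> dict:
        doc = asdict(self)
        doc["cohort"].pop("planted_effects", None)
        return doc


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: RunConfig) -> Path:
    cohort_cfg = config.cohort
    if cohort_cfg.seed != config.seed:
        cohort_cfg = CohortConfig(**{**asdict(cohort_cfg), "seed": config.seed})
    cohort = simulate_cohort(cohort_cfg)
    out = Path(config.outdir) / "simulate"
    write_cohort(cohort, out)
    logger.info("simulated %d subjects", len(cohort.subjects))
    return out


def stage_preprocess(config: RunConfig) -> Path:
    indir = Path(config.outdir) / "simulate"
    out = Path(config.outdir) / "preprocess"
    out.mkdir(parents=True, exist_ok=True)
    cohort = read_cohort(indir)
    kept, excluded = exclude_by_motion(list(cohort.subjects), config.preprocess)
    table = load_region_table()
    abbrs = list(table["abbreviation"])
    qc = {"subjects": {}, "excluded": [s.subject_id for s in excluded]}
    for subject in cohort.subjects:
        summary = summarize_head_motion(subject.motion)
        qc["subjects"][subject.subject_id] = {
            "group": subject.group,
            "translation_score_mm": summary.translation_score,
            "rotation_score_deg": summary.rotation_score,
            "max_abs_translation_mm": summary.max_abs_translation,
            "max_abs_rotation_deg": summary.max_abs_rotation,
            "excluded": subject in excluded,
        }
    for subject in kept:
        conditioned = preprocess_subject(subject, config.preprocess)
        pd.DataFrame(conditioned, columns=abbrs).to_csv(
            out / f"{subject.subject_id}_conditioned.tsv",
            sep="\t",
            index=False,
            float_format="%.6f",
        )
    (out / "qc.json").write_text(json.dumps(qc, indent=1))
    logger.info("kept %d subjects, excluded %d", len(kept), len(excluded))
    return out


def _kept_subjects(config: RunConfig) -> list[tuple[str, str]]:
    """(subject_id, group) pairs surviving motion QC, in cohort order."""
    qc = json.loads((Path(config.outdir) / "preprocess" / "qc.json").read_text())
    return [
        (sid, rec["group"])
        for sid, rec in qc["subjects"].items()
        if not rec["excluded"]
    ]


def stage_connect(config: RunConfig) -> Path:
    pre = Path(config.outdir) / "preprocess"
    out = Path(config.outdir) / "connect"
    out.mkdir(parents=True, exist_ok=True)
    table = load_region_table()
    labels = tuple(table["abbreviation"])
    coords = table[["x", "y", "z"]].to_numpy()
    per_group: dict[str, list[ConnectivityMatrix]] = {"a": [], "b": []}
    for sid, group in _kept_subjects(config):
        ts = pd.read_csv(pre / f"{sid}_conditioned.tsv", sep="\t").to_numpy()
        matrix = correlation_matrix(ts, labels=labels, tag=sid)
        write_matrix_tsv(matrix, out / f"{sid}_correlation.tsv")
        per_group[group].append(matrix)
    n_pairs = pair_count(len(labels))
    per_edge_alpha = bonferroni_threshold(config.bonferroni_alpha, n_pairs)
    for group, mats in per_group.items():
        mean = group_mean_zmatrix(mats, tag=f"group-{group}")
        write_matrix_tsv(mean, out / f"group_{group}_mean.tsv")
        graph = binarize(mean, ThresholdSpec("p_value", per_edge_alpha))
        write_pajek(graph, out / f"group_{group}_bonferroni.net", coordinates=coords)
    meta = {
        "n_pairs": n_pairs,
        "bonferroni_alpha": config.bonferroni_alpha,
        "per_edge_alpha": per_edge_alpha,
    }
    (out / "connect.json").write_text(json.dumps(meta, indent=1))
    return out


def _load_group_matrices(config: RunConfig) -> dict[str, list[ConnectivityMatrix]]:
    conn = Path(config.outdir) / "connect"
    per_group: dict[str, list[ConnectivityMatrix]] = {"a": [], "b": []}
    for sid, group in _kept_subjects(config):
        per_group[group].append(read_matrix_tsv(conn / f"{sid}_correlation.tsv"))
    return per_group


def stage_metrics(config: RunConfig) -> Path:
    conn = Path(config.outdir) / "connect"
    out = Path(config.outdir) / "metrics"
    out.mkdir(parents=True, exist_ok=True)
    spec = ThresholdSpec("z_value", config.analysis_threshold)
    per_group = _load_group_matrices(config)
    rows = []
    net_rows = {}
    for group, mats in per_group.items():
        for matrix in mats:
            g = binarize(matrix, spec)
            k, mean_k = degrees(g)
            c, _ = clustering(g)
            gamma, gamma_norm = n_to_1_connectivity(matrix)
            for i, abbr in enumerate(matrix.labels):
                rows.append(
                    dict(
                        subject_id=matrix.tag,
                        group=group,
                        region=abbr,
                        degree=int(k[i]),
                        clustering=c[i],
                        gamma=gamma[i],
                        gamma_norm=gamma_norm[i],
                    )
                )
        mean_matrix = read_matrix_tsv(conn / f"group_{group}_mean.tsv")
        g = binarize(mean_matrix, spec)
        met = network_metrics(g)
        k, _ = degrees(g)
        hub_idx = hubs(g)
        fit = fit_degree_distributions(k)
        net_rows[group] = {
            "network": asdict(met),
            "hubs": [mean_matrix.labels[i] for i in hub_idx],
            "n_hubs": int(hub_idx.size),
            "degree_fits": [asdict(f) for f in fit],
            "best_family": fit[0].family,
        }
    pd.DataFrame(rows).to_csv(out / "node_metrics.tsv", sep="\t", index=False)
    (out / "network_metrics.json").write_text(json.dumps(net_rows, indent=1))
    (out / "threshold.json").write_text(
        json.dumps({"mode": spec.mode, "value": spec.value})
    )
    return out


def stage_nulls(config: RunConfig) -> Path:
    conn = Path(config.outdir) / "connect"
    out = Path(config.outdir) / "nulls"
    out.mkdir(parents=True, exist_ok=True)
    spec = ThresholdSpec("z_value", config.analysis_threshold)
    doc = {}
    for idx, group in enumerate(("a", "b")):
        mean_matrix = read_matrix_tsv(conn / f"group_{group}_mean.tsv")
        regime = identify_regime(
            mean_matrix,
            t_step=config.regime_t_step,
            n_random=config.regime_n_random,
            seed=stage_seed(config.seed, 40 + idx),
        )
        regime.diagnostics.to_csv(
            out / f"group_{group}_regime.tsv", sep="\t", index=False
        )
        g = binarize(mean_matrix, spec)
        met = network_metrics(g)
        ens = null_ensemble(
            g,
            n_random=config.indices_n_random,
            seed=stage_seed(config.seed, 50 + idx),
            measures=("clustering", "paths"),
        )
        indices = small_world_indices(met, ens)
        doc[group] = {
            "regime": {
                "t_min": regime.t_min,
                "t_max": regime.t_max,
                "k_min": regime.k_min,
                "k_max": regime.k_max,
                "empty": regime.is_empty,
                "t_step": config.regime_t_step,
                "n_random": config.regime_n_random,
            },
            "small_world": {
                "threshold": config.analysis_threshold,
                "n_random": config.indices_n_random,
                "gamma": indices.gamma,
                "lambda": indices.lam,
                "sigma": indices.sigma,
                "C_net": met.C_net,
                "L_net": met.L_net,
                "mean_C_rand": ens.mean_C_rand,
                "mean_L_rand": ens.mean_L_rand,
            },
        }
    (out / "nulls.json").write_text(json.dumps(doc, indent=1))
    return out


def stage_compare(config: RunConfig) -> Path:
    out = Path(config.outdir) / "compare"
    out.mkdir(parents=True, exist_ok=True)
    per_group = _load_group_matrices(config)
    edges = edgewise_compare(
        per_group["a"], per_group["b"], q_level=config.q_level,
        p_premask=config.p_premask,
    )
    edges.to_csv(out / "edge_tests.tsv", sep="\t", index=False)

    node_metrics = pd.read_csv(
        Path(config.outdir) / "metrics" / "node_metrics.tsv", sep="\t"
    )
    labels = tuple(load_region_table()["abbreviation"])
    node_tables = []
    for metric in ("degree", "gamma_norm"):
        pivots = {
            grp: node_metrics[node_metrics["group"] == grp]
            .pivot(index="subject_id", columns="region", values=metric)[list(labels)]
            .to_numpy()
            for grp in ("a", "b")
        }
        node_tables.append(
            nodewise_compare(
                pivots["a"],
                pivots["b"],
                metric=metric,
                labels=labels,
                q_level=config.q_level,
                threshold_note=f"|z| > {config.analysis_threshold}",
            )
        )
    pd.concat(node_tables).to_csv(out / "node_tests.tsv", sep="\t", index=False)

    # exploratory clinical correlations in the patient group (group b)
    manifest = json.loads(
        (Path(config.outdir) / "simulate" / "manifest.json").read_text()
    )
    covars = {
        s["subject_id"]: s["covariates"]
        for s in manifest["subjects"]
        if s["covariates"]
    }
    clin_rows = []
    sub_b = node_metrics[node_metrics["group"] == "b"]
    # raw Gamma strength, not the normalized form (whose subject mean is
    # 1/90 by construction and carries no between-subject information)
    mean_gamma = sub_b.groupby("subject_id")["gamma"].mean()
    mean_degree = sub_b.groupby("subject_id")["degree"].mean()
    for covar_name in ("epilepsy_duration_years", "seizure_frequency_per_month"):
        paired = [
            (sid, covars[sid][covar_name])
            for sid in mean_gamma.index
            if sid in covars and covar_name in covars[sid]
        ]
        if len(paired) >= 3:
            sids, vals = zip(*paired)
            for metric_name, series in (
                ("mean_degree", mean_degree),
                ("mean_gamma", mean_gamma),
            ):
                res = clinical_correlation(
                    series.loc[list(sids)].to_numpy(),
                    np.array(vals),
                    metric=metric_name,
                    covariate=covar_name,
                )
                clin_rows.append(asdict(res))
    (out / "clinical_correlations.json").write_text(json.dumps(clin_rows, indent=1))
    return out


def stage_report(config: RunConfig) -> Path:
    base = Path(config.outdir)
    edges = pd.read_csv(base / "compare" / "edge_tests.tsv", sep="\t")
    nodes = pd.read_csv(base / "compare" / "node_tests.tsv", sep="\t")
    nulls = json.loads((base / "nulls" / "nulls.json").read_text())
    metrics = json.loads((base / "metrics" / "network_metrics.json").read_text())
    qc = json.loads((base / "preprocess" / "qc.json").read_text())
    sig = edges[edges["significant"]]
    report = {
        "software_version": __version__,
        "master_seed": config.seed,
        "config": config.to_dict(),
        "n_subjects_analyzed": len(qc["subjects"]) - len(qc["excluded"]),
        "n_subjects_excluded": len(qc["excluded"]),
        "edge_tests": {
            "n_pairs": int(len(edges)),
            "n_significant": int(sig.shape[0]),
            "n_increased_in_b": int((sig["direction"] < 0).sum()),
            "n_decreased_in_b": int((sig["direction"] > 0).sum()),
        },
        "node_tests": {
            metric: int(
                nodes[(nodes["metric"] == metric) & nodes["significant"]].shape[0]
            )
            for metric in nodes["metric"].unique()
        },
        "hubs": {g: metrics[g]["n_hubs"] for g in metrics},
        "best_degree_family": {g: metrics[g]["best_family"] for g in metrics},
        "small_world": {g: nulls[g]["small_world"] for g in nulls},
        "regime": {g: nulls[g]["regime"] for g in nulls},
    }
    (base / "report.json").write_text(json.dumps(report, indent=1))
    return base / "report.json"


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage in order; returns the final report document.

    A failing stage aborts with the stage name attached; outputs of
    completed stages stay on disk.
    """
    Path(config.outdir).mkdir(parents=True, exist_ok=True)
    (Path(config.outdir) / "run_config.json").write_text(
        json.dumps(config.to_dict(), indent=1)
    )
    for name, fn in zip(
        _STAGES + ("report",),
        (
            stage_simulate,
            stage_preprocess,
            stage_connect,
            stage_metrics,
            stage_nulls,
            stage_compare,
            stage_report,
        ),
    ):
        logger.info("stage %s", name)
        try:
            fn(config)
        except Exception as exc:  # attach stage context
            raise RuntimeError(f"pipeline failed in stage {name!r}: {exc}") from exc
    return json.loads((Path(config.outdir) / "report.json").read_text())
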