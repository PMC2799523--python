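"""On-disk interchange for cohorts: delimited text plus JSON sidecars.

One timeseries TSV per subject (header = region abbreviations, rows =
frames), one motion/nuisance TSV per subject (3 translations in mm,
3 rotations in degrees, then the ventricular and white-matter
reference signals), a cohort manifest (subject ids, groups,
covariates, seed), and a ground-truth ledger (planted edges and paths
to the target correlation matrices).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .regions import load_region_table
from .synth import Cohort, CohortConfig, PlantedEffect, PlantedEffectMap, SubjectRecord

MOTION_COLUMNS = [
    "trans_x_mm",
    "trans_y_mm",
    "trans_z_mm",
    "rot_x_deg",
    "rot_y_deg",
    "rot_z_deg",
    "ventricle",
    "white_matter",
]

__all__ = ["write_cohort", "read_cohort", "MOTION_COLUMNS"]


def write_cohort(cohort: Cohort, outdir: str | Path, region_table=None) -> Path:
    """Write a cohort to *outdir*; returns the directory path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = load_region_table() if region_table is None else region_table
    abbrs = list(table["abbreviation"])
    for subject in cohort.subjects:
        pd.DataFrame(subject.timeseries, columns=abbrs).to_csv(
            outdir / f"{subject.subject_id}_timeseries.tsv",
            sep="\t",
            index=False,
            float_format="%.6f",
        )
        motion = np.column_stack([subject.motion, subject.nuisance])
        pd.DataFrame(motion, columns=MOTION_COLUMNS).to_csv(
            outdir / f"{subject.subject_id}_motion.tsv",
            sep="\t",
            index=False,
            float_format="%.6f",
        )
    manifest = {
        "seed": cohort.config.seed,
        "n_timepoints": cohort.config.n_timepoints,
        "tr_seconds": cohort.config.tr_seconds,
        "subjects": [
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "covariates": s.covariates,
            }
            for s in cohort.subjects
        ],
        "motion_violators": list(cohort.violator_ids),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))

    for group in ("a", "b"):
        pd.DataFrame(cohort.truth.target(group), index=abbrs, columns=abbrs).to_csv(
            outdir / f"target_correlation_group_{group}.tsv", sep="\t"
        )
    truth = {
        "planted_edges": [
            {
                "i": e.i,
                "j": e.j,
                "region_i": abbrs[e.i],
                "region_j": abbrs[e.j],
                "delta_r": e.delta_r,
            }
            for e in cohort.truth.effects
        ],
        "target_matrices": {
            g: f"target_correlation_group_{g}.tsv" for g in ("a", "b")
        },
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    return outdir


def read_cohort(indir: str | Path) -> Cohort:
    """Read a cohort previously written by :func:`write_cohort`."""
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    subjects = []
    for entry in manifest["subjects"]:
        sid = entry["subject_id"]
        ts = pd.read_csv(indir / f"{sid}_timeseries.tsv", sep="\t").to_numpy()
        motion_full = pd.read_csv(indir / f"{sid}_motion.tsv", sep="\t").to_numpy()
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                group=entry["group"],
                timeseries=ts,
                motion=motion_full[:, :6],
                nuisance=motion_full[:, 6:8],
                covariates=entry.get("covariates", {}),
            )
        )
    truth_doc = json.loads((indir / "ground_truth.json").read_text())
    effects = tuple(
        PlantedEffect(e["i"], e["j"], e["delta_r"]) for e in truth_doc["planted_edges"]
    )
    targets = {
        g: pd.read_csv(indir / path, sep="\t", index_col=0).to_numpy()
        for g, path in truth_doc["target_matrices"].items()
    }
    truth = PlantedEffectMap(effects, targets["a"], targets["b"])
    config = CohortConfig(
        n_group_a=sum(1 for s in subjects if s.group == "a"),
        n_group_b=sum(1 for s in subjects if s.group == "b"),
        n_timepoints=manifest["n_timepoints"],
        tr_seconds=manifest["tr_seconds"],
        n_motion_violators=len(manifest.get("motion_violators", [])),
        seed=manifest["seed"],
    )
    return Cohort(
        tuple(subjects), truth, tuple(manifest.get("motion_violators", [])), config
    )
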