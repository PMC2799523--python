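"""90-region anatomical parcellation table.

The parcellation covers 45 cortical and subcortical structures per
hemisphere (90 regions total), grouped into six anatomical blocks:
medial temporal, subcortical, occipital, frontal, temporal, and
parietal-(pre)motor.  Abbreviations carry an ``l``/``r`` hemisphere
prefix (e.g. ``lHIP``, ``rPCUN``).

Centroid coordinates are synthetic: they are deterministic, plausible
stereotaxic positions (x negative on the left) intended for graph
layout export only, not for anatomical localization.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MEDIAL_TEMPORAL = "medial temporal"
SUBCORTICAL = "subcortical"
OCCIPITAL = "occipital"
FRONTAL = "frontal"
TEMPORAL = "temporal"
PARIETAL_PREMOTOR = "parietal-(pre)motor"

LOBE_GROUPS = (
    MEDIAL_TEMPORAL,
    SUBCORTICAL,
    OCCIPITAL,
    FRONTAL,
    TEMPORAL,
    PARIETAL_PREMOTOR,
)

# (region name, abbreviation stem, lobe group) — one row per structure,
# instantiated once per hemisphere below.
_BASE_REGIONS = [
    ("Amygdala", "AMYG", MEDIAL_TEMPORAL),
    ("Hippocampus", "HIP", MEDIAL_TEMPORAL),
    ("Parahippocampal gyrus", "PHIP", MEDIAL_TEMPORAL),
    ("Middle temporal gyrus, temporal pole", "MTGp", MEDIAL_TEMPORAL),
    ("Superior temporal gyrus, temporal pole", "STGp", MEDIAL_TEMPORAL),
    ("Caudate nucleus", "CAU", SUBCORTICAL),
    ("Olfactory cortex", "OLF", SUBCORTICAL),
    ("Pallidum", "PAL", SUBCORTICAL),
    ("Putamen", "PUT", SUBCORTICAL),
    ("Thalamus", "THA", SUBCORTICAL),
    ("Calcarine fissure", "CAL", OCCIPITAL),
    ("Cuneus", "CUN", OCCIPITAL),
    ("Fusiform gyrus", "FG", OCCIPITAL),
    ("Lingual gyrus", "LING", OCCIPITAL),
    ("Inferior occipital gyrus", "IOG", OCCIPITAL),
    ("Middle occipital gyrus", "MOG", OCCIPITAL),
    ("Superior occipital gyrus", "SOG", OCCIPITAL),
    ("Anterior cingulate gyrus", "ACC", FRONTAL),
    ("Inferior frontal gyrus, opercular", "IFGoper", FRONTAL),
    ("Inferior frontal gyrus, orbital", "IFGorb", FRONTAL),
    ("Inferior frontal gyrus, triangular", "IFGtri", FRONTAL),
    ("Superior frontal gyrus, medial orbital", "SFGmorb", FRONTAL),
    ("Middle frontal gyrus, orbital", "MFGorb", FRONTAL),
    ("Middle frontal gyrus", "MFG", FRONTAL),
    ("Superior frontal gyrus, medial", "SFGmed", FRONTAL),
    ("Superior frontal gyrus, orbital", "SFGorb", FRONTAL),
    ("Superior frontal gyrus", "SFG", FRONTAL),
    ("Gyrus rectus", "REG", FRONTAL),
    ("Heschl gyrus", "HES", TEMPORAL),
    ("Insula", "INS", TEMPORAL),
    ("Inferior temporal gyrus", "ITG", TEMPORAL),
    ("Middle temporal gyrus", "MTG", TEMPORAL),
    ("Superior temporal gyrus", "STG", TEMPORAL),
    ("Rolandic operculum", "ROL", PARIETAL_PREMOTOR),
    ("Angular gyrus", "ANG", PARIETAL_PREMOTOR),
    ("Median cingulate gyrus", "MCC", PARIETAL_PREMOTOR),
    ("Posterior cingulate gyrus", "PCC", PARIETAL_PREMOTOR),
    ("Paracentral lobule", "PCL", PARIETAL_PREMOTOR),
    ("Inferior parietal gyrus", "IPG", PARIETAL_PREMOTOR),
    ("Superior parietal gyrus", "SPG", PARIETAL_PREMOTOR),
    ("Postcentral gyrus", "PoCG", PARIETAL_PREMOTOR),
    ("Precentral gyrus", "PreCG", PARIETAL_PREMOTOR),
    ("Precuneus", "PCUN", PARIETAL_PREMOTOR),
    ("Supplementary motor area", "SMA", PARIETAL_PREMOTOR),
    ("Supramarginal gyrus", "SMG", PARIETAL_PREMOTOR),
]

N_REGIONS = 2 * len(_BASE_REGIONS)

_CENTROID_SEED = 20090825  # fixed: centroids are part of the shipped table


def load_region_table() -> pd.DataFrame:
    """Return the 90-row region table.

    Columns: ``index`` (0-based), ``label``, ``abbreviation``,
    ``hemisphere`` ({left, right}), ``lobe_group`` (one of the six
    blocks), ``x``/``y``/``z`` centroid coordinates in mm.
    Rows are ordered left/right interleaved per structure.
    """
    rng = np.random.default_rng(_CENTROID_SEED)
    rows = []
    for name, abbr, lobe in _BASE_REGIONS:
        x = rng.uniform(8.0, 55.0)
        y = rng.uniform(-85.0, 60.0)
        z = rng.uniform(-25.0, 65.0)
        for hemi, sign, prefix in (("left", -1.0, "l"), ("right", 1.0, "r")):
            rows.append(
                dict(
                    label=f"{name} ({hemi[0].upper()})",
                    abbreviation=prefix + abbr,
                    hemisphere=hemi,
                    lobe_group=lobe,
                    x=round(sign * x, 1),
                    y=round(y, 1),
                    z=round(z, 1),
                )
            )
    table = pd.DataFrame(rows)
    table.insert(0, "index", np.arange(len(table)))
    validate_region_table(table)
    return table


def validate_region_table(table: pd.DataFrame) -> None:
    """Raise ``ValueError`` if *table* violates the parcellation invariants."""
    if len(table) != N_REGIONS:
        raise ValueError(f"region table must have {N_REGIONS} rows, got {len(table)}")
    counts = table["hemisphere"].value_counts()
    if counts.get("left", 0) != N_REGIONS // 2 or counts.get("right", 0) != N_REGIONS // 2:
        raise ValueError("region table must contain 45 regions per hemisphere")
    if table["abbreviation"].duplicated().any():
        dupes = table.loc[table["abbreviation"].duplicated(), "abbreviation"].tolist()
        raise ValueError(f"duplicate abbreviations: {dupes}")
    bad = set(table["lobe_group"]) - set(LOBE_GROUPS)
    if bad:
        raise ValueError(f"unknown lobe groups: {sorted(bad)}")
    left = table["hemisphere"] == "left"
    if (table.loc[left, "x"] >= 0).any() or (table.loc[~left, "x"] <= 0).any():
        raise ValueError("centroid x sign must match hemisphere (left negative)")


def block_indices(table: pd.DataFrame, lobe_group: str) -> np.ndarray:
    """0-based region indices belonging to *lobe_group*."""
    if lobe_group not in LOBE_GROUPS:
        raise ValueError(f"unknown lobe group {lobe_group!r}")
    return table.index[table["lobe_group"] == lobe_group].to_numpy()
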