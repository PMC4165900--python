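"""Bundled parcellation fixture tables.

The analysis consumes an atlas purely as configuration: region name, lobe,
hemisphere and an MNI coordinate per region. Two synthetic fixture tables
ship with the package — a 90-region anatomical-style parcellation (45
bilateral pairs, AAL-style naming) and a 160-region functional-style
parcellation (network-labelled spherical ROIs including the cerebellum).
The coordinates are synthetic stand-ins generated deterministically within
lobe-typical ranges; they are NOT the published atlas centroids and carry
"synthetic" in their filenames to say so.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["make_anatomical_atlas", "make_functional_atlas", "load_bundled_atlas"]

# 45 bilateral region base names with their lobe assignment
_ANATOMICAL_REGIONS: list[tuple[str, str]] = [
    ("Precentral", "frontal"), ("Frontal_Sup", "frontal"), ("Frontal_Sup_Orb", "frontal"),
    ("Frontal_Mid", "frontal"), ("Frontal_Mid_Orb", "frontal"), ("Frontal_Inf_Oper", "frontal"),
    ("Frontal_Inf_Tri", "frontal"), ("Frontal_Inf_Orb", "frontal"), ("Rolandic_Oper", "frontal"),
    ("Supp_Motor_Area", "frontal"), ("Olfactory", "frontal"), ("Frontal_Sup_Medial", "frontal"),
    ("Frontal_Med_Orb", "frontal"), ("Rectus", "frontal"), ("Insula", "insula"),
    ("Cingulum_Ant", "limbic"), ("Cingulum_Mid", "limbic"), ("Cingulum_Post", "limbic"),
    ("Hippocampus", "limbic"), ("ParaHippocampal", "limbic"), ("Amygdala", "limbic"),
    ("Calcarine", "occipital"), ("Cuneus", "occipital"), ("Lingual", "occipital"),
    ("Occipital_Sup", "occipital"), ("Occipital_Mid", "occipital"), ("Occipital_Inf", "occipital"),
    ("Fusiform", "occipital"), ("Postcentral", "parietal"), ("Parietal_Sup", "parietal"),
    ("Parietal_Inf", "parietal"), ("SupraMarginal", "parietal"), ("Angular", "parietal"),
    ("Precuneus", "parietal"), ("Paracentral_Lobule", "parietal"), ("Caudate", "subcortical"),
    ("Putamen", "subcortical"), ("Pallidum", "subcortical"), ("Thalamus", "subcortical"),
    ("Heschl", "temporal"), ("Temporal_Sup", "temporal"), ("Temporal_Pole_Sup", "temporal"),
    ("Temporal_Mid", "temporal"), ("Temporal_Pole_Mid", "temporal"), ("Temporal_Inf", "temporal"),
]

_FUNCTIONAL_NETWORKS: list[tuple[str, str, int]] = [
    # (network, lobe bucket used for the synthetic coordinate, region count)
    ("default", "frontal", 34),
    ("fronto_parietal", "parietal", 21),
    ("cingulo_opercular", "limbic", 32),
    ("sensorimotor", "parietal", 33),
    ("occipital", "occipital", 22),
    ("cerebellum", "cerebellum", 18),
]

# synthetic lobe-typical coordinate ranges (|x|, y, z), mm
_LOBE_BOX = {
    "frontal": ((5, 55), (5, 65), (-15, 60)),
    "insula": ((30, 42), (-10, 20), (-5, 15)),
    "limbic": ((2, 30), (-50, 45), (-20, 45)),
    "occipital": ((5, 45), (-100, -55), (-15, 35)),
    "parietal": ((5, 55), (-80, -25), (20, 70)),
    "subcortical": ((5, 30), (-30, 15), (-10, 20)),
    "temporal": ((35, 60), (-45, 20), (-35, 10)),
    "cerebellum": ((2, 40), (-85, -45), (-45, -15)),
}


def _coord(lobe: str, rng: np.random.Generator, hemisphere: str) -> tuple[int, int, int]:
    (xa, xb), (ya, yb), (za, zb) = _LOBE_BOX[lobe]
    x = int(rng.integers(xa, xb + 1))
    if hemisphere == "L":
        x = -x
    return x, int(rng.integers(ya, yb + 1)), int(rng.integers(za, zb + 1))


def make_anatomical_atlas(seed: int = 20140916) -> pd.DataFrame:
    """90-region anatomical-style table: 45 bilateral pairs, synthetic MNI
    coordinates. Columns: name, lobe, hemisphere, x, y, z."""
    rng = np.random.default_rng(seed)
    rows = []
    for base, lobe in _ANATOMICAL_REGIONS:
        for hemi in ("L", "R"):
            x, y, z = _coord(lobe, rng, hemi)
            rows.append({"name": f"{base}_{hemi}", "lobe": lobe, "hemisphere": hemi,
                         "x": x, "y": y, "z": z})
    return pd.DataFrame(rows)


def make_functional_atlas(seed: int = 20140917) -> pd.DataFrame:
    """160-region functional-style table of network-labelled ROIs (synthetic
    coordinates, cerebellum included)."""
    rng = np.random.default_rng(seed)
    rows = []
    for network, lobe, count in _FUNCTIONAL_NETWORKS:
        for k in range(count):
            hemi = "L" if rng.random() < 0.5 else "R"
            x, y, z = _coord(lobe, rng, hemi)
            rows.append({"name": f"{network}_{k:02d}", "lobe": network,
                         "hemisphere": hemi, "x": x, "y": y, "z": z})
    assert len(rows) == 160
    return pd.DataFrame(rows)


def load_bundled_atlas(n_regions: int) -> pd.DataFrame:
    """Load the shipped synthetic fixture atlas with 90 or 160 regions."""
    fname = {90: "atlas90_synthetic.tsv", 160: "atlas160_synthetic.tsv"}.get(n_regions)
    if fname is None:
        raise ValueError("bundled atlases exist for 90 or 160 regions only")
    with resources.as_file(resources.files("funconn.data") / fname) as path:
        return pd.read_csv(path, sep="\t")


def _regenerate_bundled(data_dir: str | Path) -> None:
    """Rewrite the shipped fixture TSVs (maintenance helper)."""
    out = Path(data_dir)
    make_anatomical_atlas().to_csv(out / "atlas90_synthetic.tsv", sep="\t", index=False)
    make_functional_atlas().to_csv(out / "atlas160_synthetic.tsv", sep="\t", index=False)
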