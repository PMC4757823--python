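"""Re-encoded literature screening models for the mu opioid receptor.

The published MOR agonist/antagonist pharmacophore models and shape queries
are described in the literature only by their feature compositions (and, for
the shape queries, ComboScore cutoffs); their 3D geometries were never
released.  The builders here reproduce the exact feature/exclusion-volume
censuses and cutoffs with schematic but geometrically consistent
coordinates, so they are valid inputs for the matcher and generators.  They
are validated by census and cutoff only — never by screening outcome.
"""

from __future__ import annotations

import numpy as np

from .pharmacophore_screen import (
    ExclusionVolume,
    PharmacophoreFeature,
    PharmacophoreModel,
)
from .shape_screen import ShapeQuery

# Feature composition of the six published pharmacophore models
# (ordered kind counts) and their exclusion-volume counts.
PHARMACOPHORE_CENSUS: dict[str, tuple[tuple[tuple[str, int], ...], int]] = {
    "pm-ag-4dkl-model-13": ((("HBA", 1), ("PI", 1), ("H", 2)), 29),
    "pm-ag-lig-model-1": ((("HBA", 1), ("PI", 1), ("Ar", 1), ("H", 2)), 62),
    "pm-ag-lig-model-2": ((("HBA", 3), ("PI", 1), ("H", 3)), 41),
    "pm-ant-lig-model-3": ((("HBD", 1), ("PI", 1), ("H", 2), ("Ar", 1)), 36),
    "pm-ant-lig-model-4": ((("HBA", 1), ("PI", 1), ("H", 2), ("Ar", 1)), 44),
    "pm-ant-lig-model-5": ((("HBD", 1), ("HBA", 1), ("Ar", 1), ("H", 4)), 52),
}

# ComboScore cutoffs of the seven published shape queries.
SHAPE_CUTOFFS: dict[str, float] = {
    "shape-ag-model-1": 1.02,
    "shape-ag-model-2": 1.35,
    "shape-ag-model-3": 1.50,
    "shape-ant-model-1": 1.35,
    "shape-ant-model-2": 1.20,
    "shape-ant-model-3": 1.65,
    "shape-ant-model-4": 1.20,
}

# Well-separated feature positions (pairwise >= 3 A) shared by all builders.
_FEATURE_SITES = np.array(
    [
        [0.0, 0.0, 0.0],
        [3.2, 0.0, 0.0],
        [0.0, 3.2, 0.0],
        [0.0, 0.0, 3.2],
        [3.2, 3.2, 0.0],
        [3.2, 0.0, 3.2],
        [0.0, 3.2, 3.2],
        [-3.2, 0.0, 0.0],
        [0.0, -3.2, 0.0],
        [0.0, 0.0, -3.2],
    ]
)


def _fibonacci_sphere(n: int, radius: float, center: np.ndarray) -> np.ndarray:
    """Deterministic near-uniform points on a sphere."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    pts = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    return center + radius * pts


def _census_model(model_id: str) -> PharmacophoreModel:
    census, n_xvols = PHARMACOPHORE_CENSUS[model_id]
    features = []
    site = 0
    for kind, count in census:
        for _ in range(count):
            features.append(PharmacophoreFeature(kind, _FEATURE_SITES[site]))
            site += 1
    centers = np.array([f.center for f in features])
    shell = _fibonacci_sphere(n_xvols, radius=8.0, center=centers.mean(axis=0))
    xvols = tuple(ExclusionVolume(c) for c in shell)
    return PharmacophoreModel(model_id=model_id, features=tuple(features), xvols=xvols)


def mor_pharmacophore_models() -> dict[str, PharmacophoreModel]:
    """The six published MOR pharmacophore models, re-encoded by census."""
    return {mid: _census_model(mid) for mid in PHARMACOPHORE_CENSUS}


def _reference_shape(index: int, n_atoms: int) -> np.ndarray:
    """Schematic query geometry: a loose helix, distinct per query."""
    t = np.linspace(0.0, 2.0 * np.pi * (1.0 + 0.15 * index), n_atoms)
    radius = 2.0 + 0.3 * index
    pitch = 1.2 + 0.2 * index
    return np.stack(
        [radius * np.cos(t), radius * np.sin(t), pitch * t / np.pi], axis=1
    )


def mor_shape_queries() -> dict[str, ShapeQuery]:
    """The seven published MOR shape queries with their ComboScore cutoffs."""
    color_cycle = ("cation", "ring", "HBA", "HBD")
    queries = {}
    for i, (mid, cutoff) in enumerate(SHAPE_CUTOFFS.items()):
        pts = _reference_shape(i, n_atoms=9 + (i % 3))
        colors = (
            (color_cycle[i % 4], pts[0]),
            (color_cycle[(i + 1) % 4], pts[-1]),
        )
        queries[mid] = ShapeQuery(
            model_id=mid,
            heavy_atom_centers=pts,
            color_features=colors,
            combo_cutoff=cutoff,
        )
    return queries
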