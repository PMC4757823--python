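"""Seeded generators for every synthetic input class the pipeline consumes.

The generators emulate the study conditions of a retrospective MOR
virtual-screening benchmark:

* a toy binding pocket presenting the named interaction anchors (Asp147,
  Tyr148, Lys233, ...), spread widely enough that planted contacts are
  unambiguous;
* labelled ligand poses whose polar-contact patterns follow the three
  classes the interaction rules distinguish (agonist-like: the two crucial
  contacts and nothing else; antagonist-like: crucial plus an additional
  polar contact; non-binder: a crucial contact violated);
* benchmark libraries of 45 agonists / 47 antagonists / 148 inactives with
  per-model hit plans planted so that screening reproduces prescribed
  confusion counts exactly;
* matching and decoy conformers for any pharmacophore model.

Every generator is a pure function of (parameters, seed); identical seeds
give bit-identical outputs.  Poses and benchmark compounds are abstract
role-typed point sets, not chemically valid molecules — the downstream
rules operate at the interaction-type level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError
from .library_io import (
    ActivityRecord,
    Compound,
    CompoundLibrary,
    TypedConformer,
)
from .interaction_analysis import (
    LabeledPose,
    PocketAnchor,
    PocketModel,
)
from .pharmacophore_screen import (
    ExclusionVolume,
    PharmacophoreFeature,
    PharmacophoreModel,
    FEATURE_ROLE,
)
from .shape_screen import ShapeQuery

#: Default positional jitter (A) applied to generated pose atoms.
DEFAULT_NOISE_SD = 0.2
#: Above this jitter the planted contact geometry is no longer guaranteed.
SAFE_NOISE_SD = 0.4

POSE_CLASSES = ("agonist-like", "antagonist-like", "non-binder")
BENCHMARK_CLASSES = ("agonist", "antagonist", "inactive")


# ---------------------------------------------------------------------------
# Toy pocket
# ---------------------------------------------------------------------------

_POCKET_SPEC = (
    # (label, group kind, position) — anchors spread >= ~8 A apart so that a
    # contact planted at one anchor can never register at another.
    ("Asp147", "carboxylate", (0.0, 0.0, 0.0)),
    ("Tyr148", "hydroxyl", (8.0, 0.0, 0.0)),
    ("Lys233", "ammonium", (0.0, 9.0, 0.0)),
    ("Gln124", "amide", (-9.0, 0.0, 2.0)),
    ("Glu229", "carboxylate", (0.0, -9.0, 0.0)),
    ("Asn150", "amide", (8.0, 8.0, 3.0)),
    ("Trp318", "indole-NH", (-8.0, -8.0, 0.0)),
    ("Tyr128", "hydroxyl", (-8.0, 8.0, -2.0)),
    ("His297", "imidazole", (9.0, -8.0, -2.0)),
)

#: Point the planted ligand atoms are displaced toward from each anchor.
_POCKET_INTERIOR = np.array([0.0, 0.0, 10.0])


def build_toy_pocket() -> PocketModel:
    """Deterministic toy pocket with the nine named interaction anchors."""
    return PocketModel(
        tuple(
            PocketAnchor(label, kind, np.array(pos))
            for label, kind, pos in _POCKET_SPEC
        )
    )


def _inward(anchor_pos: np.ndarray, dist: float) -> np.ndarray:
    v = _POCKET_INTERIOR - anchor_pos
    return anchor_pos + dist * v / np.linalg.norm(v)


# ---------------------------------------------------------------------------
# Labelled poses
# ---------------------------------------------------------------------------

def _pose_template(label: str, pocket: PocketModel) -> tuple[np.ndarray, tuple[frozenset, ...]]:
    asp = pocket.anchor("Asp147").position
    tyr = pocket.anchor("Tyr148").position
    lys = pocket.anchor("Lys233").position
    coords: list[np.ndarray] = []
    roles: list[frozenset] = []
    if label == "non-binder":
        # the crucial ionic contact with Asp147 is deliberately broken
        coords.append(_inward(asp, 9.0))
    else:
        coords.append(_inward(asp, 3.2))
    roles.append(frozenset({"cationic"}))
    coords.append(_inward(tyr, 2.8))
    roles.append(frozenset({"HBD"}))
    if label == "antagonist-like":
        coords.append(_inward(lys, 2.8))
        roles.append(frozenset({"HBA"}))
    # hydrophobic decor atoms: never polar, never contact-forming
    coords.append(np.array([0.0, 0.0, 14.0]))
    roles.append(frozenset({"hydrophobic"}))
    coords.append(np.array([3.0, 3.0, 14.0]))
    roles.append(frozenset({"hydrophobic"}))
    return np.array(coords), tuple(roles)


def generate_pose_set(
    n_per_class: dict[str, int],
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    pocket: PocketModel | None = None,
) -> list[LabeledPose]:
    """Generate labelled poses with Gaussian positional jitter.

    Agonist-like poses place a cationic atom in ionic range of Asp147 and a
    donor in H-bond range of Tyr148 with no other polar contact;
    antagonist-like poses additionally donate/accept at Lys233; non-binders
    violate the Asp147 contact.  Jitter above :data:`SAFE_NOISE_SD` voids
    the geometric guarantee and triggers a warning.
    """
    if noise_sd < 0:
        raise DomainError("noise_sd must be non-negative")
    if any(v < 0 for v in n_per_class.values()):
        raise DomainError("class counts must be non-negative")
    unknown = set(n_per_class) - set(POSE_CLASSES)
    if unknown:
        raise DomainError(f"unknown pose classes: {sorted(unknown)}")
    if noise_sd > SAFE_NOISE_SD:
        warnings.warn(
            f"noise_sd {noise_sd} exceeds the safe bound {SAFE_NOISE_SD} A; "
            "planted contact geometry is no longer guaranteed",
            stacklevel=2,
        )
    pocket = pocket or build_toy_pocket()
    rng = np.random.default_rng(seed)
    poses: list[LabeledPose] = []
    idx = 0
    for label in POSE_CLASSES:
        count = n_per_class.get(label, 0)
        coords0, roles = _pose_template(label, pocket)
        for _ in range(count):
            jitter = rng.normal(0.0, noise_sd, size=coords0.shape) if noise_sd > 0 else 0.0
            poses.append(
                LabeledPose(
                    compound_id=f"pose-{idx:04d}",
                    coords=coords0 + jitter,
                    atom_roles=roles,
                    truth_label=label,
                )
            )
            idx += 1
    return poses


# ---------------------------------------------------------------------------
# Planted pharmacophore models and benchmark libraries
# ---------------------------------------------------------------------------

# Base features shared by every planted model; extras stack one per model so
# that model k is matched exactly by compounds carrying extras 1..k.  Each
# extra has a distinct feature kind, so a compound lacking the corresponding
# atom role can never satisfy the feature by a spurious correspondence.
_PLANT_BASE = (("PI", (0.0, 0.0, 0.0)), ("HBA", (4.0, 0.0, 0.0)), ("H", (0.0, 4.0, 0.0)))
_PLANT_EXTRAS = (("HBD", (0.0, 0.0, 4.5)), ("Ar", (-4.5, 0.0, 0.0)), ("NI", (0.0, -4.5, 0.0)))
_PLANT_XVOLS = ((12.0, 12.0, 12.0), (-12.0, -12.0, 12.0))


def planted_pharmacophore_models(model_ids: list[str]) -> list[PharmacophoreModel]:
    """Nested planted models: model k requires the base features plus extras 1..k."""
    if not 1 <= len(model_ids) <= len(_PLANT_EXTRAS):
        raise DomainError(f"between 1 and {len(_PLANT_EXTRAS)} planted models supported")
    models = []
    for k, mid in enumerate(model_ids, start=1):
        feats = [PharmacophoreFeature(kind, np.array(c)) for kind, c in _PLANT_BASE]
        feats += [PharmacophoreFeature(kind, np.array(c)) for kind, c in _PLANT_EXTRAS[:k]]
        models.append(
            PharmacophoreModel(
                model_id=mid,
                features=tuple(feats),
                xvols=tuple(ExclusionVolume(np.array(c)) for c in _PLANT_XVOLS),
            )
        )
    return models


# Distinct canonical reference shapes for planted shape queries.  Each query
# carries one colour feature of a kind unique within the ensemble; since
# every cutoff exceeds 1.0 and the colour Tanimoto of disjoint colour kinds
# is 0, a conformer planted for one query can never reach another query's
# cutoff.
def _canonical_shape(index: int) -> tuple[np.ndarray, tuple[tuple[str, np.ndarray], ...], str]:
    if index == 0:  # compact cross
        pts = np.array([[0, 0, 0], [1.5, 0, 0], [-1.5, 0, 0], [0, 1.5, 0], [0, -1.5, 0]], float)
        return pts, (("cation", pts[0]),), "cationic"
    if index == 1:  # extended chain
        pts = np.array([[1.8 * i, 0, 0] for i in range(9)], float)
        return pts, (("ring", pts[-1]),), "aromatic"
    if index == 2:  # asymmetric Y (three unequal arms)
        pts = np.array(
            [[0, 0, 0], [1.8, 0, 0], [3.6, 0, 0], [5.4, 0, 0],
             [0, 1.8, 0], [0, 3.6, 0], [0, 0, 1.8]], float)
        return pts, (("HBA", pts[3]),), "HBA"
    if index == 3:  # L-shape
        arm1 = np.array([[1.8 * i, 0, 0] for i in range(6)], float)
        arm2 = np.array([[9.0, 1.8 * (i + 1), 0] for i in range(5)], float)
        pts = np.vstack([arm1, arm2])
        return pts, (("HBD", pts[5]),), "HBD"
    raise DomainError("at most 4 planted shape queries supported")


_PLANT_SHAPE_CUTOFFS = (1.02, 1.35, 1.50, 1.20)


def planted_shape_queries(model_ids: list[str]) -> list[ShapeQuery]:
    """Planted shape queries with mutually exclusive colour kinds."""
    if not 1 <= len(model_ids) <= 4:
        raise DomainError("between 1 and 4 planted shape queries supported")
    queries = []
    for i, mid in enumerate(model_ids):
        pts, colors, _ = _canonical_shape(i)
        queries.append(
            ShapeQuery(
                model_id=mid,
                heavy_atom_centers=pts,
                color_features=colors,
                combo_cutoff=_PLANT_SHAPE_CUTOFFS[i],
            )
        )
    return queries


@dataclass
class PlantedBenchmark:
    """A planted benchmark: library, models and the hit plan they encode."""

    library: CompoundLibrary
    models: list  # PharmacophoreModel or ShapeQuery
    method: str
    hit_plan: dict[str, tuple[int, int, int]]
    planted_hits: dict[str, frozenset] = field(default_factory=dict)

    @property
    def planned_union(self) -> dict[str, int]:
        """Planned ensemble (union) retrieval count per class."""
        union: set[str] = set()
        for ids in self.planted_hits.values():
            union |= ids
        counts = {c: 0 for c in BENCHMARK_CLASSES}
        for cid in union:
            counts[self.library.annotations[cid].class_label] += 1
        return counts


def _random_rigid(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
    trans = rng.uniform(-20.0, 20.0, size=3)
    return rot, trans


def generate_benchmark_library(
    class_sizes: tuple[int, int, int],
    hit_plan: dict[str, tuple[int, int, int]],
    seed: int = 0,
    method: str = "pharmacophore",
) -> PlantedBenchmark:
    """Build a library plus planted models reproducing a confusion plan exactly.

    ``class_sizes`` is (agonists, antagonists, inactives); ``hit_plan`` maps
    each model id to the (agonist, antagonist, inactive) true-positive
    counts it must retrieve.  For the pharmacophore method the per-model hit
    sets are nested (plan counts must be non-increasing across models for
    every class; the ensemble union equals the first model's counts).  For
    the shape method the hit sets are disjoint consecutive blocks (the
    union equals the per-class sums).  Compound ids carry no class
    information; generation is a pure function of (parameters, seed).
    """
    if method not in ("pharmacophore", "shape"):
        raise DomainError(f"unknown method {method!r}")
    a_ag, a_ant, n_inact = class_sizes
    sizes = {"agonist": a_ag, "antagonist": a_ant, "inactive": n_inact}
    if any(v < 0 for v in sizes.values()):
        raise DomainError("class sizes must be non-negative")
    model_ids = list(hit_plan)
    for mid, counts in hit_plan.items():
        if len(counts) != 3 or any(c < 0 for c in counts):
            raise DomainError(f"plan for {mid!r} must be three non-negative counts")
        for cls, c in zip(BENCHMARK_CLASSES, counts):
            if c > sizes[cls]:
                raise DomainError(
                    f"plan for {mid!r} wants {c} {cls} hits but only {sizes[cls]} exist"
                )
    plan_matrix = np.array([hit_plan[m] for m in model_ids], dtype=int)
    if method == "pharmacophore":
        if np.any(np.diff(plan_matrix, axis=0) > 0):
            raise DomainError(
                "pharmacophore plans are nested: per-class counts must be "
                "non-increasing across models"
            )
        union_counts = plan_matrix[0]
    else:
        union_counts = plan_matrix.sum(axis=0)
        for j, cls in enumerate(BENCHMARK_CLASSES):
            if union_counts[j] > sizes[cls]:
                raise DomainError(
                    f"shape plans are disjoint: total {cls} hits {union_counts[j]} "
                    f"exceed the class size {sizes[cls]}"
                )

    n_total = sum(sizes.values())
    rng = np.random.default_rng(seed)
    ids = [f"M-{i:04d}" for i in range(1, n_total + 1)]
    perm = rng.permutation(n_total)
    class_of: dict[str, str] = {}
    per_class_ids: dict[str, list[str]] = {c: [] for c in BENCHMARK_CLASSES}
    bounds = np.cumsum([0, a_ag, a_ant, n_inact])
    for slot, pos in enumerate(perm):
        cls = BENCHMARK_CLASSES[int(np.searchsorted(bounds, slot, side="right")) - 1]
        class_of[ids[pos]] = cls
        per_class_ids[cls].append(ids[pos])

    if method == "pharmacophore":
        models = planted_pharmacophore_models(model_ids)
    else:
        models = planted_shape_queries(model_ids)

    planted_hits: dict[str, set[str]] = {m: set() for m in model_ids}
    extras_level: dict[str, int] = {}
    shape_assignment: dict[str, int] = {}
    for j, cls in enumerate(BENCHMARK_CLASSES):
        members = per_class_ids[cls]
        if method == "pharmacophore":
            for p, cid in enumerate(members):
                level = int(np.sum(plan_matrix[:, j] > p))
                extras_level[cid] = level
                for k in range(level):
                    planted_hits[model_ids[k]].add(cid)
        else:
            offset = 0
            for k, mid in enumerate(model_ids):
                block = members[offset: offset + plan_matrix[k, j]]
                for cid in block:
                    shape_assignment[cid] = k
                    planted_hits[mid].add(cid)
                offset += plan_matrix[k, j]

    compounds: list[Compound] = []
    annotations: dict[str, ActivityRecord] = {}
    for cid in ids:
        cls = class_of[cid]
        if method == "pharmacophore":
            level = extras_level.get(cid, 0)
            pts = [np.array(c, float) for _, c in _PLANT_BASE]
            roles = [frozenset({FEATURE_ROLE[k]}) for k, _ in _PLANT_BASE]
            for kind, c in _PLANT_EXTRAS[:level]:
                pts.append(np.array(c, float))
                roles.append(frozenset({FEATURE_ROLE[kind]}))
            pts.append(np.array([5.0, 5.0, 5.0]))  # decor atom
            roles.append(frozenset({"hydrophobic"}))
            coords = np.array(pts)
            # sub-tolerance scatter so fitness values vary across compounds
            coords = coords + rng.uniform(-0.2, 0.2, size=coords.shape)
        else:
            k = shape_assignment.get(cid)
            if k is None:
                coords = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
                roles = [frozenset(), frozenset()]
            else:
                pts, colors, color_role = _canonical_shape(k)
                coords = pts + rng.normal(0.0, 0.05, size=pts.shape)
                roles = []
                for i, p in enumerate(pts):
                    if any(np.allclose(p, c) for _, c in colors):
                        roles.append(frozenset({color_role}))
                    else:
                        roles.append(frozenset())
        rot, trans = _random_rigid(rng)
        conf = TypedConformer(coords @ rot.T + trans, tuple(roles))
        compounds.append(Compound(id=cid, conformers=[conf]))
        if cls == "inactive":
            affinity = float(rng.uniform(1000.0, 50000.0))
        else:
            affinity = float(rng.uniform(0.2, 5.0))
        annotations[cid] = ActivityRecord(
            compound_id=cid, affinity_nM=affinity, affinity_kind="Ki", class_label=cls
        )

    library = CompoundLibrary(compounds=compounds, annotations=annotations)
    return PlantedBenchmark(
        library=library,
        models=list(models),
        method=method,
        hit_plan=dict(hit_plan),
        planted_hits={m: frozenset(v) for m, v in planted_hits.items()},
    )


# ---------------------------------------------------------------------------
# Conformers for an arbitrary pharmacophore model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedConformer:
    compound_id: str
    conformer: TypedConformer
    should_match: bool


def generate_conformers_for_model(
    model: PharmacophoreModel,
    n_match: int,
    n_decoy: int,
    seed: int = 0,
) -> list[PlantedConformer]:
    """Conformers planted to match (or fail) a pharmacophore model.

    Matching conformers place one atom of the required role inside each
    feature tolerance sphere and keep every atom out of all exclusion
    volumes; decoys either omit one feature's atom or park an atom at an
    exclusion-volume center.  Raises if the model is geometrically
    infeasible (a feature center inside an exclusion volume).
    """
    if n_match < 0 or n_decoy < 0:
        raise DomainError("counts must be non-negative")
    for f in model.features:
        for xv in model.xvols:
            if np.linalg.norm(f.center - xv.center) < xv.radius:
                raise DomainError(
                    f"model {model.model_id!r} is infeasible: a {f.kind} feature "
                    "center lies inside an exclusion volume"
                )
    rng = np.random.default_rng(seed)
    out: list[PlantedConformer] = []

    def base_atoms(scatter: float) -> tuple[np.ndarray, list[frozenset]]:
        pts, roles = [], []
        for f in model.features:
            offset = rng.normal(size=3)
            offset *= (scatter * f.tolerance * rng.uniform(0, 1) ** (1 / 3)
                       / np.linalg.norm(offset))
            pts.append(f.center + offset)
            roles.append(frozenset({FEATURE_ROLE[f.kind]}))
        return np.array(pts), roles

    for i in range(n_match):
        pts, roles = base_atoms(scatter=0.3)
        if model.xvols and any(
            np.linalg.norm(p - xv.center) < xv.radius for p in pts for xv in model.xvols
        ):
            pts, roles = base_atoms(scatter=0.0)  # fall back to exact centers
        rot, trans = _random_rigid(rng)
        out.append(
            PlantedConformer(
                compound_id=f"match-{i:03d}",
                conformer=TypedConformer(pts @ rot.T + trans, tuple(roles)),
                should_match=True,
            )
        )
    for i in range(n_decoy):
        pts, roles = base_atoms(scatter=0.0)
        if model.xvols and i % 2 == 1:
            # clash decoy: an extra atom parked at an exclusion-volume center
            xv = model.xvols[(i // 2) % len(model.xvols)]
            pts = np.vstack([pts, xv.center])
            roles = roles + [frozenset({"hydrophobic"})]
        else:
            # omission decoy: drop the atom of one feature
            drop = (i // 2) % len(model.features)
            pts = np.delete(pts, drop, axis=0)
            roles = [r for j, r in enumerate(roles) if j != drop]
        rot, trans = _random_rigid(rng)
        out.append(
            PlantedConformer(
                compound_id=f"decoy-{i:03d}",
                conformer=TypedConformer(pts @ rot.T + trans, tuple(roles)),
                should_match=False,
            )
        )
    return out
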