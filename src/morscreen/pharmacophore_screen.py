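"""Pharmacophore models: representation, derivation from poses, matching, screening.

A pharmacophore model is a set of typed interaction features (hydrogen-bond
acceptor HBA, donor HBD, hydrophobic H, positively/negatively ionizable
PI/NI, aromatic Ar), each with a tolerance sphere, plus exclusion volumes
(XVols) that forbid heavy atoms of a matching conformer.

Matching searches over type-compatible feature-to-atom correspondences; each
candidate correspondence is scored by least-squares rigid superposition of
the matched atoms onto the feature centers.  A correspondence is accepted
when every matched feature's center deviation is within its tolerance and no
heavy atom of the aligned conformer lies strictly inside any exclusion
volume.  The fitness of an accepted match is

    fitness = 0.5 * (m / F) + 0.5 * (1 - mean_i(d_i / t_i))

with ``m`` matched features out of ``F`` model features, deviations ``d_i``
and tolerances ``t_i``; it is 1 exactly for a complete zero-deviation match
and 0 for a non-match.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import DomainError
from .library_io import (
    CompoundLibrary,
    ScreeningResult,
    TypedConformer,
    build_screening_result,
)
from .interaction_analysis import (
    GeometryParams,
    LabeledPose,
    PocketModel,
    perceive_polar_contacts,
)

FEATURE_KINDS = ("HBA", "HBD", "H", "PI", "NI", "Ar")

#: Atom role an atom must carry to satisfy a feature of each kind.
FEATURE_ROLE = {
    "HBA": "HBA",
    "HBD": "HBD",
    "H": "hydrophobic",
    "PI": "cationic",
    "NI": "anionic",
    "Ar": "aromatic",
}

DEFAULT_TOLERANCE = 1.5  # A, for all feature kinds
DEFAULT_XVOL_RADIUS = 1.0  # A
DIRECTION_MAX_ANGLE = 45.0  # degrees, when a direction and a partner proxy exist


@dataclass(frozen=True)
class PharmacophoreFeature:
    kind: str
    center: np.ndarray
    tolerance: float = DEFAULT_TOLERANCE
    direction: np.ndarray | None = None

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise DomainError(f"unknown feature kind {self.kind!r}")
        if self.tolerance <= 0:
            raise DomainError("tolerance must be positive")
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.direction is not None:
            d = np.asarray(self.direction, dtype=float)
            if abs(np.linalg.norm(d) - 1.0) > 1e-6:
                raise DomainError("feature direction must be unit-norm")
            object.__setattr__(self, "direction", d)


@dataclass(frozen=True)
class ExclusionVolume:
    center: np.ndarray
    radius: float = DEFAULT_XVOL_RADIUS

    def __post_init__(self):
        if self.radius <= 0:
            raise DomainError("exclusion volume radius must be positive")
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))


@dataclass(frozen=True)
class PharmacophoreModel:
    model_id: str
    features: tuple[PharmacophoreFeature, ...]
    xvols: tuple[ExclusionVolume, ...] = ()
    min_features_required: int | None = None  # None -> all features

    def __post_init__(self):
        if len(self.features) < 1:
            raise DomainError("a model needs at least one feature")
        m = self.min_features_required
        if m is not None and not (1 <= m <= len(self.features)):
            raise DomainError("min_features_required out of range")
        object.__setattr__(self, "features", tuple(self.features))
        object.__setattr__(self, "xvols", tuple(self.xvols))

    @property
    def n_required(self) -> int:
        return self.min_features_required or len(self.features)

    def feature_census(self) -> dict[str, int]:
        census: dict[str, int] = {}
        for f in self.features:
            census[f.kind] = census.get(f.kind, 0) + 1
        return census

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "features": [
                {
                    "kind": f.kind,
                    "center": [float(x) for x in f.center],
                    "tolerance": f.tolerance,
                    **({"direction": [float(x) for x in f.direction]} if f.direction is not None else {}),
                }
                for f in self.features
            ],
            "xvols": [
                {"center": [float(x) for x in v.center], "radius": v.radius}
                for v in self.xvols
            ],
            "min_features_required": self.min_features_required,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PharmacophoreModel":
        return cls(
            model_id=d["model_id"],
            features=tuple(
                PharmacophoreFeature(
                    kind=f["kind"],
                    center=np.array(f["center"], dtype=float),
                    tolerance=float(f.get("tolerance", DEFAULT_TOLERANCE)),
                    direction=(np.array(f["direction"], dtype=float)
                               if f.get("direction") is not None else None),
                )
                for f in d["features"]
            ),
            xvols=tuple(
                ExclusionVolume(np.array(v["center"], dtype=float), float(v["radius"]))
                for v in d.get("xvols", [])
            ),
            min_features_required=d.get("min_features_required"),
        )


def save_models(models: Iterable[PharmacophoreModel], path: str | Path) -> None:
    Path(path).write_text(json.dumps([m.to_dict() for m in models], indent=1))


def load_models(path: str | Path) -> list[PharmacophoreModel]:
    return [PharmacophoreModel.from_dict(d) for d in json.loads(Path(path).read_text())]


@dataclass(frozen=True)
class MatchResult:
    matched: bool
    fitness: float
    correspondence: tuple[tuple[int, int], ...] = ()  # (feature index, atom index)
    rotation: np.ndarray | None = None
    translation: np.ndarray | None = None

    def __post_init__(self):
        if not self.matched and self.fitness != 0.0:
            raise DomainError("non-matches have zero fitness")


NO_MATCH = MatchResult(matched=False, fitness=0.0)


# ---------------------------------------------------------------------------
# Rigid superposition
# ---------------------------------------------------------------------------

def kabsch(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform (R, t) minimising |R src + t - dst|^2."""
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    h = (src - cs).T @ (dst - cd)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = cd - r @ cs
    return r, t


def _score_correspondence(
    conformer: TypedConformer,
    model: PharmacophoreModel,
    feat_idx: Sequence[int],
    atom_idx: Sequence[int],
) -> MatchResult:
    """Superpose the chosen atoms onto the chosen features and score."""
    centers = np.array([model.features[i].center for i in feat_idx])
    atoms = conformer.coords[list(atom_idx)]
    if len(feat_idx) == 1:
        r = np.eye(3)
        t = centers[0] - atoms[0]
    else:
        r, t = kabsch(atoms, centers)
    aligned = atoms @ r.T + t
    devs = np.linalg.norm(aligned - centers, axis=1)
    tols = np.array([model.features[i].tolerance for i in feat_idx])
    if np.any(devs > tols + 1e-9):
        return NO_MATCH
    heavy = conformer.heavy_coords() @ r.T + t
    for xv in model.xvols:
        if np.any(np.linalg.norm(heavy - xv.center, axis=1) < xv.radius - 1e-9):
            return NO_MATCH
    # optional direction test: feature direction vs atom->center-offset proxy
    for k, fi in enumerate(feat_idx):
        f = model.features[fi]
        if f.direction is None:
            continue
        offset = centers[k] - aligned[k]
        nrm = np.linalg.norm(offset)
        if nrm < 1e-9:
            continue  # atom at center: direction satisfied by convention
        cosang = float(np.dot(offset / nrm, f.direction))
        if cosang < np.cos(np.deg2rad(DIRECTION_MAX_ANGLE)):
            return NO_MATCH
    m = len(feat_idx)
    big_f = len(model.features)
    fitness = 0.5 * (m / big_f) + 0.5 * (1.0 - float(np.mean(devs / tols)))
    return MatchResult(
        matched=True,
        fitness=fitness,
        correspondence=tuple(zip(feat_idx, atom_idx)),
        rotation=r,
        translation=t,
    )


def _candidates(conformer: TypedConformer, model: PharmacophoreModel) -> list[list[int]]:
    cands = []
    for f in model.features:
        role = FEATURE_ROLE[f.kind]
        cands.append([i for i, roles in enumerate(conformer.roles) if role in roles])
    return cands


def match_conformer(conformer: TypedConformer, model: PharmacophoreModel) -> MatchResult:
    """Best accepted correspondence of a conformer against a model.

    Uses depth-first search over injective type-compatible assignments,
    ordered by candidate scarcity; every complete assignment is scored by
    rigid superposition.  With ``min_features_required`` below the feature
    count, feature subsets down to that size are also searched.
    """
    if conformer.n_atoms == 0:
        raise DomainError("conformer has no coordinates")
    cands = _candidates(conformer, model)
    n_feat = len(model.features)
    best = NO_MATCH
    for size in range(n_feat, model.n_required - 1, -1):
        for subset in itertools.combinations(range(n_feat), size):
            if any(not cands[i] for i in subset):
                continue
            order = sorted(subset, key=lambda i: len(cands[i]))
            assignment: dict[int, int] = {}
            used: set[int] = set()

            def dfs(pos: int) -> None:
                nonlocal best
                if pos == len(order):
                    res = _score_correspondence(
                        conformer, model,
                        list(subset), [assignment[i] for i in subset],
                    )
                    if res.matched and res.fitness > best.fitness:
                        best = res
                    return
                fi = order[pos]
                for ai in cands[fi]:
                    if ai in used:
                        continue
                    assignment[fi] = ai
                    used.add(ai)
                    dfs(pos + 1)
                    used.discard(ai)
                    del assignment[fi]

            dfs(0)
    return best


def match_conformer_exhaustive(
    conformer: TypedConformer, model: PharmacophoreModel
) -> MatchResult:
    """Plain product-enumeration matcher (independent oracle for tests).

    Enumerates every injective type-compatible assignment via
    ``itertools.permutations`` with no search-order heuristics or pruning.
    """
    if conformer.n_atoms == 0:
        raise DomainError("conformer has no coordinates")
    cands = _candidates(conformer, model)
    n_feat = len(model.features)
    best = NO_MATCH
    for size in range(model.n_required, n_feat + 1):
        for subset in itertools.combinations(range(n_feat), size):
            pool = sorted(set(itertools.chain.from_iterable(cands[i] for i in subset)))
            for perm in itertools.permutations(pool, size):
                if any(perm[k] not in cands[subset[k]] for k in range(size)):
                    continue
                res = _score_correspondence(conformer, model, list(subset), list(perm))
                if res.matched and res.fitness > best.fitness:
                    best = res
    return best


# ---------------------------------------------------------------------------
# Structure-based model derivation
# ---------------------------------------------------------------------------

def derive_structure_based_model(
    pose: LabeledPose,
    pocket: PocketModel,
    params: GeometryParams | None = None,
    model_id: str = "structure-based",
) -> PharmacophoreModel:
    """Derive a pharmacophore model from a pose in a pocket.

    One feature per perceived polar contact (ionic with an anionic anchor
    becomes a PI feature at the ligand's cationic atom; a hydrogen bond
    becomes an HBA or HBD feature at the ligand atom, directed toward the
    anchor), hydrophobic features at hydrophobic-role atoms at least 3 A
    from every polar feature, and one exclusion volume per pocket anchor.
    """
    params = params or GeometryParams()
    fp = perceive_polar_contacts(pose, pocket, params)
    if not fp.contacts:
        raise DomainError("pose forms no polar contacts; nothing to derive")
    features: list[PharmacophoreFeature] = []
    polar_centers: list[np.ndarray] = []
    for residue, kind in sorted(fp.contacts):
        anchor = pocket.anchor(residue)
        d = np.linalg.norm(pose.coords - anchor.position, axis=1)
        if kind == "ionic":
            mask = [
                i for i, roles in enumerate(pose.atom_roles)
                if ("cationic" in roles and "anionic" in anchor.roles)
                or ("anionic" in roles and "cationic" in anchor.roles)
            ]
            cutoff = params.ionic_max_dist
        else:
            mask = [
                i for i, roles in enumerate(pose.atom_roles)
                if ("HBD" in roles and "HBA" in anchor.roles)
                or ("HBA" in roles and "HBD" in anchor.roles)
            ]
            cutoff = params.hbond_max_dist
        in_range = [i for i in mask if d[i] <= cutoff]
        if not in_range:
            continue
        i = min(in_range, key=lambda j: d[j])
        center = pose.coords[i]
        if kind == "ionic":
            fkind = "PI" if "cationic" in pose.atom_roles[i] else "NI"
            direction = None
        else:
            fkind = "HBD" if "HBD" in pose.atom_roles[i] else "HBA"
            vec = anchor.position - center
            direction = vec / np.linalg.norm(vec)
        features.append(PharmacophoreFeature(fkind, center, direction=direction))
        polar_centers.append(center)
    for i, roles in enumerate(pose.atom_roles):
        if "hydrophobic" not in roles:
            continue
        c = pose.coords[i]
        if all(np.linalg.norm(c - p) >= 3.0 for p in polar_centers):
            features.append(PharmacophoreFeature("H", c))
    xvols = tuple(ExclusionVolume(a.position) for a in pocket.anchors)
    return PharmacophoreModel(model_id=model_id, features=tuple(features), xvols=xvols)


# ---------------------------------------------------------------------------
# Library screening
# ---------------------------------------------------------------------------

def screen_pharmacophore(
    library: CompoundLibrary,
    models: Sequence[PharmacophoreModel],
    method: str = "pharmacophore",
    target_class: str | None = None,
) -> ScreeningResult:
    """Screen every compound against a model ensemble (union of hitlists).

    A compound is a hit when at least one model matches at least one of its
    conformers; its score is the maximum fitness over models and conformers.
    Hits are ranked by descending score, ties by compound id.
    """
    if not models:
        raise DomainError("empty model list")
    for c in library.compounds:
        if not c.conformers:
            raise DomainError(f"compound {c.id} has no conformers")
    scores: dict[str, float] = {}
    flags: dict[str, bool] = {}
    best_model: dict[str, str | None] = {}
    per_model: dict[str, set[str]] = {m.model_id: set() for m in models}
    for c in library.compounds:
        best_fit = 0.0
        best_id: str | None = None
        hit = False
        for model in models:
            for conf in c.conformers:
                res = match_conformer(conf, model)
                if res.matched:
                    hit = True
                    per_model[model.model_id].add(c.id)
                    if res.fitness > best_fit or best_id is None:
                        best_fit = res.fitness
                        best_id = model.model_id
        scores[c.id] = best_fit
        flags[c.id] = hit
        best_model[c.id] = best_id
    return build_screening_result(
        method, scores, flags, best_model, per_model, target_class=target_class
    )
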