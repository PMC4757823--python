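"""Gaussian shape overlay, colour scoring and ComboScore-based screening.

Every heavy atom is modelled as a spherical Gaussian ``p * exp(-alpha
|r - c|^2)`` with fixed amplitude ``p = 2.7`` and ``alpha`` chosen so the
Gaussian's integral equals the volume of a 1.7 A hard sphere.  Overlap
volumes use the first-order (pairwise cross term) approximation with the
closed-form two-Gaussian integral; no higher-order inclusion-exclusion
corrections are applied.  The shape Tanimoto is

    T_shape = O_AB / (O_AA + O_BB - O_AB)

and the colour Tanimoto is computed identically over same-kind colour
Gaussians (radius 1.0 A), defined as 0 when either side carries no colour
features.  The ComboScore is the unweighted sum, range 0-2.

Overlay optimization starts from centroid superposition with the four
proper principal-axis alignments and refines each with derivative-free
Nelder-Mead simplex over the six rigid-body degrees of freedom.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .errors import DomainError
from .library_io import (
    CompoundLibrary,
    ScreeningResult,
    TypedConformer,
    build_screening_result,
)

GAUSSIAN_AMPLITUDE = 2.7
ATOM_RADIUS = 1.7  # A, uniform (no per-element radii)
COLOR_RADIUS = 1.0  # A

COLOR_KINDS = ("HBA", "HBD", "cation", "anion", "ring", "hydrophobe")

#: Conformer atom role -> colour kind.
ROLE_COLOR = {
    "HBA": "HBA",
    "HBD": "HBD",
    "cationic": "cation",
    "anionic": "anion",
    "aromatic": "ring",
    "hydrophobic": "hydrophobe",
}

NM_MAX_ITER = 200
NM_TOL = 1e-4  # function-value tolerance
NM_XTOL = 1e-3  # simplex parameter tolerance (rotvec radians / Angstrom)


def gaussian_alpha(radius: float) -> float:
    """Exponent making the Gaussian's volume equal a hard sphere's."""
    return np.pi * (3.0 * GAUSSIAN_AMPLITUDE / (4.0 * np.pi * radius**3)) ** (2.0 / 3.0)


ALPHA_SHAPE = gaussian_alpha(ATOM_RADIUS)
ALPHA_COLOR = gaussian_alpha(COLOR_RADIUS)


@dataclass(frozen=True)
class ShapeQuery:
    """A shape reference: heavy-atom centers, colour features and a cutoff."""

    model_id: str
    heavy_atom_centers: np.ndarray
    color_features: tuple[tuple[str, np.ndarray], ...] = ()
    combo_cutoff: float = 1.0

    def __post_init__(self):
        centers = np.asarray(self.heavy_atom_centers, dtype=float)
        if centers.ndim != 2 or centers.shape[1] != 3 or len(centers) < 1:
            raise DomainError("a shape query needs at least one heavy atom")
        if not (0.0 <= self.combo_cutoff <= 2.0):
            raise DomainError("combo_cutoff must lie in [0, 2]")
        feats = []
        for kind, c in self.color_features:
            if kind not in COLOR_KINDS:
                raise DomainError(f"unknown colour kind {kind!r}")
            feats.append((kind, np.asarray(c, dtype=float)))
        object.__setattr__(self, "heavy_atom_centers", centers)
        object.__setattr__(self, "color_features", tuple(feats))

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "heavy_atom_centers": [[float(x) for x in c] for c in self.heavy_atom_centers],
            "color_features": [
                {"kind": k, "center": [float(x) for x in c]} for k, c in self.color_features
            ],
            "combo_cutoff": self.combo_cutoff,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ShapeQuery":
        return cls(
            model_id=d["model_id"],
            heavy_atom_centers=np.array(d["heavy_atom_centers"], dtype=float),
            color_features=tuple(
                (f["kind"], np.array(f["center"], dtype=float))
                for f in d.get("color_features", [])
            ),
            combo_cutoff=float(d.get("combo_cutoff", 1.0)),
        )


def save_queries(queries: Iterable[ShapeQuery], path: str | Path) -> None:
    Path(path).write_text(json.dumps([q.to_dict() for q in queries], indent=1))


def load_queries(path: str | Path) -> list[ShapeQuery]:
    return [ShapeQuery.from_dict(d) for d in json.loads(Path(path).read_text())]


@dataclass(frozen=True)
class Overlay:
    rotation: np.ndarray
    translation: np.ndarray
    shape_tanimoto: float
    color_tanimoto: float

    @property
    def combo(self) -> float:
        return self.shape_tanimoto + self.color_tanimoto


# ---------------------------------------------------------------------------
# Overlap volumes
# ---------------------------------------------------------------------------

def gaussian_overlap_volume(
    centers_a: np.ndarray, centers_b: np.ndarray, alpha: float = ALPHA_SHAPE
) -> float:
    """First-order Gaussian overlap volume of two center sets.

    Per pair the closed-form two-Gaussian integral
    ``p^2 (pi / (2 alpha))^{3/2} exp(-alpha d^2 / 2)`` is summed.
    """
    a = np.asarray(centers_a, dtype=float)
    b = np.asarray(centers_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DomainError("overlap of an empty center set is undefined")
    a = a.reshape(-1, 3)
    b = b.reshape(-1, 3)
    d2 = np.sum((a[:, None, :] - b[None, :, :]) ** 2, axis=-1)
    pref = GAUSSIAN_AMPLITUDE**2 * (np.pi / (2.0 * alpha)) ** 1.5
    return float(pref * np.exp(-0.5 * alpha * d2).sum())


def shape_tanimoto(centers_a: np.ndarray, centers_b: np.ndarray) -> float:
    oab = gaussian_overlap_volume(centers_a, centers_b)
    oaa = gaussian_overlap_volume(centers_a, centers_a)
    obb = gaussian_overlap_volume(centers_b, centers_b)
    return oab / (oaa + obb - oab)


def _color_groups(features: Sequence[tuple[str, np.ndarray]]) -> dict[str, np.ndarray]:
    groups: dict[str, list[np.ndarray]] = {}
    for kind, c in features:
        groups.setdefault(kind, []).append(np.asarray(c, dtype=float))
    return {k: np.array(v) for k, v in groups.items()}


def color_tanimoto(
    features_a: Sequence[tuple[str, np.ndarray]],
    features_b: Sequence[tuple[str, np.ndarray]],
) -> float:
    """Colour Tanimoto over same-kind colour Gaussians; 0 if either side is empty."""
    if not features_a or not features_b:
        return 0.0
    ga, gb = _color_groups(features_a), _color_groups(features_b)
    oab = oaa = obb = 0.0
    for kind, pts in ga.items():
        oaa += gaussian_overlap_volume(pts, pts, ALPHA_COLOR)
        if kind in gb:
            oab += gaussian_overlap_volume(pts, gb[kind], ALPHA_COLOR)
    for pts in gb.values():
        obb += gaussian_overlap_volume(pts, pts, ALPHA_COLOR)
    return oab / (oaa + obb - oab)


def conformer_color_features(conformer: TypedConformer) -> tuple[tuple[str, np.ndarray], ...]:
    """Colour features of a conformer, one per (atom, role) pair."""
    feats: list[tuple[str, np.ndarray]] = []
    for coord, roles in zip(conformer.coords, conformer.roles):
        for role in sorted(roles):
            kind = ROLE_COLOR.get(role)
            if kind is not None:
                feats.append((kind, coord))
    return tuple(feats)


# ---------------------------------------------------------------------------
# Overlay optimization
# ---------------------------------------------------------------------------

def _principal_axes(coords: np.ndarray) -> np.ndarray:
    """Orthonormal principal axes (columns), deterministic for degenerate sets."""
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered
    w, v = np.linalg.eigh(cov)
    v = v[:, ::-1]  # descending variance
    # fix signs deterministically: largest-magnitude component positive
    for j in range(3):
        k = int(np.argmax(np.abs(v[:, j])))
        if v[k, j] < 0:
            v[:, j] = -v[:, j]
    if np.linalg.det(v) < 0:
        v[:, 2] = -v[:, 2]
    return v


_SIGN_FLIPS = (
    np.diag([1.0, 1.0, 1.0]),
    np.diag([1.0, -1.0, -1.0]),
    np.diag([-1.0, 1.0, -1.0]),
    np.diag([-1.0, -1.0, 1.0]),
)


def _rotvec_to_matrix(rv: np.ndarray) -> np.ndarray:
    """Rodrigues formula; cheaper than a Rotation object in a tight loop."""
    import math

    theta = math.sqrt(rv[0] * rv[0] + rv[1] * rv[1] + rv[2] * rv[2])
    if theta < 1e-12:
        return np.eye(3)
    kx, ky, kz = rv[0] / theta, rv[1] / theta, rv[2] / theta
    s, c = math.sin(theta), math.cos(theta)
    omc = 1.0 - c
    return np.array([
        [c + kx * kx * omc, kx * ky * omc - kz * s, kx * kz * omc + ky * s],
        [ky * kx * omc + kz * s, c + ky * ky * omc, ky * kz * omc - kx * s],
        [kz * kx * omc - ky * s, kz * ky * omc + kx * s, c + kz * kz * omc],
    ])


_PAIR_PREF_SHAPE = GAUSSIAN_AMPLITUDE**2 * (np.pi / (2.0 * ALPHA_SHAPE)) ** 1.5
_PAIR_PREF_COLOR = GAUSSIAN_AMPLITUDE**2 * (np.pi / (2.0 * ALPHA_COLOR)) ** 1.5


class _OverlayProblem:
    """Pre-computed self-overlap terms for fast repeated combo evaluation."""

    def __init__(self, query: ShapeQuery, coords: np.ndarray,
                 colors: Sequence[tuple[str, np.ndarray]]):
        self.q_shape = query.heavy_atom_centers
        self.c_shape = coords
        self.cc = coords.mean(axis=0)
        self.oqq = gaussian_overlap_volume(self.q_shape, self.q_shape)
        self.occ = gaussian_overlap_volume(coords, coords)
        self.q2 = np.einsum("ij,ij->i", self.q_shape, self.q_shape)
        self.c_centered = coords - self.cc
        gq = _color_groups(query.color_features)
        gc = _color_groups([(k, c - self.cc) for k, c in colors])
        self.color_pairs = [
            (gq[k], gc[k]) for k in sorted(set(gq) & set(gc))
        ]
        self.has_colors = bool(gq) and bool(gc)
        if self.has_colors:
            self.oqq_col = sum(
                gaussian_overlap_volume(p, p, ALPHA_COLOR) for p in gq.values()
            )
            self.occ_col = sum(
                gaussian_overlap_volume(p, p, ALPHA_COLOR) for p in gc.values()
            )

    def combo(self, rotation: np.ndarray, translation: np.ndarray) -> tuple[float, float]:
        moved = self.c_centered @ rotation.T + translation
        m2 = np.einsum("ij,ij->i", moved, moved)
        d2 = self.q2[:, None] + m2[None, :] - 2.0 * (self.q_shape @ moved.T)
        oab = _PAIR_PREF_SHAPE * np.exp(-0.5 * ALPHA_SHAPE * d2).sum()
        st = oab / (self.oqq + self.occ - oab)
        if not self.has_colors:
            return float(st), 0.0
        oab_c = 0.0
        for qpts, cpts in self.color_pairs:
            moved_c = cpts @ rotation.T + translation
            d2c = np.sum((qpts[:, None, :] - moved_c[None, :, :]) ** 2, axis=-1)
            oab_c += _PAIR_PREF_COLOR * np.exp(-0.5 * ALPHA_COLOR * d2c).sum()
        ct = oab_c / (self.oqq_col + self.occ_col - oab_c)
        return float(st), float(ct)


def optimize_overlay(query: ShapeQuery, conformer: TypedConformer) -> Overlay:
    """Best rigid overlay of a conformer onto a shape query.

    Never returns a combo below the best initial alignment's combo.  The
    returned transform maps centered conformer coordinates into the query
    frame: ``x -> R (x - centroid_conf) + t``.
    """
    if conformer.n_atoms == 0:
        raise DomainError("conformer has no coordinates")
    coords = conformer.heavy_coords()
    if len(coords) == 0:
        raise DomainError("conformer has no heavy atoms")
    colors = conformer_color_features(conformer)
    problem = _OverlayProblem(query, coords, colors)
    qc = query.heavy_atom_centers.mean(axis=0)
    uq = _principal_axes(query.heavy_atom_centers)
    uc = _principal_axes(coords)

    starts: list[tuple[np.ndarray, np.ndarray]] = []
    for s in _SIGN_FLIPS:
        r0 = uq @ s @ uc.T
        if np.linalg.det(r0) < 0:  # defensive; sign flips keep det = +1
            r0 = uq @ (-s) @ uc.T
        starts.append((r0, qc.copy()))

    best_r, best_t = starts[0]
    best_st, best_ct = problem.combo(best_r, best_t)
    for r0, t0 in starts[1:]:
        st, ct = problem.combo(r0, t0)
        if st + ct > best_st + best_ct:
            best_r, best_t, best_st, best_ct = r0, t0, st, ct

    def neg_combo(x: np.ndarray) -> float:
        st, ct = problem.combo(_rotvec_to_matrix(x[:3]), x[3:])
        return -(st + ct)

    for r0, t0 in starts:
        x0 = np.concatenate([Rotation.from_matrix(r0).as_rotvec(), t0])
        res = minimize(
            neg_combo, x0, method="Nelder-Mead",
            options={"maxiter": NM_MAX_ITER, "xatol": NM_XTOL, "fatol": NM_TOL},
        )
        r = _rotvec_to_matrix(res.x[:3])
        st, ct = problem.combo(r, res.x[3:])
        if st + ct > best_st + best_ct:
            best_r, best_t, best_st, best_ct = r, res.x[3:], st, ct

    return Overlay(
        rotation=best_r, translation=best_t,
        shape_tanimoto=best_st, color_tanimoto=best_ct,
    )


# ---------------------------------------------------------------------------
# Library screening
# ---------------------------------------------------------------------------

def screen_shape(
    library: CompoundLibrary,
    queries: Sequence[ShapeQuery],
    method: str = "shape",
    target_class: str | None = None,
) -> ScreeningResult:
    """Screen a library against shape queries; hit iff best combo meets a cutoff.

    The reported score is the best combo over all queries and conformers;
    per-query hit membership is retained.  Ranking follows the
    pharmacophore convention (score descending, ties by compound id).
    """
    if not queries:
        raise DomainError("empty query list")
    for c in library.compounds:
        if not c.conformers:
            raise DomainError(f"compound {c.id} has no conformers")
    scores: dict[str, float] = {}
    flags: dict[str, bool] = {}
    best_model: dict[str, str | None] = {}
    per_model: dict[str, set[str]] = {q.model_id: set() for q in queries}
    for c in library.compounds:
        best_combo = 0.0
        best_id: str | None = None
        hit = False
        for q in queries:
            for conf in c.conformers:
                ov = optimize_overlay(q, conf)
                if ov.combo >= q.combo_cutoff:
                    hit = True
                    per_model[q.model_id].add(c.id)
                if ov.combo > best_combo:
                    best_combo = ov.combo
                    best_id = q.model_id
        scores[c.id] = best_combo
        flags[c.id] = hit
        best_model[c.id] = best_id
    return build_screening_result(
        method, scores, flags, best_model, per_model, target_class=target_class
    )
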