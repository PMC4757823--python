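"""Compound and activity data model, plus readers/writers for external formats.

A :class:`Compound` carries an optional RDKit molecular graph and any number of
role-typed 3D conformers.  Role typing (H-bond donor/acceptor, cationic,
anionic, hydrophobic, aromatic) is the level at which every downstream stage of
the pipeline operates: interaction perception, pharmacophore matching and
shape colour scoring all consume :class:`TypedConformer` objects, which can be
derived from a real molecule or generated synthetically.

Activity annotation follows the benchmark convention of the screening study
this package models: ligands with Ki or IC50 of at most 5 nM count as active,
at least 1000 nM as inactive, and the band in between is excluded from
benchmark construction ("intermediate").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdmolops

from .errors import DomainError

logger = logging.getLogger(__name__)

#: Affinity (nM) at or below which a ligand counts as active.
ACTIVE_CUTOFF_NM = 5.0
#: Affinity (nM) at or above which a ligand counts as inactive.
INACTIVE_CUTOFF_NM = 1000.0

#: Atom interaction roles understood throughout the pipeline.
ROLES = frozenset(
    {"HBA", "HBD", "cationic", "anionic", "hydrophobic", "aromatic"}
)


@dataclass(frozen=True)
class TypedConformer:
    """A 3D point set with per-point interaction roles.

    ``coords`` is an (n, 3) array in Angstrom.  ``roles`` holds one frozenset
    of role strings per point.  ``is_heavy`` marks points that are physical
    heavy atoms (aromatic ring centroids derived from a molecule are
    pseudo-points and are excluded from exclusion-volume and shape checks).
    """

    coords: np.ndarray
    roles: tuple[frozenset, ...]
    is_heavy: tuple[bool, ...] = ()

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise DomainError("conformer coordinates must be an (n, 3) array")
        if not np.all(np.isfinite(coords)):
            raise DomainError("conformer coordinates must be finite")
        if len(self.roles) != len(coords):
            raise DomainError("one role set required per atom")
        for r in self.roles:
            if not r <= ROLES:
                raise DomainError(f"unknown atom roles: {set(r) - ROLES}")
        object.__setattr__(self, "coords", coords)
        if not self.is_heavy:
            object.__setattr__(self, "is_heavy", tuple([True] * len(coords)))

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def heavy_coords(self) -> np.ndarray:
        mask = np.asarray(self.is_heavy, dtype=bool)
        return self.coords[mask]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "TypedConformer":
        """Return a copy with ``x -> R x + t`` applied to every point."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        return TypedConformer(
            coords=self.coords @ rotation.T + translation,
            roles=self.roles,
            is_heavy=self.is_heavy,
        )


@dataclass
class Compound:
    """A screened molecule: id, optional molecular graph, typed conformers."""

    id: str
    mol: Chem.Mol | None = None
    conformers: list[TypedConformer] = field(default_factory=list)

    @property
    def n_heavy_atoms(self) -> int | None:
        if self.mol is not None:
            return self.mol.GetNumHeavyAtoms()
        if self.conformers:
            return int(sum(self.conformers[0].is_heavy))
        return None


@dataclass(frozen=True)
class ActivityRecord:
    """Measured affinity and functional class of one compound.

    ``class_label`` is one of agonist / antagonist / inactive / unknown.
    Functional labels (agonist vs antagonist) always come from assay
    annotation, never from the affinity value alone.
    """

    compound_id: str
    affinity_nM: float | None = None
    affinity_kind: str = "Ki"
    class_label: str = "unknown"

    def __post_init__(self):
        if self.affinity_kind not in ("Ki", "IC50"):
            raise DomainError(f"affinity_kind must be Ki or IC50, got {self.affinity_kind!r}")
        if self.class_label not in ("agonist", "antagonist", "inactive", "unknown"):
            raise DomainError(f"unknown class_label {self.class_label!r}")
        if self.affinity_nM is not None:
            if self.affinity_nM <= 0:
                raise DomainError("affinity must be positive")
            if self.class_label in ("agonist", "antagonist") and self.affinity_nM > ACTIVE_CUTOFF_NM:
                raise DomainError(
                    f"{self.class_label} label requires affinity <= {ACTIVE_CUTOFF_NM} nM"
                )
            if self.class_label == "inactive" and self.affinity_nM < INACTIVE_CUTOFF_NM:
                raise DomainError(
                    f"inactive label requires affinity >= {INACTIVE_CUTOFF_NM} nM"
                )


@dataclass
class CompoundLibrary:
    """An ordered compound collection with optional activity annotation."""

    compounds: list[Compound]
    annotations: dict[str, ActivityRecord] = field(default_factory=dict)
    n_parse_failures: int = 0

    def __post_init__(self):
        ids = [c.id for c in self.compounds]
        if len(set(ids)) != len(ids):
            raise DomainError("compound ids must be unique within a library")
        unknown = set(self.annotations) - set(ids)
        if unknown:
            raise DomainError(f"annotations for unknown compound ids: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.compounds)

    def __iter__(self):
        return iter(self.compounds)

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.compounds]

    def compound(self, compound_id: str) -> Compound:
        for c in self.compounds:
            if c.id == compound_id:
                return c
        raise KeyError(compound_id)

    def count_active(self, active_classes: Iterable[str] = ("agonist", "antagonist")) -> int:
        active = set(active_classes)
        return sum(1 for r in self.annotations.values() if r.class_label in active)


def assign_activity_class(affinity_nM: float, affinity_kind: str = "Ki") -> str:
    """Bin an affinity into active / inactive / intermediate.

    Ki and IC50 are treated interchangeably.  The boundaries are inclusive on
    both sides: 5 nM is active, 1000 nM is inactive.
    """
    if affinity_kind not in ("Ki", "IC50"):
        raise DomainError(f"affinity_kind must be Ki or IC50, got {affinity_kind!r}")
    if not np.isfinite(affinity_nM) or affinity_nM <= 0:
        raise DomainError(f"affinity must be a positive number, got {affinity_nM}")
    if affinity_nM <= ACTIVE_CUTOFF_NM:
        return "active"
    if affinity_nM >= INACTIVE_CUTOFF_NM:
        return "inactive"
    return "intermediate"


# ---------------------------------------------------------------------------
# Role typing of real molecules
# ---------------------------------------------------------------------------

def typed_conformer_from_mol(mol: Chem.Mol, conf_id: int = 0) -> TypedConformer:
    """Derive a role-typed point set from an RDKit molecule conformer.

    Typing heuristics (documented contract of the matcher):

    * cationic: nitrogen with positive formal charge, or an sp3 amine nitrogen
      not bonded to a carbonyl carbon (positively ionizable at physiological pH)
    * anionic: atom with negative formal charge
    * HBA: neutral or anionic N/O (excluding pyrrole-type aromatic N-H)
    * HBD: N/O bearing at least one hydrogen
    * hydrophobic: carbon at topological distance >= 3 bonds from every heteroatom
    * aromatic: ring centroids of aromatic rings, added as non-heavy pseudo-points
    """
    conf = mol.GetConformer(conf_id)
    dmat = rdmolops.GetDistanceMatrix(mol)
    hetero = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() not in (1, 6)]
    coords: list[np.ndarray] = []
    roles: list[frozenset] = []
    heavy: list[bool] = []
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 1:
            continue
        pos = conf.GetAtomPosition(atom.GetIdx())
        r: set[str] = set()
        z = atom.GetAtomicNum()
        charge = atom.GetFormalCharge()
        if charge < 0:
            r.add("anionic")
        if z == 7:
            amide = any(
                nb.GetAtomicNum() == 6
                and any(b.GetBondTypeAsDouble() == 2.0 and
                        b.GetOtherAtom(nb).GetAtomicNum() in (7, 8)
                        for b in nb.GetBonds())
                for nb in atom.GetNeighbors()
            )
            if charge > 0 or (not atom.GetIsAromatic() and not amide
                              and atom.GetTotalDegree() <= 4 and charge == 0
                              and atom.GetHybridization() == Chem.HybridizationType.SP3):
                r.add("cationic")
        if z in (7, 8) and charge <= 0:
            pyrrole_like = z == 7 and atom.GetIsAromatic() and atom.GetTotalNumHs() > 0
            if not pyrrole_like:
                r.add("HBA")
        if z in (7, 8) and atom.GetTotalNumHs() > 0:
            r.add("HBD")
        if z == 6:
            if not hetero or min(dmat[atom.GetIdx(), h] for h in hetero) >= 3:
                r.add("hydrophobic")
        coords.append(np.array([pos.x, pos.y, pos.z]))
        roles.append(frozenset(r))
        heavy.append(True)
    # aromatic ring centroids as pseudo-points
    ring_info = mol.GetRingInfo()
    for ring in ring_info.AtomRings():
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            pts = np.array([[conf.GetAtomPosition(i).x,
                             conf.GetAtomPosition(i).y,
                             conf.GetAtomPosition(i).z] for i in ring])
            coords.append(pts.mean(axis=0))
            roles.append(frozenset({"aromatic"}))
            heavy.append(False)
    if not coords:
        raise DomainError("molecule has no heavy atoms")
    return TypedConformer(np.array(coords), tuple(roles), tuple(heavy))


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_compound_library(path: str | Path, format: str | None = None) -> CompoundLibrary:
    """Read an SDF (V2000) or SMILES file into a :class:`CompoundLibrary`.

    Unparsable records are skipped with a logged warning; the skip count is
    reported on the returned library (``n_parse_failures``).  SDF 3D
    coordinates are preserved verbatim; SMILES records carry no conformers.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if format is None:
        format = "sdf" if path.suffix.lower() == ".sdf" else "smiles"
    if format not in ("sdf", "smiles"):
        raise DomainError(f"unknown format {format!r}")

    compounds: list[Compound] = []
    failures = 0
    if format == "sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                failures += 1
                logger.warning("skipping unparsable SDF record %d in %s", i, path)
                continue
            cid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"record-{i}"
            conformers = []
            if mol.GetNumConformers() > 0:
                conformers.append(typed_conformer_from_mol(mol))
            compounds.append(Compound(id=cid, mol=mol, conformers=conformers))
    else:
        for i, line in enumerate(path.read_text().splitlines()):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            smiles = parts[0]
            cid = parts[1] if len(parts) > 1 else f"record-{i}"
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                failures += 1
                logger.warning("skipping unparsable SMILES on line %d of %s", i + 1, path)
                continue
            compounds.append(Compound(id=cid, mol=mol, conformers=[]))
    # de-duplicate ids defensively (parser contract: unique within library)
    seen: dict[str, int] = {}
    for c in compounds:
        if c.id in seen:
            seen[c.id] += 1
            c.id = f"{c.id}-dup{seen[c.id]}"
        else:
            seen[c.id] = 0
    return CompoundLibrary(compounds=compounds, n_parse_failures=failures)


def read_activity_table(path: str | Path) -> dict[str, ActivityRecord]:
    """Read a CSV annotation table (compound_id,affinity_nM,affinity_kind,class_label)."""
    df = pd.read_csv(path)
    required = {"compound_id", "affinity_nM", "affinity_kind", "class_label"}
    if not required <= set(df.columns):
        raise DomainError(f"annotation table must have columns {sorted(required)}")
    records = {}
    for row in df.itertuples(index=False):
        affinity = None if pd.isna(row.affinity_nM) else float(row.affinity_nM)
        records[str(row.compound_id)] = ActivityRecord(
            compound_id=str(row.compound_id),
            affinity_nM=affinity,
            affinity_kind=str(row.affinity_kind),
            class_label=str(row.class_label),
        )
    return records


def write_activity_table(records: Mapping[str, ActivityRecord], path: str | Path) -> None:
    rows = [
        {
            "compound_id": r.compound_id,
            "affinity_nM": r.affinity_nM,
            "affinity_kind": r.affinity_kind,
            "class_label": r.class_label,
        }
        for r in records.values()
    ]
    pd.DataFrame(rows, columns=["compound_id", "affinity_nM", "affinity_kind", "class_label"]).to_csv(
        path, index=False
    )


def write_library_sdf(library: CompoundLibrary, path: str | Path) -> None:
    """Write molecules (those with an RDKit graph) to an SDF file."""
    writer = Chem.SDWriter(str(path))
    try:
        for c in library.compounds:
            if c.mol is None:
                continue
            mol = Chem.Mol(c.mol)
            mol.SetProp("_Name", c.id)
            writer.write(mol)
    finally:
        writer.close()


# ---------------------------------------------------------------------------
# Screening results
# ---------------------------------------------------------------------------

REPORT_COLUMNS = ["compound_id", "method", "model_id", "score", "is_hit", "rank"]


@dataclass
class ScreeningResult:
    """Ranked per-compound outcome of screening a library against an ensemble.

    ``table`` has one row per screened compound with the documented column
    order (compound_id, method, model_id, score, is_hit, rank).  Hits are
    ranked 1..h by descending score, ties broken by compound id; non-hits
    carry a null rank.  ``per_model_hits`` records which compounds each
    individual model retrieved.
    """

    method: str
    table: pd.DataFrame
    per_model_hits: dict[str, frozenset] = field(default_factory=dict)
    target_class: str | None = None

    def hit_ids(self) -> list[str]:
        """Hit compound ids in rank order."""
        hits = self.table[self.table["is_hit"]].sort_values("rank")
        return hits["compound_id"].tolist()

    @property
    def n_hits(self) -> int:
        return int(self.table["is_hit"].sum())

    def score_of(self, compound_id: str) -> float:
        row = self.table.loc[self.table["compound_id"] == compound_id]
        if row.empty:
            raise KeyError(compound_id)
        return float(row["score"].iloc[0])


def build_screening_result(
    method: str,
    scores: Mapping[str, float],
    hit_flags: Mapping[str, bool],
    best_model: Mapping[str, str | None],
    per_model_hits: Mapping[str, Iterable[str]],
    target_class: str | None = None,
) -> ScreeningResult:
    """Assemble a ranked :class:`ScreeningResult` from per-compound outcomes."""
    ids = sorted(scores)
    order = sorted(ids, key=lambda i: (-scores[i], i))
    ranks: dict[str, int | None] = {}
    r = 0
    for cid in order:
        if hit_flags[cid]:
            r += 1
            ranks[cid] = r
        else:
            ranks[cid] = None
    rows = [
        {
            "compound_id": cid,
            "method": method,
            "model_id": best_model.get(cid),
            "score": float(scores[cid]),
            "is_hit": bool(hit_flags[cid]),
            "rank": ranks[cid],
        }
        for cid in order
    ]
    table = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    table["rank"] = table["rank"].astype("Int64")
    return ScreeningResult(
        method=method,
        table=table,
        per_model_hits={m: frozenset(v) for m, v in per_model_hits.items()},
        target_class=target_class,
    )


def write_screening_report(result: ScreeningResult, path: str | Path) -> None:
    """Write a screening result as CSV; scores round-trip to 12 significant digits."""
    if result.table.empty:
        raise DomainError("cannot write an empty screening result")
    result.table.to_csv(path, index=False, float_format="%.12g")


def read_screening_report(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if list(df.columns) != REPORT_COLUMNS:
        raise DomainError(f"report must have columns {REPORT_COLUMNS}, got {list(df.columns)}")
    df["rank"] = df["rank"].astype("Int64")
    return df
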