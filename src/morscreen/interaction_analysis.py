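"""Polar protein-ligand contact perception and binding-mode classification.

The classification rules operate on the interaction pattern a docked pose
forms with the binding pocket of the mu opioid receptor (residue numbering of
the murine MOR crystal structure, PDB 4DKL):

* binder rule: a charged (ionic) interaction with Asp147 **and** a hydrogen
  bond with Tyr148 are jointly required for binding;
* function rule: a binder that forms at least one *additional* polar contact
  with residues such as Lys233, Gln124, Glu229, Asn150, Trp318 or Tyr128 is
  called antagonist-like, a binder without any such extra contact
  agonist-like.

His297 hydrogen bonds (often water-mediated in crystal structures) are
perceivable but deliberately excluded from both rules, as are hydrophobic
contacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError

#: Residues whose polar contacts mark a binder as antagonist-like.
ADDITIONAL_RESIDUES = frozenset(
    {"Lys233", "Gln124", "Glu229", "Asn150", "Trp318", "Tyr128"}
)
#: Residue labels accepted as aliases (e.g. an alternate reading of 229).
ADDITIONAL_RESIDUE_ALIASES = {"Gln229": "Glu229"}

#: Chemical group kinds a pocket anchor may present, with the interaction
#: roles each kind supports.
GROUP_ROLES = {
    "carboxylate": frozenset({"HBA", "anionic"}),
    "hydroxyl": frozenset({"HBA", "HBD"}),
    "ammonium": frozenset({"HBD", "cationic"}),
    "amide": frozenset({"HBA", "HBD"}),
    "indole-NH": frozenset({"HBD"}),
    "imidazole": frozenset({"HBA", "HBD"}),
}


@dataclass(frozen=True)
class GeometryParams:
    """Distance/angle cutoffs for contact perception.

    Defaults follow standard interaction-profiler conventions: heavy-atom
    donor-acceptor distance 3.5 A for hydrogen bonds (with a 120 degree
    D-H...A angle test applied only when explicit hydrogens are present),
    charged-group centroid distance 5.5 A for ionic contacts.
    """

    hbond_max_dist: float = 3.5
    hbond_min_angle: float = 120.0
    ionic_max_dist: float = 5.5

    def __post_init__(self):
        if self.hbond_max_dist <= 0 or self.ionic_max_dist <= 0 or self.hbond_min_angle <= 0:
            raise DomainError("geometry parameters must be positive")


@dataclass(frozen=True)
class PocketAnchor:
    """A functional-group anchor of the binding pocket."""

    residue_label: str
    group_kind: str
    position: np.ndarray
    roles: frozenset = frozenset()

    def __post_init__(self):
        if self.group_kind not in GROUP_ROLES:
            raise DomainError(f"unknown group kind {self.group_kind!r}")
        roles = self.roles or GROUP_ROLES[self.group_kind]
        if not roles or not roles <= GROUP_ROLES[self.group_kind]:
            raise DomainError(
                f"roles {set(roles)} inconsistent with group kind {self.group_kind!r}"
            )
        object.__setattr__(self, "roles", frozenset(roles))
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))


@dataclass(frozen=True)
class PocketModel:
    """A set of uniquely labelled pocket anchors."""

    anchors: tuple[PocketAnchor, ...]

    def __post_init__(self):
        labels = [a.residue_label for a in self.anchors]
        if len(set(labels)) != len(labels):
            raise DomainError("residue labels must be unique")

    def anchor(self, residue_label: str) -> PocketAnchor:
        for a in self.anchors:
            if a.residue_label == residue_label:
                return a
        raise KeyError(residue_label)

    @property
    def labels(self) -> list[str]:
        return [a.residue_label for a in self.anchors]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "PocketModel":
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        return PocketModel(
            tuple(
                PocketAnchor(a.residue_label, a.group_kind,
                             rotation @ a.position + translation, a.roles)
                for a in self.anchors
            )
        )


@dataclass(frozen=True)
class LabeledPose:
    """A ligand pose as a role-typed heavy-atom point set with a truth label."""

    compound_id: str
    coords: np.ndarray
    atom_roles: tuple[frozenset, ...]
    truth_label: str = "unknown"

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3 or not np.all(np.isfinite(coords)):
            raise DomainError("pose coordinates must be a finite (n, 3) array")
        if len(self.atom_roles) != len(coords):
            raise DomainError("one role set per atom required")
        object.__setattr__(self, "coords", coords)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LabeledPose":
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        return LabeledPose(
            self.compound_id, self.coords @ rotation.T + translation,
            self.atom_roles, self.truth_label,
        )


@dataclass(frozen=True)
class InteractionFingerprint:
    """The set of perceived polar contacts: (residue_label, kind) pairs.

    ``kind`` is "hbond" or "ionic".  ``water_mediated`` is an optional
    separate channel (e.g. His297 via a water network) that the
    classification rules never consume.
    """

    contacts: frozenset = frozenset()
    water_mediated: frozenset = frozenset()

    def residues(self) -> frozenset:
        return frozenset(r for r, _ in self.contacts)

    def has(self, residue_label: str, kind: str) -> bool:
        return (residue_label, kind) in self.contacts


@dataclass(frozen=True)
class FunctionCall:
    """Binder verdict plus functional assignment with supporting contacts."""

    binder: bool
    function: str  # agonist-like | antagonist-like | indeterminate
    evidence: frozenset = frozenset()

    def __post_init__(self):
        if not self.binder and self.function != "indeterminate":
            raise DomainError("non-binders must be functionally indeterminate")


def perceive_polar_contacts(
    pose: LabeledPose,
    pocket: PocketModel,
    params: GeometryParams | None = None,
) -> InteractionFingerprint:
    """Perceive ionic and hydrogen-bond contacts between a pose and a pocket.

    An ionic contact (residue, ionic) is recorded when a cationic ligand atom
    lies within ``ionic_max_dist`` of an anionic anchor (or vice versa).  A
    hydrogen bond (residue, hbond) is recorded when a donor/acceptor role
    pairing lies within ``hbond_max_dist``; with no explicit hydrogens the
    test is distance-only.  Pose and pocket must share one coordinate frame
    (Angstrom); a unit mismatch is undetectable and part of the contract.
    """
    params = params or GeometryParams()
    if pose.coords.shape[0] == 0:
        raise DomainError("empty pose")
    contacts: set[tuple[str, str]] = set()
    for anchor in pocket.anchors:
        d = np.linalg.norm(pose.coords - anchor.position, axis=1)
        for i, roles in enumerate(pose.atom_roles):
            ionic_pair = ("cationic" in roles and "anionic" in anchor.roles) or (
                "anionic" in roles and "cationic" in anchor.roles
            )
            if ionic_pair and d[i] <= params.ionic_max_dist:
                contacts.add((anchor.residue_label, "ionic"))
            hb_pair = ("HBD" in roles and "HBA" in anchor.roles) or (
                "HBA" in roles and "HBD" in anchor.roles
            )
            if hb_pair and d[i] <= params.hbond_max_dist:
                contacts.add((anchor.residue_label, "hbond"))
    return InteractionFingerprint(contacts=frozenset(contacts))


def classify_binding(fp: InteractionFingerprint) -> bool:
    """Binder rule: ionic contact with Asp147 and hydrogen bond with Tyr148.

    Contacts with His297 (or any other residue) neither help nor hurt.
    """
    return fp.has("Asp147", "ionic") and fp.has("Tyr148", "hbond")


def classify_function(
    fp: InteractionFingerprint,
    additional_residues: frozenset | None = None,
    accept_aliases: bool = True,
) -> FunctionCall:
    """Function rule: extra polar contacts beyond the crucial pair mark an antagonist.

    ``additional_residues`` defaults to :data:`ADDITIONAL_RESIDUES`; with
    ``accept_aliases`` the alias spellings in
    :data:`ADDITIONAL_RESIDUE_ALIASES` also count.
    """
    residues = additional_residues if additional_residues is not None else ADDITIONAL_RESIDUES
    if accept_aliases:
        residues = frozenset(residues) | frozenset(
            alias for alias, canon in ADDITIONAL_RESIDUE_ALIASES.items() if canon in residues
        )
    if not classify_binding(fp):
        return FunctionCall(binder=False, function="indeterminate")
    extra = frozenset(c for c in fp.contacts if c[0] in residues)
    if extra:
        return FunctionCall(binder=True, function="antagonist-like", evidence=extra)
    return FunctionCall(binder=True, function="agonist-like")


def classify_pose(
    pose: LabeledPose,
    pocket: PocketModel,
    params: GeometryParams | None = None,
) -> FunctionCall:
    """Perceive contacts and apply both rules in one call."""
    return classify_function(perceive_polar_contacts(pose, pocket, params))


def summarize_class_rates(calls: list[FunctionCall], truth: list[str]):
    """Per-true-class binder rates and functional assignment rates.

    Returns a DataFrame indexed by true class with columns ``n``,
    ``binder_frac``, ``agonist_like_frac``, ``antagonist_like_frac`` and the
    corresponding percentages rounded to 0.1%.
    """
    import pandas as pd

    if len(calls) != len(truth):
        raise DomainError("calls and truth labels must have equal length")
    if not calls:
        return pd.DataFrame(
            columns=["n", "binder_frac", "agonist_like_frac", "antagonist_like_frac",
                     "binder_pct", "agonist_like_pct", "antagonist_like_pct"]
        )
    df = pd.DataFrame({"truth": truth,
                       "binder": [c.binder for c in calls],
                       "function": [c.function for c in calls]})
    rows = {}
    for label, grp in df.groupby("truth"):
        n = len(grp)
        rows[label] = {
            "n": n,
            "binder_frac": grp["binder"].mean(),
            "agonist_like_frac": (grp["function"] == "agonist-like").mean(),
            "antagonist_like_frac": (grp["function"] == "antagonist-like").mean(),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    for col in ("binder", "agonist_like", "antagonist_like"):
        out[f"{col}_pct"] = (out[f"{col}_frac"] * 1000).round() / 10
    out["n"] = out["n"].astype(int)
    return out
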