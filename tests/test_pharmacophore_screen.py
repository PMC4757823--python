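"""Pharmacophore matcher: fitness formula, invariances, oracle agreement."""

import numpy as np
import pytest

from morscreen.errors import DomainError
from morscreen.library_io import Compound, CompoundLibrary, TypedConformer
from morscreen.pharmacophore_screen import (
    FEATURE_ROLE,
    ExclusionVolume,
    PharmacophoreFeature,
    PharmacophoreModel,
    load_models,
    match_conformer,
    match_conformer_exhaustive,
    save_models,
    screen_pharmacophore,
    derive_structure_based_model,
)
from morscreen.synthetic_data import build_toy_pocket, generate_pose_set

from conftest import random_rotation

TOL = 1.5


def _model(feature_specs, xvols=(), min_req=None):
    feats = tuple(
        PharmacophoreFeature(kind, np.array(c, float), tolerance=TOL)
        for kind, c in feature_specs
    )
    xv = tuple(ExclusionVolume(np.array(c, float), r) for c, r in xvols)
    return PharmacophoreModel("m", feats, xv, min_features_required=min_req)


def _conf(atom_specs):
    coords = np.array([c for c, _ in atom_specs], float)
    roles = tuple(frozenset({r}) if isinstance(r, str) else frozenset(r) for _, r in atom_specs)
    return TypedConformer(coords, roles)


THREE_FEATURES = [("PI", (0, 0, 0)), ("HBA", (4, 0, 0)), ("H", (0, 4, 0))]
EXACT_ATOMS = [((0, 0, 0), "cationic"), ((4, 0, 0), "HBA"), ((0, 4, 0), "hydrophobic")]


def test_exact_match_has_fitness_one():
    res = match_conformer(_conf(EXACT_ATOMS), _model(THREE_FEATURES))
    assert res.matched
    assert res.fitness == pytest.approx(1.0, abs=1e-12)


def test_match_invariant_under_rigid_transform(rng):
    model = _model(THREE_FEATURES)
    conf = _conf(EXACT_ATOMS)
    moved = conf.transformed(random_rotation(rng), np.array([100.0, -50.0, 30.0]))
    res = match_conformer(moved, model)
    assert res.matched
    assert res.fitness == pytest.approx(1.0, abs=1e-9)


def test_uniform_half_tolerance_deviation_gives_fitness_three_quarters():
    """Atoms scaled radially from a regular tetrahedron of features by t/2.

    Radial displacement leaves the least-squares alignment at the identity,
    so every deviation is exactly half the tolerance and the fitness formula
    gives 0.5 + 0.5 * (1 - 1/2) = 0.75.
    """
    verts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float)
    radius = np.sqrt(3.0)
    kinds = ["PI", "HBA", "HBD", "NI"]
    model = _model(list(zip(kinds, verts)))
    scale = 1.0 + (TOL / 2.0) / radius
    atoms = list(zip((verts * scale).tolist(), ["cationic", "HBA", "HBD", "anionic"]))
    res = match_conformer(_conf(atoms), model)
    assert res.matched
    assert res.fitness == pytest.approx(0.75, abs=1e-9)


def test_deviation_beyond_tolerance_rejected():
    atoms = [((0, 0, TOL + 0.2), "cationic")]
    res = match_conformer(_conf(atoms), _model([("PI", (0, 0, 0))]))
    # single feature: translation aligns exactly, so build a 2-feature case
    model = _model([("PI", (0, 0, 0)), ("HBA", (4, 0, 0))])
    bad = _conf([((0, 0, 0), "cationic"), ((4 + 2 * TOL + 0.5, 0, 0), "HBA")])
    assert not match_conformer(bad, model).matched


def test_xvol_clash_blocks_and_is_monotone():
    model = _model(THREE_FEATURES)
    extra = EXACT_ATOMS + [((2.0, 2.0, 0.0), "hydrophobic")]
    assert match_conformer(_conf(extra), model).matched
    blocked = _model(THREE_FEATURES, xvols=[((2.0, 2.0, 0.0), 1.0)])
    assert not match_conformer(_conf(extra), blocked).matched
    # adding an XVol never converts a non-hit into a hit
    for conf in (_conf(EXACT_ATOMS), _conf(extra)):
        before = match_conformer(conf, model).matched
        after = match_conformer(conf, blocked).matched
        assert not (after and not before)


def test_missing_role_atom_prevents_match():
    conf = _conf([((0, 0, 0), "cationic"), ((4, 0, 0), "HBA")])
    assert not match_conformer(conf, _model(THREE_FEATURES)).matched


def test_partial_matching_with_min_features():
    model = _model(THREE_FEATURES, min_req=2)
    conf = _conf([((0, 0, 0), "cationic"), ((4, 0, 0), "HBA")])
    res = match_conformer(conf, model)
    assert res.matched
    # m=2 of F=3, zero deviation: fitness = 0.5*(2/3) + 0.5
    assert res.fitness == pytest.approx(0.5 * (2 / 3) + 0.5, abs=1e-9)


def _random_instance(rng):
    n_feat = rng.integers(2, 7)
    kinds = rng.choice(["PI", "HBA", "HBD", "H"], size=n_feat)
    centers = rng.uniform(-5, 5, size=(n_feat, 3))
    feats = [(k, c) for k, c in zip(kinds, centers)]
    n_atoms = rng.integers(n_feat, 13)
    atoms = []
    for i in range(n_atoms):
        if i < n_feat and rng.random() < 0.7:
            pos = centers[i] + rng.normal(0, 0.8, size=3)
            role = FEATURE_ROLE[kinds[i]]
        else:
            pos = rng.uniform(-6, 6, size=3)
            role = FEATURE_ROLE[rng.choice(["PI", "HBA", "HBD", "H"])]
        atoms.append((pos, role))
    xvols = [(rng.uniform(-6, 6, size=3), 1.0)] if rng.random() < 0.5 else []
    return _model(feats, xvols=xvols), _conf(atoms)


def test_matcher_agrees_with_exhaustive_enumeration():
    rng = np.random.default_rng(77)
    for _ in range(30):
        model, conf = _random_instance(rng)
        fast = match_conformer(conf, model)
        slow = match_conformer_exhaustive(conf, model)
        assert fast.matched == slow.matched
        assert fast.fitness == pytest.approx(slow.fitness, abs=1e-9)


def test_screen_union_scores_and_tie_breaking():
    m1 = _model(THREE_FEATURES)
    m2 = _model([("PI", (0, 0, 0)), ("HBA", (4, 0, 0))])
    m2 = PharmacophoreModel("m2", m2.features, m2.xvols)
    # compound matching both models: score is the max fitness, both flags set
    both = Compound("b", conformers=[_conf(EXACT_ATOMS)])
    onlym2 = Compound("a", conformers=[_conf([((0, 0, 0), "cationic"), ((4, 0, 0), "HBA")])])
    miss = Compound("z", conformers=[_conf([((0, 0, 0), "hydrophobic")])])
    lib = CompoundLibrary([both, onlym2, miss])
    res = screen_pharmacophore(lib, [m1, m2])
    assert res.n_hits == 2
    assert res.score_of("b") == pytest.approx(1.0)
    assert "b" in res.per_model_hits["m"] and "b" in res.per_model_hits["m2"]
    assert "a" not in res.per_model_hits["m"]
    # equal scores 1.0: ties resolve lexicographically -> 'a' before 'b'
    assert res.hit_ids() == ["a", "b"]


def test_screen_requires_models_and_conformers():
    lib = CompoundLibrary([Compound("x", conformers=[_conf(EXACT_ATOMS)])])
    with pytest.raises(DomainError):
        screen_pharmacophore(lib, [])
    with pytest.raises(DomainError):
        screen_pharmacophore(CompoundLibrary([Compound("y")]), [_model(THREE_FEATURES)])


def test_model_json_roundtrip(tmp_path):
    model = _model(THREE_FEATURES, xvols=[((9, 9, 9), 1.0)])
    direction = np.array([0.0, 0.0, 1.0])
    feats = model.features + (PharmacophoreFeature("HBD", np.array([1.0, 2, 3]), direction=direction),)
    model = PharmacophoreModel("round", feats, model.xvols, min_features_required=3)
    save_models([model], tmp_path / "models.json")
    back = load_models(tmp_path / "models.json")[0]
    assert back.model_id == "round"
    assert back.feature_census() == model.feature_census()
    assert back.min_features_required == 3
    np.testing.assert_allclose(back.features[3].direction, direction)
    np.testing.assert_allclose(back.xvols[0].center, [9, 9, 9])


def test_structure_based_model_from_pose():
    pocket = build_toy_pocket()
    poses = generate_pose_set({"agonist-like": 1, "antagonist-like": 1}, 0.0, seed=5)
    ag = next(p for p in poses if p.truth_label == "agonist-like")
    model = derive_structure_based_model(ag, pocket)
    census = model.feature_census()
    assert census.get("PI", 0) >= 1
    assert census.get("HBA", 0) + census.get("HBD", 0) >= 1
    assert len(model.xvols) == len(pocket.anchors)  # one XVol per anchor


def test_structure_based_model_requires_contacts(pocket):
    from morscreen.interaction_analysis import LabeledPose

    far = LabeledPose("far", np.array([[200.0, 0, 0]]), (frozenset({"cationic"}),))
    with pytest.raises(DomainError):
        derive_structure_based_model(far, pocket)
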