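"""Gaussian shape scoring: closed forms, invariances, optimizer quality."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from morscreen.errors import DomainError
from morscreen.library_io import Compound, CompoundLibrary, TypedConformer
from morscreen.shape_screen import (
    ALPHA_SHAPE,
    GAUSSIAN_AMPLITUDE,
    Overlay,
    ShapeQuery,
    color_tanimoto,
    gaussian_overlap_volume,
    load_queries,
    optimize_overlay,
    save_queries,
    screen_shape,
    shape_tanimoto,
    _principal_axes,
    _rotvec_to_matrix,
)

from conftest import random_rotation


def _conf(coords, roles=None):
    coords = np.asarray(coords, float)
    if roles is None:
        roles = tuple(frozenset() for _ in coords)
    return TypedConformer(coords, roles)


def test_single_atom_self_overlap_matches_closed_form():
    got = gaussian_overlap_volume(np.zeros((1, 3)), np.zeros((1, 3)))
    expected = GAUSSIAN_AMPLITUDE**2 * (np.pi / (2 * ALPHA_SHAPE)) ** 1.5
    assert got == pytest.approx(expected, rel=1e-9)


@given(st.floats(min_value=0.0, max_value=8.0), st.floats(min_value=0.1, max_value=2.0))
def test_pair_overlap_strictly_decreasing_in_distance(d, step):
    a = np.zeros((1, 3))
    near = gaussian_overlap_volume(a, np.array([[d, 0, 0]]))
    far = gaussian_overlap_volume(a, np.array([[d + step, 0, 0]]))
    assert far < near


def test_overlap_symmetric(rng):
    a = rng.uniform(-3, 3, size=(4, 3))
    b = rng.uniform(-3, 3, size=(6, 3))
    assert gaussian_overlap_volume(a, b) == pytest.approx(
        gaussian_overlap_volume(b, a), rel=1e-12
    )


def test_overlap_rejects_empty_sets():
    with pytest.raises(DomainError):
        gaussian_overlap_volume(np.zeros((0, 3)), np.zeros((1, 3)))


def test_shape_tanimoto_bounds_and_identity(rng):
    a = rng.uniform(-3, 3, size=(5, 3))
    assert shape_tanimoto(a, a) == pytest.approx(1.0, rel=1e-12)
    b = rng.uniform(-3, 3, size=(7, 3)) + 10.0
    t = shape_tanimoto(a, b)
    assert 0.0 < t < 1.0


QUERY_PTS = np.array([[0, 0, 0], [1.8, 0, 0], [3.6, 0, 0], [3.6, 1.8, 0], [0, 0, 1.8]], float)


def _query(cutoff=1.0):
    return ShapeQuery(
        "q", QUERY_PTS, color_features=(("cation", QUERY_PTS[0]), ("HBA", QUERY_PTS[3])),
        combo_cutoff=cutoff,
    )


def _matching_conf():
    roles = [frozenset({"cationic"})] + [frozenset()] * 2 + [frozenset({"HBA"})] + [frozenset()]
    return TypedConformer(QUERY_PTS.copy(), tuple(roles))


def test_self_overlay_combo_is_two(rng):
    conf = _matching_conf().transformed(random_rotation(rng), np.array([5.0, -3.0, 8.0]))
    ov = optimize_overlay(_query(), conf)
    assert ov.combo == pytest.approx(2.0, abs=1e-3)
    assert ov.shape_tanimoto == pytest.approx(1.0, abs=1e-3)


def test_color_stripped_conformer_scores_zero_color(rng):
    conf = _conf(QUERY_PTS)  # same geometry, no roles at all
    ov = optimize_overlay(_query(), conf)
    assert ov.color_tanimoto == 0.0
    assert ov.shape_tanimoto == pytest.approx(1.0, abs=1e-3)


def test_combo_invariant_under_rigid_input_transform(rng):
    conf = _matching_conf()
    ov1 = optimize_overlay(_query(), conf)
    moved = conf.transformed(random_rotation(rng), np.array([-20.0, 4.0, 11.0]))
    ov2 = optimize_overlay(_query(), moved)
    assert ov1.combo == pytest.approx(ov2.combo, abs=2e-3)


def test_two_single_atoms_superpose_exactly():
    q = ShapeQuery("q1", np.array([[1.0, 2.0, 3.0]]))
    conf = _conf(np.array([[-4.0, 0.0, 9.0]]))
    ov = optimize_overlay(q, conf)
    assert ov.shape_tanimoto == pytest.approx(1.0, abs=1e-6)


def test_optimizer_never_below_best_start():
    """Refinement may only improve on the best principal-axis alignment."""
    rng = np.random.default_rng(5)
    for _ in range(5):
        pts = rng.uniform(-3, 3, size=(6, 3))
        q = ShapeQuery("q", pts)
        conf = _conf(rng.uniform(-3, 3, size=(5, 3)))
        ov = optimize_overlay(q, conf)
        # recompute the best start combo by construction
        coords = conf.coords
        qc, cc = pts.mean(axis=0), coords.mean(axis=0)
        from morscreen.shape_screen import _SIGN_FLIPS

        uq, uc = _principal_axes(pts), _principal_axes(coords)
        best0 = -np.inf
        for s in _SIGN_FLIPS:
            r0 = uq @ s @ uc.T
            moved = (coords - cc) @ r0.T + qc
            best0 = max(best0, shape_tanimoto(pts, moved))
        assert ov.combo >= best0 - 1e-9


def _grid_best_combo(query, conf, step_deg=10.0):
    """Exhaustive Euler-angle grid oracle (centroid-aligned translation)."""
    coords = conf.heavy_coords()
    cc = coords.mean(axis=0)
    qc = query.heavy_atom_centers.mean(axis=0)
    angles = np.deg2rad(np.arange(0.0, 360.0, step_deg))
    betas = np.deg2rad(np.arange(0.0, 180.0 + step_deg, step_deg))
    best = -np.inf
    from scipy.spatial.transform import Rotation

    eulers = np.array([[a, b, g] for a in angles for b in betas for g in angles])
    mats = Rotation.from_euler("zyz", eulers).as_matrix()
    centered = coords - cc
    q = query.heavy_atom_centers
    oqq = gaussian_overlap_volume(q, q)
    occ = gaussian_overlap_volume(coords, coords)
    pref = GAUSSIAN_AMPLITUDE**2 * (np.pi / (2 * ALPHA_SHAPE)) ** 1.5
    for m in mats:
        moved = centered @ m.T + qc
        d2 = np.sum((q[:, None, :] - moved[None, :, :]) ** 2, axis=-1)
        oab = pref * np.exp(-0.5 * ALPHA_SHAPE * d2).sum()
        best = max(best, oab / (oqq + occ - oab))
    return best


@pytest.mark.parametrize(
    "q_pts,c_pts",
    [
        (np.array([[0.0, 0, 0], [2.0, 0, 0]]), np.array([[0.0, 0, 0], [0, 2.0, 0]])),
        (
            np.array([[0.0, 0, 0], [1.8, 0, 0], [0, 1.8, 0]]),
            np.array([[0.0, 0, 0], [1.8, 0, 0], [1.8, 1.8, 0]]),
        ),
        (
            np.array([[0.0, 0, 0], [1.5, 0, 0], [3.0, 0, 0], [3.0, 1.5, 0]]),
            np.array([[0.0, 0, 0], [1.5, 0, 0], [1.5, 1.5, 0], [0, 1.5, 0]]),
        ),
    ],
)
def test_optimizer_agrees_with_rotation_grid_oracle(q_pts, c_pts):
    query = ShapeQuery("q", q_pts)
    conf = _conf(c_pts)
    opt = optimize_overlay(query, conf).combo
    grid = _grid_best_combo(query, conf)
    assert opt >= grid - 0.02
    assert abs(opt - grid) <= 0.02


def test_degenerate_collinear_conformer_handled():
    conf = _conf(np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]]))
    q = ShapeQuery("q", np.array([[0.0, 0, 0], [0, 1.0, 0], [0, 2.0, 0]]))
    ov = optimize_overlay(q, conf)
    assert ov.shape_tanimoto == pytest.approx(1.0, abs=1e-3)


def test_rotvec_roundtrip_against_scipy(rng):
    from scipy.spatial.transform import Rotation

    for _ in range(10):
        rv = rng.uniform(-2, 2, size=3)
        np.testing.assert_allclose(
            _rotvec_to_matrix(rv), Rotation.from_rotvec(rv).as_matrix(), atol=1e-12
        )


def test_screen_cutoff_thresholding():
    q = _query(cutoff=1.5)
    hit = Compound("h", conformers=[_matching_conf()])  # combo ~2.0
    colorless = Compound("c", conformers=[_conf(QUERY_PTS)])  # combo ~1.0 < 1.5
    lib = CompoundLibrary([hit, colorless])
    res = screen_shape(lib, [q])
    assert res.hit_ids() == ["h"]
    assert res.score_of("c") == pytest.approx(1.0, abs=5e-3)
    # same compound against a permissive cutoff becomes a hit
    res2 = screen_shape(lib, [ShapeQuery("q2", QUERY_PTS, combo_cutoff=0.9)])
    assert set(res2.hit_ids()) == {"h", "c"}


def test_screen_requires_queries():
    lib = CompoundLibrary([Compound("x", conformers=[_matching_conf()])])
    with pytest.raises(DomainError):
        screen_shape(lib, [])


def test_query_json_roundtrip(tmp_path):
    q = _query(cutoff=1.35)
    save_queries([q], tmp_path / "queries.json")
    back = load_queries(tmp_path / "queries.json")[0]
    assert back.combo_cutoff == 1.35
    np.testing.assert_allclose(back.heavy_atom_centers, q.heavy_atom_centers)
    assert [k for k, _ in back.color_features] == ["cation", "HBA"]


def test_combo_cutoff_range_enforced():
    with pytest.raises(DomainError):
        ShapeQuery("bad", QUERY_PTS, combo_cutoff=2.5)
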