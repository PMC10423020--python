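import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from resglyph.dictionary import ShapeKind, glyph_spec_for
from resglyph.fixtures import ideal_residue
from resglyph.geometry import (
    Glyph,
    GlyphOptions,
    MissingAtomError,
    RigidFrame,
    build_glyph,
    polar_apex_direction,
    principal_frame,
    ring_geometry,
    side_chain_atoms,
)
from resglyph.structure_io import AtomRecord, ResidueRecord

from conftest import random_rotation, transform_residue


def _glyph(name3, residue=None):
    residue = residue or ideal_residue(name3)
    return build_glyph(residue, glyph_spec_for(name3))


# ---------------------------------------------------------------------------
# side_chain_atoms


@pytest.mark.parametrize(
    "name3,expected",
    [("GLY", []),
     ("ALA", ["CB"]),
     ("LYS", ["CB", "CG", "CD", "CE", "NZ"])],
)
def test_side_chain_atoms(name3, expected):
    res = ideal_residue(name3)
    assert [a.name for a in side_chain_atoms(res)] == expected


def test_side_chain_excludes_hydrogens():
    res = ideal_residue("ALA")
    res = ResidueRecord(
        "A", 1, "", "ALA",
        res.atoms + (AtomRecord(serial=99, name="HB1", element="H",
                                position=np.ones(3)),),
    )
    assert [a.name for a in side_chain_atoms(res)] == ["CB"]


# ---------------------------------------------------------------------------
# principal_frame


def test_principal_frame_collinear():
    centroid, axes, extents = principal_frame(
        np.array([[0.0, 0, 0], [0, 0, 2.0]]))
    np.testing.assert_allclose(centroid, [0, 0, 1])
    np.testing.assert_allclose(np.abs(axes[:, 0]), [0, 0, 1], atol=1e-12)
    np.testing.assert_allclose(extents, [1, 0, 0], atol=1e-12)


def test_principal_frame_single_point():
    centroid, _, extents = principal_frame(np.array([[3.0, -1.0, 2.0]]))
    np.testing.assert_allclose(centroid, [3, -1, 2])
    np.testing.assert_allclose(extents, [0, 0, 0])


def test_principal_frame_empty_rejected():
    with pytest.raises(ValueError):
        principal_frame(np.empty((0, 3)))


def test_principal_frame_matches_eig_oracle():
    """Axes agree with an independent eigendecomposition (up to sign) on
    100 seeded random point clouds."""
    import scipy.linalg

    rng = np.random.default_rng(42)
    for _ in range(100):
        pts = rng.normal(size=(50, 3)) * rng.uniform(0.5, 3.0, size=3)
        _, axes, extents = principal_frame(pts)
        cov = np.cov(pts.T, bias=True)
        w, v = scipy.linalg.eigh(cov)
        oracle = v[:, np.argsort(w)[::-1]]
        for k in range(3):
            assert abs(float(axes[:, k] @ oracle[:, k])) == pytest.approx(
                1.0, abs=1e-6)
        assert np.linalg.det(axes) == pytest.approx(1.0, abs=1e-6)
        # half-range extents are non-increasing only in eigenvalue order on
        # average; check they bound the projections exactly
        proj = (pts - pts.mean(axis=0)) @ axes
        np.testing.assert_allclose(
            (proj.max(axis=0) - proj.min(axis=0)) / 2, extents, atol=1e-12)


def test_principal_frame_hint_orients_first_axis():
    pts = np.array([[0.0, 0, 0], [0, 0, 4.0]])
    _, axes, _ = principal_frame(pts, hint=np.array([0, 0, -1.0]))
    assert axes[2, 0] < 0


# ---------------------------------------------------------------------------
# ring_geometry


def _hexagon(radius=1.39):
    ang = 2 * np.pi * np.arange(6) / 6
    return np.column_stack(
        [radius * np.cos(ang), radius * np.sin(ang), np.zeros(6)])


def _ring_residue(points, names=None):
    names = names or [f"C{i}" for i in range(len(points))]
    atoms = tuple(
        AtomRecord(serial=i + 1, name=n, element="C", position=p)
        for i, (n, p) in enumerate(zip(names, points))
    )
    return ResidueRecord("A", 1, "", "PHE", atoms), names


def test_ring_geometry_planar_hexagon():
    res, names = _ring_residue(_hexagon())
    center, normal, circum = ring_geometry(res, names)
    np.testing.assert_allclose(center, [0, 0, 0], atol=1e-12)
    np.testing.assert_allclose(normal, [0, 0, 1], atol=1e-12)
    assert circum == pytest.approx(1.39, abs=1e-12)


def test_ring_geometry_rotation_equivariant():
    rng = np.random.default_rng(7)
    hexagon = _hexagon()
    for _ in range(20):
        rot = random_rotation(rng)
        res, names = _ring_residue(hexagon @ rot.T)
        _, normal, circum = ring_geometry(res, names)
        expected = rot @ np.array([0, 0, 1.0])
        assert abs(float(normal @ expected)) == pytest.approx(1.0, abs=1e-9)
        assert circum == pytest.approx(1.39, abs=1e-9)


def test_ring_geometry_puckered_matches_lstsq_oracle():
    rng = np.random.default_rng(11)
    pts = _hexagon()
    pts[:, 2] += rng.uniform(-0.05, 0.05, size=6)
    res, names = _ring_residue(pts)
    _, normal, _ = ring_geometry(res, names)
    # independent oracle: SVD of the centered points
    centered = pts - pts.mean(axis=0)
    oracle = np.linalg.svd(centered)[2][-1]
    assert abs(float(normal @ oracle)) == pytest.approx(1.0, abs=1e-9)
    angle = math.degrees(math.acos(min(1.0, abs(normal[2]))))
    assert angle < 5.0


def test_ring_geometry_missing_atom_signals():
    res, names = _ring_residue(_hexagon())
    with pytest.raises(MissingAtomError):
        ring_geometry(res, names + ["CX"])


# ---------------------------------------------------------------------------
# polar_apex_direction


def test_polar_apex_direction_normalizes():
    atoms = (
        AtomRecord(serial=1, name="CA", element="C", position=np.zeros(3)),
        AtomRecord(serial=2, name="OG", element="O",
                   position=np.array([0.0, 0, 2.4])),
    )
    res = ResidueRecord("A", 1, "", "SER", atoms)
    np.testing.assert_allclose(polar_apex_direction(res, "OG"), [0, 0, 1])


def test_polar_apex_degenerate_rejected():
    atoms = (
        AtomRecord(serial=1, name="CA", element="C", position=np.zeros(3)),
        AtomRecord(serial=2, name="OG", element="O", position=np.zeros(3)),
    )
    res = ResidueRecord("A", 1, "", "SER", atoms)
    with pytest.raises(MissingAtomError):
        polar_apex_direction(res, "OG")


def test_polar_apex_ideal_ser():
    res = ideal_residue("SER")
    ca, og = res.atom("CA").position, res.atom("OG").position
    expected = (og - ca) / np.linalg.norm(og - ca)
    np.testing.assert_allclose(
        polar_apex_direction(res, "OG"), expected, atol=1e-6)


# ---------------------------------------------------------------------------
# build_glyph placement contracts


def test_pro_cube_centered_on_ca():
    res = ideal_residue("PRO")
    glyph = _glyph("PRO", res)
    assert glyph.shape is ShapeKind.CUBE
    np.testing.assert_allclose(glyph.frame.origin, res.atom("CA").position)


def test_gly_sphere_on_ca_ala_on_cb():
    gly, ala = ideal_residue("GLY"), ideal_residue("ALA")
    g1, g2 = _glyph("GLY", gly), _glyph("ALA", ala)
    np.testing.assert_allclose(g1.frame.origin, gly.atom("CA").position)
    np.testing.assert_allclose(g2.frame.origin, ala.atom("CB").position)
    assert g1.dimensions["radius"] < g2.dimensions["radius"]


@pytest.mark.parametrize("name3,polar", [("SER", "OG"), ("THR", "OG1"), ("CYS", "SG")])
def test_pyramid_apex_along_polar_direction(name3, polar):
    res = ideal_residue(name3)
    glyph = _glyph(name3, res)
    ca = res.atom("CA").position
    direction = res.atom(polar).position - ca
    np.testing.assert_allclose(glyph.frame.origin, ca)
    apex = glyph.frame.origin + glyph.frame.axes[:, 2] * glyph.dimensions["height"]
    assert float((apex - ca) @ direction) > 0
    np.testing.assert_allclose(
        glyph.frame.axes[:, 2], direction / np.linalg.norm(direction), atol=1e-9)
    assert glyph.dimensions["height"] == pytest.approx(
        np.linalg.norm(direction) + 0.5)


@pytest.mark.parametrize("name3,ring", [
    ("PHE", ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")),
    ("TYR", ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")),
    ("TRP", ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3")),
    ("HIS", ("CG", "ND1", "CD2", "CE1", "NE2")),
])
def test_ring_prism_centered_on_ring_centroid(name3, ring):
    res = ideal_residue(name3)
    glyph = _glyph(name3, res)
    centroid = np.mean([res.atom(n).position for n in ring], axis=0)
    np.testing.assert_allclose(glyph.frame.origin, centroid, atol=1e-6)


def test_hex_prism_elongation_covers_side_chain():
    res = ideal_residue("TRP")
    glyph = _glyph("TRP", res)
    x = glyph.frame.axes[:, 0]
    for atom in side_chain_atoms(res):
        proj = abs(float((atom.position - glyph.frame.origin) @ x))
        assert proj <= glyph.dimensions["half_length"] + 1e-6


def test_met_band_pole_nearest_sd():
    res = ideal_residue("MET")
    glyph = _glyph("MET", res)
    pole = glyph.accent_data["band_pole"]
    sd = res.atom("SD").position
    a = glyph.dimensions["a"]
    p_near = glyph.frame.origin + pole * a * glyph.frame.axes[:, 0]
    p_far = glyph.frame.origin - pole * a * glyph.frame.axes[:, 0]
    assert np.linalg.norm(p_near - sd) <= np.linalg.norm(p_far - sd)


@pytest.mark.parametrize("name3,terminal", [("LYS", ("NZ",)), ("ARG", ("NH1", "NH2", "NE"))])
def test_cuboid_end_face_nearest_terminal_group(name3, terminal):
    res = ideal_residue(name3)
    glyph = _glyph(name3, res)
    term = np.mean([res.atom(n).position for n in terminal], axis=0)
    pole = glyph.accent_data["end_pole"]
    x, hx = glyph.frame.axes[:, 0], glyph.dimensions["hx"]
    near = glyph.frame.origin + pole * hx * x
    far = glyph.frame.origin - pole * hx * x
    assert np.linalg.norm(near - term) < np.linalg.norm(far - term)
    # long axis parallel to CA -> terminal centroid
    axis = term - res.atom("CA").position
    assert abs(float(x @ axis / np.linalg.norm(axis))) == pytest.approx(1.0, abs=1e-9)


def test_tri_prism_base_centered_on_polar_atoms():
    for name3, (o_name, n_name) in (("ASN", ("OD1", "ND2")),
                                    ("ASP", ("OD1", "OD2")),
                                    ("GLN", ("OE1", "NE2")),
                                    ("GLU", ("OE1", "OE2"))):
        res = ideal_residue(name3)
        glyph = _glyph(name3, res)
        centroid = (res.atom(o_name).position + res.atom(n_name).position) / 2
        np.testing.assert_allclose(glyph.frame.origin, centroid, atol=1e-9)


def test_asn_split_face_has_two_colors():
    glyph = _glyph("ASN")
    assert "BASE_FACE" in glyph.part_colors and "BASE_FACE_N" in glyph.part_colors
    assert glyph.part_colors["BASE_FACE"] != glyph.part_colors["BASE_FACE_N"]
    # oxygen lies on the +x side of the split
    res = ideal_residue("ASN")
    od1 = res.atom("OD1").position
    assert float((od1 - glyph.frame.origin) @ glyph.frame.axes[:, 0]) > 0


def test_asp_whole_face_darker_red():
    glyph = _glyph("ASP")
    assert "BASE_FACE" in glyph.part_colors
    assert "BASE_FACE_N" not in glyph.part_colors


def test_star_for_nonstandard_on_ca():
    res = ideal_residue("MSE")
    glyph = build_glyph(res, glyph_spec_for("MSE"))
    assert glyph.shape is ShapeKind.STAR
    np.testing.assert_allclose(glyph.frame.origin, res.atom("CA").position)
    cb_dir = res.atom("CB").position - res.atom("CA").position
    np.testing.assert_allclose(
        glyph.frame.axes[:, 2], cb_dir / np.linalg.norm(cb_dir), atol=1e-9)


def test_degraded_fallback_sphere():
    res = ideal_residue("LEU")
    trimmed = ResidueRecord(
        "A", 1, "", "LEU",
        tuple(a for a in res.atoms if a.name in ("N", "CA", "C", "O", "CB")),
    )
    glyph = build_glyph(trimmed, glyph_spec_for("LEU"))
    assert glyph.degraded
    assert glyph.dimensions == {"radius": 1.0}
    np.testing.assert_allclose(glyph.frame.origin, res.atom("CA").position)
    assert glyph.part_colors == {"BODY": glyph.spec.base_color}


def test_residue_without_ca_skipped():
    res = ideal_residue("LEU")
    headless = ResidueRecord(
        "A", 1, "", "LEU", tuple(a for a in res.atoms if a.name != "CA"))
    assert build_glyph(headless, glyph_spec_for("LEU")) is None


# ---------------------------------------------------------------------------
# invariants


ALL_RESIDUES = ("GLY ALA VAL LEU ILE MET PHE TRP TYR HIS SER THR CYS ASN "
                "GLN ASP GLU LYS ARG PRO MSE").split()


def test_all_frames_orthonormal_right_handed():
    for name3 in ALL_RESIDUES:
        glyph = build_glyph(ideal_residue(name3), glyph_spec_for(name3))
        axes = glyph.frame.axes
        np.testing.assert_allclose(axes.T @ axes, np.eye(3), atol=1e-6)
        assert np.linalg.det(axes) == pytest.approx(1.0, abs=1e-6)
        assert not glyph.degraded


def test_ellipsoid_and_cuboid_contain_side_chain():
    for name3 in ("VAL", "LEU", "ILE", "MET", "LYS", "ARG"):
        res = ideal_residue(name3)
        glyph = build_glyph(res, glyph_spec_for(name3))
        pts = np.vstack([a.position for a in side_chain_atoms(res)])
        local = (pts - glyph.frame.origin) @ glyph.frame.axes
        if glyph.shape is ShapeKind.ELLIPSOID:
            semi = np.array([glyph.dimensions[k] for k in "abc"])
            assert (np.square(local / semi).sum(axis=1) <= 1 + 1e-6).all()
        else:
            half = np.array([glyph.dimensions[k] for k in ("hx", "hy", "hz")])
            assert (np.abs(local) <= half + 1e-6).all()


def test_build_glyph_deterministic():
    for name3 in ALL_RESIDUES:
        res = ideal_residue(name3)
        assert build_glyph(res, glyph_spec_for(name3)) == \
            build_glyph(res, glyph_spec_for(name3))


# Axes that are fitted to the data and hence must rotate with it (up to
# the documented sign conventions). Sphere and cube frames are fixed to
# the world axes; pyramid and star in-plane axes are cosmetic (only their
# symmetry axis, local z, is data-driven).
_DATA_AXES = {
    ShapeKind.SPHERE: (), ShapeKind.CUBE: (),
    ShapeKind.PYRAMID: (2,), ShapeKind.STAR: (2,),
    ShapeKind.ELLIPSOID: (0, 1, 2), ShapeKind.HEXAGONAL_PRISM: (0, 1, 2),
    ShapeKind.PENTAGONAL_PRISM: (0, 1, 2),
    ShapeKind.TRIANGULAR_PRISM: (0, 1, 2), ShapeKind.CUBOID: (0, 1, 2),
}


@settings(max_examples=20, derandomize=True, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_rigid_motion_equivariance(seed):
    """A rigid transform of the input coordinates transforms glyph origins
    exactly and the data-driven axes up to the documented sign
    conventions; dimensions are invariant."""
    rng = np.random.default_rng(seed)
    rot = random_rotation(rng)
    shift = rng.uniform(-20, 20, size=3)
    for name3 in ("ALA", "LEU", "MET", "PHE", "HIS", "SER", "ASN", "LYS",
                  "ARG", "PRO", "MSE"):
        res = ideal_residue(name3)
        moved = transform_residue(res, rot, shift)
        g0 = build_glyph(res, glyph_spec_for(name3))
        g1 = build_glyph(moved, glyph_spec_for(name3))
        np.testing.assert_allclose(
            g1.frame.origin, rot @ g0.frame.origin + shift, atol=1e-6)
        assert g0.dimensions.keys() == g1.dimensions.keys()
        for k in g0.dimensions:
            assert g1.dimensions[k] == pytest.approx(g0.dimensions[k], abs=1e-6)
        expected_axes = rot @ g0.frame.axes
        for k in _DATA_AXES[g0.shape]:
            cosine = abs(float(expected_axes[:, k] @ g1.frame.axes[:, k]))
            assert cosine == pytest.approx(1.0, abs=1e-6), (name3, k)


def test_rigid_frame_validation():
    with pytest.raises(ValueError):
        RigidFrame(origin=np.zeros(3), axes=np.eye(3) * 2)
    with pytest.raises(ValueError):
        bad = np.eye(3)
        bad[:, 0] = -bad[:, 0]  # det -1
        RigidFrame(origin=np.zeros(3), axes=bad)


def test_glyph_requires_positive_dimensions():
    frame = RigidFrame(origin=np.zeros(3), axes=np.eye(3))
    with pytest.raises(ValueError):
        Glyph(residue_key=("A", 1, "", "GLY"), spec=glyph_spec_for("GLY"),
              frame=frame, dimensions={"radius": 0.0},
              part_colors={"BODY": glyph_spec_for("GLY").base_color})
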