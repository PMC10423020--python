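"""Fitting glyph frames and dimensions to residue coordinates.

Every glyph is a rigid-framed primitive sized from the residue's heavy
atoms: ellipsoids and cuboids from a principal-axis fit of the side
chain, ring prisms from a least-squares plane through the ring atoms,
pyramids from the Cα→polar-atom direction, cubes/stars/spheres from
anchor atoms alone. Hydrogens never enter any fit.

All sizing constants live in :class:`SizingConfig`; the defaults are this
package's rendering choices (the grammar itself only requires that
elongation follow the side-chain dimensions).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .dictionary import AccentPart, Color, GlyphSpec, ShapeKind
from .structure_io import AtomRecord, ResidueRecord

logger = logging.getLogger("resglyph")

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

#: Ring atoms used for plane fitting, per aromatic residue. Trp uses the
#: six-membered ring of the indole; the glyph is then elongated to span
#: the five-membered ring and Cβ as well.
RING_ATOMS: Mapping[str, tuple[str, ...]] = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}

#: Polar apex atom for the pyramid residues.
POLAR_APEX_ATOM: Mapping[str, str] = {"SER": "OG", "THR": "OG1", "CYS": "SG"}

#: Terminal polar atoms of the amide/carboxylate groups; first entry is
#: the oxygen side used for the split base-face coloring, plus the sp2
#: carbon that anchors the group plane.
AMIDE_GROUPS: Mapping[str, tuple[str, str, str]] = {
    "ASN": ("OD1", "ND2", "CG"),
    "GLN": ("OE1", "NE2", "CD"),
    "ASP": ("OD1", "OD2", "CG"),
    "GLU": ("OE1", "OE2", "CD"),
}

#: Atoms whose centroid defines the charged terminal group of the cuboids.
CUBOID_TERMINAL: Mapping[str, tuple[str, ...]] = {
    "LYS": ("NZ",),
    "ARG": ("NH1", "NH2", "NE"),
}


class MissingAtomError(Exception):
    """A shape rule could not find an atom it needs (triggers fallback)."""


@dataclass(frozen=True)
class SizingConfig:
    """All glyph sizing constants, in Å."""

    ellipsoid_padding: float = 0.8
    ellipsoid_min_semi_axis: float = 0.8
    prism_half_thickness: float = 0.5
    ring_padding: float = 0.6
    pyramid_base_half_width: float = 1.0
    pyramid_height_padding: float = 0.5
    pyramid_tip_fraction: float = 0.3  # apex fraction of height colored as TIP
    cuboid_padding: float = 0.7
    cube_half_edge: float = 0.9
    gly_sphere_radius: float = 1.0
    ala_sphere_radius: float = 1.3
    star_outer_radius: float = 1.2
    star_inner_ratio: float = 0.45
    star_half_thickness: float = 0.3
    fallback_sphere_radius: float = 1.0
    met_band_fraction: float = 0.2   # outer fraction of the major axis
    tyr_segment_half_angle_deg: float = 30.0


DEFAULT_SIZING = SizingConfig()


@dataclass(frozen=True)
class RigidFrame:
    """Origin plus a right-handed orthonormal basis (columns x, y, z)."""

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self):
        origin = np.asarray(self.origin, dtype=float).reshape(3)
        axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        if not np.allclose(axes.T @ axes, np.eye(3), atol=1e-6):
            raise ValueError("frame axes must be orthonormal")
        if not math.isclose(float(np.linalg.det(axes)), 1.0, abs_tol=1e-6):
            raise ValueError("frame must be right-handed (det +1)")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "axes", axes)

    def to_world(self, local_points: np.ndarray) -> np.ndarray:
        return np.asarray(local_points) @ self.axes.T + self.origin

    def __eq__(self, other):
        return (
            isinstance(other, RigidFrame)
            and np.array_equal(self.origin, other.origin)
            and np.array_equal(self.axes, other.axes)
        )


@dataclass
class Glyph:
    """A placed glyph: shape + frame + dimensions + per-part colors."""

    residue_key: tuple[str, int, str, str]  # chain, seq, icode, name3
    spec: GlyphSpec
    frame: RigidFrame
    dimensions: dict[str, float]
    part_colors: dict[str, Color]
    accent_data: dict[str, float] = field(default_factory=dict)
    degraded: bool = False
    transparency: float | None = None

    def __post_init__(self):
        if "BODY" not in self.part_colors:
            raise ValueError("part_colors must contain BODY")
        for name, value in self.dimensions.items():
            if not value > 0:
                raise ValueError(f"dimension {name}={value} must be positive")

    @property
    def shape(self) -> ShapeKind:
        return self.spec.shape

    def __eq__(self, other):
        if not isinstance(other, Glyph):
            return NotImplemented
        return (
            self.residue_key == other.residue_key
            and self.spec == other.spec
            and self.frame == other.frame
            and self.dimensions == other.dimensions
            and self.part_colors == other.part_colors
            and self.accent_data == other.accent_data
            and self.degraded == other.degraded
            and self.transparency == other.transparency
        )


@dataclass
class GlyphOptions:
    """Per-build options: alpha override and sizing constants."""

    transparency: float | None = None
    sizing: SizingConfig = DEFAULT_SIZING


# ---------------------------------------------------------------------------
# Geometric primitives


def side_chain_atoms(residue: ResidueRecord) -> list[AtomRecord]:
    """Heavy atoms beyond the backbone (includes Cβ; empty for Gly)."""
    return [
        a for a in residue.atoms
        if not a.is_hydrogen and a.name not in BACKBONE_ATOMS
    ]


def principal_frame(
    points: Sequence[np.ndarray] | np.ndarray,
    hint: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Principal-axis frame of a point cloud.

    Returns ``(centroid, axes, extents)`` where the axes columns are the
    covariance eigenvectors ordered by decreasing eigenvalue and extents
    are the half-ranges of the point projections on each axis. The first
    axis is oriented to have a non-negative dot product with ``hint``
    (typically Cα→centroid; +z when absent or degenerate); the last axis
    is flipped if needed so the basis is right-handed.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ValueError("principal_frame requires at least one point")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    cov = centered.T @ centered / len(pts)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    axes = eigvecs[:, order]

    direction = np.array([0.0, 0.0, 1.0]) if hint is None else np.asarray(hint, float)
    if np.linalg.norm(direction) < 1e-12:
        direction = np.array([0.0, 0.0, 1.0])
    if float(axes[:, 0] @ direction) < 0:
        axes[:, 0] = -axes[:, 0]
    # deterministic sign for the middle axis, then enforce det +1
    axes[:, 1] = _canonical_sign(axes[:, 1])
    if np.linalg.det(axes) < 0:
        axes[:, 2] = -axes[:, 2]

    proj = centered @ axes
    extents = (proj.max(axis=0) - proj.min(axis=0)) / 2.0
    return centroid, axes, extents


def _canonical_sign(v: np.ndarray) -> np.ndarray:
    """Flip v so its first non-zero component along +z, +y, +x is positive."""
    for idx in (2, 1, 0):
        if abs(v[idx]) > 1e-12:
            return v if v[idx] > 0 else -v
    return v


def ring_geometry(
    residue: ResidueRecord, ring_atom_names: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, float]:
    """Center, least-squares plane normal and circumradius of a ring.

    The normal is the smallest-eigenvalue direction of the ring-atom
    covariance, signed toward the global +z (then +y, +x) axis; the
    circumradius is the largest atom distance from the ring centroid.
    """
    positions = []
    for name in ring_atom_names:
        atom = residue.atom(name)
        if atom is None:
            raise MissingAtomError(f"{residue.name3} {residue.key}: no atom {name}")
        positions.append(atom.position)
    pts = np.vstack(positions)
    center = pts.mean(axis=0)
    centered = pts - center
    _, eigvecs = np.linalg.eigh(centered.T @ centered)
    normal = _canonical_sign(eigvecs[:, 0])
    normal = normal / np.linalg.norm(normal)
    circumradius = float(np.linalg.norm(centered, axis=1).max())
    return center, normal, circumradius


def polar_apex_direction(residue: ResidueRecord, polar_atom_name: str) -> np.ndarray:
    """Unit vector from Cα to the named polar atom."""
    ca = residue.atom("CA")
    polar = residue.atom(polar_atom_name)
    if ca is None or polar is None:
        raise MissingAtomError(
            f"{residue.name3} {residue.key}: need CA and {polar_atom_name}"
        )
    vec = polar.position - ca.position
    norm = np.linalg.norm(vec)
    if norm < 1e-9:
        raise MissingAtomError(
            f"{residue.name3} {residue.key}: CA coincides with {polar_atom_name}"
        )
    return vec / norm


def _perpendicular(z: np.ndarray) -> np.ndarray:
    """Deterministic unit vector perpendicular to z."""
    ref = min(np.eye(3), key=lambda e: abs(float(e @ z)))
    v = ref - (ref @ z) * z
    return v / np.linalg.norm(v)


def _frame_from_z(origin: np.ndarray, z: np.ndarray) -> RigidFrame:
    z = z / np.linalg.norm(z)
    x = _perpendicular(z)
    y = np.cross(z, x)
    return RigidFrame(origin=origin, axes=np.column_stack([x, y, z]))


def _frame_from_zx(origin: np.ndarray, z: np.ndarray, x: np.ndarray) -> RigidFrame:
    z = z / np.linalg.norm(z)
    x = x - (x @ z) * z
    nx = np.linalg.norm(x)
    if nx < 1e-9:
        return _frame_from_z(origin, z)
    x = x / nx
    y = np.cross(z, x)
    return RigidFrame(origin=origin, axes=np.column_stack([x, y, z]))


# ---------------------------------------------------------------------------
# Shape builders


def _require(residue: ResidueRecord, name: str) -> AtomRecord:
    atom = residue.atom(name)
    if atom is None:
        raise MissingAtomError(f"{residue.name3} {residue.key}: no atom {name}")
    return atom


def _build_sphere(residue, spec, cfg) -> tuple[RigidFrame, dict, dict]:
    if spec.sizing_rule == "sphere_cb":
        center = _require(residue, "CB").position
        radius = cfg.ala_sphere_radius
    else:
        center = _require(residue, "CA").position
        radius = cfg.gly_sphere_radius
    frame = RigidFrame(origin=center, axes=np.eye(3))
    return frame, {"radius": radius}, {}


def _build_ellipsoid(residue, spec, cfg) -> tuple[RigidFrame, dict, dict]:
    ca = _require(residue, "CA")
    atoms = side_chain_atoms(residue)
    if len(atoms) < 2:
        raise MissingAtomError(f"{residue.name3}: too few side-chain atoms")
    pts = np.vstack([a.position for a in atoms])
    centroid, axes, extents = principal_frame(pts, hint=pts.mean(axis=0) - ca.position)
    # center the box mid-range so padding guarantees containment
    proj = (pts - centroid) @ axes
    mid = (proj.max(axis=0) + proj.min(axis=0)) / 2.0
    origin = centroid + axes @ mid
    semi = np.maximum(extents + cfg.ellipsoid_padding, cfg.ellipsoid_min_semi_axis)
    # an axis-aligned box fit does not bound the ellipsoid norm; rescale
    # uniformly so every atom center is on or inside the surface
    rel = (pts - origin) @ axes / semi
    r = float(np.sqrt((rel ** 2).sum(axis=1)).max())
    if r > 1.0:
        semi = semi * r

    accent: dict[str, float] = {}
    if spec.accent_part is AccentPart.END_BAND:
        sd = residue.atom("SD") or residue.atom("SE")
        if sd is None:
            raise MissingAtomError(f"{residue.name3}: no SD atom for end band")
        pole_plus = origin + axes[:, 0] * semi[0]
        pole_minus = origin - axes[:, 0] * semi[0]
        d_plus = np.linalg.norm(pole_plus - sd.position)
        d_minus = np.linalg.norm(pole_minus - sd.position)
        accent["band_pole"] = 1.0 if d_plus <= d_minus else -1.0

    frame = RigidFrame(origin=origin, axes=axes)
    dims = {"a": float(semi[0]), "b": float(semi[1]), "c": float(semi[2])}
    return frame, dims, accent


def _build_hex_prism(residue, spec, cfg) -> tuple[RigidFrame, dict, dict]:
    ring_names = RING_ATOMS[residue.name3 if residue.name3 in RING_ATOMS else "PHE"]
    center, normal, circum = ring_geometry(residue, ring_names)
    atoms = side_chain_atoms(residue)
    pts = np.vstack([a.position for a in atoms])
    # first in-plane principal axis of the side chain drives the elongation
    in_plane = pts - np.outer((pts - center) @ normal, normal)
    _, axes2, _ = principal_frame(in_plane, hint=None)
    x = axes2[:, 0] - (axes2[:, 0] @ normal) * normal
    if np.linalg.norm(x) < 1e-9:
        x = _perpendicular(normal)
    x = _canonical_sign(x / np.linalg.norm(x))
    frame = _frame_from_zx(center, normal, x)

    radius = circum + cfg.ring_padding
    span = np.abs((pts - center) @ frame.axes[:, 0])
    half_length = max(float(span.max()) + cfg.ring_padding, radius)
    dims = {
        "circumradius": radius,
        "half_thickness": cfg.prism_half_thickness,
        "half_length": half_length,
    }

    accent: dict[str, float] = {}
    if spec.accent_part is AccentPart.RING_SEGMENT:
        oh = residue.atom("OH")
        cz = residue.atom("CZ")
        if oh is None or cz is None:
            raise MissingAtomError(f"{residue.name3}: no OH for ring segment")
        d = oh.position - cz.position
        d = d - (d @ frame.axes[:, 2]) * frame.axes[:, 2]
        if np.linalg.norm(d) < 1e-9:
            raise MissingAtomError(f"{residue.name3}: degenerate OH direction")
        angle = math.atan2(float(d @ frame.axes[:, 1]), float(d @ frame.axes[:, 0]))
        accent["segment_angle"] = angle
    return frame, dims, accent


def _build_pent_prism(residue, spec, cfg) -> tuple[RigidFrame, dict, dict]:
    center, normal, circum = ring_geometry(residue, RING_ATOMS["HIS"])
    cg = _require(residue, "CG")
    x = cg.position - center
    frame = _frame_from_zx(center, normal, x)
    dims = {
        "circumradius": circum + cfg.ring_padding,
        "half_thickness": cfg.prism_half_thickness,
    }
    return frame, dims, {}


def _build_pyramid(residue, spec, cfg) -> tuple[RigidFrame, dict, dict]:
    polar_name = POLAR_APEX_ATOM[residue.name3]
    direction = polar_apex_direction(residue, polar_name)
    ca = _require(residue, "CA")
    polar = _require(residue, polar_name)
    height = float(np.linalg.norm(polar.position - ca.position)) + cfg.pyramid_height_padding
    frame = _frame_from_z(ca.position, direction)
    dims = {"base_half_width": cfg.pyramid_base_half_width, "height": height}
    return frame, dims, {}


def _build_tri_prism(residue, spec, cfg) -> tuple[RigidFrame, dict, dict]:
    o_name, n_name, c_name = AMIDE_GROUPS[residue.name3]
    o_atom = _require(residue, o_name)
    n_atom = _require(residue, n_name)
    c_atom = _require(residue, c_name)
    centroid = (o_atom.position + n_atom.position) / 2.0
    normal = np.cross(o_atom.position - c_atom.position,
                      n_atom.position - c_atom.position)
    norm = np.linalg.norm(normal)
    if norm < 1e-9:
        raise MissingAtomError(f"{residue.name3}: collinear amide group")
    normal = _canonical_sign(normal / norm)
    # local x points from the group centroid toward the oxygen: the split
    # base-face coloring puts red on x > 0 and dark blue on x < 0
    x = o_atom.position - centroid
    frame = _frame_from_zx(centroid, normal, x)
    group = np.vstack([o_atom.position, n_atom.position, c_atom.position])
    circum = float(np.linalg.norm(group - centroid, axis=1).max())
    dims = {
        "circumradius": circum + cfg.ring_padding,
        "half_thickness": cfg.prism_half_thickness,
    }
    return frame, dims, {}


def _build_cuboid(residue, spec, cfg) -> tuple[RigidFrame, dict, dict]:
    ca = _require(residue, "CA")
    terminal = [_require(residue, n).position for n in CUBOID_TERMINAL[residue.name3]]
    term_centroid = np.vstack(terminal).mean(axis=0)
    long_axis = term_centroid - ca.position
    norm = np.linalg.norm(long_axis)
    if norm < 1e-9:
        raise MissingAtomError(f"{residue.name3}: degenerate long axis")
    long_axis = long_axis / norm

    atoms = side_chain_atoms(residue)
    pts = np.vstack([a.position for a in atoms] + [ca.position])
    # transverse axes from the principal directions of the scatter in the
    # plane perpendicular to the long axis (equivariant up to sign, unlike
    # a fixed global-axis convention)
    transverse = pts - np.outer((pts - ca.position) @ long_axis, long_axis)
    _, taxes, textents = principal_frame(transverse, hint=None)
    y = taxes[:, 0] - (taxes[:, 0] @ long_axis) * long_axis
    if np.linalg.norm(y) < 1e-9 or textents[0] < 1e-9:
        y = _perpendicular(long_axis)
    else:
        y = _canonical_sign(y / np.linalg.norm(y))
    z = np.cross(long_axis, y)
    axes = np.column_stack([long_axis, y, z])
    proj = (pts - ca.position) @ axes
    mid = (proj.max(axis=0) + proj.min(axis=0)) / 2.0
    half = (proj.max(axis=0) - proj.min(axis=0)) / 2.0 + cfg.cuboid_padding
    origin = ca.position + axes @ mid
    frame = RigidFrame(origin=origin, axes=axes)
    dims = {"hx": float(half[0]), "hy": float(half[1]), "hz": float(half[2])}
    # charged end face sits at the pole nearest the terminal-group centroid
    side = 1.0 if float((term_centroid - origin) @ long_axis) >= 0 else -1.0
    return frame, dims, {"end_pole": side}


def _build_cube(residue, spec, cfg) -> tuple[RigidFrame, dict, dict]:
    ca = _require(residue, "CA")
    frame = RigidFrame(origin=ca.position, axes=np.eye(3))
    return frame, {"half_edge": cfg.cube_half_edge}, {}


def _build_star(residue, spec, cfg) -> tuple[RigidFrame, dict, dict]:
    ca = _require(residue, "CA")
    cb = residue.atom("CB")
    if cb is not None and np.linalg.norm(cb.position - ca.position) > 1e-9:
        z = cb.position - ca.position
    else:
        z = np.array([0.0, 0.0, 1.0])
    frame = _frame_from_z(ca.position, z)
    dims = {
        "outer_radius": cfg.star_outer_radius,
        "inner_radius": cfg.star_outer_radius * cfg.star_inner_ratio,
        "half_thickness": cfg.star_half_thickness,
    }
    return frame, dims, {}


_BUILDERS = {
    ShapeKind.SPHERE: _build_sphere,
    ShapeKind.ELLIPSOID: _build_ellipsoid,
    ShapeKind.HEXAGONAL_PRISM: _build_hex_prism,
    ShapeKind.PENTAGONAL_PRISM: _build_pent_prism,
    ShapeKind.PYRAMID: _build_pyramid,
    ShapeKind.TRIANGULAR_PRISM: _build_tri_prism,
    ShapeKind.CUBOID: _build_cuboid,
    ShapeKind.CUBE: _build_cube,
    ShapeKind.STAR: _build_star,
}


def _part_colors(spec: GlyphSpec) -> dict[str, Color]:
    colors = {"BODY": spec.base_color}
    if spec.accent_part is not AccentPart.NONE and spec.accent_color is not None:
        colors[spec.accent_part.name] = spec.accent_color
        if spec.accent_part is AccentPart.BASE_FACE and spec.name3 in ("ASN", "GLN"):
            # amide base face is split: oxygen side red, nitrogen side blue
            from .dictionary import palette

            colors["BASE_FACE_N"] = palette()["dark_blue"]
    return colors


def build_glyph(
    residue: ResidueRecord,
    spec: GlyphSpec,
    options: GlyphOptions | None = None,
) -> Glyph | None:
    """Fit the glyph prescribed by ``spec`` to the residue's coordinates.

    When the shape rule's atoms are missing the glyph degrades to a
    sphere at Cα in the family base color (``degraded=True``); when even
    Cα is absent the residue is skipped and ``None`` returned.
    """
    options = options or GlyphOptions()
    cfg = options.sizing
    key = (residue.chain_id, residue.seq_number, residue.insertion_code, residue.name3)

    ca = residue.atom("CA")
    builder = _BUILDERS.get(spec.shape)
    if builder is None:
        raise ValueError(f"unknown shape kind {spec.shape}")
    try:
        frame, dims, accent = builder(residue, spec, cfg)
        part_colors = _part_colors(spec)
        degraded = False
    except MissingAtomError as exc:
        if ca is None:
            logger.warning("skipping %s: no CA (%s)", key, exc)
            return None
        logger.warning("degraded glyph for %s: %s", key, exc)
        frame = RigidFrame(origin=ca.position, axes=np.eye(3))
        dims = {"radius": cfg.fallback_sphere_radius}
        part_colors = {"BODY": spec.base_color}
        accent = {}
        degraded = True

    return Glyph(
        residue_key=key,
        spec=spec,
        frame=frame,
        dimensions=dims,
        part_colors=part_colors,
        accent_data=accent,
        degraded=degraded,
        transparency=options.transparency,
    )
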