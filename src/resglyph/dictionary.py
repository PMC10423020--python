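"""The visual dictionary: residue identity → family, shape and colors.

Each of the 20 standard amino acids belongs to one of five physicochemical
families (hydrophobic, neutral polar, positively charged, negatively
charged, proline) and is drawn as one geometric primitive whose color
encodes the family and whose shape echoes the side-chain geometry:

* spheres for Gly/Ala, ellipsoids for Val/Leu/Ile/Met, elongated hexagonal
  prisms for the aromatics Phe/Trp/Tyr (all hydrophobic glyphs are green;
  Met carries a yellow band at its sulfur end, Tyr a red rim segment at
  the hydroxyl);
* pyramids for Ser/Thr/Cys pointing at the polar atom, tip red for the
  hydroxyls and yellow for the thiol;
* triangular prisms for the amides Asn/Gln (base face split red/dark blue
  over O/N) and, with the same shape, for the carboxylates Asp/Glu (base
  face in a darker red);
* an aquamarine pentagonal prism over the histidine imidazole, recolored
  dark blue when fully protonated and red when fully deprotonated;
* dark blue cuboids for Lys/Arg with the charged end in a darker blue;
* a small gray cube on the Cα for proline; and an orange star for any
  non-standard residue.

The table is available as a human-editable YAML config
(:func:`dump_dictionary` / :func:`load_dictionary`); the built-in table is
the default.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, NamedTuple

import yaml

from .structure_io import (
    HISTIDINE_NAMES,
    STANDARD_RESIDUES,
    ResidueRecord,
)


class ResidueClass(enum.Enum):
    HYDROPHOBIC = "hydrophobic"
    NEUTRAL_POLAR = "neutral_polar"
    POSITIVE = "positive"
    NEGATIVE = "negative"
    PROLINE = "proline"
    NONSTANDARD = "nonstandard"


class ShapeKind(enum.Enum):
    SPHERE = "sphere"
    ELLIPSOID = "ellipsoid"
    HEXAGONAL_PRISM = "hexagonal_prism"
    PENTAGONAL_PRISM = "pentagonal_prism"
    PYRAMID = "pyramid"
    TRIANGULAR_PRISM = "triangular_prism"
    CUBOID = "cuboid"
    CUBE = "cube"
    STAR = "star"


class AccentPart(enum.Enum):
    NONE = "none"
    TIP = "tip"
    END_BAND = "end_band"
    BASE_FACE = "base_face"
    END_FACE = "end_face"
    RING_SEGMENT = "ring_segment"


class HistidineState(enum.Enum):
    NEUTRAL = "neutral"
    PROTONATED = "protonated"
    DEPROTONATED = "deprotonated"


class Color(NamedTuple):
    """RGBA with components as fractions in [0, 1]."""

    r: float
    g: float
    b: float
    a: float = 1.0

    def with_alpha(self, alpha: float) -> "Color":
        return Color(self.r, self.g, self.b, alpha)


# The palette is this package's rendering choice: family hues follow the
# chemistry conventions (green hydrophobic, dark blue positive, red
# negative); "darker" shades reduce value at constant hue.
_PALETTE: dict[str, Color] = {
    "green": Color(0.0, 0.8, 0.0, 1.0),
    "dark_blue": Color(0.0, 0.0, 0.55, 1.0),
    "darker_blue": Color(0.0, 0.0, 0.35, 1.0),
    "red": Color(0.85, 0.0, 0.0, 1.0),
    "darker_red": Color(0.55, 0.0, 0.0, 1.0),
    "yellow": Color(1.0, 0.85, 0.0, 1.0),
    "aquamarine": Color(0.3, 0.9, 0.75, 1.0),
    "gray": Color(0.6, 0.6, 0.6, 1.0),
    "orange": Color(1.0, 0.55, 0.0, 1.0),
}


def palette() -> Mapping[str, Color]:
    """The fixed named-color table used by the dictionary."""
    return dict(_PALETTE)


#: Sizing-rule identifiers understood by :mod:`resglyph.geometry`.
SIZING_RULES = frozenset(
    {
        "sphere_ca",
        "sphere_cb",
        "ellipsoid",
        "hex_prism",
        "pent_prism",
        "pyramid",
        "tri_prism",
        "cuboid",
        "cube",
        "star",
    }
)


@dataclass(frozen=True)
class GlyphSpec:
    """One dictionary row: what to draw for a residue type."""

    name3: str
    residue_class: ResidueClass
    shape: ShapeKind
    base_color: Color
    accent_part: AccentPart = AccentPart.NONE
    accent_color: Color | None = None
    sizing_rule: str = "sphere_ca"

    def __post_init__(self):
        if (self.accent_part is AccentPart.NONE) != (self.accent_color is None):
            raise ValueError("accent_part is NONE iff accent_color is None")
        if self.sizing_rule not in SIZING_RULES:
            raise ValueError(f"unknown sizing rule {self.sizing_rule!r}")


def _spec(name3, rclass, shape, base, accent_part=AccentPart.NONE, accent=None,
          sizing="sphere_ca") -> GlyphSpec:
    return GlyphSpec(
        name3=name3,
        residue_class=rclass,
        shape=shape,
        base_color=_PALETTE[base],
        accent_part=accent_part,
        accent_color=_PALETTE[accent] if accent else None,
        sizing_rule=sizing,
    )


_H = ResidueClass.HYDROPHOBIC
_P = ResidueClass.NEUTRAL_POLAR
_POS = ResidueClass.POSITIVE
_NEG = ResidueClass.NEGATIVE

_TABLE: dict[str, GlyphSpec] = {
    "GLY": _spec("GLY", _H, ShapeKind.SPHERE, "green", sizing="sphere_ca"),
    "ALA": _spec("ALA", _H, ShapeKind.SPHERE, "green", sizing="sphere_cb"),
    "VAL": _spec("VAL", _H, ShapeKind.ELLIPSOID, "green", sizing="ellipsoid"),
    "LEU": _spec("LEU", _H, ShapeKind.ELLIPSOID, "green", sizing="ellipsoid"),
    "ILE": _spec("ILE", _H, ShapeKind.ELLIPSOID, "green", sizing="ellipsoid"),
    "MET": _spec("MET", _H, ShapeKind.ELLIPSOID, "green",
                 AccentPart.END_BAND, "yellow", "ellipsoid"),
    "PHE": _spec("PHE", _H, ShapeKind.HEXAGONAL_PRISM, "green", sizing="hex_prism"),
    "TRP": _spec("TRP", _H, ShapeKind.HEXAGONAL_PRISM, "green", sizing="hex_prism"),
    "SER": _spec("SER", _P, ShapeKind.PYRAMID, "gray",
                 AccentPart.TIP, "red", "pyramid"),
    "THR": _spec("THR", _P, ShapeKind.PYRAMID, "gray",
                 AccentPart.TIP, "red", "pyramid"),
    "CYS": _spec("CYS", _P, ShapeKind.PYRAMID, "gray",
                 AccentPart.TIP, "yellow", "pyramid"),
    "ASN": _spec("ASN", _P, ShapeKind.TRIANGULAR_PRISM, "gray",
                 AccentPart.BASE_FACE, "red", "tri_prism"),
    "GLN": _spec("GLN", _P, ShapeKind.TRIANGULAR_PRISM, "gray",
                 AccentPart.BASE_FACE, "red", "tri_prism"),
    "TYR": _spec("TYR", _P, ShapeKind.HEXAGONAL_PRISM, "gray",
                 AccentPart.RING_SEGMENT, "red", "hex_prism"),
    "HIS": _spec("HIS", _P, ShapeKind.PENTAGONAL_PRISM, "aquamarine",
                 sizing="pent_prism"),
    "LYS": _spec("LYS", _POS, ShapeKind.CUBOID, "dark_blue",
                 AccentPart.END_FACE, "darker_blue", "cuboid"),
    "ARG": _spec("ARG", _POS, ShapeKind.CUBOID, "dark_blue",
                 AccentPart.END_FACE, "darker_blue", "cuboid"),
    "ASP": _spec("ASP", _NEG, ShapeKind.TRIANGULAR_PRISM, "red",
                 AccentPart.BASE_FACE, "darker_red", "tri_prism"),
    "GLU": _spec("GLU", _NEG, ShapeKind.TRIANGULAR_PRISM, "red",
                 AccentPart.BASE_FACE, "darker_red", "tri_prism"),
    "PRO": _spec("PRO", ResidueClass.PROLINE, ShapeKind.CUBE, "gray",
                 sizing="cube"),
}

_NONSTANDARD_SPEC_TEMPLATE = dict(
    residue_class=ResidueClass.NONSTANDARD,
    shape=ShapeKind.STAR,
    base_color=_PALETTE["orange"],
    sizing_rule="star",
)


def classify_residue(name3: str) -> ResidueClass:
    """Map a 3-letter code to its family; unknown codes → NONSTANDARD.

    Histidine force-field variants (HID/HIE/HIP/HSD/HSE/HSP) count as
    histidine, i.e. neutral polar.
    """
    name3 = name3.strip().upper()
    if name3 in HISTIDINE_NAMES:
        name3 = "HIS"
    spec = _TABLE.get(name3)
    if spec is None:
        return ResidueClass.NONSTANDARD
    return spec.residue_class


def glyph_spec_for(
    name3: str,
    his_state: HistidineState | None = None,
    table: Mapping[str, GlyphSpec] | None = None,
) -> GlyphSpec:
    """Dictionary row for a residue type.

    For histidine the whole-glyph color follows the protonation state:
    aquamarine when neutral, dark blue when fully protonated, red when
    fully deprotonated. Unknown codes return the orange star spec.
    """
    table = table if table is not None else _TABLE
    name3 = name3.strip().upper()
    if name3 in HISTIDINE_NAMES:
        spec = table["HIS"]
        if his_state is HistidineState.PROTONATED:
            spec = GlyphSpec(
                name3=spec.name3, residue_class=spec.residue_class,
                shape=spec.shape, base_color=_PALETTE["dark_blue"],
                accent_part=spec.accent_part, accent_color=spec.accent_color,
                sizing_rule=spec.sizing_rule,
            )
        elif his_state is HistidineState.DEPROTONATED:
            spec = GlyphSpec(
                name3=spec.name3, residue_class=spec.residue_class,
                shape=spec.shape, base_color=_PALETTE["red"],
                accent_part=spec.accent_part, accent_color=spec.accent_color,
                sizing_rule=spec.sizing_rule,
            )
        return spec
    spec = table.get(name3)
    if spec is not None:
        return spec
    return GlyphSpec(name3=name3, **_NONSTANDARD_SPEC_TEMPLATE)


def detect_histidine_state(
    residue: ResidueRecord, override: HistidineState | None = None
) -> HistidineState:
    """Protonation state of a histidine residue.

    Priority: an explicit ``override`` wins; then force-field name
    variants (HID/HIE/HSD/HSE neutral, HIP/HSP protonated); then explicit
    hydrogens — H on both ND1 and NE2 means protonated, on exactly one
    neutral, on neither (while other hydrogens are present) deprotonated.
    A heavy-atom-only HIS defaults to neutral.
    """
    name3 = residue.name3
    if name3 not in HISTIDINE_NAMES:
        raise ValueError(f"{name3} is not a histidine variant")
    if override is not None:
        return override
    if name3 in {"HID", "HIE", "HSD", "HSE"}:
        return HistidineState.NEUTRAL
    if name3 in {"HIP", "HSP"}:
        return HistidineState.PROTONATED

    hydrogens = [a.name for a in residue.atoms if a.is_hydrogen]
    if not hydrogens:
        return HistidineState.NEUTRAL
    # ring-nitrogen protons by conventional names: HD1 on ND1, HE2 on NE2
    has_hd1 = any(h in ("HD1", "1HD1", "HND1") for h in hydrogens)
    has_he2 = any(h in ("HE2", "1HE2", "HNE2") for h in hydrogens)
    if has_hd1 and has_he2:
        return HistidineState.PROTONATED
    if has_hd1 or has_he2:
        return HistidineState.NEUTRAL
    return HistidineState.DEPROTONATED


def default_dictionary() -> dict[str, GlyphSpec]:
    """A copy of the built-in residue table (the 20 standard rows)."""
    return dict(_TABLE)


# ---------------------------------------------------------------------------
# YAML serialization of the dictionary


def _color_to_list(c: Color | None):
    return None if c is None else [c.r, c.g, c.b, c.a]


def dictionary_yaml(table: Mapping[str, GlyphSpec] | None = None) -> str:
    """The dictionary as editable YAML text (one record per residue)."""
    table = table if table is not None else _TABLE
    doc = {
        name3: {
            "class": spec.residue_class.value,
            "shape": spec.shape.value,
            "base_color": _color_to_list(spec.base_color),
            "accent_part": spec.accent_part.value,
            "accent_color": _color_to_list(spec.accent_color),
            "sizing_rule": spec.sizing_rule,
        }
        for name3, spec in sorted(table.items())
    }
    return yaml.safe_dump(doc, sort_keys=True)


def dump_dictionary(path: str | Path, table: Mapping[str, GlyphSpec] | None = None) -> None:
    """Write :func:`dictionary_yaml` to a file."""
    Path(path).write_text(dictionary_yaml(table))


def load_dictionary(path: str | Path) -> dict[str, GlyphSpec]:
    """Load a YAML dictionary written by :func:`dump_dictionary`."""
    doc = yaml.safe_load(Path(path).read_text())
    table: dict[str, GlyphSpec] = {}
    for name3, row in doc.items():
        accent = row.get("accent_color")
        table[name3.upper()] = GlyphSpec(
            name3=name3.upper(),
            residue_class=ResidueClass(row["class"]),
            shape=ShapeKind(row["shape"]),
            base_color=Color(*row["base_color"]),
            accent_part=AccentPart(row["accent_part"]),
            accent_color=Color(*accent) if accent else None,
            sizing_rule=row["sizing_rule"],
        )
    return table
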