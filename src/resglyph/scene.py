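"""Assembling glyph scenes: selections, per-model builds, trajectories.

A scene is the ordered list of glyphs for one coordinate frame under one
selection. Selections come in three kinds: everything, an explicit
residue list, or a distance zone around a reference entity (e.g. all
residues with any heavy atom within 8 Å of a bound ligand).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np

from .dictionary import (
    GlyphSpec,
    HistidineState,
    detect_histidine_state,
    glyph_spec_for,
)
from .geometry import Glyph, GlyphOptions, build_glyph
from .structure_io import (
    HISTIDINE_NAMES,
    AtomRecord,
    MolecularModel,
    ResidueRecord,
    StructureEnsemble,
    iter_polymer_residues,
)

logger = logging.getLogger("resglyph")


class SelectionKind(enum.Enum):
    ALL = "all"
    RESIDUE_LIST = "residue_list"
    ZONE = "zone"


@dataclass(frozen=True)
class SelectionExpr:
    """A selection: ALL, an explicit residue list, or a distance zone.

    ``residue_keys`` entries are ``(chain_id,)`` for a whole chain or
    ``(chain_id, seq_number)`` / ``(chain_id, seq_number, icode)`` for
    single residues. ZONE needs a ``reference`` selector — a residue name
    (e.g. a ligand code), ``"chain:seq"``, or a tuple of atom serials —
    and a positive, finite ``cutoff`` in Å.
    """

    kind: SelectionKind
    residue_keys: tuple = ()
    reference: str | tuple[int, ...] | None = None
    cutoff: float | None = None

    def __post_init__(self):
        if self.kind is SelectionKind.ZONE:
            if self.reference is None or self.cutoff is None:
                raise ValueError("ZONE selection requires reference and cutoff")
            if not (np.isfinite(self.cutoff) and self.cutoff > 0):
                raise ValueError("cutoff must be finite and positive")
        object.__setattr__(self, "residue_keys", tuple(self.residue_keys))

    def label(self) -> str:
        if self.kind is SelectionKind.ALL:
            return "all"
        if self.kind is SelectionKind.RESIDUE_LIST:
            return "residues:" + "+".join(
                ":".join(str(p) for p in key) for key in self.residue_keys
            )
        return f"zone:{self.reference}:{self.cutoff:g}"


def parse_selection(text: str) -> SelectionExpr:
    """Parse the CLI selection mini-language.

    Grammar: ``all`` | ``chain:A`` | ``resi:A:26+28`` |
    ``zone:<resname|chain:resi>:<cutoff>``.
    """
    text = text.strip()
    if text.lower() == "all":
        return SelectionExpr(kind=SelectionKind.ALL)
    parts = text.split(":")
    if parts[0] == "chain" and len(parts) == 2:
        return SelectionExpr(
            kind=SelectionKind.RESIDUE_LIST, residue_keys=((parts[1],),)
        )
    if parts[0] == "resi" and len(parts) == 3:
        chain = parts[1]
        keys = tuple((chain, int(num)) for num in parts[2].split("+"))
        return SelectionExpr(kind=SelectionKind.RESIDUE_LIST, residue_keys=keys)
    if parts[0] == "zone" and len(parts) in (3, 4):
        cutoff = float(parts[-1])
        reference = ":".join(parts[1:-1])
        return SelectionExpr(
            kind=SelectionKind.ZONE, reference=reference, cutoff=cutoff
        )
    raise ValueError(f"cannot parse selection {text!r}")


@dataclass
class SceneOptions:
    """Options threaded through scene building."""

    transparency: float | None = None
    histidine_overrides: dict[tuple[str, int, str], HistidineState] = field(
        default_factory=dict
    )
    dictionary: dict[str, GlyphSpec] | None = None
    glyph_options: GlyphOptions | None = None

    def build_glyph_options(self) -> GlyphOptions:
        if self.glyph_options is not None:
            return self.glyph_options
        return GlyphOptions(transparency=self.transparency)


@dataclass
class GlyphScene:
    """Ordered glyphs for one model under one selection."""

    glyphs: list[Glyph]
    source_label: str = ""
    model_index: int = 0
    selection_label: str = "all"
    global_alpha: float | None = None
    n_skipped: int = 0

    def __post_init__(self):
        keys = [g.residue_key for g in self.glyphs]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate residue keys in scene")

    @property
    def n_degraded(self) -> int:
        return sum(1 for g in self.glyphs if g.degraded)

    def __eq__(self, other):
        if not isinstance(other, GlyphScene):
            return NotImplemented
        return (
            self.glyphs == other.glyphs
            and self.source_label == other.source_label
            and self.model_index == other.model_index
            and self.selection_label == other.selection_label
            and self.global_alpha == other.global_alpha
        )


def zone_selection(
    model: MolecularModel,
    reference_atoms: list[AtomRecord],
    cutoff: float,
) -> set[tuple[str, int, str]]:
    """Polymer residues with any heavy atom within ``cutoff`` Å of any
    reference atom (boundary inclusive). Residues owning a reference
    atom are excluded.
    """
    if not reference_atoms:
        raise ValueError("zone selection requires a non-empty reference")
    if not cutoff > 0:
        raise ValueError("cutoff must be positive")
    ref_pos = np.vstack([a.position for a in reference_atoms])
    ref_serials = {a.serial for a in reference_atoms}

    selected: set[tuple[str, int, str]] = set()
    for residue in iter_polymer_residues(model):
        if any(a.serial in ref_serials for a in residue.atoms):
            continue
        heavy = residue.heavy_atoms()
        if not heavy:
            continue
        pos = np.vstack([a.position for a in heavy])
        d2 = ((pos[:, None, :] - ref_pos[None, :, :]) ** 2).sum(axis=2)
        if float(d2.min()) <= cutoff * cutoff:
            selected.add(residue.key)
    return selected


def resolve_reference_atoms(
    model: MolecularModel, reference: str | tuple[int, ...]
) -> list[AtomRecord]:
    """Resolve a zone reference to concrete atoms.

    Accepts a residue name (any residue of that name, polymer or not),
    ``"chain:seq"``, or an iterable of atom serial numbers.
    """
    if isinstance(reference, (tuple, list, set, frozenset)):
        serials = set(reference)
        atoms = [
            a for r in model.residues for a in r.atoms if a.serial in serials
        ]
    elif ":" in reference:
        chain, seq = reference.split(":", 1)
        atoms = [
            a
            for r in model.residues
            if r.chain_id == chain and r.seq_number == int(seq)
            for a in r.atoms
        ]
    else:
        name = reference.strip().upper()
        atoms = [a for r in model.residues if r.name3 == name for a in r.atoms]
    if not atoms:
        raise ValueError(f"zone reference {reference!r} matches no atoms")
    return atoms


def _selected_keys(
    model: MolecularModel, selection: SelectionExpr
) -> set[tuple[str, int, str]] | None:
    """Resolve a selection to residue keys; None means 'everything'."""
    if selection.kind is SelectionKind.ALL:
        return None
    if selection.kind is SelectionKind.RESIDUE_LIST:
        keys: set[tuple[str, int, str]] = set()
        for pattern in selection.residue_keys:
            for residue in model.residues:
                if len(pattern) == 1 and residue.chain_id == pattern[0]:
                    keys.add(residue.key)
                elif (
                    len(pattern) >= 2
                    and residue.chain_id == pattern[0]
                    and residue.seq_number == pattern[1]
                    and (len(pattern) < 3 or residue.insertion_code == pattern[2])
                ):
                    keys.add(residue.key)
        return keys
    reference_atoms = resolve_reference_atoms(model, selection.reference)
    return zone_selection(model, reference_atoms, selection.cutoff)


def _spec_for_residue(
    residue: ResidueRecord, options: SceneOptions
) -> GlyphSpec:
    his_state = None
    if residue.name3 in HISTIDINE_NAMES:
        override = options.histidine_overrides.get(residue.key)
        his_state = detect_histidine_state(residue, override)
    return glyph_spec_for(residue.name3, his_state, table=options.dictionary)


def build_scene(
    model: MolecularModel,
    selection: SelectionExpr,
    options: SceneOptions | None = None,
) -> GlyphScene:
    """One glyph per selected polymer residue, in model order.

    Residues without a Cα are skipped with a warning; an empty selection
    yields an empty scene (warning, not an error).
    """
    options = options or SceneOptions()
    keys = _selected_keys(model, selection)
    glyph_options = options.build_glyph_options()

    glyphs: list[Glyph] = []
    n_skipped = 0
    for residue in iter_polymer_residues(model):
        if keys is not None and residue.key not in keys:
            continue
        spec = _spec_for_residue(residue, options)
        glyph = build_glyph(residue, spec, glyph_options)
        if glyph is None:
            n_skipped += 1
            continue
        glyphs.append(glyph)
    if not glyphs:
        logger.warning("selection %s matched no residues", selection.label())
    return GlyphScene(
        glyphs=glyphs,
        model_index=model.model_index,
        selection_label=selection.label(),
        global_alpha=options.transparency,
        n_skipped=n_skipped,
    )


def build_trajectory_scenes(
    ensemble: StructureEnsemble,
    selection: SelectionExpr,
    options: SceneOptions | None = None,
    freeze_selection: bool = False,
) -> list[GlyphScene]:
    """One scene per ensemble model.

    Zone selections are re-evaluated per frame by default — the
    neighborhood of a moving ligand changes along a trajectory — or
    frozen to the first frame with ``freeze_selection=True``.
    """
    options = options or SceneOptions()
    scenes: list[GlyphScene] = []
    frozen: SelectionExpr | None = None
    if freeze_selection and selection.kind is SelectionKind.ZONE:
        keys = _selected_keys(ensemble.models[0], selection)
        frozen = SelectionExpr(
            kind=SelectionKind.RESIDUE_LIST,
            residue_keys=tuple(sorted(keys or ())),
        )
    for model in ensemble.models:
        scene = build_scene(model, frozen or selection, options)
        scene.source_label = ensemble.source_label
        scenes.append(scene)
    return scenes
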