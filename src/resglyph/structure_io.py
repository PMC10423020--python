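"""Reading protein structures into a lightweight ensemble model.

The parser is built on :mod:`gemmi` and normalises its output into plain
dataclasses: an ensemble holds one :class:`MolecularModel` per coordinate
frame (MODEL block), each model holds residues in a deterministic order,
and every residue holds its atoms after alternate-location resolution.

Only the PDB dialect is supported; the entry point :func:`read_structure`
is the single place where a second dialect (e.g. mmCIF) would be added.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import gemmi
import numpy as np

logger = logging.getLogger("resglyph")

#: The 20 standard amino-acid 3-letter codes.
STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: Histidine naming variants used by common force fields.
HISTIDINE_NAMES = frozenset({"HIS", "HID", "HIE", "HIP", "HSD", "HSE", "HSP"})

#: Chemically modified residues that occur inline in polypeptide chains.
#: They are treated as part of the polymer but classify as non-standard.
NONSTANDARD_POLYMER = frozenset(
    {"MSE", "SEC", "PYL", "SEP", "TPO", "PTR", "HYP", "MLY", "CSO", "KCX"}
)

WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})

HYDROGEN_ELEMENTS = frozenset({"H", "D", "T"})


class StructureError(Exception):
    """Base error for structure parsing problems."""


class EmptyStructureError(StructureError):
    """Raised when a file contains no atom records."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom after column parsing; positions in Å."""

    serial: int
    name: str
    element: str
    position: np.ndarray  # shape (3,), float64
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise StructureError(f"non-finite position for atom {self.name!r}")
        object.__setattr__(self, "position", pos)
        occ = self.occupancy
        if not 0.0 <= occ <= 1.0:
            clamped = min(max(occ, 0.0), 1.0)
            logger.warning(
                "atom %s serial %d: occupancy %.3f outside [0,1], clamped to %.3f",
                self.name, self.serial, occ, clamped,
            )
            object.__setattr__(self, "occupancy", clamped)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in HYDROGEN_ELEMENTS


@dataclass(frozen=True)
class ResidueRecord:
    """One residue: identity key plus its atoms in file order."""

    chain_id: str
    seq_number: int
    insertion_code: str
    name3: str
    atoms: tuple[AtomRecord, ...]
    is_polymer: bool = True

    def __post_init__(self):
        if not self.name3:
            raise StructureError("residue with empty name")
        object.__setattr__(self, "name3", self.name3.upper())
        object.__setattr__(self, "atoms", tuple(self.atoms))

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.insertion_code)

    def atom(self, name: str) -> AtomRecord | None:
        """First atom with the given name, or None."""
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if not a.is_hydrogen]


@dataclass
class MolecularModel:
    """One coordinate frame; residues sorted by (chain, seq, icode)."""

    model_index: int
    residues: list[ResidueRecord] = field(default_factory=list)

    def __post_init__(self):
        self.residues = sorted(
            self.residues, key=lambda r: (r.chain_id, r.seq_number, r.insertion_code)
        )
        seen: set[tuple[str, int, str]] = set()
        for r in self.residues:
            if r.key in seen:
                raise StructureError(f"duplicate residue key {r.key}")
            seen.add(r.key)

    def residue_keys(self) -> list[tuple[str, int, str]]:
        return [r.key for r in self.residues]

    def find(self, key: tuple[str, int, str]) -> ResidueRecord | None:
        for r in self.residues:
            if r.key == key:
                return r
        return None


@dataclass
class StructureEnsemble:
    """Ordered models from one source (MODEL blocks or trajectory frames)."""

    source_label: str
    models: list[MolecularModel]

    def __post_init__(self):
        if not self.models:
            raise StructureError("ensemble must contain at least one model")


def resolve_altlocs(residue: ResidueRecord) -> ResidueRecord:
    """Keep one location per atom name: highest occupancy, ties broken by
    the lexicographically smallest altloc character.
    """
    by_name: dict[str, AtomRecord] = {}
    order: list[str] = []
    for atom in residue.atoms:
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
            order.append(atom.name)
        else:
            # higher occupancy wins; on a tie the smaller altloc letter wins
            if (atom.occupancy, _altloc_rank(prev.altloc)) > (
                prev.occupancy, _altloc_rank(atom.altloc)
            ):
                by_name[atom.name] = atom
    return replace(residue, atoms=tuple(by_name[n] for n in order))


def _altloc_rank(altloc: str) -> str:
    # blank altloc sorts first, matching "smallest character" intent
    return altloc if altloc else ""


def _residue_is_polymer(name3: str, het_flag: str) -> bool:
    name3 = name3.upper()
    if name3 in WATER_NAMES:
        return False
    if het_flag == "A":
        return True
    # HETATM: standard codes and known inline modifications stay polymeric
    return (
        name3 in STANDARD_RESIDUES
        or name3 in HISTIDINE_NAMES
        or name3 in NONSTANDARD_POLYMER
    )


def iter_polymer_residues(model: MolecularModel) -> Iterator[ResidueRecord]:
    """Yield polymer residues (no waters, ions, ligands) in model order."""
    for residue in model.residues:
        if residue.is_polymer:
            yield residue


def _convert_residue(chain_id: str, res: gemmi.Residue) -> ResidueRecord:
    atoms = []
    for at in res:
        altloc = at.altloc if at.altloc not in ("\0", " ") else ""
        atoms.append(
            AtomRecord(
                serial=at.serial,
                name=at.name,
                element=at.element.name,
                position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                altloc=altloc,
                occupancy=at.occ,
            )
        )
    record = ResidueRecord(
        chain_id=chain_id,
        seq_number=res.seqid.num,
        insertion_code=(res.seqid.icode or "").strip(),
        name3=res.name,
        atoms=tuple(atoms),
        is_polymer=_residue_is_polymer(res.name, res.het_flag),
    )
    return resolve_altlocs(record)


def read_structure(path: str | Path) -> StructureEnsemble:
    """Parse a PDB file into a :class:`StructureEnsemble`.

    One :class:`MolecularModel` is produced per MODEL block (a single
    implicit model when the file has none). Hydrogens are retained —
    histidine protonation detection needs them — but geometric code
    ignores them. Waters are flagged non-polymer.

    Raises
    ------
    FileNotFoundError
        If the path does not exist.
    EmptyStructureError
        If no ATOM/HETATM records survive parsing.
    StructureError
        On malformed files that gemmi cannot interpret.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc

    models: list[MolecularModel] = []
    for i, gmodel in enumerate(st):
        residues: list[ResidueRecord] = []
        for chain in gmodel:
            for res in chain:
                residues.append(_convert_residue(chain.name, res))
        if residues:
            models.append(MolecularModel(model_index=i, residues=residues))
    if not models:
        raise EmptyStructureError(f"{path} contains no atom records")

    # Models of an ensemble must share a residue key sequence; if they do
    # not, warn and keep only the shared keys so per-frame scenes align.
    key_sets = [set(m.residue_keys()) for m in models]
    common = set.intersection(*key_sets)
    if any(ks != common for ks in key_sets):
        logger.warning(
            "%s: models differ in residue content; intersecting to %d shared residues",
            path.name, len(common),
        )
        models = [
            MolecularModel(
                model_index=m.model_index,
                residues=[r for r in m.residues if r.key in common],
            )
            for m in models
        ]
        models = [m for m in models if m.residues]
        if not models:
            raise EmptyStructureError(f"{path}: no residues shared across models")

    return StructureEnsemble(source_label=path.name, models=models)


def heavy_atom_positions(residues: Sequence[ResidueRecord]) -> np.ndarray:
    """Stacked (N, 3) array of heavy-atom coordinates over the residues."""
    coords = [a.position for r in residues for a in r.heavy_atoms()]
    if not coords:
        return np.empty((0, 3))
    return np.vstack(coords)
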