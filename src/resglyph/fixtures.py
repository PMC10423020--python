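"""Synthetic test structures: ideal residues, peptides, complexes.

Templates are built from internal coordinates (bond length, bond angle,
dihedral) with canonical values — Cα–Cβ ≈ 1.53 Å, aromatic C–C ≈ 1.39 Å,
exactly planar rings — which is all the glyph-fitting code cares about.
Peptides place residues on a straight axis at a fixed spacing rather
than through real peptide bonds: fixtures exercise glyph geometry and
zone selection, not chemistry, and the straight layout makes distance
constructions solvable in closed form.

Everything is deterministic; coordinate jitter is driven by a seeded
generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np

from .structure_io import (
    AtomRecord,
    MolecularModel,
    ResidueRecord,
    StructureEnsemble,
)

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "x": "MSE",  # non-standard path
}


@dataclass(frozen=True)
class PerturbSpec:
    """Isotropic Gaussian coordinate jitter."""

    seed: int
    sigma: float = 0.0

    def __post_init__(self):
        if not (math.isfinite(self.sigma) and self.sigma >= 0):
            raise ValueError("sigma must be finite and non-negative")


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Natural-extension placement: position d with |cd| = bond,
    angle(b,c,d) = angle and dihedral(a,b,c,d) = dihedral."""
    angle = math.radians(angle_deg)
    dihedral = math.radians(dihedral_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(dihedral),
        bond * math.sin(angle) * math.sin(dihedral),
    ])
    return c + np.column_stack([bc, m, n]) @ d_local


def _backbone() -> dict[str, np.ndarray]:
    ca = np.zeros(3)
    n = np.array([1.458, 0.0, 0.0])
    c = 1.525 * np.array([math.cos(math.radians(111.0)),
                          math.sin(math.radians(111.0)), 0.0])
    o = _place(n, ca, c, 1.231, 120.5, 0.0)
    return {"N": n, "CA": ca, "C": c, "O": o}


def _with_cb(atoms: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    atoms["CB"] = _place(atoms["C"], atoms["N"], atoms["CA"], 1.53, 110.4, -122.6)
    return atoms


def _chain(atoms, names_refs):
    """Extend a side chain: each entry (name, (a, b, c), bond, angle, dih)."""
    for name, (ra, rb, rc), bond, angle, dih in names_refs:
        atoms[name] = _place(atoms[ra], atoms[rb], atoms[rc], bond, angle, dih)
    return atoms


def _attach_planar(atoms: dict[str, np.ndarray],
                   layout2d: dict[str, np.ndarray],
                   anchor1: str, anchor2: str) -> dict[str, np.ndarray]:
    """Map a rigid 2D layout into 3D so both anchors land on the already
    placed 3D atoms; the plane orientation about the anchor axis is fixed
    deterministically from the Cα direction."""
    p1_2d, p2_2d = layout2d[anchor1], layout2d[anchor2]
    p1_3d, p2_3d = atoms[anchor1], atoms[anchor2]
    ex2 = p2_2d - p1_2d
    scale = np.linalg.norm(ex2)
    ex2 = ex2 / scale
    ey2 = np.array([-ex2[1], ex2[0]])

    ex3 = p2_3d - p1_3d
    ex3 = ex3 / np.linalg.norm(ex3)
    ref = atoms["CA"] - p1_3d
    ez3 = np.cross(ex3, ref)
    if np.linalg.norm(ez3) < 1e-9:
        ref = np.array([0.0, 0.0, 1.0])
        ez3 = np.cross(ex3, ref)
    ez3 = ez3 / np.linalg.norm(ez3)
    ey3 = np.cross(ez3, ex3)

    for name, p2 in layout2d.items():
        if name in (anchor1, anchor2):
            continue
        rel = p2 - p1_2d
        u, v = float(rel @ ex2), float(rel @ ey2)
        atoms[name] = p1_3d + u * ex3 + v * ey3
    return atoms


def _hexagon_layout(side: float, names: list[str], stem: float,
                    extra: dict[str, float] | None = None) -> dict[str, np.ndarray]:
    """CB at origin, CG at (0, stem), regular hexagon continuing upward.
    ``names`` orders the ring from CG counterclockwise; ``extra`` adds
    substituents beyond the para vertex (e.g. Tyr OH)."""
    center = np.array([0.0, stem + side])
    layout = {"CB": np.array([0.0, 0.0])}
    for k, name in enumerate(names):
        ang = math.radians(-90 + 60 * k)
        layout[name] = center + side * np.array([math.cos(ang), math.sin(ang)])
    if extra:
        for name, bond in extra.items():
            layout[name] = center + np.array([0.0, side + bond])
    return layout


def _pentagon_layout(side: float, names: list[str], stem: float) -> dict[str, np.ndarray]:
    radius = side / (2 * math.sin(math.pi / 5))
    center = np.array([0.0, stem + radius])
    layout = {"CB": np.array([0.0, 0.0])}
    for k, name in enumerate(names):
        ang = math.radians(-90 + 72 * k)
        layout[name] = center + radius * np.array([math.cos(ang), math.sin(ang)])
    return layout


def _indole_layout(side: float, stem: float) -> dict[str, np.ndarray]:
    """Fused pentagon + hexagon sharing the CD2–CE2 edge, plus CB."""
    layout: dict[str, np.ndarray] = {}
    cd2 = np.array([0.0, 0.0])
    ce2 = np.array([side, 0.0])
    # pentagon CD2→CE2→NE1→CD1→CG above the shared edge
    pent = [cd2, ce2]
    heading = 0.0
    for _ in range(3):
        heading += 72.0
        pent.append(pent[-1] + side * np.array(
            [math.cos(math.radians(heading)), math.sin(math.radians(heading))]))
    layout.update({"CD2": cd2, "CE2": ce2, "NE1": pent[2],
                   "CD1": pent[3], "CG": pent[4]})
    # hexagon CD2–CE2–CZ2–CH2–CZ3–CE3 below the shared edge
    hex_center = np.array([side / 2, -side * math.sqrt(3) / 2])
    for name, deg in (("CZ2", 0), ("CH2", -60), ("CZ3", -120), ("CE3", 180)):
        layout[name] = hex_center + side * np.array(
            [math.cos(math.radians(deg)), math.sin(math.radians(deg))])
    pent_center = np.mean(pent, axis=0)
    out = layout["CG"] - pent_center
    layout["CB"] = layout["CG"] + stem * out / np.linalg.norm(out)
    return layout


def _build_template(name3: str) -> list[tuple[str, str, np.ndarray]]:
    """(atom name, element, position) list for one ideal residue."""
    atoms = _backbone()
    n3 = name3

    if n3 == "GLY":
        pass
    elif n3 == "ALA":
        _with_cb(atoms)
    elif n3 == "VAL":
        _with_cb(atoms)
        _chain(atoms, [
            ("CG1", ("N", "CA", "CB"), 1.53, 110.5, 180.0),
            ("CG2", ("N", "CA", "CB"), 1.53, 110.5, -60.0),
        ])
    elif n3 == "LEU":
        _with_cb(atoms)
        _chain(atoms, [
            ("CG", ("N", "CA", "CB"), 1.53, 113.0, 180.0),
            ("CD1", ("CA", "CB", "CG"), 1.53, 110.5, 180.0),
            ("CD2", ("CA", "CB", "CG"), 1.53, 110.5, 60.0),
        ])
    elif n3 == "ILE":
        _with_cb(atoms)
        _chain(atoms, [
            ("CG1", ("N", "CA", "CB"), 1.53, 110.5, 180.0),
            ("CG2", ("N", "CA", "CB"), 1.53, 110.5, -60.0),
            ("CD1", ("CA", "CB", "CG1"), 1.53, 113.0, 180.0),
        ])
    elif n3 in ("MET", "MSE"):
        _with_cb(atoms)
        s_name = "SD" if n3 == "MET" else "SE"
        _chain(atoms, [
            ("CG", ("N", "CA", "CB"), 1.53, 113.0, 180.0),
            (s_name, ("CA", "CB", "CG"), 1.81, 112.7, 180.0),
            ("CE", ("CB", "CG", s_name), 1.79, 100.2, 180.0),
        ])
    elif n3 in ("PHE", "TYR"):
        _with_cb(atoms)
        _chain(atoms, [("CG", ("N", "CA", "CB"), 1.50, 113.8, 180.0)])
        extra = {"OH": 1.375} if n3 == "TYR" else None
        layout = _hexagon_layout(
            1.39, ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"], 1.50, extra)
        _attach_planar(atoms, layout, "CB", "CG")
    elif n3 == "TRP":
        _with_cb(atoms)
        layout = _indole_layout(1.40, 1.50)
        cg_local = layout["CG"] - layout["CB"]
        _chain(atoms, [("CG", ("N", "CA", "CB"),
                        float(np.linalg.norm(cg_local)), 113.8, 180.0)])
        _attach_planar(atoms, layout, "CB", "CG")
    elif n3 == "HIS":
        _with_cb(atoms)
        _chain(atoms, [("CG", ("N", "CA", "CB"), 1.50, 113.8, 180.0)])
        layout = _pentagon_layout(1.37, ["CG", "ND1", "CE1", "NE2", "CD2"], 1.50)
        _attach_planar(atoms, layout, "CB", "CG")
    elif n3 == "SER":
        _with_cb(atoms)
        _chain(atoms, [("OG", ("N", "CA", "CB"), 1.417, 110.8, 180.0)])
    elif n3 == "THR":
        _with_cb(atoms)
        _chain(atoms, [
            ("OG1", ("N", "CA", "CB"), 1.433, 109.6, 180.0),
            ("CG2", ("N", "CA", "CB"), 1.53, 110.5, -60.0),
        ])
    elif n3 == "CYS":
        _with_cb(atoms)
        _chain(atoms, [("SG", ("N", "CA", "CB"), 1.808, 113.8, 180.0)])
    elif n3 == "ASN":
        _with_cb(atoms)
        _chain(atoms, [
            ("CG", ("N", "CA", "CB"), 1.516, 112.6, 180.0),
            ("OD1", ("CA", "CB", "CG"), 1.231, 120.8, 0.0),
            ("ND2", ("CA", "CB", "CG"), 1.328, 116.4, 180.0),
        ])
    elif n3 == "ASP":
        _with_cb(atoms)
        _chain(atoms, [
            ("CG", ("N", "CA", "CB"), 1.516, 112.6, 180.0),
            ("OD1", ("CA", "CB", "CG"), 1.249, 118.4, 0.0),
            ("OD2", ("CA", "CB", "CG"), 1.249, 118.4, 180.0),
        ])
    elif n3 == "GLN":
        _with_cb(atoms)
        _chain(atoms, [
            ("CG", ("N", "CA", "CB"), 1.53, 113.0, 180.0),
            ("CD", ("CA", "CB", "CG"), 1.516, 112.6, 180.0),
            ("OE1", ("CB", "CG", "CD"), 1.231, 120.8, 0.0),
            ("NE2", ("CB", "CG", "CD"), 1.328, 116.4, 180.0),
        ])
    elif n3 == "GLU":
        _with_cb(atoms)
        _chain(atoms, [
            ("CG", ("N", "CA", "CB"), 1.53, 113.0, 180.0),
            ("CD", ("CA", "CB", "CG"), 1.516, 112.6, 180.0),
            ("OE1", ("CB", "CG", "CD"), 1.249, 118.4, 0.0),
            ("OE2", ("CB", "CG", "CD"), 1.249, 118.4, 180.0),
        ])
    elif n3 == "LYS":
        _with_cb(atoms)
        _chain(atoms, [
            ("CG", ("N", "CA", "CB"), 1.53, 113.0, 180.0),
            ("CD", ("CA", "CB", "CG"), 1.53, 111.3, 180.0),
            ("CE", ("CB", "CG", "CD"), 1.53, 111.3, 180.0),
            ("NZ", ("CG", "CD", "CE"), 1.489, 111.9, 180.0),
        ])
    elif n3 == "ARG":
        _with_cb(atoms)
        _chain(atoms, [
            ("CG", ("N", "CA", "CB"), 1.53, 113.0, 180.0),
            ("CD", ("CA", "CB", "CG"), 1.53, 111.3, 180.0),
            ("NE", ("CB", "CG", "CD"), 1.461, 112.0, 180.0),
            ("CZ", ("CG", "CD", "NE"), 1.33, 124.2, 180.0),
            ("NH1", ("CD", "NE", "CZ"), 1.326, 120.0, 0.0),
            ("NH2", ("CD", "NE", "CZ"), 1.326, 120.0, 180.0),
        ])
    elif n3 == "PRO":
        _with_cb(atoms)
        _chain(atoms, [
            ("CG", ("N", "CA", "CB"), 1.495, 104.5, -30.0),
            ("CD", ("CA", "CB", "CG"), 1.507, 106.1, 35.0),
        ])
    else:
        raise ValueError(f"no template for residue {name3!r}")

    def element_of(name: str) -> str:
        return "SE" if name == "SE" else name[0]

    return [(name, element_of(name), pos) for name, pos in atoms.items()]


_TEMPLATE_CACHE: dict[str, list[tuple[str, str, np.ndarray]]] = {}


def residue_template(name3: str) -> list[tuple[str, str, np.ndarray]]:
    name3 = name3.upper() if name3 != "x" else "MSE"
    if name3 not in _TEMPLATE_CACHE:
        _TEMPLATE_CACHE[name3] = _build_template(name3)
    return [(n, e, p.copy()) for n, e, p in _TEMPLATE_CACHE[name3]]


def ideal_residue(
    name3: str,
    key: tuple[str, int, str] = ("A", 1, ""),
    offset: np.ndarray | None = None,
    serial_start: int = 1,
) -> ResidueRecord:
    """An ideal-geometry residue in the canonical local frame."""
    chain_id, seq, icode = key
    shift = np.zeros(3) if offset is None else np.asarray(offset, float)
    atoms = [
        AtomRecord(serial=serial_start + i, name=n, element=e, position=p + shift)
        for i, (n, e, p) in enumerate(residue_template(name3))
    ]
    return ResidueRecord(
        chain_id=chain_id, seq_number=seq, insertion_code=icode,
        name3=name3 if name3 != "x" else "MSE", atoms=tuple(atoms),
        is_polymer=True,
    )


def synthetic_peptide(
    sequence: str,
    spacing: float = 5.0,
    perturb: PerturbSpec | None = None,
    chain_id: str = "A",
) -> MolecularModel:
    """Residues of ``sequence`` placed along the x axis at ``spacing`` Å.

    One-letter codes cover the 20 standard residues; ``x`` inserts MSE
    (selenomethionine) for the non-standard glyph path.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    residues = []
    serial = 1
    for i, letter in enumerate(sequence):
        key_letter = letter if letter == "x" else letter.upper()
        name3 = ONE_TO_THREE.get(key_letter)
        if name3 is None:
            raise ValueError(f"unknown residue letter {letter!r}")
        res = ideal_residue(
            name3, key=(chain_id, i + 1, ""),
            offset=np.array([i * spacing, 0.0, 0.0]),
            serial_start=serial,
        )
        serial += len(res.atoms)
        residues.append(res)

    model = MolecularModel(model_index=0, residues=residues)
    if perturb is not None and perturb.sigma > 0:
        rng = np.random.default_rng(perturb.seed)
        jittered = []
        for res in model.residues:
            atoms = tuple(
                AtomRecord(
                    serial=a.serial, name=a.name, element=a.element,
                    position=a.position + rng.normal(0.0, perturb.sigma, 3),
                    altloc=a.altloc, occupancy=a.occupancy,
                )
                for a in res.atoms
            )
            jittered.append(ResidueRecord(
                chain_id=res.chain_id, seq_number=res.seq_number,
                insertion_code=res.insertion_code, name3=res.name3,
                atoms=atoms, is_polymer=res.is_polymer,
            ))
        model = MolecularModel(model_index=0, residues=jittered)
    return model


def synthetic_ensemble(
    sequence: str,
    n_models: int,
    sigma: float = 0.2,
    seed: int = 0,
    spacing: float = 5.0,
) -> StructureEnsemble:
    """Multi-model ensemble: jittered copies of the same peptide."""
    models = []
    for i in range(n_models):
        perturb = PerturbSpec(seed=seed + i, sigma=sigma) if sigma > 0 else None
        model = synthetic_peptide(sequence, spacing=spacing, perturb=perturb)
        model.model_index = i
        models.append(model)
    return StructureEnsemble(source_label="synthetic_ensemble", models=models)


def synthetic_complex(
    sequence: str,
    contact_indices: set[int] | frozenset[int],
    cutoff: float = 8.0,
    spacing: float = 8.0,
    chain_id: str = "A",
) -> MolecularModel:
    """Peptide plus a one-atom HETATM ligand ("LIG") placed so that
    exactly the residues at ``contact_indices`` (1-based sequence
    positions) fall inside the ``cutoff`` zone.

    The position is found by a deterministic grid search over the plane
    above the peptide axis; infeasible contact sets raise ValueError.
    """
    contact_indices = set(contact_indices)
    model = synthetic_peptide(sequence, spacing=spacing, chain_id=chain_id)
    n = len(model.residues)
    if any(i < 1 or i > n for i in contact_indices):
        raise ValueError("contact index out of range")
    max_serial = max(a.serial for r in model.residues for a in r.atoms)

    def with_ligand(position: np.ndarray) -> MolecularModel:
        lig = ResidueRecord(
            chain_id="L", seq_number=1, insertion_code="", name3="LIG",
            atoms=(AtomRecord(serial=max_serial + 1, name="C1", element="C",
                              position=position),),
            is_polymer=False,
        )
        return MolecularModel(model_index=0,
                              residues=list(model.residues) + [lig])

    if not contact_indices:
        return with_ligand(np.array([0.0, 1000.0, 0.0]))

    # vectorized search: per-residue minimum heavy-atom distance to every
    # candidate point on a grid in the z = 0 plane above the peptide axis
    xs = np.arange(-10.0, (n - 1) * spacing + 10.0 + 1e-9, 0.25)
    ys = np.arange(0.5, 30.0 + 1e-9, 0.25)
    grid = np.array([[x, y, 0.0] for y in ys for x in xs])
    inside = np.zeros((len(grid), n), dtype=bool)
    for j, res in enumerate(model.residues):
        pos = np.vstack([a.position for a in res.heavy_atoms()])
        d2 = ((grid[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2).min(axis=1)
        inside[:, j] = d2 <= cutoff * cutoff
    want = np.zeros(n, dtype=bool)
    for i in contact_indices:
        want[i - 1] = True
    hits = np.nonzero((inside == want).all(axis=1))[0]
    if len(hits) == 0:
        raise ValueError(
            f"no ligand placement realizes contacts {sorted(contact_indices)}")
    return with_ligand(grid[hits[0]])


# ---------------------------------------------------------------------------
# PDB writing (gemmi-backed)


def _to_gemmi_model(model: MolecularModel, number: int) -> gemmi.Model:
    gmodel = gemmi.Model(number)
    chains: dict[str, gemmi.Chain] = {}
    for res in model.residues:
        chain = chains.get(res.chain_id)
        if chain is None:
            chain = gemmi.Chain(res.chain_id)
            chains[res.chain_id] = chain
        gres = gemmi.Residue()
        gres.name = res.name3
        gres.seqid = gemmi.SeqId(res.seq_number, res.insertion_code or " ")
        gres.het_flag = "A" if res.is_polymer else "H"
        for atom in res.atoms:
            gatom = gemmi.Atom()
            gatom.serial = atom.serial
            gatom.name = atom.name
            gatom.element = gemmi.Element(atom.element)
            gatom.pos = gemmi.Position(*atom.position)
            gatom.occ = atom.occupancy
            if atom.altloc:
                gatom.altloc = atom.altloc
            gres.add_atom(gatom)
        chain.add_residue(gres)
    for chain in chains.values():
        gmodel.add_chain(chain)
    return gmodel


def write_pdb(
    structure: MolecularModel | StructureEnsemble, path: str | Path
) -> None:
    """Write a model or ensemble as fixed-width PDB (MODEL/ENDMDL blocks
    for ensembles). Coordinates survive a read/write round trip to the
    format's 1e-3 Å precision."""
    st = gemmi.Structure()
    st.name = "resglyph-fixture"
    if isinstance(structure, MolecularModel):
        models = [structure]
    else:
        models = structure.models
    for i, model in enumerate(models):
        st.add_model(_to_gemmi_model(model, i + 1))
    Path(path).write_text(st.make_pdb_string())
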