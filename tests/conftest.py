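import numpy as np
import pytest

from resglyph.fixtures import ideal_residue, synthetic_peptide
from resglyph.scene import SelectionExpr, SelectionKind, build_scene
from resglyph.structure_io import AtomRecord, ResidueRecord

ALL20 = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def peptide20():
    """Ideal peptide covering all 20 standard residues."""
    return synthetic_peptide(ALL20)


@pytest.fixture(scope="session")
def scene20(peptide20):
    return build_scene(peptide20, SelectionExpr(kind=SelectionKind.ALL))


@pytest.fixture(scope="session")
def ideal():
    """Factory for single ideal residues keyed A:1."""
    return lambda name3: ideal_residue(name3)


def transform_residue(residue: ResidueRecord, rotation: np.ndarray,
                      translation: np.ndarray) -> ResidueRecord:
    atoms = tuple(
        AtomRecord(serial=a.serial, name=a.name, element=a.element,
                   position=rotation @ a.position + translation,
                   altloc=a.altloc, occupancy=a.occupancy)
        for a in residue.atoms
    )
    return ResidueRecord(
        chain_id=residue.chain_id, seq_number=residue.seq_number,
        insertion_code=residue.insertion_code, name3=residue.name3,
        atoms=atoms, is_polymer=residue.is_polymer,
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def pdb_atom_line(serial, name, resname, chain, resseq, x, y, z,
                  occ=1.0, altloc=" ", element=None, record="ATOM"):
    element = element or name[0]
    return (
        f"{record:<6s}{serial:5d} {name:<4s}{altloc}{resname:<3s} {chain}"
        f"{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )
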