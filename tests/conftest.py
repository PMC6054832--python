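import numpy as np
import pytest
from Bio.PDB.Polypeptide import protein_letters_3to1

from pocketsim.msa import AlignmentMap, MasterAlignment
from pocketsim.structures import Atom, BindingSiteComplex, load_complex
from pocketsim.synthetic import (
    ToyComplexSpec,
    ToyLigandAtom,
    ToyResidue,
    make_toy_complex,
)

ONE_TO_THREE = {v: k for k, v in protein_letters_3to1.items()}


def make_atom(name, element, xyz, resnum=1, resname="GLY", chain="A",
              is_ligand=False, is_backbone=False):
    return Atom(
        name=name, element=element, coords=tuple(float(v) for v in xyz),
        residue_uid=(chain, resnum, ""), residue_name=resname,
        is_ligand=is_ligand, is_backbone=is_backbone,
    )


def identity_map(cplx, complex_id="toy", row_name="row"):
    """Map the i-th polymer residue to column i."""
    return AlignmentMap(
        complex_id, row_name,
        {uid: i for i, uid in enumerate(cplx.residue_uids())},
        coverage=1.0,
    )


def random_rigid_transform(rng):
    """A uniform-ish random rotation matrix and translation vector."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    return rot, rng.normal(scale=10.0, size=3)


def transform_complex(cplx, rot, trans):
    def move(atom):
        return Atom(
            name=atom.name, element=atom.element,
            coords=tuple(rot @ atom.xyz + trans),
            residue_uid=atom.residue_uid, residue_name=atom.residue_name,
            is_ligand=atom.is_ligand, is_backbone=atom.is_backbone,
        )

    return BindingSiteComplex(
        complex_id=cplx.complex_id, target_name=cplx.target_name, site=cplx.site,
        protein_atoms=[move(a) for a in cplx.protein_atoms],
        ligand_atoms=[move(a) for a in cplx.ligand_atoms],
    )


@pytest.fixture
def toy_spec():
    return ToyComplexSpec(
        residues=[ToyResidue("GLY"), ToyResidue("ALA"), ToyResidue("SER")],
        ligand_atoms=[
            ToyLigandAtom("N1", "N", 0, "O", 2.9, role="donor"),
            ToyLigandAtom("O1", "O", 1, "N", 3.1, role="acceptor"),
            ToyLigandAtom("C1", "C", 2, "CA", 3.93, role="apolar"),
        ],
        include_waters=True,
        seed=7,
    )


@pytest.fixture
def toy_result(toy_spec):
    return make_toy_complex(toy_spec)


@pytest.fixture
def toy_pdb(tmp_path, toy_result):
    path = tmp_path / "toy.pdb"
    path.write_text(toy_result.pdb_text)
    return path


@pytest.fixture
def toy_complex(toy_pdb):
    return load_complex(toy_pdb, "A", ["LIG"], "cofactor", complex_id="toy")


@pytest.fixture
def small_alignment():
    return MasterAlignment(
        names=["seqA", "seqB", "seqC", "seqD"],
        rows=["ACD-E", "AVE-D", "GC-KE", "WWDYE"],
    )
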