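"""Deterministic fixture generation: toy complexes with prescribed
geometry and pharmacophore roles, and alignments with planted
binding-site neighbors.

Toy complexes place each ligand atom at an exact prescribed distance from
a named anchor atom while keeping it clear (beyond the contact cutoff) of
every other protein atom, so expected contact weights and interaction
bits follow analytically from the request. Planted alignments make
designated sequence pairs identical at the weighted site columns and
random elsewhere, providing ground truth for neighbor-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .contacts import RAMP_FULL, RAMP_ZERO, contact_strength
from .msa import MasterAlignment

__all__ = [
    "ToyLigandAtom",
    "ToyResidue",
    "ToyComplexSpec",
    "ToyComplexResult",
    "PlantedAlignmentSpec",
    "UnrealizableGeometryError",
    "make_toy_complex",
    "make_planted_alignment",
    "AMINO_ACIDS",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# minimal heavy-atom offsets for a glycine-like residue (local frame, Å)
_BACKBONE_OFFSETS = {
    "N": (0.0, 0.0, 0.0),
    "CA": (1.46, 0.0, 0.0),
    "C": (2.0, 1.42, 0.0),
    "O": (3.23, 1.58, 0.0),
}


class UnrealizableGeometryError(ValueError):
    """Raised when requested interatomic distances cannot be realized."""


@dataclass
class ToyLigandAtom:
    """One requested ligand atom.

    `role` is a pharmacophore hint used to pick the element and to
    derive the expected interaction bit: one of "donor", "acceptor",
    "cation", "anion", "apolar".
    """

    name: str
    element: str
    anchor_residue: int          # index into ToyComplexSpec.residues
    anchor_atom: str             # atom name within that residue
    distance: float              # Å to the anchor atom
    role: str = "apolar"


@dataclass
class ToyResidue:
    name: str = "GLY"
    atoms: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_BACKBONE_OFFSETS)
    )


@dataclass
class ToyComplexSpec:
    residues: list[ToyResidue]
    ligand_atoms: list[ToyLigandAtom]
    chain_id: str = "A"
    ligand_resname: str = "LIG"
    complex_id: str = "toy"
    seed: int = 0
    residue_spacing: float = 25.0   # Å between residue origins; keeps residues independent
    include_waters: bool = False

    def __post_init__(self) -> None:
        for la in self.ligand_atoms:
            if la.distance < 1.0:
                raise UnrealizableGeometryError(
                    f"requested distance {la.distance} Å below 1.0 Å for {la.name}"
                )
            if not 0 <= la.anchor_residue < len(self.residues):
                raise UnrealizableGeometryError(f"anchor residue {la.anchor_residue} out of range")


@dataclass
class ToyComplexResult:
    pdb_text: str
    expected_contact_weights: dict[int, float]   # residue index -> weight
    expected_bits: set[tuple[int, str]]          # (residue index, type)
    ligand_coords: dict[str, tuple[float, float, float]]


def _pdb_line(serial: int, name: str, resname: str, chain: str, resnum: int,
              xyz: tuple[float, float, float], element: str, het: bool,
              altloc: str = " ", occupancy: float = 1.0) -> str:
    record = "HETATM" if het else "ATOM  "
    atom_field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"{record}{serial:>5d} {atom_field:<4s}{altloc}{resname:<3s} {chain}"
        f"{resnum:>4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{occupancy:6.2f}{0.0:6.2f}          {element:>2s}"
    )


def _angle_deg(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    v1, v2 = a - vertex, b - vertex
    cos = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


def make_toy_complex(spec: ToyComplexSpec) -> ToyComplexResult:
    """Write a toy complex as PDB text together with its expected oracles.

    Residues are placed on a widely spaced line so that each ligand atom
    can only interact with its anchor residue; the atom sits on a sphere
    of the prescribed radius around the anchor atom, positioned by seeded
    rejection sampling so that (a) every atom of other residues and every
    other ligand atom stays beyond the contact cutoff and (b) the atom
    points away from the anchor's bonded neighbours (angle >= 110
    degrees), which satisfies the hydrogen-bond angle proxy by
    construction. Expected contact weights and interaction bits are
    derived by an explicit double loop over the placed geometry, so they
    include same-residue contributions from non-anchor atoms.

    Residue atom sets should stick to backbone names (N, CA, C, O, OXT):
    the expected-bit rules type protein O/OXT as acceptor, N as donor and
    OXT as anion. Ligand roles "donor"/"acceptor"/"apolar" map to
    elements N/O/C; isolated ligand N and O atoms are typed as both
    donor and acceptor downstream, which the expectation mirrors.
    """
    rng = np.random.default_rng(spec.seed)
    residue_origin = [
        np.array([i * spec.residue_spacing, 0.0, 0.0]) for i in range(len(spec.residues))
    ]
    protein_xyz: dict[tuple[int, str], np.ndarray] = {}
    for ri, res in enumerate(spec.residues):
        for aname, offset in res.atoms.items():
            protein_xyz[(ri, aname)] = residue_origin[ri] + np.asarray(offset)

    ligand_xyz: dict[str, np.ndarray] = {}
    for la in spec.ligand_atoms:
        anchor_key = (la.anchor_residue, la.anchor_atom)
        if anchor_key not in protein_xyz:
            raise UnrealizableGeometryError(
                f"anchor atom {la.anchor_atom!r} absent from residue {la.anchor_residue}"
            )
        anchor = protein_xyz[anchor_key]
        bonded = [
            xyz for key, xyz in protein_xyz.items()
            if key != anchor_key and key[0] == la.anchor_residue
            and np.linalg.norm(xyz - anchor) <= 2.0
        ]
        placed = None
        for _ in range(5000):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            candidate = anchor + la.distance * v
            if any(_angle_deg(candidate, anchor, b) < 110.0 for b in bonded):
                continue
            ok = all(
                np.linalg.norm(candidate - xyz) > RAMP_ZERO + 0.75
                for key, xyz in protein_xyz.items()
                if key[0] != la.anchor_residue
            ) and all(
                np.linalg.norm(candidate - other) > RAMP_ZERO + 0.75
                for other in ligand_xyz.values()
            )
            if ok:
                placed = candidate
                break
        if placed is None:
            raise UnrealizableGeometryError(
                f"could not place ligand atom {la.name!r} at {la.distance} Å "
                f"from {la.anchor_atom} of residue {la.anchor_residue}"
            )
        # round to PDB coordinate precision so expectations match exactly
        ligand_xyz[la.name] = np.round(placed, 3)

    # Expected oracles: explicit loops over the placed geometry.
    role_flags = {
        "donor": {"donor", "acceptor"},
        "acceptor": {"donor", "acceptor"},
        "apolar": set(),
        "cation": set(),
        "anion": set(),
    }
    expected_weights: dict[int, float] = {}
    expected_bits: set[tuple[int, str]] = set()
    for la in spec.ligand_atoms:
        lxyz = ligand_xyz[la.name]
        flags = role_flags.get(la.role, set())
        for ri, res in enumerate(spec.residues):
            hb_atoms = set()
            for aname in res.atoms:
                pxyz = protein_xyz[(ri, aname)]
                d = float(np.linalg.norm(lxyz - pxyz))
                w = contact_strength(d)
                if w > 0:
                    expected_weights[ri] = expected_weights.get(ri, 0.0) + w
                if d <= 3.5 and "donor" in flags and aname in ("O", "OXT"):
                    expected_bits.add((ri, "HBD"))
                    hb_atoms.add(aname)
                if d <= 3.5 and "acceptor" in flags and aname == "N" and res.name != "PRO":
                    ants = [
                        protein_xyz[(ri, other)] for other in res.atoms
                        if other != aname
                        and np.linalg.norm(protein_xyz[(ri, other)] - pxyz) <= 1.9
                    ]
                    if all(_angle_deg(lxyz, pxyz, a) >= 100.0 for a in ants):
                        expected_bits.add((ri, "HBA"))
                        hb_atoms.add(aname)
            for aname in res.atoms:
                d = float(np.linalg.norm(lxyz - protein_xyz[(ri, aname)]))
                if d <= 4.5 and aname not in hb_atoms:
                    expected_bits.add((ri, "SURFACE"))

    lines = []
    serial = 1
    for ri, res in enumerate(spec.residues):
        for aname in res.atoms:
            xyz = protein_xyz[(ri, aname)]
            lines.append(
                _pdb_line(serial, aname, res.name, spec.chain_id, ri + 1,
                          tuple(xyz), aname[0], het=False)
            )
            serial += 1
    lines.append(f"TER   {serial:>5d}      {spec.residues[-1].name:<3s} "
                 f"{spec.chain_id}{len(spec.residues):>4d}")
    serial += 1
    lig_resnum = len(spec.residues) + 1
    for la in spec.ligand_atoms:
        lines.append(
            _pdb_line(serial, la.name, spec.ligand_resname, spec.chain_id,
                      lig_resnum, tuple(ligand_xyz[la.name]), la.element, het=True)
        )
        serial += 1
    if spec.include_waters:
        far = residue_origin[-1] + np.array([spec.residue_spacing, 30.0, 0.0])
        lines.append(
            _pdb_line(serial, "O", "HOH", spec.chain_id, lig_resnum + 1,
                      tuple(far), "O", het=True)
        )
        serial += 1
    lines.append("END")
    return ToyComplexResult(
        pdb_text="\n".join(lines) + "\n",
        expected_contact_weights=expected_weights,
        expected_bits=expected_bits,
        ligand_coords={k: tuple(v) for k, v in ligand_xyz.items()},
    )


@dataclass
class PlantedAlignmentSpec:
    n_sequences: int
    length: int
    neighbor_pairs: list[tuple[int, int]] = field(default_factory=list)
    site_columns: list[int] = field(default_factory=list)
    background_rate: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 2:
            raise ValueError("need at least two sequences")
        if not 0.0 <= self.background_rate <= 1.0:
            raise ValueError("background rate must lie in [0, 1]")
        for c in self.site_columns:
            if not 0 <= c < self.length:
                raise ValueError(f"site column {c} outside alignment length {self.length}")
        flat = [i for pair in self.neighbor_pairs for i in pair]
        if len(set(flat)) != len(flat):
            raise ValueError("neighbor pairs must be disjoint")
        for i, j in self.neighbor_pairs:
            if not (0 <= i < self.n_sequences and 0 <= j < self.n_sequences) or i == j:
                raise ValueError(f"invalid neighbor pair ({i}, {j})")


def make_planted_alignment(
    spec: PlantedAlignmentSpec,
) -> tuple[MasterAlignment, dict[str, str]]:
    """Generate an alignment with planted binding-site neighbors.

    Every sequence is a noisy copy of a common base (each position
    resampled uniformly with probability `background_rate`); then each
    planted pair is overwritten with a pair-specific random pattern at
    the site columns, making the partners identical exactly there.
    Returns the alignment and the ground-truth partner map by name.
    """
    rng = np.random.default_rng(spec.seed)
    aa = np.array(list(AMINO_ACIDS))
    base = rng.choice(aa, size=spec.length)
    rows = []
    for _ in range(spec.n_sequences):
        seq = base.copy()
        mutate = rng.random(spec.length) < spec.background_rate
        seq[mutate] = rng.choice(aa, size=int(mutate.sum()))
        rows.append(seq)
    site = np.array(spec.site_columns, dtype=int)
    for i, j in spec.neighbor_pairs:
        pattern = rng.choice(aa, size=site.size)
        rows[i][site] = pattern
        rows[j][site] = pattern
    names = [f"seq{i:02d}" for i in range(spec.n_sequences)]
    truth = {}
    for i, j in spec.neighbor_pairs:
        truth[names[i]] = names[j]
        truth[names[j]] = names[i]
    aln = MasterAlignment(names=names, rows=["".join(r) for r in rows])
    return aln, truth


def write_fasta(aln: MasterAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, row in zip(aln.names, aln.rows):
            fh.write(f">{name}\n{row}\n")
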