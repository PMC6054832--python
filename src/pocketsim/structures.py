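"""Protein-ligand complex loading, validation and ligand RMSD matrices.

A complex is one protein chain plus one or more selected ligand HETATM
groups, reduced to heavy atoms. Waters, hydrogens, alternate locations
(all but the highest-occupancy copy) and non-selected HETATM groups are
discarded on load.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException
from Bio.PDB.Polypeptide import protein_letters_3to1

__all__ = [
    "Atom",
    "BindingSiteComplex",
    "ComplexFormatError",
    "ChainNotFoundError",
    "LigandNotFoundError",
    "DEFAULT_RESIDUE_ALIASES",
    "load_complex",
    "ligand_rmsd_matrix",
]

SITES = ("cofactor", "substrate")

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

#: Modified polymer residues mapped to their parent residue name.
DEFAULT_RESIDUE_ALIASES = {
    "MSE": "MET",
    "SEC": "CYS",
    "CSO": "CYS",
    "CME": "CYS",
    "PTR": "TYR",
    "SEP": "SER",
    "TPO": "THR",
    "MLY": "LYS",
    "KCX": "LYS",
    "HYP": "PRO",
}

BACKBONE_ATOMS = {"N", "CA", "C", "O"}


class ComplexFormatError(ValueError):
    """Raised when a structure file cannot be parsed."""


class ChainNotFoundError(KeyError):
    """Raised when the requested chain is absent from the file."""


class LigandNotFoundError(ValueError):
    """Raised when no HETATM group matches the ligand selector."""


@dataclass(frozen=True)
class Atom:
    """One heavy atom with its residue context."""

    name: str
    element: str
    coords: tuple[float, float, float]
    residue_uid: tuple[str, int, str]  # (chain, residue number, insertion code)
    residue_name: str
    is_ligand: bool = False
    is_backbone: bool = False

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError(f"atom {self.name!r} has empty element")
        if not all(math.isfinite(c) for c in self.coords):
            raise ValueError(f"atom {self.name!r} has non-finite coordinates")
        if self.is_ligand and self.is_backbone:
            raise ValueError("ligand atoms cannot be flagged as backbone")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)


@dataclass
class BindingSiteComplex:
    """One protein chain and one bound ligand group, heavy atoms only."""

    complex_id: str
    target_name: str
    site: str
    protein_atoms: list[Atom] = field(default_factory=list)
    ligand_atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ValueError(f"site must be one of {SITES}, got {self.site!r}")
        chains = {a.residue_uid[0] for a in self.protein_atoms}
        if len(chains) > 1:
            raise ValueError(f"more than one polymer chain represented: {sorted(chains)}")
        if not self.ligand_atoms:
            raise ValueError("ligand_atoms must be non-empty")
        for a in self.protein_atoms + self.ligand_atoms:
            if a.element == "H":
                raise ValueError("hydrogens must not be retained")

    @property
    def atoms(self) -> list[Atom]:
        return self.protein_atoms + self.ligand_atoms

    def residue_uids(self) -> list[tuple[str, int, str]]:
        """Polymer residue UIDs in sequence order (resnum, icode)."""
        seen: dict[tuple[str, int, str], None] = {}
        for a in self.protein_atoms:
            seen.setdefault(a.residue_uid)
        return sorted(seen, key=lambda u: (u[1], u[2]))

    def residue_name(self, uid: tuple[str, int, str]) -> str:
        for a in self.protein_atoms:
            if a.residue_uid == uid:
                return a.residue_name
        raise KeyError(uid)

    def sequence(self, aliases: dict[str, str] | None = None) -> str:
        """One-letter sequence of the observed polymer residues."""
        aliases = DEFAULT_RESIDUE_ALIASES if aliases is None else aliases
        letters = []
        for uid in self.residue_uids():
            name = self.residue_name(uid)
            name = aliases.get(name, name)
            letters.append(protein_letters_3to1.get(name, "X"))
        return "".join(letters)

    def to_tsv(self, path: str | Path) -> None:
        """Serialize as one atom per row."""
        rows = []
        for a in self.atoms:
            rows.append(
                {
                    "complex_id": self.complex_id,
                    "target": self.target_name,
                    "site": self.site,
                    "chain": a.residue_uid[0],
                    "resnum": a.residue_uid[1],
                    "icode": a.residue_uid[2] or ".",
                    "resname": a.residue_name,
                    "atom": a.name,
                    "element": a.element,
                    "x": f"{a.coords[0]:.6f}",
                    "y": f"{a.coords[1]:.6f}",
                    "z": f"{a.coords[2]:.6f}",
                    "is_ligand": int(a.is_ligand),
                    "is_backbone": int(a.is_backbone),
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BindingSiteComplex":
        df = pd.read_csv(path, sep="\t", dtype={"icode": str, "chain": str})
        if df.empty:
            raise ComplexFormatError(f"empty complex table: {path}")
        protein, ligand = [], []
        for row in df.itertuples(index=False):
            icode = "" if row.icode in (".", None) else str(row.icode)
            atom = Atom(
                name=row.atom,
                element=row.element,
                coords=(float(row.x), float(row.y), float(row.z)),
                residue_uid=(str(row.chain), int(row.resnum), icode),
                residue_name=row.resname,
                is_ligand=bool(row.is_ligand),
                is_backbone=bool(row.is_backbone),
            )
            (ligand if atom.is_ligand else protein).append(atom)
        first = df.iloc[0]
        return cls(
            complex_id=str(first["complex_id"]),
            target_name=str(first["target"]),
            site=str(first["site"]),
            protein_atoms=protein,
            ligand_atoms=ligand,
        )


def _matches_selector(resname: str, uid: tuple[str, int, str], selector: Sequence[str]) -> bool:
    """A selector entry is either a residue name ('LIG') or 'chain:resnum'."""
    for sel in selector:
        if ":" in str(sel):
            ch, num = str(sel).split(":", 1)
            if uid[0] == ch and str(uid[1]) == num:
                return True
        elif resname == str(sel):
            return True
    return False


def load_complex(
    path: str | Path,
    chain_id: str,
    ligand_selector: Sequence[str],
    site: str,
    complex_id: str | None = None,
    target_name: str = "",
    residue_aliases: dict[str, str] | None = None,
) -> BindingSiteComplex:
    """Load a PDB file and reduce it to one chain plus the selected ligand.

    Waters and non-selected HETATM groups are removed, hydrogens dropped,
    and for disordered atoms only the highest-occupancy alternate location
    is kept (ties broken by altloc label order).

    Raises
    ------
    ChainNotFoundError
        if `chain_id` is not present.
    LigandNotFoundError
        if no HETATM group matches `ligand_selector`.
    ComplexFormatError
        if the file cannot be parsed (message carries the line number
        reported by the parser).
    """
    path = Path(path)
    aliases = DEFAULT_RESIDUE_ALIASES if residue_aliases is None else residue_aliases
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = parser.get_structure(path.stem, str(path))
    except PDBConstructionException as exc:
        raise ComplexFormatError(f"cannot parse {path}: {exc}") from exc
    model = next(structure.get_models())
    chain = None
    for ch in model:
        if ch.id == chain_id:
            chain = ch
            break
    if chain is None:
        raise ChainNotFoundError(f"chain not found: {chain_id!r} in {path}")

    protein_atoms: list[Atom] = []
    ligand_atoms: list[Atom] = []
    for residue in chain:
        hetflag, resnum, icode = residue.id
        resname = residue.get_resname().strip()
        uid = (chain_id, int(resnum), icode.strip())
        if resname in WATER_NAMES or hetflag == "W":
            continue
        is_polymer = hetflag == " " or resname in aliases
        is_ligand = not is_polymer and _matches_selector(resname, uid, ligand_selector)
        if not is_polymer and not is_ligand:
            continue
        for bio_atom in residue:
            # DisorderedAtom resolves to its highest-occupancy child;
            # Biopython keeps the first-seen altloc on occupancy ties.
            element = (bio_atom.element or "").strip().upper()
            if element in ("H", "D", ""):
                continue
            # PDB stores 3 decimals; rounding undoes the parser's float32 noise
            x, y, z = (round(float(v), 3) for v in bio_atom.coord)
            atom = Atom(
                name=bio_atom.get_name(),
                element=element,
                coords=(x, y, z),
                residue_uid=uid,
                residue_name=resname,
                is_ligand=is_ligand,
                is_backbone=(not is_ligand) and bio_atom.get_name() in BACKBONE_ATOMS,
            )
            (ligand_atoms if is_ligand else protein_atoms).append(atom)

    if not ligand_atoms:
        raise LigandNotFoundError(
            f"no ligand matched selector {list(ligand_selector)!r} in chain {chain_id} of {path}"
        )
    return BindingSiteComplex(
        complex_id=complex_id or path.stem,
        target_name=target_name,
        site=site,
        protein_atoms=protein_atoms,
        ligand_atoms=ligand_atoms,
    )


def ligand_rmsd_matrix(
    complexes: Iterable[BindingSiteComplex],
    min_shared_atoms: int = 3,
) -> pd.DataFrame:
    """Pairwise ligand-coordinate RMSD over atoms matched by name.

    Coordinates are assumed to be in a common frame already; no
    re-superposition is performed. Pairs sharing fewer than
    `min_shared_atoms` atom names are reported as NaN rather than zero.
    """
    complexes = list(complexes)
    ids = [c.complex_id for c in complexes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate complex_ids in RMSD input")
    coord_maps = []
    for c in complexes:
        m: dict[str, np.ndarray] = {}
        for a in c.ligand_atoms:
            if a.name in m:
                raise ValueError(f"{c.complex_id}: duplicate ligand atom name {a.name!r}")
            m[a.name] = a.xyz
        coord_maps.append(m)
    n = len(complexes)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = sorted(set(coord_maps[i]) & set(coord_maps[j]))
            if len(shared) < min_shared_atoms:
                out[i, j] = out[j, i] = np.nan
                continue
            a = np.stack([coord_maps[i][k] for k in shared])
            b = np.stack([coord_maps[j][k] for k in shared])
            out[i, j] = out[j, i] = float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
    return pd.DataFrame(out, index=ids, columns=ids)
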