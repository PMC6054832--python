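"""Master alignment handling, structure-to-column mapping, and normalized
Gonnet per-residue similarities.

The normalized similarity is S(a, b) = M(a, b) / sqrt(M(a, a) * M(b, b))
over the Gonnet 1992 substitution matrix, so that S(a, a) = 1 for every
residue. Columns that are gapped in either sequence contribute similarity 0.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .structures import BindingSiteComplex

__all__ = [
    "MasterAlignment",
    "AlignmentMap",
    "GonnetSimilarity",
    "AlignmentFormatError",
    "StructureRowMismatchError",
    "read_alignment",
    "map_structure_to_columns",
    "gonnet_similarity",
    "load_gonnet",
]

GAP_CHARS = set("-.")

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


class AlignmentFormatError(ValueError):
    """Raised on malformed alignment files (ragged rows etc.)."""


class StructureRowMismatchError(ValueError):
    """Raised when a structure's sequence does not match its alignment row."""


@dataclass
class MasterAlignment:
    names: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise AlignmentFormatError("names and rows differ in count")
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if self.names.count(n) > 1})
            raise AlignmentFormatError(f"duplicate sequence names: {dupes}")
        if self.rows:
            length = len(self.rows[0])
            for name, row in zip(self.names, self.rows):
                if len(row) != length:
                    raise AlignmentFormatError(f"ragged alignment: {name}")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, name: str) -> str:
        try:
            return self.rows[self.names.index(name)]
        except ValueError:
            raise KeyError(f"sequence not in alignment: {name!r}") from None

    def ungapped(self, name: str) -> str:
        return "".join(c for c in self.row(name) if c not in GAP_CHARS)

    def column_of_ungapped_index(self, name: str) -> list[int]:
        """For each ungapped residue index of a row, its alignment column."""
        return [i for i, c in enumerate(self.row(name)) if c not in GAP_CHARS]


@dataclass
class AlignmentMap:
    """Mapping from a structure's residue UIDs to master-alignment columns."""

    complex_id: str
    row_name: str
    mapping: dict[tuple[str, int, str], int] = field(default_factory=dict)
    coverage: float = 0.0

    def __post_init__(self) -> None:
        cols = list(self.mapping.values())
        if len(set(cols)) != len(cols):
            raise ValueError("alignment mapping must be injective")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"complex_id": self.complex_id, "chain": uid[0], "resnum": uid[1],
             "icode": uid[2] or ".", "column": col}
            for uid, col in sorted(self.mapping.items(), key=lambda kv: kv[1])
        ]
        return pd.DataFrame(rows, columns=["complex_id", "chain", "resnum", "icode", "column"])


def read_alignment(path: str | Path) -> MasterAlignment:
    """Read a Clustal or aligned-FASTA file into a MasterAlignment.

    Format is sniffed from the first non-blank line. Clustal conservation
    lines are ignored. Ragged rows raise AlignmentFormatError naming the
    offending sequence.
    """
    path = Path(path)
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip():
                first = line
                break
    fmt = "clustal" if first.upper().startswith("CLUSTAL") else "fasta"
    names: list[str] = []
    rows: list[str] = []
    if fmt == "clustal":
        seqs: dict[str, list[str]] = {}
        with open(path) as fh:
            next(fh)  # header
            for line in fh:
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                parts = line.split()
                if len(parts) < 2 or set(parts[-1]) <= set("*:. "):
                    continue  # conservation / ruler line
                name, chunk = parts[0], parts[1]
                seqs.setdefault(name, []).append(chunk)
                if name not in names:
                    names.append(name)
        rows = ["".join(seqs[n]).upper() for n in names]
    else:
        for record in SeqIO.parse(str(path), "fasta"):
            names.append(record.id)
            rows.append(str(record.seq).upper())
    if not names:
        raise AlignmentFormatError(f"no sequences found in {path}")
    return MasterAlignment(names=names, rows=rows)


@functools.lru_cache(maxsize=1)
def load_gonnet() -> "GonnetSimilarity":
    """Load the shipped Gonnet 1992 matrix and build normalized similarities."""
    ref = resources.files("pocketsim.data") / "gonnet1992.txt"
    with resources.as_file(ref) as p:
        M = substitution_matrices.read(str(p))
    return GonnetSimilarity(M)


class GonnetSimilarity:
    """Normalized per-residue similarity derived from a substitution matrix."""

    def __init__(self, M) -> None:
        self.M = M
        self.alphabet = "".join(a for a in M.alphabet if a in STANDARD_AA)
        if set(self.alphabet) != set(STANDARD_AA):
            raise ValueError("substitution matrix must cover the 20 standard residues")
        diag = {a: float(M[a, a]) for a in self.alphabet}
        if any(v <= 0 for v in diag.values()):
            raise ValueError("diagonal of substitution matrix must be positive")
        self._S: dict[tuple[str, str], float] = {}
        for a in self.alphabet:
            for b in self.alphabet:
                s = float(M[a, b]) / np.sqrt(diag[a] * diag[b])
                self._S[(a, b)] = s
                if s > 1.0 + 1e-12:
                    raise ValueError(f"normalized similarity exceeds 1 for pair {a}{b}")

    def similarity(self, a: str, b: str, unknown_map: dict[str, float] | None = None) -> float:
        """S(a, b); non-standard letters raise unless mapped by `unknown_map`."""
        a, b = a.upper(), b.upper()
        if unknown_map is None:
            unknown_map = {"X": 0.0}
        key = (a, b)
        if key in self._S:
            return self._S[key]
        for letter in (a, b):
            if letter not in self.alphabet:
                if letter in unknown_map:
                    return unknown_map[letter]
                raise KeyError(f"non-standard residue letter: {letter!r}")
        raise KeyError(f"cannot score pair {a}{b}")  # pragma: no cover


def gonnet_similarity(a: str, b: str, unknown_map: dict[str, float] | None = None) -> float:
    """Normalized Gonnet similarity for a residue pair (module-level shortcut)."""
    return load_gonnet().similarity(a, b, unknown_map=unknown_map)


def _aligned_pairs(aligner: PairwiseAligner, seq_a: str, seq_b: str) -> list[tuple[int, int]]:
    alignment = next(iter(aligner.align(seq_a, seq_b)))
    pairs: list[tuple[int, int]] = []
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        pairs.extend(zip(range(a0, a1), range(b0, b1)))
    return pairs


def map_structure_to_columns(
    complex: BindingSiteComplex,
    aln: MasterAlignment,
    row_name: str,
    identity_floor: float = 0.60,
    residue_aliases: dict[str, str] | None = None,
) -> AlignmentMap:
    """Map a structure's residues to master-alignment columns.

    The structure's observed one-letter sequence is globally aligned
    (Gonnet scoring, affine gaps: open 10, extend 0.5) against the
    ungapped master row; the result is composed with the row's gap
    pattern. Raises StructureRowMismatchError when aligned identity falls
    below `identity_floor`.
    """
    row_ungapped = aln.ungapped(row_name)
    structure_uids = complex.residue_uids()
    structure_seq = complex.sequence(aliases=residue_aliases)
    if not structure_uids:
        raise ValueError("structure has no polymer residues")

    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("GONNET1992")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    pairs = _aligned_pairs(aligner, structure_seq, row_ungapped)

    matches = sum(1 for i, j in pairs if structure_seq[i] == row_ungapped[j])
    identity = matches / len(pairs) if pairs else 0.0
    if identity < identity_floor:
        raise StructureRowMismatchError(
            f"structure/row mismatch: {complex.complex_id} vs {row_name} "
            f"(identity {identity:.2f} < floor {identity_floor:.2f})"
        )

    columns = aln.column_of_ungapped_index(row_name)
    mapping = {structure_uids[i]: columns[j] for i, j in pairs}
    coverage = len(mapping) / len(structure_uids)
    return AlignmentMap(
        complex_id=complex.complex_id,
        row_name=row_name,
        mapping=mapping,
        coverage=coverage,
    )
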