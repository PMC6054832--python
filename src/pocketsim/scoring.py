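"""Profile-weighted sequence similarity matrices and neighbor rankings.

For each contact profile L and each pair of alignment rows, the raw score
is the profile-weighted sum of normalized Gonnet similarities over the
profile's columns (gaps contribute 0). Raw matrices are Z-standardized
over their off-diagonal upper-triangle population, averaged element-wise
across profiles, min-max normalized into [0, 1] (off-diagonal population;
diagonal reported as 1 by convention), and inverted into a distance
matrix as 1 - similarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .contacts import ContactProfile
from .msa import GAP_CHARS, MasterAlignment, load_gonnet

__all__ = [
    "ScoreMatrix",
    "ScoreStages",
    "DegenerateProfileError",
    "gonnet_pfp",
    "score_matrix",
    "rank_neighbors",
    "pocket_columns_profile",
]

STAGES = ("raw_per_profile", "zscored_per_profile", "averaged", "normalized", "distance")


class DegenerateProfileError(ValueError):
    """Raised when a profile yields a constant (or single-pair) raw matrix."""


@dataclass
class ScoreMatrix:
    """A symmetric matrix over alignment sequence names at a given stage."""

    names: list[str]
    stage: str
    values: np.ndarray
    profile_id: str | None = None

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.names), len(self.names)):
            raise ValueError("matrix shape does not match names")
        if not np.allclose(v, v.T, atol=1e-12, equal_nan=True):
            raise ValueError("matrix must be symmetric")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.names, columns=self.names)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.names.index(pair[0]), self.names.index(pair[1])
        return float(self.values[i, j])


@dataclass
class ScoreStages:
    """All intermediate stages of one similarity computation."""

    raw: list[ScoreMatrix]
    zscored: list[ScoreMatrix]
    averaged: ScoreMatrix
    normalized: ScoreMatrix
    distance: ScoreMatrix


def gonnet_pfp(seq1: str, seq2: str, profile: ContactProfile) -> float:
    """Profile-weighted similarity between two aligned rows.

    Sum over the profile's columns c of weight(c) * S(seq1[c], seq2[c]);
    a gap in either row at c contributes 0.
    """
    if len(seq1) != len(seq2):
        raise ValueError("rows must come from the same alignment (equal length)")
    gonnet = load_gonnet()
    total = 0.0
    for col, w in profile.weights.items():
        if col >= len(seq1):
            raise IndexError(f"profile column {col} out of range for alignment length {len(seq1)}")
        a, b = seq1[col], seq2[col]
        if a in GAP_CHARS or b in GAP_CHARS:
            continue
        total += w * gonnet.similarity(a, b)
    return total


def _offdiag_upper(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def score_matrix(
    aln: MasterAlignment,
    profiles: Sequence[ContactProfile],
    ddof: int = 1,
) -> ScoreStages:
    """Build all similarity stages from an alignment and contact profiles.

    Z-scores and the min-max normalization are computed over the
    off-diagonal upper-triangle population only (self-pairs excluded);
    the diagonal of the normalized matrix is set to 1 by convention and
    the distance matrix is its complement with a zero diagonal.

    Raises DegenerateProfileError when a profile's off-diagonal raw
    values are constant or when fewer than two sequence pairs exist.
    """
    if not profiles:
        raise ValueError("score_matrix requires at least one profile")
    names = list(aln.names)
    n = len(names)
    if n < 2:
        raise ValueError("score_matrix requires at least two sequences")

    raw_list: list[ScoreMatrix] = []
    z_list: list[ScoreMatrix] = []
    for profile in profiles:
        raw = np.zeros((n, n))
        for i in range(n):
            for j in range(i, n):
                raw[i, j] = raw[j, i] = gonnet_pfp(aln.rows[i], aln.rows[j], profile)
        pop = _offdiag_upper(raw)
        if pop.size < 2:
            raise DegenerateProfileError(
                f"degenerate profile {profile.target_name!r}: "
                f"off-diagonal population of size {pop.size} cannot be standardized"
            )
        sd = float(np.std(pop, ddof=ddof))
        if sd == 0.0:
            raise DegenerateProfileError(
                f"degenerate profile {profile.target_name!r}: constant raw matrix"
            )
        z = (raw - float(np.mean(pop))) / sd
        raw_list.append(ScoreMatrix(names, "raw_per_profile", raw, profile.target_name))
        z_list.append(ScoreMatrix(names, "zscored_per_profile", z, profile.target_name))

    averaged = np.mean([z.values for z in z_list], axis=0)
    pop = _offdiag_upper(averaged)
    lo, hi = float(pop.min()), float(pop.max())
    if hi == lo:
        raise DegenerateProfileError("degenerate averaged matrix: constant off-diagonal values")
    normalized = (averaged - lo) / (hi - lo)
    np.fill_diagonal(normalized, 1.0)
    distance = 1.0 - normalized

    return ScoreStages(
        raw=raw_list,
        zscored=z_list,
        averaged=ScoreMatrix(names, "averaged", averaged),
        normalized=ScoreMatrix(names, "normalized", normalized),
        distance=ScoreMatrix(names, "distance", distance),
    )


def rank_neighbors(
    matrix: ScoreMatrix,
    target: str,
    k: int | None = None,
) -> list[tuple[str, float]]:
    """Other sequences sorted by descending similarity to `target`.

    Ties are broken alphabetically; `k` larger than n-1 (or None)
    returns the full list.
    """
    if target not in matrix.names:
        raise KeyError(f"unknown target: {target!r}")
    i = matrix.names.index(target)
    pairs = [
        (name, float(matrix.values[i, j]))
        for j, name in enumerate(matrix.names)
        if name != target
    ]
    pairs.sort(key=lambda p: (-p[1], p[0]))
    return pairs if k is None else pairs[:k]


def pocket_columns_profile(
    columns: Sequence[int],
    target_name: str = "pocket",
    site: str = "cofactor",
) -> ContactProfile:
    """Uniform-weight profile over a set of columns.

    Used for the classical whole-pocket comparison variant where every
    residue within a distance cutoff of the ligands carries equal weight.
    """
    if not columns:
        raise ValueError("no pocket columns given")
    return ContactProfile(
        target_name=target_name, site=site,
        weights={int(c): 1.0 for c in columns}, n_complexes=1,
    )
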