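"""Distance-ramp contact-strength profiles per target.

Each ligand/protein heavy-atom pair contributes a soft contact score: 1 at
or below 3.23 Å, 0 at or beyond 4.63 Å, linear in between. Per-residue
totals (backbone and side chain) are keyed by master-alignment column and
aggregated over a target's complexes into an ensemble profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .msa import AlignmentMap
from .structures import BindingSiteComplex

__all__ = [
    "ContactProfile",
    "RAMP_FULL",
    "RAMP_ZERO",
    "contact_strength",
    "complex_contact_vector",
    "ensemble_profile",
]

logger = logging.getLogger(__name__)

RAMP_FULL = 3.23  # Å; plateau boundary (strength 1 at or below)
RAMP_ZERO = 4.63  # Å; cutoff (strength 0 at or beyond)


@dataclass
class ContactProfile:
    """Per-alignment-column contact weights for one target and site."""

    target_name: str
    site: str
    weights: dict[int, float] = field(default_factory=dict)
    n_complexes: int = 1

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("contact weights must be non-negative")
        if any(c < 0 for c in self.weights):
            raise ValueError("alignment columns must be non-negative")
        if not any(w > 0 for w in self.weights.values()):
            raise ValueError(f"profile for {self.target_name!r} has no positive weight")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"target": self.target_name, "site": self.site, "column": c,
             "weight": w, "n_complexes": self.n_complexes}
            for c, w in sorted(self.weights.items())
        ]
        return pd.DataFrame(rows, columns=["target", "site", "column", "weight", "n_complexes"])


def contact_strength(d: float) -> float:
    """Soft contact score for one heavy-atom pair at distance `d` (Å)."""
    if d < 0:
        raise ValueError(f"distance must be non-negative, got {d}")
    if d <= RAMP_FULL:
        return 1.0
    if d >= RAMP_ZERO:
        return 0.0
    return (RAMP_ZERO - d) / (RAMP_ZERO - RAMP_FULL)


def complex_contact_vector(
    complex: BindingSiteComplex,
    amap: AlignmentMap,
) -> dict[int, float]:
    """Total per-residue contact weight of one complex, keyed by column.

    Sums contact_strength over every (ligand heavy atom, residue heavy
    atom) pair, backbone and side chain alike. Residues without a mapped
    alignment column are dropped (count logged).
    """
    lig = np.stack([a.xyz for a in complex.ligand_atoms])
    weights: dict[int, float] = {}
    dropped = 0
    per_residue: dict[tuple[str, int, str], float] = {}
    for atom in complex.protein_atoms:
        dists = np.linalg.norm(lig - atom.xyz, axis=1)
        in_range = dists < RAMP_ZERO
        if not in_range.any():
            continue
        total = float(
            np.sum(np.clip((RAMP_ZERO - dists[in_range]) / (RAMP_ZERO - RAMP_FULL), None, 1.0))
        )
        per_residue[atom.residue_uid] = per_residue.get(atom.residue_uid, 0.0) + total
    for uid, total in per_residue.items():
        col = amap.mapping.get(uid)
        if col is None:
            dropped += 1
            continue
        weights[col] = weights.get(col, 0.0) + total
    if dropped:
        logger.info(
            "%s: %d contact residue(s) without an alignment column dropped",
            complex.complex_id, dropped,
        )
    return weights


def ensemble_profile(
    vectors: Iterable[Mapping[int, float]],
    target_name: str,
    site: str,
    mode: str = "max",
    rescale: bool = True,
) -> ContactProfile:
    """Aggregate per-complex contact vectors into one target profile.

    `mode` is "max" (default; removes redundancy between near-identical
    complexes) or "mean". With `rescale`, weights are divided by the
    maximum so the strongest column has weight 1.
    """
    vectors = [dict(v) for v in vectors]
    if not vectors:
        raise ValueError("ensemble_profile requires at least one contact vector")
    if mode not in ("max", "mean"):
        raise ValueError(f"unknown ensemble mode: {mode!r}")
    columns = sorted({c for v in vectors for c in v})
    agg: dict[int, float] = {}
    for c in columns:
        vals = [v.get(c, 0.0) for v in vectors]
        agg[c] = max(vals) if mode == "max" else float(np.mean(vals))
    agg = {c: w for c, w in agg.items() if w > 0}
    if rescale and agg:
        peak = max(agg.values())
        agg = {c: w / peak for c, w in agg.items()}
    return ContactProfile(
        target_name=target_name, site=site, weights=agg, n_complexes=len(vectors)
    )
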