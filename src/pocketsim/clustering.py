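"""Average-linkage (UPGMA) trees from distance matrices, with Newick export.

The agglomerator merges the closest pair under size-weighted arithmetic
mean linkage; ties are broken on the lexicographically smallest pair of
sorted leaf-name tuples so results are deterministic across platforms.
Cluster heights follow the standard UPGMA convention height = merge
distance / 2.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Dendrogram", "average_linkage_tree", "write_newick"]

_NEWICK_UNSAFE = re.compile(r"[\s()\[\]:;,']")


@dataclass
class Dendrogram:
    """Rooted tree as an ordered merge list.

    Node ids 0..n-1 are the leaves (in `leaves` order); merge k creates
    node n+k from (left, right) at the given height.
    """

    leaves: list[str]
    merges: list[tuple[int, int, float]] = field(default_factory=list)
    rooted: bool = True

    def __post_init__(self) -> None:
        n = len(self.leaves)
        if len(self.merges) != max(n - 1, 0):
            raise ValueError(f"expected {n - 1} merges for {n} leaves, got {len(self.merges)}")

    def heights(self) -> dict[int, float]:
        h = {i: 0.0 for i in range(len(self.leaves))}
        for k, (_, _, height) in enumerate(self.merges):
            h[len(self.leaves) + k] = height
        return h

    def members(self, node: int) -> frozenset[str]:
        n = len(self.leaves)
        if node < n:
            return frozenset([self.leaves[node]])
        left, right, _ = self.merges[node - n]
        return self.members(left) | self.members(right)

    def cophenetic(self) -> pd.DataFrame:
        """Pairwise cophenetic distances (2 x height of the joining node)."""
        n = len(self.leaves)
        out = pd.DataFrame(0.0, index=self.leaves, columns=self.leaves)
        for left, right, height in self.merges:
            for a in self.members(left):
                for b in self.members(right):
                    out.loc[a, b] = out.loc[b, a] = 2.0 * height
        return out

    def merges_frame(self) -> pd.DataFrame:
        rows = [
            {"left": ";".join(sorted(self.members(l))),
             "right": ";".join(sorted(self.members(r))),
             "height": h}
            for l, r, h in self.merges
        ]
        return pd.DataFrame(rows, columns=["left", "right", "height"])


def average_linkage_tree(dist: pd.DataFrame) -> Dendrogram:
    """UPGMA agglomeration of a symmetric zero-diagonal distance matrix.

    Raises on NaN entries (listing the offending pairs) and on fewer
    than two leaves.
    """
    names = [str(n) for n in dist.index]
    values = np.asarray(dist, dtype=float)
    if len(names) < 2:
        raise ValueError("need at least two leaves to cluster")
    if list(dist.columns) != list(dist.index):
        raise ValueError("distance matrix rows and columns must agree")
    nan_pairs = [
        (names[i], names[j])
        for i in range(len(names))
        for j in range(i + 1, len(names))
        if np.isnan(values[i, j])
    ]
    if nan_pairs:
        raise ValueError(f"NaN distances for pairs: {nan_pairs}")
    if not np.allclose(values, values.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(values), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")

    n = len(names)
    # active cluster: node id -> (sorted leaf-name tuple, size)
    active: dict[int, tuple[tuple[str, ...], int]] = {
        i: ((names[i],), 1) for i in range(n)
    }
    d: dict[frozenset[int], float] = {
        frozenset((i, j)): float(values[i, j])
        for i in range(n) for j in range(i + 1, n)
    }
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        best = None
        for i in sorted(active):
            for j in sorted(active):
                if j <= i:
                    continue
                dij = d[frozenset((i, j))]
                tie_key = tuple(sorted((active[i][0], active[j][0])))
                cand = (dij, tie_key, i, j)
                if best is None or cand < best:
                    best = cand
        dij, _, i, j = best
        size_i, size_j = active[i][1], active[j][1]
        merged_names = tuple(sorted(active[i][0] + active[j][0]))
        for k in active:
            if k in (i, j):
                continue
            dik = d[frozenset((i, k))]
            djk = d[frozenset((j, k))]
            d[frozenset((next_id, k))] = (size_i * dik + size_j * djk) / (size_i + size_j)
        del active[i], active[j]
        active[next_id] = (merged_names, size_i + size_j)
        merges.append((i, j, dij / 2.0))
        next_id += 1
    return Dendrogram(leaves=names, merges=merges)


def _quote(name: str) -> str:
    if _NEWICK_UNSAFE.search(name):
        return "'" + name.replace("'", "''") + "'"
    return name


def write_newick(tree: Dendrogram, path: str | Path | None = None) -> str:
    """Serialize a dendrogram as a rooted Newick string.

    Branch lengths are parent height minus child height; names with
    Newick-reserved characters are single-quoted.
    """
    if len(set(tree.leaves)) != len(tree.leaves):
        raise ValueError("duplicate leaf names")
    heights = tree.heights()
    n = len(tree.leaves)

    def render(node: int, parent_height: float) -> str:
        branch = parent_height - heights[node]
        if node < n:
            return f"{_quote(tree.leaves[node])}:{branch:.12g}"
        left, right, _ = tree.merges[node - n]
        inner = f"({render(left, heights[node])},{render(right, heights[node])})"
        return f"{inner}:{branch:.12g}"

    root = n + len(tree.merges) - 1
    left, right, _ = tree.merges[-1]
    newick = (
        f"({render(left, heights[root])},{render(right, heights[root])});"
    )
    if path is not None:
        Path(path).write_text(newick + "\n")
    return newick
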