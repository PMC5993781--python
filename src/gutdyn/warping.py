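"""Dynamic time warping of taxon trajectories and complete-linkage clustering.

DTW aligns two series of possibly unequal length by a monotone warping path.
The local cost is the absolute difference (Euclidean in one dimension) and
the step pattern is "symmetric2": D(i,j) = min(D(i-1,j) + c, D(i,j-1) + c,
D(i-1,j-1) + 2c) with D(1,1) = c(1,1) and no global path constraint. The
symmetric2 pattern admits normalization by n + m, which is used for the
"normalized" distance so series of different lengths are comparable.

Infant-to-infant distances average the normalized DTW distances of the four
dominant phylum trajectories, computed on the raw observed (non-interpolated)
series — coping with unequal lengths is what DTW is for. The resulting
matrix is clustered by complete linkage with a fixed lexicographic tie-break
so merges are deterministic.
"""

from __future__ import annotations

import dataclasses
import logging
from itertools import combinations

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

logger = logging.getLogger(__name__)

DEFAULT_PHYLA = ("Actinobacteria", "Bacteroidetes", "Firmicutes", "Proteobacteria")


def _dtw_raw_py(x: np.ndarray, y: np.ndarray) -> float:
    n, m = len(x), len(y)
    prev = np.empty(m)
    cur = np.empty(m)
    for j in range(m):
        c = abs(x[0] - y[j])
        prev[j] = c if j == 0 else prev[j - 1] + c
    for i in range(1, n):
        c = abs(x[i] - y[0])
        cur[0] = prev[0] + c
        for j in range(1, m):
            c = abs(x[i] - y[j])
            cur[j] = min(prev[j] + c, cur[j - 1] + c, prev[j - 1] + 2.0 * c)
        prev, cur = cur, prev
    return float(prev[m - 1])


try:  # jit the O(n*m) recursion; the pure-Python path stays as fallback
    from numba import njit

    _dtw_raw_jit = njit(cache=False)(_dtw_raw_py)
except ImportError:  # pragma: no cover
    _dtw_raw_jit = _dtw_raw_py


def dtw_distance(x, y) -> tuple[float, float]:
    """Symmetric2 DTW distance between two 1-D series.

    Returns (raw, normalized) where normalized = raw / (n + m).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty series")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite series values")
    raw = float(_dtw_raw_jit(x, y))
    return raw, raw / (len(x) + len(y))


@dataclasses.dataclass
class DtwMatrix:
    """Per-phylum and combined infant x infant normalized DTW distances."""

    per_phylum: dict[str, pd.DataFrame]
    combined: pd.DataFrame

    def to_distance_matrix(self) -> DistanceMatrix:
        return DistanceMatrix(self.combined.to_numpy(), ids=list(self.combined.index))


def phylum_series_by_infant(
    rel_phylum: pd.DataFrame, meta: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Split a phylum-level abundance table into day-ordered per-infant series."""
    out: dict[str, pd.DataFrame] = {}
    for infant_id, sub in meta.loc[rel_phylum.index].groupby("infant_id", sort=True):
        order = sub.sort_values("day_since_birth").index
        frame = rel_phylum.loc[order]
        frame.index = sub.loc[order, "day_since_birth"]
        out[str(infant_id)] = frame
    return out


def phylum_dtw_matrix(
    rel_by_infant: dict[str, pd.DataFrame],
    phyla=DEFAULT_PHYLA,
) -> DtwMatrix:
    """Mean normalized DTW distance between infants over the phylum series.

    ``rel_by_infant`` maps infant id to a day-ordered table with one column
    per phylum (lengths may differ between infants); the combined matrix is
    the arithmetic mean of the four per-phylum matrices.
    """
    ids = list(rel_by_infant)
    phyla = list(phyla)
    for inf, frame in rel_by_infant.items():
        missing = sorted(set(phyla) - set(frame.columns))
        if missing:
            raise ValueError(f"infant {inf!r} lacks phylum columns {missing}; aggregate first")
    per_phylum: dict[str, pd.DataFrame] = {}
    for ph in phyla:
        mat = np.zeros((len(ids), len(ids)))
        for a, b in combinations(range(len(ids)), 2):
            _, norm = dtw_distance(
                rel_by_infant[ids[a]][ph].to_numpy(),
                rel_by_infant[ids[b]][ph].to_numpy(),
            )
            mat[a, b] = mat[b, a] = norm
        per_phylum[ph] = pd.DataFrame(mat, index=ids, columns=ids)
    combined = sum(per_phylum[ph] for ph in phyla) / len(phyla)
    return DtwMatrix(per_phylum=per_phylum, combined=combined)


# ---------------------------------------------------------------------------
# complete-linkage clustering

@dataclasses.dataclass
class Dendrogram:
    """A complete-linkage merge tree.

    ``merges`` lists (left, right, height) with scipy-style cluster ids
    (0..n-1 are leaves, n+k is the cluster created by merge k); heights are
    non-decreasing. Newick export uses cumulative heights as node depths, so
    a branch's length is its parent's merge height minus its own.
    """

    labels: list[str]
    merges: list[tuple[int, int, float]]

    @property
    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]

    def first_merge_labels(self) -> set[str]:
        """Leaf labels under the first (lowest) merge."""
        left, right, _ = self.merges[0]
        return {self.labels[left], self.labels[right]} if left < len(self.labels) and right < len(
            self.labels
        ) else set()

    def to_newick(self) -> str:
        n = len(self.labels)
        node: dict[int, str] = {i: self.labels[i] for i in range(n)}
        height: dict[int, float] = {i: 0.0 for i in range(n)}
        for k, (a, b, h) in enumerate(self.merges):
            la = f"{node[a]}:{h - height[a]:.10g}"
            lb = f"{node[b]}:{h - height[b]:.10g}"
            node[n + k] = f"({la},{lb})"
            height[n + k] = h
        return node[n + len(self.merges) - 1] + ";"


def hierarchical_cluster(d: DistanceMatrix, linkage: str = "complete") -> Dendrogram:
    """Agglomerative clustering of a distance matrix.

    Only complete linkage (inter-cluster distance = maximum pairwise
    distance) is supported; ties in the merge choice are broken by the
    lexicographically smallest pair of cluster ids, which makes the merge
    sequence deterministic.
    """
    if linkage != "complete":
        raise ValueError(f"unsupported linkage {linkage!r}")
    D = np.asarray(d.data, dtype=float)
    if np.isnan(D).any():
        raise ValueError("NaN in distance matrix")
    labels = [str(i) for i in d.ids]
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 leaves")
    # active cluster id -> member leaf indices
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(members) > 1:
        best = None
        active = sorted(members)
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                dist = max(D[i, j] for i in members[a] for j in members[b])
                if best is None or dist < best[0]:
                    best = (dist, a, b)
        dist, a, b = best
        merges.append((a, b, float(dist)))
        members[next_id] = members.pop(a) + members.pop(b)
        next_id += 1
    heights = [h for _, _, h in merges]
    assert all(h2 >= h1 - 1e-12 for h1, h2 in zip(heights, heights[1:])), (
        "complete-linkage heights must be non-decreasing"
    )
    return Dendrogram(labels=labels, merges=merges)
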