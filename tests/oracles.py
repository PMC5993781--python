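"""Independent brute-force oracles used across the test suite.

Each oracle deliberately avoids the implementation's code paths: UniFrac is
recomputed from a dendropy-parsed tree with explicit per-branch loops, DTW
by exhaustive enumeration of monotone warping paths, PERMANOVA from the raw
sum definitions (and by full label-permutation enumeration), and complete
linkage by an O(n^3) agglomeration over frozensets.
"""

from __future__ import annotations

import itertools

import dendropy
import numpy as np


def brute_force_gunifrac(newick: str, taxa: list[str], x, y, alpha: float) -> float:
    """Generalized UniFrac via explicit branch enumeration on a dendropy tree."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    x = dict(zip(taxa, x))
    y = dict(zip(taxa, y))
    num = 0.0
    den = 0.0
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        length = edge.length or 0.0
        leaves = [lf.taxon.label for lf in edge.head_node.leaf_iter()]
        p = sum(x.get(lbl, 0.0) for lbl in leaves)
        q = sum(y.get(lbl, 0.0) for lbl in leaves)
        if p + q <= 0:
            continue
        w = length * (p + q) ** alpha
        num += w * abs(p - q) / (p + q)
        den += w
    return num / den


def brute_force_dtw(x, y) -> float:
    """Minimal symmetric2 path cost by exhaustive path enumeration.

    Paths move from (0, 0) to (n-1, m-1) by steps (1,0), (0,1), (1,1); a
    diagonal step pays 2c(i,j), the others pay c(i,j), and the start cell
    pays c(0,0) once.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)

    def cost(i, j):
        return abs(x[i] - y[j])

    best = [np.inf]

    def walk(i, j, acc):
        if acc >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = acc
            return
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, acc + 2 * cost(i + 1, j + 1))
        if i + 1 < n:
            walk(i + 1, j, acc + cost(i + 1, j))
        if j + 1 < m:
            walk(i, j + 1, acc + cost(i, j + 1))

    walk(0, 0, cost(0, 0))
    return float(best[0])


def permanova_sums(d: np.ndarray, labels) -> tuple[float, float]:
    """Pseudo-F and R^2 straight from the sum definitions (loops, no tricks)."""
    labels = np.asarray(labels)
    n = len(labels)
    ss_total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ss_total += d[i, j] ** 2
    ss_total /= n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = [i for i in range(n) if labels[i] == g]
        acc = 0.0
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                acc += d[idx[a], idx[b]] ** 2
        ss_within += acc / len(idx)
    ss_among = ss_total - ss_within
    a = len(np.unique(labels))
    f = (ss_among / (a - 1)) / (ss_within / (n - a))
    return f, ss_among / ss_total


def permanova_exact_p(d: np.ndarray, labels) -> float:
    """Exact permutation p by enumerating every label arrangement."""
    labels = list(labels)
    f_obs, _ = permanova_sums(d, labels)
    count = 0
    total = 0
    for perm in itertools.permutations(labels):
        f, _ = permanova_sums(d, list(perm))
        total += 1
        if f >= f_obs - 1e-12:
            count += 1
    return count / total


def naive_complete_linkage_heights(d: np.ndarray) -> list[float]:
    """Merge heights from a frozenset-based O(n^3) complete-linkage pass."""
    n = d.shape[0]
    clusters = [frozenset([i]) for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            dist = max(d[i, j] for i in a for j in b)
            if best is None or dist < best[0]:
                best = (dist, a, b)
        dist, a, b = best
        heights.append(dist)
        clusters = [c for c in clusters if c not in (a, b)] + [a | b]
    return heights
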