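"""Beta-diversity kernels: Bray-Curtis and generalized UniFrac.

Generalized UniFrac weights each branch's contribution by
(p+q)^alpha * |p-q| / (p+q), where p and q are the fractions of the two
communities descending from the branch; alpha = 1 recovers the
abundance-weighted normalized form, alpha -> 0 approaches presence/absence
behaviour, and alpha = 0.5 moderates the dominance of abundant lineages.
Branch masses are accumulated in a single post-order traversal (BranchTable)
rather than per-pair tree walks, which the 365-pseudo-day profiles require.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

logger = logging.getLogger(__name__)


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity: sum|x-y| / sum(x+y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors differ in length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("negative abundance entry")
    denom = (x + y).sum()
    if denom == 0:
        raise ValueError("both vectors are all-zero")
    return float(np.abs(x - y).sum() / denom)


@dataclasses.dataclass
class BranchTable:
    """Per-branch lengths and descendant-leaf indicators for a rooted tree.

    The root's own (non-)branch is excluded. ``leaf_matrix[b]`` flags the
    OTUs below branch b, in ``otu_ids`` column order, so branch masses for a
    composition x are simply ``leaf_matrix @ x``.
    """

    lengths: np.ndarray  # (n_branches,)
    leaf_matrix: np.ndarray  # (n_branches, n_otus), float 0/1
    otu_ids: list[str]

    @classmethod
    def from_tree(cls, tree: TreeNode, otu_ids) -> "BranchTable":
        otu_ids = [str(o) for o in otu_ids]
        tree = _ensure_rooted(tree)
        leaves = {leaf.name for leaf in tree.tips()}
        missing = sorted(set(otu_ids) - leaves)
        if missing:
            raise ValueError(f"OTUs missing from tree leaves: {missing[:10]}")
        col = {o: i for i, o in enumerate(otu_ids)}
        masks: dict[int, np.ndarray] = {}
        lengths = []
        rows = []
        for node in tree.postorder(include_self=True):
            if node.is_tip():
                mask = np.zeros(len(otu_ids))
                if node.name in col:
                    mask[col[node.name]] = 1.0
            else:
                mask = np.zeros(len(otu_ids))
                for child in node.children:
                    mask += masks[id(child)]
            masks[id(node)] = mask
            if node is tree:
                continue
            length = 0.0 if node.length is None else float(node.length)
            if length < 0:
                raise ValueError(f"negative branch length on node {node.name!r}")
            lengths.append(length)
            rows.append(mask)
        return cls(
            lengths=np.asarray(lengths, dtype=float),
            leaf_matrix=np.asarray(rows, dtype=float),
            otu_ids=otu_ids,
        )

    def masses(self, x: np.ndarray) -> np.ndarray:
        """Per-branch fraction of community mass below each branch."""
        return self.leaf_matrix @ np.asarray(x, dtype=float)


def _ensure_rooted(tree: TreeNode) -> TreeNode:
    # a trifurcating root is the conventional serialization of an unrooted
    # binary tree; higher-degree roots are treated as genuine polytomies
    if len(tree.children) == 3:
        logger.warning("tree looks unrooted (trifurcating root); midpoint rooting")
        return tree.root_at_midpoint()
    return tree


def gunifrac_from_masses(p: np.ndarray, q: np.ndarray, lengths: np.ndarray, alpha: float) -> float:
    """Generalized UniFrac from precomputed branch masses of two communities."""
    s = p + q
    keep = s > 0
    if not keep.any():
        raise ValueError("no shared tree mass: empty denominator")
    s = s[keep]
    w = lengths[keep] * s**alpha
    denom = w.sum()
    if denom == 0:
        raise ValueError("no shared tree mass: empty denominator")
    num = (w * np.abs(p[keep] - q[keep]) / s).sum()
    return float(num / denom)


def generalized_unifrac(x, y, branches: BranchTable, alpha: float = 0.5) -> float:
    """Generalized UniFrac between two relative-abundance vectors.

    Vectors must be compositions over ``branches.otu_ids`` (summing to 1);
    ``alpha`` must lie in [0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    for name, v in (("x", x), ("y", y)):
        if v.shape != (len(branches.otu_ids),):
            raise ValueError(f"{name} has wrong length for this BranchTable")
        if not np.isclose(v.sum(), 1.0, atol=1e-6):
            raise ValueError(f"{name} is not a composition (sum {v.sum():.6f})")
    return gunifrac_from_masses(branches.masses(x), branches.masses(y), branches.lengths, alpha)


def distance_matrix(
    rel: pd.DataFrame,
    metric: str = "bray_curtis",
    tree: TreeNode | None = None,
    alpha: float = 0.5,
) -> DistanceMatrix:
    """All-pairs distance matrix over the rows of an abundance table.

    ``metric`` is 'bray_curtis' or 'gunifrac'; the latter requires ``tree``
    and interprets rows as compositions over the table's columns.
    """
    ids = [str(i) for i in rel.index]
    X = rel.to_numpy(dtype=float)
    n = X.shape[0]
    d = np.zeros((n, n))
    if metric == "bray_curtis":
        for i in range(n - 1):
            rest = X[i + 1 :]
            num = np.abs(X[i] - rest).sum(axis=1)
            den = (X[i] + rest).sum(axis=1)
            if (den == 0).any():
                raise ValueError("pair of all-zero rows")
            d[i, i + 1 :] = num / den
    elif metric == "gunifrac":
        if tree is None:
            raise ValueError("metric 'gunifrac' requires a tree")
        bt = BranchTable.from_tree(tree, list(rel.columns))
        M = X @ bt.leaf_matrix.T  # (n, n_branches)
        L = bt.lengths
        for i in range(n - 1):
            rest = M[i + 1 :]
            s = M[i] + rest
            with np.errstate(divide="ignore", invalid="ignore"):
                # branches carrying no mass in either community are outside
                # the formula's domain and must not enter the denominator
                w = np.where(s > 0, L * np.where(s > 0, s, 1.0) ** alpha, 0.0)
                ratio = np.where(s > 0, np.abs(M[i] - rest) / np.where(s > 0, s, 1.0), 0.0)
            num = (w * ratio).sum(axis=1)
            den = w.sum(axis=1)
            if (den == 0).any():
                raise ValueError("no shared tree mass for some pair")
            d[i, i + 1 :] = num / den
    else:
        raise ValueError(f"unknown metric {metric!r}")
    d = d + d.T
    return DistanceMatrix(d, ids=ids)
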