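"""Distance-based tree construction with outgroup rooting.

Trees here are a documented stand-in for full maximum-likelihood inference:
pairwise Poisson-corrected distances from a multiple alignment, then
neighbor joining (or UPGMA for ultrametric clustering), rooted on a
designated outgroup.  Clade membership -- not branch support -- is what
these trees are used to assess.

Trees are carried as :class:`skbio.tree.TreeNode`, so Newick I/O and
standard tree operations come for free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skbio.tree import TreeNode

__all__ = [
    "DistanceMatrix",
    "protein_distance",
    "neighbor_joining",
    "upgma",
    "root_on_outgroup",
]


@dataclass
class DistanceMatrix:
    """Labelled symmetric distance matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix has a non-zero diagonal")
        if np.any(v < 0):
            raise ValueError("distance matrix has negative entries")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels")
        self.values = v


def protein_distance(msa, max_distance: float = 10.0) -> DistanceMatrix:
    """Poisson-corrected pairwise distances from an MSA.

    For each pair, p = fraction of mismatches over columns where both rows
    are ungapped, corrected as d = -ln(1 - p).  Saturated pairs (p >= 1)
    are capped at ``max_distance``.  A pair sharing no ungapped column is
    an error.
    """
    rows = msa.rows
    ids = msa.ids
    n = len(rows)
    if n < 2:
        raise ValueError("need at least 2 aligned sequences")
    arr = np.array([list(r) for r in rows])
    gap = arr == "-"
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~gap[i] & ~gap[j]
            total = int(shared.sum())
            if total == 0:
                raise ValueError(
                    f"rows {ids[i]!r} and {ids[j]!r} share no ungapped "
                    f"columns"
                )
            p = float((arr[i, shared] != arr[j, shared]).sum()) / total
            if p >= 1.0:
                dij = max_distance
            else:
                dij = min(-np.log(1.0 - p), max_distance)
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(labels=list(ids), values=d)


def _clamp(length: float, context: str) -> float:
    if length < 0:
        if length < -1e-9:
            warnings.warn(
                f"negative branch length {length:.4g} clamped to 0 "
                f"({context})", stacklevel=3)
        return 0.0
    return length


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Canonical Saitou-Nei neighbor joining with deterministic ties.

    When several pairs minimize the Q criterion, the pair whose sort keys
    (the lexicographically smallest leaf label in each cluster) are lowest
    is joined, making the output independent of input order.  Negative
    branch lengths are clamped to zero with a warning.  Returns an
    unrooted tree (trifurcating root).
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    d = dm.values.copy()
    nodes = [TreeNode(name=lab) for lab in dm.labels]
    keys = list(dm.labels)  # smallest leaf label per cluster, for ties

    while len(nodes) > 3:
        m = len(nodes)
        total = d.sum(axis=1)
        q = (m - 2) * d - total[:, None] - total[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        candidates = [
            (tuple(sorted((keys[i], keys[j]))), i, j)
            for i in range(m) for j in range(i + 1, m)
            if q[i, j] <= qmin + 1e-12
        ]
        _, i, j = min(candidates)
        li = 0.5 * d[i, j] + (total[i] - total[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        parent = TreeNode()
        nodes[i].length = _clamp(li, f"joining {keys[i]}/{keys[j]}")
        nodes[j].length = _clamp(lj, f"joining {keys[i]}/{keys[j]}")
        parent.extend([nodes[i], nodes[j]])
        new_d = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.zeros((len(keep) + 1, len(keep) + 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = new_d[keep]
        d = d2
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]

    # closed-form three-point formulas for the last three clusters
    a, b, c = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    root = TreeNode()
    a.length = _clamp(0.5 * (dab + dac - dbc), "final join")
    b.length = _clamp(0.5 * (dab + dbc - dac), "final join")
    c.length = _clamp(0.5 * (dac + dbc - dab), "final join")
    root.extend([a, b, c])
    return root


def upgma(dm: DistanceMatrix) -> TreeNode:
    """Average-linkage agglomeration into an ultrametric tree.

    Shares its engine (scipy average-linkage) with expression clustering;
    merge heights are non-decreasing, leaf depth equals half the merge
    height of the root.
    """
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    n = len(dm.labels)
    if n < 2:
        raise ValueError("UPGMA requires at least 2 taxa")
    link = linkage(squareform(dm.values, checks=False), method="average")
    nodes: dict[int, tuple[TreeNode, float]] = {
        i: (TreeNode(name=lab), 0.0) for i, lab in enumerate(dm.labels)
    }
    for k, (ia, ib, height, _) in enumerate(link):
        child_a, ha = nodes.pop(int(ia))
        child_b, hb = nodes.pop(int(ib))
        h = height / 2.0  # ultrametric node height
        child_a.length = _clamp(h - ha, "upgma")
        child_b.length = _clamp(h - hb, "upgma")
        parent = TreeNode()
        parent.extend([child_a, child_b])
        nodes[n + k] = (parent, h)
    return nodes.popitem()[1][0]


def root_on_outgroup(tree: TreeNode, outgroup_label: str) -> TreeNode:
    """Root the tree at the midpoint of the outgroup's pendant edge."""
    try:
        leaf = tree.find(outgroup_label)
    except Exception as exc:
        raise ValueError(
            f"outgroup {outgroup_label!r} is not a leaf of the tree"
        ) from exc
    if not leaf.is_tip():
        raise ValueError(f"outgroup {outgroup_label!r} is not a leaf")
    return tree.root_at(leaf, above=True)
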