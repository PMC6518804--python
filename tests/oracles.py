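"""Independent reference implementations used only to check the package.

Each oracle is deliberately naive -- exhaustive enumeration, brute-force
scanning, or closed forms -- and shares no code with the implementation
paths it validates.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np


def brute_force_global_score(a: str, b: str, score_fn, gap_open: float,
                             gap_extend: float) -> float:
    """Optimal global affine-gap score by exhaustive alignment enumeration.

    An alignment is a sequence of columns (match, delete, insert); a
    maximal run of k equal gap columns costs gap_open + (k-1)*gap_extend.
    Only feasible for short sequences.
    """

    best = [-np.inf]

    def recurse(i: int, j: int, prev: str, score: float) -> None:
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            recurse(i + 1, j + 1, "M", score + score_fn(a[i], b[j]))
        if i < len(a):
            cost = gap_extend if prev == "D" else gap_open
            recurse(i + 1, j, "D", score - cost)
        if j < len(b):
            cost = gap_extend if prev == "I" else gap_open
            recurse(i, j + 1, "I", score - cost)

    recurse(0, 0, "", 0.0)
    return best[0]


def naive_motif_count(seq: str, pattern: str, expansion: dict) -> int:
    """O(n*m) scan for degenerate motif matches on the forward strand."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    m = len(pattern)
    count = 0
    rc = "".join(comp[c] for c in reversed(seq))
    for s in (seq, rc):
        for i in range(len(s) - m + 1):
            if all(s[i + k] in expansion[pattern[k]] for k in range(m)):
                count += 1
    return count


# ---------------------------------------------------------------------------
# Random additive trees and exhaustive topology search

def random_additive_tree(rng: np.random.Generator, labels: list[str]):
    """A random binary unrooted tree as an edge list with positive lengths.

    Built by sequential taxon addition: each new leaf is attached to a
    uniformly chosen existing edge.  Returns (edges, n_nodes) where edges
    are (u, v, length) and leaves 0..len(labels)-1 map to labels.
    """
    n = len(labels)
    edges = [(0, n, rng.uniform(0.1, 1.0)), (1, n, rng.uniform(0.1, 1.0)),
             (2, n, rng.uniform(0.1, 1.0))]
    next_node = n + 1
    for leaf in range(3, n):
        k = rng.integers(0, len(edges))
        u, v, length = edges.pop(int(k))
        split = rng.uniform(0.2, 0.8) * length
        edges.append((u, next_node, split))
        edges.append((v, next_node, length - split))
        edges.append((leaf, next_node, rng.uniform(0.1, 1.0)))
        next_node += 1
    return edges, next_node


def path_distance_matrix(edges, n_leaves: int, n_nodes: int) -> np.ndarray:
    """All-pairs leaf distances of an edge-list tree (additive matrix)."""
    adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(n_nodes)}
    for u, v, w in edges:
        adj[u].append((v, w))
        adj[v].append((u, w))
    d = np.zeros((n_leaves, n_leaves))
    for src in range(n_leaves):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            x = stack.pop()
            for y, w in adj[x]:
                if y not in dist:
                    dist[y] = dist[x] + w
                    stack.append(y)
        for dst in range(n_leaves):
            d[src, dst] = dist[dst]
    return d


def tree_splits(edges, n_leaves: int, n_nodes: int) -> set[frozenset]:
    """Non-trivial bipartitions (as smaller-side frozensets) of a tree."""
    adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(n_nodes)}
    for u, v, w in edges:
        adj[u].append((v, w))
        adj[v].append((u, w))
    splits = set()
    for u, v, _ in edges:
        # leaves on u's side when edge (u,v) is removed
        side = set()
        stack = [u]
        seen = {u, v}
        while stack:
            x = stack.pop()
            if x < n_leaves:
                side.add(x)
            for y, _w in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        if 1 < len(side) < n_leaves - 1:
            full = frozenset(range(n_leaves))
            other = frozenset(full - side)
            splits.add(min(frozenset(side), other, key=sorted))
    return splits


def newick_splits(tree, labels: list[str]) -> set[frozenset]:
    """Non-trivial bipartitions of a scikit-bio tree, by label index."""
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(index[t.name] for t in node.tips())
        if 1 < len(side) < n - 1:
            other = frozenset(set(range(n)) - side)
            splits.add(min(side, other, key=sorted))
    return splits


def _all_topologies(n: int):
    """All unrooted binary topologies on n leaves, as split sets + edges."""
    base_edges = [frozenset([(0, n), (1, n), (2, n)])]
    trees = [[(0, n), (1, n), (2, n)]]
    next_node = n + 1
    for leaf in range(3, n):
        new_trees = []
        for t in trees:
            for k in range(len(t)):
                u, v = t[k]
                nt = t[:k] + t[k + 1:]
                nt = nt + [(u, next_node), (v, next_node),
                           (leaf, next_node)]
                new_trees.append(nt)
        trees = new_trees
        next_node += 1
    return trees, next_node


def least_squares_topology(d: np.ndarray, n: int) -> set[frozenset]:
    """Best-fitting topology by OLS branch lengths over all topologies.

    Returns the split set of the topology minimizing the sum of squared
    differences between tree path lengths and the input distances, with
    branch lengths fitted by (unconstrained) least squares.
    """
    pairs = list(itertools.combinations(range(n), 2))
    best_err, best_splits = np.inf, None
    trees, n_nodes = _all_topologies(n)
    for t in trees:
        edges = [(u, v, 1.0) for u, v in t]
        # design matrix: row per leaf pair, column per edge on the path
        adj: dict[int, list[tuple[int, int]]] = {i: []
                                                 for i in range(n_nodes)}
        for e_idx, (u, v, _) in enumerate(edges):
            adj[u].append((v, e_idx))
            adj[v].append((u, e_idx))
        rows = []
        for (a, b) in pairs:
            # path edges from a to b
            parent = {a: (None, None)}
            stack = [a]
            while stack:
                x = stack.pop()
                if x == b:
                    break
                for y, e_idx in adj[x]:
                    if y not in parent:
                        parent[y] = (x, e_idx)
                        stack.append(y)
            row = np.zeros(len(edges))
            x = b
            while parent[x][0] is not None:
                row[parent[x][1]] = 1.0
                x = parent[x][0]
            rows.append(row)
        A = np.array(rows)
        y = np.array([d[a, b] for a, b in pairs])
        coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
        err = float(((A @ coef - y) ** 2).sum())
        if err < best_err - 1e-12:
            best_err = err
            best_splits = tree_splits(
                [(u, v, 1.0) for u, v in t], n, n_nodes)
    return best_splits


def manual_average_linkage(d: np.ndarray, labels: list[str]):
    """Step-by-step average-linkage agglomeration; merge list with heights.

    Returns [(set_a, set_b, height), ...] in merge order.
    """
    clusters = {i: frozenset([labels[i]]) for i in range(len(labels))}
    dist = {}
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = d[i, j]
    merges = []
    next_id = n
    while len(clusters) > 1:
        (i, j), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        a, b = clusters.pop(i), clusters.pop(j)
        merges.append((a, b, h))
        new = a | b
        new_dist = {}
        for k, c in clusters.items():
            pairs_ij = [dist.get((min(k, x), max(k, x)))
                        for x in (i, j)]
            w = (len(a) * pairs_ij[0] + len(b) * pairs_ij[1]) / len(new)
            new_dist[(k, next_id)] = w
        dist = {key: v for key, v in dist.items()
                if i not in key and j not in key}
        dist.update(new_dist)
        clusters[next_id] = new
        next_id += 1
    return merges
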