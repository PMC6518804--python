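"""Global pairwise and progressive multiple alignment with affine gaps.

This is the computational substrate for phosphoacceptor-residue mapping:
every residue call in the pipeline is obtained by globally aligning a
candidate protein to a family reference and projecting the reference
coordinate through the alignment.

The pairwise aligner is a three-state Gotoh dynamic program.  A gap of
length k costs ``gap_open + (k - 1) * gap_extend``; terminal gaps are
penalized (true global alignment).  Ties are broken deterministically,
preferring match over a gap in the second sequence over a gap in the first,
so identical inputs give identical alignments on every platform.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .seqio import ProteinRecord

__all__ = [
    "PairwiseAlignment",
    "MultipleAlignment",
    "GAP",
    "default_matrix",
    "align_global",
    "project_position",
    "progressive_msa",
    "filter_columns",
]

GAP = None  # sentinel for "projects into a gap"

_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
_INDEX = {aa: i for i, aa in enumerate(_ALPHABET)}
_NEG = -1e30


def default_matrix() -> np.ndarray:
    """BLOSUM62 over the 21-letter alphabet; 'X' scores 0 against everything."""
    blosum = substitution_matrices.load("BLOSUM62")
    m = np.zeros((21, 21))
    for i, a in enumerate(_ALPHABET[:-1]):
        for j, b in enumerate(_ALPHABET[:-1]):
            m[i, j] = blosum[a][b]
    return m


_DEFAULT_MATRIX = default_matrix()


@dataclass
class PairwiseAlignment:
    """A global alignment of two sequences with a reference-column map.

    ``column_map[i]`` (0-based over reference residues) holds the 1-based
    position of the partner residue aligned to reference residue ``i + 1``,
    or ``None`` if that reference residue sits opposite a gap.
    """

    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    score: float
    column_map: tuple

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")


@dataclass
class MultipleAlignment:
    """Equal-length aligned rows; ``column_index[j]`` is the 1-based index of
    output column j in the original alignment (identity unless filtered)."""

    ids: list[str]
    rows: list[str]
    column_index: list[int]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("MSA rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def gap_fraction(self, j: int) -> float:
        col = [r[j] for r in self.rows]
        return col.count("-") / len(col)

    def gap_fractions(self) -> list[float]:
        return [self.gap_fraction(j) for j in range(self.n_columns)]


# ---------------------------------------------------------------------------
# Core Gotoh DP over a precomputed column-score matrix

def _gotoh(scores: np.ndarray, gap_open: float, gap_extend: float):
    """Three-state affine DP over an (n x m) column-score matrix.

    Returns (score, path) where path is a string over {'M','X','Y'}:
    'M' consumes one row and one column, 'X' a row against a gap,
    'Y' a column against a gap.
    """
    n, m = scores.shape
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)  # gap in second sequence (consumes row)
    Y = np.full((n + 1, m + 1), _NEG)  # gap in first sequence (consumes col)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(gap_open + (i - 1) * gap_extend)
    for j in range(1, m + 1):
        Y[0, j] = -(gap_open + (j - 1) * gap_extend)

    js = np.arange(m + 1)
    for i in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = prev_best[:-1] + scores[i - 1]
        X[i] = np.maximum(M[i - 1] - gap_open, X[i - 1] - gap_extend)
        if i == 1:
            X[1, 0] = -gap_open  # restore edge initialization
        else:
            X[i, 0] = -(gap_open + (i - 1) * gap_extend)
        M[i, 0] = _NEG
        # Y[i, j] = max_{k<j} max(M,X)[i,k] - gap_open - (j-k-1)*gap_extend
        z = np.maximum(M[i], X[i]) + js * gap_extend
        running = np.maximum.accumulate(z[:-1])
        Y[i, 1:] = running - gap_open - (js[1:] - 1) * gap_extend
        Y[i, 0] = _NEG

    # Traceback with deterministic tie-breaking: M > X > Y.
    i, j = n, m
    finals = [("M", M[n, m]), ("X", X[n, m]), ("Y", Y[n, m])]
    best = max(v for _, v in finals)
    state = next(s for s, v in finals if v >= best - 1e-9)
    score = best
    path = []
    eps = 1e-9
    while i > 0 or j > 0:
        path.append(state)
        if state == "M":
            target = M[i, j] - scores[i - 1, j - 1]
            cand = [("M", M[i - 1, j - 1]), ("X", X[i - 1, j - 1]),
                    ("Y", Y[i - 1, j - 1])]
            state = next(s for s, v in cand if abs(v - target) <= eps)
            i, j = i - 1, j - 1
        elif state == "X":
            if i == 1 and j == 0:
                i = 0
                state = "M"
                continue
            if abs(M[i - 1, j] - gap_open - X[i, j]) <= eps:
                state = "M"
            else:
                state = "X"
            i -= 1
        else:  # Y
            # gap may have opened at any k < j; walk back one extend at a
            # time, switching out of the gap as soon as scores allow (M
            # preferred over X).
            if abs(M[i, j - 1] - gap_open - Y[i, j]) <= eps:
                state = "M"
            elif abs(X[i, j - 1] - gap_open - Y[i, j]) <= eps:
                state = "X"
            else:
                state = "Y"
            j -= 1
    path.reverse()
    return score, "".join(path)


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_INDEX[c] for c in seq], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc} in sequence") from exc


def align_global(
    a: ProteinRecord,
    b: ProteinRecord,
    matrix: np.ndarray | None = None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> PairwiseAlignment:
    """Optimal global affine-gap alignment of two proteins.

    Defaults (BLOSUM62, gap open 11, extend 1) are the community standard
    for protein global alignment; the first argument is treated as the
    reference for column projection.
    """
    if not a.sequence or not b.sequence:
        raise ValueError("cannot align an empty sequence")
    if matrix is None:
        matrix = _DEFAULT_MATRIX
    ea, eb = _encode(a.sequence), _encode(b.sequence)
    scores = matrix[np.ix_(ea, eb)]
    score, path = _gotoh(scores, gap_open, gap_extend)

    out_a, out_b = [], []
    column_map: list[int | None] = []
    i = j = 0
    for op in path:
        if op == "M":
            out_a.append(a.sequence[i])
            out_b.append(b.sequence[j])
            i += 1
            j += 1
            column_map.append(j)
        elif op == "X":
            out_a.append(a.sequence[i])
            out_b.append("-")
            i += 1
            column_map.append(GAP)
        else:
            out_a.append("-")
            out_b.append(b.sequence[j])
            j += 1
    return PairwiseAlignment(
        id_a=a.id, id_b=b.id,
        aligned_a="".join(out_a), aligned_b="".join(out_b),
        score=score, column_map=tuple(column_map),
    )


def project_position(aln: PairwiseAlignment, ref_pos: int):
    """Map a 1-based reference position to the aligned partner position.

    Returns the 1-based partner position, or ``GAP`` (None) when the
    reference residue is aligned to a gap.
    """
    if not (1 <= ref_pos <= len(aln.column_map)):
        raise ValueError(
            f"reference position {ref_pos} out of range "
            f"1..{len(aln.column_map)}"
        )
    return aln.column_map[ref_pos - 1]


# ---------------------------------------------------------------------------
# Progressive MSA (simplified consistency-free progressive aligner)

def _profile_counts(rows: list[str]) -> np.ndarray:
    ncol = len(rows[0])
    counts = np.zeros((ncol, 21))
    for row in rows:
        for j, c in enumerate(row):
            if c != "-":
                counts[j, _INDEX[c]] += 1
    return counts / len(rows)


def _align_profiles(rows_a, rows_b, matrix, gap_open, gap_extend):
    fa = _profile_counts(rows_a)
    fb = _profile_counts(rows_b)
    scores = fa @ matrix @ fb.T
    _, path = _gotoh(scores, gap_open, gap_extend)
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    i = j = 0
    for op in path:
        if op == "M":
            for k, r in enumerate(rows_a):
                out_a[k] += r[i]
            for k, r in enumerate(rows_b):
                out_b[k] += r[j]
            i += 1
            j += 1
        elif op == "X":
            for k, r in enumerate(rows_a):
                out_a[k] += r[i]
            for k in range(len(rows_b)):
                out_b[k] += "-"
            i += 1
        else:
            for k in range(len(rows_a)):
                out_a[k] += "-"
            for k, r in enumerate(rows_b):
                out_b[k] += r[j]
            j += 1
    return out_a, out_b


def _strip_all_gap_columns(rows: list[str]) -> list[str]:
    keep = [j for j in range(len(rows[0]))
            if any(r[j] != "-" for r in rows)]
    return ["".join(r[j] for j in keep) for r in rows]


def _refine(rows, matrix, gap_open, gap_extend, rounds: int = 2):
    """Leave-one-out refinement: realign each row to the others' profile."""
    n = len(rows)
    for _ in range(rounds):
        for k in range(n):
            others = _strip_all_gap_columns(rows[:k] + rows[k + 1:])
            solo = [rows[k].replace("-", "")]
            new_others, new_solo = _align_profiles(
                others, solo, matrix, gap_open, gap_extend)
            rows = new_others[:k] + new_solo + new_others[k:]
    return rows


def progressive_msa(
    records: Sequence[ProteinRecord],
    matrix: np.ndarray | None = None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    refine_rounds: int = 2,
) -> MultipleAlignment:
    """Progressive multiple alignment along a UPGMA guide tree.

    The guide tree is average-linkage agglomeration on pairwise
    alignment-score distances d(a,b) = 1 - score(a,b) / min(self-score);
    profiles are merged by profile-profile global alignment with the same
    affine gap model, followed by leave-one-out refinement rounds that
    realign each sequence against the profile of the rest.  Deterministic
    given the input order.
    """
    if len(records) < 2:
        raise ValueError("progressive MSA requires at least 2 sequences")
    if matrix is None:
        matrix = _DEFAULT_MATRIX
    n = len(records)
    self_scores = [
        float(matrix[np.ix_(_encode(r.sequence), _encode(r.sequence))]
              .diagonal().sum())
        for r in records
    ]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = align_global(records[i], records[j], matrix,
                             gap_open, gap_extend).score
            denom = min(self_scores[i], self_scores[j])
            d = 1.0 - s / denom if denom > 0 else 1.0
            dist[i, j] = dist[j, i] = max(d, 0.0)

    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    link = linkage(squareform(dist, checks=False), method="average")
    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([records[i].id], [records[i].sequence]) for i in range(n)
    }
    for k, (ia, ib, _, _) in enumerate(link):
        ids_a, rows_a = clusters.pop(int(ia))
        ids_b, rows_b = clusters.pop(int(ib))
        new_a, new_b = _align_profiles(rows_a, rows_b, matrix,
                                       gap_open, gap_extend)
        clusters[n + k] = (ids_a + ids_b, new_a + new_b)
    ids, rows = clusters.popitem()[1]
    if refine_rounds > 0:
        rows = _refine(rows, matrix, gap_open, gap_extend, refine_rounds)
    # restore input order
    order = {pid: i for i, pid in enumerate(ids)}
    sorted_pairs = sorted(
        zip(ids, rows), key=lambda p: [r.id for r in records].index(p[0])
    )
    ids = [p[0] for p in sorted_pairs]
    rows = [p[1] for p in sorted_pairs]
    return MultipleAlignment(ids=ids, rows=rows,
                             column_index=list(range(1, len(rows[0]) + 1)))


def filter_columns(
    msa: MultipleAlignment, max_gap_fraction: float = 0.5
) -> MultipleAlignment:
    """Drop MSA columns whose gap fraction exceeds ``max_gap_fraction``.

    The surviving columns keep a map back to their original indices.
    Raises if every column would be removed.
    """
    if not (0.0 <= max_gap_fraction <= 1.0):
        raise ValueError("max_gap_fraction must be in [0, 1]")
    keep = [j for j in range(msa.n_columns)
            if msa.gap_fraction(j) <= max_gap_fraction]
    if not keep:
        raise ValueError(
            "all columns exceed the gap-fraction threshold; raise "
            "max_gap_fraction"
        )
    rows = ["".join(r[j] for j in keep) for r in msa.rows]
    return MultipleAlignment(
        ids=list(msa.ids), rows=rows,
        column_index=[msa.column_index[j] for j in keep],
    )
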