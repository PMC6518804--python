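"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the statistical structure the analysis assumes:
protein families as point-mutated descendants of a domain-block consensus
with rare substitutions planted at the phosphoacceptor column; chromosomes
with tandem paralog arrays; promoters with exact planted cis-element
counts on a screened background; and block-structured expression matrices
with one dominant gene per family.  Identical seeds give byte-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import AGATHY, DegenerateMotif, count_motif
from .references import ReferenceSet, default_references
from .seqio import DomainHit, ExpressionMatrix, GeneLocus, ProteinRecord, \
    assign_ranks

__all__ = [
    "FamilyTruth",
    "GenomeTruth",
    "ExpressionTruth",
    "generate_family",
    "generate_genome",
    "generate_expression",
]

_AA20 = "ACDEFGHIKLMNPQRSTVWY"

# Residues drawn when the phosphoacceptor is substituted.  Weights follow
# the variant spectra seen in phosphorelay families: the H of a
# phosphotransfer protein most often becomes N (the known inhibitory
# variant) or R; the receiver D becomes the phosphomimic E or N.
_SITE_SUBSTITUTIONS = {
    "HPT": (("N", 0.55), ("R", 0.25), ("L", 0.10), ("Q", 0.10)),
    "receiver": (("E", 0.70), ("N", 0.17), ("Q", 0.07), ("G", 0.06)),
}

# Family templates: reference consensus, phosphoacceptor coordinate, and
# the domain spans emitted as HMMER-style hits.
_TEMPLATES = {
    "HPT": ("MtHPT3_SYN", 77, "H", (("Hpt", 5, 140),)),
    "RRB": ("MtRRB3_SYN", 64, "D",
            (("Response_reg", 1, 120), ("Myb_DNA-binding", 121, 180))),
    "RRA": ("ARR6_SYN", 64, "D", (("Response_reg", 1, 120),)),
    "CHK": ("AHK4_SYN", 384, "D",
            (("CHASE", 1, 100), ("HisKA", 121, 185),
             ("HATPase_c", 191, 300), ("Response_reg", 321, 410))),
    "HK": ("AHK4_SYN", 384, "D",
           (("HisKA", 121, 185), ("HATPase_c", 191, 300),
            ("Response_reg", 321, 410))),
}


@dataclass
class FamilyTruth:
    """Ground truth for one generated protein family."""

    family: str
    q_substitution: float
    divergence: float
    seed: int
    site_position: int
    expected_residue: str
    site_residues: dict[str, str] = field(default_factory=dict)
    substituted: dict[str, bool] = field(default_factory=dict)
    # per protein: source consensus column (1-based) of each residue,
    # None for inserted residues
    source_columns: dict[str, list[int | None]] = field(default_factory=dict)

    @property
    def substituted_fraction(self) -> float:
        vals = list(self.substituted.values())
        return sum(vals) / len(vals) if vals else 0.0


def _frozen_positions(family: str, refs: ReferenceSet) -> set[int]:
    """Positions never mutated: motif windows that define canonicity."""
    if family in ("CHK", "HK"):
        frozen: set[int] = set()
        for w in refs.hk_motifs:
            frozen.update(range(w.start, w.end + 1))
        return frozen
    return set()


def generate_family(
    n: int,
    family: str = "HPT",
    q_substitution: float = 0.0,
    divergence: float = 0.05,
    seed: int = 0,
    indel_prob: float = 0.0,
    refs: ReferenceSet | None = None,
) -> tuple[list[ProteinRecord], dict[str, list[DomainHit]], FamilyTruth]:
    """Generate a protein family descended from a reference consensus.

    Each member is the consensus point-mutated at per-site rate
    ``divergence`` (motif windows frozen); the phosphoacceptor column is
    substituted with probability ``q_substitution`` by a draw from the
    family's variant spectrum.  With ``indel_prob`` > 0 each member also
    receives short (1-3 aa) insertions/deletions at that per-site rate,
    outside frozen positions.  Matching HMMER-style domain hits and full
    per-residue provenance are returned alongside.
    """
    if not (0.0 <= q_substitution <= 1.0):
        raise ValueError("q_substitution must be in [0, 1]")
    if not (0.0 < divergence <= 0.5) and divergence != 0.0:
        raise ValueError("divergence must be in (0, 0.5] or exactly 0")
    if family not in _TEMPLATES:
        raise ValueError(f"unknown family {family!r}; "
                         f"one of {sorted(_TEMPLATES)}")
    if refs is None:
        refs = default_references()
    ref_name, site, expected, spans = _TEMPLATES[family]
    consensus = refs[ref_name].sequence
    rng = np.random.default_rng(seed)
    sub_kind = "HPT" if family == "HPT" else "receiver"
    sub_residues = [r for r, _ in _SITE_SUBSTITUTIONS[sub_kind]]
    sub_weights = np.array([w for _, w in _SITE_SUBSTITUTIONS[sub_kind]])
    frozen = _frozen_positions(family, refs) | {site}

    truth = FamilyTruth(family=family, q_substitution=q_substitution,
                        divergence=divergence, seed=seed,
                        site_position=site, expected_residue=expected)
    proteins: list[ProteinRecord] = []
    hits: dict[str, list[DomainHit]] = {}
    width = len(str(n))
    for k in range(n):
        pid = f"SYN{family}{k + 1:0{width}d}"
        seq = list(consensus)
        for i in range(len(seq)):
            if (i + 1) in frozen:
                continue
            if divergence > 0 and rng.random() < divergence:
                seq[i] = _AA20[rng.integers(0, 20)]
        substituted = bool(rng.random() < q_substitution)
        if substituted:
            choice = rng.choice(len(sub_residues), p=sub_weights)
            seq[site - 1] = sub_residues[int(choice)]
        cols: list[int | None] = list(range(1, len(seq) + 1))
        if indel_prob > 0:
            seq, cols = _apply_indels(rng, seq, cols, indel_prob, frozen)
        sequence = "".join(seq)
        proteins.append(ProteinRecord(pid, sequence, organism="SYN"))
        truth.site_residues[pid] = sequence[cols.index(site)] \
            if site in cols else "-"
        truth.substituted[pid] = substituted
        truth.source_columns[pid] = cols
        hits[pid] = [
            DomainHit(name, _map_pos(cols, lo), _map_pos(cols, hi),
                      evalue=1e-20)
            for name, lo, hi in spans
        ]
    return proteins, hits, truth


def _apply_indels(rng, seq, cols, indel_prob, frozen):
    out_seq: list[str] = []
    out_cols: list[int | None] = []
    i = 0
    while i < len(seq):
        col = cols[i]
        if col not in frozen and rng.random() < indel_prob:
            length = int(rng.integers(1, 4))
            if rng.random() < 0.5:  # deletion (never deletes frozen cols)
                j = i
                while j < len(seq) and j - i < length \
                        and cols[j] not in frozen:
                    j += 1
                i = j
                continue
            for _ in range(length):  # insertion
                out_seq.append(_AA20[rng.integers(0, 20)])
                out_cols.append(None)
        out_seq.append(seq[i])
        out_cols.append(col)
        i += 1
    return out_seq, out_cols


def _map_pos(cols: list[int | None], ref_pos: int) -> int:
    """Closest residue index (1-based) derived from consensus ``ref_pos``."""
    best, best_d = 1, 10 ** 9
    for idx, col in enumerate(cols):
        if col is None:
            continue
        d = abs(col - ref_pos)
        if d < best_d:
            best, best_d = idx + 1, d
    return best


# ---------------------------------------------------------------------------
# Genome with planted tandem arrays and promoter motifs

@dataclass
class GenomeTruth:
    families: dict[str, str]
    arrays: list[list[str]]
    motif_counts: dict[str, int]
    promoters: dict[str, str]
    seed: int


_GENE_LEN = 400
_SPACER = 200


def _screened_background(rng, n: int, motif: DegenerateMotif) -> str:
    """Random sequence guaranteed free of motif matches on both strands."""
    seq = list("ACGT"[i] for i in rng.integers(0, 4, size=n))
    for _ in range(200):
        count, hit_list = count_motif("".join(seq), motif)
        if count == 0:
            return "".join(seq)
        for h in hit_list:
            for j in range(h.start, h.end):
                seq[j] = "ACGT"[rng.integers(0, 4)]
    raise RuntimeError("could not screen background sequence")


def _promoter_with_motifs(rng, length: int, k: int,
                          motif: DegenerateMotif) -> str:
    """Screened background with exactly k planted non-overlapping motifs."""
    m = len(motif)
    if k * (m + 2) > length:
        raise ValueError("promoter too short for the requested motif count")
    while True:
        seq = list(_screened_background(rng, length, motif))
        slots = sorted(rng.choice((length - m) // m, size=k, replace=False)
                       ) if k else []
        for s in slots:
            start = int(s) * m
            instance = "AGAT" + "ACT"[rng.integers(0, 3)] \
                + "CT"[rng.integers(0, 2)]
            seq[start:start + m] = instance
        out = "".join(seq)
        if count_motif(out, motif)[0] == k:
            return out


def generate_genome(
    n_genes: int = 20,
    arrays: Sequence[tuple[str, int]] = (("RRB", 4),),
    motif_counts: Mapping[str, int] | None = None,
    seed: int = 0,
    n_chromosomes: int = 2,
    promoter_length: int = 2500,
    motif: DegenerateMotif = AGATHY,
) -> tuple[dict[str, str], list[GeneLocus], GenomeTruth]:
    """A toy genome with planted tandem arrays and promoter motif counts.

    Returns (chromosome sequences, ranked loci, truth).  Array members are
    placed as consecutive genes of one family on one chromosome; all other
    genes receive unique background families.  ``motif_counts`` maps gene
    id (``G1``..``Gn``) to the exact number of cis-element instances
    planted in its promoter; unlisted genes get screened (zero-match)
    promoters.
    """
    rng = np.random.default_rng(seed)
    motif_counts = dict(motif_counts or {})
    array_sizes = [size for _, size in arrays]
    if sum(array_sizes) > n_genes:
        raise ValueError("planted arrays do not fit in n_genes")

    families: dict[str, str] = {}
    truth_arrays: list[list[str]] = []
    gene_ids = [f"G{i + 1}" for i in range(n_genes)]
    # assign array members to consecutive genes at the start of chromosome 1
    idx = 0
    for fam, size in arrays:
        members = gene_ids[idx:idx + size]
        for g in members:
            families[g] = fam
        truth_arrays.append(members)
        idx += size
    for i, g in enumerate(gene_ids[idx:]):
        families[g] = f"BG{i + 1}"

    per_chrom = -(-n_genes // n_chromosomes)  # arrays stay on chromosome 1
    chrom_of = {g: f"chr{i // per_chrom + 1}"
                for i, g in enumerate(gene_ids)}

    sequences: dict[str, list[str]] = {}
    loci: list[GeneLocus] = []
    promoters: dict[str, str] = {}
    actual_counts: dict[str, int] = {}
    for g in gene_ids:
        chrom = chrom_of[g]
        parts = sequences.setdefault(chrom, [])
        pos = sum(len(p) for p in parts)
        k = motif_counts.get(g, 0)
        promoter = _promoter_with_motifs(rng, promoter_length, k, motif)
        gene_body = _screened_background(rng, _GENE_LEN, motif)
        strand = "+" if rng.random() < 0.7 else "-"
        if strand == "+":
            parts.append(promoter)
            start = pos + promoter_length + 1
            parts.append(gene_body)
            end = start + _GENE_LEN - 1
        else:
            from Bio.Seq import Seq

            start = pos + 1
            parts.append(gene_body)
            end = start + _GENE_LEN - 1
            parts.append(str(Seq(promoter).reverse_complement()))
        parts.append(_screened_background(rng, _SPACER, motif))
        loci.append(GeneLocus(g, chrom, start, end, strand))
        promoters[g] = promoter
        actual_counts[g] = k

    chromosomes = {c: "".join(parts) for c, parts in sequences.items()}
    truth = GenomeTruth(families=families, arrays=truth_arrays,
                        motif_counts=actual_counts, promoters=promoters,
                        seed=seed)
    return chromosomes, assign_ranks(loci), truth


# ---------------------------------------------------------------------------
# Expression matrices with planted clusters and dominant genes

@dataclass
class ExpressionTruth:
    clusters: dict[str, int]
    dominant: dict[str, str]
    families: dict[str, str]
    noise_sd: float
    seed: int


def generate_expression(
    cluster_sizes: Sequence[int] = (8, 8, 8),
    families: tuple[str, ...] = ("CHK", "HPT", "RRB"),
    noise_sd: float = 0.5,
    dominant_margin: float = 3.0,
    n_samples: int = 12,
    between_cluster_gap: float = 8.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, ExpressionTruth]:
    """Block-structured log2 expression with one dominant gene per family.

    Cluster k's genes share a sample profile offset by
    ``between_cluster_gap`` from other clusters; Gaussian noise with
    ``noise_sd`` is added.  Within each family the designated dominant
    gene is raised by ``dominant_margin`` log2 units across all samples.
    Two dataset blocks split the samples to exercise block-wise
    normalization.
    """
    rng = np.random.default_rng(seed)
    genes, cluster_of, family_of = [], {}, {}
    g = 0
    for c, size in enumerate(cluster_sizes):
        for _ in range(size):
            gid = f"EXP{g + 1:03d}"
            genes.append(gid)
            cluster_of[gid] = c
            family_of[gid] = families[g % len(families)]
            g += 1

    # each cluster is "on" in its own block of samples (organ-specific
    # expression), so cluster profiles are separated by the full gap
    profiles = []
    k = len(cluster_sizes)
    block = max(1, n_samples // k)
    for c in range(k):
        base = rng.uniform(4.0, 6.0)
        profile = np.full(n_samples, base)
        lo = (c * block) % n_samples
        profile[lo:lo + block] += between_cluster_gap
        profiles.append(profile)

    # one dominant gene per family, spread across clusters so the uniform
    # expression boost does not create a spurious co-expression cluster
    dominant: dict[str, str] = {}
    for i, fam in enumerate(dict.fromkeys(families)):
        members = [gid for gid in genes if family_of[gid] == fam]
        target_cluster = i % len(cluster_sizes)
        in_target = [gid for gid in members
                     if cluster_of[gid] == target_cluster]
        dominant[fam] = (in_target or members)[0]

    rows = []
    for gid in genes:
        values = profiles[cluster_of[gid]] + rng.normal(0, noise_sd,
                                                        n_samples)
        if gid in dominant.values():
            values = values + dominant_margin
        rows.append(values)
    samples = [f"S{j + 1}" for j in range(n_samples)]
    dataset_ids = {s: ("atlas" if j < n_samples // 2 else "nodule")
                   for j, s in enumerate(samples)}
    matrix = ExpressionMatrix(
        values=pd.DataFrame(rows, index=genes, columns=samples),
        dataset_ids=dataset_ids,
    )
    truth = ExpressionTruth(clusters=dict(cluster_of), dominant=dominant,
                            families=dict(family_of), noise_sd=noise_sd,
                            seed=seed)
    return matrix, truth
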