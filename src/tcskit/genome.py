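"""Promoter extraction, degenerate motif counting, tandem-duplicate calls.

The cytokinin-response cis-element scanned here, AGATHY (H = A/C/T,
Y = C/T), is the binding motif of Type-B response-regulator transcription
factors; its count in a 2.5-kb promoter is a crude proxy for cytokinin
responsiveness of the downstream gene.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

from .seqio import GeneLocus

__all__ = [
    "DegenerateMotif",
    "AGATHY",
    "MotifHit",
    "PromoterSequence",
    "TandemPair",
    "extract_promoter",
    "count_motif",
    "find_tandem_duplicates",
    "tandem_arrays",
]

PROMOTER_LENGTH = 2500  # bp upstream of the start codon


@dataclass(frozen=True)
class DegenerateMotif:
    """A nucleotide motif over IUPAC ambiguity codes (e.g. ``AGATHY``)."""

    pattern: str
    expansion: Mapping[str, str] = field(
        default_factory=lambda: dict(ambiguous_dna_values))

    def __post_init__(self) -> None:
        for sym in self.pattern:
            if not self.expansion.get(sym):
                raise ValueError(f"IUPAC symbol {sym!r} has no expansion")

    def __len__(self) -> int:
        return len(self.pattern)

    def regex(self) -> re.Pattern:
        # N in the *sequence* never matches, so character classes list the
        # concrete bases only.
        body = "".join(
            f"[{self.expansion[s]}]" if len(self.expansion[s]) > 1
            else self.expansion[s]
            for s in self.pattern
        )
        return re.compile(f"(?=({body}))")  # overlapping matches


AGATHY = DegenerateMotif("AGATHY")


@dataclass(frozen=True)
class MotifHit:
    """A motif occurrence: 0-based half-open interval on the + strand."""

    seq_id: str
    start: int
    end: int
    strand: str


@dataclass(frozen=True)
class PromoterSequence:
    gene_id: str
    sequence: str
    truncated: bool  # promoter ran off the contig edge


def extract_promoter(
    genome_seq: str, locus: GeneLocus, length: int = PROMOTER_LENGTH
) -> PromoterSequence:
    """The ``length`` bases immediately 5' of the start codon, strand-aware.

    For a minus-strand gene the promoter lies 3' of ``locus.end`` in genome
    coordinates and is returned reverse-complemented.  Promoters truncated
    at a contig edge are flagged.
    """
    n = len(genome_seq)
    if not (1 <= locus.start <= locus.end <= n):
        raise ValueError(
            f"locus {locus.gene_id} ({locus.start}..{locus.end}) is not on "
            f"the given sequence (length {n})"
        )
    if locus.strand == "+":
        lo = max(0, locus.start - 1 - length)
        seq = genome_seq[lo:locus.start - 1]
        truncated = locus.start - 1 < length
    else:
        hi = min(n, locus.end + length)
        seq = str(Seq(genome_seq[locus.end:hi]).reverse_complement())
        truncated = n - locus.end < length
    return PromoterSequence(locus.gene_id, seq, truncated)


def count_motif(
    seq: str,
    motif: DegenerateMotif = AGATHY,
    strands: str = "+-",
    seq_id: str = "",
) -> tuple[int, list[MotifHit]]:
    """Count all (possibly overlapping) motif occurrences.

    Both strands are scanned by default; minus-strand hits are reported on
    plus-strand coordinates.  ``N`` in the sequence never matches.
    """
    seq = seq.upper()
    rx = motif.regex()
    hits: list[MotifHit] = []
    m = len(motif)
    if "+" in strands:
        for match in rx.finditer(seq):
            hits.append(MotifHit(seq_id, match.start(), match.start() + m, "+"))
    if "-" in strands:
        rc = str(Seq(seq).reverse_complement())
        n = len(seq)
        for match in rx.finditer(rc):
            start = n - (match.start() + m)
            hits.append(MotifHit(seq_id, start, start + m, "-"))
    hits.sort(key=lambda h: (h.start, h.strand))
    return len(hits), hits


@dataclass(frozen=True)
class TandemPair:
    """Two same-family paralogs separated by few genes on one chromosome."""

    gene_a: str
    gene_b: str
    chromosome: str
    intervening: int
    family: str


def find_tandem_duplicates(
    loci: Sequence[GeneLocus],
    families: Mapping[str, str],
    max_intervening: int = 10,
) -> list[TandemPair]:
    """Pairs of same-family genes within ``max_intervening`` genes.

    ``families`` maps gene id -> family label; genes present in
    ``families`` but absent from ``loci`` are skipped with a warning.
    The intervening count uses the chromosome-wide gene ranks carried by
    the loci, so unrelated genes between two paralogs count against the
    threshold.
    """
    import warnings

    by_id = {loc.gene_id: loc for loc in loci}
    missing = sorted(set(families) - set(by_id))
    if missing:
        warnings.warn(f"genes without locus, skipped: {missing}",
                      stacklevel=2)
    groups: dict[tuple[str, str], list[GeneLocus]] = {}
    for gid, fam in families.items():
        loc = by_id.get(gid)
        if loc is None:
            continue
        groups.setdefault((loc.chromosome, fam), []).append(loc)

    pairs: list[TandemPair] = []
    for (chrom, fam), members in sorted(groups.items()):
        members.sort(key=lambda loc: loc.rank)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                gap = members[j].rank - members[i].rank - 1
                if gap <= max_intervening:
                    pairs.append(TandemPair(
                        members[i].gene_id, members[j].gene_id,
                        chrom, gap, fam))
    return pairs


def tandem_arrays(pairs: Iterable[TandemPair]) -> list[list[str]]:
    """Chain tandem pairs into maximal arrays (connected components)."""
    adjacency: dict[str, set[str]] = {}
    for p in pairs:
        adjacency.setdefault(p.gene_a, set()).add(p.gene_b)
        adjacency.setdefault(p.gene_b, set()).add(p.gene_a)
    seen: set[str] = set()
    arrays: list[list[str]] = []
    for gene in sorted(adjacency):
        if gene in seen:
            continue
        stack, comp = [gene], []
        while stack:
            g = stack.pop()
            if g in seen:
                continue
            seen.add(g)
            comp.append(g)
            stack.extend(adjacency[g] - seen)
        arrays.append(sorted(comp))
    return arrays
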