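"""Phosphoacceptor-residue identification and substitution statistics.

The phosphorelay transfers phosphate along a conserved His -> Asp -> His ->
Asp chain.  For each family, the residue occupying the phosphoacceptor
position of a candidate protein is identified by globally aligning the
candidate to a family reference whose phosphoacceptor coordinate is known
(e.g. H77 of the HPT reference, D64 of the Type-B RR reference) and reading
the candidate residue in the aligned column.

Substitution-rate tables compare the phosphoacceptor column against every
other occurrence of the expected residue in the reference (the comparison
positions): conservation markedly higher at the phosphoacceptor column than
at comparison positions is the signature of purifying selection on the
relay function.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .align import GAP, align_global, project_position
from .seqio import ProteinRecord

__all__ = [
    "PhosphoSiteReference",
    "VariantClass",
    "SubstitutionTable",
    "map_phosphoacceptor",
    "classify_variant",
    "substitution_rate_table",
    "write_substitution_table_tsv",
]


@dataclass
class PhosphoSiteReference:
    """A family reference with a documented phosphoacceptor coordinate."""

    family: str
    protein: ProteinRecord
    position: int  # 1-based
    expected_residue: str
    comparison_positions: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        seq = self.protein.sequence
        if not (1 <= self.position <= len(seq)):
            raise ValueError("phosphoacceptor position out of range")
        if seq[self.position - 1] != self.expected_residue:
            raise ValueError(
                f"reference {self.protein.id} carries "
                f"{seq[self.position - 1]!r} at position {self.position}, "
                f"expected {self.expected_residue!r}"
            )
        if not self.comparison_positions:
            self.comparison_positions = [
                i + 1 for i, c in enumerate(seq)
                if c == self.expected_residue and i + 1 != self.position
            ]


@dataclass(frozen=True)
class VariantClass:
    """Canonicity verdict for one projected phosphoacceptor residue."""

    label: str
    residue: str  # single letter, or '-' for a gap projection
    canonical: bool


def map_phosphoacceptor(
    protein: ProteinRecord, ref: PhosphoSiteReference
) -> tuple[str, int | None]:
    """Residue of ``protein`` at the reference phosphoacceptor column.

    Returns ``(residue, position)`` with 1-based position in ``protein``,
    or ``('-', None)`` when the column projects into a gap (e.g. a
    truncated protein) -- a gap is a result, not an error.
    """
    aln = align_global(ref.protein, protein)
    pos = project_position(aln, ref.position)
    if pos is GAP:
        return "-", None
    return protein.sequence[pos - 1], pos


def classify_variant(residue: str, family: str) -> VariantClass:
    """Classify a projected phosphoacceptor residue.

    HPTs: H is canonical (HPT-H), N the known inhibitory variant (HPT-N),
    anything else HPT-X.  Receiver domains (RRs and the HK receiver): D is
    canonical; E (phosphomimic) and N are the named variants; other
    residues are grouped; a gap marks truncation.
    """
    if residue == "-":
        return VariantClass("truncated", "-", False)
    if family == "HPT":
        if residue == "H":
            return VariantClass("HPT-H", "H", True)
        if residue == "N":
            return VariantClass("HPT-N", "N", False)
        return VariantClass(f"HPT-X({residue})", residue, False)
    if residue == "D":
        return VariantClass("D", "D", True)
    if residue in "EN":
        return VariantClass(residue, residue, False)
    return VariantClass(f"other({residue})", residue, False)


@dataclass
class SubstitutionTable:
    """Residue-class tallies at the phosphoacceptor and comparison columns.

    ``per_position[p]`` maps residue class -> count at reference position
    ``p``; ``site_percent`` and ``pooled_percent`` give whole-percent rates
    (denominator excludes gap projections, which are reported separately).
    ``per_protein_any_percent`` is the share of proteins carrying a
    non-conserved residue (outside {expected, E, N} for receivers; outside
    {H, N} for HPTs) at one or more comparison positions.
    """

    family: str
    reference_id: str
    site_position: int
    classes: tuple[str, ...]
    per_position: dict[int, dict[str, int]]
    gap_counts: dict[int, int]
    site_percent: dict[str, float]
    pooled_percent: dict[str, float]
    per_protein_any_percent: float
    n_proteins: int


def _residue_class(residue: str, family: str) -> str:
    if family == "HPT":
        return residue if residue in "HN" else "other"
    return residue if residue in "DEN" else "other"


def substitution_rate_table(
    proteins: Sequence[ProteinRecord], ref: PhosphoSiteReference
) -> SubstitutionTable:
    """Tally residue classes at the phosphoacceptor and comparison columns.

    Every protein is aligned to the reference once; each reference column of
    interest is projected onto it and the projected residue is binned into
    the family's classes (H/N/other for HPTs, D/E/N/other for receivers).
    Percentages are rounded presentation values computed over non-gap
    projections; gap projections are counted separately.
    """
    if not proteins:
        raise ValueError("empty protein set")
    family = ref.family
    classes = ("H", "N", "other") if family == "HPT" else \
              ("D", "E", "N", "other")
    conserved = set("HN") if family == "HPT" else set("DEN")
    positions = [ref.position] + list(ref.comparison_positions)
    per_position = {p: {c: 0 for c in classes} for p in positions}
    gap_counts = {p: 0 for p in positions}
    any_nonconserved = 0

    for protein in proteins:
        aln = align_global(ref.protein, protein)
        protein_nonconserved = False
        for p in positions:
            t = project_position(aln, p)
            if t is GAP:
                gap_counts[p] += 1
                continue
            residue = protein.sequence[t - 1]
            per_position[p][_residue_class(residue, family)] += 1
            if p != ref.position and residue not in conserved:
                protein_nonconserved = True
        if protein_nonconserved:
            any_nonconserved += 1

    def percents(counts: dict[str, int]) -> dict[str, float]:
        total = sum(counts.values())
        if total == 0:
            return {c: 0.0 for c in classes}
        return {c: round(100.0 * counts[c] / total) for c in classes}

    pooled: dict[str, int] = {c: 0 for c in classes}
    for p in ref.comparison_positions:
        for c in classes:
            pooled[c] += per_position[p][c]

    return SubstitutionTable(
        family=family,
        reference_id=ref.protein.id,
        site_position=ref.position,
        classes=classes,
        per_position=per_position,
        gap_counts=gap_counts,
        site_percent=percents(per_position[ref.position]),
        pooled_percent=percents(pooled),
        per_protein_any_percent=round(
            100.0 * any_nonconserved / len(proteins)),
        n_proteins=len(proteins),
    )


def site_conservation(table: SubstitutionTable) -> tuple[float, float]:
    """(site, pooled non-site) retention rate of the expected residue class.

    For HPTs the retained class is H-or-N, for receivers D-or-E-or-N: the
    residues the relay literature treats as family-typical.  The relay
    hypothesis predicts site >= pooled.
    """
    classes = [c for c in table.classes if c != "other"]
    site = sum(table.site_percent[c] for c in classes)
    pooled = sum(table.pooled_percent[c] for c in classes)
    return site, pooled


def write_substitution_table_tsv(
    table: SubstitutionTable, path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write(f"# family={table.family} reference={table.reference_id} "
                 f"site={table.site_position} n={table.n_proteins}\n")
        cols = "\t".join(table.classes)
        fh.write(f"position\tkind\t{cols}\tgaps\n")
        for p in sorted(table.per_position):
            kind = "site" if p == table.site_position else "comparison"
            counts = "\t".join(str(table.per_position[p][c])
                               for c in table.classes)
            fh.write(f"{p}\t{kind}\t{counts}\t{table.gap_counts[p]}\n")
        site = "\t".join(f"{table.site_percent[c]:.0f}"
                         for c in table.classes)
        pooled = "\t".join(f"{table.pooled_percent[c]:.0f}"
                           for c in table.classes)
        fh.write(f"%site\tpercent\t{site}\t-\n")
        fh.write(f"%pooled\tpercent\t{pooled}\t-\n")
        fh.write(f"%proteins_any_nonconserved\tpercent\t"
                 f"{table.per_protein_any_percent:.0f}\n")
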