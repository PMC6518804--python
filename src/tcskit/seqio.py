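"""Readers and writers for the external formats the pipeline touches.

All coordinates are 1-based and inclusive, matching the residue numbering
used throughout the phosphorelay literature (H77, D64, ...); conversion to
other conventions happens only inside readers/writers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ProteinRecord",
    "DomainHit",
    "GeneLocus",
    "ExpressionMatrix",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_domtblout",
    "read_census_fixture",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_loci_tsv",
    "write_loci_tsv",
    "write_newick",
    "write_report_tsv",
    "parse_domain_string",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWYX"


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its locus tag and optional display name."""

    id: str
    sequence: str
    name: str = ""
    organism: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r} has an empty sequence")
        bad = set(self.sequence) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(
                f"protein {self.id!r} contains non-amino-acid symbols {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class DomainHit:
    """One domain hit on a protein, with per-motif residue states.

    ``motif_states`` maps a motif label (H-box ``H``, kinase boxes ``N``,
    ``G1``, ``F``, ``G2``, receiver/Hpt phosphoacceptor ``D``/``H``, ethylene
    binding residues, ...) to a one-letter state: the observed residue letter,
    ``-`` for absent, or ``?`` for not yet determined.
    """

    domain_name: str
    start: int = 1
    end: int = 1
    evalue: float = 0.0
    motif_states: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"domain {self.domain_name}: invalid span {self.start}..{self.end}"
            )
        if self.evalue < 0:
            raise ValueError(f"domain {self.domain_name}: negative e-value")


@dataclass(frozen=True)
class GeneLocus:
    """Position of a gene on a chromosome (1-based, inclusive)."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    rank: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"locus {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in "+-":
            raise ValueError(f"locus {self.gene_id}: strand must be + or -")


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of log2 expression values.

    ``values`` is a DataFrame (rows = genes, columns = samples) with NaN for
    missing values (no probe); ``dataset_ids`` tags each column with its
    dataset of origin so normalization can be applied per dataset block.
    """

    values: pd.DataFrame
    dataset_ids: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene labels: {dupes}")
        for col in self.values.columns:
            self.dataset_ids.setdefault(col, "default")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def blocks(self) -> dict[str, list[str]]:
        """Columns grouped by dataset id, preserving column order."""
        out: dict[str, list[str]] = {}
        for col in self.values.columns:
            out.setdefault(self.dataset_ids[col], []).append(col)
        return out


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein FASTA; the header's first token becomes the record id.

    Terminal ``*`` stop symbols are stripped and sequences uppercased.
    Duplicate ids or an empty file raise :class:`FormatError`.
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().rstrip("*")
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip()
        records.append(ProteinRecord(id=rec.id, sequence=seq, description=desc))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(seqrecords, str(path), "fasta")


# ---------------------------------------------------------------------------
# HMMER3 per-domain table

def read_domtblout(
    path: str | Path, evalue_max: float = 1e-10
) -> dict[str, list[DomainHit]]:
    """Parse an HMMER3 ``--domtblout`` table into per-protein domain hits.

    Hits with independent e-value above ``evalue_max`` (default 1e-10, the
    conventional cutoff for Pfam searches in this pipeline) are dropped; the
    surviving hits are sorted by alignment start.
    """
    hits: dict[str, list[DomainHit]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 23:
                raise FormatError(
                    f"{path}:{lineno}: expected >=23 whitespace-separated "
                    f"columns, got {len(parts)}"
                )
            target = parts[0]
            domain = parts[3]
            try:
                ievalue = float(parts[12])
                ali_from = int(parts[17])
                ali_to = int(parts[18])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            hits.setdefault(target, [])
            if ievalue > evalue_max:
                continue
            hits[target].append(
                DomainHit(domain_name=domain, start=ali_from, end=ali_to,
                          evalue=ievalue)
            )
    for lst in hits.values():
        lst.sort(key=lambda h: (h.start, h.end, h.domain_name))
    return hits


def write_domtblout(hits: Mapping[str, list[DomainHit]], path: str | Path) -> None:
    """Write domain hits in the HMMER3 per-domain tabular dialect."""
    with open(path, "w") as fh:
        fh.write("# target name        accession   tlen query name           "
                 "accession   qlen   E-value  score  bias   #  of  c-Evalue  "
                 "i-Evalue  score  bias  from    to  from    to  from    to  "
                 "acc description of target\n")
        for pid, lst in hits.items():
            for i, h in enumerate(lst, 1):
                fh.write(
                    f"{pid} - 0 {h.domain_name} - 0 {h.evalue:.2g} 0.0 0.0 "
                    f"{i} {len(lst)} {h.evalue:.2g} {h.evalue:.2g} 0.0 0.0 "
                    f"1 {h.end - h.start + 1} {h.start} {h.end} "
                    f"{h.start} {h.end} 0.90 -\n"
                )


# ---------------------------------------------------------------------------
# Census-table fixture (domain-string grammar)

_DOMAIN_TOKEN = re.compile(r"^([A-Za-z_][A-Za-z0-9_\-]*?)(?:\(([^)]*)\))?$")

# Motif labels per domain, in the order they appear in domain strings.
_MOTIF_LABELS = {
    "His": ["H"],
    "HATPase_c": ["N", "G1", "F", "G2"],
    "Rec": ["D"],
    "Hpt": ["H"],
    "EBD": ["D", "Y", "I1", "P", "I2", "C", "H"],
}


def parse_domain_string(text: str) -> list[DomainHit]:
    """Parse a census-style domain string into :class:`DomainHit` objects.

    Grammar: space-separated tokens; each is ``Domain``, ``Domain(states)``
    or ``-`` (absent domain, skipped). States are comma-separated motif
    residues, with ``-`` for an absent motif. ``C-ter(n)`` carries the
    transactivation-domain length in aa (``NA`` if undetermined).

    Example: ``"CHASE His(H) HATPase_c(N,G1,F,G2) Rec(D)"``.
    """
    hits: list[DomainHit] = []
    pos = 1
    for token in text.split():
        if token == "-":
            pos += 1
            continue
        m = _DOMAIN_TOKEN.match(token)
        if m is None:
            raise FormatError(f"unparseable domain token {token!r} in {text!r}")
        name, states = m.group(1), m.group(2)
        motif_states: dict[str, str] = {}
        if name == "C-ter":
            length = None if states in (None, "NA", "AA", "") else int(states)
            hit = DomainHit(domain_name="C-ter", start=pos, end=pos)
            hit.motif_states["length"] = "" if length is None else str(length)
            hits.append(hit)
            pos += 1
            continue
        labels = _MOTIF_LABELS.get(name, [])
        if states is not None:
            values = [s.strip() for s in states.split(",")]
            if labels:
                if len(values) == 1 and len(labels) == 1:
                    motif_states[labels[0]] = values[0]
                elif len(values) == len(labels):
                    # Positional: e.g. HATPase_c(-,G1,-,G2) marks which of
                    # the N/G1/F/G2 boxes are present.
                    for lab, val in zip(labels, values):
                        motif_states[lab] = "-" if val == "-" else "+"
                else:
                    raise FormatError(
                        f"domain {name!r}: expected {len(labels)} motif "
                        f"states, got {values!r} in {text!r}"
                    )
            else:
                raise FormatError(
                    f"domain {name!r} takes no motif states; got {token!r}"
                )
        hits.append(DomainHit(domain_name=name, start=pos, end=pos,
                              motif_states=motif_states))
        pos += 1
    return hits


@dataclass(frozen=True)
class CensusEntry:
    """One row of the packaged census fixture."""

    section: str
    locus: str
    previous_name: str
    name: str
    length: int
    at_homolog: str
    domains: list[DomainHit]
    unplaced: bool = False


def read_census_fixture() -> list[CensusEntry]:
    """Load the packaged census fixture (77 entries across five sections).

    Entries whose locus tag is not annotated in the reference genome release
    (``NA`` in the source) receive a synthetic ``unplaced:`` id and are
    flagged ``unplaced``.
    """
    path = resources.files("tcskit.data") / "mtruncatula_census.tsv"
    entries: list[CensusEntry] = []
    with path.open() as fh:
        header: list[str] | None = None
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise FormatError(
                    f"census fixture row has {len(fields)} fields, "
                    f"expected {len(header)}: {line!r}"
                )
            row = dict(zip(header, fields))
            unplaced = row["locus"] == "NA"
            locus = f"unplaced:{row['name']}" if unplaced else row["locus"]
            entries.append(
                CensusEntry(
                    section=row["section"],
                    locus=locus,
                    previous_name=row["previous_name"],
                    name=row["name"],
                    length=int(row["length"]),
                    at_homolog=row["at_homolog"],
                    domains=parse_domain_string(row["domains"]),
                    unplaced=unplaced,
                )
            )
    return entries


# ---------------------------------------------------------------------------
# TSV matrices, loci, Newick, reports

def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TSV of log2 values.

    An optional ``#dataset:`` comment line of the form
    ``#dataset:<sample>=<dataset_id>,...`` assigns columns to dataset blocks.
    Empty cells become NaN (missing probe), never zero.
    """
    dataset_ids: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    data_lines = []
    for line in lines:
        if line.startswith("#dataset:"):
            for assign in line[len("#dataset:"):].strip().split(","):
                if assign:
                    sample, ds = assign.split("=")
                    dataset_ids[sample.strip()] = ds.strip()
        elif not line.startswith("#"):
            data_lines.append(line)
    if not data_lines:
        raise FormatError(f"no data rows in {path}")
    header = data_lines[0].rstrip("\n").split("\t")
    ncol = len(header)
    for i, line in enumerate(data_lines[1:], 2):
        if len(line.rstrip("\n").split("\t")) != ncol:
            raise FormatError(
                f"{path}: row {i} has a different number of columns "
                f"than the header"
            )
    from io import StringIO

    df = pd.read_csv(StringIO("".join(data_lines)), sep="\t", index_col=0)
    return ExpressionMatrix(values=df.astype(float), dataset_ids=dataset_ids)


def write_expression_tsv(m: ExpressionMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        assigns = ",".join(f"{s}={d}" for s, d in m.dataset_ids.items())
        fh.write(f"#dataset:{assigns}\n")
        m.values.to_csv(fh, sep="\t")


def read_loci_tsv(path: str | Path) -> list[GeneLocus]:
    """Read a gene-locus table (gene_id, chromosome, start, end, strand).

    Ranks (gene ordinals along each chromosome) are recomputed from start
    coordinates.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id", "chromosome", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    loci = []
    for _, row in df.iterrows():
        loci.append(
            GeneLocus(
                gene_id=str(row["gene_id"]),
                chromosome=str(row["chromosome"]),
                start=int(row["start"]),
                end=int(row["end"]),
                strand=str(row["strand"]),
            )
        )
    return assign_ranks(loci)


def assign_ranks(loci: list[GeneLocus]) -> list[GeneLocus]:
    """Return loci with rank = ordinal by start position per chromosome."""
    out: list[GeneLocus] = []
    by_chrom: dict[str, list[GeneLocus]] = {}
    for loc in loci:
        by_chrom.setdefault(loc.chromosome, []).append(loc)
    ranked: dict[str, GeneLocus] = {}
    for chrom_loci in by_chrom.values():
        for rank, loc in enumerate(sorted(chrom_loci, key=lambda x: x.start), 1):
            ranked[loc.gene_id] = GeneLocus(
                gene_id=loc.gene_id, chromosome=loc.chromosome,
                start=loc.start, end=loc.end, strand=loc.strand, rank=rank,
            )
    for loc in loci:
        out.append(ranked[loc.gene_id])
    return out


def write_loci_tsv(loci: Iterable[GeneLocus], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchromosome\tstart\tend\tstrand\trank\n")
        for loc in loci:
            fh.write(f"{loc.gene_id}\t{loc.chromosome}\t{loc.start}\t"
                     f"{loc.end}\t{loc.strand}\t{loc.rank}\n")


def write_newick(tree, path: str | Path) -> None:
    """Write a scikit-bio TreeNode as Newick with branch lengths."""
    tree.write(str(path), format="newick")


def write_report_tsv(calls, path: str | Path) -> None:
    """Write classification calls as a census-shaped TSV report."""
    with open(path, "w") as fh:
        fh.write("protein_id\tname\tlength\tfamily\tcanonical\ttruncated\t"
                 "nearest_reference\tvariant_class\tdomains\n")
        for c in calls:
            fh.write(
                f"{c.protein_id}\t{c.name}\t{c.length}\t{c.family}\t"
                f"{int(c.canonical)}\t{int(c.truncated)}\t"
                f"{c.nearest_reference}\t{c.variant_class}\t{c.domain_summary}\n"
            )
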