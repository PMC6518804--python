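"""End-to-end orchestration: config, census, reports, manifest.

`run_census` wires the stages together: classification (from a protein
FASTA + domain table, or from the packaged census fixture), phosphoacceptor
variant calling, substitution tables, distance trees, promoter motif
counts, tandem arrays, and expression clustering.  Every artifact embeds
the configuration hash so runs are traceable; reruns with the same inputs
are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import annotate, expression as expr, families, genome as gen, \
    phosphosite, phylogeny, seqio
from .align import progressive_msa
from .references import default_references

logger = logging.getLogger("tcskit")

__all__ = ["PipelineConfig", "CensusResult", "run_census",
           "classify_fixture", "fixture_census"]


@dataclass
class PipelineConfig:
    """Settings for a pipeline run; defaults mirror the study settings
    (domain e-value cutoff 1e-10, 2.5-kb promoters, the AGATHY element,
    Euclidean/average-linkage clustering)."""

    proteins_fasta: str = ""
    domains_path: str = ""
    loci_tsv: str = ""
    expression_tsv: str = ""
    genome_fasta: str = ""
    out_dir: str = "tcs_out"
    evalue_max: float = 1e-10
    gap_open: float = 11.0
    gap_extend: float = 1.0
    promoter_length: int = 2500
    motif: str = "AGATHY"
    max_intervening: int = 10
    max_gap_fraction: float = 0.5
    seed: int = 0
    use_fixture: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update(overrides)
        return cls(**data)

    def config_hash(self) -> str:
        """Hash of the analysis settings (the output location is not part
        of the analysis identity)."""
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]

    def validate_paths(self) -> None:
        for key in ("proteins_fasta", "domains_path", "loci_tsv",
                    "expression_tsv", "genome_fasta"):
            value = getattr(self, key)
            if value and not Path(value).exists():
                raise FileNotFoundError(f"{key}: {value!r} does not exist")


@dataclass
class CensusResult:
    """Aggregated outputs of a census run."""

    calls: list = field(default_factory=list)
    family_counts: dict = field(default_factory=dict)
    variant_counts: dict = field(default_factory=dict)
    substitution_tables: dict = field(default_factory=dict)
    trees: dict = field(default_factory=dict)
    motif_counts: dict = field(default_factory=dict)
    tandem_arrays: list = field(default_factory=list)
    core_module: dict = field(default_factory=dict)
    config_hash: str = ""

    def census_summary(self) -> dict:
        return {
            "families": self.family_counts,
            "variants": self.variant_counts,
            "core_module": self.core_module,
            "tandem_arrays": self.tandem_arrays,
            "config_hash": self.config_hash,
        }


# ---------------------------------------------------------------------------
# Fixture path (the packaged census table)

def classify_fixture() -> list[families.TCSCall]:
    """Classify every entry of the packaged census fixture.

    Architectures come from the fixture's domain strings, so this path
    exercises the rule table without any sequence alignment.
    """
    calls = []
    for entry in seqio.read_census_fixture():
        arch = families.DomainArchitecture(
            hits=entry.domains, protein_length=entry.length)
        call = families.classify_family(arch, protein_id=entry.locus)
        call.name = entry.name
        call.length = entry.length
        call.nearest_reference = entry.at_homolog
        calls.append(call)
    return calls


def _count_families(calls) -> tuple[dict, dict]:
    fam_counts: dict[str, dict[str, int]] = {}
    var_counts: dict[str, dict[str, int]] = {}
    for c in calls:
        fc = fam_counts.setdefault(
            c.family, {"total": 0, "canonical": 0, "non_canonical": 0})
        fc["total"] += 1
        fc["canonical" if c.canonical else "non_canonical"] += 1
        vc = var_counts.setdefault(c.family, {})
        vc[c.variant_class] = vc.get(c.variant_class, 0) + 1
    return fam_counts, var_counts


def fixture_census() -> CensusResult:
    """Family and variant counts over the packaged census fixture."""
    calls = classify_fixture()
    fam_counts, var_counts = _count_families(calls)
    return CensusResult(calls=calls, family_counts=fam_counts,
                        variant_counts=var_counts)


# ---------------------------------------------------------------------------
# Full run

def run_census(config: PipelineConfig) -> CensusResult:
    """Run every stage the configuration provides inputs for.

    Outputs are written under ``config.out_dir``: the variant-call report,
    census JSON, substitution tables, Newick trees, motif counts, tandem
    arrays, core-module report, and a machine-readable run manifest.
    """
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    refs = default_references()
    result = CensusResult(config_hash=chash)

    if config.use_fixture or not config.proteins_fasta:
        logger.info("classifying the packaged census fixture")
        result.calls = classify_fixture()
        proteins = []
    else:
        logger.info("classifying %s", config.proteins_fasta)
        proteins = seqio.read_fasta(config.proteins_fasta)
        hits = seqio.read_domtblout(config.domains_path,
                                    config.evalue_max) \
            if config.domains_path else {}
        result.calls = annotate.classify_proteins(proteins, hits, refs)

    result.family_counts, result.variant_counts = _count_families(
        result.calls)
    seqio.write_report_tsv(result.calls, out / "calls.tsv")

    by_family: dict[str, list] = {}
    for p in proteins:
        call = next(c for c in result.calls if c.protein_id == p.id)
        by_family.setdefault(call.family, []).append(p)

    # substitution tables + trees for sequence families
    for fam in ("HPT", "RRB"):
        members = by_family.get(fam, [])
        if members:
            table = phosphosite.substitution_rate_table(
                members, refs.phosphosites[fam])
            result.substitution_tables[fam] = table
            phosphosite.write_substitution_table_tsv(
                table, out / f"substitutions_{fam}.tsv")
        if len(members) >= 3:
            msa = progressive_msa(members, gap_open=config.gap_open,
                                  gap_extend=config.gap_extend)
            try:
                from .align import filter_columns
                msa = filter_columns(msa, config.max_gap_fraction)
            except ValueError:
                pass
            dm = phylogeny.protein_distance(msa)
            tree = phylogeny.neighbor_joining(dm)
            result.trees[fam] = tree
            seqio.write_newick(tree, out / f"tree_{fam}.nwk")

    loci = seqio.read_loci_tsv(config.loci_tsv) if config.loci_tsv else []
    if loci and result.calls:
        fams = {c.protein_id: c.family for c in result.calls}
        pairs = gen.find_tandem_duplicates(
            loci, {g: f for g, f in fams.items()
                   if any(loc.gene_id == g for loc in loci)},
            config.max_intervening)
        result.tandem_arrays = gen.tandem_arrays(pairs)
        with open(out / "tandem_arrays.tsv", "w") as fh:
            fh.write("# config=%s\narray\tmembers\n" % chash)
            for i, arr in enumerate(result.tandem_arrays, 1):
                fh.write(f"{i}\t{','.join(arr)}\n")

    if config.genome_fasta and loci:
        motif = gen.DegenerateMotif(config.motif)
        chroms = {r.id: r.sequence
                  for r in _read_nucleotide_fasta(config.genome_fasta)}
        with open(out / "motif_counts.tsv", "w") as fh:
            fh.write(f"# config={chash}\ngene_id\tcount\ttruncated\n")
            for loc in loci:
                if loc.chromosome not in chroms:
                    logger.warning("no sequence for %s", loc.chromosome)
                    continue
                promoter = gen.extract_promoter(
                    chroms[loc.chromosome], loc, config.promoter_length)
                count, _ = gen.count_motif(promoter.sequence, motif,
                                           seq_id=loc.gene_id)
                result.motif_counts[loc.gene_id] = count
                fh.write(f"{loc.gene_id}\t{count}\t"
                         f"{int(promoter.truncated)}\n")

    if config.expression_tsv:
        matrix = seqio.read_expression_tsv(config.expression_tsv)
        fams = {c.protein_id: c.family for c in result.calls}
        by_name = {c.name: c.family for c in result.calls if c.name}
        fams.update(by_name)
        dendro = expr.cluster_genes(matrix)
        result.core_module = expr.identify_core_module(matrix, fams)
        heat = expr.normalize_heatmap(matrix)
        heat.values.to_csv(out / "heatmap.tsv", sep="\t")
        with open(out / "core_module.tsv", "w") as fh:
            fh.write(f"# config={chash}\nfamily\tgene\n")
            for fam, gid in result.core_module.items():
                fh.write(f"{fam}\t{gid}\n")
        with open(out / "expression_dendrogram.txt", "w") as fh:
            fh.write("\n".join(dendro.leaf_order) + "\n")

    with open(out / "census.json", "w") as fh:
        json.dump(result.census_summary(), fh, indent=2, sort_keys=True)
    manifest = {
        "config": asdict(config),
        "config_hash": chash,
        "n_calls": len(result.calls),
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return result


def _read_nucleotide_fasta(path):
    from Bio import SeqIO as _SeqIO

    class _Rec:
        def __init__(self, rid, seq):
            self.id, self.sequence = rid, seq

    return [_Rec(r.id, str(r.seq).upper())
            for r in _SeqIO.parse(str(path), "fasta")]
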