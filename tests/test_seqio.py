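"""Format readers/writers: round trips, error handling, and the census fixture."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcskit import seqio
from tcskit.seqio import (FormatError, GeneLocus, ProteinRecord,
                          parse_domain_string, read_domtblout, read_fasta,
                          read_census_fixture, write_fasta)

DOMTBL_HEADER = ("# target name accession tlen query name accession qlen "
                 "E-value score bias # of c-Evalue i-Evalue score bias "
                 "from to from to from to acc description\n")


def _domtbl_line(target, domain, ievalue, start, end):
    return (f"{target} - 0 {domain} - 0 {ievalue} 0 0 1 1 {ievalue} "
            f"{ievalue} 0 0 1 {end - start + 1} {start} {end} {start} {end} "
            f"0.9 -\n")


class TestFasta:
    def test_two_record_parse(self, tmp_path):
        p = tmp_path / "toy.fasta"
        p.write_text(">p1 first protein\nMKV\nLQ\n>p2\nacdef*\n")
        records = read_fasta(p)
        assert [r.id for r in records] == ["p1", "p2"]
        assert records[0].sequence == "MKVLQ"
        assert records[0].description == "first protein"
        # uppercased, terminal stop stripped
        assert records[1].sequence == "ACDEF"

    def test_round_trip_identity(self, tmp_path):
        records = [ProteinRecord("a", "MKVHD"), ProteinRecord("b", "WYX")]
        out = tmp_path / "rt.fasta"
        write_fasta(records, out)
        back = read_fasta(out)
        assert [(r.id, r.sequence) for r in back] == \
            [(r.id, r.sequence) for r in records]

    @settings(max_examples=25, deadline=None)
    @given(st.lists(
        st.text(alphabet="ACDEFGHIKLMNPQRSTVWYX", min_size=1, max_size=40),
        min_size=1, max_size=5))
    def test_round_trip_property(self, tmp_path_factory, seqs):
        records = [ProteinRecord(f"s{i}", s) for i, s in enumerate(seqs)]
        out = tmp_path_factory.mktemp("fa") / "prop.fasta"
        write_fasta(records, out)
        assert [r.sequence for r in read_fasta(out)] == seqs

    def test_empty_file_is_format_error(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(FormatError):
            read_fasta(p)

    def test_duplicate_id_names_offender(self, tmp_path):
        p = tmp_path / "dup.fasta"
        p.write_text(">x\nMK\n>x\nMV\n")
        with pytest.raises(FormatError, match="x"):
            read_fasta(p)


class TestDomtblout:
    def test_evalue_filtering(self, tmp_path):
        p = tmp_path / "hits.domtblout"
        p.write_text(DOMTBL_HEADER.replace(" ", "_")[:1] + "\n"
                     + _domtbl_line("p1", "Hpt", "1e-12", 5, 140)
                     + _domtbl_line("p1", "CHASE", "1e-5", 1, 50))
        hits = read_domtblout(p)
        # the 1e-12 hit survives the default 1e-10 cutoff, the 1e-5 does not
        assert [h.domain_name for h in hits["p1"]] == ["Hpt"]
        assert hits["p1"][0].start == 5

    def test_protein_with_no_passing_hits_keeps_empty_list(self, tmp_path):
        p = tmp_path / "hits.domtblout"
        p.write_text(_domtbl_line("p1", "Hpt", "1e-3", 1, 10))
        assert read_domtblout(p) == {"p1": []}

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.domtblout"
        p.write_text(_domtbl_line("p1", "Hpt", "1e-12", 5, 140)
                     + "too few columns\n")
        with pytest.raises(FormatError, match="2"):
            read_domtblout(p)

    def test_round_trip(self, tmp_path):
        from tcskit.seqio import DomainHit, write_domtblout

        hits = {"p1": [DomainHit("Hpt", 5, 140, 1e-20)],
                "p2": [DomainHit("Rec", 1, 120, 1e-15),
                       DomainHit("Myb", 121, 180, 1e-12)]}
        p = tmp_path / "rt.domtblout"
        write_domtblout(hits, p)
        back = read_domtblout(p)
        assert {k: [(h.domain_name, h.start, h.end) for h in v]
                for k, v in back.items()} == \
            {k: [(h.domain_name, h.start, h.end) for h in v]
             for k, v in hits.items()}


class TestCensusFixture:
    def test_section_sizes(self):
        entries = read_census_fixture()
        assert len(entries) == 77
        by_section = {}
        for e in entries:
            by_section.setdefault(e.section, []).append(e)
        assert len(by_section["HK"]) == 18  # 5 CHK + 7 HK + 6 ETR
        assert len(by_section["HPT"]) == 10
        assert len(by_section["RRA"]) == 10
        assert len(by_section["RRB"]) == 32
        assert len(by_section["clock-RR"]) == 7

    def test_cytokinin_receptor_row(self):
        entries = {e.name: e for e in read_census_fixture()}
        chk1 = entries["MtCHK1"]
        assert chk1.locus == "Medtr8g106150"
        assert chk1.at_homolog == "AHK4"
        assert chk1.previous_name == "CRE1"
        domains = {h.domain_name: h for h in chk1.domains}
        assert set(domains) == {"CHASE", "His", "HATPase_c", "Rec"}
        assert domains["His"].motif_states["H"] == "H"
        assert all(domains["HATPase_c"].motif_states[b] in ("+", b)
                   for b in ("N", "G1", "F", "G2"))
        assert domains["Rec"].motif_states["D"] == "D"

    def test_noncanonical_hpt_and_clock_rows(self):
        entries = {e.name: e for e in read_census_fixture()}
        hpt9 = entries["MtHPT9"]
        assert [h.domain_name for h in hpt9.domains] == ["Hpt"]
        assert hpt9.domains[0].motif_states["H"] == "R"
        prr1 = entries["MtPRR1"]
        names = [h.domain_name for h in prr1.domains]
        assert names == ["Rec", "CCT"]
        assert prr1.domains[0].motif_states["D"] == "E"

    def test_unannotated_locus_flagged_unplaced(self):
        entries = {e.name: e for e in read_census_fixture()}
        assert entries["MtRRB30"].unplaced
        assert entries["MtRRB30"].locus.startswith("unplaced:")
        assert sum(e.unplaced for e in read_census_fixture()) == 1

    def test_unparseable_domain_string_quotes_it(self):
        with pytest.raises(FormatError, match="His"):
            parse_domain_string("His(H,extra,states)")


class TestTables:
    def test_expression_round_trip(self, tmp_path):
        import numpy as np
        import pandas as pd

        from tcskit.seqio import (ExpressionMatrix, read_expression_tsv,
                                  write_expression_tsv)

        m = ExpressionMatrix(
            values=pd.DataFrame([[1.0, 2.0], [3.0, np.nan], [0.5, 4.0]],
                                index=["g1", "g2", "g3"],
                                columns=["s1", "s2"]),
            dataset_ids={"s1": "atlas", "s2": "nodule"})
        p = tmp_path / "expr.tsv"
        write_expression_tsv(m, p)
        back = read_expression_tsv(p)
        pd.testing.assert_frame_equal(back.values, m.values)
        assert back.dataset_ids == m.dataset_ids

    def test_ragged_expression_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("gene\ts1\ts2\ng1\t1.0\n")
        with pytest.raises(FormatError):
            seqio.read_expression_tsv(p)

    def test_loci_round_trip_and_ranks(self, tmp_path):
        from tcskit.seqio import read_loci_tsv, write_loci_tsv

        loci = [GeneLocus("g2", "chr1", 5000, 6000, "-"),
                GeneLocus("g1", "chr1", 100, 900, "+"),
                GeneLocus("g3", "chr2", 10, 20, "+")]
        p = tmp_path / "loci.tsv"
        write_loci_tsv(loci, p)
        back = {l.gene_id: l for l in read_loci_tsv(p)}
        assert back["g1"].rank == 1 and back["g2"].rank == 2
        assert back["g3"].rank == 1

    def test_invalid_locus_rejected(self, tmp_path):
        p = tmp_path / "bad_loci.tsv"
        p.write_text("gene_id\tchromosome\tstart\tend\tstrand\n"
                     "g1\tchr1\t500\t100\t+\n")
        with pytest.raises(ValueError, match="start"):
            seqio.read_loci_tsv(p)

    def test_newick_is_parseable_by_standard_tools(self, tmp_path):
        from skbio.tree import TreeNode

        from tcskit.seqio import write_newick

        tree = TreeNode.read(["(A:1,B:2,C:3);"])
        p = tmp_path / "t.nwk"
        write_newick(tree, p)
        back = TreeNode.read(str(p))
        assert sorted(t.name for t in back.tips()) == ["A", "B", "C"]
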