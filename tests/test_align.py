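"""Affine-gap alignment, reference projection, and progressive MSA."""

import numpy as np
import pytest

from oracles import brute_force_global_score
from tcskit.align import (GAP, PairwiseAlignment, align_global,
                          default_matrix, filter_columns, progressive_msa,
                          project_position)
from tcskit.seqio import ProteinRecord

MATRIX = default_matrix()
ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
IDX = {aa: i for i, aa in enumerate(ALPHABET)}


def _score_fn(x, y):
    return MATRIX[IDX[x], IDX[y]]


def _rec(pid, seq):
    return ProteinRecord(pid, seq)


class TestAlignGlobal:
    def test_self_alignment_scores_diagonal_and_maps_identity(self):
        seq = "MKVHDLQWER"
        aln = align_global(_rec("a", seq), _rec("b", seq))
        expected = sum(_score_fn(c, c) for c in seq)
        assert aln.score == pytest.approx(expected)
        assert aln.column_map == tuple(range(1, len(seq) + 1))
        assert aln.aligned_a == aln.aligned_b == seq

    def test_matches_enumeration_oracle_on_short_pairs(self):
        rng = np.random.default_rng(42)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(60):
            la, lb = rng.integers(1, 7, size=2)
            a = "".join(rng.choice(list(aas), la))
            b = "".join(rng.choice(list(aas), lb))
            got = align_global(_rec("a", a), _rec("b", b)).score
            want = brute_force_global_score(a, b, _score_fn, 11.0, 1.0)
            assert got == pytest.approx(want), (a, b)

    def test_matches_independent_aligner_on_longer_pairs(self):
        # cross-check the DP against Biopython's affine-gap aligner
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = \
            Align.substitution_matrices.load("BLOSUM62")
        aligner.mode = "global"
        aligner.open_gap_score = -11.0
        aligner.extend_gap_score = -1.0
        rng = np.random.default_rng(7)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(10):
            a = "".join(rng.choice(list(aas), 60))
            b = "".join(rng.choice(list(aas), 55))
            got = align_global(_rec("a", a), _rec("b", b)).score
            assert got == pytest.approx(aligner.score(a, b))

    def test_score_is_symmetric(self):
        a, b = _rec("a", "MKVHDLQW"), _rec("b", "MKHDLW")
        assert align_global(a, b).score == \
            pytest.approx(align_global(b, a).score)

    def test_large_gap_open_forces_terminal_gaps(self):
        aln = align_global(_rec("a", "HDHD"), _rec("b", "HD"),
                           gap_open=100.0, gap_extend=1.0)
        # both H,D columns of the short sequence are matched; the two
        # uncovered reference residues sit in one terminal gap run
        assert aln.aligned_b.strip("-") == "HD"
        assert aln.aligned_b.count("-") == 2
        assert "H" in [aln.aligned_a[i] for i in range(4)
                       if aln.aligned_b[i] == "H"]

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            ProteinRecord("a", "")

    def test_determinism(self):
        a, b = _rec("a", "MKVHDLQWERTY"), _rec("b", "MKDLQWRTY")
        first = align_global(a, b)
        second = align_global(a, b)
        assert first.aligned_a == second.aligned_a
        assert first.aligned_b == second.aligned_b


class TestProjectPosition:
    def test_self_alignment_projection_is_identity(self, refs):
        for name in ("MtHPT3_SYN", "MtRRB3_SYN"):
            rec = refs[name]
            aln = align_global(rec, rec)
            for pos in (1, len(rec) // 2, len(rec)):
                assert project_position(aln, pos) == pos

    def test_reference_gap_column_projects_to_partner(self):
        # reference AB aligned as "AB-" against target "ABC"
        aln = PairwiseAlignment("r", "t", "AB-", "ABC", 0.0,
                                column_map=(1, 2))
        assert project_position(aln, 2) == 2

    def test_deleted_target_residue_projects_to_gap(self):
        aln = PairwiseAlignment("r", "t", "ABC", "A-C", 0.0,
                                column_map=(1, GAP, 2))
        assert project_position(aln, 2) is GAP

    def test_out_of_range_position_rejected(self):
        aln = PairwiseAlignment("r", "t", "AB", "AB", 0.0, column_map=(1, 2))
        with pytest.raises(ValueError):
            project_position(aln, 3)
        with pytest.raises(ValueError):
            project_position(aln, 0)


class TestProgressiveMSA:
    def test_identical_sequences_align_gap_free(self):
        records = [_rec(f"s{i}", "MKVHDLQWER") for i in range(3)]
        msa = progressive_msa(records)
        assert all(r == "MKVHDLQWER" for r in msa.rows)

    def test_gap_free_pairwise_alignments_give_gap_free_msa(self):
        records = [_rec("s1", "MKVHDLQW"), _rec("s2", "MKVHELQW"),
                   _rec("s3", "MRVHDLQW")]
        msa = progressive_msa(records)
        assert msa.n_columns == 8
        assert not any("-" in r for r in msa.rows)

    def test_degapped_rows_recover_inputs(self):
        records = [_rec("s1", "MKVHDLQWERTY"), _rec("s2", "MKVDLQWRTY"),
                   _rec("s3", "MKVHDLWERTY")]
        msa = progressive_msa(records)
        assert msa.ids == ["s1", "s2", "s3"]
        for rec, row in zip(records, msa.rows):
            assert row.replace("-", "") == rec.sequence

    def test_planted_indel_family_columns_recovered(self):
        # sum-of-pairs recovery: fraction of truly homologous residue
        # pairs (same planted consensus column) placed in one MSA column
        import itertools

        from tcskit.synthetic import generate_family

        proteins, _, truth = generate_family(
            6, "HPT", 0.0, divergence=0.1, seed=11, indel_prob=0.02)
        msa = progressive_msa(proteins)
        pos = {}
        for pid, row in zip(msa.ids, msa.rows):
            cols = truth.source_columns[pid]
            k, mapping = 0, {}
            for j, c in enumerate(row):
                if c != "-":
                    if cols[k] is not None:
                        mapping[cols[k]] = j
                    k += 1
            pos[pid] = mapping
        good = total = 0
        for a, b in itertools.combinations(msa.ids, 2):
            for col in set(pos[a]) & set(pos[b]):
                total += 1
                good += pos[a][col] == pos[b][col]
        assert total > 1000
        assert good / total >= 0.95

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            progressive_msa([_rec("s1", "MKV")])


class TestFilterColumns:
    def _msa(self, rows):
        from tcskit.align import MultipleAlignment

        return MultipleAlignment(
            ids=[f"s{i}" for i in range(len(rows))], rows=rows,
            column_index=list(range(1, len(rows[0]) + 1)))

    def test_gap_free_msa_unchanged(self):
        msa = self._msa(["MKV", "MRV"])
        out = filter_columns(msa, 0.5)
        assert out.rows == msa.rows

    def test_majority_gap_column_removed(self):
        msa = self._msa(["A-C", "A-C", "A-C", "AGC"])  # middle col 3/4 gaps
        out = filter_columns(msa, 0.5)
        assert out.rows == ["AC", "AC", "AC", "AC"]
        assert out.column_index == [1, 3]

    def test_threshold_one_is_identity(self):
        msa = self._msa(["A--", "-G-", "--C"])
        assert filter_columns(msa, 1.0).rows == msa.rows

    def test_idempotent(self):
        msa = self._msa(["A-CD", "A-C-", "AGCD", "A-CD"])
        once = filter_columns(msa, 0.5)
        twice = filter_columns(once, 0.5)
        assert once.rows == twice.rows
        assert once.column_index == twice.column_index

    def test_removing_every_column_is_an_error(self):
        msa = self._msa(["A-", "-G"])
        with pytest.raises(ValueError, match="max_gap_fraction"):
            filter_columns(msa, 0.25)
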