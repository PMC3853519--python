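import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from orthomatrix.errors import (
    EmptyInputError,
    FrameInconsistencyError,
    InvalidAlignmentError,
    InvalidInputError,
)
from orthomatrix.iupac import CODE_TO_SET, SET_TO_CODE
from orthomatrix.orthomap import (
    Blosum62Scorer,
    CodonAlignment,
    OrthologGroup,
    OrthologHit,
    anchor_alignment,
    backtranslate,
    build_consensus,
    choose_representative,
    filter_hits,
    reciprocal_best_hit,
)


def _hit(gene="g1", taxon="tA", seq_id="s1", protein="MA", cds="ATGGCT", score=100.0, evalue=1e-20):
    return OrthologHit(gene_id=gene, taxon=taxon, seq_id=seq_id, protein=protein,
                       cds=cds, score=score, evalue=evalue)


class TestFilterHits:
    def test_empty_group_stays_empty(self):
        g = OrthologGroup(gene_id="g1", hits={}, reference_taxon="ref")
        assert filter_hits(g).n_hits() == 0

    def test_top_quartile_of_eight_keeps_two(self):
        hits = [_hit(seq_id=f"s{i}", score=10.0 * i, evalue=1e-6) for i in range(8)]
        g = OrthologGroup(gene_id="g1", hits={"tA": hits}, reference_taxon="ref")
        out = filter_hits(g)
        assert sorted(h.seq_id for h in out.hits["tA"]) == ["s6", "s7"]

    def test_evalue_cutoff_removes_weak_hit(self):
        hits = [_hit(seq_id="good", evalue=1e-9, score=50),
                _hit(seq_id="weak", evalue=1e-3, score=999)]
        g = OrthologGroup(gene_id="g1", hits={"tA": hits}, reference_taxon="ref")
        out = filter_hits(g)
        assert [h.seq_id for h in out.hits["tA"]] == ["good"]

    def test_minimum_one_survivor_retained(self):
        hits = [_hit(seq_id=f"s{i}", score=float(i), evalue=1e-6) for i in range(3)]
        g = OrthologGroup(gene_id="g1", hits={"tA": hits}, reference_taxon="ref")
        assert [h.seq_id for h in filter_hits(g).hits["tA"]] == ["s2"]

    def test_cds_protein_length_invariant_enforced(self):
        with pytest.raises(InvalidInputError):
            _hit(protein="MAA", cds="ATGGCT")


class TestReciprocalBestHit:
    TABLE = {  # printed score table of a toy 3-gene proteome
        ("q", "g1"): 90.0,
        ("q", "g2"): 75.0,
        ("q", "g3"): 40.0,
    }

    def _scorer(self, a, b):
        key = {"MKLV": "g1", "MKIV": "g2", "MAAA": "g3"}[b]
        return self.TABLE[("q", key)]

    def test_self_match_is_reciprocal(self):
        proteome = {"g1": "MA", "g2": "MV"}
        hit = _hit(gene="g1", protein="MA", cds="ATGGCT")
        assert reciprocal_best_hit(hit, proteome, Blosum62Scorer()) is True

    def test_best_match_elsewhere_fails(self):
        proteome = {"g1": "MA", "g2": "MV"}
        hit = _hit(gene="g2", protein="MA", cds="ATGGCT")
        assert reciprocal_best_hit(hit, proteome, Blosum62Scorer()) is False

    def test_matches_exhaustive_argmax_over_score_table(self):
        proteome = {"g1": "MKLV", "g2": "MKIV", "g3": "MAAA"}
        expected_best = max(self.TABLE, key=lambda k: self.TABLE[k])[1]
        for gene in proteome:
            hit = _hit(gene=gene, protein="MKLV", cds="ATGAAACTTGTT")
            assert reciprocal_best_hit(hit, proteome, self._scorer) is (gene == expected_best)

    def test_empty_proteome_rejected(self):
        with pytest.raises(InvalidInputError):
            reciprocal_best_hit(_hit(), {})


class TestBacktranslate:
    def test_gap_becomes_codon_gap(self):
        out = backtranslate({"tA": "M-A"}, {"tA": "ATGGCT"})
        assert out.rows["tA"] == "ATG---GCT"

    def test_output_length_is_three_times_protein_length(self):
        out = backtranslate({"tA": "MA-V", "tB": "M--V"}, {"tA": "ATGGCTGTT", "tB": "ATGGTT"})
        assert all(len(r) == 12 for r in out.rows.values())

    def test_translation_mismatch_names_taxon_and_column(self):
        with pytest.raises(FrameInconsistencyError, match=r"tA.*column 3"):
            backtranslate({"tA": "M-V"}, {"tA": "ATGGCT"})


def _column_union_oracle(symbols):
    union = set()
    for s in symbols:
        if s != "-":
            union |= set(CODE_TO_SET[s])
    return "-" if not union else SET_TO_CODE[frozenset(union)]


class TestBuildConsensus:
    @pytest.mark.parametrize(
        "rows,expect",
        [
            (["ACA"], "ACA"),
            (["ACA", "ACG"], "ACR"),
            (["AC-", "ACT"], "ACT"),  # gap treated as missing at a column
            (["---", "---"], "---"),
            (["ARA", "AGA"], "ARA"),  # input ambiguity contributes its whole set
        ],
    )
    def test_examples(self, rows, expect):
        assert build_consensus(rows) == expect

    def test_idempotent(self):
        rows = ["ACGT", "ACGA", "AC-T"]
        c = build_consensus(rows)
        assert build_consensus([c]) == c

    @given(st.lists(st.text(alphabet=sorted(CODE_TO_SET) + ["-"], min_size=6, max_size=6),
                    min_size=1, max_size=6))
    def test_order_invariance_and_union_oracle(self, rows):
        c = build_consensus(rows)
        assert c == build_consensus(rows[::-1])
        for col in range(6):
            assert c[col] == _column_union_oracle([r[col] for r in rows])

    def test_unequal_lengths_rejected(self):
        with pytest.raises(InvalidAlignmentError):
            build_consensus(["ACA", "AC"])

    def test_empty_rejected(self):
        with pytest.raises(EmptyInputError):
            build_consensus([])


class TestChooseRepresentative:
    REF = "ATGGCTAGTGCAGCAGCAGCA"

    def test_single_row_returned_as_is(self):
        assert choose_representative(["ATG---GCT"], "ATGGCTGCT") == "ATG---GCT"

    def test_higher_scoring_full_length_row_wins(self):
        good = self.REF
        bad = "TTTTTTTTTTTTTTTTTTTTT"
        assert choose_representative([bad, good], self.REF) == good

    def test_non_overlapping_fragments_merged(self):
        frag1 = self.REF[:9] + "-" * 12
        frag2 = "-" * 9 + self.REF[9:]
        out = choose_representative([frag1, frag2], self.REF)
        assert out == self.REF  # columns 1-9 and 10-21 concatenated

    def test_overlapping_rows_never_merged(self):
        r1 = self.REF[:12] + "-" * 9
        r2 = self.REF[:3] + "-" * 3 + self.REF[6:]
        out = choose_representative([r1, r2], self.REF)
        assert out in (r1, r2)

    def test_result_is_row_or_gap_disjoint_merge(self):
        rows = [self.REF[:6] + "-" * 15, "-" * 6 + self.REF[6:12] + "-" * 9,
                "-" * 12 + self.REF[12:]]
        out = choose_representative(rows, self.REF)
        for i, j in itertools.combinations(range(3), 2):
            assert not any(a != "-" and b != "-" for a, b in zip(rows[i], rows[j]))
        assert out == self.REF


class TestAnchorAlignment:
    def test_fragments_land_on_reference_coordinates(self):
        ref_cds = "ATGGCTAGTGCAAAAGTT"  # MASAKV
        ref_prot = "MASAKV"
        h1 = _hit(seq_id="full", protein=ref_prot, cds=ref_cds, taxon="tA")
        h2 = _hit(seq_id="frag", protein="SAK", cds="AGTGCAAAA", taxon="tB")
        aln = anchor_alignment([h1, h2], ref_prot, ref_cds, gene_id="g1")
        assert aln.rows["full"] == ref_cds
        assert aln.rows["frag"] == "------AGTGCAAAA---"
        assert aln.rows["ref"] == ref_cds

    def test_rows_share_reference_length(self):
        ref_cds = "ATGGCTAGTGCAAAAGTT"
        h = _hit(seq_id="ins", protein="MASSAKV", cds="ATGGCTAGTTCTGCAAAAGTT")
        aln = anchor_alignment([h], "MASAKV", ref_cds)
        assert len(aln.rows["ins"]) == len(ref_cds)  # insertion dropped


def test_codon_alignment_invariants():
    with pytest.raises(InvalidAlignmentError):
        CodonAlignment(gene_id="g", rows={"a": "ATG", "b": "ATGGCT"})
    with pytest.raises(InvalidAlignmentError):
        CodonAlignment(gene_id="g", rows={"a": "ATGG"})
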