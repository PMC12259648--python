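"""IMGT numbering, germline-set I/O, allele comparison, substitution grammar."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from ablineage.imgt import (
    GermlineFormatError,
    ImgtPosition,
    Substitution,
    compare_alleles,
    format_substitution,
    number_cdr3,
    number_v_domain,
    parse_substitution,
    read_germline_set,
    region_of,
)


class TestImgtPosition:
    def test_apex_ordering(self):
        """111.x ascend after 111; 112.x descend into 112."""
        shuffled = [
            ImgtPosition(112),
            ImgtPosition(111, 1),
            ImgtPosition(111),
            ImgtPosition(112, 2),
            ImgtPosition(111, 2),
            ImgtPosition(112, 1),
        ]
        assert [str(p) for p in sorted(shuffled)] == [
            "111",
            "111.1",
            "111.2",
            "112.2",
            "112.1",
            "112",
        ]
        assert ImgtPosition(110) < ImgtPosition(111) < ImgtPosition(111, 1)
        assert ImgtPosition(112, 1) < ImgtPosition(112) < ImgtPosition(113)

    def test_insertions_only_at_apex(self):
        with pytest.raises(ValueError):
            ImgtPosition(40, 1)
        with pytest.raises(ValueError):
            ImgtPosition(111, 0)

    @given(
        st.lists(
            st.one_of(
                st.integers(1, 128).map(ImgtPosition),
                st.tuples(st.sampled_from([111, 112]), st.integers(1, 13)).map(
                    lambda t: ImgtPosition(*t)
                ),
            ),
            min_size=2,
            max_size=20,
        )
    )
    def test_strict_total_order(self, positions):
        """sort_key induces a strict total order: equal keys imply equality."""
        s = sorted(positions)
        for a, b in zip(s, s[1:]):
            assert a.sort_key <= b.sort_key
            if a.sort_key == b.sort_key:
                assert a == b

    def test_regions_are_positional(self):
        assert region_of(ImgtPosition(38)) == "CDR1"
        assert region_of(ImgtPosition(62)) == "CDR2"
        assert region_of(ImgtPosition(96)) == "FR3"
        assert region_of(ImgtPosition(111, 3)) == "CDR3"
        assert region_of(ImgtPosition(118)) == "FR4"


class TestNumberCdr3:
    def test_length_13_is_gapless(self):
        assert [str(p) for p in number_cdr3("X" * 13)] == [
            str(n) for n in range(105, 118)
        ]

    def test_length_19_insertion_order(self):
        """A 19-residue loop carries 111.1-111.3 then 112.3-112.1 between
        111 and 112, in that sequential order."""
        names = [str(p) for p in number_cdr3("X" * 19)]
        i111, i112 = names.index("111"), names.index("112")
        assert names[i111 + 1 : i112] == [
            "111.1",
            "111.2",
            "111.3",
            "112.3",
            "112.2",
            "112.1",
        ]

    def test_length_14_single_insertion(self):
        names = [str(p) for p in number_cdr3("X" * 14)]
        assert names.count("112.1") == 1
        assert sum("." in n for n in names) == 1

    def test_short_loop_drops_apex_from_112_side(self):
        assert [p.number for p in number_cdr3("X" * 12)] == [
            105, 106, 107, 108, 109, 110, 111, 113, 114, 115, 116, 117,
        ]
        assert [p.number for p in number_cdr3("X" * 11)] == [
            105, 106, 107, 108, 109, 110, 113, 114, 115, 116, 117,
        ]

    @given(st.integers(1, 40))
    def test_invariants(self, length):
        positions = number_cdr3("X" * length)
        assert len(positions) == length
        assert all(a < b for a, b in zip(positions, positions[1:]))
        inserted = [p for p in positions if p.insertion is not None]
        if length <= 13:
            assert not inserted
        else:
            assert len(inserted) == length - 13
            assert {p.number for p in inserted} <= {111, 112}

    @pytest.mark.parametrize("length", [0, 41])
    def test_out_of_range(self, length):
        with pytest.raises(ValueError):
            number_cdr3("X" * length)


class TestSubstitutionGrammar:
    @pytest.mark.parametrize(
        "text,from_aa,number,insertion,chain,to_aa",
        [
            ("N40_H_T", "N", 40, None, "H", "T"),
            ("D111.3_H_E", "D", 111, 3, "H", "E"),
            ("V29_L_I", "V", 29, None, "L", "I"),
        ],
    )
    def test_parse(self, text, from_aa, number, insertion, chain, to_aa):
        s = parse_substitution(text)
        assert (s.from_aa, s.to_aa, s.chain) == (from_aa, to_aa, chain)
        assert (s.position.number, s.position.insertion) == (number, insertion)
        assert format_substitution(s) == text

    @pytest.mark.parametrize("bad", ["N40_H_N", "X40_H", "N40T", "n40_H_T", "N40_X_T"])
    def test_malformed(self, bad):
        with pytest.raises(ValueError):
            parse_substitution(bad)

    @given(
        st.sampled_from("ACDEFGHIKLMNPQRSTVWY"),
        st.integers(1, 128),
        st.sampled_from("HL"),
        st.sampled_from("ACDEFGHIKLMNPQRSTVWY"),
    )
    def test_round_trip(self, from_aa, number, chain, to_aa):
        if from_aa == to_aa:
            return
        s = Substitution(from_aa, ImgtPosition(number, chain=chain), to_aa)
        assert parse_substitution(format_substitution(s)) == s


class TestGermlineSetIO:
    def test_fixture_set_round_trips(self, germline_fasta, germline_set):
        loaded = read_germline_set(germline_fasta)
        assert len(loaded) == len(germline_set)
        assert sum(1 for a in loaded if a.segment == "V" and a.locus == "IGH") == 4
        by_name = {a.name: a for a in loaded}
        for a in germline_set:
            assert by_name[a.name].seq_nt == a.seq_nt
            assert by_name[a.name].gapped_seq_nt == a.gapped_seq_nt

    def test_bad_alphabet(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">X1*01|IGH|D\nACGU\n")
        with pytest.raises(GermlineFormatError):
            read_germline_set(p)

    def test_gapped_length_not_codon_multiple(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">X1*01|IGH|V\n" + "ACG" * 103 + "AC" + "\n")  # 311 nt
        with pytest.raises(GermlineFormatError):
            read_germline_set(p)

    def test_duplicate_names_rejected(self, tmp_path):
        p = tmp_path / "dup.fasta"
        p.write_text(">X1*01|IGH|D\nACGT\n>X1*01|IGH|D\nACGT\n")
        with pytest.raises(GermlineFormatError):
            read_germline_set(p)


class TestNumberVDomain:
    def test_gap_positions_skipped(self, germ_by_name):
        dom = number_v_domain(
            germ_by_name["SYNHV3-7*01"].seq_nt, germ_by_name["SYNHV3-7*01"], "H"
        )
        numbers = [r.position.number for r in dom if r.position.number <= 104]
        assert 9 in numbers and 11 in numbers and 10 not in numbers
        assert 31 not in numbers and 73 not in numbers

    def test_unmutated_reproduces_germline_translation(self, germline_set):
        """On its own sequence, numbering reproduces the germline protein at
        every IMGT position (whole fixture set)."""
        from Bio.Seq import Seq

        for allele in germline_set:
            if allele.segment != "V":
                continue
            dom = number_v_domain(allele.seq_nt, allele, allele.chain)
            for res in dom:
                assert res.aa == str(Seq(res.codon).translate())
            germ_map = dict(allele.position_map())
            for res in dom:
                if res.position in germ_map:
                    assert res.codon == germ_map[res.position]

    def test_indel_like_input_rejected(self, germ_by_name):
        allele = germ_by_name["SYNHV3-7*01"]
        shifted = allele.seq_nt[1:] + "A"  # frameshift: massive mismatch
        from ablineage.imgt import UnsupportedIndelError

        with pytest.raises(UnsupportedIndelError):
            number_v_domain(shifted, allele, "H")


class TestCompareAlleles:
    def test_cdr_variant_allele_pair(self, germ_by_name):
        """The *03-like allele differs from *01-like at exactly 38 (CDR1)
        and 62 (CDR2)."""
        diffs = compare_alleles(
            germ_by_name["SYNHV3-7*03"], germ_by_name["SYNHV3-7*01"]
        )
        assert [(p.number, reg) for p, _, _, reg in diffs] == [
            (38, "CDR1"),
            (62, "CDR2"),
        ]
        assert [(a, b) for _, a, b, _ in diffs] == [("E", "S"), ("G", "S")]

    def test_fr3_variant_allele_pair(self, germ_by_name):
        diffs = compare_alleles(
            germ_by_name["SYNHV3-7*02"], germ_by_name["SYNHV3-7*01"]
        )
        assert [(p.number, reg) for p, _, _, reg in diffs] == [(96, "FR3")]

    def test_identity_and_symmetry(self, germ_by_name):
        a, b = germ_by_name["SYNHV3-7*03"], germ_by_name["SYNHV3-7*02"]
        assert compare_alleles(a, a) == []
        ab = compare_alleles(a, b)
        ba = compare_alleles(b, a)
        assert [(p, y, x) for p, x, y, _ in ab] == [(p, x, y) for p, x, y, _ in ba]

    def test_synonymous_allele_is_protein_identical(self, germ_by_name):
        assert (
            compare_alleles(germ_by_name["SYNHV3-7*04"], germ_by_name["SYNHV3-7*01"])
            == []
        )

    def test_mixed_locus_rejected(self, germ_by_name):
        with pytest.raises(ValueError):
            compare_alleles(germ_by_name["SYNHV3-7*01"], germ_by_name["SYNKV2-5*01"])
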