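"""Strand chemistry model: gapmer patterns, pairing, design validation, IO."""

from dataclasses import replace

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tdnkit import (
    GAPMER_B_SCHEME,
    STERIC_BLOCKER_SCHEME,
    DuplexMap,
    GapmerScheme,
    InvalidSchemeError,
    MismatchError,
    Nucleotide,
    TDNDesign,
    build_gapmer_pattern,
    pair_strands,
    validate_design,
)
from tdnkit.io import (
    design_from_json,
    design_to_json,
    read_annotated_fasta,
    write_annotated_fasta,
)
from tdnkit.strands import StrandError

from conftest import make_strand


class TestGapmerPattern:
    @pytest.mark.parametrize(
        "scheme, expected_sugars",
        [
            # 20-nt gapmer B: 4 LNA + 2 OME wings around an 8-nt DNA gap
            (GAPMER_B_SCHEME, "LLLLMM" + "D" * 8 + "MMLLLL"),
            # published 14-nt layout: 2 LNA + 1 OME wings, 8-nt DNA gap
            (GapmerScheme(14, ("LNA", "LNA", "OME")), "LLM" + "D" * 8 + "MLL"),
            # empty wing: plain DNA 20-mer
            (GapmerScheme(20, ()), "D" * 20),
            # fully modified steric blocker: wings meet in the middle
            (STERIC_BLOCKER_SCHEME, "M" * 20),
        ],
    )
    def test_sugar_patterns(self, scheme, expected_sugars):
        code = {"DNA": "D", "RNA": "R", "LNA": "L", "OME": "M"}
        strand = build_gapmer_pattern(scheme)
        assert "".join(code[s] for s in strand.sugars) == expected_sugars
        assert len(strand) == scheme.total_length

    def test_central_dna_run_of_gapmer_b(self):
        strand = build_gapmer_pattern(GAPMER_B_SCHEME)
        assert strand.longest_sugar_run("DNA") == 8

    def test_ps_linkages_at_ends(self):
        strand = build_gapmer_pattern(GAPMER_B_SCHEME)
        links = strand.linkages
        assert [l == "PS" for l in links] == (
            [True] * 3 + [False] * 13 + [True] * 3
        )

    def test_fully_ps(self):
        scheme = replace(GAPMER_B_SCHEME, fully_ps=True)
        strand = build_gapmer_pattern(scheme)
        assert all(l == "PS" for l in strand.linkages)

    def test_wing_longer_than_half_rejected(self):
        with pytest.raises(InvalidSchemeError):
            GapmerScheme(10, ("LNA",) * 6)

    def test_seed_sequence_harmonized_to_sugar(self):
        strand = build_gapmer_pattern(GAPMER_B_SCHEME, seed_sequence="T" * 20)
        # OME positions carry U, LNA and DNA positions keep T
        bases = strand.sequence
        assert bases[4:6] == "UU" and bases[14:16] == "UU"
        assert bases[0:4] == "TTTT" and bases[6:14] == "T" * 8

    def test_seed_sequence_length_mismatch(self):
        with pytest.raises(InvalidSchemeError):
            build_gapmer_pattern(GAPMER_B_SCHEME, seed_sequence="ACGT")

    @given(
        total=st.integers(min_value=2, max_value=40),
        wing_len=st.integers(min_value=0, max_value=20),
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_length_conservation_and_symmetry(self, total, wing_len):
        if 2 * wing_len > total:
            with pytest.raises(InvalidSchemeError):
                GapmerScheme(total, ("LNA",) * wing_len)
            return
        scheme = GapmerScheme(total, ("LNA",) * wing_len)
        pattern = scheme.sugar_pattern()
        assert len(pattern) == total
        assert pattern == tuple(reversed(pattern))


class TestPairing:
    def test_rna_dna_full_complement(self):
        a = make_strand("a", "ACGU", "RRRR")
        b = make_strand("b", "ACGT")
        duplex = pair_strands(a, (1, 4), b, (1, 4))
        assert duplex.pairs == ((1, 4), (2, 3), (3, 2), (4, 1))

    def test_single_mismatch_reported(self):
        a = make_strand("a", "ACGU", "RRRR")
        b = make_strand("b", "ACGA")
        with pytest.raises(MismatchError) as exc:
            pair_strands(a, (1, 4), b, (1, 4))
        # A at position 1 faces the substituted A at partner position 4;
        # U at position 4 still legitimately pairs the A at partner position 1
        assert exc.value.positions == [(1, 4)]

    def test_no_gu_wobble(self):
        a = make_strand("a", "G", "R")
        b = make_strand("b", "U", "R")
        with pytest.raises(MismatchError):
            pair_strands(a, (1, 1), b, (1, 1))

    def test_role_swap_involutive(self):
        a = make_strand("a", "ACGU", "RRRR")
        b = make_strand("b", "ACGT")
        duplex = pair_strands(a, (1, 4), b, (1, 4))
        assert duplex.pair_set == pair_strands(b, (1, 4), a, (1, 4)).pair_set

    def test_gapmer_edge_register_on_generated_design(self, default_design):
        """Brute-force re-derivation of the heteroduplex pair map."""
        het = default_design.heteroduplex()
        assert len(het) == 20
        # antiparallel register: gapmer position 1 pairs strand position 20
        gapmer_side = {pb: pa for pa, pb in het.pairs}
        assert gapmer_side[1] == 20
        for pa, pb in het.pairs:
            assert pa + pb == 21


class TestValidation:
    def test_generated_design_passes(self, default_design):
        report = validate_design(default_design)
        assert report.passed, report.failures()
        assert set(report.strand_lengths.values()) == {64}

    def _mutate_base(self, design, strand_name, pos):
        strand = design.strands[strand_name]
        old = strand.nt(pos)
        new_base = "C" if old.base != "C" else "A"
        nts = list(strand.nts)
        nts[pos - 1] = Nucleotide(new_base, old.sugar, old.linkage3)
        mutated = replace(strand, nts=tuple(nts))
        strands = dict(design.strands)
        strands[strand_name] = mutated
        edges = tuple(
            DuplexMap(a=strands[e.a.name], b=strands[e.b.name], pairs=e.pairs)
            for e in design.edges
        )
        return replace(design, strands=strands, edges=edges)

    def test_edge_defect_detected(self, default_design):
        broken = self._mutate_base(default_design, "S2", 1)
        report = validate_design(broken)
        assert not report.passed
        assert any("complementarity" in c.name for c in report.failures())

    def test_gapmer_spanning_hinge_detected(self, default_design):
        s1 = default_design.strands["S1"]
        shifted = replace(s1, loci={"gapmer": (10, 29)})
        strands = dict(default_design.strands)
        strands["S1"] = shifted
        edges = tuple(
            DuplexMap(a=strands[e.a.name], b=strands[e.b.name], pairs=e.pairs)
            for e in default_design.edges
        )
        broken = replace(default_design, strands=strands, edges=edges)
        report = validate_design(broken)
        assert any(c.name == "gapmer_integrity" for c in report.failures())


class TestNucleotideInvariants:
    def test_uracil_never_on_dna_sugar(self):
        with pytest.raises(StrandError):
            Nucleotide("U", "DNA")

    def test_unknown_symbols_rejected(self):
        with pytest.raises(StrandError):
            Nucleotide("X")
        with pytest.raises(StrandError):
            Nucleotide("A", sugar="XNA")

    def test_overlapping_loci_rejected(self):
        with pytest.raises(StrandError):
            make_strand("s", "ACGTACGT", loci={"x": (1, 4), "y": (4, 6)})


class TestIO:
    def test_annotated_fasta_round_trip(self, default_design, tmp_path):
        strands = [default_design.strands[k] for k in sorted(default_design.strands)]
        fa, chem = tmp_path / "s.fasta", tmp_path / "s.chem"
        write_annotated_fasta(strands, fa, chem)
        back = read_annotated_fasta(fa, chem)
        by_name = {s.name: s for s in back}
        for s in strands:
            r = by_name[s.name]
            assert r.sequence == s.sequence
            assert r.sugars == s.sugars
            assert r.linkages == s.linkages

    def test_chemistry_length_mismatch_rejected(self, tmp_path):
        fa, chem = tmp_path / "s.fasta", tmp_path / "s.chem"
        write_annotated_fasta([make_strand("s", "ACGT")], fa, chem)
        chem.write_text(">s\nDDD\noo\n")  # sugar line too short
        with pytest.raises(StrandError):
            read_annotated_fasta(fa, chem)

    def test_design_json_round_trip_byte_stable(self, default_design):
        text = design_to_json(default_design)
        again = design_to_json(design_from_json(text))
        assert text == again
        loaded = design_from_json(text)
        assert validate_design(loaded).passed
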