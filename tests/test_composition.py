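import random
from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from depositcomp import (
    construct_nhtt_egfp,
    get_scheme,
    mixture_composition,
    molecular_weight,
    protein_composition,
    residue_counts,
)
from depositcomp.composition import WATER_MASS, residue_mass
from depositcomp.sequence_io import CANONICAL, ProteinRecord

seq_strategy = st.text(alphabet=CANONICAL, min_size=1, max_size=120)


class TestResidueCounts:
    @pytest.mark.parametrize(
        "seq,expected", [("QQQ", {"Q": 3}), ("QEQE", {"Q": 2, "E": 2})]
    )
    def test_simple(self, record, seq, expected):
        assert residue_counts(record(seq)) == expected

    def test_random_sequence_matches_tally_oracle(self, record):
        rng = random.Random(7)
        seq = "".join(rng.choice(CANONICAL) for _ in range(60))
        assert residue_counts(record(seq)) == dict(Counter(seq))

    def test_x_excluded_u_counts_as_cys(self, record):
        counts = residue_counts(record("XXUG"))
        assert counts == {"C": 1, "G": 1}


class TestProteinComposition:
    def test_intact_homopolymer(self, record, intact):
        comp = protein_composition(record("QQQ"), intact)
        assert comp["Q"] == pytest.approx(1.0)
        assert comp.n_residues == 3

    def test_pooling_under_hcl(self, record, hcl):
        assert protein_composition(record("QQEE"), hcl)["Glx"] == pytest.approx(1.0)

    def test_trp_lost_under_hcl_only(self, record, hcl, msa):
        assert protein_composition(record("WGGG"), hcl)["Gly"] == pytest.approx(1.0)
        comp = protein_composition(record("WGGG"), msa)
        assert comp["Trp"] == pytest.approx(0.25)
        assert comp["Gly"] == pytest.approx(0.75)

    def test_all_trp_under_hcl_is_error(self, record, hcl):
        with pytest.raises(ValueError, match="no recoverable residues"):
            protein_composition(record("WWW"), hcl)

    def test_ambiguity_codes_feed_pooled_channels(self, record, hcl):
        comp = protein_composition(record("BZ"), hcl)
        assert comp["Asx"] == pytest.approx(0.5)
        assert comp["Glx"] == pytest.approx(0.5)

    @given(seq=seq_strategy)
    @settings(max_examples=60, deadline=None)
    def test_fractions_sum_to_one(self, seq, msa):
        comp = protein_composition(ProteinRecord(id="h", sequence=seq), msa)
        assert sum(comp.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    @given(seq=st.text(alphabet=CANONICAL.replace("W", ""), min_size=1, max_size=120))
    @settings(max_examples=60, deadline=None)
    def test_pooling_conservation(self, seq):
        """For W-free sequences Glx under hcl equals Q+E under intact, Asx equals N+D."""
        rec = ProteinRecord(id="h", sequence=seq)
        pooled = protein_composition(rec, get_scheme("hcl"))
        flat = protein_composition(rec, get_scheme("intact"))
        assert pooled["Glx"] == pytest.approx(flat["Q"] + flat["E"], abs=1e-12)
        assert pooled["Asx"] == pytest.approx(flat["N"] + flat["D"], abs=1e-12)

    @given(
        seq=st.text(
            alphabet="ACFGHIKLMPRSTVY",  # no W, N, D, Q, E
            min_size=1,
            max_size=80,
        )
    )
    @settings(max_examples=40, deadline=None)
    def test_hcl_and_msa_agree_without_pooled_or_trp_residues(self, seq):
        rec = ProteinRecord(id="h", sequence=seq)
        a = protein_composition(rec, get_scheme("hcl"))
        b = protein_composition(rec, get_scheme("msa"))
        assert a.fractions == b.fractions

    def test_zero_recovery_removes_channel_and_scales_rest(self, record):
        base = get_scheme("msa")
        knocked = get_scheme("msa", recovery_overrides={"S": 0.0})
        rec = record("SSGGAAVV")
        comp0 = protein_composition(rec, base)
        comp1 = protein_composition(rec, knocked)
        assert comp1["Ser"] == 0.0
        factor = 1.0 / (1.0 - comp0["Ser"])
        for ch in base.channels:
            if ch != "Ser" and comp0[ch] > 0:
                assert comp1[ch] / comp0[ch] == pytest.approx(factor)


class TestMixtureComposition:
    def test_single_component_equals_protein_composition(self, record, intact):
        rec = record("SSGA")
        mix = mixture_composition([(rec, 1.0)], intact)
        assert mix.fractions == protein_composition(rec, intact).fractions

    def test_equal_molar_equal_length_is_mean(self, record, intact):
        a, b = record("SSSS", id="a"), record("GGGG", id="b")
        mix = mixture_composition([(a, 1.0), (b, 1.0)], intact)
        assert mix["S"] == pytest.approx(0.5)
        assert mix["G"] == pytest.approx(0.5)

    def test_hand_counted_unequal_lengths(self, record, intact):
        mix = mixture_composition(
            [(record("SS", id="a"), 1.0), (record("GGGG", id="b"), 1.0)], intact
        )
        assert mix["S"] == pytest.approx(2 / 6)
        assert mix["G"] == pytest.approx(4 / 6)

    @pytest.mark.parametrize("mode", ["molar_chain", "mass"])
    def test_all_weight_on_one_component(self, record, intact, mode):
        a, b = record("SSSS", id="a"), record("GAGA", id="b")
        mix = mixture_composition([(a, 1.0), (b, 0.0)], intact, weight_mode=mode)
        assert mix.fractions == protein_composition(a, intact).fractions

    def test_modes_agree_for_equal_chain_mass(self, record, intact):
        # L and I are isomers: identical chain masses, different channels
        a, b = record("LLLL", id="a"), record("IIII", id="b")
        molar = mixture_composition([(a, 1.0), (b, 3.0)], intact, "molar_chain")
        mass = mixture_composition([(a, 1.0), (b, 3.0)], intact, "mass")
        for ch in intact.channels:
            assert molar[ch] == pytest.approx(mass[ch], abs=1e-12)

    def test_empty_component_list_is_error(self, intact):
        with pytest.raises(ValueError, match="empty component list"):
            mixture_composition([], intact)


class TestMolecularWeight:
    def test_free_masses_of_gln_glu_nearly_equal(self):
        # the pooled-channel rationale: deamidation swaps Q for E at ~1 Da
        assert abs(molecular_weight("Q") - molecular_weight("E")) < 1.1

    def test_chain_mode_matches_elemental_oracle(self, record):
        # di-glycine: C4H8N2O3 = 132.118 with IUPAC 2021 atomic weights
        expected = 4 * 12.011 + 8 * 1.008 + 2 * 14.007 + 3 * 15.999
        assert molecular_weight(record("GG"), mode="chain") == pytest.approx(
            expected, abs=1e-9
        )

    def test_chain_mass_consistent_with_biopython(self, record):
        from Bio.SeqUtils import molecular_weight as bp_mw

        seq = "MKQVLISSGAW"
        ours = molecular_weight(record(seq), mode="chain")
        # Biopython uses a slightly different atomic-weight table
        assert ours == pytest.approx(bp_mw(seq, seq_type="protein"), abs=0.05)

    def test_ambiguity_codes_have_no_mass(self, record):
        with pytest.raises(ValueError, match="no defined mass"):
            molecular_weight(record("MBK"), mode="chain")

    def test_free_is_residue_plus_water(self):
        assert molecular_weight("G") == pytest.approx(
            residue_mass("G") + WATER_MASS, abs=1e-12
        )


class TestConstruct:
    def test_tract_arithmetic(self):
        c190 = construct_nhtt_egfp(190)
        c21 = construct_nhtt_egfp(21)
        assert len(c190) - len(c21) == 169

    def test_contains_exact_polyq_run(self):
        seq = construct_nhtt_egfp(190).sequence
        assert "Q" * 190 in seq
        assert "Q" * 191 not in seq

    def test_non_tract_sequence_shared_between_lengths(self):
        c5 = construct_nhtt_egfp(5).sequence
        c9 = construct_nhtt_egfp(9).sequence
        assert c5.replace("Q" * 5, "@", 1) == c9.replace("Q" * 9, "@", 1)

    def test_invalid_length(self):
        with pytest.raises(ValueError):
            construct_nhtt_egfp(0)
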