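import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wrkycensus.features import (
    ScanConfig,
    dedup_sequences,
    domain_summary,
    find_harf,
    find_heptapeptides,
    find_zinc_fingers,
    scan_domains,
)
from wrkycensus.physchem import (
    isoelectric_point,
    molecular_weight,
    net_charge,
)
from wrkycensus.records import ProteinRecord, SequenceSet

# building blocks for constructed proteins; filler avoids motif letters
FIL = "A"
C2H2 = "C" + FIL * 4 + "C" + FIL * 23 + "H" + FIL + "H"
C2HC = "C" + FIL * 7 + "C" + FIL * 23 + "H" + FIL + "C"


def protein(seq, pid="p"):
    return ProteinRecord(pid, seq)


class TestHeptapeptide:
    @pytest.mark.parametrize(
        "motif,variant",
        [
            ("WRKYGQK", "WRKYGQK"),
            ("WRKYGEK", "WRKYGEK"),
            ("WRKYGKK", "WRKYGKK"),
            ("WRKYGSK", "WRKYGSK"),
            ("WRKSGQR", "WRKSGQR"),
        ],
    )
    def test_named_variants_are_admitted_and_classified(self, motif, variant):
        hits = find_heptapeptides(protein(FIL * 5 + motif + FIL * 5))
        assert [h.motif for h in hits] == [motif]
        assert hits[0].variant_class == variant
        assert hits[0].position == 6

    def test_canonical_motif_has_zero_hamming(self):
        (hit,) = find_heptapeptides(protein("WRKYGQK"))
        assert hit.hamming_to_canonical == 0 and hit.is_canonical

    def test_wrk_prefix_with_two_mismatches_is_other(self):
        (hit,) = find_heptapeptides(protein(FIL + "WRKAGQA" + FIL))
        assert hit.variant_class == "other"
        assert hit.hamming_to_canonical == 2

    def test_broken_prefix_is_rejected(self):
        assert find_heptapeptides(protein("ARKYGQK")) == []
        assert find_heptapeptides(protein("AAAA")) == []

    def test_mismatch_budget_is_respected(self):
        seq = FIL + "WRKAGQA" + FIL  # hamming 2
        assert find_heptapeptides(protein(seq), max_mismatch=1) == []
        assert len(find_heptapeptides(protein(seq), max_mismatch=2)) == 1

    def test_max_mismatch_out_of_range(self):
        with pytest.raises(ValueError):
            find_heptapeptides(protein("WRKYGQK"), max_mismatch=3)


class TestZincFinger:
    def test_c2h2_with_spacers_4_23(self):
        seq = FIL * 10 + C2H2 + FIL * 10
        (hit,) = find_zinc_fingers(protein(seq))
        assert hit.finger_type == "C2H2"
        assert hit.spacer_lengths == (4, 23)
        assert hit.position == 11

    def test_c2hc_with_spacer_7(self):
        seq = FIL * 3 + C2HC + FIL * 3
        (hit,) = find_zinc_fingers(protein(seq))
        assert hit.finger_type == "C2HC"
        assert hit.spacer_lengths == (7, 23)

    def test_search_start_skips_upstream_matches(self):
        seq = C2H2 + FIL * 5 + C2H2
        all_hits = find_zinc_fingers(protein(seq))
        assert len(all_hits) == 2
        later = find_zinc_fingers(protein(seq), search_start=2)
        assert [h.position for h in later] == [all_hits[1].position]

    def test_polyalanine_has_no_fingers(self):
        assert find_zinc_fingers(protein(FIL * 80)) == []


class TestScanDomains:
    def test_single_domain_pairing(self):
        seq = FIL * 5 + "WRKYGQK" + FIL * 8 + C2H2 + FIL * 5
        (domain,) = scan_domains(protein(seq))
        assert domain.finger_type == "C2H2"
        assert domain.heptapeptide.position == 6

    def test_two_domains_counted(self):
        unit = "WRKYGQK" + FIL * 8 + C2H2
        seq = FIL * 4 + unit + FIL * 20 + unit + FIL * 4
        domains = scan_domains(protein(seq))
        assert len(domains) == 2
        assert domain_summary(domains)[:2] == (2, "C2H2")

    def test_linker_budget_excludes_distant_finger(self):
        seq = FIL * 2 + "WRKYGQK" + FIL * 60 + C2H2
        assert scan_domains(protein(seq)) == []
        assert len(scan_domains(protein(seq), ScanConfig(linker_max=60))) == 1

    def test_unpaired_parts_are_not_domains(self):
        assert scan_domains(protein(FIL * 4 + "WRKYGQK" + FIL * 4)) == []
        assert scan_domains(protein(FIL * 4 + C2HC + FIL * 4)) == []
        assert scan_domains(protein(FIL * 60)) == []

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(shift=st.integers(min_value=0, max_value=40))
    def test_shift_equivariance(self, shift):
        core = "WRKYGQK" + FIL * 8 + C2HC
        base = scan_domains(protein(FIL * 2 + core))
        moved = scan_domains(protein(FIL * (2 + shift) + core))
        assert len(base) == len(moved) == 1
        assert (
            moved[0].heptapeptide.position
            == base[0].heptapeptide.position + shift
        )
        assert (
            moved[0].zinc_finger.position
            == base[0].zinc_finger.position + shift
        )


class TestHarf:
    @pytest.mark.parametrize("motif", ["RTGHARFRRAP", "RTGHARFRRGP"])
    def test_both_harf_forms_found(self, motif):
        assert find_harf(protein(FIL * 6 + motif + FIL * 6)) == [7]

    def test_absent_harf(self):
        assert find_harf(protein(FIL * 30)) == []


class TestPhysChem:
    def test_free_glycine_mass(self):
        assert molecular_weight(protein("G")) == pytest.approx(0.07507, abs=1e-4)

    def test_diglycine_mass_matches_hand_sum(self):
        # 2 x 57.052 residue mass + 18.015 water
        assert molecular_weight(protein("GG")) == pytest.approx(0.13212, abs=1e-4)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        a=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=12),
        b=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=12),
    )
    def test_mass_additivity(self, a, b):
        water = 0.0180153
        lhs = molecular_weight(protein(a + b))
        rhs = molecular_weight(protein(a)) + molecular_weight(protein(b)) - water
        assert lhs == pytest.approx(rhs, abs=1e-6)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seq=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30))
    def test_pi_root_property_and_arginine_monotonicity(self, seq):
        pi = isoelectric_point(ProteinRecord("q", seq))
        assert abs(net_charge(seq, pi)) < 1e-4
        assert isoelectric_point(ProteinRecord("qr", seq + "R")) >= pi

    def test_acidic_protein_has_low_pi_basic_high(self):
        assert isoelectric_point(protein("DDEEDDEE")) < 5.0
        assert isoelectric_point(protein("KKRRKKRR")) > 9.0


class TestDedup:
    def test_identical_records_collapse(self):
        seqs = SequenceSet(
            [protein("MKVLWRAGA" * 10, "a"), protein("MKVLWRAGA" * 10, "b")],
            "protein",
        )
        assert dedup_sequences(seqs).ids == ["a"]

    def test_unrelated_records_survive(self):
        seqs = SequenceSet(
            [protein("MKVLWR" * 15, "a"), protein("DDEEPPTTGG" * 9, "b")],
            "protein",
        )
        assert dedup_sequences(seqs, 0.95).ids == ["a", "b"]

    def test_single_substitution_in_100_is_redundant(self):
        base = ("ACDEFGHIKLMNPQRSTVWY" * 5)[:100]
        variant = "W" + base[1:]
        seqs = SequenceSet(
            [protein(base, "a"), protein(variant, "b")], "protein"
        )
        # identity 0.99 >= 0.95: one representative, input order kept
        assert dedup_sequences(seqs, 0.95).ids == ["a"]

    def test_threshold_validation(self):
        seqs = SequenceSet([protein("MKV", "a")], "protein")
        with pytest.raises(ValueError):
            dedup_sequences(seqs, 0.4)
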