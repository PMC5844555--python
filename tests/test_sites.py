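import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirseed import sites
from mirseed.io import SequenceRecord
from conftest import LET7
from oracles import (
    oracle_canonical,
    oracle_centered,
    oracle_gbulge,
    oracle_mismatch,
    oracle_offset6,
    oracle_supp3p,
    rc,
)

rna = st.text(alphabet="ACGU", min_size=0, max_size=60)


def classes(found):
    return {(s.site_class, s.start, s.end) for s in found}


class TestReverseComplement:
    def test_hand_example(self):
        assert sites.reverse_complement("GAGGUA") == "UACCUC"

    def test_empty(self):
        assert sites.reverse_complement("") == ""

    @given(rna)
    @settings(deadline=None)
    def test_involution(self, s):
        assert sites.reverse_complement(sites.reverse_complement(s)) == s


class TestCanonical:
    def test_8mer_with_a1_and_m8(self):
        assert classes(sites.scan_canonical(LET7, "AAAACUACCUCAAAA")) == {("8mer", 5, 12)}

    def test_6mer_when_m8_and_a1_absent(self):
        assert classes(sites.scan_canonical(LET7, "GGGUACCUCGGG")) == {("6mer", 4, 9)}

    def test_7mer_m8_guarded_against_a1(self):
        # m8 target C before seed match, non-A after
        assert classes(sites.scan_canonical(LET7, "GGCUACCUCGGG")) == {("7mer-m8", 3, 9)}

    def test_7mer_a1_requires_adenosine_not_nt1_match(self):
        # A opposite nt1 even though let-7a nt1 is U (WC partner would be A anyway);
        # use a miRNA whose nt1 is G to make the distinction sharp
        mir = "GGAGGUAGUAGGUUGUAUAGUU"  # nt2-7 unchanged, nt1=G
        assert classes(sites.scan_canonical(mir, "GGGUACCUCAGG")) == {("7mer-A1", 4, 10)}
        # WC partner of nt1 (C) does not make a 7mer-A1
        assert classes(sites.scan_canonical(mir, "GGGUACCUCCGG")) == {("6mer", 4, 9)}

    def test_no_seed_match_no_sites(self):
        assert sites.scan_canonical(LET7, "GGGGGGGGGGGG") == []


class TestOffset6:
    def test_detected_with_nt2_mismatch(self):
        assert classes(sites.scan_offset6(LET7, "AACUACCUAA")) == {("offset6", 3, 8)}

    def test_excluded_when_locus_canonical(self):
        assert sites.scan_offset6(LET7, "AACUACCUCAA") == []

    def test_empty_utr(self):
        assert sites.scan_offset6(LET7, "A") == []


class TestMismatchWobble:
    def test_gu_wobble_at_position_2(self):
        (s,) = sites.scan_mismatch_wobble(LET7, "AAUACCUUAA")
        assert (s.site_class, s.start, s.end, s.mismatch_pos) == ("gu_wobble", 3, 8, 2)

    def test_two_mismatches_rejected(self):
        # window UACGAC vs perfect UACCUC: non-WC at seed positions 3 and 4
        found = sites.scan_mismatch_wobble(LET7, "AAUACGACAA")
        assert all(not (s.start == 3 and s.end == 8) for s in found)

    def test_perfect_seed_not_a_mismatch_site(self):
        found = sites.scan_mismatch_wobble(LET7, "AAUACCUCAA")
        assert all(not (s.start == 3 and s.end == 8) for s in found) or found == []


class TestGBulge:
    def test_single_bulged_g(self):
        assert classes(sites.scan_gbulge(LET7, "AAUAGCCUCAA")) == {("gbulge", 3, 9)}

    def test_no_extra_g_no_site(self):
        assert sites.scan_gbulge(LET7, "AAUACCUCAA") == []

    def test_g_run_counts_once(self):
        # miRNA nt6=C → seed target UGCCUC; bulged pattern UG G CCUC has a
        # G run across the insertion point but is still one window, one site
        mir = "UGAGGCAGUAGGUUGUAUAGUU"
        assert rc(mir[1:7]) == "UGCCUC"
        found = sites.scan_gbulge(mir, "AAUGGCCUCAA")
        assert classes(found) == {("gbulge", 3, 9)}


class TestCentered:
    def test_eleven_central_pairs(self):
        assert classes(sites.scan_centered(LET7, "GGAACCUACUACCGG")) == \
            {("centered", 3, 13)}

    def test_ten_pairs_insufficient(self):
        # break the pairing to nt 14 (and 15) so only nt 4-13 can pair
        utr = "GGACCUACUACCGG"
        assert all(s.site_class != "centered" for s in sites.scan_centered(LET7, utr))

    def test_canonical_register_excluded(self):
        full = rc(LET7)  # perfect full-length complement includes the seed
        assert sites.scan_centered(LET7, full) == []

    def test_short_mirna_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert sites.scan_centered("UGAGGUAGUAGGUU", "AAAA") == []


class TestThreePrimePairing:
    UTR_SUPP = "AAACAAGGGGGUACCUCAAA"  # ACAA at positions 3-6 pairs nt 16-13

    def test_supplementary_detected(self):
        (site,) = sites.scan_canonical(LET7, self.UTR_SUPP)
        flagged = sites.flag_3prime_pairing(site, LET7, self.UTR_SUPP)
        assert flagged.supp3p and not flagged.comp3p  # comp3p: mismatch sites only

    def test_truncation_at_utr_start_is_false(self):
        utr = "UACCUCAAA"  # site at position 1, nothing 5' of it
        (site,) = sites.scan_canonical(LET7, utr)
        assert site.start == 1
        assert not sites.flag_3prime_pairing(site, LET7, utr).supp3p

    def test_two_contiguous_pairs_insufficient(self):
        # pair nt 13-14 only (target AA), break nt 15-16
        utr = "AAAUUAAGGGGUACCUCAAA"
        (site,) = sites.scan_canonical(LET7, utr)
        assert not sites.flag_3prime_pairing(site, LET7, utr).supp3p

    def test_compensatory_on_wobble_site(self):
        # wobble seed (gu at nt2) plus 4 pairs at nt 12-17 upstream
        # nt 12..17 of let-7a = G,U,U,G,U,A → target complement UACAAC
        utr = "AAAUACAACGGGGUACCUUAA"
        found = [s for s in sites.scan_mismatch_wobble(LET7, utr)
                 if s.site_class == "gu_wobble"]
        flagged = [sites.flag_3prime_pairing(s, LET7, utr) for s in found]
        assert any(s.comp3p for s in flagged)


class TestOracleAgreement:
    """Every scanner equals a brute-force window-enumeration oracle."""

    @pytest.mark.parametrize("seed", range(4))
    def test_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(60):
            mir = "".join("ACGU"[i] for i in rng.integers(0, 4, 22))
            utr = "".join("ACGU"[i] for i in rng.integers(0, 4, 200))
            assert classes(sites.scan_canonical(mir, utr)) == oracle_canonical(mir, utr)
            assert classes(sites.scan_offset6(mir, utr)) == oracle_offset6(mir, utr)
            assert {(s.site_class, s.start, s.end, s.mismatch_pos)
                    for s in sites.scan_mismatch_wobble(mir, utr)} == \
                oracle_mismatch(mir, utr)
            assert classes(sites.scan_gbulge(mir, utr)) == oracle_gbulge(mir, utr)
            assert classes(sites.scan_centered(mir, utr)) == oracle_centered(mir, utr)
            for s in sites.scan_pair(mir, utr):
                assert s.supp3p == oracle_supp3p(mir, utr, s.register)

    def test_case_and_ut_representation_invariance(self):
        variants = ["aaaacuaccucaaaa", "AAAACTACCTCAAAA", "aaaaCUACcucAAAA"]
        expected = classes(sites.scan_pair(LET7, "AAAACUACCUCAAAA"))
        for v in variants:
            assert classes(sites.scan_pair(LET7.replace("U", "t"), v)) == expected

    def test_coordinates_are_utr_substring_spans(self, rng):
        mir = "".join("ACGU"[i] for i in rng.integers(0, 4, 22))
        utr = "".join("ACGU"[i] for i in rng.integers(0, 4, 300))
        for s in sites.scan_pair(mir, utr):
            assert 1 <= s.start <= s.end <= len(utr)
            window = utr[s.start - 1 : s.end]
            if s.site_class == "6mer":
                assert window == rc(mir[1:7])
            elif s.site_class == "8mer":
                assert window == rc(mir[1:8]) + "A"
            elif s.site_class == "gbulge":
                p = rc(mir[1:7])
                assert window == p[:2] + "G" + p[2:]


class TestCombinationAnnotation:
    def test_composition_of_multiple_sites(self):
        utr = "AAAACUACCUCAAAAGGGUACCUCGGG"  # one 8mer + one 6mer
        ann = sites.annotate_combination(LET7, utr)
        assert ann["n_8mer"] == 1 and ann["n_6mer"] == 1
        assert ann["any_canonical"] and ann["multiple_canonical"]
        assert ann["n_canonical"] == 2

    def test_no_sites_all_counts_zero(self):
        ann = sites.annotate_combination(LET7, "GGGGGGGG")
        assert not ann["any_canonical"]
        assert ann["n_canonical"] == 0
        assert all(ann[f"n_{c}"] == 0 for c in
                   ("8mer", "7mer_m8", "7mer_a1", "6mer", "offset6", "gbulge"))

    def test_canonical_counts_sum_to_total(self, rng):
        """Site-level canonical classes are exclusive and exhaustive."""
        for _ in range(30):
            mir = "".join("ACGU"[i] for i in rng.integers(0, 4, 22))
            utr = "".join("ACGU"[i] for i in rng.integers(0, 4, 400))
            ann = sites.annotate_combination(mir, utr)
            assert (ann["n_8mer"] + ann["n_7mer_m8"] + ann["n_7mer_a1"]
                    + ann["n_6mer"]) == ann["n_canonical"]

    def test_generator_truth_matches_scanner(self):
        from mirseed import generate_sequence_fixtures

        mirnas, utrs, truth = generate_sequence_fixtures(
            5, 20, 120, implant_spec=[("8mer", 1), ("offset6", 1)], rng_seed=7
        )
        for m, u in zip([mirnas[j % 5] for j in range(20)], utrs):
            found = sites.scan_pair(m, u, classes=("8mer", "offset6"))
            expected = truth[(truth["mirna"] == m.id) & (truth["utr"] == u.id)]
            assert {(s.site_class, s.start, s.end) for s in found} == \
                set(map(tuple, expected[["site_class", "start", "end"]].values))


class TestExports:
    def test_site_frame_and_bed_conversion(self):
        found = sites.scan_pair(
            SequenceRecord("let7", LET7, "miRNA"),
            SequenceRecord("U1", "AAAACUACCUCAAAA", "UTR"),
        )
        frame = sites.sites_to_frame(found)
        bed = sites.sites_to_bed(found)
        row = frame.loc[frame["site_class"] == "8mer"].iloc[0]
        bed_row = bed.loc[bed["name"].str.contains("8mer")].iloc[0]
        assert (row["start"], row["end"]) == (5, 12)
        assert (bed_row["start"], bed_row["end"]) == (4, 12)  # 0-based half-open
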