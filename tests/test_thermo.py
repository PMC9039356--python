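"""Thermodynamic core: duplex Tm, wristwatch duplexes, site scanning,
structure screens."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_sites, nn_oracle_tm, random_dna
from wwpcr import (
    DegenerateBaseError,
    MaskError,
    SequenceTooShortError,
    ThermoModel,
    scan_annealing_sites,
    structure_screens,
    tm_perfect_duplex,
    tm_wristwatch_duplex,
)
from wwpcr.thermo import revcomp

dna = st.text(alphabet="ACGT", min_size=8, max_size=40)


class TestPerfectDuplexTm:
    @pytest.mark.parametrize("seq", [
        "ACGTACGTACGTACGTACGT",
        "CGTCTCCAGTCTCCATGTGTTCGTC",
        "CGTCTCCAGTCTTAGGCACAGTGTC",
        "TCCATACCCTCATCTCCATTTCCAT",
        "AAAATTTTAAAATTTT",
        "GCGCGCGCGCGC",
    ])
    def test_matches_hand_summed_oracle(self, seq, model):
        assert tm_perfect_duplex(seq, model) == pytest.approx(
            nn_oracle_tm(seq), abs=0.1)

    def test_matches_biopython_reference(self, model, wwps):
        mt = pytest.importorskip("Bio.SeqUtils.MeltingTemp")
        for p in wwps:
            ref = mt.Tm_NN(p.sequence, nn_table=mt.DNA_NN3, Na=50,
                           dnac1=200, dnac2=0, saltcorr=5)
            assert tm_perfect_duplex(p.sequence, model) == pytest.approx(
                ref, abs=0.05)

    def test_published_wwps_melt_in_60_65_window(self, model, wwps):
        for p in wwps:
            assert 60.0 <= tm_perfect_duplex(p.sequence, model) <= 65.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(seq=dna)
    def test_strand_symmetry(self, seq):
        model = ThermoModel()
        assert tm_perfect_duplex(seq, model) == pytest.approx(
            tm_perfect_duplex(revcomp(seq), model), abs=1e-6)

    def test_too_short_sequence_rejected(self, model):
        with pytest.raises(SequenceTooShortError):
            tm_perfect_duplex("ACGT", model)

    def test_degenerate_base_rejected_with_distinct_error(self, model):
        with pytest.raises(DegenerateBaseError):
            tm_perfect_duplex("ACGTNACGTACG", model)


class TestWristwatchDuplexTm:
    def test_full_mask_equals_perfect_duplex(self, model, wwps):
        for p in wwps:
            full = [True] * len(p.sequence)
            assert tm_wristwatch_duplex(
                p.sequence, revcomp(p.sequence), full, model
            ) == pytest.approx(tm_perfect_duplex(p.sequence, model), abs=1e-9)

    def test_wristwatch_pairs_melt_near_40(self, model, wwps):
        # 12-nt prefix + 3-nt suffix paired, 10-nt spacer looped out
        mask = [True] * 12 + [False] * 10 + [True] * 3
        for a in wwps:
            for b in wwps:
                if a is b:
                    continue
                tm = tm_wristwatch_duplex(a.sequence, revcomp(b.sequence),
                                          mask, model)
                assert 33.0 <= tm <= 47.0

    def test_suffix_only_mask_far_below_bipartite(self, model, wwps):
        ww_mask = [True] * 12 + [False] * 10 + [True] * 3
        sfx_mask = [False] * 22 + [True] * 3
        a, b = wwps[0], wwps[1]
        ww = tm_wristwatch_duplex(a.sequence, revcomp(b.sequence), ww_mask, model)
        sfx = tm_wristwatch_duplex(a.sequence, revcomp(b.sequence), sfx_mask, model)
        assert sfx < ww

    def test_noncomplementary_pairing_rejected(self, model, wwps):
        a, b = wwps[0], wwps[1]
        # full mask pairs the mismatched spacers -> must be rejected
        with pytest.raises(MaskError):
            tm_wristwatch_duplex(a.sequence, revcomp(b.sequence),
                                 [True] * 25, model)

    def test_empty_and_unanchored_masks_rejected(self, model, wwps):
        s = wwps[0].sequence
        with pytest.raises(MaskError):
            tm_wristwatch_duplex(s, revcomp(s), [False] * 25, model)
        with pytest.raises(MaskError):
            tm_wristwatch_duplex(s, revcomp(s), [True] * 24 + [False], model)


class TestAnnealingSiteScan:
    def test_planted_perfect_site_found_exactly_once(self, model, wwps):
        rng = np.random.default_rng(11)
        t = random_dna(rng, 2000)
        planted = t[:1200] + revcomp(wwps[0].sequence) + t[1200:]
        sites = scan_annealing_sites(wwps[0].sequence, planted, 65.0, model)
        assert [s.three_prime_pos for s in sites] == [1200]
        assert sites[0].terminal_match_run == 25
        assert sites[0].duplex_tm == pytest.approx(
            tm_perfect_duplex(wwps[0].sequence, model))

    def test_unrelated_primer_finds_nothing_at_high_stringency(self, model):
        rng = np.random.default_rng(12)
        template = random_dna(rng, 2000)
        primer = random_dna(rng, 25)
        assert scan_annealing_sites(primer, template, 65.0, model) == []

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_offset_oracle(self, seed, model, wwps):
        rng = np.random.default_rng(seed)
        template = random_dna(rng, 3000)
        for temp in (25.0, 40.0):
            sites = scan_annealing_sites(wwps[0].sequence, template, temp,
                                         model)
            oracle = brute_force_sites(wwps[0].sequence, template, temp, model)
            assert [(s.three_prime_pos, pytest.approx(s.duplex_tm))
                    for s in sites] == oracle

    def test_higher_temperature_returns_subset(self, model, wwps):
        rng = np.random.default_rng(13)
        template = random_dna(rng, 5000)
        low = {s.three_prime_pos
               for s in scan_annealing_sites(wwps[0].sequence, template, 25.0,
                                             model)}
        high = {s.three_prime_pos
                for s in scan_annealing_sites(wwps[0].sequence, template, 40.0,
                                              model)}
        assert high <= low

    def test_sites_sorted_by_coordinate(self, model, wwps):
        rng = np.random.default_rng(14)
        template = random_dna(rng, 5000)
        pos = [s.three_prime_pos
               for s in scan_annealing_sites(wwps[0].sequence, template, 25.0,
                                             model)]
        assert pos == sorted(pos)

    def test_template_shorter_than_primer_rejected(self, model, wwps):
        with pytest.raises(SequenceTooShortError):
            scan_annealing_sites(wwps[0].sequence, "ACGTACGT", 25.0, model)


class TestStructureScreens:
    def test_perfect_palindrome_raises_self_dimer_flag(self):
        rep = structure_screens("ACGTACGAATTCGAATTCACGTAC")
        assert rep.self_dimer_run >= 12
        assert not rep.self_dimer_ok

    def test_published_primer_pairs_are_dimer_free(self, wwps, gada_gsps):
        for w in wwps:
            for g in gada_gsps:
                assert structure_screens(w.sequence, g.sequence).cross_dimer_ok

    def test_reverse_complement_gives_full_length_cross_dimer(self, wwps):
        s = wwps[0].sequence
        rep = structure_screens(s, revcomp(s))
        assert rep.cross_dimer_run == len(s)

    def test_hairpin_stem_detected(self):
        # 8-bp stem around a 4-nt loop
        stem = "GCATCGGC"
        rep = structure_screens(stem + "TTTT" + revcomp(stem))
        assert rep.hairpin_stem >= 8
        assert not rep.hairpin_ok
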