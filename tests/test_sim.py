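"""Walking-PCR simulator: staged rounds, product classification, bands."""

import numpy as np
import pytest

from conftest import random_dna
from wwpcr import (
    CyclingProfile,
    ProfileError,
    SimulationError,
    SpeciesRecord,
    classify_species,
    predict_band_pattern,
    simulate_round,
    simulate_walk,
    species_sequence,
)
from wwpcr.thermo import revcomp


class TestCyclingProfile:
    def test_defaults_match_published_protocol(self):
        primary = CyclingProfile.primary()
        secondary = CyclingProfile.secondary()
        assert primary.stage1 == (65.0, 5)
        assert primary.stage2 == (25.0, 1)
        assert primary.stage3 == (65.0, 25)
        assert secondary.stage2 == (40.0, 1)
        assert primary.extension_cap_nt == 4000

    def test_multiple_partial_annealing_cycles_rejected(self):
        with pytest.raises(ProfileError, match="once only"):
            CyclingProfile(stage2=(25.0, 2))

    def test_stage2_may_not_be_hotter_than_flanking_stages(self):
        with pytest.raises(ProfileError):
            CyclingProfile(stage1=(40.0, 5), stage2=(65.0, 1))


class TestSimulateRound:
    def test_round1_exponentials_are_gsp_wwp_defined(self, walk_case):
        fx, result = walk_case
        for sp in result.rounds[0]:
            if sp.amplification_class != "exponential":
                continue
            names = {sp.five_prime_primer, sp.three_prime_primer}
            assert fx.gsps[0].name in names
            assert fx.permutation[0].name in names

    def test_genome_without_gsp_site_yields_no_exponential(self, wwps, model):
        rng = np.random.default_rng(31)
        genome = random_dna(rng, 5000)
        gsp = None
        from wwpcr import PrimerRecord
        while gsp is None:
            cand = random_dna(rng, 25)
            if genome.find(cand) < 0 and genome.find(revcomp(cand)) < 0:
                gsp = PrimerRecord("GSPx", cand, "GSP", 1)
        pool = [SpeciesRecord("g", "+", 0, len(genome)),
                SpeciesRecord("g", "-", 0, len(genome))]
        out = simulate_round(pool, gsp, wwps[0], None,
                             CyclingProfile.primary(), model, genome,
                             {wwps[0].name: wwps[0].sequence})
        assert all(sp.amplification_class != "exponential" for sp in out)

    def test_wristwatch_products_map_onto_round1_wwp_termini(self, walk_case):
        """Each second-round tail product re-docks on a first-round walking
        primer 5' terminus, and every reachable terminus is re-docked."""
        fx, result = walk_case
        gsp2 = fx.gsps[1]
        a2, b2 = fx.gsp_footprints[gsp2.name]
        cap = fx.profiles[1].extension_cap_nt
        wwp1 = fx.permutation[0].name
        tails = {sp.end for sp in result.rounds[1]
                 if sp.five_prime_primer == gsp2.name
                 and sp.three_prime_primer == wwp1 and sp.strand == "+"}
        reachable = {sp.end for sp in result.rounds[0]
                     if sp.five_prime_primer == wwp1 and sp.strand == "-"
                     and sp.start <= a2 and b2 < sp.end
                     and sp.end - b2 <= cap}
        assert tails == reachable
        assert tails, "fixture should produce at least one wristwatch event"


class TestClassifySpecies:
    @pytest.fixture()
    def primers(self, wwps, gada_gsps):
        return {p.name: p for p in wwps + gada_gsps}

    def test_wwp_at_both_ends_is_type_iii(self, primers):
        sp = SpeciesRecord("g", "-", 100, 900, "WWP2", 25, "WWP1", 25,
                           "primer_site")
        assert classify_species(sp, {"gadAGSP1": (0, 25)}, primers) == "typeIII"

    def test_gsp_at_authentic_locus_plus_wwp_is_target(self, primers):
        sp = SpeciesRecord("g", "+", 100, 900, "gadAGSP1", 25, "WWP1", 25,
                           "primer_site")
        assert classify_species(sp, {"gadAGSP1": (100, 125)}, primers) == "target"

    def test_gsp_at_decoy_locus_plus_wwp_is_type_ii(self, primers):
        sp = SpeciesRecord("g", "+", 3000, 3800, "gadAGSP1", 25, "WWP1", 25,
                           "primer_site")
        assert classify_species(sp, {"gadAGSP1": (100, 125)}, primers) == "typeII"

    def test_gsp_at_both_ends_is_type_i(self, primers):
        sp = SpeciesRecord("g", "+", 100, 900, "gadAGSP1", 25, "gadAGSP2", 25,
                           "primer_site")
        assert classify_species(sp, {"gadAGSP1": (100, 125)}, primers) == "typeI"

    def test_unknown_provenance_rejected(self, primers):
        sp = SpeciesRecord("g", "+", 100, 900, "mystery", 25, "WWP1", 25,
                           "primer_site")
        with pytest.raises(SimulationError):
            classify_species(sp, {}, primers)


class TestSimulateWalk:
    def test_final_bands_read_wwp_to_gsp_complement(self, walk_case):
        """Every predicted band has a strand that starts with the tertiary
        walking primer and ends with the tertiary GSP's complement."""
        fx, result = walk_case
        assert result.final_bands
        intervals = {(sp.start, sp.end) for sp in result.final_bands}
        wwp3, gsp3 = fx.permutation[2], fx.gsps[2]
        primer_seqs = {p.name: p.sequence
                       for p in fx.gsps + list(fx.permutation)}
        for iv in intervals:
            minus = [sp for sp in result.final_bands
                     if (sp.start, sp.end) == iv and sp.strand == "-"
                     and sp.five_prime_primer == wwp3.name
                     and sp.three_prime_primer == gsp3.name]
            assert minus, f"no WWP-led strand for band {iv}"
            seq = species_sequence(minus[0], fx.genome, primer_seqs)
            assert seq.startswith(wwp3.sequence)
            assert seq.endswith(revcomp(gsp3.sequence))

    def test_type_iii_never_exponential(self, walk_case):
        _, result = walk_case
        for ledger in result.rounds:
            for sp in ledger:
                if sp.product_class == "typeIII":
                    assert sp.amplification_class != "exponential"

    def test_round3_exponential_loci_nest_within_round2(self, walk_case):
        fx, result = walk_case
        a2 = fx.gsp_footprints[fx.gsps[1].name][0]
        a3 = fx.gsp_footprints[fx.gsps[2].name][0]
        ends_r2 = {sp.end for sp in result.rounds[1]
                   if sp.amplification_class == "exponential"
                   and sp.start == a2}
        ends_r3 = {sp.end for sp in result.rounds[2]
                   if sp.amplification_class == "exponential"
                   and sp.start == a3}
        cap = fx.profiles[2].extension_cap_nt
        reachable = {w for w in ends_r2 if w - a3 <= cap + 25}
        assert ends_r3 <= ends_r2 | reachable

    def test_byte_identical_reruns(self, walk_case):
        fx, result = walk_case
        again = simulate_walk(fx.genome, fx.known_region, fx.gsps,
                              fx.permutation, fx.profiles, fx.model,
                              genome_id=fx.genome_id)
        assert again.to_json() == result.to_json()

    def test_missing_gsp_rejected(self, wwps, model):
        from wwpcr import PrimerRecord
        rng = np.random.default_rng(41)
        genome = random_dna(rng, 5000)
        fake = [PrimerRecord(f"GSP{i}", random_dna(rng, 25), "GSP", i)
                for i in (1, 2, 3)]
        with pytest.raises(SimulationError):
            simulate_walk(genome, (0, 1000), fake, wwps)


class TestBandPattern:
    def test_sizes_descending_and_capped(self, walk_case):
        fx, result = walk_case
        bands = predict_band_pattern(result)
        sizes = [b.size for b in bands]
        assert sizes == sorted(sizes, reverse=True)
        cap = fx.profiles[0].extension_cap_nt
        assert all(b.size <= cap + 25 for b in bands)

    def test_secondary_band_exceeds_tertiary_by_gsp_offset(self, walk_case):
        fx, result = walk_case
        a2 = fx.gsp_footprints[fx.gsps[1].name][0]
        a3 = fx.gsp_footprints[fx.gsps[2].name][0]
        r2 = {sp.end: sp.size for sp in result.rounds[1]
              if sp.amplification_class == "exponential" and sp.start == a2}
        r3 = {sp.end: sp.size for sp in result.rounds[2]
              if sp.amplification_class == "exponential" and sp.start == a3}
        shared = set(r2) & set(r3)
        assert shared, "no paired secondary/tertiary bands in fixture"
        for w in shared:
            assert r2[w] - r3[w] == a3 - a2

    def test_empty_result_gives_empty_pattern(self):
        from wwpcr import WalkResult
        assert predict_band_pattern(WalkResult(genome_id="g")) == []
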