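"""Seeded synthetic fixtures: genomes with planted known regions, decoy
GSP sites and independently enumerated ground-truth amplicons.

The generator emulates a right-walking experiment: a stretch of the genome
is declared "known", nested GSPs are designed from it pointing into the
flank to the right of the junction, and everything beyond the junction
plays the role of unknown sequence to be recovered.  Optional decoy sites —
near-exact copies of the outer GSP planted in the flank — exercise the
mispriming path that produces type II background.

``enumerate_truth_amplicons`` recomputes the expected tertiary bands from
scratch by chaining exhaustive stage-2 site enumerations with the reach
constraints of each round; it shares no code with the walk simulator and
serves as its oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .design import PrimerRecord, design_gsp_nest
from .errors import DesignError, WWPCRError
from .sim import CyclingProfile, default_profiles
from .thermo import ThermoModel, revcomp, scan_annealing_sites

BASES = np.array(list("ACGT"))


def make_genome(length: int, gc_fraction: float = 0.5, seed: int = 0) -> str:
    """Reproducible i.i.d. random genome with the given expected GC."""
    if length < 1000:
        raise WWPCRError("genome length must be >= 1000")
    if not (0.0 < gc_fraction < 1.0):
        raise WWPCRError("gc_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    p_at = (1.0 - gc_fraction) / 2.0
    p_gc = gc_fraction / 2.0
    draws = rng.choice(BASES, size=length, p=[p_at, p_gc, p_gc, p_at])
    return "".join(draws)


@dataclass(frozen=True)
class TruthAmplicon:
    """One ground-truth tertiary amplicon: final GSP to a walking-primer
    annealing locus."""

    five_prime_primer: str
    three_prime_primer: str
    start: int
    end: int

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass
class WalkFixture:
    """A synthetic walking experiment with known ground truth."""

    genome_id: str
    genome: str
    known_region: Tuple[int, int]
    decoy_sites: List[Tuple[int, int]]
    gsps: List[PrimerRecord]
    wwps: List[PrimerRecord]
    permutation: List[PrimerRecord]
    profiles: List[CyclingProfile]
    model: ThermoModel
    truth_amplicons: List[TruthAmplicon]
    seed: int
    gsp_footprints: Dict[str, Tuple[int, int]] = field(default_factory=dict)

    @property
    def junction(self) -> int:
        return self.known_region[1]


def enumerate_truth_amplicons(
    genome: str,
    gsp_footprints: Sequence[Tuple[int, int]],
    permutation: Sequence[PrimerRecord],
    profiles: Optional[Sequence[CyclingProfile]] = None,
    model: Optional[ThermoModel] = None,
    gsp3_name: str = "GSP3",
) -> List[TruthAmplicon]:
    """Exhaustively enumerate the tertiary target amplicons of a
    right-directed walk.

    Round by round, collects every genomic locus where the round's walking
    primer can anneal at its stage-2 stringency — on the flank copied by the
    round's GSP, or onto the previous walking primer's locus through the
    wristwatch tail — and applies the extension-reach constraints that the
    chained products must satisfy.  The surviving round-3 termini define the
    bands from the innermost GSP.
    """
    model = model or ThermoModel()
    profiles = list(profiles) if profiles is not None else default_profiles()
    g_len = len(genome)
    cap = profiles[0].extension_cap_nt
    (a1, b1), (a2, b2), (a3, b3) = gsp_footprints
    w0, w1, w2 = permutation
    lw0, lw1, lw2 = (len(p.sequence) for p in permutation)
    t_lsc = profiles[0].stage2[0]
    t_rsc2 = profiles[1].stage2[0]
    t_rsc3 = profiles[2].stage2[0]

    # Round 1: the first walking primer samples the flank copied from GSP1's
    # locus (and the genomic plus strand itself, which carries over).
    ends1 = set()
    seg = genome[a1:min(a3 + lw0 + cap, g_len)]
    for s in scan_annealing_sites(w0.sequence, seg, t_lsc, model):
        if s.three_prime_pos >= 1:
            ends1.add(a1 + s.three_prime_pos + lw0)

    def _consume(tails, gsp_start, gsp_end, wwp, temp, t3_cap=None):
        """Endpoints created when a nested GSP copies each tailed product
        up to the previous walking primer and the round's walking primer
        re-anneals — on the wristwatch tail or internally."""
        ends = set()
        for w, tail, ltail in tails:
            # the tailed product must host the GSP site, and the GSP must
            # reach the tail within one extension
            if not (gsp_end < w <= gsp_end + cap):
                continue
            if (w - ltail) - gsp_start > cap:
                continue
            text = genome[gsp_start:w - ltail] + revcomp(tail.sequence)
            for s in scan_annealing_sites(wwp.sequence, text, temp, model):
                if s.three_prime_pos >= 1 and (
                        t3_cap is None or s.three_prime_pos <= t3_cap):
                    ends.add(gsp_start + s.three_prime_pos + len(wwp.sequence))
        return ends

    # Round 2: WWP2 re-docks on WWP1 tails (wristwatch) or anneals directly
    # at its own stage-2 sites on the GSP2-copied strand.
    tails1 = [(w, w0, lw0) for w in sorted(ends1)]
    ends2 = _consume(tails1, a2, b2, w1, t_rsc2)
    seg = genome[a2:min(a3 + lw1 + cap, g_len)]
    for s in scan_annealing_sites(w1.sequence, seg, t_rsc2, model):
        if s.three_prime_pos >= 1:
            ends2.add(a2 + s.three_prime_pos + lw1)

    # Round 3: GSP3 copies round-2 tails — and round-1 tails directly, since
    # the full pool carries over and every WWP shares the wristwatch overlap.
    # The final minus-strand product must reach back to GSP3's start to
    # carry its perfect site, capping the anchor offset at one extension.
    tails = tails1 + [(w, w1, lw1) for w in sorted(ends2)]
    ends3 = _consume(tails, a3, b3, w2, t_rsc3, t3_cap=cap)
    seg = genome[a3:min(a3 + lw2 + cap, g_len)]
    for s in scan_annealing_sites(w2.sequence, seg, t_rsc3, model):
        if 1 <= s.three_prime_pos <= cap:
            ends3.add(a3 + s.three_prime_pos + lw2)

    return [
        TruthAmplicon(gsp3_name, w2.name, a3, w)
        for w in sorted(ends3)
    ]


def make_walk_fixture(
    genome_len: int = 10000,
    known_len: int = 1000,
    wwps: Optional[Sequence[PrimerRecord]] = None,
    model: Optional[ThermoModel] = None,
    seed: int = 0,
    n_decoys: int = 0,
    gc_fraction: float = 0.5,
    known_start: int = 500,
    decoy_mismatches: int = 1,
    profiles: Optional[Sequence[CyclingProfile]] = None,
    permutation_index: int = 0,
) -> WalkFixture:
    """Build a complete right-walking fixture.

    Plants a known region, designs a GSP nest from it, optionally plants
    decoy copies of GSP1 (with ``decoy_mismatches`` substitutions at the
    primer's 5'-facing end, leaving the 3' seed intact) in the unknown
    flank, and enumerates the ground-truth amplicons on the final genome.
    """
    if known_len < 200:
        raise WWPCRError("known_len must be >= 200")
    if wwps is None:
        from .io import load_published_primers
        wwps = [p for p in load_published_primers() if p.role == "WWP"]
    wwps = list(wwps)
    model = model or ThermoModel()
    profiles = list(profiles) if profiles is not None else default_profiles()
    genome = make_genome(genome_len, gc_fraction, seed)
    k0, k1 = known_start, known_start + known_len
    if k1 + 1000 > genome_len:
        raise WWPCRError("genome too short for the known region plus flank")

    # GSPs must pass the high-stringency gate even after a decoy copy loses
    # ``decoy_mismatches`` 5'-terminal base pairs, so planted decoys really
    # exercise the mispriming path.
    min_tm = model.priming_gate(profiles[0].stage1[0]) + 2.0 * decoy_mismatches
    gsps = design_gsp_nest(
        genome[k0:k1], "right", wwps, model, min_tm=min_tm
    )
    feet = []
    for g in gsps:
        pos = genome.find(g.sequence)
        if pos < 0 or genome.find(g.sequence, pos + 1) >= 0:
            raise DesignError(f"{g.name} is not unique in the genome")
        feet.append((pos, pos + len(g.sequence)))

    rng = np.random.default_rng((seed, 1))
    decoys: List[Tuple[int, int]] = []
    if n_decoys:
        gsp1 = gsps[0].sequence
        decoy_seq = list(gsp1)
        for i in range(decoy_mismatches):
            orig = decoy_seq[i]
            decoy_seq[i] = "ACGT"[("ACGT".index(orig) + 1) % 4]
        decoy_seq = "".join(decoy_seq)
        lo, hi = k1 + 200, genome_len - 200 - len(decoy_seq)
        attempts = 0
        while len(decoys) < n_decoys and attempts < 1000:
            attempts += 1
            d = int(rng.integers(lo, hi))
            if all(abs(d - e[0]) >= 100 for e in decoys):
                decoys.append((d, d + len(decoy_seq)))
        if len(decoys) < n_decoys:
            raise WWPCRError("could not place the requested decoys")
        garr = list(genome)
        for d, _ in decoys:
            garr[d:d + len(decoy_seq)] = decoy_seq
        genome = "".join(garr)
        for g, (a, b) in zip(gsps, feet):
            if genome[a:b] != g.sequence:
                raise WWPCRError("decoy planting clobbered a GSP locus")

    perms = [wwps, [wwps[1], wwps[2], wwps[0]], [wwps[2], wwps[0], wwps[1]]]
    permutation = list(perms[permutation_index])
    truth = enumerate_truth_amplicons(genome, feet, permutation, profiles,
                                      model, gsp3_name=gsps[2].name)
    return WalkFixture(
        genome_id=f"synthetic_walk_seed{seed}",
        genome=genome,
        known_region=(k0, k1),
        decoy_sites=decoys,
        gsps=gsps,
        wwps=wwps,
        permutation=permutation,
        profiles=profiles,
        model=model,
        truth_amplicons=truth,
        seed=seed,
        gsp_footprints={g.name: f for g, f in zip(gsps, feet)},
    )
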