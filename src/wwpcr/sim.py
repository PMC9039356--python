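"""In-silico simulation of one three-round wristwatch walking-PCR set.

Each round has three annealing stages: several high-stringency cycles in
which only the gene-specific primer (GSP) primes, exactly one low- or
reduced-stringency cycle in which the walking primer (WWP) partially
anneals — arbitrarily on the genome in round 1, or onto the previous WWP's
locus through the bipartite wristwatch duplex in rounds 2/3 — and a block of
high-stringency cycles that can convert only those single strands carrying
perfect high-stringency sites for *both* current primers into exponentially
amplified double-stranded product.  Everything else accumulates at best
linearly and is diluted away in the next round.

Amplification is tracked as a class (exponential / linear / none) per
product species, not as molecule counts: the method's selectivity argument
is about the presence or absence of perfect primer sites, and band
intensity is outside the model.  Species are represented by their projection
onto the + strand of the input genome plus the primer-derived sequence at
their termini, which is exact because every simulated product is
primer + template copy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

from .design import PrimerRecord
from .errors import ProfileError, SimulationError
from .thermo import ThermoModel, revcomp, scan_annealing_sites

EXPONENTIAL = "exponential"
LINEAR = "linear"
NONE = "none"

TARGET = "target"
TYPE_I = "typeI"
TYPE_II = "typeII"
TYPE_III = "typeIII"
NA = "n/a"


@dataclass(frozen=True)
class CyclingProfile:
    """Staged annealing temperatures and cycle counts for one PCR round.

    ``stage2`` must run exactly one cycle — the method's core constraint:
    a primer is allowed to anneal partially to the template once only.
    """

    stage1: Tuple[float, int] = (65.0, 5)
    stage2: Tuple[float, int] = (25.0, 1)
    stage3: Tuple[float, int] = (65.0, 25)
    denature_temp: float = 94.0
    extension_temp: float = 72.0
    extension_time_s: float = 120.0
    elongation_rate_nt_s: float = 100.0 / 3.0  # ~2 kb/min

    def __post_init__(self) -> None:
        if self.stage2[1] != 1:
            raise ProfileError(
                "stage 2 must have exactly one cycle: the walking primer "
                "may partially anneal to the template once only"
            )
        if self.stage1[0] < self.stage2[0] or self.stage3[0] < self.stage2[0]:
            raise ProfileError(
                "stage 1/3 annealing temperatures must not drop below stage 2"
            )

    @property
    def extension_cap_nt(self) -> int:
        """Maximum new synthesis per priming event, nt."""
        return int(round(self.elongation_rate_nt_s * self.extension_time_s))

    @classmethod
    def primary(cls) -> "CyclingProfile":
        return cls(stage2=(25.0, 1))

    @classmethod
    def secondary(cls) -> "CyclingProfile":
        return cls(stage2=(40.0, 1))

    tertiary = secondary


def default_profiles() -> list:
    return [CyclingProfile.primary(), CyclingProfile.secondary(),
            CyclingProfile.secondary()]


@dataclass
class SpeciesRecord:
    """One ssDNA/dsDNA product species.

    ``start``/``end`` are the 0-based half-open projection of the species
    onto the + strand of the reference genome; ``strand`` says which sense
    the represented sequence reads.  Primer-derived termini are recorded by
    primer name: the species' 5' end is the named primer verbatim, its 3'
    end the reverse complement of the named primer.
    """

    template_id: str
    strand: str
    start: int
    end: int
    five_prime_primer: Optional[str] = None
    five_prime_len: int = 0
    three_prime_primer: Optional[str] = None
    three_prime_len: int = 0
    three_prime_boundary_origin: str = "template_end"
    amplification_class: str = NONE
    product_class: str = NA
    round_created: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise SimulationError("species must have start < end")
        if self.strand not in "+-":
            raise SimulationError("strand must be '+' or '-'")

    @property
    def key(self) -> tuple:
        return (self.five_prime_primer, self.start, self.end, self.strand)

    @property
    def size(self) -> int:
        return self.end - self.start

    def primer_footprint(self, terminus: str) -> Optional[tuple]:
        """Genome footprint of the primer at a terminus ('5' or '3')."""
        if terminus == "5":
            if not self.five_prime_primer:
                return None
            ln = self.five_prime_len
            return (self.start, self.start + ln) if self.strand == "+" else (
                self.end - ln, self.end)
        if not self.three_prime_primer:
            return None
        ln = self.three_prime_len
        return (self.end - ln, self.end) if self.strand == "+" else (
            self.start, self.start + ln)

    def to_dict(self) -> dict:
        return {
            "template_id": self.template_id,
            "strand": self.strand,
            "start": self.start,
            "end": self.end,
            "size": self.size,
            "five_prime_primer": self.five_prime_primer,
            "three_prime_primer": self.three_prime_primer,
            "three_prime_boundary_origin": self.three_prime_boundary_origin,
            "amplification_class": self.amplification_class,
            "product_class": self.product_class,
            "round_created": self.round_created,
        }


def species_sequence(sp: SpeciesRecord, genome: str,
                     primer_seqs: Dict[str, str]) -> str:
    """Reconstruct the exact 5'->3' sequence of a species."""
    l5, l3 = sp.five_prime_len, sp.three_prime_len
    p5 = primer_seqs[sp.five_prime_primer] if sp.five_prime_primer else ""
    p3 = revcomp(primer_seqs[sp.three_prime_primer]) if sp.three_prime_primer else ""
    if sp.strand == "+":
        core = genome[sp.start + l5:sp.end - l3]
    else:
        core = revcomp(genome[sp.start + l3:sp.end - l5])
    return p5 + core + p3


@dataclass
class WalkResult:
    """Per-round species ledgers, final predicted bands and class tallies."""

    genome_id: str
    rounds: List[List[SpeciesRecord]] = field(default_factory=list)
    final_bands: List[SpeciesRecord] = field(default_factory=list)
    tallies: List[Dict[str, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        def _sorted(specs):
            return sorted(specs, key=lambda s: (s.start, s.end, s.strand,
                                                s.five_prime_primer or "",
                                                s.three_prime_primer or ""))
        return {
            "genome_id": self.genome_id,
            "rounds": [[s.to_dict() for s in _sorted(r)] for r in self.rounds],
            "final_bands": [s.to_dict() for s in _sorted(self.final_bands)],
            "tallies": self.tallies,
        }

    def to_json(self, indent: Optional[int] = None) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=indent)


class _Pool:
    """Deduplicated species pool with cached reconstructed sequences."""

    def __init__(self, genome: str, primer_seqs: Dict[str, str]):
        self.genome = genome
        self.primer_seqs = primer_seqs
        self.species: Dict[tuple, SpeciesRecord] = {}
        self._seqs: Dict[tuple, str] = {}

    def add(self, sp: SpeciesRecord) -> bool:
        if sp.key in self.species:
            return False
        self.species[sp.key] = sp
        return True

    def seq(self, sp: SpeciesRecord) -> str:
        s = self._seqs.get(sp.key)
        if s is None:
            s = species_sequence(sp, self.genome, self.primer_seqs)
            self._seqs[sp.key] = s
        return s

    def __iter__(self):
        return iter(list(self.species.values()))

    def __len__(self):
        return len(self.species)


def _extend_from_site(template: SpeciesRecord, t_len: int, site,
                      primer: PrimerRecord, cap: int,
                      round_no: int) -> Optional[SpeciesRecord]:
    """Product species from one priming event on a template species.

    The primer footprint covers template-sequence indices
    ``[t3, t3 + len(primer))``; synthesis copies indices ``[c0, t3)``
    (toward the template 5' end), capped at ``cap`` new nucleotides.
    """
    lp = len(primer.sequence)
    t3 = site.three_prime_pos
    if t3 == 0:
        return None  # nothing to extend into
    l3t = template.three_prime_len
    if l3t and t3 > t_len - l3t:
        return None  # footprint straddles the template's 3' primer tail
    l5t = template.five_prime_len
    c0 = max(0, t3 - cap)
    if 0 < c0 < l5t:
        c0 = l5t  # do not copy a partial primer region
    if c0 == 0:
        origin = "primer_site" if l5t else "template_end"
        p3_name, p3_len = template.five_prime_primer, l5t
    else:
        origin = "extension_limit"
        p3_name, p3_len = None, 0
    if template.strand == "+":
        start = template.start + c0
        end = template.start + t3 + lp
        strand = "-"
    else:
        start = template.end - (t3 + lp)
        end = template.end - c0
        strand = "+"
    return SpeciesRecord(
        template_id=template.template_id,
        strand=strand,
        start=start,
        end=end,
        five_prime_primer=primer.name,
        five_prime_len=lp,
        three_prime_primer=p3_name,
        three_prime_len=p3_len,
        three_prime_boundary_origin=origin,
        round_created=round_no,
    )


def _facing_pairs(sites_direct, sites_rc, seq_len: int,
                  len_direct: int, len_rc: int, cap: int) -> list:
    """Converging (direct-strand, reverse-strand) site pairs on one species.

    The rc-strand primer (footprint ``[seq_len - u - len_rc, seq_len - u)``
    in direct coordinates) must sit left of the direct-strand site so the
    two extensions regenerate each other within the elongation cap.
    Returns ``(lo, hi)`` amplicon intervals in direct-sequence coordinates.
    """
    pairs = []
    for a in sites_direct:
        hi = a.three_prime_pos + len_direct
        for b in sites_rc:
            lo = seq_len - b.three_prime_pos - len_rc
            b_end = seq_len - b.three_prime_pos
            if b_end <= a.three_prime_pos:
                amplicon = hi - lo
                if amplicon - len_direct <= cap and amplicon - len_rc <= cap:
                    pairs.append((lo, hi))
    return pairs


def simulate_round(
    templates: Sequence[SpeciesRecord],
    gsp: PrimerRecord,
    wwp: PrimerRecord,
    prev_wwp: Optional[PrimerRecord],
    profile: CyclingProfile,
    model: ThermoModel,
    genome: str,
    primer_seqs: Dict[str, str],
    round_no: int = 1,
) -> List[SpeciesRecord]:
    """Simulate one walking-PCR round on a species pool.

    Stage 1 extends from every high-stringency GSP site; stage 2 (one cycle)
    extends from every reduced-stringency WWP site on every strand present —
    in rounds 2/3 this includes the wristwatch site on the previous WWP's
    locus, which emerges from the scan because the species' 3' tail is that
    primer's complement; stage 3 marks a species exponential only when it
    carries converging high-stringency sites for both current primers.
    The full deduplicated pool carries over (dilution of unamplifiable
    species is expressed by the class labels, not by removal).
    """
    if profile.stage2[1] != 1:
        raise ProfileError("stage 2 must run exactly one cycle")
    primer_seqs = dict(primer_seqs)
    primer_seqs.setdefault(gsp.name, gsp.sequence)
    primer_seqs.setdefault(wwp.name, wwp.sequence)
    cap = profile.extension_cap_nt
    pool = _Pool(genome, primer_seqs)
    for sp in templates:
        pool.add(sp)

    def _prime(primer: PrimerRecord, temp: float) -> None:
        for t in pool:
            t_seq = pool.seq(t)
            if len(t_seq) < len(primer.sequence):
                continue
            for site in scan_annealing_sites(
                primer.sequence, t_seq, temp, model,
                template_id=t.template_id, strand=t.strand,
            ):
                prod = _extend_from_site(t, len(t_seq), site, primer, cap,
                                         round_no)
                if prod is not None:
                    pool.add(prod)

    _prime(gsp, profile.stage1[0])
    _prime(wwp, profile.stage2[0])

    lg, lw = len(gsp.sequence), len(wwp.sequence)
    t3 = profile.stage3[0]
    amplicons: List[SpeciesRecord] = []
    for sp in pool:
        s = pool.seq(sp)
        if len(s) < min(lg, lw):
            sp.amplification_class = NONE
            continue
        rc = revcomp(s)
        gsp_d = scan_annealing_sites(gsp.sequence, s, t3, model) if len(s) >= lg else []
        gsp_r = scan_annealing_sites(gsp.sequence, rc, t3, model) if len(s) >= lg else []
        wwp_d = scan_annealing_sites(wwp.sequence, s, t3, model) if len(s) >= lw else []
        wwp_r = scan_annealing_sites(wwp.sequence, rc, t3, model) if len(s) >= lw else []
        n = len(s)
        pairs_g = _facing_pairs(gsp_d, wwp_r, n, lg, lw, cap)
        pairs_w = _facing_pairs(wwp_d, gsp_r, n, lw, lg, cap)
        if pairs_g or pairs_w:
            # The exponentially regenerated dsDNA is the interval between
            # the converging primer sites.  A species that *is* that
            # amplicon is exponential; a longer species hosting the pair
            # only templates it (linear), and the amplicon is materialized
            # as its own species (a no-op if it already exists).
            exponential = False
            for (lo, hi), p5, l5, p3, l3 in (
                [(p, gsp.name, lg, wwp.name, lw) for p in pairs_g]
                + [(p, wwp.name, lw, gsp.name, lg) for p in pairs_w]
            ):
                if sp.strand == "+":
                    g0, g1, strand = sp.start + lo, sp.start + hi, "-"
                else:
                    g0, g1, strand = sp.end - hi, sp.end - lo, "+"
                if (g0, g1) == (sp.start, sp.end):
                    exponential = True
                amplicons.append(SpeciesRecord(
                    template_id=sp.template_id, strand=strand,
                    start=g0, end=g1,
                    five_prime_primer=p5, five_prime_len=l5,
                    three_prime_primer=p3, three_prime_len=l3,
                    three_prime_boundary_origin="primer_site",
                    amplification_class=EXPONENTIAL,
                    round_created=round_no,
                ))
            sp.amplification_class = EXPONENTIAL if exponential else LINEAR
        elif gsp_d or gsp_r or wwp_d or wwp_r:
            sp.amplification_class = LINEAR
        else:
            sp.amplification_class = NONE
    for amp in amplicons:
        existing = pool.species.get(amp.key)
        if existing is None:
            pool.add(amp)
        else:
            existing.amplification_class = EXPONENTIAL
    return list(pool)


def classify_species(
    sp: SpeciesRecord,
    gsp_true_footprints: Dict[str, tuple],
    primers: Dict[str, PrimerRecord],
) -> str:
    """Product class from primer provenance at the two termini.

    target  — GSP at its authentic locus at one end, WWP at the other;
    typeI   — GSP at both ends;
    typeII  — GSP at an off-target locus plus WWP;
    typeIII — WWP at both ends;
    n/a     — at least one terminus is not primer-defined.
    """
    name5, name3 = sp.five_prime_primer, sp.three_prime_primer
    if not name5 or not name3:
        return NA
    for nm in (name5, name3):
        if nm not in primers:
            raise SimulationError(f"unknown primer provenance: {nm!r}")
    role5, role3 = primers[name5].role, primers[name3].role
    if role5 == "GSP" and role3 == "GSP":
        return TYPE_I
    if role5 == "WWP" and role3 == "WWP":
        return TYPE_III
    gsp_terminus = "5" if role5 == "GSP" else "3"
    gsp_name = name5 if role5 == "GSP" else name3
    foot = sp.primer_footprint(gsp_terminus)
    true = gsp_true_footprints.get(gsp_name)
    return TARGET if true is not None and foot == tuple(true) else TYPE_II


def locate_gsps(genome: str, gsps: Sequence[PrimerRecord],
                known_region: tuple) -> Tuple[Dict[str, tuple], str]:
    """Authentic genomic footprints of the nested GSPs and their strand.

    A plus-strand GSP occurs verbatim in the genome (it walks rightward);
    a minus-strand GSP occurs as its reverse complement (walking leftward).
    All three must sit inside the known region on the same strand.
    """
    k0, k1 = known_region
    feet: Dict[str, tuple] = {}
    strands = set()
    for g in gsps:
        pos = genome.find(g.sequence)
        if pos >= 0:
            feet[g.name] = (pos, pos + len(g.sequence))
            strands.add("+")
        else:
            pos = genome.find(revcomp(g.sequence))
            if pos < 0:
                raise SimulationError(f"{g.name} not found in the genome")
            feet[g.name] = (pos, pos + len(g.sequence))
            strands.add("-")
    if len(strands) != 1:
        raise SimulationError("nested GSPs must share one strand")
    for name, (a, b) in feet.items():
        if not (k0 <= a and b <= k1):
            raise SimulationError(
                f"{name} footprint {a}-{b} lies outside the known region "
                f"{k0}-{k1}"
            )
    return feet, strands.pop()


def simulate_walk(
    genome: str,
    known_region: tuple,
    gsps: Sequence[PrimerRecord],
    wwp_permutation: Sequence[PrimerRecord],
    profiles: Optional[Sequence[CyclingProfile]] = None,
    model: Optional[ThermoModel] = None,
    genome_id: str = "genome",
) -> WalkResult:
    """Chain the three nested rounds of one wristwatch walking-PCR set.

    Round n+1 is templated on round n's full product pool, mirroring the
    direct carry-over of one microliter of product between rounds.  Final
    predicted bands are the exponential species of round 3.
    """
    model = model or ThermoModel()
    profiles = list(profiles) if profiles is not None else default_profiles()
    if len(gsps) != 3 or len(wwp_permutation) != 3 or len(profiles) != 3:
        raise SimulationError("a walk takes 3 GSPs, 3 WWPs and 3 profiles")
    gsp_feet, _strand = locate_gsps(genome, gsps, known_region)
    primer_seqs = {p.name: p.sequence for p in list(gsps) + list(wwp_permutation)}
    primers = {p.name: p for p in list(gsps) + list(wwp_permutation)}

    pool: List[SpeciesRecord] = [
        SpeciesRecord(genome_id, "+", 0, len(genome)),
        SpeciesRecord(genome_id, "-", 0, len(genome)),
    ]
    result = WalkResult(genome_id=genome_id)
    prev_wwp = None
    for rnd, (gsp, wwp, profile) in enumerate(
            zip(gsps, wwp_permutation, profiles), start=1):
        pool = simulate_round(pool, gsp, wwp, prev_wwp, profile, model,
                              genome, primer_seqs, round_no=rnd)
        tally: Dict[str, int] = {}
        for sp in pool:
            sp.product_class = classify_species(sp, gsp_feet, primers)
            tally[sp.product_class] = tally.get(sp.product_class, 0) + 1
            k = f"{sp.amplification_class}"
            tally[k] = tally.get(k, 0) + 1
        result.rounds.append([replace(sp) for sp in pool])
        result.tallies.append(tally)
        prev_wwp = wwp
    result.final_bands = [
        replace(sp) for sp in pool if sp.amplification_class == EXPONENTIAL
    ]
    return result


@dataclass(frozen=True)
class Band:
    """One predicted electrophoresis band."""

    size: int
    start: int
    end: int
    strand: str
    primer_pair: str
    round_created: int


def predict_band_pattern(result: WalkResult) -> List[Band]:
    """Distinct predicted bands (one per dsDNA interval), largest first.

    Coordinates are reported on the + strand of the reference; the
    annotation comes from the walking-primer-led strand when present, so
    the pair names the primers of the final round.
    """
    groups: Dict[tuple, List[SpeciesRecord]] = {}
    for sp in result.final_bands:
        groups.setdefault((sp.start, sp.end), []).append(sp)
    bands = []
    for (start, end), specs in groups.items():
        rep = next((s for s in specs if s.strand == "-"), specs[0])
        pair = "/".join(sorted(filter(
            None, [rep.five_prime_primer, rep.three_prime_primer])))
        bands.append(Band(end - start, start, end, "+", pair,
                          rep.round_created))
    bands.sort(key=lambda b: (-b.size, b.start))
    return bands
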