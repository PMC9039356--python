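# Methods

## Duplex thermodynamics

Melting temperatures use the unified SantaLucia-1998 nearest-neighbor
parameter set with the two-state excess-primer formula

    Tm = ΔH / (ΔS + R ln C) − 273.15,

where C is the primer strand concentration (primer in large excess over
template, as in PCR). Initiation terms are applied per helix end according
to the terminal base pair, and the monovalent-salt correction
ΔS += 0.368 · N_stacks · ln[Na⁺] is entropic. Defaults: 50 mM monovalent
salt, 200 nM primer — a standard primer dose of 1 µL of 10 µM in a 50 µL
reaction. Divalent ions are not modeled; users can fold Mg²⁺ into a
monovalent equivalent through the salt parameter. Degenerate (IUPAC) bases
are rejected rather than wildcarded: the bundled primers are fully
specified, and silently averaging over ambiguity codes would invent
semantics the model cannot support.

Under these conditions the three bundled walking primers melt at
62.18 / 61.92 / 60.74 °C (inside the designed 60–65 °C window), agreeing
with Biopython's `Tm_NN` reference to < 0.05 °C (tested).

### Bipartite ("wristwatch") duplexes

A wristwatch duplex pairs two blocks — the shared 12-nt prefix and 3-nt
suffix — around unpaired spacers. Stacks are summed within paired blocks
only; each internal unpaired run of r primer bases faces r template bases
and is charged as a 2r-nt symmetric loop. The loop penalty is purely
entropic, tabulated linearly at ΔG37 = 0.10 kcal/mol per loop nucleotide
(2.0 kcal/mol for the canonical 20-nt wristwatch loop). This scale is a
deliberate calibration: published hybridization loop tables (≈5–6 kcal/mol
at this size) would put the wristwatch duplex near 29–32 °C, too unstable
to dock at the 40 °C reduced-stringency cycle the protocol prescribes,
whereas the calibrated value reproduces the ≈40 °C inter-primer annealing
the primer set was designed around (40.01 °C for the bundled set) together
with the ≥20 °C self-vs-wristwatch gap (20.73 °C). Unpaired terminal
overhangs are free.

One caveat: Tm is *not* strictly monotone in the paired set. Adding a
terminal A:T pair (initiation penalty) or a stack whose ΔH/ΔS ratio lies
below the current Tm lowers a two-state Tm — this affects ~3% of random
single-position mask extensions (dips ≤ ~2.6 °C). The scanner is immune:
it maximizes Tm over 3′-anchored arrangements, so its reported value never
decreases when more pairing becomes available.

## Annealing-site scanning

Site search is 3′-anchored seed-and-verify: an exact match of the primer's
3′-terminal k bases (k = `min_3prime_match`, default 3 — the wristwatch
3′-overlap length; functional priming needs at least 2) seeds a site, then
the best pairing arrangement is chosen among "pair every complementary
position from a 5′ cut onward" candidates and scored with the bipartite
model above. Only full primer footprints are considered. Sites are
reported in ascending template coordinate. The vectorized scanner is
checked against an exhaustive per-offset brute force (tested on 50 seeded
templates up to 5 kb).

### The functional priming gate

A site primes when its duplex Tm reaches
`priming_gate(T) = T − 5 − 0.25·max(0, 65 − T)` °C. Two facts motivate a
gate below the programmed annealing temperature T: primers prime at
annealing temperatures above their two-state Tm (polymerase engagement
stabilizes transient duplexes), and arbitrary priming at low stringency is
kinetically trapped rather than equilibrium-bound, so the effective margin
widens as T drops. The defaults give:

| stage | T (°C) | gate (°C) | consequence |
|---|---|---|---|
| high stringency | 65 | 60.0 | perfect 25-mers (Tm ≥ 60) prime; shifted/mismatched near-sites (Tm ≤ ~56) and the 40 °C wristwatch duplex do not |
| reduced stringency | 40 | 28.75 | the wristwatch duplex docks; random internal sites are rare (~1 per 25 kb) |
| low stringency | 25 | 10.0 | arbitrary annealing at ~1 site per 2 kb of random sequence, matching the multi-band walks the method produces |

The margin at high stringency (5 °C) must stay below the ≥20 °C
self-vs-wristwatch gap; that inequality, not the margin's exact value, is
what the method's selectivity rests on. Both knobs are configurable; zero
restores a strict `Tm ≥ T` gate.

## Primer-set validation and generation

`validate_wwp_set` checks: per-primer length (25); shared prefix/suffix
lengths (12/3); spacer mutual dissimilarity (pairwise Hamming ≥ half the
spacer length and no shared 6-mer — an operationalization of "mutually
mismatched" that guarantees individualized arbitrary annealing); self-Tm
window [60, 65] °C; min(self-Tm) − max(wristwatch Tm) ≥ 20 °C; base
balance; hairpin/self-/cross-dimer screens. Base balance allows each
nucleotide count within ±4.5 of L/4: the bundled, experimentally validated
set itself contains a primer with counts A=2/C=9/T=9, so a tighter bound
would reject the very sets known to work. Structure screens are exhaustive
small-scale searches scored by longest complementary run (dimers, fail
> 8) and longest stem closing a ≥3-nt loop (hairpins, fail > 6); the
bundled primers score ≤ 6 on all screens.

`generate_wwp_set` draws a prefix/suffix whose wristwatch Tm lands in
[35, 40] °C (the intersection of the ±5 °C target window with the gap
constraint), then rejection-samples spacers per primer against the window,
balance, dissimilarity and screen checks, and finally revalidates the whole
set — the validator is the generator's acceptance oracle (tested over 100
seeds). Exhaustion raises an error naming the dominant violated check.

`design_gsp_nest` slides a 25-nt window from the junction inward, keeping
candidates whose Tm lies within ±4.5 °C of every walking primer (the
published nests span up to 4.1 °C under this model) and which pass all
screens; the first three non-overlapping hits become GSP3 (innermost),
GSP2, GSP1 — so successive nested products shrink by exactly the
GSP offsets.

## The walking simulator

Products are tracked as *species*: coordinates projected on the + strand
of the reference, a strand flag, and primer-derived termini by name (the
5′ end is the primer verbatim; the 3′ end, when extension reached a
template's 5′ terminus, is that template's primer complement). Every
simulated product is primer + template copy, so this representation
reconstructs exact sequences. Species are deduplicated on
(5′ primer, start, end, strand); the full pool carries over between rounds
(dilution of unamplifiable species is expressed by class labels, not
removal).

Each round: stage 1 extends from every high-stringency GSP site on every
pooled strand; stage 2 — structurally constrained to one cycle — extends
from every reduced/low-stringency walking-primer site, which in rounds 2/3
includes the wristwatch dock on the previous walking primer's tail
*emergently* (the tail is that primer's complement, and the scan sees it
like any other site; internal re-annealing is likewise emergent and
observed to be rare). Extension is capped at elongation_rate ×
extension_time (default 33.3 nt/s × 120 s ≈ 4 kb, matching the longest
products the protocol reports; configurable). Stage 3 classifies: a
species is **exponential** only if it *is* the amplicon between converging
high-stringency sites for both current primers; a longer species hosting
such a pair is linear and the amplicon is materialized as its own species;
one perfect site gives linear, none gives dilution. Final bands are the
exponential species of round 3. Product classes follow primer provenance:
GSP at its authentic locus + walking primer = target; GSP at both ends =
type I; off-target GSP + walking primer = type II; walking primer at both
ends = type III. Type III can never be exponential in rounds 2–3 — its
termini melt ≥20 °C below the high-stringency gate — which is the method's
central suppression claim, exercised end-to-end in the tests rather than
assumed.

Identical inputs give byte-identical serialized results (tested).

## Synthetic fixtures and ground truth

`make_walk_fixture` plants a 1-kb known region in a seeded i.i.d. 10-kb
genome (GC 0.5), designs a GSP nest from it (requiring GSP Tm ≥ gate +
2 °C per planned decoy mismatch, so decoys stay above the mispriming
threshold), optionally plants decoy copies of GSP1 in the unknown flank
(1 substitution at the 5′-facing end by default; the 3′ seed stays
intact), and enumerates ground-truth amplicons on the final genome.

The truth enumerator shares no code with the simulator: it chains
exhaustive stage-2 site scans over genomic segments and synthesized
tail-texts, applying each round's extension-reach constraints — including
the skip-round path where the innermost GSP directly copies a first-round
product that the middle GSP could not span (all walking primers share the
wristwatch overlap, so any of them docks on any tail). On 20 seeded
fixtures the simulator's final bands equal the truth sets exactly.

What the fixtures do *not* show: real genomes have repeats, biased
composition and low-complexity tracts that concentrate spurious walker
sites (an optional repeat-injection knob and the GC dial exist for stress
testing); wet-lab band intensity, PCR efficiency and plateau kinetics are
outside the model entirely — the simulator predicts presence, size and
class of discrete products, not gel intensities. Published wet-lab band
patterns on real genomes are therefore not a test surface; the simulator
is validated on properties (oracle equivalence, truth recovery,
suppression, nesting geometry) instead.

## Numerical and convention notes

- Coordinates are 0-based half-open on the + strand; minus-strand species
  store their + strand projection with a strand flag.
- Scanning ties: sites sort by template coordinate; arrangement ties go to
  the fewer-positions candidate.
- The salt correction uses N_stacks (= paired bases − blocks), reducing to
  the standard length−1 for contiguous duplexes.
- Tm computations are deterministic; all randomness (genome synthesis,
  primer generation, decoy placement) flows from explicit integer seeds
  through `numpy.random.default_rng`.
- Problem sizes in the test suite — 10 kb fixture genomes, 20-fixture
  acceptance fleets, 50 oracle templates ≤ 5 kb, 100 generator seeds —
  were chosen so the full property surface (including the 100-kb pool-
  boundedness check) runs in seconds while covering every walking path the
  model admits.

## Known limitations

- The loop penalty and priming-gate margins are calibrated to the
  method's operating points, not fitted to hybridization data; absolute
  wristwatch Tms carry model freedom of several °C.
- Walking primers of unequal length within one set are not supported by
  the tail-docking bookkeeping (the architecture fixes one length anyway).
- Mg²⁺/dNTP-dependent corrections, full partition-function hybridization
  and RNA parameters are out of scope.
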