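# wwpcr — wristwatch-PCR genome walking, in silico

Genome walking is the problem of recovering unknown DNA flanking a known
anchor sequence — a gene boundary, a transgene integration site, an
insertion junction — without a genomic library. Wristwatch PCR solves it
with a set of *wristwatch primers* (WWPs): random 25-mers that share a
12-nt 5′ prefix and a 3-nt 3′ suffix around mutually mismatched 10-nt
spacers. Any two WWPs can therefore anneal to each other's genomic
complement in a bipartite, wristwatch-shaped duplex — paired at both ends,
looped in the middle — whose melting temperature (≈40 °C) sits at least
20 °C below the primers' own T_m (60–65 °C).

That temperature gap drives a three-round nested PCR with staged annealing
stringency. Each round runs 5 high-stringency cycles (65 °C, only the
nested gene-specific primer GSP1/2/3 primes), exactly **one** low- or
reduced-stringency cycle (25 °C in the primary round, where WWP1 anneals
arbitrarily on the flank; 40 °C in the secondary/tertiary rounds, where the
next WWP docks onto the previous WWP's locus through the wristwatch
duplex), then 25 high-stringency cycles. Only a strand carrying perfect
high-stringency sites for *both* current primers amplifies exponentially;
everything else — GSP-only (type I), GSP-plus-walker off target (type II),
and the classically hard walker-only products (type III) — accumulates at
best linearly and is diluted away. This package implements the whole
scheme as software:

- `wwpcr.thermo` — SantaLucia-1998 nearest-neighbor T_m, bipartite
  (wristwatch) duplex T_m with internal-loop penalties, temperature-gated
  3′-anchored annealing-site scanning, hairpin/dimer screens;
- `wwpcr.design` — WWP set validation and seeded generation, nested GSP
  selection from a known sequence, the three cyclic walking permutations;
- `wwpcr.sim` — the three-round walking simulator: per-stage priming,
  product-species ledger, target/type I–III classification, band
  prediction;
- `wwpcr.synthetic` — seeded fixture genomes with planted known regions,
  decoy GSP sites, and independently enumerated ground-truth amplicons;
- `wwpcr.io` / `wwpcr.cli` — FASTA/TSV/BED/JSON round-trips and the
  `wwpcr` command line (`design-wwp`, `design-gsp`, `validate`,
  `simulate`, `fixture`).

## Worked example

```python
from wwpcr import (ThermoModel, load_published_primers, tm_perfect_duplex,
                   wristwatch_pair_tm, make_walk_fixture, simulate_walk,
                   predict_band_pattern)

model = ThermoModel()
wwps = [p for p in load_published_primers() if p.role == "WWP"]
for p in wwps:
    print(p.name, p.sequence, round(tm_perfect_duplex(p.sequence, model), 2))
print("wristwatch Tm:",
      round(wristwatch_pair_tm(wwps[0].sequence, wwps[1].sequence, model), 2))

fx = make_walk_fixture(seed=2, n_decoys=3)   # 10 kb genome, 1 kb known region
result = simulate_walk(fx.genome, fx.known_region, fx.gsps, fx.permutation,
                       fx.profiles, fx.model)
for band in predict_band_pattern(result):
    print(band.size, "nt", f"{band.start}-{band.end}", band.primer_pair)
```

prints

```
WWP1 CGTCTCCAGTCTCCATGTGTTCGTC 62.18
WWP2 CGTCTCCAGTCTTAGGCACAGTGTC 61.92
WWP3 CGTCTCCAGTCTAGTCAGTCAGGTC 60.74
wristwatch Tm: 40.01
808 nt 1473-2281 GSP3/WWP3
383 nt 1473-1856 GSP3/WWP3
294 nt 1473-1767 GSP3/WWP3
102 nt 1473-1575 GSP3/WWP3
```

The three bundled walking primers melt at 60.7–62.2 °C while the
wristwatch duplex between any two melts at 40.0 °C — the ≥20 °C gap the
method requires. The simulated walk then predicts four tertiary bands, all
anchored at GSP3 (genome position 1473 in this fixture) and each ending at
a distinct walking-primer annealing locus in the unknown flank; on this
fixture they coincide exactly with the independently enumerated
ground-truth amplicons (`fx.truth_amplicons`).

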