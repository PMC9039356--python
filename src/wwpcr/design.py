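"""Design and validation of wristwatch-primer (WWP) sets and nested GSPs.

A wristwatch-primer set consists of >= 2 random primers of one length that
share a 5' prefix and a 3' suffix around mutually mismatched spacers.  Any
two members can therefore anneal to each other's genomic complement in a
bipartite, wristwatch-shaped duplex whose Tm sits far below the primers'
own Tm — the temperature gap that lets a staged-stringency walking PCR
admit partial annealing exactly once per round.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import DesignError
from .thermo import (
    ScreenThresholds,
    ThermoModel,
    revcomp,
    structure_screens,
    tm_perfect_duplex,
    tm_wristwatch_duplex,
    validate_dna,
)

BASES = "ACGT"


@dataclass(frozen=True)
class WWPArchitecture:
    """Structural and thermodynamic constraints a WWP set must satisfy.

    Defaults describe the validated 25-nt layout: a shared 12-nt prefix and
    3-nt suffix around a 10-nt heterologous spacer, self-Tm confined to
    60-65 degC, inter-primer (wristwatch) annealing near 40 degC, and a Tm
    gap of at least 20 degC between the two.
    """

    total_len: int = 25
    prefix_len: int = 12
    spacer_len: int = 10
    suffix_len: int = 3
    self_tm_window: tuple = (60.0, 65.0)
    inter_tm_target: float = 40.0
    inter_tm_tolerance: float = 5.0
    min_tm_gap: float = 20.0
    base_balance_tolerance: float = 4.5
    spacer_shared_kmer: int = 6
    spacer_min_hamming: Optional[int] = None

    def __post_init__(self) -> None:
        if self.prefix_len + self.spacer_len + self.suffix_len != self.total_len:
            raise ValueError("prefix_len + spacer_len + suffix_len must equal total_len")
        if self.min_tm_gap < 20.0:
            raise ValueError("min_tm_gap must be >= 20 degC")
        if self.self_tm_window[0] <= self.inter_tm_target:
            raise ValueError("self_tm_window lower bound must exceed inter_tm_target")

    @property
    def min_hamming(self) -> int:
        if self.spacer_min_hamming is not None:
            return self.spacer_min_hamming
        return self.spacer_len // 2

    def wristwatch_mask(self) -> list:
        """Primer-indexed mask pairing only the shared prefix and suffix."""
        return (
            [True] * self.prefix_len
            + [False] * self.spacer_len
            + [True] * self.suffix_len
        )


@dataclass(frozen=True)
class PrimerRecord:
    """One primer: name, 5'->3' sequence, role and nested-use tier."""

    name: str
    sequence: str
    role: str = "WWP"
    tier: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sequence", validate_dna(self.sequence, min_len=2, what=self.name)
        )
        if self.role not in ("WWP", "GSP"):
            raise ValueError(f"role must be WWP or GSP, got {self.role!r}")
        if self.tier is not None and self.tier not in (1, 2, 3):
            raise ValueError("tier must be 1, 2 or 3")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class CheckResult:
    passed: bool
    measured: object = None
    detail: str = ""


@dataclass
class ValidationReport:
    """Per-check verdicts for one WWP set; overall pass iff all pass."""

    checks: dict = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks.values())

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "checks": {
                name: {"passed": c.passed, "measured": c.measured, "detail": c.detail}
                for name, c in self.checks.items()
            },
        }

    def __str__(self) -> str:
        lines = [f"overall: {'PASS' if self.passed else 'FAIL'}"]
        for name, c in self.checks.items():
            lines.append(
                f"  [{'ok' if c.passed else 'FAIL'}] {name}: {c.measured} {c.detail}"
            )
        return "\n".join(lines)


def _common_prefix_len(seqs: Sequence[str]) -> int:
    n = min(len(s) for s in seqs)
    for i in range(n):
        if len({s[i] for s in seqs}) > 1:
            return i
    return n


def _common_suffix_len(seqs: Sequence[str]) -> int:
    return _common_prefix_len([s[::-1] for s in seqs])


def wristwatch_pair_tm(
    a: str, b: str, model: ThermoModel, arch: Optional[WWPArchitecture] = None
) -> Optional[float]:
    """Tm of the wristwatch duplex formed when primer ``a`` anneals to the
    genomic complement of primer ``b``.

    Pairs every position where the two primers agree (those are the
    positions where ``a`` is complementary to ``revcomp(b)``); runs of
    disagreement form internal loops.  Returns None when the 3' termini
    differ (no wristwatch can prime).
    """
    if len(a) != len(b):
        return None
    mask = [x == y for x, y in zip(a, b)]
    if not mask[-1]:
        return None
    return tm_wristwatch_duplex(a, revcomp(b), mask, model)


def validate_wwp_set(
    primers: Sequence[PrimerRecord],
    arch: Optional[WWPArchitecture] = None,
    model: Optional[ThermoModel] = None,
    thresholds: Optional[ScreenThresholds] = None,
) -> ValidationReport:
    """Check a WWP set against the wristwatch architecture.

    Checks: per-primer length; shared prefix/suffix lengths; spacer mutual
    dissimilarity (no shared k-mer, minimum Hamming distance); self-Tm
    window; Tm gap between the weakest self duplex and the strongest
    pairwise wristwatch duplex; base balance; hairpin/dimer screens.
    """
    arch = arch or WWPArchitecture()
    model = model or ThermoModel()
    thresholds = thresholds or ScreenThresholds()
    wwps = [p for p in primers if p.role == "WWP"]
    if len(wwps) < 2:
        raise DesignError("a wristwatch set needs at least two WWPs")
    seqs = [p.sequence for p in wwps]
    report = ValidationReport()

    lengths = [len(s) for s in seqs]
    report.checks["length"] = CheckResult(
        all(n == arch.total_len for n in lengths), lengths,
        f"expected {arch.total_len} nt each",
    )

    cp = _common_prefix_len(seqs)
    cs = _common_suffix_len(seqs)
    report.checks["common_prefix"] = CheckResult(
        cp == arch.prefix_len, cp, f"expected {arch.prefix_len}"
    )
    report.checks["common_suffix"] = CheckResult(
        cs == arch.suffix_len, cs, f"expected {arch.suffix_len}"
    )

    spacers = [
        s[arch.prefix_len:arch.prefix_len + arch.spacer_len] for s in seqs
    ]
    dissim_ok = True
    dissim_measured = []
    for i in range(len(spacers)):
        for j in range(i + 1, len(spacers)):
            si, sj = spacers[i], spacers[j]
            ham = sum(x != y for x, y in zip(si, sj))
            k = arch.spacer_shared_kmer
            shared = any(
                si[t:t + k] in sj for t in range(len(si) - k + 1)
            )
            dissim_measured.append((wwps[i].name, wwps[j].name, ham, shared))
            if ham < arch.min_hamming or shared:
                dissim_ok = False
    report.checks["spacer_dissimilarity"] = CheckResult(
        dissim_ok, dissim_measured,
        f"need Hamming >= {arch.min_hamming} and no shared {arch.spacer_shared_kmer}-mer",
    )

    self_tms = {p.name: tm_perfect_duplex(p.sequence, model) for p in wwps}
    lo, hi = arch.self_tm_window
    report.checks["self_tm_window"] = CheckResult(
        all(lo <= t <= hi for t in self_tms.values()),
        {k: round(v, 2) for k, v in self_tms.items()},
        f"window [{lo}, {hi}] degC",
    )

    pair_tms = {}
    for i, a in enumerate(wwps):
        for j, b in enumerate(wwps):
            if i != j:
                pair_tms[(a.name, b.name)] = wristwatch_pair_tm(
                    a.sequence, b.sequence, model, arch
                )
    if any(v is None for v in pair_tms.values()):
        report.checks["tm_gap"] = CheckResult(
            False, None, "3' termini differ; wristwatch duplex cannot prime"
        )
    else:
        gap = min(self_tms.values()) - max(pair_tms.values())
        report.checks["tm_gap"] = CheckResult(
            gap >= arch.min_tm_gap,
            round(gap, 2),
            f"min self-Tm minus max wristwatch Tm, need >= {arch.min_tm_gap}",
        )

    target = arch.total_len / 4.0
    balances = {
        p.name: {b: p.sequence.count(b) for b in BASES} for p in wwps
    }
    report.checks["base_balance"] = CheckResult(
        all(
            abs(c - target) <= arch.base_balance_tolerance
            for counts in balances.values()
            for c in counts.values()
        ),
        balances,
        f"each base within +/-{arch.base_balance_tolerance} of {target}",
    )

    screens_ok = True
    screen_measured = {}
    for p in wwps:
        rep = structure_screens(p.sequence, thresholds=thresholds)
        screen_measured[p.name] = (rep.hairpin_stem, rep.self_dimer_run)
        screens_ok &= rep.passed
    for i in range(len(wwps)):
        for j in range(i + 1, len(wwps)):
            rep = structure_screens(
                wwps[i].sequence, wwps[j].sequence, thresholds=thresholds
            )
            screen_measured[(wwps[i].name, wwps[j].name)] = rep.cross_dimer_run
            screens_ok &= rep.cross_dimer_ok
    report.checks["structure_screens"] = CheckResult(
        screens_ok, screen_measured,
        f"runs <= {thresholds.max_dimer_run}, stems <= {thresholds.max_hairpin_stem}",
    )
    return report


def _draw(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))


def generate_wwp_set(
    n: int,
    arch: Optional[WWPArchitecture] = None,
    model: Optional[ThermoModel] = None,
    seed: int = 0,
    max_attempts: int = 200,
    spacer_attempts: int = 200,
    thresholds: Optional[ScreenThresholds] = None,
) -> list:
    """Generate ``n`` random WWPs satisfying ``validate_wwp_set``.

    One seeded generator drives the whole search; spacers are redrawn
    before prefixes so the shared-overlap architecture is preserved while
    searching.  Raises DesignError naming the dominant violated constraint
    when the attempt budget is exhausted.
    """
    arch = arch or WWPArchitecture()
    model = model or ThermoModel()
    thresholds = thresholds or ScreenThresholds()
    if n < 2:
        raise DesignError("a wristwatch needs a partner: n must be >= 2")
    rng = np.random.default_rng(seed)
    failures: dict = {}

    def _fail(reason: str) -> None:
        failures[reason] = failures.get(reason, 0) + 1

    ww_lo = arch.inter_tm_target - arch.inter_tm_tolerance
    ww_hi = min(
        arch.inter_tm_target + arch.inter_tm_tolerance,
        arch.self_tm_window[0] - arch.min_tm_gap,
    )
    mask = arch.wristwatch_mask()
    for _ in range(max_attempts):
        prefix = _draw(rng, arch.prefix_len)
        suffix = _draw(rng, arch.suffix_len)
        probe = prefix + "A" * arch.spacer_len + suffix
        ww_tm = tm_wristwatch_duplex(probe, revcomp(probe), mask, model)
        if not (ww_lo <= ww_tm <= ww_hi):
            _fail("inter_tm_target")
            continue
        accepted: list = []
        for _i in range(n):
            seq = None
            for _t in range(spacer_attempts):
                spacer = _draw(rng, arch.spacer_len)
                cand = prefix + spacer + suffix
                tm = tm_perfect_duplex(cand, model)
                if not (arch.self_tm_window[0] <= tm <= arch.self_tm_window[1]):
                    _fail("self_tm_window")
                    continue
                target = arch.total_len / 4.0
                if any(
                    abs(cand.count(b) - target) > arch.base_balance_tolerance
                    for b in BASES
                ):
                    _fail("base_balance")
                    continue
                k = arch.spacer_shared_kmer
                prev_spacers = [
                    s[arch.prefix_len:arch.prefix_len + arch.spacer_len]
                    for s in accepted
                ]
                if any(
                    sum(x != y for x, y in zip(spacer, ps)) < arch.min_hamming
                    or any(
                        spacer[t:t + k] in ps
                        for t in range(len(spacer) - k + 1)
                    )
                    for ps in prev_spacers
                ):
                    _fail("spacer_dissimilarity")
                    continue
                rep = structure_screens(cand, thresholds=thresholds)
                if not rep.passed:
                    _fail("structure_screens")
                    continue
                if any(
                    not structure_screens(
                        cand, prev, thresholds=thresholds
                    ).cross_dimer_ok
                    for prev in accepted
                ):
                    _fail("structure_screens")
                    continue
                seq = cand
                break
            if seq is None:
                break
            accepted.append(seq)
        if len(accepted) < n:
            continue
        records = [
            PrimerRecord(
                name=f"WWP{i + 1}",
                sequence=s,
                role="WWP",
                tier=i + 1 if i < 3 else None,
            )
            for i, s in enumerate(accepted)
        ]
        if validate_wwp_set(records, arch, model, thresholds).passed:
            return records
        _fail("final_validation")
    dominant = max(failures, key=failures.get) if failures else "attempt budget"
    raise DesignError(
        f"could not generate a valid WWP set in {max_attempts} attempts; "
        f"dominant violated check: {dominant} (tallies: {failures})"
    )


def design_gsp_nest(
    known_seq: str,
    walk_direction: str,
    wwps: Sequence[PrimerRecord],
    model: Optional[ThermoModel] = None,
    gsp_len: int = 25,
    tm_tolerance: float = 4.5,
    min_tm: Optional[float] = None,
    min_junction_gap: int = 0,
    thresholds: Optional[ScreenThresholds] = None,
    name_prefix: str = "GSP",
) -> list:
    """Select three nested gene-specific primers from a known sequence.

    The GSPs sit on the strand pointing into the unknown flank: for
    ``walk_direction='right'`` the junction is the right end of
    ``known_seq`` and GSPs are plus-strand windows; for ``'left'`` the
    reverse complement is used.  GSP1 lies farthest from the junction and
    GSP3 nearest, so each successive nested product is slightly shorter.
    Every candidate must melt within ``tm_tolerance`` of each provided
    WWP's self-Tm and pass hairpin/self-dimer and WWP cross-dimer screens.
    """
    model = model or ThermoModel()
    thresholds = thresholds or ScreenThresholds()
    if walk_direction not in ("left", "right"):
        raise DesignError("walk_direction must be 'left' or 'right'")
    known = validate_dna(known_seq, what="known sequence")
    if len(known) < 3 * gsp_len:
        raise DesignError(
            f"known sequence ({len(known)} nt) cannot host three "
            f"{gsp_len}-nt nested primers"
        )
    oriented = known if walk_direction == "right" else revcomp(known)
    wwp_tms = [tm_perfect_duplex(w.sequence, model) for w in wwps]
    chosen: list = []  # innermost (GSP3) first
    limit = len(oriented) - gsp_len - min_junction_gap
    p = limit
    while p >= 0 and len(chosen) < 3:
        cand = oriented[p:p + gsp_len]
        tm = tm_perfect_duplex(cand, model)
        if (min_tm is None or tm >= min_tm) and all(
                abs(tm - wt) <= tm_tolerance for wt in wwp_tms):
            rep = structure_screens(cand, thresholds=thresholds)
            cross_ok = all(
                structure_screens(
                    cand, w.sequence, thresholds=thresholds
                ).cross_dimer_ok
                for w in wwps
            )
            if rep.passed and cross_ok:
                chosen.append(p)
                p -= gsp_len  # non-overlapping
                continue
        p -= 1
    if len(chosen) < 3:
        raise DesignError(
            "no Tm-compatible nested GSP candidates in the known sequence"
        )
    records = []
    for tier, pos in zip((3, 2, 1), chosen):
        records.append(
            PrimerRecord(
                name=f"{name_prefix}{tier}",
                sequence=oriented[pos:pos + gsp_len],
                role="GSP",
                tier=tier,
            )
        )
    return records[::-1]  # GSP1, GSP2, GSP3


def validate_gsp_pairing(
    gsps: Sequence[PrimerRecord],
    wwps: Sequence[PrimerRecord],
    model: Optional[ThermoModel] = None,
    tm_tolerance: float = 4.5,
    thresholds: Optional[ScreenThresholds] = None,
) -> ValidationReport:
    """Check GSP/WWP compatibility: Tm similarity and cross-dimer screens.

    Because the walking permutations pair every GSP with every WWP over the
    three parallel sets, each GSP is checked against all WWPs.
    """
    model = model or ThermoModel()
    thresholds = thresholds or ScreenThresholds()
    report = ValidationReport()
    wwp_tms = {w.name: tm_perfect_duplex(w.sequence, model) for w in wwps}
    diffs = {}
    crosses = {}
    for g in gsps:
        gt = tm_perfect_duplex(g.sequence, model)
        for w in wwps:
            diffs[(g.name, w.name)] = round(abs(gt - wwp_tms[w.name]), 2)
            crosses[(g.name, w.name)] = structure_screens(
                g.sequence, w.sequence, thresholds=thresholds
            ).cross_dimer_run
    report.checks["tm_similarity"] = CheckResult(
        all(d <= tm_tolerance for d in diffs.values()), diffs,
        f"|Tm(GSP) - Tm(WWP)| <= {tm_tolerance} degC",
    )
    report.checks["cross_dimer"] = CheckResult(
        all(c <= thresholds.max_dimer_run for c in crosses.values()), crosses,
        f"runs <= {thresholds.max_dimer_run}",
    )
    return report


def walk_permutations(wwps: Sequence[PrimerRecord]) -> list:
    """The three cyclic use-orders of a three-WWP set.

    Returns ``[(W1,W2,W3), (W2,W3,W1), (W3,W1,W2)]``: each WWP leads
    exactly one permutation and occupies each round-tier exactly once.
    """
    if len(wwps) != 3:
        raise DesignError("walk permutations are defined for exactly 3 WWPs")
    w = list(wwps)
    return [tuple(w), (w[1], w[2], w[0]), (w[2], w[0], w[1])]
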