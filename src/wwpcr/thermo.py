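"""Nearest-neighbor duplex thermodynamics and annealing-site scanning.

The melting-temperature model is the unified SantaLucia-1998 nearest-neighbor
parameter set with an entropic monovalent-salt correction and the
excess-primer two-state formula

    Tm = dH / (dS + R ln C_primer) ,

appropriate for PCR where the primer is in large excess over the template.

Bipartite ("wristwatch") duplexes — two helical blocks flanking an internal
loop — are scored by summing stacks within each paired block and charging an
entropic penalty per unpaired internal-loop nucleotide (both strands count).
The penalty scale is calibrated so that the canonical wristwatch duplex of a
walking-primer set (12 bp 5'-block + 3 bp 3'-block around a 10-nt spacer)
melts near 40 degC, the reduced-stringency annealing temperature the method
operates at.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import DegenerateBaseError, MaskError, SequenceTooShortError

R_GAS = 1.987  # cal / (mol K)
T37 = 310.15  # K

# Unified SantaLucia-1998 stack parameters, 1 M NaCl.
# Keyed by the 5'->3' dinucleotide of one strand (the complement is implied).
NN_DH = {  # kcal/mol
    "AA": -7.9, "TT": -7.9, "AT": -7.2, "TA": -7.2,
    "CA": -8.5, "TG": -8.5, "GT": -8.4, "AC": -8.4,
    "CT": -7.8, "AG": -7.8, "GA": -8.2, "TC": -8.2,
    "CG": -10.6, "GC": -9.8, "GG": -8.0, "CC": -8.0,
}
NN_DS = {  # cal/(mol K)
    "AA": -22.2, "TT": -22.2, "AT": -20.4, "TA": -21.3,
    "CA": -22.7, "TG": -22.7, "GT": -22.4, "AC": -22.4,
    "CT": -21.0, "AG": -21.0, "GA": -22.2, "TC": -22.2,
    "CG": -27.2, "GC": -24.4, "GG": -19.9, "CC": -19.9,
}
# Duplex-initiation terms applied once per helix end, by the terminal base pair.
INIT_DH = {"G": 0.1, "C": 0.1, "A": 2.3, "T": 2.3}
INIT_DS = {"G": -2.8, "C": -2.8, "A": 4.1, "T": 4.1}

# Internal-loop destabilization, kcal/mol of free energy at 37 degC per loop
# nucleotide (counting both strands).  A 10-nt spacer mismatch on each strand
# (20 loop nt) therefore costs 2.0 kcal/mol.  See module docstring for the
# calibration rationale; the penalty is charged purely as entropy.
LOOP_DG37_PER_NT = 0.10

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


def validate_dna(seq: str, min_len: int = 1, what: str = "sequence") -> str:
    """Uppercase and check a DNA string; reject degenerate bases."""
    s = seq.upper()
    if len(s) < min_len:
        raise SequenceTooShortError(
            f"{what} has length {len(s)}, minimum is {min_len}"
        )
    bad = set(s) - set("ACGT")
    if bad:
        raise DegenerateBaseError(
            f"{what} contains non-ACGT character(s): {sorted(bad)}; "
            "degenerate/IUPAC bases are not supported"
        )
    return s


@dataclass(frozen=True)
class ThermoModel:
    """Thermodynamic conditions and priming rules.

    Parameters
    ----------
    nn_parameter_set :
        Identifier of the nearest-neighbor table (only ``santalucia1998``).
    monovalent_salt_mM :
        Monovalent cation concentration in mM.  Divalent ions are not
        modeled; express Mg2+ as a monovalent equivalent if needed.
    primer_conc_nM :
        Primer strand concentration in nM (primer in excess over template).
    loop_dg37_per_nt :
        Internal-loop penalty, kcal/mol at 37 degC per loop nucleotide
        (both strands counted).
    min_3prime_match :
        Number of 3'-terminal primer bases that must pair contiguously for
        productive priming.  Functional priming requires at least a 2-nt
        accurate 3' match; the default of 3 matches the 3'-overlap length
        of a wristwatch-primer set.
    anneal_margin :
        Degrees below the programmed annealing temperature at which a duplex
        still primes, evaluated at ``margin_ref_temp``: a site passes when
        ``duplex_tm >= priming_gate(anneal_temp)``.  Polymerase-stabilized
        transient annealing lets primers function below their two-state
        duplex Tm, and increasingly so at lower temperatures where even
        marginal duplexes are sampled long enough to be extended; the
        margin therefore widens by ``margin_slope`` degC per degC below the
        reference.  Defaults (5 degC at 65 degC, slope 0.25) give a tight
        high-stringency gate (60 degC, excluding shifted or heavily
        mismatched sites) and a realistic arbitrary-priming density at the
        25 degC low-stringency cycle (~1 site per 2 kb for a 25-mer), while
        the 40 degC wristwatch duplex passes the reduced-stringency gate
        (~29 degC) but never a high-stringency one — the inequality the
        whole method rests on.  Set margin and slope to 0 for a strict
        Tm gate.
    """

    nn_parameter_set: str = "santalucia1998"
    monovalent_salt_mM: float = 50.0
    primer_conc_nM: float = 200.0
    loop_dg37_per_nt: float = LOOP_DG37_PER_NT
    min_3prime_match: int = 3
    anneal_margin: float = 5.0
    margin_slope: float = 0.25
    margin_ref_temp: float = 65.0

    def __post_init__(self) -> None:
        if self.nn_parameter_set != "santalucia1998":
            raise ValueError(f"unknown NN parameter set {self.nn_parameter_set!r}")
        if self.monovalent_salt_mM <= 0:
            raise ValueError("monovalent_salt_mM must be > 0")
        if self.primer_conc_nM <= 0:
            raise ValueError("primer_conc_nM must be > 0")
        if self.min_3prime_match < 2:
            raise ValueError("min_3prime_match must be >= 2")
        if self.loop_dg37_per_nt < 0:
            raise ValueError("loop_dg37_per_nt must be >= 0")

    @property
    def salt_M(self) -> float:
        return self.monovalent_salt_mM / 1000.0

    @property
    def conc_M(self) -> float:
        return self.primer_conc_nM * 1e-9

    @property
    def loop_ds_per_nt(self) -> float:
        """Entropy charged per internal-loop nucleotide, cal/(mol K)."""
        return -self.loop_dg37_per_nt * 1000.0 / T37

    def priming_gate(self, anneal_temp: float) -> float:
        """Minimum duplex Tm for productive priming at ``anneal_temp``."""
        widen = self.margin_slope * max(0.0, self.margin_ref_temp - anneal_temp)
        return anneal_temp - self.anneal_margin - widen


@dataclass(frozen=True)
class AnnealingSite:
    """One predicted primer-binding event on a template strand.

    ``three_prime_pos`` is the 0-based template coordinate paired with the
    primer's 3'-terminal base; the primer footprint on the template is
    ``[three_prime_pos, three_prime_pos + len(primer))`` and extension
    proceeds toward template coordinate 0 (the template 5' end).
    ``pairing_mask`` is indexed by primer position (5'->3').
    """

    template_id: str
    strand: str
    three_prime_pos: int
    pairing_mask: tuple
    duplex_tm: float
    terminal_match_run: int

    @property
    def footprint(self) -> tuple:
        return (self.three_prime_pos, self.three_prime_pos + len(self.pairing_mask))


def _mask_dh_ds(primer: str, mask: Sequence[bool], model: ThermoModel):
    """dH (kcal) and salt-corrected dS (cal/K) for a masked duplex.

    Stacks are summed within maximal paired runs; every internal unpaired
    run of length r is charged as a 2r-nt loop; unpaired terminal overhangs
    are free.  Initiation terms apply at the two outermost paired bases.
    """
    paired = [i for i, m in enumerate(mask) if m]
    if not paired:
        raise MaskError("mask pairs zero positions")
    dh = 0.0
    ds = 0.0
    n_stacks = 0
    for i in range(len(primer) - 1):
        if mask[i] and mask[i + 1]:
            dh += NN_DH[primer[i:i + 2]]
            ds += NN_DS[primer[i:i + 2]]
            n_stacks += 1
    for end in (paired[0], paired[-1]):
        dh += INIT_DH[primer[end]]
        ds += INIT_DS[primer[end]]
    internal_unpaired = sum(
        1 for i in range(paired[0], paired[-1]) if not mask[i]
    )
    ds += model.loop_ds_per_nt * 2 * internal_unpaired
    ds += 0.368 * n_stacks * np.log(model.salt_M)
    return dh, ds


def _tm_from_dh_ds(dh: float, ds: float, model: ThermoModel) -> float:
    return dh * 1000.0 / (ds + R_GAS * np.log(model.conc_M)) - 273.15


def tm_perfect_duplex(seq: str, model: Optional[ThermoModel] = None) -> float:
    """Melting temperature (degC) of ``seq`` against its exact complement."""
    model = model or ThermoModel()
    s = validate_dna(seq, min_len=8, what="duplex sequence")
    dh, ds = _mask_dh_ds(s, [True] * len(s), model)
    return _tm_from_dh_ds(dh, ds, model)


def tm_wristwatch_duplex(
    primer: str,
    site: str,
    mask: Sequence[bool],
    model: Optional[ThermoModel] = None,
) -> float:
    """Tm of a bipartite duplex between ``primer`` and a template window.

    ``site`` is the template window written 5'->3' with the same length as
    the primer; antiparallel pairing means primer position ``i`` faces site
    position ``len - 1 - i``.  ``mask`` (primer-indexed) marks the paired
    positions; every marked position must be complementary, the primer 3'
    terminus must be paired, and unpaired internal runs are charged as loops.
    """
    model = model or ThermoModel()
    p = validate_dna(primer, min_len=2, what="primer")
    s = validate_dna(site, what="site")
    if len(s) != len(p):
        raise MaskError("site window must have the same length as the primer")
    mask = list(bool(m) for m in mask)
    if len(mask) != len(p):
        raise MaskError("mask must have the same length as the primer")
    if not any(mask):
        raise MaskError("mask pairs zero positions")
    if not mask[-1]:
        raise MaskError("the primer 3' terminus must be paired")
    n = len(p)
    for i, m in enumerate(mask):
        if m and p[i] != complement_base(s[n - 1 - i]):
            raise MaskError(
                f"mask pairs non-complementary bases at primer position {i}: "
                f"{p[i]} vs site {s[n - 1 - i]}"
            )
    dh, ds = _mask_dh_ds(p, mask, model)
    return _tm_from_dh_ds(dh, ds, model)


class _PrimerProfile:
    """Precomputed per-primer arrays for vectorized site scanning."""

    def __init__(self, primer: str, model: ThermoModel):
        self.primer = primer
        self.model = model
        n = len(primer)
        # cp[j] = complement of primer base pairing template offset j
        # (primer index n-1-j), as uint8 codes.
        self.cp = np.frombuffer(revcomp(primer).encode(), dtype=np.uint8)
        self.stack_dh = np.array(
            [NN_DH[primer[i:i + 2]] for i in range(n - 1)]
        )
        self.stack_ds = np.array(
            [NN_DS[primer[i:i + 2]] for i in range(n - 1)]
        )
        self.init_dh = np.array([INIT_DH[b] for b in primer])
        self.init_ds = np.array([INIT_DS[b] for b in primer])
        self.salt_ln = float(np.log(model.salt_M))
        self.rlnc = R_GAS * float(np.log(model.conc_M))

    def best_tms(self, masks: np.ndarray):
        """Best 3'-anchored arrangement Tm for each pairable mask (row).

        Candidate arrangements keep every pairable position from a chosen
        5' cut to the 3' terminus; the cut maximizing Tm wins (ties go to
        the shorter arrangement).  Returns (tm, cut_index) arrays.
        """
        n = len(self.primer)
        adj = masks[:, :-1] & masks[:, 1:]
        # suffix sums: contribution of stacks/loops at positions >= cut
        h_suf = np.zeros(masks.shape, dtype=float)
        s_suf = np.zeros(masks.shape, dtype=float)
        k_suf = np.zeros(masks.shape, dtype=float)  # stack counts
        h_suf[:, :-1] = np.cumsum((adj * self.stack_dh)[:, ::-1], axis=1)[:, ::-1]
        s_suf[:, :-1] = np.cumsum((adj * self.stack_ds)[:, ::-1], axis=1)[:, ::-1]
        k_suf[:, :-1] = np.cumsum(adj[:, ::-1], axis=1)[:, ::-1]
        unpaired = (~masks).astype(float)
        u_suf = np.cumsum(unpaired[:, ::-1], axis=1)[:, ::-1]
        dh = h_suf + self.init_dh[n - 1] + self.init_dh[None, :]
        ds = (
            s_suf
            + self.init_ds[n - 1]
            + self.init_ds[None, :]
            + 0.368 * k_suf * self.salt_ln
            + self.model.loop_ds_per_nt * 2.0 * u_suf
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            tm = dh * 1000.0 / (ds + self.rlnc) - 273.15
        tm[~masks] = -np.inf  # a cut must sit on a paired position
        best_cut = tm.shape[1] - 1 - np.argmax(tm[:, ::-1], axis=1)
        best_tm = tm[np.arange(tm.shape[0]), best_cut]
        return best_tm, best_cut


_profile_cache: dict = {}


def _primer_profile(primer: str, model: ThermoModel) -> _PrimerProfile:
    key = (primer, model)
    prof = _profile_cache.get(key)
    if prof is None:
        prof = _PrimerProfile(primer, model)
        if len(_profile_cache) > 256:
            _profile_cache.clear()
        _profile_cache[key] = prof
    return prof


def scan_annealing_sites(
    primer: str,
    template: str,
    anneal_temp: float,
    model: Optional[ThermoModel] = None,
    template_id: str = "template",
    strand: str = "+",
) -> list:
    """Every 3'-anchored annealing site of ``primer`` on ``template``.

    A position qualifies when (a) the primer's 3'-terminal
    ``model.min_3prime_match`` bases pair contiguously with the template and
    (b) the best 3'-anchored pairing arrangement has a duplex Tm passing the
    annealing gate (``model.priming_gate(anneal_temp)``).  Only full
    primer footprints are considered (no overhang past either template
    end).  Sites are returned in ascending template coordinate.
    """
    model = model or ThermoModel()
    p = validate_dna(primer, min_len=model.min_3prime_match, what="primer")
    t = validate_dna(template, what="template")
    n = len(p)
    if len(t) < n:
        raise SequenceTooShortError(
            f"template ({len(t)} nt) is shorter than the primer ({n} nt)"
        )
    prof = _primer_profile(p, model)
    tarr = np.frombuffer(t.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(tarr, n)
    match = windows == prof.cp  # (n_pos, n), template-offset indexed
    k = model.min_3prime_match
    seeded = match[:, :k].all(axis=1)
    idx = np.nonzero(seeded)[0]
    if idx.size == 0:
        return []
    # primer-indexed pairable masks (reverse the template-offset axis)
    masks = match[idx, ::-1]
    tms, cuts = prof.best_tms(masks)
    gate = model.priming_gate(anneal_temp)
    sites = []
    for row, t3 in enumerate(idx):
        if tms[row] < gate:
            continue
        pairable = masks[row]
        cut = cuts[row]
        chosen = pairable.copy()
        chosen[:cut] = False
        run = 0
        for m in chosen[::-1]:
            if not m:
                break
            run += 1
        sites.append(
            AnnealingSite(
                template_id=template_id,
                strand=strand,
                three_prime_pos=int(t3),
                pairing_mask=tuple(bool(x) for x in chosen),
                duplex_tm=float(tms[row]),
                terminal_match_run=run,
            )
        )
    return sites


@dataclass(frozen=True)
class ScreenThresholds:
    """Pass/fail limits for primer secondary-structure screens."""

    max_dimer_run: int = 8      # longest tolerated contiguous dimer stretch
    max_hairpin_stem: int = 6   # longest tolerated hairpin stem
    min_hairpin_loop: int = 3   # smallest physical hairpin loop


@dataclass(frozen=True)
class ScreenReport:
    """Worst-case secondary-structure scores for one primer (or a pair)."""

    hairpin_stem: int
    self_dimer_run: int
    cross_dimer_run: Optional[int]
    thresholds: ScreenThresholds = field(default_factory=ScreenThresholds)

    @property
    def hairpin_ok(self) -> bool:
        return self.hairpin_stem <= self.thresholds.max_hairpin_stem

    @property
    def self_dimer_ok(self) -> bool:
        return self.self_dimer_run <= self.thresholds.max_dimer_run

    @property
    def cross_dimer_ok(self) -> bool:
        if self.cross_dimer_run is None:
            return True
        return self.cross_dimer_run <= self.thresholds.max_dimer_run

    @property
    def passed(self) -> bool:
        return self.hairpin_ok and self.self_dimer_ok and self.cross_dimer_ok


def max_dimer_run(seq_a: str, seq_b: str) -> int:
    """Longest contiguous complementary stretch over all antiparallel
    alignments of two sequences (exhaustive offset search)."""
    a = seq_a
    b = revcomp(seq_b)  # a[i] pairs b_orig antiparallel <=> a[i] == b[i - s]
    best = 0
    for s in range(-(len(b) - 1), len(a)):
        run = 0
        lo = max(0, s)
        hi = min(len(a), s + len(b))
        for i in range(lo, hi):
            if a[i] == b[i - s]:
                run += 1
                best = max(best, run)
            else:
                run = 0
    return best


def max_hairpin_stem(seq: str, min_loop: int = 3) -> int:
    """Longest self-complementary stem closing a loop of >= min_loop nt."""
    n = len(seq)
    best = 0
    for p in range(n):
        for q in range(p + min_loop + 1, n):
            if seq[p] != complement_base(seq[q]):
                continue
            stem = 1
            while (
                p - stem >= 0
                and q + stem < n
                and seq[p - stem] == complement_base(seq[q + stem])
            ):
                stem += 1
            best = max(best, stem)
    return best


def structure_screens(
    seq_a: str,
    seq_b: Optional[str] = None,
    model: Optional[ThermoModel] = None,
    thresholds: Optional[ScreenThresholds] = None,
) -> ScreenReport:
    """Hairpin / self-dimer screens for ``seq_a`` and, if given, the
    cross-dimer screen against ``seq_b``."""
    thresholds = thresholds or ScreenThresholds()
    a = validate_dna(seq_a, what="sequence A")
    b = validate_dna(seq_b, what="sequence B") if seq_b is not None else None
    return ScreenReport(
        hairpin_stem=max_hairpin_stem(a, thresholds.min_hairpin_loop),
        self_dimer_run=max_dimer_run(a, a),
        cross_dimer_run=None if b is None else max_dimer_run(a, b),
        thresholds=thresholds,
    )
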