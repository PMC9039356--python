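"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from wwpcr import (
    ThermoModel,
    load_published_primers,
    make_walk_fixture,
    simulate_walk,
    tm_wristwatch_duplex,
)
from wwpcr.thermo import complement_base, revcomp

# ---------------------------------------------------------------------------
# Independent nearest-neighbor oracle: plain hand-summed enthalpy/entropy over
# the stacks of a contiguous duplex, written without any wwpcr internals.

_ORACLE_DH = {
    "AA": -7.9, "TT": -7.9, "AT": -7.2, "TA": -7.2,
    "CA": -8.5, "TG": -8.5, "GT": -8.4, "AC": -8.4,
    "CT": -7.8, "AG": -7.8, "GA": -8.2, "TC": -8.2,
    "CG": -10.6, "GC": -9.8, "GG": -8.0, "CC": -8.0,
}
_ORACLE_DS = {
    "AA": -22.2, "TT": -22.2, "AT": -20.4, "TA": -21.3,
    "CA": -22.7, "TG": -22.7, "GT": -22.4, "AC": -22.4,
    "CT": -21.0, "AG": -21.0, "GA": -22.2, "TC": -22.2,
    "CG": -27.2, "GC": -24.4, "GG": -19.9, "CC": -19.9,
}


def nn_oracle_tm(seq: str, na_mM: float = 50.0, conc_nM: float = 200.0) -> float:
    """Hand-summed SantaLucia-1998 Tm of a perfect duplex (excess primer)."""
    dh = sum(_ORACLE_DH[seq[i:i + 2]] for i in range(len(seq) - 1))
    ds = sum(_ORACLE_DS[seq[i:i + 2]] for i in range(len(seq) - 1))
    for terminal in (seq[0], seq[-1]):
        if terminal in "GC":
            dh += 0.1
            ds += -2.8
        else:
            dh += 2.3
            ds += 4.1
    ds += 0.368 * (len(seq) - 1) * math.log(na_mM / 1000.0)
    return dh * 1000.0 / (ds + 1.987 * math.log(conc_nM * 1e-9)) - 273.15


# ---------------------------------------------------------------------------
# Exhaustive-offset scanning oracle: tries every template offset, rebuilds the
# pairing mask by direct base comparison and scores candidate 3'-anchored
# arrangements through the public mask-Tm function.

def brute_force_sites(primer: str, template: str, anneal_temp: float,
                      model: ThermoModel) -> list:
    """All (three_prime_pos, best_tm) site tuples, by exhaustive offsets."""
    n = len(primer)
    k = model.min_3prime_match
    gate = model.priming_gate(anneal_temp)
    out = []
    for t3 in range(len(template) - n + 1):
        window = template[t3:t3 + n]
        mask = [primer[i] == complement_base(window[n - 1 - i])
                for i in range(n)]
        if not all(mask[n - k:]):
            continue
        best = None
        for cut in range(n):
            if not mask[cut]:
                continue
            cand = [m and i >= cut for i, m in enumerate(mask)]
            tm = tm_wristwatch_duplex(primer, window, cand, model)
            if best is None or tm > best:
                best = tm
        if best is not None and best >= gate:
            out.append((t3, best))
    return out


# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def model():
    return ThermoModel()


@pytest.fixture(scope="session")
def published_primers():
    return load_published_primers()


@pytest.fixture(scope="session")
def wwps(published_primers):
    return [p for p in published_primers if p.role == "WWP"]


@pytest.fixture(scope="session")
def gada_gsps(published_primers):
    return [p for p in published_primers if p.name.startswith("gadA")]


@pytest.fixture(scope="session")
def walk_case():
    """One synthetic walking experiment with decoys, simulated once."""
    fx = make_walk_fixture(seed=2, n_decoys=3)
    result = simulate_walk(fx.genome, fx.known_region, fx.gsps,
                           fx.permutation, fx.profiles, fx.model,
                           genome_id=fx.genome_id)
    return fx, result


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


__all__ = ["nn_oracle_tm", "brute_force_sites", "random_dna", "revcomp"]
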