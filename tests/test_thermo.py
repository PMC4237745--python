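"""Nearest-neighbor Tm model: oracles, invariants, population statistics."""

import itertools
import math

import numpy as np
import pytest
from Bio.SeqUtils import MeltingTemp as mt
from hypothesis import given, settings
from hypothesis import strategies as st

from biomemory import thermo
from biomemory.seqs import InvalidSequenceError, encode, revcomp

COND = thermo.LEARNING_CONDITIONS
R = 1.987


def hand_tm(seq: str, cond: thermo.DuplexConditions) -> float:
    """Independent Tm oracle: literal table, explicit stack-by-stack sums."""
    DH = {"AA": -7.9, "AT": -7.2, "TA": -7.2, "CA": -8.5, "GT": -8.4,
          "CT": -7.8, "GA": -8.2, "CG": -10.6, "GC": -9.8, "GG": -8.0}
    DS = {"AA": -22.2, "AT": -20.4, "TA": -21.3, "CA": -22.7, "GT": -22.4,
          "CT": -21.0, "GA": -22.2, "CG": -27.2, "GC": -24.4, "GG": -19.9}

    def stack(p):
        if p in DH:
            return DH[p], DS[p]
        rc = revcomp(p)
        return DH[rc], DS[rc]

    dh = ds = 0.0
    for i in range(len(seq) - 1):
        h, s = stack(seq[i : i + 2])
        dh, ds = dh + h, ds + s
    for end in (seq[0], seq[-1]):
        if end in "AT":
            dh, ds = dh + 2.3, ds + 4.1
        else:
            dh, ds = dh + 0.1, ds - 2.8
    if seq == revcomp(seq):
        ds -= 1.4
    tm_k = dh * 1000.0 / (ds + R * math.log(cond.strand_conc))
    # magnesium-dominated Owczarzy correction (sqrt(mg)/mon > 6 here)
    mg = max(cond.mg - cond.dntp, 0.0)
    fgc = sum(c in "GC" for c in seq) / len(seq)
    lnmg = math.log(mg)
    corr = (3.92 - 0.911 * lnmg + fgc * (6.26 + 1.42 * lnmg)
            + (1.0 / (2 * (len(seq) - 1))) * (-48.2 + 52.5 * lnmg + 8.31 * lnmg**2)
            ) * 1e-5
    return 1.0 / (1.0 / tm_k + corr) - 273.15


@pytest.mark.parametrize("seq", ["GATTACCA", "GCGCGCGC", "ATATATAT", "ACCGGTTA"])
def test_tm_matches_hand_summed_oracle(seq):
    """Stack-by-stack manual NN summation reproduces tm_duplex to 1e-6."""
    assert thermo.tm_duplex(seq, COND) == pytest.approx(hand_tm(seq, COND), abs=1e-6)


def test_tm_matches_biopython_reference():
    """Independent reference: Biopython Tm_NN with the same table and the
    Owczarzy magnesium correction (free Mg passed explicitly, and the
    self-complementarity flag set where it applies)."""
    rng = np.random.default_rng(5)
    for _ in range(200):
        k = int(rng.integers(2, 26))
        seq = "".join(rng.choice(list("ACGT"), k))
        ref = mt.Tm_NN(
            seq,
            dnac1=COND.strand_conc * 1e9,
            dnac2=0,
            selfcomp=(seq == revcomp(seq)),
            Na=COND.na * 1e3,
            Mg=COND.free_mg * 1e3,
            dNTPs=0,
            saltcorr=7,
            nn_table=mt.DNA_NN3,
        )
        assert thermo.tm_duplex(seq, COND) == pytest.approx(ref, abs=1e-6)


def test_concentration_monotonicity():
    """Two-state model: 10x more strand raises every Tm."""
    hi = thermo.DuplexConditions(strand_conc=1.6e-5)
    for seq in ("ACGTACG", "TTTTTTTT", "GCGCGC"):
        assert thermo.tm_duplex(seq, hi) > thermo.tm_duplex(seq, COND)


def test_salt_monotonicity():
    """Tm rises with monovalent salt (Mg-free) and with free magnesium."""
    seq = "ACGTACGTACGT"
    lo_na = thermo.DuplexConditions(na=0.05, mg=0.0, dntp=0.0)
    hi_na = thermo.DuplexConditions(na=0.5, mg=0.0, dntp=0.0)
    assert thermo.tm_duplex(seq, hi_na) > thermo.tm_duplex(seq, lo_na)
    lo_mg = thermo.DuplexConditions(mg=0.006, dntp=0.0)
    hi_mg = thermo.DuplexConditions(mg=0.012, dntp=0.0)
    assert thermo.tm_duplex(seq, hi_mg) > thermo.tm_duplex(seq, lo_mg)


def test_length_monotonicity_within_composition():
    """Appending a stabilizing stack to a homogeneous sequence raises Tm."""
    for k in range(3, 12):
        assert thermo.tm_duplex("GC" * k, COND) > thermo.tm_duplex("GC" * (k - 1), COND)


@pytest.mark.parametrize("bad", ["", "A", "ACGX", "ACGU"])
def test_invalid_sequences_rejected(bad):
    with pytest.raises((InvalidSequenceError, ValueError)):
        thermo.tm_duplex(bad, COND)


def test_population_stats_exhaustive_equals_enumeration_oracle():
    """Exhaustive k-mer statistics match an independent itertools scan."""
    for k in (2, 4):
        tms = [thermo.tm_duplex("".join(p), COND)
               for p in itertools.product("ACGT", repeat=k)]
        st_ = thermo.tm_population_stats(k, COND, mode="exhaustive")
        assert st_["min"] == pytest.approx(min(tms), abs=1e-9)
        assert st_["mean"] == pytest.approx(float(np.mean(tms)), abs=1e-9)
        assert st_["max"] == pytest.approx(max(tms), abs=1e-9)
        assert st_["min"] <= st_["mean"] <= st_["max"]
        assert st_["param_set"] == "santalucia-unified-1998"


def test_subspace_extrema_attain_global_extrema():
    """The A/T-only subspace attains the population minimum and the
    G/C-only subspace the maximum (basis of the exact k=20 extrema)."""
    for k in (4, 5, 6):
        full = thermo.tm_population_stats(k, COND, mode="exhaustive")
        assert thermo.subspace_extremum(k, COND, which="min") == pytest.approx(
            full["min"], abs=1e-9
        )
        assert thermo.subspace_extremum(k, COND, which="max") == pytest.approx(
            full["max"], abs=1e-9
        )


def test_population_stats_sampled_mode_records_method():
    st_ = thermo.tm_population_stats(12, COND, mode="sampled", n_samples=500, seed=1)
    assert st_["method"] == "sampled-mean+exact-subspace-extrema"
    assert st_["min"] <= st_["mean"] <= st_["max"]


def test_population_stats_errors():
    with pytest.raises(InvalidSequenceError):
        thermo.tm_population_stats(1, COND)
    with pytest.raises(ValueError):
        thermo.tm_population_stats(12, COND, mode="exhaustive")
    with pytest.raises(ValueError):
        thermo.tm_population_stats(12, COND, mode="sampled", n_samples=0)


def test_anchor_length_floor_and_scan_oracle():
    """The anchor length equals a brute-force first-k scan of the
    population statistic, at the low-temperature floor and at 55 °C."""
    first = next(
        k
        for k in range(2, 41)
        if thermo.tm_population_stats(k, COND, "exhaustive")["mean"] >= 0.0
    )
    assert thermo.min_stable_anchor_length(0.0, COND, stat="mean") == first
    k55 = thermo.min_stable_anchor_length(55.0, COND, stat="mean")
    for k in range(2, k55):
        if k <= 10:
            v = thermo.tm_population_stats(k, COND, "exhaustive")["mean"]
        else:
            v = thermo.tm_population_stats(k, COND, "sampled", 20_000, seed=k)["mean"]
        assert v < 55.0
    assert thermo.min_stable_anchor_length(55.0, COND, stat="mean") == k55  # stable


def test_anchor_length_monotone_in_temperature():
    ks = [thermo.min_stable_anchor_length(t, COND, stat="mean") for t in (10, 25, 40, 55)]
    assert ks == sorted(ks)


def test_anchor_length_invalid_temperature():
    with pytest.raises(ValueError):
        thermo.min_stable_anchor_length(150.0, COND)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=2, max_size=30))
def test_tm_invariant_under_reverse_complement(seq):
    """A duplex and its flipped representation have identical Tm."""
    assert thermo.tm_duplex(seq, COND) == pytest.approx(
        thermo.tm_duplex(revcomp(seq), COND), abs=1e-9
    )


def test_conditions_validation():
    with pytest.raises(ValueError):
        thermo.DuplexConditions(strand_conc=-1.0)
    with pytest.raises(ValueError):
        thermo.DuplexConditions(na=-0.1)
    assert thermo.DuplexConditions(mg=0.002, dntp=0.004).free_mg == 0.0
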