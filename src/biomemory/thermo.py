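"""Nearest-neighbor duplex thermodynamics.

Melting temperatures of perfect-match DNA duplexes under the learning
reaction conditions, population statistics over the space of k-mers, and
the shortest anchor length that is stable at a given temperature.

Model
-----
Two-state nearest-neighbor model: ΔH and ΔS are sums over dinucleotide
stacks plus duplex-initiation terms (unified SantaLucia 1998 table).  The
probe strand is assumed in excess over its genomic complement, so

    Tm = ΔH · 1000 / (ΔS + R · ln CT)    [K]

with CT the molar probe concentration.  Self-complementary sequences are
detected and receive the symmetry entropy term.  The 1 M Na+ melting
temperature is then corrected for monovalent and free magnesium
(dNTP-chelated) concentrations with the Owczarzy decision tree, applied
on the 1/Tm scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .seqs import (
    COMPLEMENT,
    InvalidSequenceError,
    encode,
    enumerate_kmers,
)

R_GAS = 1.987  # cal / (mol K)
CELSIUS = 273.15

__all__ = [
    "DuplexConditions",
    "NNParameterSet",
    "SANTALUCIA_1998",
    "LEARNING_CONDITIONS",
    "tm_duplex",
    "tm_array",
    "duplex_dh_ds",
    "free_energy",
    "tm_population_stats",
    "subspace_extremum",
    "min_stable_anchor_length",
]


@dataclass(frozen=True)
class DuplexConditions:
    """Solution conditions entering every Tm computation.

    Parameters
    ----------
    strand_conc : molar concentration of the probe (excess) strand.
    na : monovalent cation molarity.
    mg : total Mg2+ molarity.
    dntp : dNTP molarity; dNTPs chelate Mg stoichiometrically, so the
        free magnesium is ``max(mg - dntp, 0)``.
    temperature : °C, used by stability queries (annealing, digestion).
    """

    strand_conc: float = 1.6e-6
    na: float = 0.010
    mg: float = 0.010
    dntp: float = 0.004
    temperature: float = 25.0

    def __post_init__(self) -> None:
        for name in ("strand_conc", "na", "mg", "dntp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.strand_conc == 0:
            raise ValueError("strand_conc must be positive")

    @property
    def free_mg(self) -> float:
        return max(self.mg - self.dntp, 0.0)


#: the reaction condition of the learning protocol
#: (1.6 uM oligo, 10 mM Na+, 10 mM Mg2+, 4 mM dNTPs)
LEARNING_CONDITIONS = DuplexConditions()


@dataclass(frozen=True)
class NNParameterSet:
    """A nearest-neighbor parameter table (ΔH kcal/mol, ΔS cal/mol/K).

    ``dh``/``ds`` are length-16 arrays indexed by stack code
    ``4 * first_base + second_base`` of the top (5'→3') strand.
    """

    name: str
    dh: np.ndarray
    ds: np.ndarray
    init_at: tuple[float, float]  # per A·T terminal (dh, ds)
    init_gc: tuple[float, float]  # per G·C terminal
    sym: tuple[float, float]  # self-complementary correction

    def __post_init__(self) -> None:
        if self.dh.shape != (16,) or self.ds.shape != (16,):
            raise ValueError("parameter table must cover all 16 stacks")


def _build_table(name, stacks, init_at, init_gc, sym) -> NNParameterSet:
    code = {b: i for i, b in enumerate("ACGT")}
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    dh = np.full(16, np.nan)
    ds = np.full(16, np.nan)
    for pair, (h, s) in stacks.items():
        rc = comp[pair[1]] + comp[pair[0]]
        for p in (pair, rc):
            dh[4 * code[p[0]] + code[p[1]]] = h
            ds[4 * code[p[0]] + code[p[1]]] = s
    assert not np.isnan(dh).any()
    return NNParameterSet(name, dh, ds, init_at, init_gc, sym)


#: unified oligonucleotide parameters (SantaLucia 1998)
SANTALUCIA_1998 = _build_table(
    "santalucia-unified-1998",
    {
        "AA": (-7.9, -22.2),
        "AT": (-7.2, -20.4),
        "TA": (-7.2, -21.3),
        "CA": (-8.5, -22.7),
        "GT": (-8.4, -22.4),
        "CT": (-7.8, -21.0),
        "GA": (-8.2, -22.2),
        "CG": (-10.6, -27.2),
        "GC": (-9.8, -24.4),
        "GG": (-8.0, -19.9),
    },
    init_at=(2.3, 4.1),
    init_gc=(0.1, -2.8),
    sym=(0.0, -1.4),
)


def _selfcomp_mask(mat: np.ndarray) -> np.ndarray:
    """Rows equal to their own reverse complement."""
    if mat.shape[1] % 2 == 1:
        return np.zeros(mat.shape[0], dtype=bool)
    rc = COMPLEMENT[mat[:, ::-1]]
    return (mat == rc).all(axis=1)


def _dh_ds_batch(
    mat: np.ndarray, params: NNParameterSet, with_sym: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """ΔH (kcal/mol) and ΔS (cal/mol/K) per row of a code matrix."""
    stacks = 4 * mat[:, :-1].astype(np.intp) + mat[:, 1:]
    dh = params.dh[stacks].sum(axis=1)
    ds = params.ds[stacks].sum(axis=1)
    for end in (mat[:, 0], mat[:, -1]):
        at_end = (end == 0) | (end == 3)
        dh += np.where(at_end, params.init_at[0], params.init_gc[0])
        ds += np.where(at_end, params.init_at[1], params.init_gc[1])
    if with_sym:
        sym = _selfcomp_mask(mat)
        if sym.any():
            dh = dh + sym * params.sym[0]
            ds = ds + sym * params.sym[1]
    return dh, ds


def _inv_tm_salt_correction(
    fgc: np.ndarray | float, nbp: int, cond: DuplexConditions
) -> np.ndarray | float:
    """Additive correction to 1/Tm for monovalent + magnesium (Owczarzy).

    Decision tree on R = sqrt([Mg2+_free]) / [mon]: monovalent-dominated
    (R < 0.22), competitive (0.22 <= R < 6, monovalent-modified
    coefficients), and magnesium-dominated (R >= 6) regimes.
    """
    mon = cond.na
    mg = cond.free_mg
    if mon == 0 and mg == 0:
        return 0.0 if np.isscalar(fgc) else np.zeros_like(fgc)
    a, b, c, d = 3.92, -0.911, 6.26, 1.42
    e, f, g = -48.2, 52.5, 8.31
    if mon > 0:
        lnm = math.log(mon)
        if mg == 0 or math.sqrt(mg) / mon < 0.22:
            return (4.29 * fgc - 3.95) * 1e-5 * lnm + 9.40e-6 * lnm**2
        if math.sqrt(mg) / mon < 6.0:
            a = 3.92 * (0.843 - 0.352 * math.sqrt(mon) * lnm)
            d = 1.42 * (1.279 - 4.03e-3 * lnm - 8.03e-3 * lnm**2)
            g = 8.31 * (0.486 - 0.258 * lnm + 5.25e-3 * lnm**3)
    lnmg = math.log(mg)
    return (
        a
        + b * lnmg
        + fgc * (c + d * lnmg)
        + (1.0 / (2.0 * (nbp - 1))) * (e + f * lnmg + g * lnmg**2)
    ) * 1e-5


def tm_array(
    mat: np.ndarray,
    cond: DuplexConditions = LEARNING_CONDITIONS,
    params: NNParameterSet = SANTALUCIA_1998,
) -> np.ndarray:
    """Melting temperatures (°C) for each row of an (n, k) code matrix."""
    mat = np.atleast_2d(np.asarray(mat, dtype=np.uint8))
    if mat.shape[1] < 2:
        raise InvalidSequenceError("duplex needs at least 2 base pairs")
    dh, ds = _dh_ds_batch(mat, params)
    tm_1m = dh * 1000.0 / (ds + R_GAS * math.log(cond.strand_conc))
    fgc = np.mean((mat == 1) | (mat == 2), axis=1)
    corr = _inv_tm_salt_correction(fgc, mat.shape[1], cond)
    return 1.0 / (1.0 / tm_1m + corr) - CELSIUS


def tm_duplex(
    seq: str,
    cond: DuplexConditions = LEARNING_CONDITIONS,
    params: NNParameterSet = SANTALUCIA_1998,
) -> float:
    """Tm (°C) of ``seq`` paired with its exact complement under ``cond``."""
    if not seq or len(seq) < 2:
        raise InvalidSequenceError("duplex needs at least 2 base pairs")
    return float(tm_array(encode(seq)[None, :], cond, params)[0])


def duplex_dh_ds(
    seq: str, params: NNParameterSet = SANTALUCIA_1998
) -> tuple[float, float]:
    """(ΔH kcal/mol, ΔS cal/mol/K) of the perfect-match duplex."""
    dh, ds = _dh_ds_batch(encode(seq)[None, :], params)
    return float(dh[0]), float(ds[0])


def free_energy(
    seq: str, temperature: float, params: NNParameterSet = SANTALUCIA_1998
) -> float:
    """ΔG° (kcal/mol) of duplex formation at ``temperature`` °C."""
    dh, ds = duplex_dh_ds(seq, params)
    return dh - (temperature + CELSIUS) * ds / 1000.0


def _two_letter_matrix(k: int, bases: tuple[int, int]) -> np.ndarray:
    """All 2**k sequences over a two-letter code subspace, as a matrix."""
    if k > 22:
        raise ValueError("two-letter enumeration limited to k <= 22")
    idx = np.arange(2**k, dtype=np.int64)
    mat = np.empty((2**k, k), dtype=np.uint8)
    lo, hi = bases
    for j in range(k):
        bit = (idx >> j) & 1
        mat[:, k - 1 - j] = np.where(bit == 1, hi, lo).astype(np.uint8)
    return mat


def subspace_extremum(
    k: int,
    cond: DuplexConditions = LEARNING_CONDITIONS,
    params: NNParameterSet = SANTALUCIA_1998,
    which: str = "min",
) -> float:
    """Exact population extremum of Tm over all k-mers.

    The minimum is attained in the A/T-only subspace (weakest stacks) and
    the maximum in the G/C-only subspace (strongest stacks), so each can
    be found by exhausting 2**k two-letter sequences instead of 4**k.
    This subspace property is verified against full enumeration for
    small k in the test suite.
    """
    bases = (0, 3) if which == "min" else (1, 2)
    if k <= 22:
        mat = _two_letter_matrix(k, bases)
        tms = tm_array(mat, cond, params)
        return float(tms.min() if which == "min" else tms.max())
    return _composition_extremum(k, bases, cond, params, which)


def _composition_extremum(
    k: int,
    bases: tuple[int, int],
    cond: DuplexConditions,
    params: NNParameterSet,
    which: str,
) -> float:
    """Extremum over a two-letter subspace via stack-composition counts.

    Within {X, complement(X)} the NN sums depend only on the counts of
    the three distinct stack types (XX≡YY, XY, YX), with achievability
    |n_XY - n_YX| <= 1 (transition counts of a two-state walk).  Used
    for k > 22 where bit enumeration is too large; the symmetry term of
    palindromic representatives (at most 1.4 cal/mol/K) is applied to
    the minimum as a conservative bound.
    """
    lo, hi = bases
    s_same = 4 * lo + lo
    s_xy = 4 * lo + hi
    s_yx = 4 * hi + lo
    at_end = lo in (0, 3)
    init = params.init_at if at_end else params.init_gc
    fgc = 0.0 if at_end else 1.0
    best = None
    for n_xy in range(k):
        for n_yx in range(k):
            if abs(n_xy - n_yx) > 1:
                continue
            n_same = k - 1 - n_xy - n_yx
            if n_same < 0:
                continue
            dh = (
                n_same * params.dh[s_same]
                + n_xy * params.dh[s_xy]
                + n_yx * params.dh[s_yx]
                + 2 * init[0]
            )
            ds = (
                n_same * params.ds[s_same]
                + n_xy * params.ds[s_xy]
                + n_yx * params.ds[s_yx]
                + 2 * init[1]
            )
            if which == "min" and k % 2 == 0:
                ds += params.sym[1]
                dh += params.sym[0]
            tm_1m = dh * 1000.0 / (ds + R_GAS * math.log(cond.strand_conc))
            corr = _inv_tm_salt_correction(fgc, k, cond)
            tm = 1.0 / (1.0 / tm_1m + corr) - CELSIUS
            if best is None or (tm < best if which == "min" else tm > best):
                best = tm
    return float(best)


def tm_population_stats(
    k: int,
    cond: DuplexConditions = LEARNING_CONDITIONS,
    mode: str = "auto",
    n_samples: int = 100_000,
    seed: int = 0,
    params: NNParameterSet = SANTALUCIA_1998,
) -> dict:
    """min/mean/max of Tm over the population of all k-mers.

    ``mode='exhaustive'`` enumerates all 4**k sequences (k <= 10).
    ``mode='sampled'`` estimates the mean from ``n_samples`` uniform
    draws while the min and max are computed exactly over the A/T-only
    and G/C-only subspaces.  The method used is recorded in the result.
    """
    if k < 2:
        raise InvalidSequenceError("k must be >= 2")
    if mode == "auto":
        mode = "exhaustive" if k <= 10 else "sampled"
    if mode == "exhaustive":
        if k > 10:
            raise ValueError("exhaustive mode requires k <= 10")
        tms = tm_array(enumerate_kmers(k), cond, params)
        result = {
            "min": float(tms.min()),
            "mean": float(tms.mean()),
            "max": float(tms.max()),
            "method": "exhaustive",
        }
    elif mode == "sampled":
        if n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        rng = np.random.default_rng(seed)
        sample = rng.integers(0, 4, size=(n_samples, k), dtype=np.int64).astype(
            np.uint8
        )
        tms = tm_array(sample, cond, params)
        result = {
            "min": min(float(tms.min()), subspace_extremum(k, cond, params, "min")),
            "mean": float(tms.mean()),
            "max": max(float(tms.max()), subspace_extremum(k, cond, params, "max")),
            "method": "sampled-mean+exact-subspace-extrema",
        }
    else:
        raise ValueError(f"unknown mode {mode!r}")
    result.update({"k": k, "param_set": params.name})
    return result


def min_stable_anchor_length(
    temperature: float,
    cond: DuplexConditions = LEARNING_CONDITIONS,
    stat: str = "mean",
    params: NNParameterSet = SANTALUCIA_1998,
    k_max: int = 40,
) -> int:
    """Smallest k whose population Tm statistic reaches ``temperature``.

    ``stat='mean'`` answers "how long a duplex does a *typical* k-mer
    need to be stable at this temperature"; ``stat='max'`` answers "what
    is the shortest duplex that *any* k-mer composition can stabilize"
    (the admissibility floor used by the annealing search).  Returns the
    ``k_max`` sentinel when no length reaches the temperature.
    """
    if not 0.0 <= temperature <= 100.0:
        raise ValueError("temperature must be within 0-100 °C")
    for k in range(2, k_max + 1):
        if stat == "mean":
            if k <= 10:
                v = tm_population_stats(k, cond, "exhaustive", params=params)["mean"]
            else:
                v = tm_population_stats(
                    k, cond, "sampled", n_samples=20_000, seed=k, params=params
                )["mean"]
        elif stat == "max":
            v = subspace_extremum(k, cond, params, "max")
        elif stat == "min":
            v = subspace_extremum(k, cond, params, "min")
        else:
            raise ValueError(f"unknown stat {stat!r}")
        if v >= temperature:
            return k
    return k_max
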