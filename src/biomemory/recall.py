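"""Microarray-based associative recall.

Learned pools are printed as replicate spots, input fragments are
fluorescently labeled on purines and hybridized, and each spot yields a
raw intensity, a local background, a background-subtracted intensity
(BSI) and an SNR, with detection called at SNR > 3.

Signal model
------------
A labeled probe fragment is retained on a spot when it shares a
sufficiently long, thermodynamically stable exact-complement window
with a learned product: at least ``k_min`` contiguous bases (default
18 — array specificity requires extensive contiguous complementarity,
not the short chance words that any two random strands share) whose
duplex Tm reaches the effective hybridization stringency.  The expected
spot signal sums, over qualifying (product, probe) pairs, the two-state
duplex occupancy of the best shared window times the probe's label
count, then saturates against a finite spot capacity.  Observed
intensities add lognormal background; the scanner PMT gain multiplies
raw and background alike, leaving SNR invariant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import thermo
from .genome import Fragment, FragmentPool, Genome, dnase_fragment, mix_pools
from .learning import LearnedPool, TagLibrary, make_tag_library, run_learning
from .matching import SeedIndex, find_sites
from .seqs import encode

DEFAULT_HYB_KMIN = 18
SNR_THRESHOLD = 3.0


@dataclass(frozen=True)
class NoiseModel:
    """Lognormal spot background and scanner gain.

    ``bg_mean`` is the mean local background in intensity units;
    ``bg_sigma`` the lognormal shape; ``pmtg`` the scanner PMT gain
    preset (800/900/1000), acting as a pure multiplicative factor on
    raw and background so SNR is gain-invariant.
    """

    bg_mean: float = 400.0
    bg_sigma: float = 0.25
    pmtg: int = 1000

    @property
    def gain(self) -> float:
        return self.pmtg / 1000.0

    @property
    def bg_sd(self) -> float:
        """Standard deviation of a background draw (pre-gain)."""
        return self.bg_mean * math.sqrt(math.exp(self.bg_sigma**2) - 1.0)

    def draw_background(self, rng: np.random.Generator, size=None) -> np.ndarray:
        mu = math.log(self.bg_mean) - self.bg_sigma**2 / 2.0
        return rng.lognormal(mu, self.bg_sigma, size=size)


@dataclass(frozen=True)
class ArraySpot:
    spot_id: str
    role: str  # 'sample' | 'negative_control' | 'blank'
    pool_index: int  # index into PrintedArray.pools; -1 for blanks
    pool_label: str
    dilution: float
    replicate: int


@dataclass
class PrintedArray:
    """Spot layout plus the pools the spots reference."""

    pools: list[LearnedPool]
    spots: list[ArraySpot]


@dataclass
class ProbeSet:
    """Labeled input fragments; label counts are per-fragment dye counts."""

    fragments: list[Fragment]
    label_counts: np.ndarray
    label_rate: float


@dataclass(frozen=True)
class HybSignal:
    spot_id: str
    role: str
    pool_label: str
    dilution: float
    replicate: int
    raw: float
    background: float
    bsi: float
    snr: float
    detected: bool


def print_array(
    pools: list[LearnedPool],
    dilutions: tuple[float, ...] = (1.0, 0.2, 0.04),
    replicates: int = 10,
    negative_control: LearnedPool | None = None,
    blank_replicates: int | None = None,
    seed: int = 0,
) -> PrintedArray:
    """Print sample pools (plus controls) as replicate spots.

    Every pool × dilution combination is printed ``replicates`` times;
    a negative control (learned without input DNA) is printed the same
    way when provided, and blank spots (printing buffer only) complete
    the layout.
    """
    if not pools:
        raise ValueError("need at least one pool")
    all_pools = list(pools)
    roles = ["sample"] * len(pools)
    if negative_control is not None:
        all_pools.append(negative_control)
        roles.append("negative_control")
    spots: list[ArraySpot] = []
    for pi, (pool, role) in enumerate(zip(all_pools, roles)):
        for dil in dilutions:
            for rep in range(1, replicates + 1):
                spots.append(
                    ArraySpot(
                        spot_id=f"{pool.label}:d{dil:g}:r{rep}",
                        role=role,
                        pool_index=pi,
                        pool_label=pool.label,
                        dilution=dil,
                        replicate=rep,
                    )
                )
    n_blank = replicates if blank_replicates is None else blank_replicates
    for rep in range(1, n_blank + 1):
        spots.append(ArraySpot(f"blank:r{rep}", "blank", -1, "blank", 1.0, rep))
    # seeded layout shuffle (spot order on the slide)
    rng = np.random.default_rng(seed)
    rng.shuffle(spots)
    return PrintedArray(pools=all_pools, spots=spots)


def label_probes(
    pool: FragmentPool, label_rate: float = 0.05, seed: int = 0
) -> ProbeSet:
    """Label each fragment's purines independently at ``label_rate``."""
    if not 0.0 <= label_rate <= 1.0:
        raise ValueError("label_rate must be within [0, 1]")
    rng = np.random.default_rng(seed)
    purines = np.array(
        [sum(c in "AG" for c in f.sequence) for f in pool.fragments], dtype=int
    )
    counts = rng.binomial(purines, label_rate) if len(purines) else np.array([], int)
    return ProbeSet(list(pool.fragments), counts, label_rate)


def pair_template_weights(
    pool: LearnedPool,
    index: SeedIndex,
    temperature: float,
    cond: thermo.DuplexConditions = thermo.LEARNING_CONDITIONS,
    k_min: int = DEFAULT_HYB_KMIN,
) -> np.ndarray:
    """Per-probe-fragment occupancy weights against a learned pool.

    Entry t sums, over the pool's products, the two-state occupancy of
    the best qualifying shared window between the product and probe
    fragment t.  The expected (unlabeled) spot signal for a probe set
    with label counts L is then ``weights @ L``.
    """
    w = np.zeros(len(index.templates))
    if not pool.products or not index.templates:
        return w
    queries = [encode(p.sequence) for p in pool.products]
    sites = find_sites(queries, index, temperature, cond, k_min)
    best: dict[tuple[int, int], float] = {}
    t_k = temperature + thermo.CELSIUS
    ln_c = math.log(cond.strand_conc)
    for s in sites:
        dg = s.dh * 1000.0 - t_k * s.ds
        ln_kc = -dg / (thermo.R_GAS * t_k) + ln_c
        theta = 1.0 / (1.0 + math.exp(-min(max(ln_kc, -500.0), 500.0)))
        key = (s.query_index, s.template_index)
        if theta > best.get(key, 0.0):
            best[key] = theta
    for (_, t), theta in best.items():
        w[t] += theta
    return w


def _pool_expected_signal(
    pool: LearnedPool,
    probes: ProbeSet,
    index: SeedIndex,
    temperature: float,
    cond: thermo.DuplexConditions,
    k_min: int,
) -> float:
    """Σ over (product, probe) pairs: occupancy of best window × labels."""
    if not pool.products or not probes.fragments:
        return 0.0
    w = pair_template_weights(pool, index, temperature, cond, k_min)
    return float(w @ probes.label_counts)


def hybridize(
    array: PrintedArray,
    probes: ProbeSet,
    temperature: float = 55.0,
    cond: thermo.DuplexConditions = thermo.LEARNING_CONDITIONS,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    k_min: int = DEFAULT_HYB_KMIN,
    capacity: float = 2e5,
    snr_threshold: float = SNR_THRESHOLD,
) -> list[HybSignal]:
    """Hybridize labeled probes to a printed array and read out signals.

    ``temperature`` is the effective hybridization stringency in °C
    (hybridization-buffer formamide and post-hybridization washes raise
    the effective stringency well above the ambient incubation
    temperature).
    """
    if not array.spots:
        raise ValueError("array has no spots")
    if not probes.fragments:
        raise ValueError("probe set is empty")
    index = SeedIndex([encode(f.sequence) for f in probes.fragments])
    expected: dict[int, float] = {}
    for spot in array.spots:
        if spot.pool_index >= 0 and spot.pool_index not in expected:
            expected[spot.pool_index] = _pool_expected_signal(
                array.pools[spot.pool_index], probes, index, temperature, cond, k_min
            )
    rng = np.random.default_rng(seed)
    out: list[HybSignal] = []
    for spot in array.spots:
        base = expected.get(spot.pool_index, 0.0) if spot.pool_index >= 0 else 0.0
        sig = capacity * -math.expm1(-(base * spot.dilution) / capacity)
        bg_true = noise.draw_background(rng)
        bg_est = noise.draw_background(rng)
        raw = noise.gain * (sig + bg_true)
        background = noise.gain * bg_est
        bsi = raw - background
        snr = bsi / (noise.gain * noise.bg_sd)
        out.append(
            HybSignal(
                spot_id=spot.spot_id,
                role=spot.role,
                pool_label=spot.pool_label,
                dilution=spot.dilution,
                replicate=spot.replicate,
                raw=raw,
                background=background,
                bsi=bsi,
                snr=snr,
                detected=bool(snr > snr_threshold),
            )
        )
    return out


def signals_to_frame(signals: list[HybSignal]) -> pd.DataFrame:
    """Signal table in the comma-delimited layout the scanner software emits."""
    return pd.DataFrame(
        [
            {
                "spot_id": s.spot_id,
                "role": s.role,
                "pool": s.pool_label,
                "dilution": s.dilution,
                "replicate": s.replicate,
                "raw": s.raw,
                "background": s.background,
                "BSI": s.bsi,
                "SNR": s.snr,
                "detected": s.detected,
            }
            for s in signals
        ]
    )


def titration_experiment(
    fractions: list[float],
    genome_a: Genome,
    genome_b: Genome,
    n_tags: int = 30_000,
    total_fragments: int = 1000,
    mean_fragment_len: float = 200.0,
    anneal_temp: float = 55.0,
    hyb_temp: float = 55.0,
    cond: thermo.DuplexConditions = thermo.LEARNING_CONDITIONS,
    label_rate: float = 0.05,
    replicates: int = 10,
    learning_replicates: int = 3,
    noise: NoiseModel = NoiseModel(),
    k_min_hyb: int = DEFAULT_HYB_KMIN,
    seed: int = 0,
    snr_threshold: float = SNR_THRESHOLD,
) -> pd.DataFrame:
    """Learn mixtures of genome A in a background of genome B, recall with
    pure-A probes, and tabulate detection across the fraction series.

    ``fractions`` are percentages (0-100) of genome A in the input.
    Each fraction is learned ``learning_replicates`` times independently
    (fresh mixture draw and tag library) and every learned pool is
    printed with ``replicates`` replicate spots; the row reports the
    mean BSI/SNR over all spots of the fraction and a detection call on
    the mean SNR.
    """
    if any(not 0.0 <= f <= 100.0 for f in fractions):
        raise ValueError("fractions must be percentages within [0, 100]")
    root = np.random.SeedSequence(seed)
    n_seeds = 3 + 2 * len(fractions) * learning_replicates
    s_frag_a, s_frag_b, s_probe, *s_rep = [
        int(s.generate_state(1)[0] % 2**31) for s in root.spawn(n_seeds)
    ]
    pool_a = dnase_fragment(genome_a, mean_fragment_len, seed=s_frag_a)
    pool_b = dnase_fragment(genome_b, mean_fragment_len, seed=s_frag_b)
    probes = label_probes(pool_a, label_rate, seed=s_probe)
    rows = []
    for i, frac in enumerate(fractions):
        f = frac / 100.0
        bsis: list[float] = []
        snrs: list[float] = []
        n_products = n_target = 0
        for r in range(learning_replicates):
            j = 2 * (i * learning_replicates + r)
            s_mix, s_learn = s_rep[j], s_rep[j + 1]
            mixed = mix_pools(
                [(pool_a, f), (pool_b, 1.0 - f)],
                total_fragments,
                seed=s_mix,
                label=f"A{frac:g}%",
            )
            tags = make_tag_library(n_tags, seed=s_learn)
            learned = run_learning(
                mixed, tags, "AED", temperature=anneal_temp, cond=cond, seed=s_learn
            )
            array = print_array(
                [learned], dilutions=(1.0,), replicates=replicates, seed=s_mix
            )
            signals = hybridize(
                array,
                probes,
                temperature=hyb_temp,
                cond=cond,
                noise=noise,
                seed=s_learn,
                k_min=k_min_hyb,
                snr_threshold=snr_threshold,
            )
            sample = [s for s in signals if s.role == "sample"]
            bsis.extend(s.bsi for s in sample)
            snrs.extend(s.snr for s in sample)
            n_products += len(learned)
            n_target += sum(
                1
                for p in learned.products
                if p.provenance == "I-M"
                and p.template_kind == "fragment"
                and mixed.fragments[p.template_index].parent_id == genome_a.id
            )
        mean_snr = float(np.mean(snrs))
        rows.append(
            {
                "fraction": frac,
                "n_products": n_products,
                "n_target_products": n_target,
                "mean_bsi": float(np.mean(bsis)),
                "mean_snr": mean_snr,
                "detected": bool(mean_snr > snr_threshold),
            }
        )
    return pd.DataFrame(rows)
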