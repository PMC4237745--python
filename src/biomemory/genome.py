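"""Synthetic genomes, DNase I fragmentation, pool mixing and FASTA I/O.

The wet protocol digests bacterial genomic DNA with DNase I (a random
single-strand nicking endonuclease) to ~200-base fragments and then
denatures, so the learning step sees single strands from both strands of
the duplex.  Here genomes are i.i.d. base sequences at a chosen GC
content, nicking is a memoryless Bernoulli process per backbone bond per
strand, and "mixing" subsamples fragment pools at stated mass fractions.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from .seqs import InvalidSequenceError, decode, encode, random_codes, revcomp


@dataclass
class Genome:
    """A plus-strand genome sequence."""

    id: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise InvalidSequenceError("genome must be non-empty")
        encode(self.sequence)  # alphabet check

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Fragment:
    """A single-stranded fragment in 0-based half-open plus-strand coordinates.

    ``sequence`` is the 5'→3' sequence of the indicated strand; for the
    minus strand it is the reverse complement of the plus-strand slice.
    """

    parent_id: str
    strand: str  # '+' or '-'
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if not 0 <= self.start < self.end:
            raise ValueError("need 0 <= start < end")
        if len(self.sequence) != self.end - self.start:
            raise ValueError("sequence length does not match coordinates")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class FragmentPool:
    """A multiset of single-stranded fragments with mixture bookkeeping."""

    fragments: list[Fragment]
    label: str = "pool"
    mass_conc: float | None = None
    mixture: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.mixture is not None:
            total = sum(self.mixture.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError("mixture fractions must sum to 1")

    def __len__(self) -> int:
        return len(self.fragments)

    def total_bases(self) -> int:
        return sum(len(f) for f in self.fragments)

    def origin_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for f in self.fragments:
            out[f.parent_id] = out.get(f.parent_id, 0) + 1
        return out


def generate_genome(
    length: int, gc: float = 0.5, seed: int = 0, id: str | None = None
) -> Genome:
    """i.i.d. random genome with P(G) + P(C) = ``gc``."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be within [0, 1]")
    rng = np.random.default_rng(seed)
    seq = decode(random_codes(rng, length, gc))
    return Genome(id or f"synth_gc{gc:g}_seed{seed}", seq)


def _strand_fragments(
    genome: Genome, strand: str, mean_len: float, rng: np.random.Generator
) -> list[Fragment]:
    """Nick one strand at Bernoulli(1/mean_len) per internal bond."""
    L = len(genome)
    nicks = np.flatnonzero(rng.random(L - 1) < 1.0 / mean_len) + 1 if L > 1 else np.array([], dtype=int)
    if genome.circular and L > 1:
        # wrap-around: treat nick positions on the circle; with no nicks the
        # whole circle is one fragment starting at origin
        if nicks.size == 0:
            bounds = [(0, L)]
        else:
            bounds = [
                (int(nicks[i]), int(nicks[(i + 1) % nicks.size]) + (L if i == nicks.size - 1 else 0))
                for i in range(nicks.size)
            ]
    else:
        cuts = [0, *nicks.tolist(), L]
        bounds = list(zip(cuts[:-1], cuts[1:]))
    frags = []
    for s, e in bounds:
        if e <= L:
            plus_slice = genome.sequence[s:e]
            start, end = s, e
        else:  # circular wrap
            plus_slice = genome.sequence[s:] + genome.sequence[: e - L]
            start, end = s, e  # end may exceed L for wrapped fragments
        seq = plus_slice if strand == "+" else revcomp(plus_slice)
        frags.append(Fragment(genome.id, strand, start, end, seq))
    return frags


def dnase_fragment(genome: Genome, mean_len: float = 200.0, seed: int = 0) -> FragmentPool:
    """Random-nicking digestion of both strands, then denaturation.

    Each strand is nicked independently with per-bond probability
    1/mean_len (memoryless, geometric inter-nick distances); every
    inter-nick interval becomes one single-stranded fragment.
    """
    if mean_len < 10:
        raise ValueError("mean_len must be >= 10")
    rng = np.random.default_rng(seed)
    frags = _strand_fragments(genome, "+", mean_len, rng)
    frags += _strand_fragments(genome, "-", mean_len, rng)
    return FragmentPool(frags, label=genome.id)


def mix_pools(
    pools: list[tuple[FragmentPool, float]],
    total: int,
    seed: int = 0,
    label: str | None = None,
) -> FragmentPool:
    """Subsample ``total`` fragments from pools at the given fractions.

    Fragments are drawn with replacement (mass-fraction semantics: the
    same molecular species can be sampled repeatedly), with the number
    per source multinomially distributed.
    """
    fracs = [f for _, f in pools]
    if any(f < 0 for f in fracs):
        raise ValueError("fractions must be >= 0")
    if abs(sum(fracs) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(total, fracs)
    out: list[Fragment] = []
    for (pool, frac), n in zip(pools, counts):
        if n and not pool.fragments:
            raise ValueError(f"pool {pool.label!r} is empty but has fraction {frac}")
        if n:
            idx = rng.integers(0, len(pool.fragments), size=n)
            out.extend(pool.fragments[i] for i in idx)
    mixture = {pool.label: frac for pool, frac in pools}
    return FragmentPool(out, label=label or "+".join(mixture), mixture=mixture)


# ---------------------------------------------------------------------------
# FASTA round-trip; fragment provenance is encoded in the header as
# parent|strand|start|end so learned-product origins remain checkable.


def write_genome_fasta(genome: Genome, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.id}\n")
        for i in range(0, len(genome.sequence), 80):
            fh.write(genome.sequence[i : i + 80] + "\n")


def read_genome_fasta(path) -> Genome:
    rec = next(SeqIO.parse(str(path), "fasta"))
    return Genome(rec.id, str(rec.seq).upper())


def write_pool_fasta(pool: FragmentPool, path) -> None:
    with open(path, "w") as fh:
        for i, f in enumerate(pool.fragments):
            fh.write(f">frag{i} {f.parent_id}|{f.strand}|{f.start}|{f.end}\n")
            for j in range(0, len(f.sequence), 80):
                fh.write(f.sequence[j : j + 80] + "\n")


def read_pool_fasta(path, label: str = "pool") -> FragmentPool:
    frags = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parent, strand, start, end = rec.description.split(" ", 1)[1].split("|")
        frags.append(
            Fragment(parent, strand, int(start), int(end), str(rec.seq).upper())
        )
    return FragmentPool(frags, label=label)
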