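"""K-mer set analytics and closed-form counting.

Quantifies how much sequence content two genomes (or fragment pools)
share at word length k — the basis for expecting two unrelated bacterial
genomes to be discriminable by learned-product hybridization — plus the
combinatoric bookkeeping of the random-probe design space and oligo
molecular weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import FragmentPool, Genome
from .seqs import encode, kmer_codes, revcomp

AVOGADRO = 6.02214076e23

#: anhydrous average residue masses (g/mol) of nucleotide monophosphates
#: within a DNA strand; an undetermined N position averages the four.
_RESIDUE_MW = {"A": 313.21, "C": 289.18, "G": 329.21, "T": 304.20}
_RESIDUE_MW["N"] = sum(_RESIDUE_MW[b] for b in "ACGT") / 4.0
#: a free 5'-OH strand lacks one phosphate-water unit relative to the sum
_STRAND_OFFSET = -61.96

#: 5' modification masses (g/mol): biotin phosphoramidite, C6 amino linker
MODIFICATION_MW = {"biotin": 405.45, "amine": 164.16, "none": 0.0}


@dataclass(frozen=True)
class KmerSet:
    """Distinct k-mers of a source, packed as 2-bit integer codes."""

    k: int
    codes: frozenset
    mode: str  # 'strand-specific' | 'both-strands'
    source: str = ""

    def __len__(self) -> int:
        return len(self.codes)


@dataclass(frozen=True)
class CommonalityRecord:
    """Shared k-mer content between two sources.

    ``fraction`` divides the intersection by the smaller set (the
    convention used for the "common sequences" comparison);
    ``fraction_union`` is the Jaccard index.
    """

    k: int
    size_a: int
    size_b: int
    intersection: int
    union: int

    @property
    def fraction(self) -> float:
        m = min(self.size_a, self.size_b)
        return self.intersection / m if m else 0.0

    @property
    def fraction_union(self) -> float:
        return self.intersection / self.union if self.union else 0.0


def _sequences_of(source: Genome | FragmentPool | list[str]) -> tuple[list[str], str]:
    if isinstance(source, Genome):
        return [source.sequence], source.id
    if isinstance(source, FragmentPool):
        return [f.sequence for f in source.fragments], source.label
    return list(source), ""


def kmer_set(
    source: Genome | FragmentPool | list[str], k: int, mode: str = "both-strands"
) -> KmerSet:
    """Distinct k-mers of a genome or pool (optionally both strands)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if mode not in ("strand-specific", "both-strands"):
        raise ValueError("mode must be 'strand-specific' or 'both-strands'")
    seqs, label = _sequences_of(source)
    codes: set[int] = set()
    for s in seqs:
        codes.update(kmer_codes(encode(s), k).tolist())
        if mode == "both-strands":
            codes.update(kmer_codes(encode(revcomp(s)), k).tolist())
    return KmerSet(k, frozenset(codes), mode, label)


def common_fraction(a: KmerSet, b: KmerSet) -> CommonalityRecord:
    """Exact shared k-mer counts between two sets of matching k and mode."""
    if a.k != b.k:
        raise ValueError("k mismatch")
    if a.mode != b.mode:
        raise ValueError("canonicalization mode mismatch")
    inter = len(a.codes & b.codes)
    return CommonalityRecord(
        k=a.k,
        size_a=len(a),
        size_b=len(b),
        intersection=inter,
        union=len(a) + len(b) - inter,
    )


def design_space(k: int) -> int:
    """Number of distinct k-base sequences, exactly 4**k."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return 4**k


def strands_in_volume(conc: float, volume: float) -> float:
    """Number of strands at molar concentration ``conc`` in ``volume`` liters."""
    if conc < 0 or volume < 0:
        raise ValueError("conc and volume must be >= 0")
    return conc * volume * AVOGADRO


def copies_per_unique(conc: float, volume: float, k: int) -> float:
    """Expected copies of each distinct random k-mer in the reaction volume."""
    return strands_in_volume(conc, volume) / design_space(k)


def oligo_mw(sequence: str, modification: str = "none") -> float:
    """Anhydrous average molecular weight (g/mol) of a synthetic oligo.

    ``N`` positions average over the four bases; the 5' modification
    adds a vendor linker mass.  An empty sequence returns the
    modification mass alone.
    """
    if modification not in MODIFICATION_MW:
        raise ValueError(f"unknown modification {modification!r}")
    total = MODIFICATION_MW[modification]
    if sequence:
        for base in sequence.upper():
            if base not in _RESIDUE_MW:
                raise ValueError(f"unknown base {base!r}")
            total += _RESIDUE_MW[base]
        total += _STRAND_OFFSET
    return total
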