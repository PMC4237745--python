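"""Low-level nucleotide sequence utilities.

Sequences are plain Python strings over ``ACGT`` at the API surface and
``numpy.uint8`` arrays (A=0, C=1, G=2, T=3) internally, so that batch
operations (thermodynamic sums, k-mer rolling codes) vectorize.
"""

from __future__ import annotations

import numpy as np

ALPHABET = "ACGT"

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(ALPHABET):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)

#: complement in code space: A<->T, C<->G
COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.uint8)

_COMP_STR = str.maketrans("ACGTacgt", "TGCAtgca")


class InvalidSequenceError(ValueError):
    """Raised when a sequence is empty or contains a non-ACGT character."""


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string into a uint8 code array."""
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.size and arr.max() > 3:
        bad = seq[int(np.argmax(arr > 3))]
        raise InvalidSequenceError(f"unknown base {bad!r} in sequence")
    return arr


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return _DECODE[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMP_STR)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return COMPLEMENT[codes][::-1]


def is_self_complementary(seq: str) -> bool:
    return seq == revcomp(seq)


def gc_fraction(seq: str) -> float:
    codes = encode(seq)
    return float(np.mean((codes == 1) | (codes == 2))) if codes.size else 0.0


def purine_count(seq: str) -> int:
    """Number of purines (A or G) — the bases targeted by N7 dye chemistry."""
    codes = encode(seq)
    return int(np.sum((codes == 0) | (codes == 2)))


def random_codes(rng: np.random.Generator, length: int, gc: float = 0.5) -> np.ndarray:
    """i.i.d. base codes with P(G)+P(C) = ``gc``."""
    p_at = (1.0 - gc) / 2.0
    p_gc = gc / 2.0
    return rng.choice(4, size=length, p=[p_at, p_gc, p_gc, p_at]).astype(np.uint8)


def random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    return decode(random_codes(rng, length, gc))


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Rolling 2-bit packed codes of all k-mers of ``codes`` (int64).

    Requires ``k <= 31``. Returns an empty array when the sequence is
    shorter than k.
    """
    if k > 31:
        raise ValueError("packed k-mer codes support k <= 31")
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    c = codes.astype(np.int64)
    out = np.zeros(n, dtype=np.int64)
    for i in range(k):
        out = (out << 2) | c[i : i + n] if i else c[:n].copy()
    return out


def enumerate_kmers(k: int) -> np.ndarray:
    """All 4**k k-mers as a (4**k, k) uint8 code matrix (k <= 12)."""
    if k > 12:
        raise ValueError("exhaustive enumeration limited to k <= 12")
    idx = np.arange(4**k, dtype=np.int64)
    mat = np.empty((4**k, k), dtype=np.uint8)
    for j in range(k):
        mat[:, k - 1 - j] = (idx >> (2 * j)) & 3
    return mat
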