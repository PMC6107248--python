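"""Shared low-level sequence helpers (DNA alphabet, Hamming comparisons)."""

from __future__ import annotations

import numpy as np

DNA = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: byte values of A/C/G/T, used to decode integer code arrays into sequences
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence (N allowed, maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def as_dna(seq: str) -> str:
    """Upper-case and convert RNA U to DNA T (single storage alphabet)."""
    return seq.upper().replace("U", "T")


def hamming_within(a: str, b: str, limit: int) -> int:
    """Number of substitutions between equal-length strings, or -1 if > limit.

    Early exit keeps the inner loop of the seed-and-verify matcher cheap.
    """
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return -1
    return mm


def random_sequences(rng: np.random.Generator, lengths) -> list[str]:
    """Draw uniform random A/C/G/T sequences with the given lengths.

    Vectorised over one flat byte buffer so that library-scale draws
    (10^5-10^6 reads) stay fast.
    """
    lengths = [int(x) for x in lengths]
    total = sum(lengths)
    codes = rng.integers(0, 4, size=total, dtype=np.uint8)
    flat = _BASE_BYTES[codes].tobytes()
    out = []
    off = 0
    for length in lengths:
        out.append(flat[off : off + length].decode("ascii"))
        off += length
    return out


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return random_sequences(rng, [length])[0]


def derive_seeds(seed: int, n: int) -> list[int]:
    """Derive n reproducible 31-bit child seeds from one master seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]
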