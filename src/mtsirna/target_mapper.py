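"""Mismatch-tolerant placement of siRNAs onto transcripts, both strands.

Matching is full-length and ungapped with at most ``max_mm`` substitutions
(default 1): siRNA-directed cleavage requires near-perfect pairing, and
indel-tolerant alignment would blur cleavage-site coordinates. The fast path
is seed-and-verify with pigeonhole seeding: the query is split into
``max_mm + 1`` segments, at least one of which must match exactly, so looking
up the k-mer at each segment start finds every valid placement provided
k <= floor(|siRNA| / (max_mm + 1)). A brute-force sliding-window scanner with
identical semantics serves as the independent oracle in tests.

A '+' hit means the siRNA shares the transcript strand; a '-' hit means the
reverse complement of the siRNA matches the transcript window (the siRNA is
complementary to the transcript). Minus-strand hits are recorded at the
coordinates of the matched transcript window. Coordinates are 0-based
half-open internally; serialisers emit 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from ._util import hamming_within, revcomp

__all__ = ["TargetHit", "KmerIndex", "build_index", "map_sirna", "brute_force_map"]

SIRNA_MIN_LEN = 18
SIRNA_MAX_LEN = 26
DEFAULT_INDEX_K = 8  # satisfies the pigeonhole bound for 18-nt reads at max_mm=1


@dataclass(frozen=True)
class TargetHit:
    """Placement of one siRNA on one transcript."""

    sirna: str
    transcript_id: str
    start: int
    end: int
    strand: str
    mismatches: int

    @property
    def sort_key(self):
        return (self.transcript_id, self.start, self.strand, self.sirna)


class KmerIndex:
    """Exact k-mer -> (transcript_id, position) index over a transcript set."""

    def __init__(self, transcripts: Mapping[str, str], k: int = DEFAULT_INDEX_K):
        if k < 4:
            raise ValueError("k must be >= 4")
        self.k = k
        self.transcripts = dict(transcripts)
        index: dict[str, list[tuple[str, int]]] = {}
        for tid, seq in self.transcripts.items():
            for pos in range(len(seq) - k + 1):
                index.setdefault(seq[pos : pos + k], []).append((tid, pos))
        self._index = index

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self._index.get(kmer, [])

    @property
    def n_positions(self) -> int:
        return sum(len(v) for v in self._index.values())


def build_index(transcripts: Mapping[str, str], k: int = DEFAULT_INDEX_K) -> KmerIndex:
    return KmerIndex(transcripts, k=k)


def _validate_query(sirna: str, max_mm: int) -> None:
    if "N" in sirna:
        raise ValueError("siRNA contains ambiguous base N")
    if not SIRNA_MIN_LEN <= len(sirna) <= SIRNA_MAX_LEN:
        raise ValueError(
            f"siRNA length {len(sirna)} outside [{SIRNA_MIN_LEN}, {SIRNA_MAX_LEN}]"
        )
    if max_mm not in (0, 1, 2):
        raise ValueError("max_mm must be 0, 1 or 2")


def map_sirna(sirna: str, index: KmerIndex, max_mm: int = 1) -> list[TargetHit]:
    """All full-length ungapped placements with <= max_mm substitutions.

    Complete by the pigeonhole principle; requires
    ``index.k <= len(sirna) // (max_mm + 1)``.
    """
    _validate_query(sirna, max_mm)
    length = len(sirna)
    seg = length // (max_mm + 1)
    if index.k > seg:
        raise ValueError(
            f"index k={index.k} too large for pigeonhole seeding of a "
            f"{length}-nt siRNA at max_mm={max_mm} (need k <= {seg})"
        )
    hits: set[TargetHit] = set()
    for strand, pattern in (("+", sirna), ("-", revcomp(sirna))):
        for i in range(max_mm + 1):
            seg_start = i * seg
            seed = pattern[seg_start : seg_start + index.k]
            for tid, pos in index.lookup(seed):
                start = pos - seg_start
                transcript = index.transcripts[tid]
                if start < 0 or start + length > len(transcript):
                    continue
                mm = hamming_within(transcript[start : start + length], pattern, max_mm)
                if mm >= 0:
                    hits.add(TargetHit(sirna, tid, start, start + length, strand, mm))
    return sorted(hits, key=lambda h: h.sort_key)


def brute_force_map(
    sirna: str, transcripts: Mapping[str, str], max_mm: int = 1
) -> list[TargetHit]:
    """Exhaustive sliding-window Hamming scan, both strands (test oracle).

    O(total transcript length x siRNA length); intended for small inputs.
    """
    _validate_query(sirna, max_mm)
    length = len(sirna)
    hits: list[TargetHit] = []
    for tid, seq in transcripts.items():
        for start in range(len(seq) - length + 1):
            window = seq[start : start + length]
            for strand, pattern in (("+", sirna), ("-", revcomp(sirna))):
                mm = hamming_within(window, pattern, max_mm)
                if mm >= 0:
                    hits.append(
                        TargetHit(sirna, tid, start, start + length, strand, mm)
                    )
    return sorted(set(hits), key=lambda h: h.sort_key)


def map_many(
    sirnas: Iterable[str], index: KmerIndex, max_mm: int = 1
) -> list[TargetHit]:
    """Map a collection of siRNAs; concatenated, canonically sorted hits."""
    hits: list[TargetHit] = []
    for s in sirnas:
        hits.extend(map_sirna(s, index, max_mm=max_mm))
    return sorted(hits, key=lambda h: h.sort_key)
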