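"""5'RACE product trimming, alignment and cleavage-site calling.

A 5'RACE read of a cleavage product carries (optionally) vector sequence, the
anchor adaptor, a terminal-transferase poly(C) tail, and then the transcript
suffix whose first base is the cleavage position. Trimming removes the vector
prefix (exact), the adaptor (<= 1 mismatch, at the read start) and the maximal
run of >= 3 C following it; shorter C runs are treated as genuine sequence.
The trimmed insert is aligned full-length and ungapped to the transgene
transcript; the placement of its first base is the inferred 5' end. Reads with
two or more equally good placements are flagged ambiguous and excluded from
calling, because cleavage-position evidence must be unique. Supported sites
are then classified as inside/outside the designed target element; the design
behaves sequence-specifically when every supported site lies inside it.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from ._util import hamming_within
from .target_mapper import TargetHit

__all__ = [
    "TrimResult",
    "AlignResult",
    "CleavageCall",
    "SpecificitySummary",
    "trim_race_read",
    "align_5prime",
    "call_cleavage_sites",
    "classify_specificity",
    "map_race_reads",
]

MIN_TRIMMED_LEN = 15
MIN_POLYC_RUN = 3


@dataclass(frozen=True)
class TrimResult:
    sequence: str
    status: str  # "ok" | "no_adaptor" | "too_short"
    reason: str = ""

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def trim_race_read(
    read: str,
    adaptor: str,
    vector: str | None = None,
    max_adaptor_mm: int = 1,
    min_len: int = MIN_TRIMMED_LEN,
) -> TrimResult:
    """Strip vector prefix, adaptor and poly(C) tail from a RACE read.

    Reads lacking the adaptor are rejected but pass their sequence through
    unchanged, so trimming is idempotent on the sequence component.
    """
    if not read:
        raise ValueError("empty read")
    seq = read
    if vector and seq.startswith(vector):
        seq = seq[len(vector) :]
    if len(seq) < len(adaptor) or hamming_within(
        seq[: len(adaptor)], adaptor, max_adaptor_mm
    ) < 0:
        return TrimResult(read, "no_adaptor", "adaptor not found at read start")
    seq = seq[len(adaptor) :]
    run = 0
    while run < len(seq) and seq[run] == "C":
        run += 1
    if run >= MIN_POLYC_RUN:
        seq = seq[run:]
    if len(seq) < min_len:
        return TrimResult(seq, "too_short", f"trimmed remainder < {min_len} nt")
    return TrimResult(seq, "ok")


@dataclass(frozen=True)
class AlignResult:
    status: str  # "unique" | "ambiguous" | "no_hit"
    position: int | None = None
    mismatches: int | None = None


def align_5prime(trimmed: str, transcript: str, max_mm: int = 1) -> AlignResult:
    """Best full-length ungapped placement of the insert on the transcript.

    Returns the position of the insert's first base (the inferred cleavage
    site). If two or more placements tie at the minimal mismatch count, the
    read is ambiguous; if no placement has <= max_mm mismatches, no-hit.
    """
    if len(trimmed) < MIN_TRIMMED_LEN:
        raise ValueError(f"trimmed read shorter than {MIN_TRIMMED_LEN} nt")
    best_mm = max_mm + 1
    best_pos: int | None = None
    n_best = 0
    for start in range(len(transcript) - len(trimmed) + 1):
        mm = hamming_within(transcript[start : start + len(trimmed)], trimmed, best_mm)
        if mm < 0:
            continue
        if mm < best_mm:
            best_mm, best_pos, n_best = mm, start, 1
        elif mm == best_mm:
            n_best += 1
    if best_pos is None:
        return AlignResult("no_hit")
    if n_best > 1:
        return AlignResult("ambiguous", position=None, mismatches=best_mm)
    return AlignResult("unique", position=best_pos, mismatches=best_mm)


@dataclass
class CleavageCall:
    position: int  # 0-based transcript coordinate of the inferred 5' end
    support: int
    within_target: bool | None = None
    nearest_sirna_hit: TargetHit | None = None


def call_cleavage_sites(
    positions: Sequence[int], min_support: int = 2
) -> list[CleavageCall]:
    """Group identical 5'-end positions; keep groups with enough read support."""
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    counts = Counter(int(p) for p in positions)
    return [
        CleavageCall(position=p, support=c)
        for p, c in sorted(counts.items())
        if c >= min_support
    ]


@dataclass
class SpecificitySummary:
    n_within: int
    n_outside: int
    fraction_within: float | None
    verdict: str  # "sequence-specific" | "off-target cleavage" | "no cleavage detected"
    calls: list[CleavageCall]

    def to_frame(self, transcript_length: int | None = None) -> pd.DataFrame:
        rows = []
        for c in self.calls:
            row = {
                "position": c.position + 1,  # 1-based in reports
                "support": c.support,
                "within_target": c.within_target,
                "nearest_sirna": c.nearest_sirna_hit.sirna if c.nearest_sirna_hit else "",
            }
            if transcript_length is not None:
                # distance from the cleavage site to the 3'-end RACE primer:
                # the expected size of the cleaved 5'RACE product
                row["product_size"] = transcript_length - c.position
            rows.append(row)
        return pd.DataFrame(rows)


def classify_specificity(
    calls: Iterable[CleavageCall],
    target_interval: tuple[int, int],
    hits: Iterable[TargetHit] = (),
) -> SpecificitySummary:
    """Label calls inside/outside the target element and render a verdict.

    A call falling inside an siRNA hit footprint gets that hit attached
    (closest footprint centre when several contain it).
    """
    t0, t1 = target_interval
    if t0 > t1:
        raise ValueError("invalid target interval")
    hits = list(hits)
    labelled: list[CleavageCall] = []
    for c in sorted(calls, key=lambda c: c.position):
        within = t0 <= c.position < t1
        containing = [h for h in hits if h.start <= c.position < h.end]
        nearest = (
            min(containing, key=lambda h: abs((h.start + h.end) / 2 - c.position))
            if containing
            else None
        )
        labelled.append(
            CleavageCall(c.position, c.support, within_target=within, nearest_sirna_hit=nearest)
        )
    n_within = sum(1 for c in labelled if c.within_target)
    n_outside = len(labelled) - n_within
    if not labelled:
        return SpecificitySummary(0, 0, None, "no cleavage detected", [])
    fraction = n_within / len(labelled)
    verdict = "sequence-specific" if n_outside == 0 else "off-target cleavage"
    return SpecificitySummary(n_within, n_outside, fraction, verdict, labelled)


@dataclass
class RaceMappingStats:
    n_reads: int
    n_trimmed: int
    n_rejected: int
    n_no_hit: int
    n_ambiguous: int
    positions: list[int]


def map_race_reads(
    reads: Iterable[tuple[str, str]],
    transcript: str,
    adaptor: str,
    vector: str | None = None,
    max_mm: int = 1,
) -> RaceMappingStats:
    """Trim and align a RACE read set; collect unambiguous 5'-end positions."""
    n_reads = n_trimmed = n_rejected = n_no_hit = n_ambiguous = 0
    positions: list[int] = []
    for _rid, seq in reads:
        n_reads += 1
        trimmed = trim_race_read(seq, adaptor, vector=vector)
        if not trimmed.ok:
            n_rejected += 1
            continue
        n_trimmed += 1
        aln = align_5prime(trimmed.sequence, transcript, max_mm=max_mm)
        if aln.status == "no_hit":
            n_no_hit += 1
        elif aln.status == "ambiguous":
            n_ambiguous += 1
        else:
            positions.append(aln.position)
    return RaceMappingStats(n_reads, n_trimmed, n_rejected, n_no_hit, n_ambiguous, positions)
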