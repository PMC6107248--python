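"""Stranded recognition-site coverage profiles and dense fixed-width windows.

The profile accumulates, per transcript position, the tassel abundance (TPM)
of every siRNA hit covering that position, separately for hits sharing the
transcript strand (plus) and complementary hits (minus), together with
distinct-hit counters. Candidate target regions are fixed-width windows
(default 201 nt) scored by the number of distinct siRNAs whose recognition
site lies fully inside the window; best windows are selected greedily with
overlap suppression (ties: larger TPM mass, then leftmost).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .target_mapper import TargetHit

__all__ = [
    "CoverageProfile",
    "CandidateRegion",
    "build_profile",
    "find_windows",
    "annotate_regions",
]

DEFAULT_WINDOW = 201
DEFAULT_MIN_DISTINCT = 5


@dataclass
class CoverageProfile:
    transcript_id: str
    length: int
    plus: np.ndarray
    minus: np.ndarray
    distinct_plus: np.ndarray
    distinct_minus: np.ndarray
    hits: list[TargetHit] = field(default_factory=list)
    tpm: dict[str, float] = field(default_factory=dict)

    @property
    def total_mass(self) -> float:
        return float(self.plus.sum() + self.minus.sum())


@dataclass
class CandidateRegion:
    transcript_id: str
    start: int
    end: int
    distinct_sirnas: int
    tpm_mass: float
    rank: int

    @property
    def width(self) -> int:
        return self.end - self.start


def build_profile(
    hits: Iterable[TargetHit],
    sirna_tpm: Mapping[str, float],
    transcript_id: str,
    transcript_length: int,
) -> CoverageProfile:
    """Accumulate per-position TPM and distinct-hit counts for one transcript."""
    hits = list(hits)
    plus = np.zeros(transcript_length)
    minus = np.zeros(transcript_length)
    d_plus = np.zeros(transcript_length, dtype=np.int64)
    d_minus = np.zeros(transcript_length, dtype=np.int64)
    for h in hits:
        if h.transcript_id != transcript_id:
            raise ValueError(f"hit on {h.transcript_id} given to {transcript_id} profile")
        if h.start < 0 or h.end > transcript_length:
            raise ValueError(f"hit [{h.start}, {h.end}) out of bounds")
        tpm = float(sirna_tpm.get(h.sirna, 0.0))
        if h.strand == "+":
            plus[h.start : h.end] += tpm
            d_plus[h.start : h.end] += 1
        else:
            minus[h.start : h.end] += tpm
            d_minus[h.start : h.end] += 1
    return CoverageProfile(
        transcript_id=transcript_id,
        length=transcript_length,
        plus=plus,
        minus=minus,
        distinct_plus=d_plus,
        distinct_minus=d_minus,
        hits=hits,
        tpm={h.sirna: float(sirna_tpm.get(h.sirna, 0.0)) for h in hits},
    )


def _window_scores(profile: CoverageProfile, W: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-start distinct-hit count and TPM mass of fully contained hits."""
    n_starts = profile.length - W + 1
    count_diff = np.zeros(n_starts + 1)
    mass_diff = np.zeros(n_starts + 1)
    for h in profile.hits:
        lo = max(0, h.end - W)
        hi = min(h.start, n_starts - 1)
        if lo > hi:
            continue  # hit longer than window or near an edge; never contained
        count_diff[lo] += 1
        count_diff[hi + 1] -= 1
        tpm = profile.tpm.get(h.sirna, 0.0)
        mass_diff[lo] += tpm
        mass_diff[hi + 1] -= tpm
    return np.cumsum(count_diff[:-1]), np.cumsum(mass_diff[:-1])


def find_windows(
    profile: CoverageProfile,
    W: int = DEFAULT_WINDOW,
    min_distinct: int = DEFAULT_MIN_DISTINCT,
    step: int = 1,
) -> list[CandidateRegion]:
    """Greedy selection of non-overlapping width-W windows dense in hits.

    Windows are scored by the number of distinct siRNA hits fully contained;
    candidates with score >= min_distinct are selected best-first (ties broken
    by larger TPM mass, then leftmost) suppressing overlaps with already
    selected windows.
    """
    if W > profile.length:
        raise ValueError(f"window {W} wider than transcript {profile.length}")
    if W < 1 or step < 1:
        raise ValueError("W and step must be >= 1")
    counts, masses = _window_scores(profile, W)
    candidates = [
        (int(s), int(counts[s]), float(masses[s]))
        for s in range(0, len(counts), step)
        if counts[s] >= min_distinct
    ]
    candidates.sort(key=lambda c: (-c[1], -c[2], c[0]))
    selected: list[CandidateRegion] = []
    for start, score, mass in candidates:
        if any(start < r.end and start + W > r.start for r in selected):
            continue
        selected.append(
            CandidateRegion(
                transcript_id=profile.transcript_id,
                start=start,
                end=start + W,
                distinct_sirnas=score,
                tpm_mass=round(mass, 6),
                rank=len(selected) + 1,
            )
        )
    return selected


def annotate_regions(
    regions: Iterable[CandidateRegion],
    profile: CoverageProfile,
    transcripts: Mapping[str, str],
) -> pd.DataFrame:
    """Region report rows: 1-based inclusive coordinates, per-strand distinct
    counts, TPM mass and the window sequence."""
    rows = []
    for r in regions:
        seq = transcripts[r.transcript_id][r.start : r.end]
        contained = [
            h
            for h in profile.hits
            if h.transcript_id == r.transcript_id
            and h.start >= r.start
            and h.end <= r.end
        ]
        rows.append(
            {
                "transcript_id": r.transcript_id,
                "start": r.start + 1,  # 1-based inclusive in reports
                "end": r.end,
                "width": r.width,
                "rank": r.rank,
                "distinct_sirnas": r.distinct_sirnas,
                "distinct_plus": sum(1 for h in contained if h.strand == "+"),
                "distinct_minus": sum(1 for h in contained if h.strand == "-"),
                "tpm_mass": r.tpm_mass,
                "sequence": seq,
            }
        )
    return pd.DataFrame(rows)
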