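"""Synthetic multi-tissue small RNA study with planted ground truth.

This module generates every input the pipeline consumes: a random
transcriptome with one designated donor transcript, a cluster of
tassel-enriched siRNAs (18-26 nt, both strands) planted inside a chosen donor
region, multi-tissue sequencing libraries in which the planted siRNAs realise
target abundances in a configurable TPM window (default [40, 2660] reads per
million), germplasm amplicon variants at a controlled substitution divergence,
a microarray-style replicate signal panel, and 5'RACE product reads decorated
with adaptor / poly(C) / vector sequence that begin exactly at planted
cleavage positions. The planted truth travels alongside as a JSON-serialisable
:class:`GroundTruth`, so every downstream stage can be scored against a known
answer.

Deliberately not modelled: sequencing errors, adapter dimers and RNA secondary
structure; read counts are Poisson with no PCR-duplicate structure.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import derive_seeds, random_sequence, random_sequences, revcomp
from .smallrna_catalog import SmallRNALibrary

__all__ = [
    "GroundTruth",
    "PlantedSirna",
    "TissueSample",
    "DEFAULT_PANEL",
    "DEFAULT_TPM_WINDOW",
    "DEFAULT_LENGTH_WEIGHTS",
    "DEFAULT_RACE_ADAPTOR",
    "SYNTHETIC_VECTOR",
    "generate_transcriptome",
    "plant_sirna_cluster",
    "generate_libraries",
    "generate_race_reads",
    "generate_germplasm_variants",
    "generate_microarray_panel",
]

SIRNA_MIN_LEN = 18
SIRNA_MAX_LEN = 26

#: tassel-tissue abundance window for planted siRNAs, reads per million
DEFAULT_TPM_WINDOW = (40.0, 2660.0)

#: siRNA length distribution over 18-26 nt, peaked at the canonical 21/22/24
DEFAULT_LENGTH_WEIGHTS = {
    18: 0.03, 19: 0.04, 20: 0.07, 21: 0.22, 22: 0.16,
    23: 0.08, 24: 0.25, 25: 0.10, 26: 0.05,
}

#: synthetic RACE anchor-adaptor (constant; avoids a trailing C so the
#: adaptor/poly(C) boundary is unambiguous)
DEFAULT_RACE_ADAPTOR = "CGACTGGAGCACGAGGACACTGA"

#: synthetic 60-nt cloning-vector contaminant prefix (fixed constant so that
#: vector trimming is exactly testable)
SYNTHETIC_VECTOR = (
    "TGTAAAACGACGGCCAGTGAATTGTAATACGACTCACTATAGGGCGAATTGGGTACACTA"
)


@dataclass(frozen=True)
class PlantedSirna:
    """One planted siRNA: sequence, donor-strand placement and abundance target.

    ``start``/``end`` are 0-based half-open coordinates of the recognition site
    on the donor transcript; for strand '-' the siRNA sequence is the reverse
    complement of donor[start:end].
    """

    sequence: str
    strand: str
    start: int
    end: int
    tpm_target: float


@dataclass
class GroundTruth:
    """Planted truth for one synthetic study."""

    donor_transcript_id: str
    planted_region: tuple[int, int]
    planted_sirnas: list[PlantedSirna] = field(default_factory=list)
    cleavage_positions: list[int] = field(default_factory=list)
    germplasm_divergence: float = 0.0
    seed: int = 0

    @property
    def planted_sequences(self) -> set[str]:
        return {p.sequence for p in self.planted_sirnas}

    def to_json(self, path: str | Path) -> None:
        doc = asdict(self)
        doc["planted_region"] = list(self.planted_region)
        Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        doc = json.loads(Path(path).read_text())
        doc["planted_region"] = tuple(doc["planted_region"])
        doc["planted_sirnas"] = [PlantedSirna(**p) for p in doc["planted_sirnas"]]
        return cls(**doc)


@dataclass(frozen=True)
class TissueSample:
    tissue: str
    stage: str = ""
    replicate: int = 1

    @property
    def library_id(self) -> str:
        return f"{self.tissue}_{self.stage}_r{self.replicate}"


#: 15-organ panel: tassel at three developmental stages plus leaf, root, ear,
#: silk and shoot samples across stages (one library per organ/stage).
DEFAULT_PANEL: list[TissueSample] = [
    TissueSample("tassel", "V6"),
    TissueSample("tassel", "V8"),
    TissueSample("tassel", "V10"),
    TissueSample("leaf", "V6"),
    TissueSample("leaf", "V10"),
    TissueSample("leaf", "VT"),
    TissueSample("root", "VE"),
    TissueSample("root", "V6"),
    TissueSample("root", "V10"),
    TissueSample("ear", "5DBP"),
    TissueSample("ear", "1DAP"),
    TissueSample("ear", "10DAP"),
    TissueSample("silk", "VT"),
    TissueSample("shoot", "VE"),
    TissueSample("ear", "silking"),
]


def generate_transcriptome(
    n_transcripts: int,
    length_range: tuple[int, int],
    seed: int,
    donor_length: int | None = None,
) -> tuple[dict[str, str], GroundTruth]:
    """Uniform random A/C/G/T transcripts; the first one is the donor.

    ``donor_length`` pins the donor to an exact length (e.g. 1826 nt to mirror
    a real exemplar cDNA) while the rest are drawn from ``length_range``.
    """
    if n_transcripts < 1:
        raise ValueError("n_transcripts must be >= 1")
    lo, hi = int(length_range[0]), int(length_range[1])
    if lo < 300 or hi < lo:
        raise ValueError("transcript lengths must be >= 300 with lo <= hi")
    if donor_length is not None and donor_length < 300:
        raise ValueError("donor_length must be >= 300")
    rng = np.random.default_rng(seed)
    lengths = rng.integers(lo, hi + 1, size=n_transcripts).tolist()
    if donor_length is not None:
        lengths[0] = int(donor_length)
    seqs = random_sequences(rng, lengths)
    transcripts = {f"TX{i + 1:04d}": s for i, s in enumerate(seqs)}
    donor_id = "TX0001"
    truth = GroundTruth(donor_transcript_id=donor_id, planted_region=(0, 0), seed=seed)
    return transcripts, truth


def _draw_lengths(rng: np.random.Generator, n: int, length_dist) -> np.ndarray:
    dist = dict(DEFAULT_LENGTH_WEIGHTS if length_dist is None else length_dist)
    lens = np.array(sorted(dist), dtype=int)
    if lens.min() < SIRNA_MIN_LEN or lens.max() > SIRNA_MAX_LEN:
        raise ValueError("length distribution must be supported on [18, 26]")
    w = np.array([dist[int(l)] for l in lens], dtype=float)
    w = w / w.sum()
    return rng.choice(lens, size=n, p=w)


def plant_sirna_cluster(
    donor: str,
    region: tuple[int, int],
    n_sirnas: int,
    strand_mix: float = 0.5,
    length_dist: dict[int, float] | None = None,
    seed: int = 0,
    tpm_window: tuple[float, float] = DEFAULT_TPM_WINDOW,
) -> list[PlantedSirna]:
    """Plant ``n_sirnas`` distinct siRNAs inside ``region`` of the donor.

    ``strand_mix`` is the fraction of minus-strand (complementary) siRNAs;
    0 means all plus-strand. Overlaps are permitted. The first two siRNAs are
    anchored at the region boundaries so the cluster spans the full region,
    which makes the densest fixed-width window well defined. Tassel abundance
    targets are drawn log-uniformly from ``tpm_window``.
    """
    r0, r1 = int(region[0]), int(region[1])
    if not (0 <= r0 < r1 <= len(donor)):
        raise ValueError(f"region {region} outside donor of length {len(donor)}")
    if r1 - r0 < SIRNA_MAX_LEN + 1:
        raise ValueError(f"region width {r1 - r0} narrower than {SIRNA_MAX_LEN + 1}")
    if n_sirnas < 1:
        raise ValueError("n_sirnas must be >= 1")
    if not 0.0 <= strand_mix <= 1.0:
        raise ValueError("strand_mix must be in [0, 1]")

    rng = np.random.default_rng(seed)
    lo, hi = tpm_window
    planted: list[PlantedSirna] = []
    seen: set[str] = set()
    attempts = 0
    while len(planted) < n_sirnas:
        attempts += 1
        if attempts > 200 * n_sirnas:
            raise RuntimeError("could not plant enough distinct siRNAs in region")
        length = int(_draw_lengths(rng, 1, length_dist)[0])
        idx = len(planted)
        if idx == 0:
            start = r0  # anchor cluster at region start
        elif idx == 1:
            start = r1 - length  # anchor cluster at region end
        else:
            start = int(rng.integers(r0, r1 - length + 1))
        end = start + length
        minus = rng.random() < strand_mix
        site = donor[start:end]
        seq = revcomp(site) if minus else site
        if seq in seen:
            continue
        seen.add(seq)
        tpm = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        planted.append(
            PlantedSirna(seq, "-" if minus else "+", start, end, round(tpm, 3))
        )
    return planted


def _truncated_poisson(rng: np.random.Generator, lam: float, lo: int, hi: int) -> int:
    """Poisson draw resampled (then clamped) into [lo, hi].

    Truncation enforces the contract that realised tassel TPM stays inside the
    target window even for siRNAs whose target sits at a window edge.
    """
    for _ in range(30):
        x = int(rng.poisson(lam))
        if lo <= x <= hi:
            return x
    return min(max(int(rng.poisson(lam)), lo), hi)


def generate_libraries(
    samples: list[TissueSample],
    truth: GroundTruth,
    depth: int = 1_000_000,
    background_rate: float = 0.0,
    seed: int = 0,
    target_tissue: str = "tassel",
    tpm_window: tuple[float, float] = DEFAULT_TPM_WINDOW,
    length_dist: dict[int, float] | None = None,
) -> list[SmallRNALibrary]:
    """Simulate one collapsed library per sample at exactly ``depth`` reads.

    Planted siRNAs realise truncated-Poisson counts inside ``tpm_window`` in
    target-tissue libraries, leak into other tissues at ``background_rate``
    (0 = no leak), and the remaining depth is filled with distinct uniform
    random 18-26-nt background sequences, one read each.
    """
    if depth < 25_000:
        raise ValueError(
            f"depth {depth} < 25000: the {tpm_window[0]:.0f}-TPM floor would "
            "require less than one read"
        )
    tissues = {s.tissue for s in samples}
    if target_tissue not in tissues:
        raise ValueError(f"no {target_tissue!r} sample in the panel")
    if not 0.0 <= background_rate <= 1.0:
        raise ValueError("background_rate must be in [0, 1]")
    ids = [s.library_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate library_id in sample panel")

    lo_count = max(1, math.ceil(tpm_window[0] * depth / 1e6))
    hi_count = max(lo_count, math.floor(tpm_window[1] * depth / 1e6))
    planted_set = truth.planted_sequences
    libs: list[SmallRNALibrary] = []
    child_seeds = derive_seeds(seed, len(samples))
    for sample, child in zip(samples, child_seeds):
        rng = np.random.default_rng(child)
        counts: dict[str, int] = {}
        for ps in truth.planted_sirnas:
            lam = ps.tpm_target * depth / 1e6
            if sample.tissue == target_tissue:
                c = _truncated_poisson(rng, lam, lo_count, hi_count)
            elif background_rate > 0:
                c = int(rng.poisson(background_rate * lam))
            else:
                c = 0
            if c:
                counts[ps.sequence] = counts.get(ps.sequence, 0) + c
        n_bg = depth - sum(counts.values())
        if n_bg < 0:
            raise ValueError(
                f"depth {depth} too small for the planted siRNA abundance mass"
            )
        lengths = _draw_lengths(rng, n_bg, length_dist)
        background = random_sequences(rng, lengths)
        # keep background sequences distinct (count 1 each) and disjoint from
        # the planted set so ground truth stays clean
        taken = set(counts) | planted_set
        for i, s in enumerate(background):
            while s in taken:
                s = random_sequence(rng, len(s))
            taken.add(s)
            background[i] = s
            counts[s] = 1
        libs.append(
            SmallRNALibrary(
                library_id=sample.library_id,
                tissue=sample.tissue,
                stage=sample.stage,
                unique_counts=counts,
                total_reads=depth,
            )
        )
    return libs


def generate_race_reads(
    transcript: str,
    cleavage_positions: list[int],
    n_per_site: int,
    adaptor: str = DEFAULT_RACE_ADAPTOR,
    polyc_len_dist: dict[int, float] | None = None,
    vector_contam_rate: float = 0.2,
    seed: int = 0,
    insert_len: int = 100,
    vector: str = SYNTHETIC_VECTOR,
) -> list[tuple[str, str]]:
    """5'RACE product reads: [vector] + adaptor + poly(C) + transcript suffix.

    Each read's insert starts exactly at a cleavage position. Positions whose
    transcript base is C are refused: maximal-run poly(C) trimming could not
    then recover the exact 5' end (the terminal-transferase tail would be
    indistinguishable from genuine insert sequence).
    """
    if not cleavage_positions:
        raise ValueError("cleavage position list is empty")
    if n_per_site < 1:
        raise ValueError("n_per_site must be >= 1")
    for p in cleavage_positions:
        if not 0 <= p < len(transcript):
            raise ValueError(f"cleavage position {p} outside transcript")
        if transcript[p] == "C":
            raise ValueError(
                f"cleavage position {p} starts with C; poly(C) trimming would "
                "be ambiguous there"
            )
    if polyc_len_dist is None:
        polyc_len_dist = {k: 1.0 for k in range(8, 15)}
    tail_lens = np.array(sorted(polyc_len_dist), dtype=int)
    tail_w = np.array([polyc_len_dist[int(k)] for k in tail_lens], dtype=float)
    tail_w = tail_w / tail_w.sum()

    rng = np.random.default_rng(seed)
    reads: list[tuple[str, str]] = []
    for p in cleavage_positions:
        insert = transcript[p : p + insert_len]
        for i in range(n_per_site):
            tail = "C" * int(rng.choice(tail_lens, p=tail_w))
            seq = adaptor + tail + insert
            if rng.random() < vector_contam_rate:
                seq = vector + seq
            reads.append((f"race_p{p}_{i + 1}", seq))
    return reads


def generate_germplasm_variants(
    reference: str, n: int, divergence: float, seed: int = 0
) -> dict[str, str]:
    """``n`` variants differing from ``reference`` by substitutions only.

    Exactly round(divergence * length) positions are substituted per variant,
    so identity against the reference is 1 - realised substitution fraction.
    """
    if not 0.0 <= divergence <= 0.2:
        raise ValueError("divergence must be in [0, 0.2]")
    if n < 1:
        raise ValueError("n must be >= 1")
    if not reference:
        raise ValueError("empty reference sequence")
    rng = np.random.default_rng(seed)
    n_sub = round(divergence * len(reference))
    others = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}
    out: dict[str, str] = {}
    for i in range(n):
        seq = list(reference)
        for pos in rng.choice(len(reference), size=n_sub, replace=False):
            seq[pos] = others[seq[pos]][rng.integers(0, 3)]
        out[f"germplasm_{i + 1:02d}"] = "".join(seq)
    return out


def generate_microarray_panel(
    probes: list[str],
    samples: list[TissueSample],
    replicates: int = 3,
    target_tissue: str = "tassel",
    fold: float = 16.0,
    base_signal: float = 120.0,
    noise_sd_log2: float = 0.2,
    seed: int = 0,
):
    """Microarray-style signal table for mts-siRNA probes across tissues.

    Probes carry a ``fold``-times higher signal in target-tissue samples, with
    log-normal noise of ``noise_sd_log2`` log2 units; replicates per
    tissue/stage sample.
    """
    from .specificity_screen import MicroarrayPanel

    rng = np.random.default_rng(seed)
    cols: list[str] = []
    groups: dict[str, str] = {}
    means: list[float] = []
    for s in samples:
        mean = base_signal * (fold if s.tissue == target_tissue else 1.0)
        for r in range(1, replicates + 1):
            col = f"{s.tissue}_{s.stage}_rep{r}"
            cols.append(col)
            groups[col] = s.tissue
            means.append(mean)
    noise = rng.normal(0.0, noise_sd_log2, size=(len(probes), len(cols)))
    signal = np.array(means)[None, :] * np.exp2(noise)
    df = pd.DataFrame(signal, index=probes, columns=cols)
    return MicroarrayPanel(signals=df, groups=groups)
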