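"""Transgene cassette assembly and the three in-silico safety screens.

The cassette places the siRNA target element immediately after the coding
sequence's stop codon and before the 3'UTR, so that tassel-expressed siRNAs
direct cleavage of the transgene mRNA without altering the encoded protein.
Three screens guard the design:

* miRNA-site screen — position-weighted complementarity penalty in the plant
  miRNA-target convention (mismatch 1, G:U wobble 0.5, doubled over miRNA
  positions 2-13, site called when penalty <= cutoff, default 4.0); a clean
  element has no calls, so no endogenous miRNA silences the transgene outside
  the intended tissue.
* conservation screen — global pairwise alignment identity of germplasm
  amplicons against the target locus (match +1, mismatch -1, gap open -2,
  extend -0.5; identity = matches / alignment columns), predicting trait
  penetrance across breeding backgrounds.
* transitivity screen — the computational analogue of probing a small RNA
  blot with everything but the target element: small RNA reads are mapped
  against the cassette transcript and any hit not overlapping the target
  element counts as evidence of secondary siRNA production. A clean design
  reports zero matches in every library.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from Bio import Align
from pydantic import BaseModel

from ._util import complement
from .smallrna_catalog import SmallRNALibrary
from .target_mapper import KmerIndex, map_sirna

__all__ = [
    "CassetteDesign",
    "MirnaSiteCall",
    "TransitivityReport",
    "assemble_cassette",
    "screen_mirna_sites",
    "screen_conservation",
    "screen_transitivity",
    "design_report",
    "DesignReport",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}
MIRNA_MIN_LEN = 19
MIRNA_MAX_LEN = 24


@dataclass
class CassetteDesign:
    """CDS + target element + 3'UTR, with feature coordinates on the mRNA."""

    cds: str
    target_element: str
    utr3: str

    @property
    def assembled(self) -> str:
        return self.cds + self.target_element + self.utr3

    @property
    def target_interval(self) -> tuple[int, int]:
        return (len(self.cds), len(self.cds) + len(self.target_element))

    def features(self) -> list[tuple[str, int, int]]:
        a = len(self.cds)
        b = a + len(self.target_element)
        c = b + len(self.utr3)
        return [("CDS", 0, a), ("siRNA_target_element", a, b), ("three_prime_UTR", b, c)]


def assemble_cassette(cds: str, region_sequence: str, utr3: str) -> CassetteDesign:
    """Assemble transcript = CDS + target element + 3'UTR.

    The CDS must end with a stop codon and the 3'UTR must be non-empty
    (poly(A) context).
    """
    if len(cds) < 3 or cds[-3:] not in STOP_CODONS:
        raise ValueError("CDS does not end with a stop codon (TAA/TAG/TGA)")
    if not region_sequence:
        raise ValueError("empty target element")
    if not utr3:
        raise ValueError("empty 3'UTR (required for poly(A) context)")
    return CassetteDesign(cds=cds, target_element=region_sequence, utr3=utr3)


@dataclass(frozen=True)
class MirnaSiteCall:
    mirna_id: str
    position: int  # 0-based start of the site on the target element
    penalty: float
    is_site: bool


def _pairing_penalty(mirna: str, site: str) -> float:
    """Plant-style position-weighted penalty of a miRNA against one site.

    The site is the target-element window read 5'->3'; pairing is antiparallel
    so miRNA position i (1-based from its 5' end) faces site position L-i.
    Watson-Crick pairs cost 0, G:U wobbles 0.5, other mismatches 1, all
    doubled over miRNA positions 2-13 (the seed plus central cleavage region).
    """
    length = len(mirna)
    penalty = 0.0
    for i in range(length):
        m = mirna[i]
        t = site[length - 1 - i]
        if t == complement(m):
            continue
        cost = 0.5 if (m == "G" and t == "T") or (m == "T" and t == "G") else 1.0
        if 2 <= i + 1 <= 13:
            cost *= 2.0
        penalty += cost
    return penalty


def screen_mirna_sites(
    target: str, mirnas: Mapping[str, str], cutoff: float = 4.0
) -> list[MirnaSiteCall]:
    """All miRNA/offset combinations with penalty <= cutoff; empty = clean."""
    calls: list[MirnaSiteCall] = []
    for mid, mseq in mirnas.items():
        if not MIRNA_MIN_LEN <= len(mseq) <= MIRNA_MAX_LEN:
            raise ValueError(
                f"miRNA {mid}: length {len(mseq)} outside "
                f"[{MIRNA_MIN_LEN}, {MIRNA_MAX_LEN}]"
            )
        for pos in range(len(target) - len(mseq) + 1):
            penalty = _pairing_penalty(mseq, target[pos : pos + len(mseq)])
            if penalty <= cutoff:
                calls.append(MirnaSiteCall(mid, pos, penalty, True))
    return sorted(calls, key=lambda c: (c.mirna_id, c.position))


def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -0.5
    return aligner


def screen_conservation(
    target: str, germplasm_seqs: Mapping[str, str], min_identity: float = 0.90
) -> pd.DataFrame:
    """Percent identity of each germplasm sequence against the target locus.

    Identity = matched columns / total alignment columns of the best global
    alignment; pass when identity >= min_identity.
    """
    if not target:
        raise ValueError("empty target sequence")
    if not germplasm_seqs:
        raise ValueError("at least one germplasm sequence required")
    aligner = _global_aligner()
    rows = []
    for gid, seq in germplasm_seqs.items():
        if not seq:
            raise ValueError(f"germplasm {gid}: empty sequence")
        aln = aligner.align(target, seq)[0]
        counts = aln.counts()
        identity = counts.identities / aln.length
        rows.append(
            {"germplasm_id": gid, "identity": identity, "passes": identity >= min_identity}
        )
    return pd.DataFrame(rows).set_index("germplasm_id")


@dataclass
class TransitivityReport:
    per_library: pd.DataFrame  # distinct_matching, reads_matching per library
    excluded_interval: tuple[int, int]

    @property
    def clean(self) -> bool:
        return bool(
            (self.per_library[["distinct_matching", "reads_matching"]] == 0).all().all()
        )


def screen_transitivity(
    design: CassetteDesign,
    libraries: Iterable[SmallRNALibrary],
    max_mm: int = 1,
    index_k: int = 8,
    excluded_interval: tuple[int, int] | None = None,
) -> TransitivityReport:
    """Count library sequences matching the cassette outside the target element.

    Libraries must already be length-filtered to 18-26 nt. A hit is counted
    unless it overlaps the excluded interval (default: the target element),
    mirroring probes that tile the whole transcript except the element. Any
    nonzero count indicates secondary (transitive) siRNA production.
    """
    transcript = design.assembled
    if excluded_interval is None:
        excluded_interval = design.target_interval
    x0, x1 = excluded_interval
    if not (0 <= x0 <= x1 <= len(transcript)):
        raise ValueError(f"excluded interval {excluded_interval} outside transcript")
    index = KmerIndex({"cassette": transcript}, k=index_k)
    rows = []
    for lib in libraries:
        distinct = 0
        reads = 0
        for seq, count in lib.unique_counts.items():
            hits = map_sirna(seq, index, max_mm=max_mm)
            outside = [h for h in hits if h.end <= x0 or h.start >= x1]
            if outside:
                distinct += 1
                reads += count
        rows.append(
            {
                "library_id": lib.library_id,
                "tissue": lib.tissue,
                "distinct_matching": distinct,
                "reads_matching": reads,
            }
        )
    per_library = pd.DataFrame(rows).set_index("library_id")
    return TransitivityReport(per_library=per_library, excluded_interval=(x0, x1))


class ScreenResult(BaseModel):
    name: str
    passed: bool
    details: dict


class DesignReport(BaseModel):
    """Schema for the machine-readable design report."""

    status: str
    failed_screens: list[str]
    screens: list[ScreenResult]
    layout: list[tuple[str, int, int]]
    parameters: dict
    seed: int
    version: str


def design_report(
    design: CassetteDesign,
    screens: Mapping[str, tuple[bool, dict]],
    parameters: Mapping | None = None,
    seed: int = 0,
) -> DesignReport:
    """Single report over all executed screens: PASS iff every screen passed."""
    from . import __version__

    results = [
        ScreenResult(name=name, passed=passed, details=dict(details))
        for name, (passed, details) in screens.items()
    ]
    failed = [r.name for r in results if not r.passed]
    return DesignReport(
        status="FAIL" if failed else "PASS",
        failed_screens=failed,
        screens=results,
        layout=design.features(),
        parameters=dict(parameters or {}),
        seed=seed,
        version=__version__,
    )
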