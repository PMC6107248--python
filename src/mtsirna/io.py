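"""File-format helpers: FASTA/FASTQ writers, GFF3 serialisation, manifests.

Internal coordinates are 0-based half-open; every written report (TSV, GFF3)
uses 1-based inclusive coordinates, enforced here in the serialisers.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_fastq",
    "write_library_fasta",
    "write_manifest",
    "regions_to_gff3",
    "cassette_to_gff3",
    "read_gff3",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _records(seqs: Mapping[str, str] | Iterable[tuple[str, str]]):
    items = seqs.items() if isinstance(seqs, Mapping) else seqs
    for name, seq in items:
        yield SeqRecord(Seq(seq), id=name, description="")


def write_fasta(seqs, path: str | Path) -> None:
    SeqIO.write(_records(seqs), str(path), "fasta")


def write_fastq(seqs, path: str | Path) -> None:
    """FASTQ with dummy qualities ('I' = Q40) for simulated reads."""
    records = []
    for rec in _records(seqs):
        rec.letter_annotations["phred_quality"] = [40] * len(rec.seq)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def write_library_fasta(lib, path: str | Path) -> None:
    """Expand a collapsed library back to redundant FASTA reads."""
    def reads():
        i = 0
        for seq, count in lib.unique_counts.items():
            for _ in range(count):
                i += 1
                yield (f"{lib.library_id}_{i}", seq)

    write_fasta(reads(), path)


def write_manifest(rows: Iterable[Mapping], path: str | Path) -> None:
    pd.DataFrame(list(rows)).to_csv(path, sep="\t", index=False)


_GFF_HEADER = "##gff-version 3"


def _gff_line(seqid, source, ftype, start0, end, score, strand, attrs) -> str:
    attr_str = ";".join(f"{k}={v}" for k, v in attrs.items())
    return "\t".join(
        [seqid, source, ftype, str(start0 + 1), str(end), score, strand, ".", attr_str]
    )


def regions_to_gff3(regions, path: str | Path, source: str = "mtsirna") -> None:
    """Candidate target regions as GFF3 features (1-based inclusive)."""
    lines = [_GFF_HEADER]
    for r in regions:
        lines.append(
            _gff_line(
                r.transcript_id,
                source,
                "siRNA_target_region",
                r.start,
                r.end,
                str(r.distinct_sirnas),
                "+",
                {
                    "ID": f"region_{r.rank}",
                    "rank": r.rank,
                    "distinct_sirnas": r.distinct_sirnas,
                    "tpm_mass": f"{r.tpm_mass:.3f}",
                },
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def cassette_to_gff3(design, path: str | Path, seqid: str = "cassette") -> None:
    lines = [_GFF_HEADER]
    for name, start, end in design.features():
        lines.append(
            _gff_line(seqid, "mtsirna", name, start, end, ".", "+", {"ID": name})
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Parse a GFF3 file into a DataFrame with 0-based half-open coordinates."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ValueError(f"malformed GFF3 line: {line!r}")
        attrs = dict(
            kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
        )
        rows.append(
            {
                "seqid": fields[0],
                "source": fields[1],
                "type": fields[2],
                "start": int(fields[3]) - 1,  # back to 0-based half-open
                "end": int(fields[4]),
                "score": fields[5],
                "strand": fields[6],
                "attributes": attrs,
            }
        )
    return pd.DataFrame(rows)


def hits_to_frame(hits) -> pd.DataFrame:
    """TargetHit list as a report table (1-based inclusive coordinates)."""
    return pd.DataFrame(
        [
            {
                "sirna": h.sirna,
                "transcript_id": h.transcript_id,
                "start": h.start + 1,
                "end": h.end,
                "strand": h.strand,
                "mismatches": h.mismatches,
            }
            for h in hits
        ]
    )
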