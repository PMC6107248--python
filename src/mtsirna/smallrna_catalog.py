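"""Small RNA library ingestion, length filtering, collapsing and TPM normalisation.

A sequencing library is stored collapsed: a map from distinct read sequence to
its redundant read count, plus the total-read denominator. Unique reads do not
include redundant reads; total reads count both. Abundances are expressed as
reads per million library reads (TPM), the standard normalisation for small
RNA abundance comparisons across tissues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._util import as_dna

__all__ = [
    "SmallRNALibrary",
    "ExpressionMatrix",
    "read_library",
    "read_manifest",
    "filter_by_length",
    "collapse_report",
    "normalize_tpm",
    "build_matrix",
]


class LibraryParseError(ValueError):
    """Raised when a FASTA/FASTQ library record cannot be parsed."""


@dataclass
class SmallRNALibrary:
    """One tissue/stage sequencing library, collapsed to distinct sequences.

    ``raw_total`` keeps the pre-filter read total after length filtering so it
    remains selectable as the normalisation denominator.
    """

    library_id: str
    tissue: str
    stage: str
    unique_counts: dict[str, int] = field(default_factory=dict)
    total_reads: int = 0
    raw_total: int | None = None

    def __post_init__(self) -> None:
        observed = sum(self.unique_counts.values())
        if self.total_reads != observed:
            raise ValueError(
                f"library {self.library_id}: total_reads={self.total_reads} "
                f"differs from sum of unique counts {observed}"
            )

    @property
    def unique_reads(self) -> int:
        return len(self.unique_counts)


def read_library(path: str | Path, manifest_row: Mapping[str, str]) -> SmallRNALibrary:
    """Read a FASTA or FASTQ file into a collapsed library.

    U is converted to T, sequences are case-folded, and reads containing
    ambiguous bases (N) are discarded because they break the exact/near-exact
    matching semantics downstream.
    """
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
    counts: dict[str, int] = {}
    total = 0
    record_no = 0
    try:
        for record_no, rec in enumerate(SeqIO.parse(str(path), fmt), start=1):
            seq = as_dna(str(rec.seq))
            if not seq or "N" in seq:
                continue
            counts[seq] = counts.get(seq, 0) + 1
            total += 1
    except ValueError as exc:
        lines_per_record = 4 if fmt == "fastq" else 2
        raise LibraryParseError(
            f"{path}: malformed {fmt} near record {record_no + 1} "
            f"(about line {record_no * lines_per_record + 1}): {exc}"
        ) from exc
    if total == 0:
        warnings.warn(f"{path}: empty library", stacklevel=2)
    return SmallRNALibrary(
        library_id=str(manifest_row["library_id"]),
        tissue=str(manifest_row["tissue"]),
        stage=str(manifest_row.get("stage", "")),
        unique_counts=counts,
        total_reads=total,
    )


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read the TSV manifest (library_id, tissue, stage, replicate, path)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"library_id", "tissue", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} lacks columns: {sorted(missing)}")
    return df


def filter_by_length(
    lib: SmallRNALibrary, min_len: int = 18, max_len: int = 26
) -> SmallRNALibrary:
    """Keep only sequences with length in [min_len, max_len].

    The original total is retained in ``raw_total`` as an alternative
    normalisation denominator.
    """
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    kept = {s: c for s, c in lib.unique_counts.items() if min_len <= len(s) <= max_len}
    return SmallRNALibrary(
        library_id=lib.library_id,
        tissue=lib.tissue,
        stage=lib.stage,
        unique_counts=kept,
        total_reads=sum(kept.values()),
        raw_total=lib.raw_total if lib.raw_total is not None else lib.total_reads,
    )


def collapse_report(lib: SmallRNALibrary) -> tuple[int, int]:
    """(unique_reads, total_reads) for a library; unique never exceeds total."""
    return lib.unique_reads, lib.total_reads


def _denominator(lib: SmallRNALibrary, policy: str) -> int:
    if policy == "post_filter":
        return lib.total_reads
    if policy == "raw":
        return lib.raw_total if lib.raw_total is not None else lib.total_reads
    raise ValueError(f"unknown denominator policy {policy!r}")


def normalize_tpm(lib: SmallRNALibrary, denominator_policy: str = "post_filter") -> pd.Series:
    """TPM column for one library: count / denominator * 1e6."""
    denom = _denominator(lib, denominator_policy)
    if denom <= 0:
        raise ValueError(f"library {lib.library_id}: zero normalisation denominator")
    scale = 1e6 / denom
    return pd.Series(
        {s: c * scale for s, c in lib.unique_counts.items()},
        name=lib.library_id,
        dtype=float,
    )


class ExpressionMatrix:
    """siRNA x library TPM matrix with tissue labels on the columns."""

    def __init__(
        self,
        values: pd.DataFrame,
        tissues: Mapping[str, str],
        stages: Mapping[str, str] | None = None,
    ):
        missing = set(values.columns) - set(tissues)
        if missing:
            raise ValueError(f"columns without tissue label: {sorted(missing)}")
        self.values = values
        self.tissues = dict(tissues)
        self.stages = dict(stages or {})

    @property
    def sequences(self) -> pd.Index:
        return self.values.index

    @property
    def library_ids(self) -> list[str]:
        return list(self.values.columns)

    def columns_for_tissue(self, tissue: str) -> list[str]:
        cols = [c for c in self.values.columns if self.tissues[c] == tissue]
        if not cols:
            raise ValueError(f"tissue {tissue!r} not present in matrix")
        return cols

    def to_tsv(self, path: str | Path) -> None:
        header = pd.DataFrame(
            [[self.tissues[c] for c in self.values.columns]],
            index=["#tissue"],
            columns=self.values.columns,
        )
        pd.concat([header, self.values]).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        tissues = df.loc["#tissue"].to_dict()
        values = df.drop(index="#tissue").astype(float)
        return cls(values, tissues)


def build_matrix(
    libs: Iterable[SmallRNALibrary], denominator_policy: str = "post_filter"
) -> ExpressionMatrix:
    """Union all libraries into one TPM matrix (absent sequence -> 0 TPM)."""
    libs = list(libs)
    if not libs:
        raise ValueError("at least one library required")
    ids = [lib.library_id for lib in libs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate library_id in input libraries")

    seq_row: dict[str, int] = {}
    cols: list[np.ndarray] = []
    rows: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    for j, lib in enumerate(libs):
        denom = _denominator(lib, denominator_policy)
        if denom <= 0:
            raise ValueError(f"library {lib.library_id}: zero normalisation denominator")
        scale = 1e6 / denom
        r = np.empty(len(lib.unique_counts), dtype=np.int64)
        v = np.empty(len(lib.unique_counts), dtype=float)
        for i, (s, c) in enumerate(lib.unique_counts.items()):
            idx = seq_row.get(s)
            if idx is None:
                idx = len(seq_row)
                seq_row[s] = idx
            r[i] = idx
            v[i] = c * scale
        rows.append(r)
        vals.append(v)
        cols.append(np.full(len(r), j, dtype=np.int64))

    mat = np.zeros((len(seq_row), len(libs)), dtype=float)
    if seq_row:
        mat[np.concatenate(rows), np.concatenate(cols)] = np.concatenate(vals)
    values = pd.DataFrame(mat, index=list(seq_row), columns=ids)
    return ExpressionMatrix(
        values,
        tissues={lib.library_id: lib.tissue for lib in libs},
        stages={lib.library_id: lib.stage for lib in libs},
    )
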