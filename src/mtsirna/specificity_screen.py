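"""Calling male-tissue-specific siRNAs and the microarray replicate test.

An siRNA is called male-tissue-specific (mts) when its abundance reaches the
minimum tassel level (``tau_min``, default 40 TPM — the lower end of the
abundance range such siRNAs show in tassel libraries) while its maximum
abundance in every other tissue stays below a leak ceiling,
max(leak_abs, leak_frac * tassel maximum). The microarray test is a two-sided
Welch t on log2(signal + 1), target-tissue replicates against all pooled
others, significant when p < alpha and the target mean is the higher one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .smallrna_catalog import ExpressionMatrix

__all__ = [
    "SpecificityCall",
    "MicroarrayPanel",
    "call_mts_sirnas",
    "calls_from_frame",
    "rank_and_select",
    "microarray_ttest",
]

ENRICHMENT_PSEUDOCOUNT = 0.1  # TPM, avoids division by zero


@dataclass(frozen=True)
class SpecificityCall:
    sequence: str
    target_tpm_max: float
    other_tpm_max: float
    enrichment: float
    is_mts: bool


@dataclass
class MicroarrayPanel:
    """Probe x sample signal table with a sample -> tissue grouping."""

    signals: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        missing = set(self.signals.columns) - set(self.groups)
        if missing:
            raise ValueError(f"samples without tissue group: {sorted(missing)}")
        if (self.signals.values < 0).any():
            raise ValueError("negative signal after background subtraction")


def call_mts_sirnas(
    matrix: ExpressionMatrix,
    target_tissue: str,
    tau_min: float = 40.0,
    leak_frac: float = 0.05,
    leak_abs: float = 1.0,
) -> pd.DataFrame:
    """Specificity call per catalogued sequence, vectorised over the matrix.

    Returns a DataFrame indexed by sequence with columns
    target_tpm_max / other_tpm_max / enrichment / is_mts (one row per
    :class:`SpecificityCall`).
    """
    target_cols = matrix.columns_for_tissue(target_tissue)
    other_cols = [c for c in matrix.library_ids if c not in target_cols]
    values = matrix.values
    tmax = values[target_cols].max(axis=1)
    omax = (
        values[other_cols].max(axis=1)
        if other_cols
        else pd.Series(0.0, index=values.index)
    )
    leak_ceiling = np.maximum(leak_abs, leak_frac * tmax)
    out = pd.DataFrame(
        {
            "target_tpm_max": tmax,
            "other_tpm_max": omax,
            "enrichment": tmax / (omax + ENRICHMENT_PSEUDOCOUNT),
            "is_mts": (tmax >= tau_min) & (omax <= leak_ceiling),
        }
    )
    out.index.name = "sequence"
    return out


def calls_from_frame(calls: pd.DataFrame) -> list[SpecificityCall]:
    """Materialise DataFrame rows as SpecificityCall records."""
    return [
        SpecificityCall(
            sequence=str(seq),
            target_tpm_max=float(row.target_tpm_max),
            other_tpm_max=float(row.other_tpm_max),
            enrichment=float(row.enrichment),
            is_mts=bool(row.is_mts),
        )
        for seq, row in calls.iterrows()
    ]


def rank_and_select(calls: pd.DataFrame, k: int) -> pd.DataFrame:
    """Top-k mts calls by (tassel TPM desc, sequence asc) — deterministic."""
    if k < 1:
        raise ValueError("k must be >= 1")
    mts = calls[calls["is_mts"]]
    ordered = (
        mts.reset_index()
        .sort_values(by=["target_tpm_max", "sequence"], ascending=[False, True])
        .set_index("sequence")
    )
    if k > len(ordered):
        warnings.warn(
            f"requested top {k} mts-siRNAs but only {len(ordered)} called",
            stacklevel=2,
        )
        return ordered
    return ordered.head(k)


def microarray_ttest(
    panel: MicroarrayPanel,
    target_tissue: str,
    alpha: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-probe Welch t-test of target replicates vs pooled others.

    Two-sided on log2(signal + 1); ``significant`` additionally requires the
    target mean to exceed the pooled-other mean (enrichment direction). No
    multiple-testing correction by default (raw p < alpha); ``fdr=True``
    adds Benjamini-Hochberg q-values and gates significance on q < alpha.
    """
    target_cols = [c for c in panel.signals.columns if panel.groups[c] == target_tissue]
    other_cols = [c for c in panel.signals.columns if panel.groups[c] != target_tissue]
    if len(target_cols) < 2:
        raise ValueError(
            f"group {target_tissue!r} has {len(target_cols)} replicate(s); >= 2 required"
        )
    if len(other_cols) < 2:
        raise ValueError(
            f"pooled non-{target_tissue} group has {len(other_cols)} replicate(s); "
            ">= 2 required"
        )
    log = np.log2(panel.signals + 1.0)
    t_vals = log[target_cols].to_numpy()
    o_vals = log[other_cols].to_numpy()
    stat, p = stats.ttest_ind(t_vals, o_vals, axis=1, equal_var=False)
    enriched = t_vals.mean(axis=1) > o_vals.mean(axis=1)
    out = pd.DataFrame(
        {"statistic": stat, "p": p, "significant": (p < alpha) & enriched},
        index=panel.signals.index,
    )
    if fdr:
        from statsmodels.stats.multitest import multipletests

        _, q, _, _ = multipletests(out["p"].to_numpy(), method="fdr_bh")
        out["q"] = q
        out["significant"] = (q < alpha) & enriched
    return out
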