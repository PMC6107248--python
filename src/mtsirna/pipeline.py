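"""End-to-end orchestration: simulate -> catalog -> specificity -> mapping ->
clustering -> design screens -> RACE validation.

One :class:`RunConfig` carries every stage parameter (paper-anchored defaults:
18-26 nt length window, 40 TPM tassel floor, 201-nt target window, p < 0.05,
90% identity threshold) plus one master seed behind all randomness; a run with
the same config and seed writes byte-identical reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import pandas as pd
import yaml
from pydantic import BaseModel

from . import io as mio
from . import synthetic_data as syn
from ._util import derive_seeds, random_sequence
from .cassette_designer import (
    CassetteDesign,
    assemble_cassette,
    design_report,
    screen_conservation,
    screen_mirna_sites,
    screen_transitivity,
)
from .cluster_finder import CandidateRegion, build_profile, find_windows, annotate_regions
from .race_cleavage_mapper import (
    call_cleavage_sites,
    classify_specificity,
    map_race_reads,
)
from .smallrna_catalog import (
    build_matrix,
    collapse_report,
    filter_by_length,
    read_library,
    read_manifest,
)
from .specificity_screen import call_mts_sirnas, microarray_ttest, rank_and_select
from .target_mapper import build_index, map_many

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


class RunConfig(BaseModel):
    """All pipeline parameters with paper-anchored defaults."""

    seed: int = 0
    outdir: str = "mtsirna_run"
    synthetic: bool = True

    # external inputs (non-synthetic mode)
    manifest: str | None = None
    transcripts: str | None = None
    mirnas: str | None = None
    germplasm: str | None = None
    race_reads: str | None = None

    # catalog
    min_len: int = 18
    max_len: int = 26
    denominator_policy: str = "post_filter"

    # specificity
    target_tissue: str = "tassel"
    tau_min: float = 40.0
    leak_frac: float = 0.05
    leak_abs: float = 1.0
    select_k: int = 1216
    alpha: float = 0.05

    # mapping
    max_mm: int = 1
    kmer: int = 8

    # clustering
    window: int = 201
    min_distinct: int = 5

    # design screens
    mirna_cutoff: float = 4.0
    min_identity: float = 0.90

    # RACE
    min_support: int = 2
    race_max_mm: int = 1
    race_reads_per_site: int = 6
    n_race_sites: int = 5
    n_offtarget_sites: int = 0
    vector_contam_rate: float = 0.2

    # synthetic generation
    n_transcripts: int = 5
    length_lo: int = 800
    length_hi: int = 2200
    donor_length: int = 1826
    region_start: int = 550
    n_sirnas: int = 30
    strand_mix: float = 0.5
    depth: int = 1_000_000
    background_rate: float = 0.0
    tpm_lo: float = 40.0
    tpm_hi: float = 2660.0
    n_germplasm: int = 31
    germplasm_divergence: float = 0.08
    amplicon_length: int = 313
    cds_length: int = 1368
    utr3_length: int = 200
    n_mirnas: int = 20
    microarray_probes: int = 10
    microarray_replicates: int = 3

    write_libraries: bool = False  # full per-library FASTA output is large

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))


@dataclass
class PipelineResult:
    outdir: Path
    truth: syn.GroundTruth | None
    calls: pd.DataFrame
    selected: pd.DataFrame
    regions: list[CandidateRegion]
    design: CassetteDesign | None
    report: dict
    metrics: dict


def _stage_seeds(seed: int) -> dict[str, int]:
    names = [
        "transcriptome", "cluster", "libraries", "germplasm", "microarray",
        "race", "cds", "utr", "mirnas",
    ]
    return dict(zip(names, derive_seeds(seed, len(names))))


def _interval_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _pick_cleavage_positions(
    transcript: str, hits, interval: tuple[int, int], n_sites: int
) -> list[int]:
    """Cleavage positions inside siRNA hit footprints within the interval.

    The canonical slicing point sits ~10 nt into the recognition site; sites
    landing on a C are slid downstream (poly(C)-trimming ambiguity).
    """
    positions: list[int] = []
    for h in sorted(hits, key=lambda h: h.start):
        if h.start < interval[0] or h.end > interval[1]:
            continue
        p = h.start + 10
        while p < h.end - 1 and transcript[p] == "C":
            p += 1
        if transcript[p] != "C" and p not in positions:
            positions.append(p)
        if len(positions) >= n_sites:
            break
    return positions


def run_pipeline(config: RunConfig) -> PipelineResult:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    log_lines = [f"seed={config.seed}", f"parameters={config.model_dump()}"]

    # ---- stage 0: inputs -------------------------------------------------
    truth: syn.GroundTruth | None = None
    if config.synthetic:
        import numpy as np

        transcripts, truth = syn.generate_transcriptome(
            config.n_transcripts,
            (config.length_lo, config.length_hi),
            seed=seeds["transcriptome"],
            donor_length=config.donor_length,
        )
        donor = transcripts[truth.donor_transcript_id]
        region = (config.region_start, config.region_start + config.window)
        truth.planted_region = region
        truth.planted_sirnas = syn.plant_sirna_cluster(
            donor,
            region,
            config.n_sirnas,
            strand_mix=config.strand_mix,
            seed=seeds["cluster"],
            tpm_window=(config.tpm_lo, config.tpm_hi),
        )
        truth.germplasm_divergence = config.germplasm_divergence
        panel = syn.DEFAULT_PANEL
        libraries = syn.generate_libraries(
            panel,
            truth,
            depth=config.depth,
            background_rate=config.background_rate,
            seed=seeds["libraries"],
            target_tissue=config.target_tissue,
            tpm_window=(config.tpm_lo, config.tpm_hi),
        )
        mio.write_fasta(transcripts, outdir / "transcripts.fasta")
        mio.write_manifest(
            [
                {
                    "library_id": s.library_id,
                    "tissue": s.tissue,
                    "stage": s.stage,
                    "replicate": s.replicate,
                    "path": f"libraries/{s.library_id}.fasta",
                }
                for s in panel
            ],
            outdir / "manifest.tsv",
        )
        if config.write_libraries:
            (outdir / "libraries").mkdir(exist_ok=True)
            for lib in libraries:
                mio.write_library_fasta(lib, outdir / "libraries" / f"{lib.library_id}.fasta")
    else:
        if config.manifest is None or not Path(config.manifest).exists():
            raise FileNotFoundError(f"manifest not found: {config.manifest}")
        if config.transcripts is None or not Path(config.transcripts).exists():
            raise FileNotFoundError(f"transcripts not found: {config.transcripts}")
        manifest = read_manifest(config.manifest)
        base = Path(config.manifest).parent
        libraries = [
            read_library(base / row["path"], row) for _, row in manifest.iterrows()
        ]
        transcripts = mio.read_fasta(config.transcripts)
        donor = None
    log_lines.append(f"stage=inputs libraries={len(libraries)}")

    # ---- stage 1: catalog ------------------------------------------------
    libraries = [
        filter_by_length(lib, config.min_len, config.max_len) for lib in libraries
    ]
    summary = pd.DataFrame(
        [
            {
                "library_id": lib.library_id,
                "tissue": lib.tissue,
                "stage": lib.stage,
                "unique_reads": collapse_report(lib)[0],
                "total_reads": collapse_report(lib)[1],
            }
            for lib in libraries
        ]
    )
    summary.to_csv(outdir / "catalog_summary.tsv", sep="\t", index=False)
    matrix = build_matrix(libraries, denominator_policy=config.denominator_policy)
    log_lines.append(f"stage=catalog sequences={len(matrix.sequences)}")

    # ---- stage 2: specificity -------------------------------------------
    calls = call_mts_sirnas(
        matrix,
        config.target_tissue,
        tau_min=config.tau_min,
        leak_frac=config.leak_frac,
        leak_abs=config.leak_abs,
    )
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        selected = rank_and_select(calls, config.select_k)
    selected.to_csv(outdir / "mts_calls.tsv", sep="\t")
    microarray = None
    if config.synthetic and len(selected) >= 1:
        probes = list(selected.index[: config.microarray_probes])
        panel_samples = sorted(
            {(lib.tissue, lib.stage) for lib in libraries}
        )
        ma_panel = syn.generate_microarray_panel(
            probes,
            [syn.TissueSample(t, s) for t, s in panel_samples],
            replicates=config.microarray_replicates,
            target_tissue=config.target_tissue,
            seed=seeds["microarray"],
        )
        microarray = microarray_ttest(ma_panel, config.target_tissue, alpha=config.alpha)
        microarray.to_csv(outdir / "microarray_ttest.tsv", sep="\t")
    log_lines.append(f"stage=specificity mts_called={int(calls['is_mts'].sum())}")

    # ---- stage 3: mapping ------------------------------------------------
    index = build_index(transcripts, k=config.kmer)
    hits = map_many(selected.index, index, max_mm=config.max_mm)
    mio.hits_to_frame(hits).to_csv(outdir / "hits.tsv", sep="\t", index=False)
    log_lines.append(f"stage=mapping hits={len(hits)}")

    # ---- stage 4: clustering --------------------------------------------
    tpm_map = selected["target_tpm_max"].to_dict()
    all_regions: list[CandidateRegion] = []
    profiles = {}
    for tid, seq in transcripts.items():
        t_hits = [h for h in hits if h.transcript_id == tid]
        profile = build_profile(t_hits, tpm_map, tid, len(seq))
        profiles[tid] = profile
        if len(seq) >= config.window:
            all_regions.extend(
                find_windows(profile, W=config.window, min_distinct=config.min_distinct)
            )
    all_regions.sort(key=lambda r: (-r.distinct_sirnas, -r.tpm_mass, r.transcript_id, r.start))
    for rank, r in enumerate(all_regions, start=1):
        r.rank = rank
    if all_regions:
        region_frames = [
            annotate_regions(
                [r for r in all_regions if r.transcript_id == tid],
                profiles[tid],
                transcripts,
            )
            for tid in {r.transcript_id for r in all_regions}
        ]
        pd.concat(region_frames).to_csv(outdir / "regions.tsv", sep="\t", index=False)
        mio.regions_to_gff3(all_regions, outdir / "regions.gff3")
    log_lines.append(f"stage=clustering regions={len(all_regions)}")

    # ---- stage 5: design + screens --------------------------------------
    design = None
    report_doc: dict = {}
    race_summary = None
    metrics: dict[str, Any] = {}
    if all_regions:
        top = all_regions[0]
        element = transcripts[top.transcript_id][top.start : top.end]
        if config.synthetic:
            import numpy as np

            rng_cds = np.random.default_rng(seeds["cds"])
            cds = random_sequence(rng_cds, config.cds_length - 3) + "TAA"
            utr3 = random_sequence(np.random.default_rng(seeds["utr"]), config.utr3_length)
            mirnas = {
                f"miR_{i + 1:03d}": random_sequence(
                    np.random.default_rng(seeds["mirnas"] + i), 21
                )
                for i in range(config.n_mirnas)
            }
            amp_start = max(0, top.start - (config.amplicon_length - top.width) // 2)
            amplicon = transcripts[top.transcript_id][
                amp_start : amp_start + config.amplicon_length
            ]
            germplasm = syn.generate_germplasm_variants(
                amplicon,
                config.n_germplasm,
                config.germplasm_divergence,
                seed=seeds["germplasm"],
            )
        else:
            cds = utr3 = None
            mirnas = mio.read_fasta(config.mirnas) if config.mirnas else {}
            germplasm = mio.read_fasta(config.germplasm) if config.germplasm else {}
            amplicon = element
        if cds is not None:
            design = assemble_cassette(cds, element, utr3)
            mio.write_fasta({"cassette": design.assembled}, outdir / "cassette.fasta")
            mio.cassette_to_gff3(design, outdir / "cassette.gff3")

        screens: dict[str, tuple[bool, dict]] = {}
        mirna_calls = screen_mirna_sites(element, mirnas, cutoff=config.mirna_cutoff)
        screens["mirna_sites"] = (
            len(mirna_calls) == 0,
            {"n_sites": len(mirna_calls), "cutoff": config.mirna_cutoff},
        )
        conservation = screen_conservation(
            amplicon, germplasm, min_identity=config.min_identity
        )
        screens["conservation"] = (
            bool(conservation["passes"].all()),
            {
                "n_germplasm": len(conservation),
                "min_identity": config.min_identity,
                "mean_identity": float(conservation["identity"].mean()),
                "min_observed": float(conservation["identity"].min()),
            },
        )
        conservation.to_csv(outdir / "conservation.tsv", sep="\t")
        if design is not None:
            transitivity = screen_transitivity(
                design, libraries, max_mm=config.max_mm, index_k=config.kmer
            )
            screens["transitivity"] = (
                transitivity.clean,
                {
                    "total_distinct_matching": int(
                        transitivity.per_library["distinct_matching"].sum()
                    ),
                    "total_reads_matching": int(
                        transitivity.per_library["reads_matching"].sum()
                    ),
                },
            )
            transitivity.per_library.to_csv(outdir / "transitivity.tsv", sep="\t")

            # ---- stage 6: RACE validation -------------------------------
            cass_index = build_index({"cassette": design.assembled}, k=config.kmer)
            cass_hits = map_many(selected.index, cass_index, max_mm=config.max_mm)
            if config.synthetic:
                cleavage_positions = _pick_cleavage_positions(
                    design.assembled, cass_hits, design.target_interval, config.n_race_sites
                )
                offtargets = []
                if config.n_offtarget_sites:
                    p = 50
                    while (
                        len(offtargets) < config.n_offtarget_sites
                        and p < design.target_interval[0]
                    ):
                        if design.assembled[p] != "C":
                            offtargets.append(p)
                        p += 37
                truth.cleavage_positions = cleavage_positions + offtargets
                race_reads = syn.generate_race_reads(
                    design.assembled,
                    truth.cleavage_positions,
                    n_per_site=config.race_reads_per_site,
                    vector_contam_rate=config.vector_contam_rate,
                    seed=seeds["race"],
                )
                mio.write_fasta(race_reads, outdir / "race_reads.fasta")
            else:
                race_reads = (
                    list(mio.read_fasta(config.race_reads).items())
                    if config.race_reads
                    else []
                )
            if race_reads:
                stats = map_race_reads(
                    race_reads,
                    design.assembled,
                    adaptor=syn.DEFAULT_RACE_ADAPTOR,
                    vector=syn.SYNTHETIC_VECTOR,
                    max_mm=config.race_max_mm,
                )
                cleavage_calls = call_cleavage_sites(
                    stats.positions, min_support=config.min_support
                )
                race_summary = classify_specificity(
                    cleavage_calls, design.target_interval, cass_hits
                )
                race_summary.to_frame(len(design.assembled)).to_csv(
                    outdir / "cleavage_calls.tsv", sep="\t", index=False
                )
                screens["race_specificity"] = (
                    race_summary.verdict == "sequence-specific",
                    {
                        "n_within": race_summary.n_within,
                        "n_outside": race_summary.n_outside,
                        "fraction_within": race_summary.fraction_within,
                        "verdict": race_summary.verdict,
                        "n_ambiguous_reads": stats.n_ambiguous,
                    },
                )
        if design is not None:
            rep = design_report(
                design,
                screens,
                parameters=config.model_dump(exclude={"outdir"}),
                seed=config.seed,
            )
            report_doc = rep.model_dump()
            (outdir / "design_report.json").write_text(
                json.dumps(report_doc, indent=2, sort_keys=True) + "\n"
            )
        log_lines.append(f"stage=design screens={list(screens)}")

    # ---- metrics against planted truth ----------------------------------
    if truth is not None:
        called = set(calls.index[calls["is_mts"]])
        planted = truth.planted_sequences
        tp = len(called & planted)
        metrics["precision"] = tp / len(called) if called else 0.0
        metrics["recall"] = tp / len(planted) if planted else 0.0
        if all_regions:
            top = all_regions[0]
            overlap = (
                _interval_overlap((top.start, top.end), truth.planted_region)
                if top.transcript_id == truth.donor_transcript_id
                else 0
            )
            metrics["region_overlap_fraction"] = overlap / (
                truth.planted_region[1] - truth.planted_region[0]
            )
            metrics["n_regions"] = len(all_regions)
        if race_summary is not None:
            called_pos = {c.position for c in race_summary.calls}
            planted_pos = set(truth.cleavage_positions)
            metrics["race_sites_recovered"] = len(called_pos & planted_pos) / len(
                planted_pos
            )
            metrics["race_fraction_within"] = race_summary.fraction_within
        if microarray is not None:
            metrics["microarray_significant"] = int(microarray["significant"].sum())
        truth.to_json(outdir / "ground_truth.json")

    run_report = {
        "status": report_doc.get("status", "PASS" if all_regions else "NO_REGIONS"),
        "seed": config.seed,
        "parameters": config.model_dump(exclude={"outdir"}),
        "metrics": metrics,
        "n_libraries": len(libraries),
        "n_mts_called": int(calls["is_mts"].sum()),
        "n_regions": len(all_regions),
    }
    (outdir / "run_report.json").write_text(
        json.dumps(run_report, indent=2, sort_keys=True) + "\n"
    )
    (outdir / "log.txt").write_text("\n".join(log_lines) + "\n")
    return PipelineResult(
        outdir=outdir,
        truth=truth,
        calls=calls,
        selected=selected,
        regions=all_regions,
        design=design,
        report=run_report,
        metrics=metrics,
    )
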