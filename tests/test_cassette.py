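"""Cassette assembly and the miRNA / conservation / transitivity screens."""

import numpy as np
import pytest
from pydantic import ValidationError

from mtsirna._util import random_sequence, revcomp
from mtsirna.cassette_designer import (
    DesignReport,
    assemble_cassette,
    design_report,
    screen_conservation,
    screen_mirna_sites,
    screen_transitivity,
)
from mtsirna.io import cassette_to_gff3, read_gff3
from mtsirna.smallrna_catalog import SmallRNALibrary
from mtsirna.synthetic_data import generate_germplasm_variants


def _cassette(rng, cds_len=1368, elem_len=201, utr_len=500):
    cds = random_sequence(rng, cds_len - 3) + "TAA"
    return assemble_cassette(
        cds, random_sequence(rng, elem_len), random_sequence(rng, utr_len)
    )


class TestAssemble:
    def test_layout_arithmetic(self, rng):
        design = _cassette(rng)
        assert len(design.assembled) == 1368 + 201 + 500
        assert design.target_interval == (1368, 1569)
        assert design.features()[0] == ("CDS", 0, 1368)

    def test_missing_stop_codon_rejected(self, rng):
        with pytest.raises(ValueError, match="stop codon"):
            assemble_cassette("ATGAAA", random_sequence(rng, 201), "AAAA")

    def test_empty_utr_rejected(self, rng):
        cds = random_sequence(rng, 99) + "TGA"
        with pytest.raises(ValueError, match="UTR"):
            assemble_cassette(cds, random_sequence(rng, 201), "")

    def test_gff3_round_trip(self, rng, tmp_path):
        design = _cassette(rng)
        path = tmp_path / "cassette.gff3"
        cassette_to_gff3(design, path)
        back = read_gff3(path)
        layout = {
            r["type"]: (r["start"], r["end"]) for _, r in back.iterrows()
        }
        assert layout == {name: (a, b) for name, a, b in design.features()}


class TestMirnaScreen:
    def test_perfect_complement_is_zero_penalty_site(self, rng):
        target = random_sequence(rng, 201)
        mirna = revcomp(target[50:71])
        calls = screen_mirna_sites(target, {"mir1": mirna})
        exact = [c for c in calls if c.position == 50]
        assert exact and exact[0].penalty == 0.0 and exact[0].is_site

    def test_penalty_monotone_in_mismatches(self, rng):
        target = random_sequence(rng, 60)
        site = target[10:31]
        from mtsirna.cassette_designer import _pairing_penalty

        mirna = revcomp(site)
        penalties = [_pairing_penalty(mirna, site)]
        m = list(mirna)
        for i in (0, 4, 9):  # progressively corrupt
            m[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[m[i]]
            penalties.append(_pairing_penalty("".join(m), site))
        assert penalties[0] == 0.0
        assert all(a < b for a, b in zip(penalties, penalties[1:]))

    def test_gu_wobble_half_weight(self):
        site = "A" * 10 + "G" + "A" * 10  # target G at centre
        mirna = revcomp(site)  # pairs perfectly
        from mtsirna.cassette_designer import _pairing_penalty

        # replace the paired C (miRNA) with T -> T:G wobble, position 11 (doubled)
        pos = len(mirna) - 1 - 10
        wobbled = mirna[:pos] + "T" + mirna[pos + 1 :]
        assert _pairing_penalty(wobbled, site) == 1.0  # 0.5 doubled

    def test_random_target_clean_at_default_cutoff(self, rng):
        target = random_sequence(rng, 201)
        mirnas = {f"m{i}": random_sequence(rng, 21) for i in range(20)}
        assert screen_mirna_sites(target, mirnas) == []

    def test_mirna_length_validated(self, rng):
        with pytest.raises(ValueError, match="length"):
            screen_mirna_sites(random_sequence(rng, 100), {"bad": "ACGT" * 10})


class TestConservationScreen:
    def test_reflexive_identity(self, rng):
        x = random_sequence(rng, 313)
        table = screen_conservation(x, {"self": x})
        assert table.loc["self", "identity"] == pytest.approx(1.0)
        assert bool(table.loc["self", "passes"])

    def test_divergence_008_passes_090(self, rng):
        ref = random_sequence(rng, 313)
        variants = generate_germplasm_variants(ref, 31, 0.08, seed=2)
        table = screen_conservation(ref, variants, min_identity=0.90)
        assert table["passes"].all()
        assert table["identity"].mean() == pytest.approx(0.92, abs=0.01)

    def test_divergence_015_fails_090(self, rng):
        ref = random_sequence(rng, 313)
        variants = generate_germplasm_variants(ref, 5, 0.15, seed=3)
        table = screen_conservation(ref, variants, min_identity=0.90)
        assert not table["passes"].any()

    def test_empty_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            screen_conservation("", {"a": "ACGT"})
        with pytest.raises(ValueError):
            screen_conservation("ACGT" * 20, {"a": ""})


def _library(counts, lib_id="L1", tissue="tassel"):
    return SmallRNALibrary(lib_id, tissue, "V8", counts, sum(counts.values()))


class TestTransitivityScreen:
    def test_clean_libraries_all_zero(self, rng):
        design = _cassette(rng, cds_len=600, utr_len=200)
        libs = [_library({random_sequence(rng, 21): 3, random_sequence(rng, 22): 1})]
        report = screen_transitivity(design, libs)
        assert report.clean
        assert (report.per_library["distinct_matching"] == 0).all()

    def test_cds_spike_detected(self, rng):
        design = _cassette(rng, cds_len=600, utr_len=200)
        spike = design.cds[100:121]
        report = screen_transitivity(design, [_library({spike: 5})])
        assert not report.clean
        assert report.per_library.loc["L1", "distinct_matching"] == 1
        assert report.per_library.loc["L1", "reads_matching"] == 5

    def test_target_element_spike_excluded(self, rng):
        design = _cassette(rng, cds_len=600, utr_len=200)
        spike = design.target_element[50:71]
        report = screen_transitivity(design, [_library({spike: 4})])
        assert report.clean

    def test_whole_transcript_exclusion_is_vacuous(self, rng):
        design = _cassette(rng, cds_len=600, utr_len=200)
        spike = design.cds[10:31]
        report = screen_transitivity(
            design,
            [_library({spike: 2})],
            excluded_interval=(0, len(design.assembled)),
        )
        assert report.clean


class TestDesignReport:
    def test_all_pass_status(self, rng):
        design = _cassette(rng)
        rep = design_report(design, {"mirna_sites": (True, {}), "conservation": (True, {})})
        assert rep.status == "PASS" and rep.failed_screens == []

    def test_failure_names_screen(self, rng):
        design = _cassette(rng)
        rep = design_report(design, {"mirna_sites": (True, {}), "conservation": (False, {"n": 1})})
        assert rep.status == "FAIL"
        assert rep.failed_screens == ["conservation"]

    def test_schema_validation_round_trip(self, rng):
        design = _cassette(rng)
        rep = design_report(design, {"mirna_sites": (True, {})}, parameters={"w": 201}, seed=3)
        doc = rep.model_dump()
        assert DesignReport.model_validate(doc) == rep
        with pytest.raises(ValidationError):
            DesignReport.model_validate({"status": "PASS"})
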