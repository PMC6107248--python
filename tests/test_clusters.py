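"""Coverage profiles and dense-window selection."""

import numpy as np
import pytest

from mtsirna.cluster_finder import annotate_regions, build_profile, find_windows
from mtsirna.io import read_gff3, regions_to_gff3
from mtsirna.target_mapper import TargetHit


def _hit(start, end, strand="+", sirna=None, tid="t"):
    sirna = sirna or f"S{start}_{end}_{strand}"
    return TargetHit(sirna, tid, start, end, strand, 0)


class TestBuildProfile:
    def test_no_hits_all_zero(self):
        p = build_profile([], {}, "t", 500)
        assert p.total_mass == 0.0
        assert p.plus.sum() == 0 and p.minus.sum() == 0

    def test_single_plus_hit_block(self):
        h = _hit(100, 121)
        p = build_profile([h], {h.sirna: 40.0}, "t", 500)
        assert (p.plus[100:121] == 40.0).all()
        assert p.plus.sum() == pytest.approx(40.0 * 21)
        assert p.minus.sum() == 0.0
        assert p.distinct_plus[110] == 1

    def test_mass_conservation_identity(self, rng):
        hits = [_hit(int(s), int(s) + 21, "+" if i % 2 else "-", sirna=f"s{i}")
                for i, s in enumerate(rng.integers(0, 400, size=30))]
        tpm = {h.sirna: float(i + 1) for i, h in enumerate(hits)}
        p = build_profile(hits, tpm, "t", 500)
        expected = sum(tpm[h.sirna] * (h.end - h.start) for h in hits)
        assert p.total_mass == pytest.approx(expected)
        assert p.distinct_plus.sum() + p.distinct_minus.sum() == sum(
            h.end - h.start for h in hits
        )

    def test_out_of_bounds_hit_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            build_profile([_hit(490, 512)], {}, "t", 500)

    def test_wrong_transcript_rejected(self):
        with pytest.raises(ValueError):
            build_profile([_hit(0, 20, tid="other")], {}, "t", 500)


class TestFindWindows:
    def test_planted_cluster_recovered(self, small_study):
        from mtsirna.smallrna_catalog import build_matrix
        from mtsirna.specificity_screen import call_mts_sirnas
        from mtsirna.target_mapper import build_index, map_many

        transcripts, truth, libraries = small_study
        m = build_matrix(libraries)
        calls = call_mts_sirnas(m, "tassel").query("is_mts")
        index = build_index(transcripts)
        hits = map_many(calls.index, index)
        donor = truth.donor_transcript_id
        profile = build_profile(
            [h for h in hits if h.transcript_id == donor],
            calls["target_tpm_max"].to_dict(),
            donor,
            len(transcripts[donor]),
        )
        regions = find_windows(profile, W=201, min_distinct=5)
        assert len(regions) >= 1
        top = regions[0]
        lo, hi = truth.planted_region
        overlap = max(0, min(top.end, hi) - max(top.start, lo))
        assert overlap / (hi - lo) >= 0.95

    def test_sparse_hits_below_threshold_empty(self):
        hits = [_hit(0, 20), _hit(300, 321)]
        p = build_profile(hits, {}, "t", 500)
        assert find_windows(p, W=201, min_distinct=5) == []

    def test_window_wider_than_transcript_rejected(self):
        p = build_profile([], {}, "t", 100)
        with pytest.raises(ValueError, match="wider"):
            find_windows(p, W=201)

    def test_score_counts_fully_contained_only(self):
        hits = [_hit(10, 30), _hit(20, 40), _hit(95, 115)]  # third straddles edge
        p = build_profile(hits, {}, "t", 200)
        regions = find_windows(p, W=100, min_distinct=2)
        assert regions[0].start == 0
        assert regions[0].distinct_sirnas == 2

    def test_selected_regions_never_overlap(self, rng):
        hits = [
            _hit(int(s), int(s) + 20, sirna=f"s{i}")
            for i, s in enumerate(rng.integers(0, 950, size=80))
        ]
        p = build_profile(hits, {h.sirna: 1.0 for h in hits}, "t", 1000)
        regions = find_windows(p, W=150, min_distinct=2)
        for a in regions:
            for b in regions:
                if a is not b:
                    assert a.end <= b.start or b.end <= a.start

    def test_first_region_has_global_max_score(self, rng):
        hits = [
            _hit(int(s), int(s) + 20, sirna=f"s{i}")
            for i, s in enumerate(rng.integers(0, 950, size=60))
        ]
        p = build_profile(hits, {h.sirna: 1.0 for h in hits}, "t", 1000)
        regions = find_windows(p, W=150, min_distinct=1)
        # exhaustive check over every possible start
        best = max(
            sum(1 for h in hits if h.start >= s and h.end <= s + 150)
            for s in range(1000 - 150 + 1)
        )
        assert regions[0].distinct_sirnas == best

    def test_score_invariant_under_hit_reordering(self, rng):
        hits = [
            _hit(int(s), int(s) + 20, sirna=f"s{i}")
            for i, s in enumerate(rng.integers(0, 300, size=30))
        ]
        tpm = {h.sirna: 1.0 for h in hits}
        p1 = build_profile(hits, tpm, "t", 400)
        p2 = build_profile(hits[::-1], tpm, "t", 400)
        r1 = find_windows(p1, W=100, min_distinct=2)
        r2 = find_windows(p2, W=100, min_distinct=2)
        assert [(r.start, r.distinct_sirnas) for r in r1] == [
            (r.start, r.distinct_sirnas) for r in r2
        ]

    def test_translation_equivariance(self):
        hits = [_hit(50, 70, sirna="a"), _hit(60, 82, sirna="b"), _hit(55, 80, sirna="c")]
        shifted = [_hit(h.start + 37, h.end + 37, sirna=h.sirna) for h in hits]
        p1 = build_profile(hits, {}, "t", 300)
        p2 = build_profile(shifted, {}, "t", 337)
        r1 = find_windows(p1, W=60, min_distinct=3)
        r2 = find_windows(p2, W=60, min_distinct=3)
        assert [r.start + 37 for r in r1] == [r.start for r in r2]


class TestAnnotate:
    def test_region_report_and_gff3_round_trip(self, tmp_path, rng):
        from mtsirna._util import random_sequence

        tx = random_sequence(rng, 400)
        hits = [_hit(100, 121, "+", "a"), _hit(110, 132, "-", "b"), _hit(105, 126, "+", "c")]
        p = build_profile(hits, {"a": 10.0, "b": 20.0, "c": 5.0}, "t", 400)
        regions = find_windows(p, W=100, min_distinct=3)
        df = annotate_regions(regions, p, {"t": tx})
        row = df.iloc[0]
        assert row["width"] == 100
        assert len(row["sequence"]) == 100
        # report coordinates are 1-based inclusive
        assert row["sequence"] == tx[row["start"] - 1 : row["end"]]
        assert row["distinct_plus"] == 2 and row["distinct_minus"] == 1

        gff = tmp_path / "regions.gff3"
        regions_to_gff3(regions, gff)
        back = read_gff3(gff)
        assert back.iloc[0]["start"] == regions[0].start  # 0-based round trip
        assert back.iloc[0]["end"] == regions[0].end
        assert back.iloc[0]["type"] == "siRNA_target_region"
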