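"""Generator contracts: determinism, planted invariants, round-trips."""

import numpy as np
import pytest

from mtsirna import synthetic_data as syn
from mtsirna._util import revcomp
from mtsirna.race_cleavage_mapper import map_race_reads
from mtsirna.target_mapper import brute_force_map

from conftest import SMALL_PANEL, SMALL_DEPTH


class TestTranscriptome:
    def test_exemplar_donor_length(self):
        transcripts, truth = syn.generate_transcriptome(1, (1826, 1826), seed=7)
        assert len(transcripts) == 1
        assert len(transcripts[truth.donor_transcript_id]) == 1826

    def test_deterministic_for_fixed_seed(self):
        a, _ = syn.generate_transcriptome(4, (300, 900), seed=3)
        b, _ = syn.generate_transcriptome(4, (300, 900), seed=3)
        assert a == b
        c, _ = syn.generate_transcriptome(4, (300, 900), seed=4)
        assert a != c

    @pytest.mark.parametrize(
        "n,rng_", [(0, (300, 400)), (1, (100, 200)), (2, (500, 400))]
    )
    def test_invalid_arguments(self, n, rng_):
        with pytest.raises(ValueError):
            syn.generate_transcriptome(n, rng_, seed=0)


class TestPlantedCluster:
    def test_sirnas_lie_inside_region_and_length_bounds(self):
        transcripts, truth = syn.generate_transcriptome(1, (1826, 1826), seed=7)
        donor = transcripts[truth.donor_transcript_id]
        region = (550, 751)
        planted = syn.plant_sirna_cluster(donor, region, 30, seed=1)
        assert len(planted) == 30
        assert len({p.sequence for p in planted}) == 30
        for p in planted:
            assert 18 <= len(p.sequence) <= 26
            assert region[0] <= p.start and p.end <= region[1]
            site = donor[p.start : p.end]
            assert p.sequence == (revcomp(site) if p.strand == "-" else site)

    def test_cluster_spans_region(self):
        transcripts, truth = syn.generate_transcriptome(1, (1000, 1000), seed=2)
        donor = transcripts[truth.donor_transcript_id]
        planted = syn.plant_sirna_cluster(donor, (100, 301), 10, seed=3)
        assert min(p.start for p in planted) == 100
        assert max(p.end for p in planted) == 301

    def test_strand_mix_zero_is_all_plus(self):
        transcripts, truth = syn.generate_transcriptome(1, (600, 600), seed=2)
        donor = transcripts[truth.donor_transcript_id]
        planted = syn.plant_sirna_cluster(donor, (100, 301), 15, strand_mix=0.0, seed=4)
        assert all(p.strand == "+" for p in planted)

    def test_narrow_region_rejected(self):
        transcripts, truth = syn.generate_transcriptome(1, (600, 600), seed=2)
        donor = transcripts[truth.donor_transcript_id]
        with pytest.raises(ValueError):
            syn.plant_sirna_cluster(donor, (100, 126), 5, seed=0)

    def test_round_trip_through_mapper(self):
        """Brute-force mapping recovers exactly the planted placements."""
        transcripts, truth = syn.generate_transcriptome(1, (1500, 1500), seed=9)
        donor = transcripts[truth.donor_transcript_id]
        planted = syn.plant_sirna_cluster(donor, (400, 700), 50, seed=10)
        for p in planted:
            hits = brute_force_map(p.sequence, transcripts, max_mm=0)
            assert any(
                h.start == p.start and h.end == p.end and h.strand == p.strand
                for h in hits
            )


class TestLibraries:
    def test_depth_floor_enforced(self, small_study):
        _, truth, _ = small_study
        with pytest.raises(ValueError, match="depth"):
            syn.generate_libraries(SMALL_PANEL, truth, depth=10_000, seed=0)

    def test_panel_must_contain_target_tissue(self, small_study):
        _, truth, _ = small_study
        panel = [syn.TissueSample("leaf", "V6"), syn.TissueSample("root", "VE")]
        with pytest.raises(ValueError, match="tassel"):
            syn.generate_libraries(panel, truth, depth=30_000, seed=0)

    def test_total_reads_equal_depth(self, small_study):
        _, _, libraries = small_study
        for lib in libraries:
            assert lib.total_reads == SMALL_DEPTH
            assert sum(lib.unique_counts.values()) == SMALL_DEPTH

    def test_no_leak_when_background_rate_zero(self, small_study):
        _, truth, libraries = small_study
        planted = truth.planted_sequences
        for lib in libraries:
            present = planted & set(lib.unique_counts)
            if lib.tissue == "tassel":
                assert present == planted
            else:
                assert not present

    def test_realized_tpm_within_window_and_poisson_band(self, small_study):
        """Tassel TPM inside [40, 2660] and within 5 SD of the Poisson mean."""
        _, truth, libraries = small_study
        for lib in libraries:
            if lib.tissue != "tassel":
                continue
            for p in truth.planted_sirnas:
                count = lib.unique_counts[p.sequence]
                tpm = count / lib.total_reads * 1e6
                assert 40.0 <= tpm <= 2660.0
                lam = p.tpm_target * lib.total_reads / 1e6
                assert abs(count - lam) <= 5 * np.sqrt(lam) + 1

    def test_deterministic_for_fixed_seed(self, small_study):
        _, truth, libraries = small_study
        again = syn.generate_libraries(
            SMALL_PANEL, truth, depth=SMALL_DEPTH, background_rate=0.0, seed=13
        )
        for a, b in zip(libraries, again):
            assert a.library_id == b.library_id
            assert a.unique_counts == b.unique_counts

    def test_background_leak_rate_nonzero(self, small_study):
        _, truth, _ = small_study
        libs = syn.generate_libraries(
            SMALL_PANEL, truth, depth=30_000, background_rate=0.5, seed=21
        )
        leaf = next(l for l in libs if l.tissue == "leaf")
        assert truth.planted_sequences & set(leaf.unique_counts)


class TestRaceReads:
    def test_read_counting(self):
        tx = "ATG" + "A" * 200
        reads = syn.generate_race_reads(tx, [10, 50], n_per_site=3, seed=0)
        assert len(reads) == 6

    def test_empty_cleavage_list_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_race_reads("A" * 100, [], n_per_site=2, seed=0)

    def test_c_start_position_rejected(self):
        tx = "A" * 50 + "C" + "A" * 50
        with pytest.raises(ValueError, match="poly"):
            syn.generate_race_reads(tx, [50], n_per_site=1, seed=0)

    def test_zero_length_polyc_allowed(self):
        tx = "ATGAGATTAGGAGATATAGAGATTATAGGATTAAGGATTTAGAGAGGATTAG" * 4
        reads = syn.generate_race_reads(
            tx, [5], n_per_site=2, polyc_len_dist={0: 1.0}, vector_contam_rate=0, seed=0
        )
        for _, seq in reads:
            assert seq == syn.DEFAULT_RACE_ADAPTOR + tx[5 : 5 + 100]

    def test_round_trip_recovers_planted_positions(self, rng):
        from mtsirna._util import random_sequence

        tx = random_sequence(rng, 800)
        positions = [p for p in (100, 250, 431) if tx[p] != "C"]
        reads = syn.generate_race_reads(tx, positions, n_per_site=4, seed=3)
        stats = map_race_reads(
            reads, tx, adaptor=syn.DEFAULT_RACE_ADAPTOR, vector=syn.SYNTHETIC_VECTOR
        )
        assert stats.n_rejected == 0 and stats.n_ambiguous == 0
        assert sorted(set(stats.positions)) == positions


class TestGermplasm:
    def test_zero_divergence_identical(self):
        ref = "ACGT" * 80
        variants = syn.generate_germplasm_variants(ref, 5, 0.0, seed=0)
        assert all(v == ref for v in variants.values())

    def test_planted_substitution_fraction(self, rng):
        from mtsirna._util import random_sequence

        ref = random_sequence(rng, 313)
        variants = syn.generate_germplasm_variants(ref, 31, 0.08, seed=1)
        assert len(variants) == 31
        expected = round(0.08 * 313)
        for v in variants.values():
            subs = sum(1 for a, b in zip(ref, v) if a != b)
            assert subs == expected

    def test_divergence_bounds(self):
        with pytest.raises(ValueError):
            syn.generate_germplasm_variants("ACGT" * 50, 3, 0.5, seed=0)
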