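"""Mate-pair distance scan, IS classification, read-depth duplications."""

import numpy as np
import pandas as pd
import pytest

import evotrace as et
from evotrace.errors import DegenerateDataError, InsufficientDataError
from evotrace.sv_detection import counterpart_clusters


def pairs_from_distances(distances, left0=0, spacing=100, read_length=50):
    left = np.arange(len(distances)) * spacing + left0
    frame = pd.DataFrame({
        "pair_id": np.arange(len(distances)),
        "left_pos": left.astype(float),
        "right_pos": left + np.asarray(distances, dtype=float),
        "mapq": 60, "min_baseq": 38, "counterpart": "",
    })
    return et.MappedPairSet(frame, read_length=read_length)


class TestFilterPairs:
    @pytest.mark.parametrize("mapq,baseq,kept", [
        (9, 38, False),    # "< 10" removed
        (10, 30, True),    # boundary retained
        (60, 29, False),   # base-quality clause
        (60, 38, True),
    ])
    def test_quality_boundaries(self, mapq, baseq, kept):
        frame = pd.DataFrame({"pair_id": [0], "left_pos": [0.0],
                              "right_pos": [1200.0], "mapq": [mapq],
                              "min_baseq": [baseq], "counterpart": [""]})
        out = et.filter_pairs(et.MappedPairSet(frame))
        assert len(out) == (1 if kept else 0)


class TestGlobalDistanceStats:
    def test_closed_form(self):
        stats = et.global_distance_stats(
            pairs_from_distances([1100, 1200, 1300]))
        assert stats.mean_distance == pytest.approx(1200)
        assert stats.sd_distance == pytest.approx(100)

    def test_degenerate_spread_raises_downstream(self):
        stats = et.global_distance_stats(pairs_from_distances([1200] * 10))
        assert stats.sd_distance == 0
        with pytest.raises(DegenerateDataError):
            et.scan_distance_deviation(pairs_from_distances([1200] * 10),
                                       stats)

    def test_insufficient_pairs(self):
        with pytest.raises(InsufficientDataError):
            et.global_distance_stats(pairs_from_distances([1200]))

    def test_sampling_accuracy_at_1e5_pairs(self, null_pairs):
        stats = et.global_distance_stats(null_pairs)
        assert abs(stats.mean_distance - 1200) < 1.5
        assert abs(stats.sd_distance - 100) < 1.5


class TestScan:
    def test_event_free_genome_not_flagged(self, null_pairs):
        stats = et.global_distance_stats(null_pairs)
        flagged = et.scan_distance_deviation(null_pairs, stats,
                                             ref_length=100_000)
        assert flagged == []

    def test_null_false_positive_rate_across_seeds(self):
        """Event-free genomes flag nothing in (at least) 9 of 10 runs."""
        clean = 0
        g = et.generate_reference(60_000, seed=30)
        sample = et.plant_events(g, [])
        for seed in range(10):
            pairs = et.simulate_mate_pairs(sample, et.ReadSimConfig(
                insert_mean=1200, insert_sd=100, pair_coverage=40,
                seed=100 + seed))
            if not et.detect_large_indels(pairs, ref_length=60_000):
                clean += 1
        assert clean >= 9

    def test_planted_6775_deletion_flagged_with_matching_shift(self):
        g = et.generate_reference(150_000, seed=31)
        s = et.plant_events(g, [et.PlantedEvent("large_deletion", 70_000,
                                                6775)])
        pairs = et.simulate_mate_pairs(s, et.ReadSimConfig(
            insert_mean=1200, insert_sd=100, pair_coverage=50, seed=32))
        calls = et.detect_large_indels(pairs, ref_length=150_000)
        assert len(calls) == 1
        c = calls[0]
        assert c.kind == "deletion"
        n = c.support
        assert abs(c.size_estimate - 6775) < max(3 * 100 / np.sqrt(n), 10)

    def test_88bp_deletion_below_3sd_not_flagged(self):
        """An 88 bp shift is 0.88 library SD at sd=100: invisible to the
        scan (the pileup indel caller owns it instead)."""
        g = et.generate_reference(80_000, seed=33)
        s = et.plant_events(g, [et.PlantedEvent("small_deletion", 40_000,
                                                88)])
        pairs = et.simulate_mate_pairs(s, et.ReadSimConfig(
            insert_mean=1200, insert_sd=100, pair_coverage=50, seed=34))
        stats = et.global_distance_stats(pairs)
        flagged = et.scan_distance_deviation(pairs, stats,
                                             ref_length=80_000)
        assert flagged == []

    def test_sign_law_and_size_consistency(self):
        """Planted deletions always stretch the regional median above the
        mean, insertions shrink it; sizes track truth within sampling
        error in >= 17/20 seeded runs."""
        hits = 0
        for i, L in enumerate([600, 1000, 6775]):
            g = et.generate_reference(120_000, seed=40 + i)
            s = et.plant_events(g, [et.PlantedEvent("large_deletion",
                                                    60_000, L)])
            for seed in range(7 if L != 6775 else 6):
                pairs = et.simulate_mate_pairs(s, et.ReadSimConfig(
                    insert_mean=1200, insert_sd=100, pair_coverage=30,
                    seed=500 + 10 * i + seed))
                calls = [c for c in et.detect_large_indels(
                    pairs, ref_length=120_000) if c.kind == "deletion"]
                assert len(calls) == 1
                c = calls[0]
                assert c.z > 0  # sign law: deletion median above mean
                tol = max(3 * 100 / np.sqrt(c.support), 10)
                if abs(c.size_estimate - L) <= tol:
                    hits += 1
        assert hits >= 17


class TestISClassification:
    def test_uncensored_insertion_sized_and_classified(self):
        g = et.generate_reference(150_000, seed=35)
        s = et.plant_events(g, [et.PlantedEvent("large_insertion", 75_000,
                                                1199, "IS5")])
        pairs = et.simulate_mate_pairs(s, et.ReadSimConfig(
            insert_mean=5000, insert_sd=50, pair_coverage=50, seed=36))
        calls = et.detect_large_indels(pairs, window_size=5000,
                                       ref_length=150_000)
        ins = [c for c in calls if c.kind == "insertion"]
        assert len(ins) == 1
        c = ins[0]
        assert c.is_element == "IS5"
        assert c.z < 0  # insertion shrinks the regional median
        assert not c.censored
        assert abs(c.size_estimate - 1199) < 25

    def test_censored_insertion_found_via_counterpart_cluster(self):
        """With a ~1.2 kb library a 1199 bp insertion loses its both-flank
        pairs to fragment-length censoring; the counterpart-read cluster
        still recovers and classifies it, flagged censored."""
        g = et.generate_reference(100_000, seed=37)
        s = et.plant_events(g, [et.PlantedEvent("large_insertion", 50_000,
                                                1199, "IS5")])
        pairs = et.simulate_mate_pairs(s, et.ReadSimConfig(
            insert_mean=1200, insert_sd=100, pair_coverage=50, seed=38))
        calls = et.detect_large_indels(pairs, ref_length=100_000)
        ins = [c for c in calls if c.is_element == "IS5"]
        assert len(ins) == 1
        assert ins[0].censored
        assert abs(ins[0].position - 50_000) < 2000

    def test_region_without_counterparts_left_unclassified(self):
        g = et.generate_reference(120_000, seed=39)
        s = et.plant_events(g, [et.PlantedEvent("large_deletion", 60_000,
                                                2000)])
        pairs = et.simulate_mate_pairs(s, et.ReadSimConfig(
            insert_mean=1200, insert_sd=100, pair_coverage=40, seed=41))
        calls = et.detect_large_indels(pairs, ref_length=120_000)
        assert all(c.is_element is None for c in calls)

    def test_counterpart_clusters_group_by_element_and_distance(self):
        frame = pd.DataFrame({
            "pair_id": range(8),
            "left_pos": [100.0, 150, 200, 30_000, 30_100, 30_200, 60_000,
                         60_050],
            "right_pos": [np.nan] * 8,
            "mapq": 60, "min_baseq": 38,
            "counterpart": ["IS5"] * 3 + ["IS186"] * 3 + ["IS5"] * 2,
        })
        clusters = counterpart_clusters(et.MappedPairSet(frame),
                                        min_is_support=3)
        assert len(clusters) == 2
        assert {c["is_element"] for c in clusters} == {"IS5", "IS186"}


class TestCoverageAndDuplication:
    def test_uniform_coverage_profile(self, null_pairs):
        prof = et.coverage_profile(null_pairs, 5000, ref_length=100_000)
        expect = 50.0
        count_per_window = expect * 5000 / 50
        tol = 4 * np.sqrt(count_per_window) / count_per_window * expect
        # first/last windows sit inside the fragment-placement margin and
        # run slightly low; interior windows must be Poisson-flat
        assert np.all(np.abs(prof.depth[1:-1] - expect) < tol)
        assert np.all(prof.depth[[0, -1]] > 0.8 * expect)

    def test_empty_input_zero_profile(self):
        frame = pd.DataFrame({c: [] for c in et.MappedPairSet.COLUMNS})
        prof = et.coverage_profile(et.MappedPairSet(frame), 1000,
                                   ref_length=10_000)
        assert np.all(prof.depth == 0)

    def test_flat_profile_no_calls(self):
        prof = et.CoverageProfile(5000, np.arange(0, 100_000, 5000),
                                  np.full(20, 50.0))
        assert et.detect_duplication(prof) == []

    def test_planted_duplication_recovered_with_double_ratio(self):
        g = et.generate_reference(400_000, seed=42)
        s = et.plant_events(g, [et.PlantedEvent("duplication", 100_000,
                                                80_000)])
        pairs = et.simulate_mate_pairs(s, et.ReadSimConfig(
            insert_mean=1200, insert_sd=100, pair_coverage=40, seed=43))
        prof = et.coverage_profile(pairs, 5000, ref_length=400_000)
        calls = et.detect_duplication(prof)
        assert len(calls) == 1
        c = calls[0]
        assert abs(c.length - 80_000) <= 5000
        assert c.mean_ratio == pytest.approx(2.0, abs=0.15)

    def test_two_separated_duplications_not_merged(self):
        depth = np.full(60, 50.0)
        depth[10:22] = 100.0
        depth[40:52] = 100.0
        prof = et.CoverageProfile(5000, np.arange(60) * 5000, depth)
        calls = et.detect_duplication(prof)
        assert len(calls) == 2

    def test_zero_median_raises(self):
        prof = et.CoverageProfile(5000, np.arange(20) * 5000, np.zeros(20))
        with pytest.raises(InsufficientDataError):
            et.detect_duplication(prof)
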