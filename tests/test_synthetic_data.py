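"""Generator contracts: genomes, planted events, liftover, reads, pileups,
expression/metabolome/OD/population simulators."""

import numpy as np
import pandas as pd
import pytest

import evotrace as et
from evotrace.errors import ConflictError, InvalidArgumentError


class TestGenerateReference:
    def test_length_and_gene_count(self):
        g = et.generate_reference(10_000, 0.5, n_genes=5, seed=1)
        assert len(g) == 10_000
        assert len(g.gene_annotations) == 5
        assert set(g.sequence) <= set("ACGT")
        for _, a, b, _ in g.gene_annotations:
            assert 0 <= a < b <= 10_000

    def test_seed_determinism(self):
        a = et.generate_reference(10_000, 0.5, 5, seed=1)
        b = et.generate_reference(10_000, 0.5, 5, seed=1)
        assert a.sequence == b.sequence
        assert a.is_catalog == b.is_catalog

    def test_gc_fraction_at_megabase_scale(self):
        g = et.generate_reference(1_000_000, 0.508, n_genes=0, seed=2)
        gc = sum(c in "GC" for c in g.sequence) / len(g)
        # binomial SE at n=1e6 is 0.0005; 0.005 is a 10-sigma bound
        assert abs(gc - 0.508) < 0.005

    def test_is_catalog_lengths(self):
        g = et.generate_reference(1000, seed=0)
        assert len(g.is_catalog["IS5"]) == 1199
        assert len(g.is_catalog["IS186"]) == 1343

    def test_rejects_bad_arguments(self):
        with pytest.raises(InvalidArgumentError):
            et.generate_reference(0, 0.5)
        with pytest.raises(InvalidArgumentError):
            et.generate_reference(100, 1.5)


class TestPlantEvents:
    @pytest.mark.parametrize("events,delta", [
        ([et.PlantedEvent("snv", 500, 0, "A")], 0),
        ([et.PlantedEvent("small_deletion", 500, 88)], -88),
        ([et.PlantedEvent("large_insertion", 500, 1199, "IS5")], 1199),
        ([et.PlantedEvent("small_insertion", 500, 3, "CCG")], 3),
        ([et.PlantedEvent("duplication", 200, 400)], 400),
        ([et.PlantedEvent("small_deletion", 100, 88),
          et.PlantedEvent("large_insertion", 700, 1343, "IS186")],
         1343 - 88),
    ])
    def test_length_conservation(self, events, delta):
        g = et.generate_reference(2000, seed=3)
        s = et.plant_events(g, events)
        assert len(s) == len(g) + delta
        assert len(s) == len(g) + sum(e.signed_length for e in events)

    def test_overlapping_events_conflict(self):
        g = et.generate_reference(2000, seed=3)
        with pytest.raises(ConflictError):
            et.plant_events(g, [et.PlantedEvent("small_deletion", 100, 88),
                                et.PlantedEvent("snv", 150, 0, "A")])

    def test_unknown_is_name_rejected(self):
        g = et.generate_reference(2000, seed=3)
        with pytest.raises(InvalidArgumentError):
            et.plant_events(g, [et.PlantedEvent("large_insertion", 100,
                                                1199, "IS999")])

    def test_snv_base_is_edited(self):
        g = et.generate_reference(2000, seed=3)
        alt = "T" if g.sequence[900] != "T" else "A"
        s = et.plant_events(g, [et.PlantedEvent("snv", 900, 0, alt)])
        assert s.sequence[900] == alt
        assert s.sequence[:900] == g.sequence[:900]
        assert s.sequence[901:] == g.sequence[901:]

    def test_liftover_roundtrip_outside_footprints(self):
        g = et.generate_reference(50_000, seed=4)
        events = [et.PlantedEvent("small_deletion", 10_000, 88),
                  et.PlantedEvent("large_insertion", 20_000, 1199, "IS5"),
                  et.PlantedEvent("duplication", 30_000, 2000),
                  et.PlantedEvent("snv", 40_000, 0, "A")]
        s = et.plant_events(g, events)
        rng = np.random.default_rng(0)
        pos = rng.integers(0, 50_000, 1000)
        footprints = [e.footprint() for e in events]
        outside = np.array([not any(a <= p < b for a, b in footprints)
                            for p in pos])
        pos = pos[outside]
        samp = s.liftover.ref_to_sample(pos)
        back = s.liftover.sample_to_ref(samp)
        np.testing.assert_array_equal(back, pos)

    def test_duplication_second_copy_lifts_to_same_reference(self):
        g = et.generate_reference(10_000, seed=5)
        s = et.plant_events(g, [et.PlantedEvent("duplication", 4000, 1000)])
        # sample [4000,5000) and [5000,6000) both carry reference [4000,5000)
        assert s.sequence[4000:5000] == s.sequence[5000:6000]
        ref = s.liftover.sample_to_ref([5500])[0]
        assert ref == 4500


class TestSimulateMatePairs:
    def test_event_free_mean_distance(self, null_pairs):
        d = null_pairs.both_mapped().distances.to_numpy()
        n = len(d)
        assert abs(d.mean() - 1200) < 3 * 100 / np.sqrt(n)

    def test_deletion_shifts_spanning_distance_exactly(self):
        """With a degenerate fragment length, spanning pairs show exactly
        fragment + deletion length (coordinate-arithmetic oracle)."""
        g = et.generate_reference(20_000, seed=6)
        s = et.plant_events(g, [et.PlantedEvent("small_deletion", 10_000, 88)])
        cfg = et.ReadSimConfig(insert_mean=1200, insert_sd=0.0,
                               read_length=50, pair_coverage=30, seed=1)
        pairs = et.simulate_mate_pairs(s, cfg)
        d = pairs.both_mapped().distances.to_numpy()
        assert set(np.unique(d)) == {1200.0, 1288.0}
        spanning = pairs.frame[(pairs.frame.left_pos < 10_000)
                               & (pairs.frame.right_pos > 10_088)]
        assert (spanning.right_pos - spanning.left_pos == 1288).all()

    def test_insertion_both_flank_geometry(self):
        """Both-flank pairs across an L-bp insertion require fragments of at
        least L + 2 x read_length; shorter libraries yield none."""
        g = et.generate_reference(20_000, seed=6)
        s = et.plant_events(g, [et.PlantedEvent("large_insertion", 10_000,
                                                1199, "IS5")])
        short = et.simulate_mate_pairs(s, et.ReadSimConfig(
            insert_mean=1250, insert_sd=0.0, read_length=50,
            pair_coverage=30, seed=2))
        # 1250 < 1199 + 100: every both-mapped pair avoids the insertion
        assert (short.both_mapped().distances == 1250).all()
        long = et.simulate_mate_pairs(s, et.ReadSimConfig(
            insert_mean=1400, insert_sd=0.0, read_length=50,
            pair_coverage=30, seed=2))
        d = long.both_mapped().distances.to_numpy()
        assert (d == 1400 - 1199).sum() > 0  # spanning pairs at F - L

    def test_counterpart_reads_name_the_is_element(self,
                                                   strain_f_like_sample):
        cfg = et.ReadSimConfig(insert_mean=1200, insert_sd=100,
                               pair_coverage=50, seed=3)
        pairs = et.simulate_mate_pairs(strain_f_like_sample, cfg)
        cp = pairs.frame["counterpart"]
        assert (cp == "IS5").sum() > 10
        near = pairs.frame[cp == "IS5"]["left_pos"]
        assert near.between(43_000, 46_500).all()

    def test_seed_determinism(self, strain_f_like_sample):
        cfg = et.ReadSimConfig(insert_mean=1200, insert_sd=100,
                               pair_coverage=5, seed=9)
        a = et.simulate_mate_pairs(strain_f_like_sample, cfg)
        b = et.simulate_mate_pairs(strain_f_like_sample, cfg)
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_pair_tsv_roundtrip(self, tmp_path, null_pairs):
        p = tmp_path / "pairs.tsv"
        null_pairs.to_tsv(p)
        back = et.MappedPairSet.from_tsv(p)
        assert len(back) == len(null_pairs)
        np.testing.assert_allclose(back.frame.left_pos,
                                   null_pairs.frame.left_pos)


class TestSimulatePileups:
    def _population(self, fraction=1.0, error=0.0, seed=1, snv_pos=5000):
        g = et.generate_reference(10_000, seed=8)
        alt = "T" if g.sequence[snv_pos] != "T" else "A"
        s = et.plant_events(g, [et.PlantedEvent("snv", snv_pos, 0, alt,
                                                allele_fraction=fraction)])
        cfg = et.ReadSimConfig(pair_coverage=200, base_error_rate=error,
                               seed=seed)
        return et.simulate_pileups([(s, 1.0)], cfg), snv_pos

    def test_fixed_snv_without_error_has_unit_ratio(self):
        pile, pos = self._population(1.0, 0.0)
        assert pile.variant_count[pos] == pile.depth[pos] > 0

    def test_half_fraction_ratio_within_binomial_error(self):
        pile, pos = self._population(0.5, 0.0)
        ratio = pile.variant_count[pos] / pile.depth[pos]
        se = np.sqrt(0.25 / pile.depth[pos])
        assert abs(ratio - 0.5) < 3 * se

    def test_background_error_rate(self):
        g = et.generate_reference(10_000, seed=8)
        s = et.plant_events(g, [])
        pile = et.simulate_pileups([(s, 1.0)], et.ReadSimConfig(
            pair_coverage=100, base_error_rate=0.01, seed=2))
        mean_vc = pile.variant_count.mean()
        assert abs(mean_vc - 0.01 * pile.depth.mean()) < 0.1

    def test_indel_evidence_emitted(self):
        g = et.generate_reference(10_000, seed=8)
        s = et.plant_events(g, [et.PlantedEvent("small_deletion", 4000, 88)])
        pile = et.simulate_pileups([(s, 1.0)], et.ReadSimConfig(
            pair_coverage=50, seed=3))
        slen, count = pile.indel_evidence[4000]
        assert slen == -88
        assert count == pile.depth[4000]

    def test_empty_population_rejected(self):
        with pytest.raises(InvalidArgumentError):
            et.simulate_pileups([], et.ReadSimConfig())


class TestExpressionSimulator:
    def test_column_layout_matches_study_grid(self):
        em = et.simulate_expression_timecourse(n_genes=50, strains=6, seed=1)
        assert em.values.shape == (50, 6 * 6 + 1)
        assert "parent" in em.values.columns
        assert set(em.metadata.loc[em.values.columns[1:], "time_h"]) == set(
            et.EXPRESSION_TIMEPOINTS_H)

    def test_zero_noise_strains_identical(self):
        em = et.simulate_expression_timecourse(n_genes=100, strains=2,
                                               noise_sd=0.0, seed=2)
        a = np.log10(em.values["A_t2496"] / em.values["parent"])
        b = np.log10(em.values["B_t2496"] / em.values["parent"])
        np.testing.assert_allclose(a, b, atol=1e-12)
        assert np.corrcoef(a, b)[0, 1] == pytest.approx(1.0)

    def test_divergent_strain_correlates_less(self):
        em = et.simulate_expression_timecourse(
            n_genes=400, strains=4, noise_sd=0.05, divergent_strain=1,
            seed=3)
        lr = {s: np.log10(em.values[f"{s}_t2496"] / em.values["parent"])
              for s in "ABCD"}
        r = pd.DataFrame(lr).corr()
        divergent = [r.loc["B", s] for s in "ACD"]
        others = [r.loc[a, b] for a, b in [("A", "C"), ("A", "D"),
                                           ("C", "D")]]
        assert max(divergent) < min(others)

    def test_negative_noise_rejected(self):
        with pytest.raises(InvalidArgumentError):
            et.simulate_expression_timecourse(n_genes=10, noise_sd=-1)


class TestMetabolomeSimulator:
    def test_default_panel_has_83_metabolites(self):
        mt = et.simulate_metabolome(seed=1)
        assert mt.shape == (83, 7)
        assert (mt > 0).all().all()

    def test_zero_noise_gives_perfect_pairwise_correlation(self):
        mt = et.simulate_metabolome(strains=3, noise_sd=0.0, seed=2)
        lr = np.log10(mt[["A", "B", "C"]].div(mt["parent"], axis=0))
        corr = lr.corr()
        np.testing.assert_allclose(corr, 1.0, atol=1e-12)

    def test_no_shared_shift_gives_null_correlation(self):
        mt = et.simulate_metabolome(n_metabolites=2000, strains=2,
                                    shared_logshift_sd=0.0, noise_sd=0.3,
                                    seed=3)
        lr = np.log10(mt[["A", "B"]].div(mt["parent"], axis=0))
        assert abs(lr.corr().loc["A", "B"]) < 0.1


class TestODAndPopulation:
    def test_exact_exponential(self):
        s = et.simulate_od_series(0.2, od0=0.05, duration=1.0, interval=1.0)
        assert s.od600[-1] == pytest.approx(0.05 * np.exp(0.2))

    def test_zero_rate_constant(self):
        s = et.simulate_od_series(0.0, od0=0.1, duration=5, interval=1)
        np.testing.assert_allclose(s.od600, 0.1)

    def test_noisy_series_recoverable(self):
        s = et.simulate_od_series(0.2, duration=9.5, interval=0.5,
                                  noise_sd=0.02, seed=4)
        est = et.specific_growth_rate(s)
        assert abs(est.mu - 0.2) / 0.2 < 0.05

    def test_population_table_roundtrip(self):
        tbl = et.simulate_population_timecourse(
            ["m1", "m2"],
            {"m1": [0, 0.3, 1.0], "m2": [0.5, 0.4, 0.1]},
            timepoints=[216, 576, 1224])
        assert tbl.shape == (2, 3)
        np.testing.assert_allclose(tbl.loc["m1"], [0, 0.3, 1.0])
        np.testing.assert_allclose(tbl.loc["m2"], [0.5, 0.4, 0.1])

    def test_study_grid_has_12_timepoints(self):
        tbl = et.simulate_population_timecourse(
            ["m"], {"m": [0] * 12})
        assert tbl.shape[1] == 12
        assert list(tbl.columns) == list(et.POPULATION_TIMEPOINTS_H)

    def test_out_of_range_frequency_rejected(self):
        with pytest.raises(InvalidArgumentError):
            et.simulate_population_timecourse(
                ["m"], {"m": [0.5] * 11 + [1.2]})
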