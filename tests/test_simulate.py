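"""Population simulation: exclusions, strata, resampling, failure rates."""

import numpy as np
import pandas as pd
import pytest

import dietcorrect as dc
from dietcorrect.metrics import FEMALE, MALE
from dietcorrect.simulate import DEFAULT_AGE_BIN_EDGES


@pytest.fixture
def raw_with_flags():
    return pd.DataFrame({
        "id": range(6),
        "sex": [1, 2, 1, 2, 1, 2],
        "age_years": [44.0, 30.0, 17.0, 50.0, 60.0, 28.0],
        "weight_kg": [80.0, 62.0, 70.0, 58.0, 90.0, 66.0],
        "ei_claimed_kcal": [2000.0, 1800.0, 2100.0, np.nan, 2200.0, 1900.0],
        "special_diet": [False, True, False, False, False, False],
        "atypical_day": [False, False, False, False, True, False],
    })


class TestApplyExclusions:
    def test_rules_and_counts(self, raw_with_flags):
        kept, counts = dc.apply_exclusions(raw_with_flags)
        assert counts == {"special_diet": 1, "atypical_day": 1,
                          "nonreporter": 1, "under_18": 1}
        assert set(kept["id"]) == {0, 5}

    def test_clean_adults_retained(self, tiny_persons):
        kept, counts = dc.apply_exclusions(tiny_persons)
        assert len(kept) == len(tiny_persons)
        assert sum(counts.values()) == 0


class TestFilterPopulation:
    def test_nonblack_and_age_window(self):
        df = pd.DataFrame({"sex": [1, 1, 2], "age_years": [30.0, 50.0, 55.0],
                           "race_group": ["black", "nonblack", "nonblack"]})
        assert len(dc.filter_population(df, "all_adults")) == 3
        assert len(dc.filter_population(df, "nonblack")) == 2
        assert list(dc.filter_population(df, "nonblack_40_69")["age_years"]) == [50.0, 55.0]
        with pytest.raises(ValueError):
            dc.filter_population(df, "everyone")


class TestBuildStrata:
    def test_four_singleton_strata(self):
        df = pd.DataFrame({"sex": [1, 1, 2, 2], "age_years": [20.0, 40.0, 20.0, 40.0],
                           "weight_kg": 70.0, "ei_claimed_kcal": 2000.0,
                           "height_cm": 170.0})
        table = dc.build_strata(df, age_bin_edges=(18.0, 30.0))
        assert len(table.strata) == 4
        assert all(len(v) == 1 for v in table.strata.values())

    def test_interior_edge_goes_to_upper_bin(self):
        df = pd.DataFrame({"sex": [1], "age_years": [30.0], "weight_kg": [70.0],
                           "ei_claimed_kcal": [2000.0], "height_cm": [170.0]})
        table = dc.build_strata(df, age_bin_edges=(18.0, 30.0, 40.0))
        assert (MALE, 1) in table.strata

    def test_above_last_edge_goes_to_final_bin(self):
        df = pd.DataFrame({"sex": [2], "age_years": [85.0], "weight_kg": [60.0],
                           "ei_claimed_kcal": [1800.0], "height_cm": [160.0]})
        table = dc.build_strata(df, age_bin_edges=DEFAULT_AGE_BIN_EDGES)
        assert (FEMALE, len(DEFAULT_AGE_BIN_EDGES) - 1) in table.strata

    def test_unsorted_edges_rejected(self, tiny_persons):
        with pytest.raises(ValueError):
            dc.build_strata(tiny_persons, age_bin_edges=(30.0, 18.0))

    def test_empty_table_rejected(self, tiny_persons):
        with pytest.raises(ValueError):
            dc.build_strata(tiny_persons.iloc[:0])


class TestSamplePopulation:
    def test_degenerate_weights_hit_one_cell(self, tiny_persons):
        table = dc.build_strata(tiny_persons)
        cell = sorted(table.strata)[0]
        weights = {c: (1.0 if c == cell else 0.0) for c in table.strata}
        pop = dc.sample_population(table, weights, 50, np.random.default_rng(0))
        assert len(pop) == 50
        assert set(pop["sex"]) == {cell[0]}

    def test_same_seed_identical_population(self, nhanes_pop):
        _, strata = nhanes_pop
        weights = dc.default_agesex_weights("2007")
        a = dc.sample_population(strata, weights, 500, np.random.default_rng(42))
        b = dc.sample_population(strata, weights, 500, np.random.default_rng(42))
        pd.testing.assert_frame_equal(a, b)

    def test_realised_fractions_track_weights(self, nhanes_pop):
        _, strata = nhanes_pop
        male_cell = next(c for c in sorted(strata.strata) if c[0] == MALE)
        female_cell = next(c for c in sorted(strata.strata) if c[0] == FEMALE)
        weights = {c: 0.0 for c in strata.strata}
        weights[male_cell] = 0.6
        weights[female_cell] = 0.4
        pop = dc.sample_population(strata, weights, 100_000, np.random.default_rng(1))
        assert (pop["sex"] == MALE).mean() == pytest.approx(0.6, abs=0.01)

    def test_positively_weighted_empty_stratum_rejected(self, tiny_persons):
        table = dc.build_strata(tiny_persons)
        weights = {c: 0.0 for c in table.strata}
        weights[next(iter(table.strata))] = 0.5
        weights[(MALE, 99)] = 0.5
        with pytest.raises(ValueError):
            dc.sample_population(table, weights, 10, np.random.default_rng(0))

    def test_weights_must_sum_to_one(self, tiny_persons):
        table = dc.build_strata(tiny_persons)
        weights = {c: 0.4 for c in table.strata}
        with pytest.raises(ValueError):
            dc.sample_population(table, weights, 10, np.random.default_rng(0))


class TestRunSimulation:
    def test_constructed_failure_fraction_recovered(self):
        # population built so ~30% of IndEI values are out of bounds
        df, strata = dc.generate_nhanes_like(dc.NhanesLikeConfig(
            n=20_000, implausible_fraction_target=0.30, seed=4))
        weights = dc.default_agesex_weights("2007")
        cfg = dc.SimulationConfig(n_individuals=5_000, n_replicates=20, seed=4,
                                  method="none")
        res = dc.run_simulation(cfg, strata, weights)
        assert res.failure_rate_mean == pytest.approx(30.0, abs=2.0)

    def test_correction_to_constant_plausible_indei_zeroes_failures(self, nhanes_pop):
        # a model predicting the exact misreport that lands IndEI at ~1.5
        # cannot be expressed as a constant model; instead verify via bounds
        # so wide that everything is plausible after no correction
        _, strata = nhanes_pop
        weights = dc.default_agesex_weights("2007")
        wide = dc.PlausibilityBounds(min_indei=1e-6, max_indei_female=1e3,
                                     max_indei_male=1e3)
        cfg = dc.SimulationConfig(n_individuals=2_000, n_replicates=5, seed=1,
                                  method="none", bounds=wide)
        res = dc.run_simulation(cfg, strata, weights)
        assert res.failure_rate_mean == 0.0

    def test_determinism_bitwise(self, nhanes_pop):
        _, strata = nhanes_pop
        weights = dc.default_agesex_weights("2007")
        cfg = dc.SimulationConfig(n_individuals=1_000, n_replicates=5, seed=77,
                                  method="intake_shift")
        pal = dc.default_pal_distributions()
        a = dc.run_simulation(cfg, strata, weights, pal_dists=pal)
        b = dc.run_simulation(cfg, strata, weights, pal_dists=pal)
        np.testing.assert_array_equal(a.failure_rate_per_replicate,
                                      b.failure_rate_per_replicate)
        assert a.shift_kcal_by_sex == b.shift_kcal_by_sex

    def test_method_requires_matching_inputs(self, nhanes_pop):
        _, strata = nhanes_pop
        weights = dc.default_agesex_weights("2007")
        cfg = dc.SimulationConfig(n_individuals=100, n_replicates=1, method="regression")
        with pytest.raises(ValueError):
            dc.run_simulation(cfg, strata, weights)

    def test_replicate_rates_are_iid_so_se_scales_with_replicates(self, nhanes_pop):
        # SD of means of disjoint 10-replicate blocks ~ SD(single)/sqrt(10)
        _, strata = nhanes_pop
        weights = dc.default_agesex_weights("2007")
        cfg = dc.SimulationConfig(n_individuals=400, n_replicates=200, seed=6,
                                  method="none")
        res = dc.run_simulation(cfg, strata, weights)
        rates = res.failure_rate_per_replicate
        block_means = rates.reshape(20, 10).mean(axis=1)
        ratio = block_means.std(ddof=1) / (rates.std(ddof=1) / np.sqrt(10))
        assert 0.6 < ratio < 1.5

    def test_result_invariants(self, nhanes_pop):
        _, strata = nhanes_pop
        weights = dc.default_agesex_weights("2007")
        cfg = dc.SimulationConfig(n_individuals=500, n_replicates=8, seed=2,
                                  method="none")
        res = dc.run_simulation(cfg, strata, weights)
        assert res.n_replicates == 8 and len(res.failure_rate_per_replicate) == 8
        assert np.all((res.failure_rate_per_replicate >= 0)
                      & (res.failure_rate_per_replicate <= 100))
        assert "failure rate" in res.summary()


class TestPopulationSimulation:
    def test_end_to_end_from_raw_table(self):
        df, _ = dc.generate_nhanes_like(dc.NhanesLikeConfig(n=3_000, seed=9))
        cfg = dc.SimulationConfig(n_individuals=1_000, n_replicates=3, seed=9,
                                  method="intake_shift",
                                  population_filter="nonblack")
        sim = dc.PopulationSimulation(cfg, df, pal_dists=dc.default_pal_distributions())
        assert all(v == 0 for v in sim.exclusion_counts.values())
        res = sim.run()
        assert res.n_replicates == 3
        assert set(res.shift_kcal_by_sex) == {MALE, FEMALE}
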