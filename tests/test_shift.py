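"""Intake-shift method: log-normal PAL fits, quantile alignment, shifts."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

import dietcorrect as dc
from dietcorrect.metrics import FEMALE, MALE


class TestPALDistribution:
    def test_geometric_reading_of_published_fits(self):
        d = dc.default_pal_distributions()
        assert d[MALE].geometric_mean == pytest.approx(1.83)
        assert d[MALE].geometric_sd == pytest.approx(1.14)
        assert d[FEMALE].geometric_mean == pytest.approx(1.63)
        assert d[FEMALE].geometric_sd == pytest.approx(1.13)

    def test_physiologic_range_enforced(self):
        with pytest.raises(ValueError):
            dc.PALDistribution(sex=MALE, log_mean=np.log(7.0), log_sd=0.1)

    def test_json_round_trip(self, tmp_path):
        d = dc.default_pal_distributions()[FEMALE]
        p = tmp_path / "pal.json"
        d.to_json(p)
        assert dc.PALDistribution.from_json(p) == d


class TestFitLognormalPAL:
    def test_monte_carlo_recovery_within_one_percent(self):
        rng = np.random.default_rng(21)
        target = dc.default_pal_distributions()[MALE]
        draws = rng.lognormal(target.log_mean, target.log_sd, 10_000)
        fit = dc.fit_lognormal_pal(draws, MALE)
        assert fit.geometric_mean == pytest.approx(1.83, rel=0.01)
        assert fit.geometric_sd == pytest.approx(1.14, rel=0.01)

    def test_constant_input_degenerates(self):
        fit = dc.fit_lognormal_pal(np.full(20, 1.6), FEMALE)
        assert fit.log_sd == pytest.approx(0.0, abs=1e-12)
        assert fit.geometric_mean == pytest.approx(1.6)

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            dc.fit_lognormal_pal(np.r_[np.full(19, 1.6), 0.0], MALE)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            dc.fit_lognormal_pal(np.full(5, 1.6), MALE)


class TestLognormalQuantiles:
    def test_single_value_is_geometric_mean(self):
        d = dc.default_pal_distributions()[MALE]
        q = dc.lognormal_quantiles(d, 1)
        assert q[0] == pytest.approx(d.geometric_mean)

    def test_degenerate_sd_gives_constant(self):
        d = dc.PALDistribution(sex=FEMALE, log_mean=np.log(1.7), log_sd=0.0)
        np.testing.assert_allclose(dc.lognormal_quantiles(d, 7), 1.7)

    def test_plotting_position_arithmetic(self):
        # geometric mean 2, log-sd 0.1, n=4: 3rd value = 2*exp(0.1*z(0.625))
        d = dc.PALDistribution(sex=MALE, log_mean=np.log(2.0), log_sd=0.1)
        q = dc.lognormal_quantiles(d, 4)
        assert q[2] == pytest.approx(2.0 * np.exp(0.1 * scipy.stats.norm.ppf(0.625)))
        assert q[2] == pytest.approx(2.0648, abs=2e-4)

    @pytest.mark.parametrize("n", [1, 4, 101])
    def test_matches_direct_normal_quantile_arithmetic(self, n):
        d = dc.default_pal_distributions()[FEMALE]
        expected = np.exp(d.log_mean + d.log_sd
                          * scipy.stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n))
        np.testing.assert_allclose(dc.lognormal_quantiles(d, n), expected)

    @settings(derandomize=True, max_examples=30)
    @given(gm=st.floats(1.2, 3.0), gsd=st.floats(1.0, 1.5), n=st.integers(1, 300))
    def test_output_nondecreasing(self, gm, gsd, n):
        d = dc.PALDistribution(sex=MALE, log_mean=np.log(gm), log_sd=np.log(gsd))
        q = dc.lognormal_quantiles(d, n)
        assert np.all(np.diff(q) >= 0)

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError):
            dc.lognormal_quantiles(dc.default_pal_distributions()[MALE], 0)


class TestComputeShift:
    def test_perfect_alignment_gives_zero_shift(self):
        d = dc.default_pal_distributions()[MALE]
        q = dc.lognormal_quantiles(d, 50)
        res = dc.compute_shift(q, np.full(50, 1800.0), d, sex=MALE)
        assert res.shift_kcal == pytest.approx(0.0, abs=1e-9)

    def test_constant_offset_recovered_algebraically(self):
        d = dc.default_pal_distributions()[FEMALE]
        q = dc.lognormal_quantiles(d, 40)
        res = dc.compute_shift(q - 0.25, np.full(40, 2000.0), d, sex=FEMALE)
        assert res.shift_kcal == pytest.approx(0.25 * 2000.0)

    def test_matches_brute_force_loop(self):
        # 7 handcrafted persons with heterogeneous RMR vs an independent loop
        d = dc.PALDistribution(sex=MALE, log_mean=np.log(1.8), log_sd=np.log(1.15))
        ind_ei = np.array([1.9, 0.8, 1.4, 2.6, 1.4, 1.1, 3.1])
        rmr = np.array([1500.0, 1720.0, 1655.0, 1890.0, 1433.0, 2010.0, 1588.0])
        res = dc.compute_shift(ind_ei, rmr, d, sex=MALE)

        order = sorted(range(7), key=lambda i: ind_ei[i])
        deltas = []
        for rank, i in enumerate(order):
            z = scipy.stats.norm.ppf((rank + 0.5) / 7)
            pal_q = np.exp(d.log_mean + d.log_sd * z)
            deltas.append((pal_q - ind_ei[i]) * rmr[i])
        assert res.shift_kcal == pytest.approx(sum(deltas) / 7, abs=1e-12)
        np.testing.assert_allclose(np.sort(res.per_person_delta), np.sort(deltas))

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        d = dc.default_pal_distributions()[MALE]
        ind_ei = rng.uniform(0.8, 3.0, 100)
        rmr = rng.uniform(1400, 2100, 100)
        a = dc.compute_shift(ind_ei, rmr, d)
        perm = rng.permutation(100)
        b = dc.compute_shift(ind_ei[perm], rmr[perm], d)
        assert a.shift_kcal == pytest.approx(b.shift_kcal, abs=1e-9)

    def test_constant_caloric_underreport_recovered(self):
        # a known per-sex caloric offset is recovered within 25 kcal at n=10k
        rng = np.random.default_rng(1)
        dists = dc.default_pal_distributions()
        for sex, offset in [(MALE, 905.0), (FEMALE, 600.0)]:
            d = dists[sex]
            n = 10_000
            pal = rng.lognormal(d.log_mean, d.log_sd, n)
            rmr = dc.schofield_rmr(np.full(n, sex), rng.uniform(40, 69, n),
                                   rng.normal(81, 17.6, n).clip(40))
            res = dc.compute_shift(pal - offset / rmr, rmr, d, sex=sex)
            assert res.shift_kcal == pytest.approx(offset, abs=25.0)

    def test_empty_and_mixed_sex_rejected(self):
        d = dc.default_pal_distributions()[MALE]
        with pytest.raises(ValueError):
            dc.compute_shift(np.array([]), np.array([]), d)
        with pytest.raises(ValueError):
            dc.compute_shift(np.array([1.5, 1.6]), np.array([1700.0, 1700.0]),
                             d, sex=np.array([MALE, FEMALE]))


class TestApplyShift:
    def test_zero_shift_is_identity(self):
        ei = np.array([1500.0, 2000.0])
        np.testing.assert_array_equal(dc.apply_shift(ei, 0.0), ei)

    def test_addition_and_floor(self):
        assert dc.apply_shift(1500.0, 600.0) == 2100.0
        assert dc.apply_shift(100.0, -600.0) == 0.0


class TestComparePALByGroup:
    def test_identical_groups_not_significant(self):
        x = np.r_[np.linspace(1.2, 2.4, 50), np.linspace(1.2, 2.4, 50)]
        labels = np.r_[["a"] * 50, ["b"] * 50]
        F, p = dc.compare_pal_by_group(x, labels)
        assert F == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(9)
        x = np.r_[rng.lognormal(np.log(1.4), 0.12, 200),
                  rng.lognormal(np.log(2.2), 0.12, 200)]
        labels = np.r_[["lo"] * 200, ["hi"] * 200]
        _, p = dc.compare_pal_by_group(x, labels)
        assert p < 1e-3

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            dc.compare_pal_by_group(np.ones(10), np.array(["a"] * 10))


class TestIntakeShiftModel:
    def test_fit_from_training_matches_function(self, open_train):
        results = dc.IntakeShiftModel.from_dataframe(open_train).fit()
        prof = dc.derive_profiles(open_train)
        for sex in (MALE, FEMALE):
            vals = prof.loc[prof["sex"] == sex, "pal"].to_numpy()
            direct = dc.fit_lognormal_pal(vals, sex)
            assert results.pal_by_sex[sex].log_mean == pytest.approx(direct.log_mean)

    def test_apply_aligns_mean_indei_with_pal_mean(self, open_train, nhanes_pop):
        # after shifting, per-sex mean IndEI matches the mean of the matched
        # PAL quantiles (first-moment alignment by construction)
        pop, _ = nhanes_pop
        results = dc.IntakeShiftModel(pal_by_sex=dc.default_pal_distributions()).fit()
        prof = dc.derive_profiles(pop)
        shifted = results.apply_to(prof)
        for sex, dist in results.pal_by_sex.items():
            m = shifted["sex"] == sex
            q = dc.lognormal_quantiles(dist, int(m.sum()))
            # floor at 0 kcal never binds here (shifts are positive)
            mean_indei = (shifted.loc[m, "ei_adjusted"] / shifted.loc[m, "rmr_kcal"]).mean()
            target = (shifted.loc[m, "ind_ei_claimed"]
                      + results.shifts_for(prof)[sex].shift_kcal / shifted.loc[m, "rmr_kcal"]).mean()
            assert mean_indei == pytest.approx(target, rel=1e-12)
            # and the shift itself aligns first moments up to RMR/rank coupling
            assert mean_indei == pytest.approx(q.mean(), rel=0.05)

    def test_summary_table(self):
        results = dc.IntakeShiftModel(pal_by_sex=dc.default_pal_distributions()).fit()
        s = results.summary()
        assert set(s["sex"]) == {"male", "female"}
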