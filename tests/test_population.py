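"""Sliding departure, pattern shuffles, bias tests, chi-square, cessation."""

import numpy as np
import pytest
from scipy import stats

from vlpag import population as pop
from vlpag import synth
from vlpag.session import Session, default_design


class TestSlidingDeparture:
    def test_identical_populations_never_depart(self, rng):
        z = rng.normal(size=(10, 100))
        res = pop.sliding_departure(z, z.copy())
        assert res.departure_time_p05 is None
        assert res.departure_time_bonferroni is None

    def test_planted_step_found_near_its_onset(self):
        """Step of 1 Z at 3.0 s across 20 units: departure in [2.1, 3.2] s.

        The corrected departure is asserted — the uncorrected p<0.05 crossing
        can fire spuriously in the ~20 overlapping pre-step windows.
        """
        local = np.random.default_rng(314)
        n_units, n_bins = 20, 100
        a = local.normal(0, 0.3, size=(n_units, n_bins))
        b = local.normal(0, 0.3, size=(n_units, n_bins))
        a[:, 30:] += 1.0
        res = pop.sliding_departure(a, b)
        assert res.departure_time_bonferroni is not None
        assert 2.1 <= res.departure_time_bonferroni <= 3.2
        assert res.departure_time_p05 <= res.departure_time_bonferroni

    def test_window_count_and_bonferroni_divisor(self, rng):
        a = rng.normal(size=(5, 100))
        b = rng.normal(size=(5, 100))
        res = pop.sliding_departure(a, b)
        assert res.n_windows == 91
        assert res.bonferroni_divisor == 91 * 2
        assert res.bonferroni_threshold == pytest.approx(0.05 / 182)
        override = pop.sliding_departure(a, b, bonferroni_divisor=200)
        assert override.bonferroni_threshold == pytest.approx(0.05 / 200)

    def test_bonferroni_departure_not_earlier_than_p05(self, rng):
        a = rng.normal(0, 0.5, size=(15, 100))
        b = rng.normal(0, 0.5, size=(15, 100))
        a[:, 50:] += np.linspace(0, 2, 50)
        res = pop.sliding_departure(a, b)
        if res.departure_time_bonferroni is not None:
            assert res.departure_time_bonferroni >= res.departure_time_p05

    def test_unit_order_invariance(self, rng):
        a = rng.normal(size=(12, 100)); a[:, 40:] += 0.8
        b = rng.normal(size=(12, 100))
        r1 = pop.sliding_departure(a, b)
        perm = rng.permutation(12)
        r2 = pop.sliding_departure(a[perm], b[perm])
        assert np.allclose(r1.pvalues, r2.pvalues)


class TestRateOfIncrease:
    def test_linear_ramp_recovers_slope(self):
        t = np.arange(100) * 0.1
        z = np.tile(0.7 * t, (3, 1))
        rate = pop.rate_of_increase(z, departure_time=2.0)
        assert rate == pytest.approx(0.7, abs=0.05)

    def test_equal_endpoints_give_zero(self):
        z = np.ones((2, 100))
        assert pop.rate_of_increase(z, departure_time=3.0) == 0.0

    def test_departure_at_last_window_flagged(self):
        z = np.ones((2, 100))
        assert np.isnan(pop.rate_of_increase(z, departure_time=9.0))
        assert np.isnan(pop.rate_of_increase(z, departure_time=None))


class TestPatterns:
    @pytest.mark.parametrize("vals, expected", [
        ((2.0, 1.0, 0.0), "d>u>s"),
        ((0.0, 1.0, 2.0), "s>u>d"),
        ((1.0, 2.0, 0.0), "u>d>s"),
        ((2.0, 0.0, 1.0), "d>s>u"),
    ])
    def test_strict_orderings(self, vals, expected):
        assert pop.categorize_pattern(*vals) == expected

    def test_tie_broken_deterministically(self):
        assert pop.categorize_pattern(1.0, 1.0, 0.0) == "d>u>s"
        assert pop.categorize_pattern(0.0, 1.0, 1.0) == "u>s>d"

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            pop.categorize_pattern(np.nan, 0.0, 1.0)

    def test_shuffle_null_median_is_uniform_over_orderings(self, rng):
        vals = rng.normal(size=(30, 3))
        res = pop.shuffle_pattern_null(vals, seed=0)
        for _, row in res.shuffle_summary.iterrows():
            assert abs(row["median"] - 30 / 6) <= 1.0

    def test_shuffle_null_deterministic_under_seed(self, rng):
        vals = rng.normal(size=(20, 3))
        a = pop.shuffle_pattern_null(vals, seed=3)
        b = pop.shuffle_pattern_null(vals, seed=3)
        assert a.shuffle_summary.equals(b.shuffle_summary)

    def test_planted_consistent_population_exceeds_chance(self, rng):
        vals = np.column_stack([
            rng.normal(2, 0.2, 30), rng.normal(1, 0.2, 30),
            rng.normal(0, 0.2, 30)])
        res = pop.shuffle_pattern_null(vals, seed=1)
        assert res.exceeds_chance["d>u>s"]
        assert not any(v for k, v in res.exceeds_chance.items() if k != "d>u>s")
        assert sum(res.observed.values()) == 30


class TestBiasTests:
    def test_perfect_identity_all_ties(self):
        x = np.arange(10.0)
        res = pop.bias_tests(x, x.copy())
        assert res["r_squared"] == pytest.approx(1.0)
        assert res["n_ties"] == 10
        assert np.isnan(res["p_sign"])

    def test_sign_test_matches_exact_binomial(self):
        """25 of 29 positive differences: p from the closed-form binomial sum."""
        rng = np.random.default_rng(0)
        y = rng.normal(size=29)
        x = y.copy()
        x[:25] += 1.0
        x[25:] -= 1.0
        res = pop.bias_tests(x, y)
        # independent oracle: two-tailed exact binomial tail sum
        from math import comb

        def exact_two_tailed(k, n):
            pmf = [comb(n, i) * 0.5**n for i in range(n + 1)]
            return sum(p for p in pmf if p <= pmf[k] + 1e-12)

        assert res["n_positive"] == 25
        assert res["p_sign"] == pytest.approx(exact_two_tailed(25, 29), rel=1e-9)

    def test_null_pairs_sign_test_calibrated(self, rng):
        """Independent pairs: P(p <= alpha) <= alpha (exact test is valid,
        and conservative because the binomial is discrete)."""
        ps = np.array([
            pop.bias_tests(rng.normal(size=21), rng.normal(size=21))["p_sign"]
            for _ in range(400)
        ])
        for alpha in (0.05, 0.1, 0.25):
            se = np.sqrt(alpha * (1 - alpha) / ps.size)
            assert (ps <= alpha).mean() <= alpha + 3 * se

    def test_zero_variance_correlation_flagged(self):
        res = pop.bias_tests(np.ones(5), np.arange(5.0))
        assert np.isnan(res["r_squared"])


class TestChiSquare:
    def test_equal_proportions_give_zero(self):
        res = pop.chisq_proportions(5, 10, 10, 20)
        assert res.statistic == pytest.approx(0.0)

    @pytest.mark.parametrize("k1, n1, k2, n2", [
        (13, 20, 4, 20), (6, 20, 1, 20), (7, 9, 2, 11),
    ])
    def test_matches_hand_computed_pearson(self, k1, n1, k2, n2):
        """Independent oracle: Pearson formula from expected counts."""
        obs = np.array([[k1, n1 - k1], [k2, n2 - k2]], float)
        row, col, n = obs.sum(1), obs.sum(0), obs.sum()
        expected = np.outer(row, col) / n
        chi2 = ((obs - expected) ** 2 / expected).sum()
        res = pop.chisq_proportions(k1, n1, k2, n2)
        assert res.statistic == pytest.approx(chi2, rel=1e-12)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            pop.chisq_proportions(0, 5, 0, 7)


class TestCessation:
    def test_continuous_poking_yields_empty_result(self, design, trials):
        span = synth.session_span_for(trials, design)
        dense = np.arange(0.0, span, 0.5)  # no 5 s gap anywhere
        from vlpag.session import BehaviorRecord

        session = Session(design=design, trials=trials,
                          behavior=BehaviorRecord(dense), units=[],
                          session_span=span)
        spec = synth.UnitSpec(profile="nonresponsive", baseline_rate=5.0)
        unit = synth.simulate_unit(trials, spec, 2, design=design)
        res = pop.poke_cessation_control(unit, session)
        assert res.gap_onsets.size == 0
        assert res.test is None

    def test_flat_unit_rarely_significant(self, design):
        """Null control: <=~5% of flat units show cessation-locked change."""
        rng = np.random.default_rng(10)
        spec = synth.UnitSpec(profile="nonresponsive", baseline_rate=8.0)
        n_sig = n_tested = 0
        for seed in range(40):
            trials = synth.make_trial_sequence(design, seed=seed, min_iti=15.0)
            span = synth.session_span_for(trials, design)
            beh = synth.simulate_pokes(trials, synth.BehaviorSpec(), seed + 400,
                                       design=design, session_span=span)
            session = Session(design=design, trials=trials, behavior=beh,
                              units=[], session_span=span)
            unit = synth.simulate_unit(trials, spec, rng, design=design,
                                       session_span=span)
            res = pop.poke_cessation_control(unit, session)
            if res.test is not None:
                n_tested += 1
                if res.test.pvalue < 0.05:
                    n_sig += 1
        assert n_tested >= 10  # gaps occur naturally at 1 poke/s
        assert n_sig / n_tested <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_tested)

    def test_planted_cessation_locked_unit_detected(self):
        """Unit whose rate drops whenever poking stops is flagged."""
        design = default_design(mean_iti=120.0)  # long ITIs: many natural gaps
        trials = synth.make_trial_sequence(design, seed=30, min_iti=20.0)
        span = synth.session_span_for(trials, design)
        beh = synth.simulate_pokes(trials, synth.BehaviorSpec(), 77,
                                   design=design, session_span=span)
        session = Session(design=design, trials=trials, behavior=beh,
                          units=[], session_span=span)
        probe = pop.poke_cessation_control(
            synth.simulate_unit(trials,
                                synth.UnitSpec(profile="nonresponsive",
                                               baseline_rate=5.0),
                                1, design=design, session_span=span),
            session)
        assert probe.gap_onsets.size >= 3
        # build a unit firing at 20 Hz except silent after each gap onset
        rng = np.random.default_rng(5)
        spikes = np.sort(rng.uniform(0, span, int(20 * span)))
        for onset in probe.gap_onsets:
            spikes = spikes[~((spikes >= onset) & (spikes < onset + 5.0))]
        from vlpag.session import UnitRecord, WaveformFeatures

        unit = UnitRecord("locked", spikes, WaveformFeatures(0.2, 0.0, 20.0))
        res = pop.poke_cessation_control(unit, session)
        assert res.test is not None and res.test.pvalue < 0.01
        assert res.post_rates.mean() < res.pre_rates.mean()
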