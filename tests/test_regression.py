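"""OLS contracts, the printed example, sweeps, post-cue fits, pairs analysis."""

import numpy as np
import pandas as pd
import pytest

from vlpag import normalize, regression as reg, suppression, synth
from vlpag.session import Session, default_design, load_worked_example


def _ols_oracle(X, y):
    """Independent normal-equations solver (explicit inverse, no library fit)."""
    XtX = X.T @ X
    return np.linalg.solve(XtX, X.T @ y)


class TestFitOLS:
    def test_worked_example_reproduces_printed_betas(self):
        betas = reg.fit_worked_example()
        assert round(betas.beta("interval_fear"), 2) == pytest.approx(0.24)
        assert round(betas.beta("total_fear"), 2) == pytest.approx(-0.14)
        assert round(betas.beta("probability"), 2) == pytest.approx(2.19)

    def test_constant_response_zeroes_slopes(self):
        df = load_worked_example().copy()
        df["z_firing"] = 1.0
        betas = reg.fit_ols(reg.matrix_from_frame(df))
        for name in ("interval_fear", "total_fear", "probability"):
            assert betas.beta(name) == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle_on_random_designs(self, rng):
        """1000 random full-rank designs agree with the oracle to 1e-9."""
        for _ in range(1000):
            n, k = 32, 4
            X = np.column_stack([np.ones(n), rng.normal(size=(n, k - 1))])
            y = rng.normal(size=n)
            frame = pd.DataFrame({
                "trial": np.arange(1, n + 1), "trial_type": "safety",
                "z_firing": y, "constant": 1.0,
                "interval_fear": X[:, 1], "total_fear": X[:, 2],
                "probability": X[:, 3],
            })
            betas = reg.fit_ols(reg.matrix_from_frame(frame))
            expect = _ols_oracle(X, y)
            assert np.allclose(betas.table["beta"].to_numpy(), expect, atol=1e-9)

    def test_rank_deficient_design_identifies_columns(self):
        df = load_worked_example().copy()
        df["interval_fear"] = df["probability"]  # collinear
        with pytest.raises(reg.RankError, match="interval_fear"):
            reg.matrix_from_frame(df)


class TestBuildRegressors:
    @pytest.fixture(scope="class")
    def unit_inputs(self, design, trials, measures, behavior_session):
        spec = synth.DEFAULT_PROFILES["onset"]
        unit = synth.simulate_unit(trials, spec, 42, design=design)
        z = normalize.interval_trial_z(unit, trials, (0.0, 1.0))
        return behavior_session, measures, z

    def test_rows_ordered_by_trial_type(self, unit_inputs):
        session, measures, z = unit_inputs
        m = reg.build_regressors(session, measures, z, interval=0)
        types = list(m.frame["trial_type"])
        order = ["danger", "uncertainty_shock", "uncertainty_omission", "safety"]
        assert types == sorted(types, key=order.index)
        assert len(m.frame) == 32
        assert (m.frame["constant"] == 1.0).all()

    def test_probability_column_tracks_u_assign(self, unit_inputs):
        session, measures, z = unit_inputs
        m = reg.build_regressors(session, measures, z, interval=0, u_assign=1.0)
        probs = m.frame.set_index("trial_type")["probability"]
        assert set(probs.loc[["uncertainty_shock", "uncertainty_omission"]]) == {1.0}
        assert set(probs.loc["danger"]) == {1.0}
        assert set(probs.loc["safety"]) == {0.0}

    def test_constant_behavior_raises_rank_error(self, unit_inputs, design):
        session, measures, z = unit_inputs
        import dataclasses

        flat = dataclasses.replace(
            measures,
            total=np.ones_like(measures.total),
            intervals=np.ones_like(measures.intervals),
        )
        with pytest.raises(reg.RankError):
            reg.build_regressors(session, flat, z, interval=0)


class TestIntervalSweep:
    @pytest.fixture(scope="class")
    def pure_probability_population(self, design, trials, measures,
                                    behavior_session):
        """Betas for 40 onset units whose firing tracks probability only."""
        rng = np.random.default_rng(7)
        frames = []
        for i in range(40):
            unit = synth.simulate_unit(trials, synth.DEFAULT_PROFILES["onset"],
                                       rng, design=design)
            z = {k: normalize.interval_trial_z(
                unit, trials, normalize.cue_interval_window(k, design))
                for k in range(10)}
            frames.append(reg.interval_sweep(behavior_session, measures, z,
                                             unit_id=f"u{i}"))
        return pd.concat(frames, ignore_index=True)

    def test_probability_dominates_first_interval(
            self, pure_probability_population):
        summary = reg.population_interval_summary(pure_probability_population)
        first = summary[summary["interval"] == 0].set_index("regressor")
        assert first.loc["probability", "significant"]
        assert first.loc["probability", "mean_beta"] > 0
        for fear in ("interval_fear", "total_fear"):
            assert abs(first.loc[fear, "mean_beta"]) < \
                first.loc["probability", "mean_beta"] / 3

    def test_fear_driven_population_prefers_fear(self, design, trials,
                                                 behavior_session, measures):
        """Units coupled to the latent fear state: fear beta > probability."""
        rng = np.random.default_rng(8)
        latent = synth.draw_trial_fear(trials, synth.BehaviorSpec(), 88)
        spec = synth.UnitSpec(profile="onset", baseline_rate=3.0,
                              probability_gain=0.0, fear_gain=12.0)
        betas = []
        for i in range(30):
            unit = synth.simulate_unit(trials, spec, rng, design=design,
                                       behavior=latent)
            z = normalize.interval_trial_z(unit, trials, (0.0, 1.0))
            b = reg.fit_ols(reg.build_regressors(behavior_session, measures, z,
                                                 interval=0))
            betas.append({"total_fear": b.beta("total_fear"),
                          "probability": b.beta("probability")})
        df = pd.DataFrame(betas)
        assert df["total_fear"].mean() > 0

    def test_noise_units_near_nominal_false_positive_rate(
            self, design, trials, behavior_session, measures):
        rng = np.random.default_rng(9)
        spec = synth.UnitSpec(profile="nonresponsive", baseline_rate=5.0)
        n_sig = n_tot = 0
        for i in range(40):
            unit = synth.simulate_unit(trials, spec, rng, design=design)
            z = {k: normalize.interval_trial_z(
                unit, trials, normalize.cue_interval_window(k, design))
                for k in range(10)}
            sweep = reg.interval_sweep(behavior_session, measures, z,
                                       unit_id=f"n{i}")
            probs = sweep[sweep["regressor"] == "probability"]
            n_sig += int((probs["p"] < 0.05).sum())
            n_tot += len(probs)
        rate = n_sig / n_tot
        se = np.sqrt(0.05 * 0.95 / n_tot)
        assert rate <= 0.05 + 3 * se

    def test_shuffling_response_destroys_significance(
            self, design, trials, behavior_session, measures):
        """Permutation sanity: shuffled z kills the probability beta."""
        rng = np.random.default_rng(10)
        n_sig = n_tot = 0
        for i in range(40):
            unit = synth.simulate_unit(trials, synth.DEFAULT_PROFILES["onset"],
                                       rng, design=design)
            z = normalize.interval_trial_z(unit, trials, (0.0, 1.0))
            rng.shuffle(z)
            b = reg.fit_ols(reg.build_regressors(behavior_session, measures, z,
                                                 interval=0))
            n_tot += 1
            n_sig += int(b.p("probability") < 0.05)
        assert n_sig / n_tot <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_tot)


class TestTuning:
    def test_curve_value_at_programmed_u_equals_base_fit(
            self, design, trials, behavior_session, measures):
        unit = synth.simulate_unit(trials, synth.DEFAULT_PROFILES["onset"], 55,
                                   design=design)
        z = normalize.interval_trial_z(unit, trials, (0.0, 1.0))
        base = reg.fit_ols(reg.build_regressors(behavior_session, measures, z,
                                                interval=0, u_assign=0.375))
        curve = reg.tuning_sweep(behavior_session, measures, {"u": z},
                                 interval=0)
        at_0375 = curve.mean_beta[list(curve.u_assign).index(0.375)]
        assert at_0375 == pytest.approx(base.beta("probability"), abs=1e-12)

    def test_grid_has_nine_points(self):
        assert len(reg.TUNING_GRID) == 9
        assert reg.TUNING_GRID[0] == 0.0 and reg.TUNING_GRID[-1] == 1.0
        assert np.allclose(np.diff(reg.TUNING_GRID), 0.125)

    def test_mixed_fear_probability_cohort_peaks_right_of_0375(self, design):
        """Ramping units carrying fear as well as probability: peak > 0.375.

        Units are pooled across sessions, as the recorded population is;
        pooling averages over per-session behavioral realizations, which
        otherwise dominate the flat top of the tuning curve.
        """
        builders = {}
        for k in range(10):
            session = synth.simulate_session(
                design, synth.BehaviorSpec(),
                [synth.DEFAULT_PROFILES["ramping"]] * 12, seed=1000 + k,
                min_iti=15.0)
            m = suppression.compute_suppression(session)
            for u in session.units:
                z = normalize.interval_trial_z(
                    u, session.trials, normalize.cue_interval_window(9, design))
                builders[f"s{k}/{u.unit_id}"] = (
                    lambda ua, _s=session, _m=m, _z=z: reg.build_regressors(
                        _s, _m, _z, 9, u_assign=ua))
        curve = reg.tuning_from_builders(builders)
        assert curve.peak > 0.375
        # the shift is an asymmetry: the right flank exceeds the left
        grid = list(curve.u_assign)
        assert curve.mean_beta[grid.index(0.5)] > curve.mean_beta[grid.index(0.25)]


class TestPostcue:
    @pytest.fixture(scope="class")
    def ramping_postcue(self, design):
        session = synth.simulate_session(
            design, synth.BehaviorSpec(),
            [synth.DEFAULT_PROFILES["ramping"]] * 30, seed=301, min_iti=15.0)
        m = suppression.compute_suppression(session)
        frames = []
        for u in session.units:
            z = {k: normalize.interval_trial_z(
                u, session.trials, normalize.postcue_interval_window(k, design))
                for k in reg.POSTCUE_INTERVALS}
            frames.append(reg.postcue_regression(session, m, z,
                                                 unit_id=u.unit_id))
        return pd.concat(frames, ignore_index=True)

    def test_nine_intervals_no_total_fear(self, ramping_postcue):
        assert sorted(ramping_postcue["interval"].unique()) == \
            list(reg.POSTCUE_INTERVALS)
        assert reg.SHOCK_INTERVAL not in set(ramping_postcue["interval"])
        assert "total_fear" not in set(ramping_postcue["regressor"])

    def test_ramping_probability_beta_delay_positive_postshock_flat(
            self, ramping_postcue):
        probs = ramping_postcue[ramping_postcue["regressor"] == "probability"]
        delay = probs[probs["interval"].isin(reg.DELAY_INTERVALS)]
        post = probs[probs["interval"].isin(reg.POSTSHOCK_INTERVALS)]
        delay_mean = delay.groupby("interval")["beta"].mean()
        assert (delay_mean > 0).all()
        assert delay["beta"].mean() > 3 * abs(post["beta"].mean())


class TestBetaCorrelation:
    def test_persistent_betas_give_unit_r_squared(self, rng):
        base = rng.normal(size=20)
        frame = pd.DataFrame({i: base for i in reg.POSTCUE_INTERVALS})
        mat = reg.beta_correlation_matrix(frame)
        assert np.allclose(mat.cross_block["r_squared"], 1.0)
        assert mat.n_significant_05 == 20

    def test_iid_betas_near_nominal_significance(self, rng):
        counts = []
        for _ in range(30):
            frame = pd.DataFrame({
                i: rng.normal(size=25) for i in reg.POSTCUE_INTERVALS})
            counts.append(reg.beta_correlation_matrix(frame).n_significant_05)
        rate = np.sum(counts) / (30 * 20)
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / (30 * 20))

    def test_matrix_symmetric(self, rng):
        frame = pd.DataFrame({
            i: rng.normal(size=15) for i in reg.POSTCUE_INTERVALS})
        mat = reg.beta_correlation_matrix(frame)
        assert np.allclose(mat.r_squared, mat.r_squared.T, equal_nan=True)


class TestPairs:
    def test_identical_series_give_unit_beta(self, rng):
        z = rng.normal(size=(32, 10))
        res = reg.pairs_regression(z, z.copy())
        assert np.allclose(res["beta"], 1.0)
        assert (res["p"] < 1e-12).all()
        assert not res["negative_significant"].any()

    def test_independent_pairs_rarely_negative_significant(self, rng):
        n_flag = n_tot = 0
        for _ in range(60):
            a = rng.normal(size=(32, 10))
            b = rng.normal(size=(32, 10))
            res = reg.pairs_regression(a, b)
            n_flag += int(res["negative_significant"].sum())
            n_tot += len(res)
        assert n_flag / n_tot <= 0.025 + 3 * np.sqrt(0.025 * 0.975 / n_tot)

    def test_anticorrelated_pair_flagged(self, rng):
        shared = rng.normal(size=(32, 10))
        onset = shared + 0.4 * rng.normal(size=(32, 10))
        ramping = -shared + 0.4 * rng.normal(size=(32, 10))
        res = reg.pairs_regression(onset, ramping)
        assert res["negative_significant"].mean() > 0.5
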