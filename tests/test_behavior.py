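"""Behavioral fitting: observer weights, psychometrics, eye traces, statistics."""

import numpy as np
import pandas as pd
import pytest

from pivotflow import behavior as B
from pivotflow import geometry as G
from pivotflow import synth as S
from pivotflow.observer import EyeCondition, GeometryCondition, ObserverParams


def make_observer(a_ret, a_eye, kappa=20.0, lapse=0.0, seed=0, g_pursuit=1.0):
    params = {
        (geom, eye): ObserverParams(
            g_ret=min(a_ret, 1.0), g_eye=1.0, a_ret=a_ret, a_eye=a_eye,
            g_pursuit=g_pursuit,
        )
        for geom in GeometryCondition
        for eye in EyeCondition
    }
    return S.SyntheticObserverSpec(
        params=params, report_noise_kappa=kappa, lapse=lapse, seed=seed,
        participant_id="t000",
    )


def one_condition_trials(a_ret, a_eye, kappa=20.0, reps=7, seed=0):
    design = S.ExperimentDesign.exp1(
        reps=reps, conditions=((GeometryCondition.RT, EyeCondition.FIXATION),)
    )
    obs = make_observer(a_ret, a_eye, kappa=kappa, seed=seed)
    return S.generate_trials(design, obs)


class TestFitLinearObserver:
    def test_identity_observer_recovers_zero_weights(self):
        trials = one_condition_trials(0.0, 0.0, kappa=2000.0, seed=1)
        fit = B.fit_linear_observer(trials, alpha_grid=[1e-4], bootstrap_n=0, seed=0)
        assert fit.a_ret == pytest.approx(0.0, abs=0.05)
        assert fit.a_eye == pytest.approx(0.0, abs=0.05)

    def test_full_coordinate_transform_observer(self):
        # a coordinate-transforming observer should show a_ret ~ 0, a_eye ~ 1
        trials = one_condition_trials(0.0, 1.0, kappa=2000.0, seed=2)
        fit = B.fit_linear_observer(trials, alpha_grid=[1e-4], bootstrap_n=0, seed=0)
        assert fit.a_ret == pytest.approx(0.0, abs=0.05)
        assert fit.a_eye == pytest.approx(1.0, abs=0.05)

    def test_weights_respect_unit_interval(self):
        trials = one_condition_trials(0.9, 0.1, kappa=5.0, seed=3)
        fit = B.fit_linear_observer(trials, alpha_grid=[1e-2], bootstrap_n=0, seed=0)
        assert 0.0 <= fit.a_ret <= 1.0
        assert 0.0 <= fit.a_eye <= 1.0

    def test_recovery_with_report_noise(self):
        errs = []
        for seed in range(5):
            trials = one_condition_trials(0.8, 0.1, kappa=20.0, seed=seed)
            fit = B.fit_linear_observer(trials, alpha_grid=[1e-4], bootstrap_n=0, seed=seed)
            errs.append(max(abs(fit.a_ret - 0.8), abs(fit.a_eye - 0.1)))
        assert np.median(errs) < 0.1

    def test_slip_correction_restores_weights(self):
        # generator applies physical slip with gain 0.7; fitting with the
        # measured gain should recover the intended weights
        design = S.ExperimentDesign.exp1(
            reps=7, conditions=((GeometryCondition.RT, EyeCondition.PURSUIT),)
        )
        obs = make_observer(0.5, 0.2, kappa=2000.0, seed=4, g_pursuit=0.7)
        trials = S.generate_trials(design, obs)
        fit = B.fit_linear_observer(
            trials, g_pursuit=0.7, alpha_grid=[1e-4], bootstrap_n=0, seed=0
        )
        assert fit.a_ret == pytest.approx(0.5, abs=0.06)
        assert fit.a_eye == pytest.approx(0.2, abs=0.06)

    def test_underdetermined_design_rejected(self):
        trials = one_condition_trials(0.2, 0.2, seed=5)
        single = trials[trials["retinal_dir_deg"] == 0.0]
        with pytest.raises(B.UnderdeterminedFitError):
            B.fit_linear_observer(single, alpha_grid=[1e-4], bootstrap_n=0)

    def test_bootstrap_ci_brackets_estimate(self):
        trials = one_condition_trials(0.4, 0.3, kappa=20.0, seed=6)
        fit = B.fit_linear_observer(trials, alpha_grid=[1e-4], bootstrap_n=30, seed=1)
        lo, hi = fit.a_ret_ci
        assert lo <= fit.a_ret <= hi


class TestFitPsychometric:
    @staticmethod
    def simulate(m, w, lam, gam, n_per_level, rng, levels=None):
        if levels is None:
            levels = np.arange(-90.0, 91.0, 15.0)
        x = np.repeat(levels, n_per_level)
        p = B.psychometric_function(x, m, w, lam, gam)
        return x, (rng.random(len(x)) < p).astype(float)

    def test_standardized_width_constant(self):
        assert B.PSYCH_C == pytest.approx(3.2897, abs=1e-4)

    def test_midpoint_property(self):
        val = B.psychometric_function(10.0, 10.0, 30.0, 0.04, 0.02)
        assert val == pytest.approx(0.02 + (1 - 0.04 - 0.02) / 2)

    def test_parameter_recovery(self, rng):
        ms, ws = [], []
        for _ in range(20):
            x, y = self.simulate(10.0, 30.0, 0.02, 0.02, 20, rng)
            fit = B.fit_psychometric(x, y)
            ms.append(fit.mean_m)
            ws.append(fit.width_w)
        assert abs(np.median(ms) - 10.0) < 5.0
        assert abs(np.median(ws) - 30.0) / 30.0 < 0.2

    def test_descending_function_gets_negative_slope(self, rng):
        x, y = self.simulate(0.0, 30.0, 0.02, 0.02, 20, rng)
        fit_up = B.fit_psychometric(x, y)
        fit_down = B.fit_psychometric(x, 1.0 - y)
        assert fit_up.slope > 0 > fit_down.slope
        assert abs(fit_up.slope) == pytest.approx(abs(fit_down.slope), rel=1e-6)

    def test_all_identical_responses_flagged(self):
        x = np.repeat(np.arange(-30.0, 31.0, 15.0), 5)
        with pytest.warns(UserWarning):
            fit = B.fit_psychometric(x, np.ones(len(x)))
        assert fit.boundary_flag
        assert fit.slope == 0.0

    def test_needs_three_levels(self):
        with pytest.raises(ValueError):
            B.fit_psychometric([0.0, 1.0] * 10, [0, 1] * 10)

    def test_bootstrap_ci(self, rng):
        x, y = self.simulate(0.0, 40.0, 0.02, 0.02, 20, rng)
        fit = B.fit_psychometric(x, y, bootstrap_n=30, seed=0)
        lo, hi = fit.ci["slope"]
        assert lo < hi


class TestPursuitGain:
    def test_perfect_tracking_gain_one(self):
        traces, profile = S.generate_eye_traces(
            n_trials=5, g_pursuit_true=1.0, noise_sd=0.0, saccade_rate=0.0, seed=0
        )
        assert B.compute_pursuit_gain(traces, profile) == pytest.approx(1.0, abs=1e-3)

    @pytest.mark.parametrize("gain", [0.7, 0.85, 1.0])
    def test_scaled_tracking_recovers_gain(self, gain):
        traces, profile = S.generate_eye_traces(
            n_trials=5, g_pursuit_true=gain, noise_sd=0.0, saccade_rate=0.0, seed=1
        )
        assert B.compute_pursuit_gain(traces, profile) == pytest.approx(gain, abs=0.01)

    def test_robust_to_catchup_saccades(self):
        traces, profile = S.generate_eye_traces(
            n_trials=20, g_pursuit_true=0.8, noise_sd=0.05, saccade_rate=1.5, seed=2
        )
        assert B.compute_pursuit_gain(traces, profile) == pytest.approx(0.8, abs=0.03)

    def test_invariant_to_position_offset(self):
        traces, profile = S.generate_eye_traces(
            n_trials=5, g_pursuit_true=0.9, noise_sd=0.0, saccade_rate=0.0, seed=3
        )
        g0 = B.compute_pursuit_gain(traces, profile)
        for tr in traces:
            tr.gaze_x = tr.gaze_x + 3.7
        assert B.compute_pursuit_gain(traces, profile) == pytest.approx(g0, abs=1e-9)

    def test_all_samples_removed_raises(self):
        traces, profile = S.generate_eye_traces(
            n_trials=2, g_pursuit_true=1.0, noise_sd=0.0, seed=4
        )
        fast = [
            B.EyeTrace(
                time=tr.time, gaze_x=np.linspace(0, 100, len(tr.time)),
                gaze_y=tr.gaze_y, target_x=tr.target_x, sample_rate=tr.sample_rate,
            )
            for tr in traces
        ]
        with pytest.raises(B.NoPursuitDataError):
            B.compute_pursuit_gain(fast, profile)


class TestFixationCheck:
    @staticmethod
    def trace(gaze_x, rate=1000.0):
        n = len(gaze_x)
        return B.EyeTrace(
            time=np.arange(n) / rate, gaze_x=np.asarray(gaze_x, float),
            gaze_y=np.zeros(n), target_x=np.zeros(n), sample_rate=rate,
        )

    def test_steady_fixation_passes(self):
        assert B.fixation_check(self.trace(np.zeros(500)))

    def test_long_excursion_fails(self):
        g = np.zeros(500)
        g[200:350] = 8.0  # 150 ms at +8 deg
        assert not B.fixation_check(self.trace(g), window_half_width=5.0)

    def test_short_excursion_tolerated(self):
        g = np.zeros(500)
        g[200:250] = 8.0  # 50 ms
        assert B.fixation_check(self.trace(g), window_half_width=5.0, max_violation_ms=100.0)


class TestFoldAndPool:
    @staticmethod
    def table(direction, report, eye_dir):
        return pd.DataFrame(
            {
                "participant": ["p"], "experiment": ["Exp1"], "geometry": ["R"],
                "eye_condition": ["Fixation"], "eye_dir": [eye_dir],
                "retinal_dir_deg": [direction], "retinal_speed_deg_s": [2.67],
                "eye_speed_deg_s": [5.3], "report_dir_deg": [report],
                "depth_report": [None], "valid": [True],
            }
        )

    def test_lower_hemifield_reflected(self):
        out = B.fold_and_pool(self.table(120.0, 120.0, -1.0))
        assert out["retinal_dir_deg"].iloc[0] == pytest.approx(60.0)
        assert out["report_dir_deg"].iloc[0] == pytest.approx(60.0)

    def test_rightward_eye_mirrored(self):
        out = B.fold_and_pool(self.table(30.0, 30.0, 1.0))
        assert out["retinal_dir_deg"].iloc[0] == pytest.approx(-30.0)
        assert out["report_dir_deg"].iloc[0] == pytest.approx(-30.0)
        assert out["eye_dir"].iloc[0] == -1.0

    def test_idempotent_on_folded_set(self):
        once = B.fold_and_pool(self.table(200.0, 210.0, 1.0))
        twice = B.fold_and_pool(once)
        pd.testing.assert_frame_equal(once, twice)


class TestGroupStats:
    def test_identical_pairs(self):
        res = B.group_stats([1.0, 2.0, 3.0, 4.0, 5.0], [1.0, 2.0, 3.0, 4.0, 5.0])
        assert res["p"] == 1.0
        assert res["hodges_lehmann_estimate"] == 0.0

    def test_constant_shift_recovered(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        res = B.group_stats(a + 0.4, a)
        assert res["hodges_lehmann_estimate"] == pytest.approx(0.4)
        assert res["wilcoxon_Z"] > 0

    def test_matches_reference_implementation(self):
        # fixture cross-checked against scipy.stats.wilcoxon (method="approx")
        a = np.array([2.1, 3.3, 1.8, 4.0, 5.2, 2.9, 3.7, 4.4])
        b = np.array([1.5, 2.8, 2.0, 3.1, 4.0, 2.2, 3.0, 4.9])
        from scipy import stats as sps

        res = B.group_stats(a, b)
        ref = sps.wilcoxon(a, b, method="approx")
        assert res["p"] == pytest.approx(ref.pvalue)
        assert abs(res["wilcoxon_Z"]) == pytest.approx(
            abs(sps.norm.ppf(ref.pvalue / 2.0)), abs=1e-6
        )
        assert res["effect_r"] == pytest.approx(res["wilcoxon_Z"] / np.sqrt(8))

    def test_hodges_lehmann_ci_covers_estimate(self, rng):
        d = rng.normal(0.5, 1.0, 12)
        est, (lo, hi) = B.hodges_lehmann(d)
        assert lo <= est <= hi

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            B.group_stats([1.0, 2.0], [0.0, 1.0])


class TestPermutationTest:
    @staticmethod
    def depth_table(slope_sign, n_per_level, rng, noise_w=40.0):
        levels = np.arange(-90.0, 91.0, 15.0)
        x = np.repeat(levels, n_per_level)
        p = B.psychometric_function(x * slope_sign, 0.0, noise_w, 0.02, 0.02)
        y = rng.random(len(x)) < p
        return pd.DataFrame(
            {
                "participant": "p", "experiment": "Exp2", "geometry": "RT",
                "eye_condition": "Fixation", "eye_dir": -1.0,
                "retinal_dir_deg": x, "retinal_speed_deg_s": 2.67,
                "eye_speed_deg_s": 5.3, "report_dir_deg": np.nan,
                "depth_report": np.where(y, "far", "near"), "valid": True,
            }
        )

    def test_separated_conditions_detected(self, rng):
        steep = self.depth_table(1.0, 20, rng, noise_w=30.0)
        flat = self.depth_table(0.02, 20, rng, noise_w=500.0)
        p = B.participant_permutation_test(steep, flat, n_perm=200, seed=0)
        assert p < 0.05

    def test_null_calibration(self, rng):
        a = self.depth_table(1.0, 10, rng)
        b = self.depth_table(1.0, 10, rng)
        p = B.participant_permutation_test(a, b, n_perm=200, seed=1)
        assert p > 0.05
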