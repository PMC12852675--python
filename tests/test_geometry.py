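"""Equation engine, velocity profiles, and the projection flow simulator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pivotflow import geometry as G

finite = st.floats(-50, 50, allow_nan=False, allow_infinity=False)


class TestObjectWorldMotion:
    @pytest.mark.parametrize(
        "omega_ret, omega_eye, dprime, pprime, expected",
        [
            # p'=0: coordinate transformation, depth drops out
            ((3.0, 4.0), -3.0, 0.7, 0.0, (0.0, 4.0)),
            ((3.0, 4.0), -3.0, -0.7, 0.0, (0.0, 4.0)),
            # p'=1, stationary object at d' = w_ret/w_eye
            ((2.0, 0.0), 4.0, 0.5, 1.0, (0.0, 0.0)),
            # coefficient 1 - (1+1)(0.5) = 0
            ((2.0, 1.0), 4.0, 1.0, 0.5, (2.0, 1.0)),
        ],
    )
    def test_examples(self, omega_ret, omega_eye, dprime, pprime, expected):
        out = G.object_world_motion(omega_ret, omega_eye, dprime, pprime)
        assert out == pytest.approx(expected, abs=1e-12)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            G.object_world_motion((np.nan, 0.0), 1.0, 0.0, 0.0)

    @given(ret_x=finite, ret_y=finite, eye=finite, dp=st.floats(-0.9, 0.9))
    @settings(max_examples=200, deadline=None)
    def test_pure_rotation_reduces_to_vector_addition(self, ret_x, ret_y, eye, dp):
        out = G.object_world_motion((ret_x, ret_y), eye, dp, 0.0)
        assert out[0] == pytest.approx(ret_x + eye, abs=1e-9)
        assert out[1] == ret_y

    @given(
        obj_x=finite, obj_y=finite, eye=finite,
        dp=st.floats(-0.9, 0.9), pp=st.floats(0.0, 1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_round_trip_world_to_retina_and_back(self, obj_x, obj_y, eye, dp, pp):
        ret = G.retinal_from_world((obj_x, obj_y), eye, dp, pp)
        back = G.object_world_motion(ret, eye, dp, pp)
        assert back == pytest.approx((obj_x, obj_y), abs=1e-9)


class TestDepthFromParallax:
    @pytest.mark.parametrize(
        "ret, obj, eye, expected",
        [(2.0, 0.0, 4.0, 0.5), (2.0, 2.0, 4.0, 0.0), (-3.0, 1.0, 8.0, -0.5)],
    )
    def test_examples(self, ret, obj, eye, expected):
        assert G.depth_from_parallax(ret, obj, eye) == pytest.approx(expected)

    def test_zero_eye_velocity_is_undefined(self):
        with pytest.raises(G.UndefinedDepthError):
            G.depth_from_parallax(2.0, 0.0, 0.0)

    @given(dp=st.floats(-0.9, 0.9), eye=st.floats(0.5, 20))
    @settings(max_examples=100, deadline=None)
    def test_inverts_fixation_pivot_flow(self, dp, eye):
        # stationary object at the fixation pivot: retinal motion d' * w_eye
        ret = G.retinal_from_world((0.0, 0.0), eye, dp, 1.0)
        assert G.depth_from_parallax(ret[0], 0.0, eye) == pytest.approx(dp, abs=1e-9)


class TestStationaryDotFlow:
    def test_rotational_flow_is_depth_invariant(self):
        for dp in (-0.8, -0.1, 0.0, 0.4, 0.9):
            assert G.stationary_dot_flow(dp, 0.0, 5.0) == pytest.approx(-5.0)

    def test_fixation_pivot_near_far_opposite(self):
        assert G.stationary_dot_flow(-0.5, 1.0, 5.0) == pytest.approx(-2.5)
        assert G.stationary_dot_flow(+0.5, 1.0, 5.0) == pytest.approx(+2.5)

    def test_intermediate_pivot(self):
        # coefficient 1 - 1.25 * 0.5 = 0.375 -> flow -0.375 * 8
        assert G.stationary_dot_flow(0.25, 0.5, 8.0) == pytest.approx(-3.0)


class TestVelocityProfile:
    def test_mean_speed_is_displacement_over_duration(self):
        p = G.gaussian_velocity_profile(2.67, 1.0, 60.0)
        assert p.mean_speed == pytest.approx(2.67)
        assert np.mean(p.velocity_samples) == pytest.approx(2.67, rel=1e-9)

    def test_zero_displacement_gives_zero_profile(self):
        p = G.gaussian_velocity_profile(0.0, 1.0, 60.0)
        assert np.all(p.velocity_samples == 0.0)

    def test_peak_speed_from_truncated_gaussian(self):
        # D * 6 / (erf(3/sqrt(2)) * sqrt(2 pi) * T) for D=2.67, T=1
        p = G.gaussian_velocity_profile(2.67, 1.0, 600.0)
        assert p.peak_speed == pytest.approx(6.41, abs=0.01)

    @pytest.mark.parametrize("D,T,rate", [(2.67, 1.0, 60.0), (5.3, 1.0, 1000.0), (-3.0, 0.5, 120.0)])
    def test_integral_conservation_and_symmetry(self, D, T, rate):
        p = G.gaussian_velocity_profile(D, T, rate)
        assert p.position()[-1] == pytest.approx(D, rel=1e-9)
        assert np.allclose(p.velocity_samples, p.velocity_samples[::-1])

    def test_invalid_duration(self):
        with pytest.raises(ValueError):
            G.gaussian_velocity_profile(1.0, -1.0, 60.0)


class TestViewingGeometry:
    def test_pprime_normalization(self):
        g = G.ViewingGeometry.from_pprime(0.5, 4.0, viewing_distance_f=60.0)
        assert g.pivot_p == pytest.approx(30.0)
        assert g.pivot_norm_pprime == pytest.approx(0.5)

    def test_component_split_must_sum(self):
        with pytest.raises(ValueError):
            G.ViewingGeometry(
                viewing_distance_f=57.0, pivot_p=0.0, eye_rotation_omega_eye=5.0,
                eye_translation_component_omegaT=1.0, pursuit_component_omegaP=1.0,
            )

    def test_scene_object_normalized_depth(self):
        obj = G.SceneObject(depth_d=-28.5, viewing_distance_f=57.0)
        assert obj.depth_norm_dprime == pytest.approx(-0.5)


class TestFlowSimulator:
    def test_pure_rotation_flow_is_uniform(self):
        geom = G.ViewingGeometry.pure_rotation(5.0)
        ff = G.simulate_flow_field(geom, n_dots=300, seed=0, field_deg=(4, 4))
        assert np.allclose(ff.image_velocities[:, 0], -5.0, atol=1e-6)

    def test_fixation_pivot_zero_at_fixation_and_opposite_signs(self):
        geom = G.ViewingGeometry.rotation_translation(5.0)
        ff = G.simulate_flow_field(
            geom, n_dots=3000, seed=0, field_deg=(6, 6), depth_range=(-20, 20)
        )
        z = ff.dot_positions[:, 2]
        at_fixation = np.abs(z - 57.0) < 0.5
        assert np.all(np.abs(ff.image_velocities[at_fixation, 0]) < 0.1)
        near, far = z < 47.0, z > 67.0
        vx = ff.image_velocities[:, 0]
        assert np.sign(vx[near].mean()) == -np.sign(vx[far].mean())

    @pytest.mark.parametrize("pprime", [0.0, 0.3, 0.7, 1.0])
    def test_matches_linear_engine_at_small_eccentricity(self, pprime):
        geom = G.ViewingGeometry.from_pprime(pprime, 5.0)
        ff = G.simulate_flow_field(
            geom, n_dots=3000, seed=2, field_deg=(20, 20), depth_range=(-14, 24)
        )
        dprime = G.equation_depth(ff.dot_positions, 57.0)
        pred = G.stationary_dot_flow(dprime, pprime, 5.0)
        ecc = np.hypot(*ff.image_positions.T)
        sel = (ecc < 10.0) & (np.abs(dprime) < 0.3)
        err = ff.image_velocities[sel, 0] - pred[sel]
        rel = np.linalg.norm(err) / np.linalg.norm(pred[sel])
        assert rel < 0.05

    def test_object_mask_removes_dots(self):
        geom = G.ViewingGeometry.pure_rotation(5.0)
        ff = G.simulate_flow_field(
            geom, n_dots=2000, seed=3, object_mask=((10.0, 0.0), 2.5)
        )
        dist = np.hypot(ff.image_positions[:, 0] - 10.0, ff.image_positions[:, 1])
        assert np.all(dist > 5.0)

    def test_seed_reproducibility(self):
        geom = G.ViewingGeometry.rotation_translation(5.0)
        a = G.simulate_flow_field(geom, n_dots=50, seed=7)
        b = G.simulate_flow_field(geom, n_dots=50, seed=7)
        assert np.array_equal(a.image_velocities, b.image_velocities)

    def test_csv_export_schema(self, tmp_path):
        geom = G.ViewingGeometry.pure_rotation(5.0)
        ff = G.simulate_flow_field(geom, n_dots=20, seed=0)
        df = ff.to_dataframe()
        assert list(df.columns) == [
            "dot_id", "x_deg", "y_deg", "vx_deg_s", "vy_deg_s", "depth_cm"
        ]
        assert len(df) == len(ff)


def test_field_of_view_of_study_display():
    h, v = G.field_of_view(105.2, 59.2, 57.0)
    assert h == pytest.approx(85.0, abs=1.0)
    assert v == pytest.approx(55.0, abs=1.0)


def test_direction_convention_up_zero_clockwise():
    assert G.velocity_to_direction(0.0, 1.0) == pytest.approx(0.0)
    assert G.velocity_to_direction(1.0, 0.0) == pytest.approx(90.0)
    v = G.direction_to_velocity(45.0, np.sqrt(2.0))
    assert v == pytest.approx([1.0, 1.0])
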