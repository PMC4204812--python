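"""Rigid-transform construction, total displacement, sweeps, sign discordance."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import motionqc as mq
from motionqc.kinematics import fibonacci_sphere

from conftest import pure_rotation_params, pure_translation_params


class TestParamsToTransform:
    def test_identity(self):
        m = mq.params_to_transform(np.zeros(6))
        assert np.allclose(m.matrix, np.eye(4))

    def test_pure_translation(self):
        m = mq.params_to_transform([3, 0, 0, 0, 0, 0])
        assert np.allclose(m.matrix[:, 3], [3, 0, 0, 1])
        assert np.allclose(m.rotation, np.eye(3))

    def test_quarter_turn_about_z_moves_x_to_y(self):
        m = mq.params_to_transform([0, 0, 0, 0, 0, np.pi / 2])
        assert np.allclose(m.apply([1.0, 0.0, 0.0]), [0.0, 1.0, 0.0], atol=1e-12)

    def test_non_finite_rejected(self):
        with pytest.raises(mq.InvalidParameterError):
            mq.params_to_transform([np.nan, 0, 0, 0, 0, 0])

    @given(st.lists(st.floats(-2, 2), min_size=6, max_size=6))
    def test_orthonormality_and_roundtrip(self, row):
        row = np.asarray(row)
        row[3:] = np.clip(row[3:], -1.2, 1.2)  # below gimbal lock
        m = mq.params_to_transform(row)
        r = m.rotation
        assert np.allclose(r @ r.T, np.eye(3), atol=1e-9)
        assert np.isclose(np.linalg.det(r), 1.0, atol=1e-9)
        assert np.allclose(mq.transform_to_params(m), row, atol=1e-9)


class TestReduceParams:
    def test_reductions_zero_the_complement(self):
        p = mq.RealignmentParams([[1, 2, 3, 0.01, 0.02, 0.03]])
        to = mq.reduce_params(p, "translation_only")
        ro = mq.reduce_params(p, "rotation_only")
        assert np.allclose(to.values, [[1, 2, 3, 0, 0, 0]])
        assert np.allclose(ro.values, [[0, 0, 0, 0.01, 0.02, 0.03]])
        # original untouched
        assert np.allclose(p.values, [[1, 2, 3, 0.01, 0.02, 0.03]])

    def test_zero_fixed_point(self):
        p = mq.RealignmentParams(np.zeros((3, 6)))
        for mode in ("translation_only", "rotation_only"):
            assert np.allclose(mq.reduce_params(p, mode).values, 0.0)

    def test_unknown_mode_rejected(self):
        p = mq.RealignmentParams(np.zeros((2, 6)))
        with pytest.raises(mq.InvalidParameterError):
            mq.reduce_params(p, "rotations_only")


class TestDisplacementSeries:
    @pytest.mark.parametrize("method", mq.kinematics.DISPLACEMENT_METHODS)
    @pytest.mark.parametrize("mode", ["absolute", "relative"])
    def test_zero_motion_fixed_point(self, method, mode):
        p = mq.RealignmentParams(np.zeros((5, 6)))
        s = mq.displacement_series(p, 65.0, mode=mode, method=method)
        assert np.allclose(s.values, 0.0)

    def test_pythagoras_translation_only_row(self):
        p = mq.RealignmentParams([[3.0, 4.0, 0, 0, 0, 0]])
        s = mq.displacement_series(p, 65.0, "absolute", "fig1_vector_sum")
        assert np.isclose(s.values[0], 5.0)

    def test_pure_rotation_row_scales_with_lever_arm(self):
        p = mq.RealignmentParams([[0, 0, 0, 0, 0, 0.01]])
        s = mq.displacement_series(p, 65.0, "absolute", "fig1_vector_sum")
        assert np.isclose(s.values[0], 0.65)

    @pytest.mark.parametrize("method", mq.kinematics.DISPLACEMENT_METHODS)
    def test_translation_invariant_to_lever_arm(self, method):
        p = pure_translation_params(t=12)
        a = mq.displacement_series(p, 50.0, method=method).values
        b = mq.displacement_series(p, 80.0, method=method).values
        assert np.allclose(a, b, atol=1e-12)

    def test_sphere_mean_matches_dense_monte_carlo_oracle(self, rng):
        """Quasi-uniform sphere sampling agrees with a 1e5-point MC oracle."""
        pts = rng.standard_normal((100_000, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        rows = np.hstack([
            rng.normal(0, 1.0, (20, 3)), rng.normal(0, 0.02, (20, 3))
        ])
        d = 65.0
        p = mq.RealignmentParams(rows)
        got = mq.displacement_series(p, d, "absolute", "sphere_mean").values
        for t, row in enumerate(rows):
            m = mq.params_to_transform(row)
            oracle = np.mean(np.linalg.norm(m.apply(d * pts) - d * pts, axis=1))
            assert got[t] == pytest.approx(oracle, rel=5e-3)

    @pytest.mark.parametrize("axis", [3, 4, 5])
    @pytest.mark.parametrize("phi", [0.005, 0.02, 0.05])
    def test_small_angle_closed_form(self, axis, phi):
        """Pure single-axis rotation: mean sphere displacement is
        (pi/4) * 2 * d * sin(phi/2) (mean of sin(inclination) over the sphere
        is pi/4)."""
        row = np.zeros(6)
        row[axis] = phi
        p = mq.RealignmentParams([row])
        d = 65.0
        got = mq.displacement_series(p, d, "absolute", "sphere_mean").values[0]
        expected = (np.pi / 4.0) * 2.0 * d * np.sin(phi / 2.0)
        assert got == pytest.approx(expected, rel=1e-2)

    def test_reduction_can_exceed_complete(self):
        """Opposing rotation shrinks the combined displacement below the
        translation-only value (non-additivity, >100% datapoints)."""
        p = mq.RealignmentParams([[1.0, 0, 0, -1.5 / 65.0, 0, 0]])
        td_complete = mq.displacement_series(p, 65.0).values[0]
        td_to = mq.displacement_series(p, 65.0, parameter_set="translation_only").values[0]
        assert td_to > td_complete

    def test_relative_of_constant_trajectory_is_zero(self):
        p = mq.RealignmentParams(np.tile([1, 2, 3, 0.01, 0.02, 0.03], (6, 1)))
        s = mq.displacement_series(p, 65.0, mode="relative")
        assert np.allclose(s.values, 0.0)

    def test_relative_transform_composition_variant_close_to_differencing(self):
        # conventions agree to second order while rotations stay small
        rng = np.random.default_rng(3)
        vals = np.vstack([
            np.zeros(6),
            np.cumsum(np.hstack([rng.normal(0, 0.05, (40, 3)),
                                 rng.normal(0, 5e-4, (40, 3))]), axis=0),
        ])
        p = mq.RealignmentParams(vals)
        a = mq.displacement_series(p, mode="relative").values
        b = mq.displacement_series(p, mode="relative",
                                   relative_via_transforms=True).values
        assert np.allclose(a, b, atol=5e-3)

    def test_invalid_inputs(self, drifting_params):
        with pytest.raises(mq.MotionQCError):
            mq.displacement_series(drifting_params, d_avg=0.0)
        with pytest.raises(mq.InvalidParameterError):
            mq.displacement_series(drifting_params, mode="sideways")


class TestSensitivitySweep:
    def test_pure_translation_flat_at_100(self):
        sweep = mq.davg_sensitivity_sweep(pure_translation_params(t=30))
        assert len(sweep) == 61
        assert np.allclose(sweep["percent_absolute"], 100.0)
        assert np.allclose(sweep["percent_relative"], 100.0)

    def test_pure_rotation_linear_in_lever_arm(self):
        sweep = mq.davg_sensitivity_sweep(pure_rotation_params(t=30))
        at60 = sweep.loc[np.isclose(sweep["d_avg"], 60.0)].iloc[0]
        assert at60["percent_absolute"] == pytest.approx(100.0 * 60 / 65, abs=1e-9)
        assert np.allclose(
            sweep["percent_absolute"], 100.0 * sweep["d_avg"] / 65.0, atol=1e-9
        )

    def test_reference_row_is_exactly_100(self, drifting_params):
        sweep = mq.davg_sensitivity_sweep(drifting_params)
        ref = sweep.loc[np.isclose(sweep["d_avg"], 65.0)].iloc[0]
        assert ref["percent_absolute"] == 100.0
        assert ref["percent_relative"] == 100.0

    def test_matches_direct_recomputation(self, drifting_params):
        sweep = mq.davg_sensitivity_sweep(
            drifting_params, d_min=60, d_max=70, step=2.5, d_ref=65
        )
        ref = np.median(mq.displacement_series(drifting_params, 65.0).values)
        for _, row in sweep.iterrows():
            med = np.median(
                mq.displacement_series(drifting_params, row["d_avg"]).values
            )
            assert row["percent_absolute"] == pytest.approx(100.0 * med / ref)

    def test_degenerate_range_rejected(self, drifting_params):
        with pytest.raises(mq.MotionQCError):
            mq.davg_sensitivity_sweep(drifting_params, d_min=66, d_max=80)


class TestSignDiscordance:
    def test_concordant_rows(self):
        p = mq.RealignmentParams(np.tile([1, 1, 1, 0.1, 0.1, 0.1], (7, 1)))
        assert mq.sign_discordance(p).per_axis == (0, 0, 0)

    def test_constructed_discordance(self):
        p = mq.RealignmentParams(np.tile([1, 1, 1, -0.1, 0.1, -0.1], (7, 1)))
        assert mq.sign_discordance(p).per_axis == (7, 0, 7)

    def test_zeros_count_as_concordant(self):
        p = mq.RealignmentParams([[0, 1, -1, 0.1, 0.0, 0.0]])
        assert mq.sign_discordance(p).per_axis == (0, 0, 0)

    def test_independent_coin_flips_near_half(self, rng):
        t = 10_000
        signs = rng.choice((-1.0, 1.0), size=(t, 6))
        p = mq.RealignmentParams(signs)
        counts = mq.sign_discordance(p).per_axis
        sigma = np.sqrt(t * 0.25)
        for c in counts:
            assert abs(c - t / 2) < 3 * sigma


def test_fibonacci_sphere_is_unit_and_balanced():
    pts = fibonacci_sphere(500)
    assert np.allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
    assert np.allclose(pts.mean(axis=0), 0.0, atol=5e-3)
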