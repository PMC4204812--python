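"""Phantom replay, ROI derivation, signal-change scoring and fingerprints."""

import numpy as np
import pytest

import motionqc as mq
from motionqc.phantom import FmriSeries, fingerprint_traces
from motionqc.synth import simulate_fmri


def _series_from_volume(data, t, affine=None):
    stack = np.repeat(data[..., None], t, axis=3)
    return FmriSeries(stack, np.eye(4) if affine is None else affine)


class TestBuildPhantom:
    def test_zero_motion_is_identity(self, small_brain):
        brain, _, _ = small_brain
        series = _series_from_volume(brain.data, 4, brain.affine)
        params = mq.RealignmentParams(np.zeros((4, 6)))
        phantom = mq.build_phantom(series, params)
        scale = np.abs(brain.data).max()
        assert np.abs(phantom.data - series.data).max() <= 1e-6 * scale

    def test_integer_translation_matches_rolled_array(self):
        block = np.zeros((16, 16, 16))
        block[5:9, 6:10, 7:11] = 1.0
        series = _series_from_volume(block, 2)
        params = mq.RealignmentParams([[0] * 6, [2, 0, 0, 0, 0, 0]])
        phantom = mq.build_phantom(series, params, spline_order=7)
        assert np.allclose(phantom.data[..., 1], np.roll(block, 2, axis=0), atol=1e-9)

    def test_quarter_turn_matches_axis_swapped_array(self):
        n = 15
        cross = np.zeros((n, n, n))
        cross[3:6, 7, 7] = 1.0
        cross[7, 5:10, 7] = 2.0
        cross[7, 7, 2:13] = 3.0
        affine = np.eye(4)
        affine[:3, 3] = -(n - 1) / 2.0  # world origin at grid center
        series = _series_from_volume(cross, 2, affine)
        params = mq.RealignmentParams([[0] * 6, [0, 0, 0, 0, 0, np.pi / 2]])
        phantom = mq.build_phantom(series, params, spline_order=7)
        assert np.allclose(
            phantom.data[..., 1], np.rot90(cross, 1, axes=(0, 1)), atol=1e-9
        )

    def test_row_count_mismatch_rejected(self, small_brain):
        brain, _, _ = small_brain
        series = _series_from_volume(brain.data, 3, brain.affine)
        with pytest.raises(mq.GeometryError):
            mq.build_phantom(series, mq.RealignmentParams(np.zeros((5, 6))))


class TestDeriveRois:
    def test_nine_disjoint_rois_on_ellipsoid(self, small_brain):
        _, mask, _ = small_brain
        rois = mq.derive_rois(mask)
        assert len(rois) == 9
        labelled = rois.labelled_volume().data
        # disjointness: label volume voxel counts add up
        total = sum(int(m.sum()) for m in rois.masks.values())
        assert int((labelled > 0).sum()) == total
        # center ROI strictly interior, corner ROIs on the boundary shell
        interior = mask.astype_mask()
        from scipy import ndimage

        eroded = ndimage.binary_erosion(interior, iterations=2)
        assert rois.masks["center"][eroded].sum() == rois.masks["center"].sum()

    def test_sphere_corner_rois_sit_at_the_radius(self):
        half = 16
        dim = 2 * half + 1
        g = np.ogrid[0:dim, 0:dim, 0:dim]
        r2 = sum((gi - half) ** 2 for gi in g)
        radius = 12.0
        mask = mq.VolumeGrid(r2 <= radius**2, np.eye(4))
        rois = mq.derive_rois(mask)
        center = np.array([half] * 3, float)
        for i in range(1, 9):
            vox = np.argwhere(rois.masks[f"corner_{i}"])
            dist = np.linalg.norm(vox - center, axis=1)
            assert np.all(np.abs(dist - radius) <= 1.0 + np.sqrt(3))

    def test_empty_mask_rejected(self):
        with pytest.raises(mq.GeometryError):
            mq.derive_rois(mq.VolumeGrid(np.zeros((12, 12, 12)), np.eye(4)))


class TestRoiTraces:
    def test_constant_series_gives_constant_traces(self, small_brain):
        brain, mask, _ = small_brain
        series = _series_from_volume(brain.data, 5, brain.affine)
        rois = mq.derive_rois(mask)
        traces = mq.roi_traces(series, rois)
        assert traces.shape == (9, 5)
        assert np.allclose(traces, traces[:, :1])

    def test_traces_are_roi_means(self, small_brain, rng):
        brain, mask, _ = small_brain
        data = rng.random(brain.data.shape + (3,))
        series = FmriSeries(data, brain.affine)
        rois = mq.derive_rois(mask)
        traces = mq.roi_traces(series, rois)
        for r, m in enumerate(rois.masks.values()):
            for t in range(3):
                assert traces[r, t] == pytest.approx(data[..., t][m].mean())


class TestSignalChangeScore:
    def test_constant_traces_score_zero(self):
        sc = mq.signal_change_score(np.ones((9, 6)))
        assert sc.score == 0.0

    def test_single_stepping_roi_arithmetic(self):
        traces = np.zeros((9, 5))
        traces[0, 1:] = 2.0
        sc = mq.signal_change_score(traces)
        assert sc.score == pytest.approx(2.0 / 9.0)

    def test_zero_motion_pipeline_score_below_interpolation_noise(self, small_brain):
        brain, mask, _ = small_brain
        series = _series_from_volume(brain.data, 4, brain.affine)
        phantom = mq.build_phantom(series, mq.RealignmentParams(np.zeros((4, 6))))
        traces = mq.roi_traces(phantom, mq.derive_rois(mask))
        sc = mq.signal_change_score(traces)
        assert sc.score < 1e-3 * np.abs(brain.data).max()

    def test_score_monotone_in_motion_amplitude(self, small_brain):
        brain, mask, _ = small_brain
        base = np.vstack([np.zeros(6), np.tile([0.5, 0.3, -0.4, 0.006, -0.004, 0.005], (3, 1))])
        rois = mq.derive_rois(mask)
        scores = []
        for c in (1.0, 2.0):
            params = mq.RealignmentParams(c * base)
            series = _series_from_volume(brain.data, 4, brain.affine)
            phantom = mq.build_phantom(series, params, spline_order=3)
            scores.append(mq.signal_change_score(mq.roi_traces(phantom, rois)).score)
        assert scores[1] >= scores[0]

    def test_corner_rois_feel_rotation_more_than_center(self, small_brain):
        brain, mask, _ = small_brain
        params = mq.RealignmentParams(
            np.vstack([np.zeros(6), np.tile([0, 0, 0, 0.0, 0.0, 0.05], (3, 1))])
        )
        series = _series_from_volume(brain.data, 4, brain.affine)
        phantom = mq.build_phantom(series, params, spline_order=3)
        traces = mq.roi_traces(phantom, mq.derive_rois(mask))
        sc = mq.signal_change_score(traces)
        per_roi = sc.per_roi_trace[:, 1:].mean(axis=1)
        assert per_roi[:8].mean() > per_roi[8]

    def test_reduced_sets_can_score_above_and_below_complete(self):
        """With contrast concentrated near the +z pole, a rotation that
        cancels the translation there makes translation_only overshoot the
        complete score; a rotation-dominant trajectory undershoots."""
        n = 33
        half = (n - 1) // 2
        g = np.ogrid[0:n, 0:n, 0:n]
        r2 = sum((gi - half) ** 2 for gi in g)
        mask_data = r2 <= 12.0**2
        blob = np.exp(-((g[0] - half) ** 2 + (g[1] - half) ** 2 + (g[2] - (half + 12)) ** 2) / 8.0)
        intensity = 1000.0 * blob * mask_data
        affine = np.eye(4)
        affine[:3, 3] = -half
        brain = mq.VolumeGrid(intensity, affine)
        mask = mq.VolumeGrid(mask_data, affine)
        rois = mq.derive_rois(mask)

        def score(params):
            series = _series_from_volume(brain.data, 3, affine)
            phantom = mq.build_phantom(series, params, spline_order=3)
            return mq.signal_change_score(mq.roi_traces(phantom, rois)).score

        # translation +x cancelled at the pole by rotation about y
        cancelling = np.vstack([np.zeros(6), np.tile([1.0, 0, 0, 0, -1.0 / 12.0, 0], (2, 1))])
        p = mq.RealignmentParams(cancelling)
        assert score(p.reduced("translation_only")) > score(p)
        # rotation-dominant: removing rotation removes most of the signal change
        rot_heavy = np.vstack([np.zeros(6), np.tile([0.05, 0, 0, 0, 0.1, 0], (2, 1))])
        q = mq.RealignmentParams(rot_heavy)
        assert score(q.reduced("translation_only")) < score(q)


class TestFingerprintTraces:
    def test_column_counts(self, rng):
        traces = rng.random((9, 20))
        assert fingerprint_traces(traces, k=3, include_shifted=True)[0].shape == (20, 6)
        assert fingerprint_traces(traces, k=9, include_shifted=True)[0].shape == (20, 18)
        assert fingerprint_traces(traces, k=3, include_shifted=False)[0].shape == (20, 3)

    def test_rank_one_traces_live_in_first_component(self, rng):
        t = 30
        base = np.sin(np.linspace(0, 4, t))
        traces = np.outer(rng.random(9) + 0.5, base)
        cols, _ = fingerprint_traces(traces, k=3, include_shifted=False)
        var = cols.var(axis=0)
        assert var[0] / var.sum() > 0.999

    def test_pca_matches_covariance_eigendecomposition(self, rng):
        traces = rng.random((9, 40))
        cols, _ = fingerprint_traces(traces, k=3, include_shifted=False)
        x = traces.T - traces.T.mean(axis=0)
        evals, evecs = np.linalg.eigh(x.T @ x)
        order = np.argsort(evals)[::-1][:3]
        ref = x @ evecs[:, order]
        for j in range(3):
            assert np.allclose(np.abs(cols[:, j]), np.abs(ref[:, j]), atol=1e-8)

    def test_shift_zero_pads_first_row(self, rng):
        traces = rng.random((9, 10))
        cols, names = fingerprint_traces(traces, k=3, include_shifted=True)
        assert np.allclose(cols[0, 3:], 0.0)
        assert np.allclose(cols[1:, 3:], cols[:-1, :3])
        assert names[3:] == ["mfp_pc1_lag1", "mfp_pc2_lag1", "mfp_pc3_lag1"]

    def test_invalid_k_rejected(self, rng):
        with pytest.raises(mq.MotionQCError):
            fingerprint_traces(rng.random((9, 10)), k=4)


def test_forward_simulation_and_replay_round_trip(small_brain):
    """simulate_fmri's forward motion and build_phantom's inverted replay
    use the same transform convention: replaying the simulator's own
    parameters reproduces its volumes."""
    brain, _, _ = small_brain
    params = mq.RealignmentParams(
        np.vstack([np.zeros(6), [[0.8, -0.5, 0.3, 0.01, 0.008, -0.012]] * 3])
    )
    series = simulate_fmri(brain, params, noise_sd=0.0)
    phantom = mq.build_phantom(series, params)
    scale = np.abs(series.data).max()
    assert np.abs(phantom.data - series.data).max() < 1e-3 * scale
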