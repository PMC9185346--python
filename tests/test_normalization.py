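"""The two-step normalization: position shifting, the seven scaling rules,
segment reference scales and the full per-frame transform."""

import numpy as np
import pytest

from gaitnorm import (DegenerateFrameError, GaitSegment, NormalizationMethod,
                      RecenterOffset, frame_scale, normalize_segment,
                      position_shift, segment_reference)
from gaitnorm.keypoints import Keypoint as K
from gaitnorm.normalization import ISOTROPIC_METHODS, _frame_scales_arrays
from gaitnorm.synthetic import (SyntheticGaitConfig, make_walker,
                                project_to_camera, simulate_segment)

from conftest import make_pose, make_segment

ALL_METHODS = list(NormalizationMethod)
BOX_METHODS = [m for m in ALL_METHODS if m not in ISOTROPIC_METHODS]

#: The worked torso: Ls (0,0), Rs (2,0), Lh (0,-4), Rh (2,-4).
TORSO = {K.LEFT_SHOULDER: (0.0, 0.0), K.RIGHT_SHOULDER: (2.0, 0.0),
         K.LEFT_HIP: (0.0, -4.0), K.RIGHT_HIP: (2.0, -4.0)}


class TestPositionShift:
    def test_hand_example(self):
        pose = make_pose(overrides={K.LEFT_SHOULDER: (4, 2), K.RIGHT_SHOULDER: (6, 2),
                                    K.NOSE: (5, 6)})
        shifted = position_shift(pose)
        assert (shifted.x[K.NOSE], shifted.y[K.NOSE]) == (0.0, 4.0)
        ms = (shifted.x[K.LEFT_SHOULDER] + shifted.x[K.RIGHT_SHOULDER]) / 2
        assert ms == 0.0

    def test_centered_pose_is_fixed_point(self):
        pose = make_pose(overrides={K.LEFT_SHOULDER: (-1, 0), K.RIGHT_SHOULDER: (1, 0)})
        shifted = position_shift(pose)
        np.testing.assert_array_equal(shifted.x, pose.x)
        np.testing.assert_array_equal(shifted.y, pose.y)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_pose_midshoulder_at_origin(self, seed):
        pose = position_shift(make_pose(rng=np.random.default_rng(seed)))
        mx = (pose.x[K.LEFT_SHOULDER] + pose.x[K.RIGHT_SHOULDER]) / 2
        my = (pose.y[K.LEFT_SHOULDER] + pose.y[K.RIGHT_SHOULDER]) / 2
        assert np.hypot(mx, my) < 1e-12

    def test_confidences_untouched(self, rng):
        pose = make_pose(rng=rng)
        np.testing.assert_array_equal(position_shift(pose).confidence,
                                      pose.confidence)


class TestFrameScale:
    @pytest.mark.parametrize("method,expected", [
        (NormalizationMethod.LS_RH_D, np.sqrt(20.0)),
        (NormalizationMethod.MS_MH_D, 4.0),
        (NormalizationMethod.ASH, np.sqrt(20.0)),
    ])
    def test_isotropic_on_worked_torso(self, method, expected):
        pose = make_pose(overrides=TORSO)
        w, h = frame_scale(pose, method)
        assert w == pytest.approx(expected, abs=1e-12)
        assert h == w

    def test_collinear_hips_degenerate_for_h(self):
        pose = make_pose(overrides=TORSO)
        with pytest.raises(DegenerateFrameError, match="method h"):
            frame_scale(pose, NormalizationMethod.H)

    def test_box_extents(self):
        pose = make_pose(overrides=TORSO)
        w, h = frame_scale(pose, NormalizationMethod.LS_RH)
        assert (w, h) == (2.0, 4.0)
        w, h = frame_scale(pose, NormalizationMethod.BON)
        assert w == pose.x.max() - pose.x.min()
        assert h == pose.y.max() - pose.y.min()

    @pytest.mark.parametrize("seed", range(10))
    def test_ash_matches_direct_reimplementation(self, seed):
        """ASH equals the mean of the two diagonal distances, recomputed
        keypoint-by-keypoint without the vectorized path."""
        pose = make_pose(rng=np.random.default_rng(seed))
        d1 = np.sqrt((pose.x[K.LEFT_SHOULDER] - pose.x[K.RIGHT_HIP]) ** 2
                     + (pose.y[K.LEFT_SHOULDER] - pose.y[K.RIGHT_HIP]) ** 2)
        d2 = np.sqrt((pose.x[K.RIGHT_SHOULDER] - pose.x[K.LEFT_HIP]) ** 2
                     + (pose.y[K.RIGHT_SHOULDER] - pose.y[K.LEFT_HIP]) ** 2)
        w, h = frame_scale(pose, NormalizationMethod.ASH)
        assert w == pytest.approx((d1 + d2) / 2, rel=1e-12)


class TestSegmentReference:
    def test_two_point_mean(self, rng):
        seg = make_segment(2, rng=rng)
        # pin ASH anchors so per-frame scales are 3 and 5
        for i, d in enumerate((3.0, 5.0)):
            seg.x[i, [K.LEFT_SHOULDER, K.RIGHT_SHOULDER]] = [0.0, 0.0]
            seg.y[i, [K.LEFT_SHOULDER, K.RIGHT_SHOULDER]] = [0.0, 0.0]
            seg.x[i, [K.LEFT_HIP, K.RIGHT_HIP]] = [0.0, 0.0]
            seg.y[i, [K.LEFT_HIP, K.RIGHT_HIP]] = [d, d]
        ref = segment_reference(seg, NormalizationMethod.ASH)
        assert ref.w0 == pytest.approx(4.0)
        np.testing.assert_allclose(ref.per_frame_w, [3.0, 5.0])

    def test_constant_segment(self, rng):
        pose = make_pose(rng=rng)
        seg = GaitSegment(frame_indices=[0, 1, 2],
                          x=np.tile(pose.x, (3, 1)), y=np.tile(pose.y, (3, 1)),
                          confidence=np.tile(pose.confidence, (3, 1)))
        ref = segment_reference(seg, NormalizationMethod.BON)
        np.testing.assert_allclose(ref.per_frame_w, ref.w0)

    def test_ramp_closed_form(self):
        """Rigid torso under a scale ramp: w0 = d * mean(ramp)."""
        cfg = SyntheticGaitConfig(n_frames=50, noise_sd=0.0, dropout_rate=0.0,
                                  scale_start=1.0, scale_end=2.0, seed=2)
        cx, cy = make_walker(cfg)
        seg, truth = project_to_camera((cx, cy), cfg)
        d = _frame_scales_arrays(cx[0], cy[0], NormalizationMethod.ASH)[0]
        ref = segment_reference(seg, NormalizationMethod.ASH)
        assert ref.w0 == pytest.approx(float(d) * truth.applied_scales.mean(), rel=1e-9)

    def test_skip_policy_drops_degenerate_frames(self, rng):
        seg = make_segment(4, rng=rng)
        seg.y[2, K.LEFT_HIP] = seg.y[2, K.RIGHT_HIP]  # level hips in frame 2
        with pytest.raises(DegenerateFrameError):
            segment_reference(seg, NormalizationMethod.H, on_degenerate="error")
        ref = segment_reference(seg, NormalizationMethod.H, on_degenerate="skip")
        np.testing.assert_array_equal(ref.retained, [True, True, False, True])
        assert ref.w0 == pytest.approx(ref.per_frame_w[ref.retained].mean())


class TestNormalizeSegment:
    def test_identical_frames_land_on_offset(self, rng):
        pose = make_pose(rng=rng)
        seg = GaitSegment(frame_indices=[0, 1],
                          x=np.tile(pose.x, (2, 1)), y=np.tile(pose.y, (2, 1)),
                          confidence=np.tile(pose.confidence, (2, 1)))
        out = normalize_segment(seg, NormalizationMethod.ASH)
        np.testing.assert_allclose(out.x[0], out.x[1])
        ms_x = out.x[:, [K.LEFT_SHOULDER, K.RIGHT_SHOULDER]].mean(axis=1)
        ms_y = out.y[:, [K.LEFT_SHOULDER, K.RIGHT_SHOULDER]].mean(axis=1)
        np.testing.assert_allclose(ms_x, 640.0, atol=1e-12)
        np.testing.assert_allclose(ms_y, 200.0, atol=1e-12)

    @pytest.mark.parametrize("method", list(ISOTROPIC_METHODS))
    def test_similar_frames_coincide(self, method, rng):
        """Frame 2 = frame 1 uniformly scaled x2 and translated: after any
        isotropic normalization the two frames coincide."""
        pose = make_pose(rng=rng)
        seg = GaitSegment(
            frame_indices=[0, 1],
            x=np.stack([pose.x, 2.0 * pose.x + 30.0]),
            y=np.stack([pose.y, 2.0 * pose.y - 10.0]),
            confidence=np.tile(pose.confidence, (2, 1)))
        out = normalize_segment(seg, method)
        np.testing.assert_allclose(out.x[0], out.x[1], atol=1e-9)
        np.testing.assert_allclose(out.y[0], out.y[1], atol=1e-9)

    @pytest.mark.parametrize("method", ALL_METHODS)
    def test_anchoring_and_idempotence(self, method, rng):
        seg = make_segment(6, rng=rng)
        out = normalize_segment(seg, method)
        # the method's own extent equals (w0, h0) in every output frame
        ref_in = segment_reference(seg, method)
        w_out, h_out = _frame_scales_arrays(out.x, out.y, method)
        np.testing.assert_allclose(w_out, ref_in.w0, rtol=1e-12)
        np.testing.assert_allclose(h_out, ref_in.h0, rtol=1e-12)
        again = normalize_segment(out, method)
        np.testing.assert_allclose(again.x, out.x, atol=1e-9)
        np.testing.assert_allclose(again.y, out.y, atol=1e-9)

    @pytest.mark.parametrize("method", ALL_METHODS)
    def test_per_frame_similarity_invariance(self, method, rng):
        """A per-frame translation + positive uniform scaling of the input
        changes the output only through the segment-mean reference (w0, h0):
        a global per-axis rescaling about the offset.  When the warp
        preserves the mean reference scale, the output is unchanged."""
        seg = make_segment(6, rng=rng)
        s = rng.uniform(0.5, 3.0, (6, 1))
        # rescale the factors so the mean per-frame reference is preserved
        w, _ = _frame_scales_arrays(seg.x, seg.y, method)
        s *= w.mean() / (s[:, 0] * w).mean()
        tx = rng.uniform(-50, 50, (6, 1))
        ty = rng.uniform(-50, 50, (6, 1))
        warped = seg.with_coordinates(s * seg.x + tx, s * seg.y + ty)
        a = normalize_segment(seg, method)
        b = normalize_segment(warped, method)
        if method in ISOTROPIC_METHODS:
            np.testing.assert_allclose(a.x, b.x, atol=1e-9)
            np.testing.assert_allclose(a.y, b.y, atol=1e-9)
        else:
            # anisotropic methods: h is preserved only up to h0'/h0
            ra = segment_reference(seg, method)
            rb = segment_reference(warped, method)
            np.testing.assert_allclose(a.x, b.x, atol=1e-9)
            np.testing.assert_allclose(
                (rb.h0 / ra.h0) * (a.y - 200.0) + 200.0, b.y, atol=1e-9)

    @pytest.mark.parametrize("method", BOX_METHODS)
    def test_box_methods_survive_anisotropic_scaling(self, method, rng):
        """Box methods separate x from y, so independent mean-preserving
        per-axis scalings leave the output unchanged."""
        seg = make_segment(6, rng=rng)
        sx = rng.uniform(0.5, 2.0, (6, 1))
        sy = rng.uniform(0.5, 2.0, (6, 1))
        w, h = _frame_scales_arrays(seg.x, seg.y, method)
        sx *= w.mean() / (sx[:, 0] * w).mean()
        sy *= h.mean() / (sy[:, 0] * h).mean()
        warped = seg.with_coordinates(sx * seg.x, sy * seg.y)
        a = normalize_segment(seg, method)
        b = normalize_segment(warped, method)
        np.testing.assert_allclose(a.x, b.x, atol=1e-9)
        np.testing.assert_allclose(a.y, b.y, atol=1e-9)

    @pytest.mark.parametrize("method", ALL_METHODS)
    def test_unconstrained_warp_changes_output_by_global_factor(self, method, rng):
        """The complementary exact statement for arbitrary warps: the output
        differs by the per-axis factor (w0'/w0, h0'/h0) about the offset."""
        seg = make_segment(6, rng=rng)
        s = rng.uniform(0.5, 3.0, (6, 1))
        warped = seg.with_coordinates(s * seg.x + 20.0, s * seg.y - 15.0)
        a = normalize_segment(seg, method)
        b = normalize_segment(warped, method)
        ra = segment_reference(seg, method)
        rb = segment_reference(warped, method)
        np.testing.assert_allclose(
            (rb.w0 / ra.w0) * (a.x - 640.0) + 640.0, b.x, atol=1e-9)
        np.testing.assert_allclose(
            (rb.h0 / ra.h0) * (a.y - 200.0) + 200.0, b.y, atol=1e-9)

    def test_metadata_confidence_frames_carried_through(self, rng):
        seg = make_segment(5, rng=rng, participant_id="EOA03", group="EOA",
                           direction="away", segment_label="w2")
        out = normalize_segment(seg, NormalizationMethod.MS_MH_D)
        assert out.metadata() == seg.metadata()
        np.testing.assert_array_equal(out.confidence, seg.confidence)
        np.testing.assert_array_equal(out.frame_indices, seg.frame_indices)

    def test_custom_offset(self, rng):
        seg = make_segment(3, rng=rng)
        out = normalize_segment(seg, NormalizationMethod.ASH,
                                RecenterOffset(100.0, 50.0))
        ms_x = out.x[:, [K.LEFT_SHOULDER, K.RIGHT_SHOULDER]].mean(axis=1)
        np.testing.assert_allclose(ms_x, 100.0, atol=1e-12)

    def test_degenerate_error_carries_method_and_frame(self, rng):
        seg = make_segment(4, rng=rng)
        seg.y[2, K.LEFT_SHOULDER] = seg.y[2, K.RIGHT_SHOULDER]
        with pytest.raises(DegenerateFrameError) as exc:
            normalize_segment(seg, NormalizationMethod.S)
        assert exc.value.frame_index == 2
        assert exc.value.method is NormalizationMethod.S

    def test_skip_policy_consistent_reference_and_output(self, rng):
        seg = make_segment(5, rng=rng)
        seg.y[1, K.LEFT_HIP] = seg.y[1, K.RIGHT_HIP]
        out = normalize_segment(seg, NormalizationMethod.H, on_degenerate="skip")
        assert out.n_frames == 4
        assert 1 not in out.frame_indices
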