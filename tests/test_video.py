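"""Skeleton normalization chain and the 250 x 60 video feature matrix."""

import numpy as np
import pytest

from fidgetfusion import (
    KeypointSnippet,
    SnippetMeta,
    VideoFeatureExtractor,
    build_video_features,
    center_skeleton,
    clean_trajectories,
    rotate_skeleton,
    scale_skeleton,
)
from fidgetfusion.snippets import HIP_INDICES, SHOULDER_INDICES, DegenerateDataError
from fidgetfusion.video import (
    hip_center,
    keypoint_velocity,
    preprocess_keypoints,
    shoulder_center,
)


def kp_snippet(values, label=1):
    meta = SnippetMeta(snippet_id="kp", infant_id="inf00", label=label)
    return KeypointSnippet(values=np.asarray(values, dtype=float), meta=meta)


def static_skeleton(rng=None, jitter=0.0):
    """A plausible static supine skeleton (may add small jitter)."""
    base = np.array([
        (0, 210), (-12, 222), (12, 222), (-40, 150), (40, 150),
        (-75, 105), (75, 105), (-100, 55), (100, 55), (-25, 0), (25, 0),
        (-38, -75), (38, -75), (-48, -150), (48, -150)], dtype=float)
    values = np.tile(base + [960.0, 400.0], (250, 1, 1))
    if jitter and rng is not None:
        values = values + rng.normal(0, jitter, values.shape)
    return values


class TestCleaning:
    def test_constant_trajectories_unchanged(self):
        snip = kp_snippet(static_skeleton())
        np.testing.assert_allclose(clean_trajectories(snip).values, snip.values,
                                   atol=1e-12)

    def test_single_frame_spike_removed(self):
        values = static_skeleton()
        spiked = values.copy()
        spiked[100, 7, 0] += 100.0          # one-frame outlier on a wrist
        cleaned = clean_trajectories(kp_snippet(spiked))
        clean_ref = clean_trajectories(kp_snippet(values))
        np.testing.assert_allclose(cleaned.values[95:105], clean_ref.values[95:105],
                                   atol=1e-9)

    def test_smooth_sinusoid_barely_changed(self):
        t = np.arange(250) / 50.0
        values = static_skeleton()
        wave = 20.0 * np.sin(2 * np.pi * 0.4 * t)
        values[:, 7, 0] += wave
        cleaned = clean_trajectories(kp_snippet(values))
        # moving-average attenuation of a slow sinusoid is tiny; bound by the
        # exact second-order error of a window-5 average
        err = np.abs(cleaned.values[5:-5, 7, 0] - values[5:-5, 7, 0])
        bound = 20.0 * (2 * np.pi * 0.4 / 50.0) ** 2 * 10
        assert err.max() < bound


class TestGeometry:
    def test_center_subtracts_time_averaged_hip_midpoint(self):
        values = static_skeleton()
        values[:, HIP_INDICES[0]] = [10.0, 20.0]
        values[:, HIP_INDICES[1]] = [14.0, 20.0]
        centered = center_skeleton(kp_snippet(values))
        np.testing.assert_allclose(hip_center(centered.values), [0.0, 0.0],
                                   atol=1e-9)
        np.testing.assert_allclose(centered.values,
                                   values - np.array([12.0, 20.0]), atol=1e-9)

    def test_centering_idempotent(self, rng):
        snip = kp_snippet(static_skeleton(rng, jitter=2.0))
        once = center_skeleton(snip)
        twice = center_skeleton(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-9)

    def test_hip_center_matches_hand_computation(self, rng):
        values = static_skeleton(rng, jitter=5.0)
        hips = values[:, HIP_INDICES, :]
        np.testing.assert_allclose(hip_center(values),
                                   hips.reshape(-1, 2).mean(axis=0), atol=1e-12)

    @pytest.mark.parametrize("sc, expected_alignment", [
        ((0.0, 5.0), True),     # already aligned -> identity
        ((5.0, 0.0), True),     # right tilt
        ((-5.0, 0.0), True),    # left tilt: signed angle still lands on +Y
        ((3.0, -4.0), True),
    ])
    def test_rotation_aligns_shoulder_center_on_positive_y(self, sc, expected_alignment):
        values = np.zeros((250, 15, 2))
        values[:, SHOULDER_INDICES[0]] = sc
        values[:, SHOULDER_INDICES[1]] = sc
        rotated = rotate_skeleton(kp_snippet(values))
        sc_rot = shoulder_center(rotated.values)
        assert sc_rot[0] == pytest.approx(0.0, abs=1e-9)
        assert sc_rot[1] == pytest.approx(np.hypot(*sc), abs=1e-9)

    def test_rotation_degenerate_geometry_raises(self):
        with pytest.raises(DegenerateDataError):
            rotate_skeleton(kp_snippet(np.zeros((250, 15, 2))))

    def test_scaling_sets_trunk_length_to_one_third(self):
        values = np.zeros((250, 15, 2))
        values[:, SHOULDER_INDICES[0]] = [0.0, 0.9]
        values[:, SHOULDER_INDICES[1]] = [0.0, 0.9]
        scaled = scale_skeleton(kp_snippet(values))
        # divide by 3 * 0.9 = 2.7; shoulder center lands at 1/3
        assert shoulder_center(scaled.values)[1] == pytest.approx(1.0 / 3.0, abs=1e-9)
        trunk = abs(hip_center(scaled.values)[1] - shoulder_center(scaled.values)[1])
        assert trunk == pytest.approx(1.0 / 3.0, abs=1e-9)

    def test_scaling_fixed_point_and_homogeneity(self, rng):
        values = static_skeleton(rng, jitter=1.0)
        centered = center_skeleton(kp_snippet(values))
        once = scale_skeleton(centered)
        np.testing.assert_allclose(scale_skeleton(once).values, once.values,
                                   atol=1e-9)
        doubled = scale_skeleton(kp_snippet(centered.values * 2.0))
        np.testing.assert_allclose(doubled.values, once.values, atol=1e-9)

    def test_scaling_degenerate_raises(self):
        with pytest.raises(DegenerateDataError):
            scale_skeleton(kp_snippet(np.zeros((250, 15, 2))))


class TestFeatureMatrix:
    @staticmethod
    def _stats(snips, **kw):
        return VideoFeatureExtractor(**kw).fit(snips).norm_stats_

    def test_sixty_columns_by_default(self, tiny_cohort):
        snips = [t.keypoints for t in tiny_cohort.triples[:4]]
        fm = build_video_features(snips[0], self._stats(snips))
        assert fm.values.shape == (250, 60)
        assert fm.modality == "VID"

    def test_ninety_columns_with_acceleration(self, tiny_cohort):
        snips = [t.keypoints for t in tiny_cohort.triples[:4]]
        stats = self._stats(snips, include_acceleration=True)
        fm = build_video_features(snips[0], stats, include_acceleration=True)
        assert fm.values.shape == (250, 90)

    def test_missing_stats_group_raises(self, tiny_cohort):
        snips = [t.keypoints for t in tiny_cohort.triples[:4]]
        stats = self._stats(snips)             # no acceleration group
        with pytest.raises(KeyError, match="acceleration"):
            build_video_features(snips[0], stats, include_acceleration=True)

    def test_constant_input_gives_constant_velocity_columns(self, rng, tiny_cohort):
        snips = [t.keypoints for t in tiny_cohort.triples[:4]]
        stats = self._stats(snips)
        fm = build_video_features(kp_snippet(static_skeleton()), stats)
        vel = fm.values[:, 30:]
        np.testing.assert_allclose(vel - vel[0], 0.0, atol=1e-12)

    def test_prenormalization_column_means_are_zero(self, tiny_cohort):
        pos = preprocess_keypoints(tiny_cohort.triples[0].keypoints)
        np.testing.assert_allclose(pos.mean(axis=0), 0.0, atol=1e-9)

    def test_velocity_is_central_difference(self, rng):
        pos = rng.normal(size=(10, 2, 2))
        v = keypoint_velocity(pos)
        np.testing.assert_allclose(v[5], (pos[6] - pos[4]) / 2.0, atol=1e-12)
        np.testing.assert_allclose(v[0], pos[1] - pos[0], atol=1e-12)

    def test_similarity_invariance_of_full_pipeline(self, rng):
        """Global translation + rotation + scaling of the raw key points
        leaves the normalized features unchanged.

        Linear-in-time trajectories are used so the (nonlinear) median
        filter acts identically in both frames.
        """
        base = static_skeleton()
        drift = rng.normal(0, 0.5, (15, 2))
        t = np.arange(250)[:, None, None]
        values = base + drift[None] * t / 50.0

        theta = 0.83
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        transformed = 2.3 * (values @ rot.T) + np.array([111.0, -55.0])

        snips = [kp_snippet(values)]
        stats = self._stats(snips)
        fm_a = build_video_features(kp_snippet(values), stats)
        fm_b = build_video_features(kp_snippet(transformed), stats)
        np.testing.assert_allclose(fm_a.values, fm_b.values, atol=1e-6)

    def test_repeat_run_bit_identical(self, tiny_cohort):
        snips = [t.keypoints for t in tiny_cohort.triples[:4]]
        stats = self._stats(snips)
        a = build_video_features(snips[0], stats)
        b = build_video_features(snips[0], stats)
        np.testing.assert_array_equal(a.values, b.values)

    def test_extractor_transform_stacks_snippets(self, tiny_cohort):
        snips = [t.keypoints for t in tiny_cohort.triples[:5]]
        X = VideoFeatureExtractor().fit(snips).transform(snips)
        assert X.shape == (5, 250, 60)
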