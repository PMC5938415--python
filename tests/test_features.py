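"""Keypoint detection and ratio-test descriptor matching."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from ratlas.features import (
    FeatureSet,
    MatchConfig,
    detect_features,
    match_descriptors,
    to_grayscale_u8,
)
from ratlas.synth import FixtureImageSpec, make_image


@pytest.fixture(scope="module")
def textured_image():
    return make_image(FixtureImageSpec(seed=4))


@pytest.fixture(scope="module")
def textured_features(textured_image):
    return detect_features(textured_image, "full")


def _brute_force_matches(roi_desc, target_desc, ratio, abs_threshold=None):
    """Independent oracle: exhaustive pairwise nearest/second-nearest."""
    out = []
    for i, u in enumerate(roi_desc):
        dists = [float(np.linalg.norm(u - v)) for v in target_desc]
        order = sorted(range(len(dists)), key=lambda j: (dists[j], j))
        best, second = order[0], order[1]
        d1, d2 = dists[best], dists[second]
        accept = (d1 / d2 < ratio) if d2 > 0 else False
        if abs_threshold is not None:
            accept = accept and d1 < abs_threshold
        if accept:
            out.append((i, best, d1))
    return out


class TestDetection:
    def test_constant_image_has_no_features(self):
        flat = np.full((64, 64), 128, dtype=np.uint8)
        assert len(detect_features(flat)) == 0

    def test_descriptors_are_128d_and_parallel(self, textured_features):
        f = textured_features
        assert len(f) >= 100
        assert f.descriptors.shape == (len(f), 128)
        assert np.all(f.descriptors >= 0)
        assert np.all((0 <= f.orientations) & (f.orientations < 2 * np.pi))
        assert np.all(f.scales > 0)

    def test_detection_is_deterministic(self, textured_image):
        a = detect_features(textured_image)
        b = detect_features(textured_image)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.descriptors, b.descriptors)

    def test_rotated_copy_recovers_keypoint_positions(self, textured_image,
                                                      textured_features):
        """At least half the keypoints must reappear within 2 px of their
        mapped position after a 90-degree rotation (exact pixel mapping, so
        no interpolation confound)."""
        rotated = np.rot90(textured_image)
        rotated_features = detect_features(rotated)
        width = textured_image.shape[1]
        mapped = np.column_stack(
            [width - 1 - textured_features.positions[:, 1],
             textured_features.positions[:, 0]]
        )
        dist, _ = cKDTree(rotated_features.positions).query(mapped)
        assert (dist <= 2.0).mean() >= 0.5

    def test_crop_keypoints_coincide_with_full_image(self, textured_image,
                                                     textured_features):
        """Keypoints whose measurement support lies inside the crop (farther
        than 6x their detection scale from the border) must coincide exactly
        with full-image keypoints once offset by the crop origin."""
        r0, c0, h, w = 100, 120, 220, 220
        roi = detect_features(textured_image[r0:r0 + h, c0:c0 + w])
        margin = np.maximum(6.0 * roi.scales, 8.0)
        inner = (
            (roi.positions[:, 0] > margin) & (roi.positions[:, 0] < h - margin)
            & (roi.positions[:, 1] > margin) & (roi.positions[:, 1] < w - margin)
        )
        assert inner.sum() >= 50
        offset = roi.positions[inner] + [r0, c0]
        dist, _ = cKDTree(textured_features.positions).query(offset)
        assert dist.max() <= 1.0

    def test_multichannel_input_converted_to_luminance(self, textured_image):
        rgb = np.stack([textured_image] * 3, axis=-1)
        assert np.array_equal(to_grayscale_u8(rgb), textured_image)

    def test_16bit_input_rescaled(self):
        img16 = (np.arange(64 * 64, dtype=np.uint16).reshape(64, 64) * 16)
        out = to_grayscale_u8(img16)
        assert out.dtype == np.uint8 and out.max() <= 255


def _feature_set_from_descriptors(desc):
    n = len(desc)
    return FeatureSet(
        positions=np.zeros((n, 2)), scales=np.ones(n),
        orientations=np.zeros(n), descriptors=np.asarray(desc, dtype=np.float32),
    )


class TestMatching:
    def test_ratio_rule_accepts_and_rejects(self):
        # nearest at distance 1.0 vs second at 2.0 -> ratio 0.5 < 0.8: match;
        # nearest at 1.8 vs 2.0 -> 0.9: no match
        roi = _feature_set_from_descriptors(
            [np.zeros(128), np.r_[np.full(1, 10.0), np.zeros(127)]]
        )
        t0 = np.zeros(128); t0[0] = 1.0          # dist 1.0 to roi[0]
        t1 = np.zeros(128); t1[0] = -2.0         # dist 2.0 to roi[0]
        t2 = np.zeros(128); t2[0] = 10.0 - 1.8   # dist 1.8 to roi[1]
        t3 = np.zeros(128); t3[0] = 10.0 + 2.0   # dist 2.0 to roi[1]
        target = _feature_set_from_descriptors([t0, t1, t2, t3])
        matches = match_descriptors(roi, target, MatchConfig(ratio=0.8))
        assert [(m.roi_index, m.target_index) for m in matches] == [(0, 0)]
        assert matches.pairs[0].distance == pytest.approx(1.0)

    def test_absolute_threshold_filters_when_enabled(self):
        roi = _feature_set_from_descriptors([np.zeros(128)])
        t0 = np.zeros(128); t0[0] = 1.0
        t1 = np.zeros(128); t1[0] = 5.0
        target = _feature_set_from_descriptors([t0, t1])
        assert len(match_descriptors(roi, target, MatchConfig(0.8, None))) == 1
        assert len(match_descriptors(roi, target, MatchConfig(0.8, 0.5))) == 0

    def test_matches_agree_with_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        roi = _feature_set_from_descriptors(rng.uniform(0, 100, (20, 128)))
        target = _feature_set_from_descriptors(rng.uniform(0, 100, (30, 128)))
        for config in (MatchConfig(0.8), MatchConfig(0.95), MatchConfig(0.8, 400.0)):
            got = [
                (m.roi_index, m.target_index)
                for m in match_descriptors(roi, target, config)
            ]
            expected = [
                (i, j) for i, j, _ in _brute_force_matches(
                    roi.descriptors.astype(float),
                    target.descriptors.astype(float),
                    config.ratio, config.abs_threshold,
                )
            ]
            assert got == expected

    def test_ratio_one_reduces_to_nearest_neighbor(self):
        rng = np.random.default_rng(7)
        roi = _feature_set_from_descriptors(rng.uniform(0, 10, (15, 128)))
        target = _feature_set_from_descriptors(rng.uniform(0, 10, (25, 128)))
        matches = match_descriptors(roi, target, MatchConfig(ratio=1.0))
        assert len(matches) == len(roi)
        dist = np.linalg.norm(
            roi.descriptors[:, None, :].astype(float)
            - target.descriptors[None, :, :].astype(float), axis=2,
        )
        assert [m.target_index for m in matches] == list(dist.argmin(axis=1))

    def test_invariant_to_target_permutation(self):
        rng = np.random.default_rng(3)
        roi = _feature_set_from_descriptors(rng.uniform(0, 10, (10, 128)))
        desc = rng.uniform(0, 10, (20, 128))
        perm = rng.permutation(20)
        a = match_descriptors(roi, _feature_set_from_descriptors(desc))
        b = match_descriptors(roi, _feature_set_from_descriptors(desc[perm]))
        remapped = [(m.roi_index, perm[m.target_index]) for m in b]
        assert [(m.roi_index, m.target_index) for m in a] == remapped

    def test_self_match_with_decoy_is_exact(self):
        rng = np.random.default_rng(5)
        desc = rng.uniform(0, 10, (12, 128))
        roi = _feature_set_from_descriptors(desc)
        decoy = np.full((1, 128), 1e4)
        target = _feature_set_from_descriptors(np.vstack([desc, decoy]))
        matches = match_descriptors(roi, target)
        assert [(m.roi_index, m.target_index) for m in matches] == [
            (i, i) for i in range(12)
        ]
        assert all(m.distance == 0.0 for m in matches)

    def test_target_needs_two_descriptors(self):
        roi = _feature_set_from_descriptors([np.zeros(128)])
        single = _feature_set_from_descriptors([np.ones(128)])
        with pytest.raises(ValueError, match="ratio test"):
            match_descriptors(roi, single)
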