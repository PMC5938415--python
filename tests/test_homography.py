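"""Normalized-DLT homography fitting and RANSAC consensus search."""

import numpy as np
import pytest

from ratlas.homography import (
    DegenerateSampleError,
    Homography,
    RansacConfig,
    count_inliers,
    fit_homography,
    ransac,
    reprojection_error,
)

UNIT_SQUARE = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


def _random_projective(rng):
    return np.array(
        [
            [rng.uniform(0.8, 1.3), rng.uniform(-0.2, 0.2), rng.uniform(-20, 20)],
            [rng.uniform(-0.2, 0.2), rng.uniform(0.8, 1.3), rng.uniform(-20, 20)],
            [rng.uniform(-2e-4, 2e-4), rng.uniform(-2e-4, 2e-4), 1.0],
        ]
    )


class TestFitHomography:
    def test_identity_from_unit_square(self):
        H = fit_homography(UNIT_SQUARE, UNIT_SQUARE)
        assert np.allclose(H.matrix, np.eye(3), atol=1e-9)

    def test_pure_translation(self):
        H = fit_homography(UNIT_SQUARE, UNIT_SQUARE + [5.0, 3.0])
        assert np.allclose(H.matrix[:2, :2], np.eye(2), atol=1e-9)
        assert np.allclose(H.matrix[:2, 2], [5.0, 3.0], atol=1e-9)
        assert np.allclose(H.matrix[2], [0.0, 0.0, 1.0], atol=1e-9)

    def test_exact_four_point_fit_reprojects_below_1e6(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(0, 200, (4, 2))
            q = rng.uniform(0, 200, (4, 2))
            try:
                H = fit_homography(p, q)
            except DegenerateSampleError:
                continue
            errors = [reprojection_error(H, pi, qi) for pi, qi in zip(p, q)]
            assert max(errors) < 1e-6

    def test_recovers_planted_projective_map_from_six_points(self):
        rng = np.random.default_rng(123)
        truth = _random_projective(rng)
        p = rng.uniform(0, 100, (6, 2))
        q = Homography(truth).apply(p)
        H = fit_homography(p, q)
        assert np.allclose(H.matrix, truth / truth[2, 2], atol=1e-8)
        assert max(reprojection_error(H, pi, qi) for pi, qi in zip(p, q)) < 1e-6

    def test_agrees_with_reference_estimator(self):
        """Cross-check the DLT against scikit-image's projective estimator."""
        from skimage.transform import ProjectiveTransform

        rng = np.random.default_rng(9)
        p = rng.uniform(0, 100, (8, 2))
        q = Homography(_random_projective(rng)).apply(p) + rng.normal(0, 0.3, (8, 2))
        ours = fit_homography(p, q)
        ref = ProjectiveTransform.from_estimate(p, q)
        assert ref
        assert np.allclose(ours.matrix, ref.params / ref.params[2, 2], atol=1e-6)

    def test_collinear_sample_is_degenerate(self):
        p = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [0.0, 5.0]])
        with pytest.raises(DegenerateSampleError):
            fit_homography(p, UNIT_SQUARE)

    def test_repeated_point_is_degenerate(self):
        p = UNIT_SQUARE.copy()
        p[3] = p[0]
        with pytest.raises(DegenerateSampleError):
            fit_homography(p, UNIT_SQUARE)


class TestReprojectionError:
    def test_identity_on_fixed_point_is_zero(self):
        assert reprojection_error(Homography.identity(), (10, 10), (10, 10)) == 0.0

    def test_three_four_five(self):
        assert reprojection_error(Homography.identity(), (0, 0), (3, 4)) == 5.0

    def test_known_perturbation_norm(self):
        rng = np.random.default_rng(77)
        H = Homography(_random_projective(rng))
        p = rng.uniform(0, 50, 2)
        q = H.apply(p)[0] + np.array([0.6, -0.8])
        assert reprojection_error(H, p, q) == pytest.approx(1.0, abs=1e-12)

    def test_point_mapped_to_infinity_gives_inf(self):
        # invertible map whose bottom row (0, 1, 0) sends y = 0 points to
        # the plane at infinity
        H = Homography(np.array([[1.0, 0, 0], [0, 0, 1.0], [0, 1.0, 0]]))
        assert reprojection_error(H, (5.0, 0.0), (0.0, 0.0)) == np.inf


def _planted_matches(seed, n=40, n_outliers=12, spread=200.0):
    rng = np.random.default_rng(seed)
    truth = _random_projective(rng)
    p = rng.uniform(0, spread, (n, 2))
    q = Homography(truth).apply(p)
    outlier_idx = rng.choice(n, size=n_outliers, replace=False)
    planted = np.ones(n, dtype=bool)
    planted[outlier_idx] = False
    H = Homography(truth)
    for i in outlier_idx:
        while True:  # place outliers safely outside the inlier threshold
            q[i] = rng.uniform(-spread, 2 * spread, 2)
            if reprojection_error(H, p[i], q[i]) > 40.0:
                break
    return np.stack([p, q], axis=1), planted


class TestRansac:
    def test_exact_identity_correspondences_are_all_inliers(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0, 100, (20, 2))
        result = ransac(np.stack([p, p], axis=1), RansacConfig(seed=0))
        assert result.inlier_count == 20
        assert result.inlier_flags.all()

    def test_below_minimal_sample_returns_empty(self):
        pairs = np.stack([UNIT_SQUARE[:3], UNIT_SQUARE[:3]], axis=1)
        result = ransac(pairs, RansacConfig(seed=0))
        assert result.inlier_count == 0
        assert result.homography is None

    @pytest.mark.parametrize("seed", range(20))
    def test_planted_inlier_set_recovered_for_every_seed(self, seed):
        """With 70% planted inliers and 2000 samples the probability of
        never drawing an all-inlier quadruple is negligible, so recovery
        must be exact for all seeds."""
        pairs, planted = _planted_matches(seed)
        result = ransac(pairs, RansacConfig(seed=seed))
        assert result.inlier_count == planted.sum() == 28
        assert np.array_equal(result.inlier_flags, planted)

    def test_error_equal_to_threshold_is_an_outlier(self):
        """The scoring rule shared by the search and refit paths: strictly
        below the threshold is in, exactly at the threshold is out."""
        pairs = np.array([
            [[0.0, 0.0], [9.999999, 0.0]],   # just inside
            [[50.0, 50.0], [60.0, 50.0]],    # exactly 10 px: outlier
            [[80.0, 10.0], [80.0, 10.0]],    # exact match
        ])
        flags = count_inliers(Homography.identity(), pairs, 10.0)
        assert list(flags) == [True, False, True]

    def test_duplicated_inlier_raises_count_by_one(self):
        pairs, planted = _planted_matches(99)
        dup_index = int(np.flatnonzero(planted)[0])
        with_dup = np.concatenate([pairs, pairs[dup_index:dup_index + 1]])
        base = ransac(pairs, RansacConfig(seed=5))
        more = ransac(with_dup, RansacConfig(seed=5))
        assert more.inlier_count == base.inlier_count + 1

    def test_bit_for_bit_reproducible(self):
        pairs, _ = _planted_matches(7)
        a = ransac(pairs, RansacConfig(seed=11))
        b = ransac(pairs, RansacConfig(seed=11))
        assert np.array_equal(a.inlier_flags, b.inlier_flags)
        assert np.array_equal(a.homography.matrix, b.homography.matrix)

    def test_flagged_matches_reproject_below_threshold(self):
        pairs, _ = _planted_matches(13)
        config = RansacConfig(seed=2)
        result = ransac(pairs, config)
        for flag, (p, q) in zip(result.inlier_flags, pairs):
            err = reprojection_error(result.homography, p, q)
            assert (err < config.inlier_threshold_px) == bool(flag)

    def test_degenerate_only_input_yields_zero(self):
        # every point identical: no non-degenerate quadruple exists
        p = np.tile([[5.0, 5.0]], (6, 1))
        result = ransac(np.stack([p, p], axis=1), RansacConfig(seed=0))
        assert result.inlier_count == 0 and result.homography is None

    def test_min_sample_fixed_at_four(self):
        with pytest.raises(ValueError):
            RansacConfig(min_sample=3)
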