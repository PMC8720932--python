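import numpy as np
import pytest

from chromastress.discomfort_stats import spearman_point
from chromastress.natural_stats import (
    NaturalDistribution,
    corpus_distribution,
    crop_left_third,
    rank_extreme_patches,
    rectified_zscores,
    sample_patches,
    shift_correlation_analysis,
)


@pytest.fixture
def toy_dist():
    return corpus_distribution(
        np.array([0.003, 0.004, 0.005, 0.006, 0.007, 0.009])
    )


class TestCorpusDistribution:
    def test_two_point_moments(self):
        dist = corpus_distribution([0.0, 1.0])
        assert dist.mu == 0.5
        assert dist.sigma == pytest.approx(np.sqrt(0.5))

    def test_degenerate_corpus_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            corpus_distribution([0.01] * 5)

    def test_density_integrates_to_one(self, toy_dist):
        grid = np.linspace(-0.02, 0.04, 2000)
        mass = np.trapezoid(toy_dist.density(grid), grid)
        assert mass == pytest.approx(1.0, abs=0.01)


class TestPatches:
    def test_same_seed_same_offsets(self, rng):
        img = rng.uniform(0, 1, (40, 60, 3))
        a = sample_patches(img, 5, size=16, seed=11)
        b = sample_patches(img, 5, size=16, seed=11)
        assert [(p.top, p.left) for p in a] == [(p.top, p.left) for p in b]

    def test_exact_size_image_single_position(self, rng):
        img = rng.uniform(0, 1, (16, 16, 3))
        patches = sample_patches(img, 4, size=16, seed=0)
        assert all(p.top == 0 and p.left == 0 for p in patches)

    def test_patch_count_scales_with_images(self, rng):
        imgs = [rng.uniform(0, 1, (20, 20, 3)) for _ in range(3)]
        total = sum(
            len(sample_patches(im, 25, size=16, seed=i))
            for i, im in enumerate(imgs)
        )
        assert total == 75

    def test_too_small_image_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_patches(rng.uniform(0, 1, (8, 8, 3)), 1, size=16, seed=0)


class TestCropRule:
    def test_left_third_removed(self, rng):
        # 756×1134-style frame with the calibration region on the left
        img = rng.uniform(0, 1, (12, 18, 3))
        out = crop_left_third(img)
        assert out.shape == (12, 12, 3)
        assert np.array_equal(out, img[:, 6:])


class TestRectifiedZ:
    def test_at_mean_is_zero(self, toy_dist):
        assert rectified_zscores([toy_dist.mu], toy_dist)[0] == 0.0

    def test_two_sigma_above_is_two(self, toy_dist):
        x = toy_dist.mu + 2 * toy_dist.sigma
        assert rectified_zscores([x], toy_dist)[0] == pytest.approx(2.0)

    def test_below_mean_rectified_to_zero(self, toy_dist):
        xs = toy_dist.mu - np.array([0.5, 1.0, 3.0]) * toy_dist.sigma
        assert np.all(rectified_zscores(xs, toy_dist) == 0.0)

    def test_monotone_and_shift_invariant(self, toy_dist):
        xs = np.sort(np.linspace(0.001, 0.02, 9))
        z = rectified_zscores(xs, toy_dist)
        assert np.all(np.diff(z) >= 0)
        shifted = NaturalDistribution(
            toy_dist.samples, toy_dist.mu + 0.004, toy_dist.sigma,
            toy_dist.density,
        )
        z2 = rectified_zscores(xs + 0.004, shifted)
        assert np.allclose(z, z2)


class TestShiftAnalysis:
    def test_strongly_negative_shift_equals_plain_spearman(self, rng):
        metrics = rng.uniform(0.002, 0.02, 20)
        ratings = rng.uniform(1, 5, 20)
        dist = corpus_distribution(rng.normal(0.0056, 0.0023, 50))
        curve = shift_correlation_analysis(
            metrics, ratings, dist, shifts=[-10 * dist.sigma], B=200, seed=1
        )
        assert curve.rho[0] == pytest.approx(
            spearman_point(metrics, ratings), abs=1e-12
        )

    def test_shift_beyond_max_gives_undefined_marker(self, rng):
        metrics = rng.uniform(0.002, 0.01, 10)
        ratings = rng.uniform(1, 5, 10)
        dist = corpus_distribution(rng.normal(0.0056, 0.0023, 50))
        big = (metrics.max() - dist.mu) / 1 + dist.sigma
        curve = shift_correlation_analysis(
            metrics, ratings, dist, shifts=[big * 2], B=200, seed=1
        )
        assert np.isnan(curve.rho[0])

    def test_ratings_built_from_rectified_z_peak_at_zero_shift(self, rng):
        dist = corpus_distribution(rng.normal(0.0056, 0.0023, 100))
        metrics = rng.uniform(0.004, 0.018, 40)
        z0 = np.maximum(0, (metrics - dist.mu) / dist.sigma)
        ratings = z0 + rng.normal(0, 0.15, metrics.size)
        curve = shift_correlation_analysis(
            metrics, ratings, dist,
            shifts=[0.0, 2 * dist.sigma], B=200, seed=2,
        )
        assert curve.rho[0] > curve.rho[1]

    def test_empty_shift_grid_rejected(self, toy_dist, rng):
        with pytest.raises(ValueError):
            shift_correlation_analysis(
                rng.uniform(0, 1, 5), rng.uniform(1, 5, 5), toy_dist,
                shifts=[],
            )


class TestExtremePatches:
    def _patches(self, metrics):
        from chromastress.natural_stats import PatchSample

        return [
            PatchSample(f"s{i}", 0, 0, 16, m) for i, m in enumerate(metrics)
        ]

    def test_full_sort_when_k_equals_n(self):
        patches = self._patches([0.3, 0.1, 0.2])
        top, bottom = rank_extreme_patches(patches, 3)
        assert [p.metric for p in top] == [0.3, 0.2, 0.1]
        assert top == bottom

    def test_injected_high_metric_patch_ranked_first(self):
        patches = self._patches([0.004, 0.005, 0.006, 0.09, 0.005])
        top, _ = rank_extreme_patches(patches, 2)
        assert top[0].metric == 0.09

    def test_top_and_bottom_disjoint(self):
        patches = self._patches(np.linspace(0.001, 0.01, 10))
        top, bottom = rank_extreme_patches(patches, 4)
        assert not (set(id(p) for p in top) & set(id(p) for p in bottom))
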