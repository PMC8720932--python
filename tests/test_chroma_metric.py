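import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chromastress.chroma_metric import (
    average_chromaticity_difference,
    field_average_difference,
    heatmap_histogram,
    local_chromaticity_difference,
    pair_distance,
)
from chromastress.colorspace import ChromaLumImage, rgb_to_chromalum
from chromastress.synthetic_data import make_two_color_image

from conftest import brute_force_heatmap


coords = st.floats(min_value=0.0, max_value=0.7, allow_nan=False)


class TestPairDistance:
    def test_identity_is_zero(self):
        assert pair_distance((0.2, 0.4), (0.2, 0.4)) == 0.0

    def test_hand_evaluated_example(self):
        d = pair_distance((0.20, 0.45), (0.25, 0.50))
        assert d == pytest.approx(np.sqrt(0.05**2 + 0.05**2), abs=1e-15)

    def test_symmetric(self):
        p, q = (0.1, 0.6), (0.33, 0.21)
        assert pair_distance(p, q) == pair_distance(q, p)

    @settings(derandomize=True, max_examples=50)
    @given(coords, coords, coords, coords, coords, coords)
    def test_triangle_inequality(self, u1, v1, u2, v2, u3, v3):
        p, q, r = (u1, v1), (u2, v2), (u3, v3)
        assert pair_distance(p, r) <= (
            pair_distance(p, q) + pair_distance(q, r) + 1e-12
        )

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            pair_distance((np.nan, 0.1), (0.2, 0.2))


class TestLocalDifference:
    def test_constant_field_all_zero(self):
        field = ChromaLumImage(
            np.full((5, 7), 0.2), np.full((5, 7), 0.45), np.ones((5, 7))
        )
        assert np.all(local_chromaticity_difference(field) == 0)

    def test_matches_brute_force_on_random_fields(self, rng):
        for _ in range(20):
            h = int(rng.integers(2, 17))
            w = int(rng.integers(2, 17))
            u = rng.uniform(0, 0.7, (h, w))
            v = rng.uniform(0, 0.7, (h, w))
            field = ChromaLumImage(u, v, np.ones((h, w)))
            fast = local_chromaticity_difference(field)
            slow = brute_force_heatmap(u, v)
            assert np.allclose(fast, slow, atol=1e-12)

    def test_two_by_two_halves_closed_form(self):
        # left column chromaticity a, right column b: each pixel has three
        # neighbors, one sharing its chromaticity and two at distance d
        u = np.array([[0.1, 0.3], [0.1, 0.3]])
        v = np.array([[0.5, 0.2], [0.5, 0.2]])
        d = np.hypot(0.2, 0.3)
        field = ChromaLumImage(u, v, np.ones((2, 2)))
        assert np.allclose(
            local_chromaticity_difference(field), 2 * d / 3, atol=1e-14
        )

    def test_corner_averages_exactly_three_neighbors(self, rng):
        u = rng.uniform(0, 0.7, (6, 6))
        v = rng.uniform(0, 0.7, (6, 6))
        field = ChromaLumImage(u, v, np.ones((6, 6)))
        hm = local_chromaticity_difference(field)
        manual = (
            np.hypot(u[0, 0] - u[0, 1], v[0, 0] - v[0, 1])
            + np.hypot(u[0, 0] - u[1, 0], v[0, 0] - v[1, 0])
            + np.hypot(u[0, 0] - u[1, 1], v[0, 0] - v[1, 1])
        ) / 3
        assert hm[0, 0] == pytest.approx(manual, abs=1e-15)

    def test_degenerate_shapes_rejected(self):
        field = ChromaLumImage(
            np.zeros((1, 5)), np.zeros((1, 5)), np.ones((1, 5))
        )
        with pytest.raises(ValueError):
            local_chromaticity_difference(field)


class TestImageMetric:
    def test_uniform_image_metric_zero(self):
        img = np.full((300, 300, 3), 0.42)
        assert average_chromaticity_difference(img) == 0.0

    def test_constant_chromaticity_varying_luminance_is_zero(self, rng):
        # per-pixel scaling of one linear-RGB color: chromaticity constant
        from chromastress.colorspace import decode_srgb, encode_srgb

        base = decode_srgb(np.full((32, 32, 3), [0.8, 0.5, 0.3]))
        scale = rng.uniform(0.2, 1.0, (32, 32, 1))
        img = encode_srgb(base * scale)
        assert average_chromaticity_difference(img) < 1e-6

    def test_large_checkerboard_approaches_half_pair_distance(self):
        img = make_two_color_image((1, 0, 0), (0, 1, 0), "checkerboard", 256)
        f = rgb_to_chromalum(img)
        d = pair_distance(
            (f.u_prime[0, 0], f.v_prime[0, 0]),
            (f.u_prime[0, 1], f.v_prime[0, 1]),
        )
        m = average_chromaticity_difference(img)
        assert m == pytest.approx(d / 2, rel=0.01)

    def test_stripes_interior_is_six_eighths(self):
        img = make_two_color_image((0, 0, 1), (1, 1, 0), "stripes", 64)
        f = rgb_to_chromalum(img)
        d = pair_distance(
            (f.u_prime[0, 0], f.v_prime[0, 0]),
            (f.u_prime[0, 1], f.v_prime[0, 1]),
        )
        hm = local_chromaticity_difference(f)
        assert np.allclose(hm[1:-1, 1:-1], 6 * d / 8, atol=1e-12)

    def test_resize_applied_above_256(self, rng):
        # a 512-wide 1-pixel checkerboard collapses to a constant image
        # under the odd-row/odd-column subsampling rule
        img = make_two_color_image((1, 0, 0), (0, 1, 0), "checkerboard", 512)
        assert average_chromaticity_difference(img) == pytest.approx(0.0)
        assert average_chromaticity_difference(img, resize=False) > 0.1

    def test_metric_invariant_to_luminance_permutation(self, rng):
        u = rng.uniform(0.1, 0.4, (10, 10))
        v = rng.uniform(0.3, 0.6, (10, 10))
        lum_a = rng.uniform(0.1, 0.9, (10, 10))
        lum_b = rng.permutation(lum_a.ravel()).reshape(10, 10)
        fa = ChromaLumImage(u, v, lum_a)
        fb = ChromaLumImage(u, v, lum_b)
        assert field_average_difference(fa) == field_average_difference(fb)


class TestFieldInvariances:
    def test_affine_scaling_multiplies_metric(self, random_field, rng):
        pivot = (0.25, 0.45)
        base = field_average_difference(random_field)
        for s in (0.3, 1.7):
            scaled = ChromaLumImage(
                pivot[0] + s * (random_field.u_prime - pivot[0]),
                pivot[1] + s * (random_field.v_prime - pivot[1]),
                random_field.lum,
            )
            assert field_average_difference(scaled) == pytest.approx(
                s * base, rel=1e-12
            )

    def test_rigid_rotation_leaves_metric_unchanged(self, random_field):
        base = field_average_difference(random_field)
        for theta in (0.4, 2.0, np.pi):
            c, s = np.cos(theta), np.sin(theta)
            du = random_field.u_prime - 0.3
            dv = random_field.v_prime - 0.4
            rot = ChromaLumImage(
                0.3 + c * du - s * dv, 0.4 + s * du + c * dv,
                random_field.lum,
            )
            assert field_average_difference(rot) == pytest.approx(
                base, rel=1e-12
            )


class TestHistogram:
    def test_all_zero_heatmap_mass_in_first_bin(self):
        edges, counts, mean = heatmap_histogram(np.zeros((8, 8)), 10)
        assert counts[0] == 64 and counts[1:].sum() == 0
        assert mean == 0.0

    def test_counts_conserved(self, rng):
        hm = rng.uniform(0, 0.1, (17, 23))
        _, counts, _ = heatmap_histogram(hm, 7)
        assert counts.sum() == 17 * 23

    def test_two_value_heatmap_proportions(self):
        hm = np.concatenate([np.zeros(30), np.full(10, 0.5)])
        hm = hm.reshape(4, 10)
        _, counts, _ = heatmap_histogram(hm, 2)
        assert counts.tolist() == [30, 10]
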