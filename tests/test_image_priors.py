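"""Image-to-prior construction: capping, aggregation, quantile mapping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gist import (
    ImageRaster,
    PatchProbabilityMap,
    SpotGeometry,
    ValidationError,
    beta_shapes,
    cap_and_rescale,
    patch_map_to_spots,
    prior_from_values,
    quantile_map,
    spot_mean_intensity,
)


class TestCapAndRescale:
    def test_printed_0_to_100_sequence(self):
        img = ImageRaster(np.arange(101.0).reshape(1, 101))
        out = cap_and_rescale(img, low_pct=1, high_pct=99).pixels.ravel()
        # percentiles of 0..100 are exact: p1 = 1, p99 = 99
        assert out.max() == 1.0
        assert out[0] == 0.0  # 0 < p1 -> zeroed
        np.testing.assert_allclose(out[100], 1.0)  # 100 capped to 99, /99
        np.testing.assert_allclose(out[50], 50 / 99)

    def test_constant_positive_image_maps_to_ones(self):
        out = cap_and_rescale(ImageRaster(np.full((4, 5), 3.7)))
        np.testing.assert_array_equal(out.pixels, np.ones((4, 5)))

    def test_all_zero_image_unchanged(self):
        out = cap_and_rescale(ImageRaster(np.zeros((3, 3))))
        np.testing.assert_array_equal(out.pixels, np.zeros((3, 3)))

    def test_invalid_percentile_order(self):
        with pytest.raises(ValidationError):
            cap_and_rescale(ImageRaster(np.ones((2, 2))), low_pct=50, high_pct=10)

    @pytest.mark.parametrize("seed", range(4))
    def test_idempotent_on_own_output(self, seed):
        rng = np.random.default_rng(seed)
        img = ImageRaster(rng.gamma(2.0, 10.0, (40, 40)))
        once = cap_and_rescale(img)
        twice = cap_and_rescale(once)
        np.testing.assert_allclose(twice.pixels, once.pixels, atol=1e-12)


def _brute_force_spot_mean(pixels, center, radius):
    total, count = 0.0, 0
    for r in range(pixels.shape[0]):
        for c in range(pixels.shape[1]):
            if (r - center[0]) ** 2 + (c - center[1]) ** 2 <= radius**2:
                total += pixels[r, c]
                count += 1
    return total / count if count else 0.0


class TestSpotMeanIntensity:
    def test_uniform_image_gives_uniform_values(self):
        img = ImageRaster(np.full((50, 50), 0.42))
        geom = SpotGeometry(["s1", "s2"], [[10, 10], [30, 30]], 5.0)
        vals = spot_mean_intensity(img, geom)
        np.testing.assert_allclose(vals.values, 0.42)

    def test_disk_indicator_image(self):
        pixels = np.zeros((60, 60))
        rr, cc = np.mgrid[0:60, 0:60]
        pixels[(rr - 20) ** 2 + (cc - 20) ** 2 <= 64] = 1.0
        geom = SpotGeometry(["in", "out"], [[20, 20], [45, 45]], 8.0)
        vals = spot_mean_intensity(ImageRaster(pixels), geom)
        assert vals.values[0] == 1.0
        assert vals.values[1] == 0.0

    def test_single_pixel_disk(self):
        pixels = np.arange(16.0).reshape(4, 4) / 16.0
        geom = SpotGeometry(["s"], [[2, 3]], 0.5)
        vals = spot_mean_intensity(ImageRaster(pixels), geom)
        assert vals.values[0] == pixels[2, 3]

    def test_spot_outside_image_is_zero(self):
        geom = SpotGeometry(["far"], [[500, 500]], 3.0)
        vals = spot_mean_intensity(ImageRaster(np.ones((10, 10))), geom)
        assert vals.values[0] == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_pixel_loop(self, seed):
        rng = np.random.default_rng(seed)
        shape = (rng.integers(16, 64), rng.integers(16, 64))
        pixels = rng.random(shape)
        n_spots = rng.integers(1, 6)
        centers = np.column_stack(
            [rng.uniform(-5, shape[0] + 5, n_spots), rng.uniform(-5, shape[1] + 5, n_spots)]
        )
        radius = rng.uniform(0.5, 12.0)
        geom = SpotGeometry([f"s{j}" for j in range(n_spots)], centers, radius)
        vals = spot_mean_intensity(ImageRaster(pixels), geom)
        expected = [_brute_force_spot_mean(pixels, c, radius) for c in centers]
        np.testing.assert_allclose(vals.values, expected, atol=1e-9)


def _brute_force_patch_value(patches, center, radius, shape):
    total, weight = 0.0, 0
    for r in range(shape[0]):
        for c in range(shape[1]):
            if (r - center[0]) ** 2 + (c - center[1]) ** 2 > radius**2:
                continue
            for r0, c0, h, w, prob in patches:
                if r0 <= r < r0 + h and c0 <= c < c0 + w:
                    total += prob
                    weight += 1
    return total / weight if weight else 0.0


class TestPatchMapToSpots:
    def test_single_covering_patch(self):
        pm = PatchProbabilityMap([(0, 0, 100, 100, 0.8)])
        geom = SpotGeometry(["s"], [[50, 50]], 10.0)
        np.testing.assert_allclose(patch_map_to_spots(pm, geom).values, [0.8])

    def test_two_equal_overlap_patches_average(self):
        # patches split the plane at column 30; spot disk centered on the
        # boundary overlaps both by the same pixel count
        pm = PatchProbabilityMap([(0, 0, 60, 30, 0.0), (0, 30, 60, 30, 1.0)])
        geom = SpotGeometry(["s"], [[30, 29.5]], 6.0)
        np.testing.assert_allclose(patch_map_to_spots(pm, geom).values, [0.5])

    def test_spot_outside_all_patches_is_zero(self):
        pm = PatchProbabilityMap([(0, 0, 10, 10, 0.9)])
        geom = SpotGeometry(["s"], [[100, 100]], 4.0)
        assert patch_map_to_spots(pm, geom).values[0] == 0.0

    def test_probability_outside_unit_interval_rejected(self):
        with pytest.raises(ValidationError):
            PatchProbabilityMap([(0, 0, 10, 10, 1.4)])

    def test_values_bounded_by_patch_probabilities(self):
        rng = np.random.default_rng(0)
        patches = [
            (float(rng.integers(0, 40)), float(rng.integers(0, 40)),
             float(rng.integers(5, 15)), float(rng.integers(5, 15)),
             float(rng.random()))
            for _ in range(8)
        ]
        pm = PatchProbabilityMap(patches)
        geom = SpotGeometry(
            [f"s{j}" for j in range(4)], rng.uniform(0, 50, (4, 2)), 7.0
        )
        vals = patch_map_to_spots(pm, geom).values
        probs = [p[4] for p in patches]
        for v in vals:
            if v > 0:
                assert min(probs) <= v <= max(probs)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_overlap_oracle(self, seed):
        rng = np.random.default_rng(seed)
        patches = [
            (float(rng.integers(0, 30)), float(rng.integers(0, 30)),
             float(rng.integers(4, 12)), float(rng.integers(4, 12)),
             float(rng.random()))
            for _ in range(5)
        ]
        pm = PatchProbabilityMap(patches)
        centers = rng.uniform(0, 40, (3, 2))
        radius = rng.uniform(2, 8)
        geom = SpotGeometry([f"s{j}" for j in range(3)], centers, radius)
        vals = patch_map_to_spots(pm, geom).values
        shape = (60, 60)
        expected = [_brute_force_patch_value(patches, c, radius, shape) for c in centers]
        np.testing.assert_allclose(vals, expected, atol=1e-9)


class TestQuantileMap:
    def test_identity_when_source_equals_target(self):
        rng = np.random.default_rng(1)
        x = rng.random(25)
        np.testing.assert_allclose(quantile_map(x, x), x, atol=1e-12)

    def test_rank_preserving_reassignment(self):
        out = quantile_map(np.array([0.1, 0.2, 0.3]), np.array([0.5, 0.7, 0.9]))
        np.testing.assert_allclose(out, [0.5, 0.7, 0.9])

    def test_all_ties_map_to_target_median(self):
        target = np.array([0.1, 0.4, 0.9, 0.2, 0.6])
        out = quantile_map(np.full(5, 0.3), target)
        np.testing.assert_allclose(out, np.median(target))

    def test_output_distribution_equals_target(self):
        rng = np.random.default_rng(2)
        source = rng.random(40)  # continuous, no ties
        target = rng.gamma(2.0, 1.0, 40)
        out = quantile_map(source, target)
        np.testing.assert_allclose(np.sort(out), np.sort(target), atol=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_monotone_in_source(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 30))
        source = rng.random(n).round(1)  # ties likely
        target = rng.normal(size=n)
        out = quantile_map(source, target)
        order = np.argsort(source, kind="stable")
        assert np.all(np.diff(out[order]) >= -1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            quantile_map(np.ones(3), np.ones(4))


class TestBetaShapes:
    def test_mean_half_concentration_50(self):
        assert beta_shapes(0.5, 50) == (25.0, 25.0)

    def test_mean_tenth_concentration_10(self):
        a, b = beta_shapes(0.1, 10)
        np.testing.assert_allclose([a, b], [1.0, 9.0])

    def test_interior_mean_required(self):
        with pytest.raises(ValidationError):
            beta_shapes(1.0, 10)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.floats(min_value=1e-3, max_value=1 - 1e-3),
        st.floats(min_value=1e-3, max_value=1e4),
    )
    def test_beta_mean_and_concentration_recovered(self, tau, lam):
        a, b = beta_shapes(tau, lam)
        assert a > 0 and b > 0
        np.testing.assert_allclose(a / (a + b), tau, rtol=1e-12)
        np.testing.assert_allclose(a + b, lam, rtol=1e-12)


def test_prior_from_values_clamps_to_interior():
    prior = prior_from_values(np.array([0.0, 0.5, 1.0]), "neuron", lam=50.0)
    assert prior.tau[0] == 1e-4
    assert prior.tau[2] == 1 - 1e-4
    assert prior.lam == 50.0
    assert prior.target_types == ("neuron",)
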