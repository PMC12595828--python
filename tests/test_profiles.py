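"""Profile extraction, background subtraction, region metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gcxquant import (
    IntensityProfile,
    band_mask_along_surface,
    extract_line_profile,
    labeled_region_areas,
    positivity_rate,
    region_mean_intensity,
    subtract_background,
)

PX = 0.1


class TestIntensityProfile:
    def test_rejects_short_or_nonuniform(self):
        with pytest.raises(ValueError, match="at least"):
            IntensityProfile(np.arange(5) * 0.1, np.ones(5))
        x = np.arange(20) * 0.1
        x[10] += 0.03
        with pytest.raises(ValueError, match="uniform"):
            IntensityProfile(x, np.ones(20))

    def test_intensities_clamped_non_negative(self):
        p = IntensityProfile(np.arange(20) * 0.1, np.linspace(-5, 5, 20))
        assert p.intensities.min() == 0.0

    def test_csv_round_trip(self, tmp_path):
        p = IntensityProfile(np.arange(20) * 0.1, np.arange(20.0), "lectin")
        path = tmp_path / "p.csv"
        p.to_csv(path)
        q = IntensityProfile.from_csv(path, channel="lectin")
        np.testing.assert_allclose(q.intensities, p.intensities)


class TestExtractLineProfile:
    def test_uniform_image_gives_constant_profile(self):
        img = np.full((40, 40), 50.0)
        (prof,) = extract_line_profile(img, PX, (0.2, 2.0), (3.5, 2.0))
        assert np.allclose(prof.intensities, 50.0)
        assert prof.positions[0] == 0.0

    def test_averaging_width_irrelevant_without_transverse_variation(self):
        img = np.tile(np.linspace(0, 90, 40), (40, 1))  # varies along x only
        p0, p1 = (0.5, 2.0), (3.2, 2.0)
        (a,) = extract_line_profile(img, PX, p0, p1, averaging_width=1)
        (b,) = extract_line_profile(img, PX, p0, p1, averaging_width=5)
        np.testing.assert_allclose(a.intensities, b.intensities, atol=1e-9)

    def test_translation_equivariance_whole_pixels(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 100, (60, 60))
        shifted = np.roll(img, (3, 5), axis=(0, 1))
        (a,) = extract_line_profile(img, PX, (0.5, 1.0), (3.0, 1.0))
        (b,) = extract_line_profile(shifted, PX, (0.5 + 5 * PX, 1.0 + 3 * PX),
                                    (3.0 + 5 * PX, 1.0 + 3 * PX))
        np.testing.assert_allclose(a.intensities, b.intensities, atol=1e-9)

    def test_short_line_rejected(self):
        img = np.zeros((40, 40))
        with pytest.raises(ValueError, match="need >= 16"):
            extract_line_profile(img, PX, (1.0, 1.0), (1.5, 1.0))

    def test_endpoint_outside_image_rejected(self):
        img = np.zeros((40, 40))
        with pytest.raises(ValueError, match="outside"):
            extract_line_profile(img, PX, (1.0, 1.0), (10.0, 1.0))


class TestSubtractBackground:
    def test_constant_subtraction(self):
        p = IntensityProfile(np.arange(16) * 0.1, np.linspace(30, 40, 16))
        q = subtract_background(p, "constant", 10.0)
        np.testing.assert_allclose(q.intensities, p.intensities - 10.0)
        np.testing.assert_array_equal(q.positions, p.positions)

    def test_percentile_on_constant_profile_zeroes_and_warns(self):
        p = IntensityProfile(np.arange(16) * 0.1, np.full(16, 7.0))
        with pytest.warns(UserWarning, match="all zero"):
            q = subtract_background(p, "percentile", 5.0)
        assert np.all(q.intensities == 0.0)

    def test_constant_idempotent_when_positive(self):
        p = IntensityProfile(np.arange(16) * 0.1, np.linspace(30, 40, 16))
        q1 = subtract_background(p, "constant", 0.0)
        q2 = subtract_background(q1, "constant", 0.0)
        np.testing.assert_array_equal(q1.intensities, q2.intensities)

    def test_invalid_args(self):
        p = IntensityProfile(np.arange(16) * 0.1, np.ones(16))
        with pytest.raises(ValueError):
            subtract_background(p, "percentile", 80.0)
        with pytest.raises(ValueError):
            subtract_background(p, "constant", -1.0)


class TestRegionMetrics:
    def test_constant_region(self):
        img = np.full((10, 10), 7.0)
        mask = np.zeros((10, 10), bool)
        mask[2:5, 2:5] = True
        m = region_mean_intensity(img, mask, "gcx_band")
        assert m.mean_intensity == 7.0 and m.pixel_count == 9

    def test_half_and_half(self):
        img = np.zeros((4, 10))
        img[:, 5:] = 10.0
        m = region_mean_intensity(img, np.ones((4, 10), bool))
        assert m.mean_intensity == pytest.approx(5.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            region_mean_intensity(np.ones((4, 4)), np.zeros((4, 4), bool))


class TestBandMask:
    def test_straight_surface_area_matches_rectangle(self):
        # horizontal surface through a 100x200 image at y = 5 µm; 17-µm band
        poly = np.array([[0.0, 5.0], [199 * PX, 5.0]])
        mask = band_mask_along_surface(poly, (300, 200), PX, band_width=17.0,
                                       side="parenchymal")
        expected = 17.0 / PX * 200  # rows in band × cols
        assert abs(mask.sum() - expected) < 2 * 200  # ± one boundary row each side

    def test_zero_width_empty(self):
        poly = np.array([[0.0, 2.0], [5.0, 2.0]])
        assert band_mask_along_surface(poly, (50, 50), PX, 0.0).sum() == 0

    def test_band_stays_on_one_side(self):
        poly = np.array([[0.0, 2.5], [4.9, 2.5]])
        par = band_mask_along_surface(poly, (50, 50), PX, 1.0, side="parenchymal")
        lum = band_mask_along_surface(poly, (50, 50), PX, 1.0, side="luminal")
        assert not np.any(par & lum)
        rows_par = np.nonzero(par.any(axis=1))[0]
        rows_lum = np.nonzero(lum.any(axis=1))[0]
        assert rows_par.min() > rows_lum.max()  # parenchyma below the surface

    def test_degenerate_polyline_rejected(self):
        with pytest.raises(ValueError):
            band_mask_along_surface(np.array([[1.0, 1.0], [1.0, 1.0]]), (20, 20), PX, 1.0)


class TestPositivityRate:
    def test_examples(self):
        assert positivity_rate([1, 2, 3], 10.0) == 0.0
        assert positivity_rate([1, 2, 3, 4, 5, 6, 7, 8, 11, 12], 10.0) == 20.0

    def test_ties_count_negative(self):
        assert positivity_rate([5.0, 5.0, 6.0], 5.0) == pytest.approx(100.0 / 3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            positivity_rate([], 1.0)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 100), min_size=1, max_size=30),
           st.floats(0, 100), st.floats(0, 100))
    def test_monotone_nonincreasing_in_threshold(self, vals, t1, t2):
        lo, hi = sorted((t1, t2))
        assert positivity_rate(vals, lo) >= positivity_rate(vals, hi)

    def test_two_population_rates_recovered(self):
        """Binomial simulation at the observed cytoplasmic positivity rates."""
        rng = np.random.default_rng(42)
        for rate in (0.0297, 0.2030):
            n = 4000
            values = np.where(rng.uniform(size=n) < rate, 50.0, 1.0)
            est = positivity_rate(values, 10.0)
            mc_err = 100 * 3 * np.sqrt(rate * (1 - rate) / n)
            assert abs(est - 100 * rate) < mc_err


class TestLabeledRegionAreas:
    def test_single_blob_area(self):
        mask = np.zeros((30, 30), bool)
        mask[5:15, 5:15] = True
        (area,) = labeled_region_areas(mask, pixel_size=0.5)
        assert area == pytest.approx(100 * 0.25)  # 25 µm²

    def test_two_disjoint_blobs(self):
        mask = np.zeros((30, 30), bool)
        mask[2:6, 2:6] = True
        mask[20:26, 20:26] = True
        assert len(labeled_region_areas(mask, 1.0)) == 2

    def test_diagonal_touch_is_one_component(self):
        mask = np.zeros((10, 10), bool)
        mask[2:5, 2:5] = True
        mask[5:8, 5:8] = True  # touches only at the (4,4)/(5,5) diagonal
        assert len(labeled_region_areas(mask, 1.0)) == 1

    def test_min_area_filter_and_empty(self):
        mask = np.zeros((10, 10), bool)
        mask[0, 0] = True  # single pixel, below default min_area
        assert labeled_region_areas(mask, 1.0) == []
        assert labeled_region_areas(np.zeros((5, 5), bool), 1.0) == []
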