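"""Periphery band, quadrant folding, and the angular intensity profile."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import as_mask, rasterize_disk

from mitoshear.myosin_profile import (
    angular_profile,
    fold_angle,
    periphery_band,
    profile_contrast,
)
from mitoshear.segmentation import CellMask, ImageFrame, detect_cells, equivalent_ellipse
from mitoshear.spindle_tracking import spindle_from_plate
from mitoshear.synthgen import GeneratorConfig, simulate_if_cohort


class TestFoldAngle:
    @pytest.mark.parametrize(
        "alpha_off,expected", [(0.0, 0.0), (135.0, 45.0), (270.0, 90.0), (90.0, 90.0)]
    )
    def test_examples(self, alpha_off, expected):
        assert fold_angle(57.0 + alpha_off, 57.0) == pytest.approx(expected, abs=1e-9)

    @settings(derandomize=True, max_examples=200)
    @given(
        alpha=st.floats(-720, 720, allow_nan=False),
        theta0=st.floats(-720, 720, allow_nan=False),
    )
    def test_range_and_reflection_symmetry(self, alpha, theta0):
        f = fold_angle(alpha, theta0)
        assert 0.0 <= f <= 90.0
        # reflecting the input about theta0 leaves the folded angle unchanged
        assert fold_angle(2 * theta0 - alpha, theta0) == pytest.approx(f, abs=1e-6)


class TestPeripheryBand:
    def test_disk_band_area_matches_annulus(self):
        # 20 um disk at 0.5 um/px, 1 um band: area ~ pi (20^2 - 19^2) um^2
        mask = as_mask(rasterize_disk(40, shape=(128, 128)))
        band = periphery_band(mask, 1.0, 0.5)
        area_um2 = band.sum() * 0.5**2
        assert area_um2 == pytest.approx(np.pi * (20**2 - 19**2), rel=0.10)

    def test_wide_band_saturates_to_whole_mask(self):
        mask = as_mask(rasterize_disk(20, shape=(64, 64)))
        band = periphery_band(mask, 25.0, 1.0)
        assert np.array_equal(band, mask.pixels)

    def test_square_inset_against_bruteforce_distance(self):
        square = np.zeros((40, 40), bool)
        square[10:30, 10:30] = True
        band = periphery_band(as_mask(square), 3.0, 1.0)
        # oracle: explicit min distance to the complement for each pixel
        comp = np.argwhere(~square)
        for y, x in np.argwhere(square):
            d = np.min(np.hypot(comp[:, 0] - y, comp[:, 1] - x))
            assert band[y, x] == (d <= 3.0)

    def test_below_pixel_width_rejected(self):
        with pytest.raises(ValueError):
            periphery_band(as_mask(rasterize_disk(20, shape=(64, 64))), 0.4, 0.65)


class TestAngularProfile:
    def test_uniform_intensity_gives_flat_unit_profile(self):
        img = np.full((96, 96), 500.0)
        frame = ImageFrame(img, pixel_size_um=0.5)
        cells = [
            (frame, as_mask(rasterize_disk(30, shape=(96, 96))), th0, 10.0)
            for th0 in (0.0, 30.0, 77.0)
        ]
        prof = angular_profile(cells)
        assert np.allclose(prof.mean_norm_intensity, 1.0, atol=1e-9)

    def test_normalization_makes_body_mean_exactly_one(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(100, 900, size=(96, 96))
        mask = rasterize_disk(30, shape=(96, 96))
        assert np.mean(img[mask] / img[mask].mean()) == pytest.approx(1.0, abs=1e-12)

    def test_two_bin_means_match_hand_enumeration(self):
        """Tiny mask with hand-placed intensities vs explicit pixel loops."""
        mask = rasterize_disk(5, shape=(15, 15))
        rng = np.random.default_rng(8)
        img = rng.uniform(10, 100, size=(15, 15))
        frame = ImageFrame(np.pad(img, 9), pixel_size_um=1.0)  # pad to satisfy min size
        padded_mask = np.pad(mask, 9)
        theta0 = 20.0
        prof = angular_profile([(frame, as_mask(padded_mask), theta0, 10.0)], n_bins=2)
        # oracle: enumerate band pixels by hand
        from scipy.ndimage import distance_transform_edt

        edt = distance_transform_edt(padded_mask)
        band = padded_mask & (edt <= 1.0)
        ys, xs = np.nonzero(padded_mask)
        cy, cx = ys.mean(), xs.mean()
        body_mean = frame.pixels[padded_mask].mean()
        sums, counts = [0.0, 0.0], [0, 0]
        for y, x in np.argwhere(band):
            alpha = np.rad2deg(np.arctan2(y - cy, x - cx))
            d = (alpha - theta0) % 180.0
            f = d if d <= 90.0 else 180.0 - d
            b = 0 if f < 45.0 else 1
            sums[b] += frame.pixels[y, x] / body_mean
            counts[b] += 1
        expected = [s / c for s, c in zip(sums, counts)]
        assert prof.mean_norm_intensity == pytest.approx(expected, rel=1e-9)

    def test_elongation_filter_and_empty_error(self):
        img = np.full((96, 96), 500.0)
        frame = ImageFrame(img, pixel_size_um=0.5)
        cells = [(frame, as_mask(rasterize_disk(30, shape=(96, 96))), 0.0, 75.0)]
        with pytest.raises(ValueError, match="elongation"):
            angular_profile(cells, elongation_max_pct=60.0)

    def test_reference_mode_agreement_for_elongated_cells(self):
        """Body-axis and spindle-axis references give near-identical profiles."""
        cfg = GeneratorConfig(seed=17)
        stills = simulate_if_cohort(20, cfg, elongation_mean_pct=32.0, myosin_contrast=0.15, seed=17)
        by_body, by_spin = [], []
        for s in stills:
            m = detect_cells(s.myosin, include_rim=True)[0]
            ell = equivalent_ellipse(m)
            th_plate = spindle_from_plate(s.dna, m)
            by_body.append((s.myosin, m, ell.theta_cell_deg, ell.elongation_pct))
            by_spin.append((s.myosin, m, th_plate, ell.elongation_pct))
        p_body = angular_profile(by_body, reference_mode="cell_body")
        p_spin = angular_profile(by_spin, reference_mode="spindle")
        # peaks in the same (pole) bin within one bin shift
        assert abs(
            int(np.nanargmax(p_body.mean_norm_intensity))
            - int(np.nanargmax(p_spin.mean_norm_intensity))
        ) <= 1
        assert np.nanmax(np.abs(p_body.mean_norm_intensity - p_spin.mean_norm_intensity)) < 0.05

    def test_contrast_estimate_tracks_generator_setting(self):
        cfg = GeneratorConfig(seed=5)
        stills = simulate_if_cohort(25, cfg, myosin_contrast=0.2, seed=31)
        cells = []
        for s in stills:
            m = detect_cells(s.myosin, include_rim=True)[0]
            th0 = spindle_from_plate(s.dna, m)
            cells.append((s.myosin, m, th0, equivalent_ellipse(m).elongation_pct))
        est = profile_contrast(angular_profile(cells))
        assert est == pytest.approx(0.2, rel=0.2)
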