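"""Generator behavior: determinism, dynamics, monotone responses, spectra."""

import numpy as np
import pytest
from scipy import ndimage

from mitoshear.angles import axial_resultant, orientation_relative
from mitoshear.synthgen import (
    GeneratorConfig,
    ShearProtocol,
    render_cell,
    render_if_still,
    simulate_experiment,
    simulate_spectrum,
    steady_state_elongation,
)


@pytest.fixture(scope="module")
def quick_config():
    return GeneratorConfig(n_cells=8, n_frames=12, seed=42, anaphase_mean_s=1e6, anaphase_sd_s=1.0)


class TestProtocol:
    def test_switch_events_change_axis(self):
        p = ShearProtocol(strain_axis_deg=0.0, switch_events=((100.0, 90.0),))
        assert p.strain_axis_at(50.0) == 0.0
        assert p.strain_axis_at(150.0) == 90.0
        assert p.zero_force_at(150.0) == 0.0

    def test_invalid_protocols_rejected(self):
        with pytest.raises(ValueError):
            ShearProtocol(amplitude_gamma=-0.1)
        with pytest.raises(ValueError):
            ShearProtocol(switch_events=((100.0, 90.0), (100.0, 0.0)))


class TestRenderCell:
    def test_noise_free_circle_rim_is_one_closed_ring(self):
        frame = render_cell((128, 128, 30, 30, 0.0), None, noise_sd=0.0)
        from skimage.filters import threshold_otsu

        edges = frame.pixels > threshold_otsu(frame.pixels)
        n_components = ndimage.label(edges)[1]
        assert n_components == 1
        # the ring encloses a hole: filling changes the pixel count
        assert ndimage.binary_fill_holes(edges).sum() > edges.sum()

    def test_rim_is_brightest_structure(self):
        frame = render_cell((128, 128, 40, 25, 10.0), (20, 6, 10.0), noise_sd=0.0)
        assert frame.pixels.max() == pytest.approx(52000, abs=1)

    def test_cell_outside_frame_names_the_cell(self):
        with pytest.raises(ValueError, match="cell 7"):
            render_cell((10, 10, 30, 30, 0.0), None, shape=(64, 64), cell_index=7)


class TestDynamics:
    def test_bit_identical_for_fixed_seed(self, quick_config):
        p = ShearProtocol()
        m1, t1 = simulate_experiment(p, quick_config)
        m2, t2 = simulate_experiment(p, quick_config)
        assert all(np.array_equal(a.pixels, b.pixels) for a, b in zip(m1, m2))
        assert t1.frames.equals(t2.frames)
        assert t1.cells.equals(t2.cells)

    def test_zero_strain_keeps_baseline_elongation(self):
        p = ShearProtocol(amplitude_gamma=0.0, frequency_hz=0.0)
        cfg = GeneratorConfig(n_cells=30, n_frames=8, seed=9, anaphase_mean_s=1e6, anaphase_sd_s=1.0)
        _, truth = simulate_experiment(p, cfg)
        per_frame = truth.frames.groupby("frame").elongation_pct.mean()
        assert np.allclose(per_frame, 10.0, atol=1.5)

    def test_response_monotone_in_amplitude_and_frequency(self):
        cfg = GeneratorConfig()
        gammas = [0.0, 0.1, 0.3, 0.5, 1.0]
        e_gamma = [steady_state_elongation(g, 3.0, cfg) for g in gammas]
        assert all(b >= a for a, b in zip(e_gamma, e_gamma[1:]))
        freqs = [0.0, 0.01, 0.03, 0.1, 0.3, 3.0]
        e_freq = [steady_state_elongation(1.0, f, cfg) for f in freqs]
        assert all(b >= a for a, b in zip(e_freq, e_freq[1:]))

    def test_truth_angles_are_axial(self, quick_config):
        _, truth = simulate_experiment(ShearProtocol(), quick_config)
        th = truth.frames[["theta_cell_deg", "theta_spin_deg"]].to_numpy()
        th = th[~np.isnan(th)]
        assert np.all((th >= 0.0) & (th < 180.0))

    def test_switch_rotates_asymptotic_mean_by_90(self):
        p = ShearProtocol(
            amplitude_gamma=1.0, frequency_hz=0.3, strain_axis_deg=0.0,
            switch_events=((0.0, 90.0),),
        )
        cfg = GeneratorConfig(n_cells=30, n_frames=40, seed=7, anaphase_mean_s=1e6, anaphase_sd_s=1.0)
        _, truth = simulate_experiment(p, cfg)
        first = truth.frames[truth.frames.frame == 0].theta_cell_deg
        last = truth.frames[truth.frames.frame == 39].theta_cell_deg
        assert orientation_relative(first, 90.0).mean() < 10.0  # adapted to old axis
        assert orientation_relative(last, 0.0).mean() < 5.0  # settled on new axis

    def test_switch_relaxation_time_constant_matches_k_shape(self):
        """Exponential fit on truth recovers the generator's own rate."""
        p = ShearProtocol(
            amplitude_gamma=1.0, frequency_hz=0.3, strain_axis_deg=0.0,
            switch_events=((0.0, 90.0),),
        )
        cfg = GeneratorConfig(n_cells=44, n_frames=40, seed=7, anaphase_mean_s=1e6, anaphase_sd_s=1.0)
        _, truth = simulate_experiment(p, cfg)
        tf = truth.frames
        t_min, offsets = [], []
        for k in range(40):
            sub = tf[tf.frame == k]
            off = float(orientation_relative(sub.theta_cell_deg, 0.0).mean())
            if off > 5.0:
                t_min.append(k * cfg.frame_interval_s / 60.0)
                offsets.append(off)
        slope = np.polyfit(t_min, np.log(offsets), 1)[0]
        assert -slope == pytest.approx(cfg.k_shape_per_min, rel=0.25)

    def test_decoupled_spindle_is_uncorrelated_with_cell_axis(self):
        cfg = GeneratorConfig(
            n_cells=40, n_frames=10, seed=2, k_align_per_min=0.0,
            anaphase_mean_s=1e6, anaphase_sd_s=1.0,
        )
        _, truth = simulate_experiment(ShearProtocol(), cfg)
        last = truth.frames[truth.frames.frame == 9]
        diffs = np.asarray(last.theta_spin_deg) - np.asarray(last.theta_cell_deg)
        # Rayleigh-style: resultant below the p=0.05 critical value
        assert axial_resultant(diffs) < np.sqrt(-np.log(0.05) / len(diffs))

    def test_region_count_tracks_anaphases(self, small_movie):
        from mitoshear.pipeline import segment_movie

        protocol, config, frames, truth = small_movie
        masks = segment_movie(frames)
        dt = config.frame_interval_s
        for k in (0, len(frames) - 1):
            t = k * dt
            n_divided = int((truth.cells.anaphase_s <= t).sum())
            assert len(masks[k]) == config.n_cells + n_divided


class TestIFStills:
    def test_band_below_one_pixel_is_rejected(self):
        cfg = GeneratorConfig(pixel_size_um=2.0)
        with pytest.raises(ValueError, match="finer sampling"):
            render_if_still(30.0, 0.1, 0.0, cfg)

    def test_contrast_bounds_checked(self):
        cfg = GeneratorConfig()
        with pytest.raises(ValueError):
            render_if_still(30.0, 1.5, 0.0, cfg)

    def test_pole_band_brighter_than_equator_by_contrast(self):
        cfg = GeneratorConfig(intensity_noise=0.0)
        still = render_if_still(32.0, 0.1, 0.0, cfg)
        img = still.myosin.pixels.astype(float)
        cy = cx = img.shape[0] // 2
        # theta0 = 0: the pole lies along +x, the equator along +y
        pole_val = img[cy, cx:][img[cy, cx:] > 20000].max()
        eq_val = img[cy:, cx][img[cy:, cx] > 20000].max()
        assert pole_val / eq_val == pytest.approx(1.1, abs=0.02)


class TestSpectra:
    def test_fringe_period_matches_closed_form(self):
        tr = simulate_spectrum(10.0, noise_sd=0.0)
        nu = 1.0 / (tr.wavelength_nm / 1000.0)
        # count sign changes of the detrended signal: 2 per fringe
        y = tr.intensity - tr.intensity.mean()
        crossings = int(np.sum(np.diff(np.sign(y)) != 0))
        span = nu.max() - nu.min()
        expected = 2.0 * 2.0 * 1.33 * 10.0 * span
        assert crossings == pytest.approx(expected, abs=2)

    def test_doubling_gap_doubles_fringes(self):
        def n_crossings(h):
            tr = simulate_spectrum(h, noise_sd=0.0)
            y = tr.intensity - tr.intensity.mean()
            return int(np.sum(np.diff(np.sign(y)) != 0))

        assert n_crossings(10.0) == pytest.approx(2 * n_crossings(5.0), abs=3)

    def test_too_few_fringes_rejected(self):
        with pytest.raises(ValueError, match="unresolvable"):
            simulate_spectrum(0.5)
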