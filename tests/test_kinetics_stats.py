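"""Ensemble kinetics, rotation speeds, division statistics, Mann-Whitney."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from conftest import as_mask, rasterize_disk

from mitoshear.angles import wrap_axial
from mitoshear.kinetics_stats import (
    DivisionAngleSample,
    angle_vs_elongation,
    division_angle_histogram,
    ensemble_timecourse,
    mann_whitney_u,
    onset_cumulative,
    reflected_angles,
    rotation_speed,
)
from mitoshear.segmentation import EquivalentEllipse
from mitoshear.spindle_tracking import CellTrack, SpindleDetection, TrackRecord


def make_track(times, theta_spin, theta_cell=None, elong=30.0, cell_id=0):
    recs = []
    for i, t in enumerate(times):
        tc = theta_cell[i] if theta_cell is not None else theta_spin[i]
        ell = EquivalentEllipse(50.0, 50.0, 17 * (1 + elong / 100.0), 17.0, wrap_axial(tc))
        sp = SpindleDetection(50.0, 50.0, wrap_axial(theta_spin[i]), 150, i, cell_id)
        recs.append(
            TrackRecord(i, t, as_mask(rasterize_disk(17, shape=(48, 48))), ell, sp)
        )
    return CellTrack(cell_id, recs)


class TestEnsembleTimecourse:
    def test_axial_mean_wraps_correctly(self):
        ts = np.arange(0.0, 100.0, 20.0)
        tr1 = make_track(ts, [10.0] * 5, cell_id=0)
        tr2 = make_track(ts, [170.0] * 5, cell_id=1)
        table = ensemble_timecourse([tr1, tr2])
        assert np.allclose(table.theta_spin_mean, 0.0, atol=1e-6)

    def test_constant_elongation_mean_and_sd(self):
        ts = np.arange(0.0, 100.0, 20.0)
        tracks = [make_track(ts, [40.0] * 5, elong=10.0, cell_id=i) for i in range(4)]
        table = ensemble_timecourse(tracks)
        assert np.allclose(table.elongation_mean, 10.0, atol=1e-9)
        assert np.allclose(table.elongation_sd, 0.0, atol=1e-9)

    def test_mean_invariant_under_adding_180(self):
        ts = np.arange(0.0, 100.0, 20.0)
        base = [make_track(ts, [30.0] * 5, cell_id=0), make_track(ts, [50.0] * 5, cell_id=1)]
        flipped = [make_track(ts, [210.0] * 5, cell_id=0), make_track(ts, [50.0] * 5, cell_id=1)]
        t1 = ensemble_timecourse(base)
        t2 = ensemble_timecourse(flipped)
        assert np.allclose(t1.theta_spin_mean, t2.theta_spin_mean, atol=1e-9)

    def test_empty_overlap_raises(self):
        with pytest.raises(ValueError):
            ensemble_timecourse([make_track([0.0], [10.0])])


class TestRotationSpeed:
    def test_noiseless_ramp_to_four_significant_figures(self):
        ts = np.arange(0.0, 300.0, 20.0)
        th = 10.0 + 9.0 * ts / 60.0  # 9 deg/min away from the strain axis at 0
        rec = rotation_speed(make_track(ts, th), 0.0)
        assert rec.rotation_speed_deg_per_min == pytest.approx(9.0, rel=1e-4)

    def test_frozen_spindle_has_zero_speed(self):
        ts = np.arange(0.0, 300.0, 20.0)
        rec = rotation_speed(make_track(ts, [37.0] * len(ts)), 0.0)
        assert rec.rotation_speed_deg_per_min == pytest.approx(0.0, abs=1e-12)

    def test_drift_toward_strain_is_negative(self):
        ts = np.arange(0.0, 300.0, 20.0)
        th = 80.0 - 9.0 * ts / 60.0
        rec = rotation_speed(make_track(ts, th), 0.0)
        assert rec.rotation_speed_deg_per_min == pytest.approx(-9.0, rel=1e-4)

    def test_too_few_detections_names_the_cell(self):
        ts = np.array([0.0, 20.0])
        with pytest.raises(ValueError, match="cell 0"):
            rotation_speed(make_track(ts, [10.0, 11.0]), 0.0)


class TestReflectedAngles:
    @pytest.mark.parametrize("theta,expected", [(90.0, 0.0), (30.0, 60.0), (0.0, 90.0)])
    def test_examples(self, theta, expected):
        assert reflected_angles([theta])[0] == pytest.approx(expected)

    def test_uniform_maps_to_uniform(self):
        rng = np.random.default_rng(12)
        refl = reflected_angles(rng.uniform(0.0, 180.0, 10_000))
        stat = sps.kstest(refl / 90.0, "uniform")
        assert stat.pvalue > 0.01

    @settings(derandomize=True, max_examples=100)
    @given(theta=st.floats(0, 180, exclude_max=True, allow_nan=False))
    def test_reflection_symmetry_about_90(self, theta):
        a = reflected_angles([theta])[0]
        b = reflected_angles([wrap_axial(180.0 - theta)])[0]
        assert a == pytest.approx(b, abs=1e-9)


class TestMannWhitney:
    def test_worked_example(self):
        u, p = mann_whitney_u([1, 2], [3, 4], mode="exact")
        assert u == 0.0
        assert p == pytest.approx(1.0 / 3.0)

    def test_identical_samples_give_p_one(self):
        u, p = mann_whitney_u([5, 6, 7], [5, 6, 7], mode="exact")
        assert p == 1.0

    def test_exact_limit_enforced(self):
        with pytest.raises(ValueError, match="normal"):
            mann_whitney_u(np.arange(12), np.arange(12), mode="exact")

    def test_exact_matches_bruteforce_oracle(self):
        """Tie-aware exact p equals a naive full-enumeration oracle."""
        rng = np.random.default_rng(99)
        for _ in range(100):
            n, m = rng.integers(1, 8, size=2)
            pooled_vals = rng.integers(0, 6, size=n + m).astype(float)  # ties likely
            a, b = pooled_vals[:n], pooled_vals[n:]
            u_obs, p_obs = mann_whitney_u(a, b, mode="exact")

            def u_stat(x, y):
                return sum(
                    1.0 if xi > yi else 0.5 if xi == yi else 0.0 for xi in x for yi in y
                )

            pooled = list(pooled_vals)
            center = n * m / 2.0
            null = []
            for idx in itertools.combinations(range(n + m), n):
                ga = [pooled[i] for i in idx]
                gb = [pooled[i] for i in range(n + m) if i not in idx]
                null.append(u_stat(ga, gb))
            p_oracle = np.mean(
                [abs(u - center) >= abs(u_obs - center) - 1e-9 for u in null]
            )
            assert u_obs == pytest.approx(u_stat(a, b))
            assert p_obs == pytest.approx(p_oracle, abs=1e-12)

    def test_exact_matches_scipy_on_continuous_data(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a = rng.normal(size=6)
            b = rng.normal(0.8, 1.0, size=7)
            u, p = mann_whitney_u(a, b, mode="exact")
            ref = sps.mannwhitneyu(a, b, method="exact")
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_normal_mode_close_to_scipy_asymptotic(self):
        rng = np.random.default_rng(21)
        a = rng.normal(size=40)
        b = rng.normal(0.5, 1.0, size=35)
        _, p = mann_whitney_u(a, b, mode="normal")
        ref = sps.mannwhitneyu(a, b, method="asymptotic")
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


class TestDivisionAngles:
    def test_all_perpendicular_gives_fraction_one(self):
        s = DivisionAngleSample(np.full(20, 90.0))
        _, frac = division_angle_histogram(s, 30.0)
        assert frac == 1.0

    def test_uniform_angles_give_window_measure(self):
        rng = np.random.default_rng(1)
        s = DivisionAngleSample(rng.uniform(0, 180, 20_000))
        _, frac = division_angle_histogram(s, 30.0)
        assert frac == pytest.approx(1.0 / 6.0, abs=0.01)

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            division_angle_histogram(DivisionAngleSample([90.0]), 0.0)


class TestOnsetCumulative:
    def test_single_step_cdf(self):
        tracks = [make_track([0.0, 20.0], [10.0, 10.0], cell_id=i) for i in range(3)]
        for tr in tracks:
            tr.anaphase_onset_s = 1800.0
            tr.censored = False
        cdf, frac = onset_cumulative(tracks)
        assert frac == 1.0
        assert set(cdf.onset_s) == {1800.0}
        assert cdf.cum_fraction.iloc[-1] == 1.0

    def test_lognormal_round_trip(self):
        rng = np.random.default_rng(44)
        mean, sd = 3600.0, 2400.0
        sigma2 = np.log(1 + (sd / mean) ** 2)
        mu = np.log(mean) - sigma2 / 2
        onsets = rng.lognormal(mu, np.sqrt(sigma2), size=200)
        tracks = []
        for i, o in enumerate(onsets):
            tr = make_track([0.0, 20.0], [10.0, 10.0], cell_id=i)
            tr.anaphase_onset_s = float(o)
            tr.censored = False
            tracks.append(tr)
        cdf, _ = onset_cumulative(tracks, horizon_s=np.inf)
        stat = sps.kstest(cdf.onset_s, sps.lognorm(np.sqrt(sigma2), scale=np.exp(mu)).cdf)
        assert stat.pvalue > 0.01

    def test_half_censored_fraction(self):
        tracks = []
        for i in range(10):
            tr = make_track([0.0, 20.0], [10.0, 10.0], cell_id=i)
            if i < 5:
                tr.anaphase_onset_s = 1000.0
                tr.censored = False
            tracks.append(tr)
        _, frac = onset_cumulative(tracks)
        assert frac == 0.5


class TestAngleVsElongation:
    def test_coupled_cohort_concentrates_below_20_deg(self, small_tracks):
        protocol, config, truth, tracks = small_tracks
        table = angle_vs_elongation(tracks)
        strong = table[table.elongation_pct > 25.0]
        assert len(strong) > 10
        assert (strong.angle_diff_deg < 20.0).mean() > 0.9

    def test_decoupled_angles_are_uniform(self):
        rng = np.random.default_rng(0)
        ts = np.arange(0.0, 200.0, 20.0)
        tracks = [
            make_track(
                ts, rng.uniform(0, 180, ts.size), theta_cell=rng.uniform(0, 180, ts.size),
                cell_id=i,
            )
            for i in range(60)
        ]
        table = angle_vs_elongation(tracks)
        stat = sps.kstest(table.angle_diff_deg / 90.0, "uniform")
        assert stat.pvalue > 0.01

    def test_round_cells_show_no_significant_bias(self):
        """Below ~10% elongation the spindle is random wrt the body axis."""
        from mitoshear.pipeline import build_tracks, segment_movie
        from mitoshear.synthgen import GeneratorConfig, ShearProtocol, simulate_experiment

        protocol = ShearProtocol(amplitude_gamma=0.0, frequency_hz=0.0)
        config = GeneratorConfig(
            n_cells=25, n_frames=8, seed=6, anaphase_mean_s=1e6, anaphase_sd_s=1.0
        )
        frames, _ = simulate_experiment(protocol, config)
        tracks = build_tracks(frames, segment_movie(frames))
        table = angle_vs_elongation(tracks)
        # one independent sample per cell (frames within a cell are highly
        # correlated): take each cell's last pre-anaphase row
        sub = table[table.elongation_pct < 10.0].groupby("cell_id").last()
        assert len(sub) >= 10
        rng = np.random.default_rng(11)
        _, p = mann_whitney_u(
            sub.angle_diff_deg.to_numpy(), rng.uniform(0, 90, 500), mode="normal"
        )
        assert p > 0.05
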