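"""Synthetic data emulating dynamic-shear experiments on confined mitotic cells.

The generator produces the three kinds of raw data the analysis pipeline
consumes, together with ground-truth records for parameter-recovery tests:

* **time-lapse movies** of bright-rimmed, near-elliptic mitotic cells that
  elongate along the zero-force direction (perpendicular to the shear
  displacement), align their spindle with the cell long axis, and split
  into two daughter regions at anaphase;
* **two-channel immunofluorescence stills** (myosin periphery band + DNA
  metaphase plate) with a controlled pole/equator intensity excess;
* **reflected-intensity spectra** from the two plates bounding the shear
  chamber, periodic in the wavenumber with a period set by the plate gap.

Model, in brief.  Steady-state elongation saturates with both strain
amplitude gamma and frequency f:

    E(gamma, f) = E_base + E_max * gamma^n / (gamma_half^n + gamma^n)
                         * f / (f_half + f)

The cell long axis relaxes exponentially toward the zero-force direction at
rate ``k_shape_per_min`` and the spindle axis relaxes toward the cell long
axis at rate ``k_align_per_min``, each with additive Gaussian angle noise.
Anaphase onset times are log-normal; the division axis is the spindle axis
at onset, and anaphase is rendered as two separating daughter regions.
All angles are axial, in [0, 180) degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .angles import axial_difference, wrap_axial
from .optics_geometry import SpectrumTrace
from .segmentation import ImageFrame

__all__ = [
    "ShearProtocol",
    "GeneratorConfig",
    "GroundTruth",
    "IFStill",
    "render_cell",
    "simulate_experiment",
    "render_if_still",
    "simulate_if_cohort",
    "simulate_spectrum",
]

# Rendered intensity levels (uint16 counts). The rim is the brightest
# structure, as in phase contrast where the edge of a round cell is very
# bright; the interior is darker than the background.
LEVEL_BACKGROUND = 12000
LEVEL_INTERIOR = 6000
LEVEL_SPINDLE = 30000
LEVEL_RIM = 52000
FULL_SCALE = 65535

#: rim half-widths in px: the ring straddles the true contour, mostly outward,
#: so the enclosed hole closely matches the true cell interior.
_RIM_OUT = 2.0
_RIM_IN = 0.5


@dataclass(frozen=True)
class ShearProtocol:
    """Shear-stimulation protocol applied to the chamber.

    ``amplitude_gamma`` is the dimensionless shear strain gamma = dy / h
    (plate displacement over plate gap); ``strain_axis_deg`` is the
    direction of plate translation in image coordinates, so the zero-force
    direction (no imposed force) is ``strain_axis_deg + 90``.
    ``switch_events`` is a time-ordered list of (time_s, new_strain_axis_deg)
    rotations of the force direction.
    """

    amplitude_gamma: float = 1.0
    frequency_hz: float = 0.3
    strain_axis_deg: float = 0.0
    switch_events: tuple = ()
    gap_um: float = 10.0

    def __post_init__(self) -> None:
        if self.amplitude_gamma < 0:
            raise ValueError("amplitude_gamma must be >= 0")
        if self.frequency_hz < 0:
            raise ValueError("frequency_hz must be >= 0")
        if self.gap_um <= 0:
            raise ValueError("gap_um must be positive")
        times = [t for t, _ in self.switch_events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("switch_events must be strictly increasing in time")
        object.__setattr__(self, "switch_events", tuple((float(t), float(a)) for t, a in self.switch_events))

    def strain_axis_at(self, time_s: float) -> float:
        axis = self.strain_axis_deg
        for t, new_axis in self.switch_events:
            if time_s >= t:
                axis = new_axis
        return wrap_axial(axis)

    def zero_force_at(self, time_s: float) -> float:
        return wrap_axial(self.strain_axis_at(time_s) + 90.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic experiment.

    Rates are per minute; times in seconds; lengths in micrometres unless
    suffixed ``_px``.  The defaults reproduce the study conditions: 20 s
    frame interval, ~10 % baseline elongation, saturating elongation
    response (E_max 45 %, gamma_half 0.4, Hill exponent 2, f_half 0.1 Hz),
    shape relaxation 0.5 / min and spindle alignment 2 / min.
    """

    n_cells: int = 20
    n_frames: int = 60
    field_shape_px: tuple | None = None  # (rows, cols); derived from n_cells if None
    pixel_size_um: float = 0.65
    frame_interval_s: float = 20.0
    cell_radius_um: float = 10.0
    baseline_elongation_pct: float = 10.0
    e_max_pct: float = 45.0
    gamma_half: float = 0.4
    hill_n: float = 2.0
    f_half_hz: float = 0.1
    k_align_per_min: float = 2.0
    k_shape_per_min: float = 0.5
    anaphase_mean_s: float = 3600.0
    anaphase_sd_s: float = 2400.0
    angle_noise_deg: float = 2.0
    elongation_noise_pct: float = 1.0
    intensity_noise: float = 0.02
    myosin_contrast: float = 0.1
    #: spindle-shape coupling ramps linearly from 0 at the onset elongation
    #: to full strength at the saturation elongation: round cells present no
    #: shape cue, and the bias appears only above ~10 % elongation
    align_onset_elongation_pct: float = 10.0
    align_full_elongation_pct: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "pixel_size_um", "frame_interval_s", "cell_radius_um",
            "anaphase_mean_s", "anaphase_sd_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "baseline_elongation_pct", "e_max_pct", "gamma_half", "f_half_hz",
            "k_align_per_min", "k_shape_per_min", "angle_noise_deg",
            "elongation_noise_pct", "intensity_noise",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.hill_n < 1:
            raise ValueError("hill_n must be >= 1")
        if self.n_cells < 1 or self.n_frames < 1:
            raise ValueError("n_cells and n_frames must be >= 1")

    @property
    def cell_radius_px(self) -> float:
        return self.cell_radius_um / self.pixel_size_um

    @property
    def grid_spacing_px(self) -> float:
        return max(90.0, 5.8 * self.cell_radius_px)

    def resolved_field_shape(self) -> tuple[int, int]:
        if self.field_shape_px is not None:
            return tuple(int(v) for v in self.field_shape_px)
        cols = math.ceil(math.sqrt(self.n_cells))
        rows = math.ceil(self.n_cells / cols)
        s = self.grid_spacing_px
        return (int(rows * s + 20), int(cols * s + 20))

    def cell_positions(self) -> np.ndarray:
        """Deterministic grid of (cx, cy) centres, one per cell."""
        cols = math.ceil(math.sqrt(self.n_cells))
        s = self.grid_spacing_px
        pos = []
        for i in range(self.n_cells):
            r, c = divmod(i, cols)
            pos.append((10 + s * (c + 0.5), 10 + s * (r + 0.5)))
        return np.asarray(pos)


@dataclass
class GroundTruth:
    """Per-frame and per-cell truth records matching a generated movie.

    ``frames`` has one row per cell per frame (frame, time_s, cell_id, cx,
    cy, a_px, b_px, theta_cell_deg, theta_spin_deg, elongation_pct, phase,
    split_offset_px); ``cells`` has one row per cell (cell_id, anaphase_s,
    division_angle_deg, divides_in_movie).
    """

    frames: pd.DataFrame
    cells: pd.DataFrame


def steady_state_elongation(gamma: float, frequency_hz: float, config: GeneratorConfig) -> float:
    """Saturating amplitude/frequency response of the steady-state elongation (%)."""
    if gamma <= 0 or frequency_hz <= 0:
        return config.baseline_elongation_pct
    hill = gamma ** config.hill_n / (config.gamma_half ** config.hill_n + gamma ** config.hill_n)
    fsat = frequency_hz / (config.f_half_hz + frequency_hz)
    return config.baseline_elongation_pct + config.e_max_pct * hill * fsat


def _ellipse_q(X, Y, cx, cy, a, b, theta_deg):
    """Normalized ellipse quadratic form; <= 1 inside the (a, b) ellipse."""
    t = np.deg2rad(theta_deg)
    dx, dy = X - cx, Y - cy
    xr = dx * np.cos(t) + dy * np.sin(t)
    yr = -dx * np.sin(t) + dy * np.cos(t)
    return (xr / a) ** 2 + (yr / b) ** 2


def _paint_cell(canvas, cx, cy, a, b, theta_deg, spindle=None):
    """Draw one rimmed cell (optionally with a spindle blob) onto the canvas."""
    H, W = canvas.shape
    ext = a + _RIM_OUT + 2
    y0, y1 = max(0, int(cy - ext)), min(H, int(cy + ext) + 1)
    x0, x1 = max(0, int(cx - ext)), min(W, int(cx + ext) + 1)
    Y, X = np.mgrid[y0:y1, x0:x1]
    inner = _ellipse_q(X, Y, cx, cy, a - _RIM_IN, b - _RIM_IN, theta_deg) <= 1.0
    outer = _ellipse_q(X, Y, cx, cy, a + _RIM_OUT, b + _RIM_OUT, theta_deg) <= 1.0
    patch = canvas[y0:y1, x0:x1]
    patch[inner] = LEVEL_INTERIOR
    if spindle is not None:
        a_s, b_s, th_s = spindle
        blob = _ellipse_q(X, Y, cx, cy, a_s, b_s, th_s) <= 1.0
        patch[blob & inner] = LEVEL_SPINDLE
    patch[outer & ~inner] = LEVEL_RIM


def _spindle_axes(a: float, b: float) -> tuple[float, float]:
    # elongated interior blob, ~12 % of the cell area: recognisable by the
    # size window and long enough for a stable orientation estimate
    return 0.5 * a, max(2.5, 0.25 * b)


def render_cell(
    ellipse_params,
    spindle_params=None,
    shape=(256, 256),
    noise_sd: float = 0.0,
    seed=None,
    pixel_size_um: float = 1.0,
    time_s: float = 0.0,
    cell_index: int = 0,
) -> ImageFrame:
    """Render a single mitotic cell as a phase-contrast-like frame.

    ``ellipse_params`` is (cx, cy, a, b, theta_deg) in pixels/degrees;
    ``spindle_params`` an optional (a_s, b_s, theta_s) interior blob.  The
    rim (width ~2 px) is the brightest structure; the interior is darker
    than the background; ``noise_sd`` is additive Gaussian noise as a
    fraction of full scale.
    """
    cx, cy, a, b, theta = ellipse_params
    if a < 3 or b < 3:
        raise ValueError(f"cell {cell_index}: semi-axes must be >= 3 px (got a={a}, b={b})")
    H, W = shape
    ext = a + _RIM_OUT
    if cx - ext < 0 or cy - ext < 0 or cx + ext > W - 1 or cy + ext > H - 1:
        raise ValueError(f"cell {cell_index} does not fit inside the {shape} frame")
    canvas = np.full(shape, float(LEVEL_BACKGROUND), dtype=np.float64)
    _paint_cell(canvas, cx, cy, a, b, theta, spindle_params)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        canvas += rng.normal(0.0, noise_sd * FULL_SCALE, size=canvas.shape)
    pixels = np.clip(np.rint(canvas), 0, FULL_SCALE).astype(np.uint16)
    return ImageFrame(pixels=pixels, pixel_size_um=pixel_size_um, time_s=time_s, channel="phase")


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - 0.5 * sigma2
    return mu, math.sqrt(sigma2)


def simulate_experiment(protocol: ShearProtocol, config: GeneratorConfig):
    """Simulate a full shear time-lapse experiment.

    Returns ``(movie, truth)`` where ``movie`` is a list of phase-channel
    :class:`~mitoshear.segmentation.ImageFrame` (uint16) and ``truth`` a
    :class:`GroundTruth`.  Identical (protocol, config) yield bit-identical
    output; per-cell random substreams are derived from (seed, cell_id) so
    that adding cells does not perturb existing trajectories.
    """
    cfg = config
    dt = cfg.frame_interval_s
    dt_min = dt / 60.0
    shape = cfg.resolved_field_shape()
    positions = cfg.cell_positions()
    r_px = cfg.cell_radius_px
    e_target = steady_state_elongation(protocol.amplitude_gamma, protocol.frequency_hz, cfg)
    lam_shape = 1.0 - math.exp(-cfg.k_shape_per_min * dt_min)
    mu_ana, sg_ana = _lognormal_params(cfg.anaphase_mean_s, cfg.anaphase_sd_s)
    r_daughter = 0.62 * r_px
    movie_end = (cfg.n_frames - 1) * dt

    frame_rows = []
    cell_rows = []
    # states[cell] = per-frame (cx, cy, a, b, th_cell, th_spin, phase, offset)
    states = np.empty((cfg.n_cells, cfg.n_frames, 6), dtype=float)
    phases = np.empty((cfg.n_cells, cfg.n_frames), dtype=object)
    offsets = np.zeros((cfg.n_cells, cfg.n_frames), dtype=float)

    # with no strain (or a static one) there is no preferred in-plane
    # direction: orientations start uniform and the shape axis only drifts
    aligned = protocol.amplitude_gamma > 0 and protocol.frequency_hz > 0

    def _align_gain(elong_pct: float) -> float:
        lo, hi = cfg.align_onset_elongation_pct, cfg.align_full_elongation_pct
        if hi <= lo:
            return 1.0 if elong_pct >= hi else 0.0
        return float(np.clip((elong_pct - lo) / (hi - lo), 0.0, 1.0))

    for cid in range(cfg.n_cells):
        rng = np.random.default_rng([cfg.seed, cid])
        cx, cy = positions[cid]
        if aligned:
            # cells start adapted to the protocol's initial stimulation
            # direction (switch events act later)
            th_cell = wrap_axial(protocol.strain_axis_deg + 90.0 + rng.normal(0.0, 8.0))
        else:
            th_cell = rng.uniform(0.0, 180.0)
        elong_det = e_target  # noise-free elongation state, drives the coupling
        elong = max(0.0, e_target + rng.normal(0.0, cfg.elongation_noise_pct))
        if cfg.k_align_per_min > 0 and aligned and _align_gain(elong_det) > 0.5:
            th_spin = wrap_axial(th_cell + rng.normal(0.0, 4.0))
        else:
            th_spin = rng.uniform(0.0, 180.0)
        anaphase_s = float(rng.lognormal(mu_ana, sg_ana))
        if anaphase_s <= 0:
            raise ValueError(f"cell {cid}: anaphase time before the first frame")
        division_angle = np.nan

        for k in range(cfg.n_frames):
            t = k * dt
            R = 1.0 + elong / 100.0
            a = r_px * math.sqrt(R)
            b = r_px / math.sqrt(R)
            if t < anaphase_s:
                states[cid, k] = (cx, cy, a, b, th_cell, th_spin)
                phases[cid, k] = "metaphase"
                division_angle = th_spin  # axis frozen at the last metaphase state
            else:
                off = min(r_daughter + 3.0 + 2.0 * (t - anaphase_s) / dt, 25.0)
                states[cid, k] = (cx, cy, r_daughter, r_daughter, division_angle, np.nan)
                phases[cid, k] = "anaphase"
                offsets[cid, k] = off
            # advance dynamics toward the state at t + dt
            drift = 0.0
            if aligned:
                target = protocol.zero_force_at(t + dt)
                drift = lam_shape * axial_difference(target, th_cell)
            th_cell = wrap_axial(th_cell + drift + rng.normal(0.0, 0.5 * cfg.angle_noise_deg))
            elong_det = elong_det + lam_shape * (e_target - elong_det)
            elong = max(0.0, elong + lam_shape * (e_target - elong) + rng.normal(0.0, cfg.elongation_noise_pct))
            gain = _align_gain(elong_det) if cfg.k_align_per_min > 0 else 0.0
            lam_eff = 1.0 - math.exp(-cfg.k_align_per_min * gain * dt_min)
            th_spin = wrap_axial(
                th_spin
                + lam_eff * axial_difference(th_cell, th_spin)
                + rng.normal(0.0, cfg.angle_noise_deg)
            )

        cell_rows.append(
            dict(
                cell_id=cid,
                anaphase_s=anaphase_s,
                division_angle_deg=wrap_axial(division_angle),
                divides_in_movie=bool(anaphase_s <= movie_end),
            )
        )

    movie = []
    for k in range(cfg.n_frames):
        t = k * dt
        canvas = np.full(shape, float(LEVEL_BACKGROUND), dtype=np.float64)
        for cid in range(cfg.n_cells):
            cx, cy, a, b, th_c, th_s = states[cid, k]
            if phases[cid, k] == "metaphase":
                _paint_cell(canvas, cx, cy, a, b, th_c, spindle=(*_spindle_axes(a, b), th_s))
            else:
                off = offsets[cid, k]
                dxy = off * np.array([math.cos(math.radians(th_c)), math.sin(math.radians(th_c))])
                _paint_cell(canvas, cx + dxy[0], cy + dxy[1], a, b, th_c)
                _paint_cell(canvas, cx - dxy[0], cy - dxy[1], a, b, th_c)
            frame_rows.append(
                dict(
                    frame=k,
                    time_s=t,
                    cell_id=cid,
                    cx=cx,
                    cy=cy,
                    a_px=a,
                    b_px=b,
                    theta_cell_deg=th_c,
                    theta_spin_deg=th_s,
                    elongation_pct=(a / b - 1.0) * 100.0,
                    phase=phases[cid, k],
                    split_offset_px=offsets[cid, k],
                )
            )
        rng_frame = np.random.default_rng([cfg.seed, 999_983, k])
        if cfg.intensity_noise > 0:
            canvas += rng_frame.normal(0.0, cfg.intensity_noise * FULL_SCALE, size=canvas.shape)
        pixels = np.clip(np.rint(canvas), 0, FULL_SCALE).astype(np.uint16)
        movie.append(ImageFrame(pixels=pixels, pixel_size_um=cfg.pixel_size_um, time_s=t, channel="phase"))

    truth = GroundTruth(frames=pd.DataFrame(frame_rows), cells=pd.DataFrame(cell_rows))
    return movie, truth


# ---------------------------------------------------------------------------
# immunofluorescence-like stills

@dataclass
class IFStill:
    """A rendered two-channel immunofluorescence still with its truth."""

    myosin: ImageFrame
    dna: ImageFrame
    mask: np.ndarray  # bool, true cell region
    theta0_deg: float
    myosin_contrast: float
    elongation_pct: float


def render_if_still(
    elongation_pct: float,
    myosin_contrast: float,
    theta0_deg: float,
    config: GeneratorConfig,
    seed=None,
    band_width_um: float = 1.0,
) -> IFStill:
    """Render a metaphase cell as a myosin + DNA two-channel still.

    The myosin channel is a bright periphery band of width ``band_width_um``
    whose intensity along the contour is

        I(alpha) = I_base * (1 + c * (1 + cos 2(alpha - theta0)) / 2),

    so the pole (alpha = theta0) exceeds the equator by exactly the
    fractional contrast ``c``, plus a dim interior haze.  The DNA channel is
    a bright metaphase-plate bar perpendicular to ``theta0`` at the
    centroid.
    """
    from scipy import ndimage  # local import keeps module load light

    if abs(myosin_contrast) >= 1:
        raise ValueError("|myosin_contrast| must be < 1")
    if elongation_pct < 0:
        raise ValueError("elongation_pct must be >= 0")
    width_px = band_width_um / config.pixel_size_um
    if width_px < 1.0:
        raise ValueError(
            f"periphery band of {band_width_um} um is below 1 px at "
            f"{config.pixel_size_um} um/px; use finer sampling"
        )
    rng = np.random.default_rng(seed)
    r_px = config.cell_radius_px
    R = 1.0 + elongation_pct / 100.0
    a, b = r_px * math.sqrt(R), r_px / math.sqrt(R)
    n = int(2 * (a + 8))
    n = max(n, 64)
    cx = cy = n / 2.0
    Y, X = np.mgrid[0:n, 0:n]
    mask = _ellipse_q(X, Y, cx, cy, a, b, theta0_deg) <= 1.0
    edt = ndimage.distance_transform_edt(mask)
    band = mask & (edt <= width_px)
    alpha = np.rad2deg(np.arctan2(Y - cy, X - cx))
    modulation = 1.0 + myosin_contrast * (1.0 + np.cos(2.0 * np.deg2rad(alpha - theta0_deg))) / 2.0

    myo = np.full((n, n), 3000.0)
    myo[mask] = 9000.0
    myo[band] = 33000.0 * modulation[band]
    myo += rng.normal(0.0, config.intensity_noise * FULL_SCALE, size=myo.shape)
    myo_px = np.clip(np.rint(myo), 0, FULL_SCALE).astype(np.uint16)

    dna = np.full((n, n), 2000.0)
    bar = _ellipse_q(X, Y, cx, cy, 0.7 * b, max(1.5, 0.12 * b), theta0_deg + 90.0) <= 1.0
    dna[bar & mask] = 40000.0
    dna += rng.normal(0.0, config.intensity_noise * FULL_SCALE, size=dna.shape)
    dna_px = np.clip(np.rint(dna), 0, FULL_SCALE).astype(np.uint16)

    return IFStill(
        myosin=ImageFrame(myo_px, config.pixel_size_um, 0.0, "myosin"),
        dna=ImageFrame(dna_px, config.pixel_size_um, 0.0, "dna"),
        mask=mask,
        theta0_deg=wrap_axial(theta0_deg),
        myosin_contrast=myosin_contrast,
        elongation_pct=elongation_pct,
    )


def simulate_if_cohort(
    n_cells: int,
    config: GeneratorConfig,
    elongation_mean_pct: float = 32.0,
    elongation_sd_pct: float = 5.0,
    myosin_contrast: float | None = None,
    seed: int | None = None,
) -> list[IFStill]:
    """A cohort of stills with random orientations and jittered elongations.

    Defaults mirror the sheared cohort (mean elongation 32 % +/- 5 %); use
    ``elongation_mean_pct=10, elongation_sd_pct=1`` for a control-like one.
    """
    c = config.myosin_contrast if myosin_contrast is None else myosin_contrast
    base_seed = config.seed if seed is None else seed
    stills = []
    for i in range(n_cells):
        rng = np.random.default_rng([base_seed, 777, i])
        theta0 = rng.uniform(0.0, 180.0)
        elong = max(0.0, rng.normal(elongation_mean_pct, elongation_sd_pct))
        stills.append(
            render_if_still(elong, c, theta0, config, seed=np.random.default_rng([base_seed, 778, i]))
        )
    return stills


# ---------------------------------------------------------------------------
# interference spectra

def simulate_spectrum(
    gap_um: float,
    n_w: float = 1.33,
    wavelength_range_nm=(400.0, 800.0),
    n_samples: int = 400,
    noise_sd: float = 0.0,
    seed=None,
    i0: float = 1.0,
    fringe_amplitude: float = 0.5,
    phase_rad: float = 0.3,
) -> SpectrumTrace:
    """Two-beam interference spectrum reflected from the chamber plates.

    I(lambda) = I0 + B cos(4 pi n_w h / lambda + phi) + noise, sampled
    uniformly in wavelength.  The signal is exactly periodic in 1/lambda
    with period 1 / (2 n_w h); at least 3 fringes must fit in the range,
    otherwise the gap is unresolvable and an error is raised.
    """
    if gap_um <= 0:
        raise ValueError("gap_um must be positive")
    lo, hi = wavelength_range_nm
    if lo <= 0 or hi <= lo:
        raise ValueError("wavelength range must be positive and increasing")
    span_inv_um = 1000.0 / lo - 1000.0 / hi  # in 1/um
    n_fringes = 2.0 * n_w * gap_um * span_inv_um
    if n_fringes < 3:
        raise ValueError(
            f"only {n_fringes:.2f} fringes across {wavelength_range_nm} nm; "
            "gap unresolvable (need >= 3)"
        )
    lam_nm = np.linspace(lo, hi, n_samples)
    lam_um = lam_nm / 1000.0
    intensity = i0 + fringe_amplitude * np.cos(4.0 * np.pi * n_w * gap_um / lam_um + phase_rad)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise_sd, size=intensity.shape)
    return SpectrumTrace(wavelength_nm=lam_nm, intensity=np.clip(intensity, 0.0, None), n_w=n_w)
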