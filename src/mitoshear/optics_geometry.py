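"""Interferometric plate-gap estimation and ellipse curvature / Laplace law.

The shear chamber's plate gap h is measured from the spectrum of light
reflected by the two water-glass interfaces: for normal incidence the
intensity is periodic in the wavenumber 1/lambda with period 1/(2 n_w h),
where n_w = 1.33 is the refractive index of the aqueous medium.  Estimating
the dominant fringe period therefore yields h with micrometre accuracy for
visible-range spectra.

The geometry half interprets the myosin measurements: for a cortex shaped
as an ellipse with semi-axes a >= b, the contour curvature is maximal at
the poles (C_p = a / b^2) and minimal at the equator (C_e = b / a^2), so
C_p / C_e = (a/b)^3 — about 2 for a 30 %-elongated cell.  Under the Laplace
law dp = sigma * C with uniform pressure, tension would have to be *lower*
at the poles by that same factor, which a ~10 % myosin excess at the poles
cannot provide; the tension profile quantifies that discrepancy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SpectrumTrace",
    "GapEstimate",
    "CortexGeometry",
    "estimate_gap",
    "ellipse_curvature",
    "laplace_tension_profile",
]

WATER_REFRACTIVE_INDEX = 1.33


@dataclass(frozen=True)
class SpectrumTrace:
    """A reflected-intensity spectrum: wavelength (nm) vs intensity."""

    wavelength_nm: np.ndarray
    intensity: np.ndarray
    n_w: float = WATER_REFRACTIVE_INDEX

    def __post_init__(self) -> None:
        lam = np.asarray(self.wavelength_nm, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if lam.ndim != 1 or lam.size != inten.size:
            raise ValueError("wavelength and intensity must be 1-D arrays of equal length")
        if lam.size < 16:
            raise ValueError("need at least 16 spectral samples")
        if np.any(np.diff(lam) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(inten < 0):
            raise ValueError("intensity must be non-negative")
        object.__setattr__(self, "wavelength_nm", lam)
        object.__setattr__(self, "intensity", inten)


@dataclass(frozen=True)
class GapEstimate:
    """Result of the fringe-period analysis.

    ``h_um`` is None when the fringe contrast is too low to resolve a gap
    (``ok`` is False); ``period_inv_lambda_per_um`` is the fringe period in
    the 1/lambda variable (1/um) and ``quality`` the spectral peak
    prominence over the background.
    """

    h_um: float | None
    period_inv_lambda_per_um: float | None
    quality: float

    @property
    def ok(self) -> bool:
        return self.h_um is not None


def estimate_gap(
    trace: SpectrumTrace,
    quality_min: float = 8.0,
    oversample: int = 4,
    pad_factor: int = 8,
) -> GapEstimate:
    """Estimate the plate gap from the dominant fringe period.

    The spectrum is resampled uniformly in the wavenumber-like variable
    nu = 1/lambda, linearly detrended, Hann-windowed, and Fourier
    transformed (zero-padded ``pad_factor`` times); the dominant peak
    frequency f (in um) is refined by quadratic interpolation of the log
    power, giving h = f / (2 n_w).  A flat trace (no fringes) returns a
    failure result instead of a gap.
    """
    nu = 1.0 / (np.asarray(trace.wavelength_nm, float) / 1000.0)  # 1/um, decreasing
    nu, inten = nu[::-1], np.asarray(trace.intensity, float)[::-1]
    n = max(64, oversample * nu.size)
    nu_u = np.linspace(nu[0], nu[-1], n)
    y = np.interp(nu_u, nu, inten)
    # detrend (remove offset + slow background) and window
    coef = np.polyfit(nu_u, y, 1)
    y = y - np.polyval(coef, nu_u)
    # fringe-contrast floor: a flat trace has no fringes to measure
    mean_level = float(np.mean(np.abs(inten)))
    if mean_level <= 0 or float(np.std(y)) / max(mean_level, 1e-300) < 1e-3:
        return GapEstimate(None, None, 0.0)
    y = y * np.hanning(n)
    spec = np.abs(np.fft.rfft(y, n=pad_factor * n)) ** 2
    dnu = nu_u[1] - nu_u[0]
    freqs = np.fft.rfftfreq(pad_factor * n, d=dnu)  # cycles per (1/um) => um
    span = nu_u[-1] - nu_u[0]
    # ignore the DC/window lobe: require at least ~1.5 fringes across the span
    valid = freqs > 1.5 / span
    if not np.any(valid):
        return GapEstimate(None, None, 0.0)
    k0 = np.argmax(np.where(valid, spec, 0.0))
    background = np.median(spec[valid])
    quality = float(spec[k0] / background) if background > 0 else 0.0
    if quality < quality_min or k0 == 0 or k0 >= spec.size - 1:
        return GapEstimate(None, None, quality)
    # sub-bin refinement: quadratic fit through the log-power peak
    with np.errstate(divide="ignore"):
        lp = np.log(spec[k0 - 1 : k0 + 2])
    denom = lp[0] - 2.0 * lp[1] + lp[2]
    delta = 0.5 * (lp[0] - lp[2]) / denom if denom != 0 else 0.0
    f_peak = (k0 + float(np.clip(delta, -0.5, 0.5))) * freqs[1]
    h_um = f_peak / (2.0 * trace.n_w)
    return GapEstimate(float(h_um), float(1.0 / f_peak), quality)


# ---------------------------------------------------------------------------
# ellipse curvature and cortical tension

def ellipse_curvature(a: float, b: float, alpha_deg) -> np.ndarray | float:
    """Contour curvature (1/length) of an ellipse at position angle alpha.

    ``alpha_deg`` is the angular position of the contour point about the
    centre (0 = pole on the major axis, 90 = equator), consistent with the
    periphery-profile convention.  Internally the position angle is
    converted to the ellipse parameter t (x = a cos t, y = b sin t) and

        C(t) = a b / (a^2 sin^2 t + b^2 cos^2 t)^(3/2),

    giving C = a/b^2 at the pole and C = b/a^2 at the equator, hence the
    pole/equator ratio (a/b)^3.
    """
    if not (a >= b > 0):
        raise ValueError("require a >= b > 0")
    alpha = np.deg2rad(np.asarray(alpha_deg, dtype=float))
    t = np.arctan2(a * np.sin(alpha), b * np.cos(alpha))
    c = a * b / (a**2 * np.sin(t) ** 2 + b**2 * np.cos(t) ** 2) ** 1.5
    return c if c.ndim else float(c)


@dataclass(frozen=True)
class CortexGeometry:
    """In-plane cortex geometry of an elongated mitotic cell (um)."""

    semi_major_a_um: float
    semi_minor_b_um: float

    def __post_init__(self) -> None:
        if not (self.semi_major_a_um >= self.semi_minor_b_um > 0):
            raise ValueError("require a >= b > 0")

    def curvature(self, alpha_deg):
        return ellipse_curvature(self.semi_major_a_um, self.semi_minor_b_um, alpha_deg)

    def curvature_ratio(self) -> float:
        """Pole/equator curvature ratio, (a/b)^3."""
        return (self.semi_major_a_um / self.semi_minor_b_um) ** 3


def laplace_tension_profile(geometry: CortexGeometry, delta_p: float, alpha_deg=None):
    """Cortical tension sigma(alpha) = dp / C(alpha) under uniform pressure.

    For a 30 %-elongated ellipse the pole/equator tension ratio is
    (b/a)^3 ~ 0.455: uniform pressure predicts *less* tension at the poles,
    opposite in trend to the measured myosin excess there.
    """
    if delta_p <= 0:
        raise ValueError("delta_p must be positive")
    if alpha_deg is None:
        alpha_deg = np.linspace(0.0, 90.0, 91)
    return delta_p / geometry.curvature(alpha_deg)
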