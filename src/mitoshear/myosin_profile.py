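"""Quadrant-folded angular profiling of periphery (myosin) intensity.

Myosin II sits in a thin band under the cell edge, so its signal is
quantified in a 1 um wide periphery region of the cell mask.  Each band
pixel gets an angular position alpha about the cell centroid; because a
metaphase cell has two-fold symmetry and no chirality, angles are folded
into a single quadrant [0, 90] by reflecting about the reference axis
theta0 and about theta0 + 90 (0 = pole direction, 90 = equatorial plane).
Intensities are normalized by the mean intensity over the whole cell body,
binned per cell first, then averaged across cells, with the standard error
taken across cells.

The reference axis theta0 is either the cell-body orientation or the
spindle axis; round control cells have an ill-defined body axis, so the
spindle reference is the robust choice there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .segmentation import CellMask

__all__ = [
    "AngularProfile",
    "periphery_band",
    "fold_angle",
    "angular_profile",
    "profile_contrast",
]

log = logging.getLogger(__name__)

DEFAULT_N_BINS = 9  # 10-degree bins over [0, 90]
DEFAULT_ELONGATION_MAX_PCT = 60.0
DEFAULT_BAND_WIDTH_UM = 1.0


@dataclass(frozen=True)
class AngularProfile:
    """Cross-cell mean periphery intensity vs folded angle.

    ``mean_norm_intensity[i]`` is the average over cells of the per-cell
    mean band intensity in bin i, normalized per cell by its whole-body
    mean; ``se`` is the cross-cell standard error.
    """

    bin_centers_deg: np.ndarray
    mean_norm_intensity: np.ndarray
    se: np.ndarray
    n_cells: int
    reference_mode: str = "spindle"
    n_excluded: int = 0


def periphery_band(mask: CellMask, width_um: float, pixel_size_um: float) -> np.ndarray:
    """Band of mask pixels within ``width_um`` of the mask boundary.

    Computed from the Euclidean distance transform; the band is a subset of
    the mask and forms a closed ring for simply connected masks.  The
    returned boolean array is aligned with ``mask.pixels`` (the mask's crop
    window).
    """
    width_px = width_um / pixel_size_um
    if width_px < 1.0:
        raise ValueError(
            f"band width {width_um} um is below one pixel at {pixel_size_um} um/px"
        )
    edt = ndimage.distance_transform_edt(mask.pixels)
    band = mask.pixels & (edt <= width_px)
    if not band.any():
        raise ValueError("empty periphery band")
    return band


def fold_angle(alpha_deg, theta0_deg):
    """Fold an angular position into the quadrant [0, 90] about theta0.

    d = (alpha - theta0) mod 180, reflected about 90: the result is the
    distance to the pole direction, with 0 = pole and 90 = equator.
    """
    d = np.mod(np.asarray(alpha_deg, dtype=float) - theta0_deg, 180.0)
    folded = np.where(d <= 90.0, d, 180.0 - d)
    return folded if folded.ndim else float(folded)


def angular_profile(
    cells,
    n_bins: int = DEFAULT_N_BINS,
    elongation_max_pct: float = DEFAULT_ELONGATION_MAX_PCT,
    band_width_um: float = DEFAULT_BAND_WIDTH_UM,
    reference_mode: str = "spindle",
) -> AngularProfile:
    """Quadrant-folded periphery intensity profile averaged over cells.

    Parameters
    ----------
    cells
        Iterable of ``(frame, mask, theta0_deg, elongation_pct)`` where
        ``frame`` is the myosin-channel ImageFrame and ``theta0_deg`` the
        reference axis chosen per ``reference_mode``.
    n_bins
        Number of equal bins covering [0, 90].
    elongation_max_pct
        Cells at or above this elongation are excluded (guards against
        artefacts from extreme shapes); exclusions are logged and counted.

    Averaging is per cell first (each cell contributes one mean per bin,
    so large cells do not dominate), then across cells; ``se`` is the
    cross-cell standard error.
    """
    edges = np.linspace(0.0, 90.0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    per_cell = []
    n_excluded = 0
    for frame, mask, theta0, elong in cells:
        if elong >= elongation_max_pct:
            n_excluded += 1
            continue
        band = periphery_band(mask, band_width_um, frame.pixel_size_um)
        img = mask.crop_from(np.asarray(frame.pixels, dtype=float))
        body_mean = img[mask.pixels].mean()
        cx, cy = mask.centroid
        ys, xs = np.nonzero(band)
        alpha = np.rad2deg(
            np.arctan2(ys + mask.offset[0] - cy, xs + mask.offset[1] - cx)
        )
        folded = fold_angle(alpha, theta0)
        norm = img[ys, xs] / body_mean
        idx = np.clip(np.digitize(folded, edges) - 1, 0, n_bins - 1)
        sums = np.bincount(idx, weights=norm, minlength=n_bins)
        counts = np.bincount(idx, minlength=n_bins)
        with np.errstate(invalid="ignore"):
            per_cell.append(np.where(counts > 0, sums / np.maximum(counts, 1), np.nan))
    if not per_cell:
        raise ValueError(
            f"no cells below the elongation filter ({elongation_max_pct}%): "
            f"{n_excluded} excluded"
        )
    if n_excluded:
        log.info("angular_profile: excluded %d cells at elongation >= %.0f%%",
                 n_excluded, elongation_max_pct)
    arr = np.asarray(per_cell)
    mean = np.nanmean(arr, axis=0)
    n_eff = np.sum(~np.isnan(arr), axis=0)
    if arr.shape[0] > 1:
        with np.errstate(invalid="ignore"):
            se = np.nanstd(arr, axis=0, ddof=1) / np.sqrt(np.maximum(n_eff, 1))
        se = np.where(n_eff > 1, se, 0.0)
    else:
        se = np.zeros(n_bins)
    return AngularProfile(
        bin_centers_deg=centers,
        mean_norm_intensity=mean,
        se=se,
        n_cells=len(per_cell),
        reference_mode=reference_mode,
        n_excluded=n_excluded,
    )


def profile_contrast(profile: AngularProfile) -> float:
    """Fractional pole/equator intensity excess from a cos-2 fit.

    Fits mean(theta) ~ A + B cos(2 theta) over the bin centers by least
    squares and reports 2B / (A - B), the relative excess of the pole
    (theta = 0) over the equator (theta = 90).
    """
    x = np.cos(2.0 * np.deg2rad(profile.bin_centers_deg))
    good = ~np.isnan(profile.mean_norm_intensity)
    design = np.column_stack([np.ones(good.sum()), x[good]])
    coef, *_ = np.linalg.lstsq(design, profile.mean_norm_intensity[good], rcond=None)
    a_fit, b_fit = coef
    return float(2.0 * b_fit / (a_fit - b_fit))
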