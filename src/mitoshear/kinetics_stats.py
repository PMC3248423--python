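"""Kinetics and statistics of spindle orientation and cell division.

Turns per-cell tracks into the headline quantities of the shear
experiments: ensemble time courses of elongation and orientation around a
force-switch, signed spindle rotation speeds (positive = rotating away
from the strain axis), division-angle distributions with the fraction
dividing perpendicular to the force within a window, cumulative anaphase
onset histograms, and the Mann-Whitney U test on reflected angles
|theta - 90| used to compare conditions.

Angle reporting convention: division angles are measured with the strain
axis at 0 deg, so divisions along the zero-force direction peak at 90 deg
and the reflected statistic |theta - 90| is small for aligned divisions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .angles import (
    axial_difference,
    axial_mean,
    axial_std,
    orientation_relative,
    unwrap_axial,
    wrap_axial,
)

__all__ = [
    "RotationRecord",
    "DivisionAngleSample",
    "ensemble_timecourse",
    "rotation_speed",
    "reflected_angles",
    "mann_whitney_u",
    "division_angle_histogram",
    "onset_cumulative",
    "angle_vs_elongation",
]

EXACT_MW_LIMIT = 20  # hard ceiling for exact enumeration
EXACT_MW_DEFAULT = 16  # auto mode switches to normal above this total n
DEFAULT_ROTATION_WINDOW_S = 300.0  # 0-5 min after a force switch
DEFAULT_CENSOR_HORIZON_S = 7200.0  # 2 h observation window


@dataclass(frozen=True)
class RotationRecord:
    """Signed spindle rotation speed for one cell (deg/min)."""

    cell_id: int
    rotation_speed_deg_per_min: float
    window_used_s: float
    treatment_label: str = ""


@dataclass(frozen=True)
class DivisionAngleSample:
    """Division angles (axial, deg) for one experimental condition."""

    angles_deg: np.ndarray
    gamma: float = np.nan
    frequency_hz: float = np.nan
    coating: str = ""
    drug: str = ""

    def __post_init__(self) -> None:
        ang = wrap_axial(np.asarray(self.angles_deg, dtype=float))
        object.__setattr__(self, "angles_deg", ang)


def ensemble_timecourse(tracks, switch_time_s: float = 0.0) -> pd.DataFrame:
    """Mean +/- sd of elongation and orientations vs time across tracks.

    Angular quantities (cell axis, spindle axis) are averaged as axial
    means on the doubled angle, with the corresponding circular standard
    deviation; elongation is averaged arithmetically.  Times are reported
    relative to ``switch_time_s``.  Only time points covered by at least
    two tracks enter the table; an empty overlap is an error.
    """
    buckets: dict[float, dict[str, list]] = {}
    for tr in tracks:
        for rec in tr.pre_anaphase_records():
            b = buckets.setdefault(rec.time_s, {"elong": [], "tc": [], "ts": []})
            b["elong"].append(rec.ellipse.elongation_pct)
            b["tc"].append(rec.ellipse.theta_cell_deg)
            if rec.spindle is not None:
                b["ts"].append(rec.spindle.theta_spin_deg)
    rows = []
    for t in sorted(buckets):
        b = buckets[t]
        if len(b["elong"]) < 2:
            continue
        row = dict(
            time_s=t - switch_time_s,
            n=len(b["elong"]),
            elongation_mean=float(np.mean(b["elong"])),
            elongation_sd=float(np.std(b["elong"], ddof=1)),
            theta_cell_mean=float(axial_mean(b["tc"])),
            theta_cell_sd=float(axial_std(b["tc"])),
        )
        if len(b["ts"]) >= 2:
            row["theta_spin_mean"] = float(axial_mean(b["ts"]))
            row["theta_spin_sd"] = float(axial_std(b["ts"]))
        else:
            row["theta_spin_mean"] = np.nan
            row["theta_spin_sd"] = np.nan
        rows.append(row)
    if not rows:
        raise ValueError("no time point is covered by at least two tracks")
    return pd.DataFrame(rows)


def rotation_speed(
    track,
    strain_axis_deg: float,
    window_s: float = DEFAULT_ROTATION_WINDOW_S,
    switch_time_s: float = 0.0,
    treatment_label: str = "",
) -> RotationRecord:
    """Spindle rotation speed from a linear fit of the angle to the strain axis.

    The spindle series inside ``[switch_time_s, switch_time_s + window_s]``
    is unwrapped (axial 180-deg jumps removed) and expressed as a signed
    offset from the strain axis; the fitted slope of its magnitude, in
    deg/min, is positive when the spindle rotates *away* from the external
    strain and negative when it rotates towards it.
    """
    t, th = track.theta_spin_series()
    sel = (t >= switch_time_s) & (t <= switch_time_s + window_s)
    if sel.sum() < 3:
        raise ValueError(
            f"cell {track.cell_id}: only {int(sel.sum())} spindle detections "
            f"in the {window_s:.0f}s window (need >= 3)"
        )
    tt = (t[sel] - switch_time_s) / 60.0  # minutes
    u = unwrap_axial(th[sel])
    # signed offset from the strain axis, continuous across the window,
    # anchored so the first sample lies in (-90, 90]
    offset = axial_difference(u[0], strain_axis_deg) + (u - u[0])
    slope, _ = np.polyfit(tt, offset, 1)
    direction = np.sign(np.mean(offset)) or 1.0
    speed = float(slope * direction)
    return RotationRecord(
        cell_id=track.cell_id,
        rotation_speed_deg_per_min=speed,
        window_used_s=float(window_s),
        treatment_label=treatment_label,
    )


def reflected_angles(angles_deg) -> np.ndarray:
    """Reflect axial angles about 90 deg: |theta - 90| in [0, 90].

    With the strain axis at 0 deg, divisions perpendicular to the force
    (the 90-deg peak) map to small reflected values, making a one-sided
    comparison against a control interpretable.
    """
    ang = wrap_axial(np.asarray(angles_deg, dtype=float))
    return np.abs(ang - 90.0)


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U = #(a > b) pairs + half ties (scipy's U1 convention)."""
    diff = a[:, None] - b[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def mann_whitney_u(sample_a, sample_b, mode: str = "auto"):
    """Two-sided Mann-Whitney U test; exact enumeration for small samples.

    ``mode='exact'`` enumerates all C(n+m, n) assignments of the pooled
    values to the two groups (tie-aware; limited to n+m <= 20);
    ``mode='normal'`` uses the tie-corrected Gaussian approximation with
    continuity correction; ``'auto'`` picks exact for n+m <= 16.

    Returns ``(U, p)`` with U = #(a > b) pairs + half ties and p in (0, 1].
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    n, m = a.size, b.size
    if n == 0 or m == 0:
        raise ValueError("both samples must be non-empty")
    u_obs = _u_statistic(a, b)
    if mode == "auto":
        mode = "exact" if n + m <= EXACT_MW_DEFAULT else "normal"
    if mode == "exact":
        if n + m > EXACT_MW_LIMIT:
            raise ValueError(
                f"exact mode with n+m={n + m} > {EXACT_MW_LIMIT}; use mode='normal'"
            )
        pooled = np.concatenate([a, b])
        # midranks make U a pure function of which positions go to group a
        ranks = sps.rankdata(pooled)
        null_u = np.array([
            ranks[list(idx)].sum() - n * (n + 1) / 2.0
            for idx in itertools.combinations(range(n + m), n)
        ])
        center = n * m / 2.0
        p = float(np.mean(np.abs(null_u - center) >= abs(u_obs - center) - 1e-9))
        return u_obs, max(p, np.finfo(float).tiny)
    if mode == "normal":
        N = n + m
        _, tie_counts = np.unique(np.concatenate([a, b]), return_counts=True)
        tie_term = np.sum(tie_counts**3 - tie_counts) / (N * (N - 1.0))
        sigma2 = n * m / 12.0 * ((N + 1.0) - tie_term)
        if sigma2 <= 0:
            return u_obs, 1.0
        z = (abs(u_obs - n * m / 2.0) - 0.5) / math.sqrt(sigma2)
        p = float(min(1.0, 2.0 * sps.norm.sf(max(z, 0.0))))
        return u_obs, max(p, np.finfo(float).tiny)
    raise ValueError(f"unknown mode {mode!r}")


def division_angle_histogram(sample: DivisionAngleSample, window_deg: float = 30.0, n_bins: int = 18):
    """Histogram of division angles and the aligned fraction.

    Returns ``(hist_df, fraction_within_window)`` where the fraction counts
    reflected angles |theta - 90| <= window_deg / 2, i.e. divisions
    perpendicular to the force within the window.
    """
    if window_deg <= 0:
        raise ValueError("window_deg must be positive")
    ang = sample.angles_deg
    if ang.size == 0:
        raise ValueError("need at least one division angle")
    counts, edges = np.histogram(ang, bins=n_bins, range=(0.0, 180.0))
    hist = pd.DataFrame(
        dict(bin_left_deg=edges[:-1], bin_right_deg=edges[1:], count=counts)
    )
    frac = float(np.mean(reflected_angles(ang) <= window_deg / 2.0))
    return hist, frac


def onset_cumulative(tracks, horizon_s: float = DEFAULT_CENSOR_HORIZON_S):
    """Empirical CDF of anaphase-onset times plus the divided fraction.

    Censored tracks (no onset within the observation window) are excluded
    from the CDF but counted in the denominator of ``fraction_divided``.
    Returns ``(cdf_df, fraction_divided)``.
    """
    onsets = sorted(
        tr.anaphase_onset_s
        for tr in tracks
        if tr.anaphase_onset_s is not None and tr.anaphase_onset_s <= horizon_s
    )
    n_total = len(tracks)
    if not onsets:
        return pd.DataFrame(dict(onset_s=[], cum_fraction=[])), 0.0
    cdf = pd.DataFrame(
        dict(
            onset_s=onsets,
            cum_fraction=np.arange(1, len(onsets) + 1) / len(onsets),
        )
    )
    return cdf, len(onsets) / n_total


def angle_vs_elongation(tracks) -> pd.DataFrame:
    """Per-frame folded spindle-to-body angle vs cell elongation.

    One row per (cell, frame) before anaphase where both the cell axis and
    the spindle axis are available — the scatter that shows spindle capture
    by the long axis once elongation exceeds ~10-15 %.
    """
    rows = []
    for tr in tracks:
        for rec in tr.pre_anaphase_records():
            if rec.spindle is None:
                continue
            rows.append(
                dict(
                    cell_id=tr.cell_id,
                    time_s=rec.time_s,
                    elongation_pct=rec.ellipse.elongation_pct,
                    angle_diff_deg=float(
                        orientation_relative(
                            rec.ellipse.theta_cell_deg, rec.spindle.theta_spin_deg
                        )
                    ),
                )
            )
    return pd.DataFrame(rows)
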