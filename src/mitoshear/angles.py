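"""Axial-angle bookkeeping.

Cell-body orientations, spindle axes and division axes are headless (axial)
directions: ``theta`` and ``theta + 180`` name the same axis.  Every public
orientation in the package is therefore folded into [0, 180) degrees, and
averages are taken on the doubled angle so that 10 deg and 170 deg average
to 0 deg rather than 90 deg.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_axial",
    "axial_difference",
    "orientation_relative",
    "axial_mean",
    "axial_resultant",
    "axial_std",
    "unwrap_axial",
]


def wrap_axial(theta_deg):
    """Fold an angle (deg) into the axial range [0, 180).

    Guards the floating-point edge where ``mod`` of a tiny negative value
    rounds to exactly 180.
    """
    r = np.mod(theta_deg, 180.0)
    r = np.where(r >= 180.0, 0.0, r)
    return r if r.ndim else float(r)


def axial_difference(theta_deg, reference_deg):
    """Signed axial difference ``theta - reference`` folded into [-90, 90).

    The result is the smallest rotation (in degrees) carrying the reference
    axis onto ``theta``; sign follows the mathematical convention of the
    image coordinate frame.
    """
    return np.mod(np.asarray(theta_deg, dtype=float) - reference_deg + 90.0, 180.0) - 90.0


def orientation_relative(theta_deg, reference_deg):
    """Unsigned acute angle in [0, 90] between two axial directions.

    This is the angular difference used when comparing the spindle axis with
    the cell long axis: ``min(d, 180 - d)`` with ``d = |theta - ref| mod 180``.
    """
    return np.abs(axial_difference(theta_deg, reference_deg))


def _doubled(theta_deg):
    return np.deg2rad(np.asarray(theta_deg, dtype=float)) * 2.0


def axial_mean(theta_deg, axis=None):
    """Mean axial direction via the doubled-angle resultant, in [0, 180)."""
    d = _doubled(theta_deg)
    s = np.mean(np.sin(d), axis=axis)
    c = np.mean(np.cos(d), axis=axis)
    return wrap_axial(np.rad2deg(np.arctan2(s, c)) / 2.0)


def axial_resultant(theta_deg, axis=None):
    """Mean resultant length of the doubled angles (1 = perfectly aligned)."""
    d = _doubled(theta_deg)
    s = np.mean(np.sin(d), axis=axis)
    c = np.mean(np.cos(d), axis=axis)
    return np.hypot(s, c)


def axial_std(theta_deg, axis=None):
    """Circular standard deviation of axial data, in degrees.

    Computed on the doubled angle (``sqrt(-2 ln R)``) and halved, so for
    tightly clustered data it agrees with the ordinary standard deviation.
    """
    r = np.clip(axial_resultant(theta_deg, axis=axis), 1e-12, 1.0)
    return np.rad2deg(np.sqrt(-2.0 * np.log(r))) / 2.0


def unwrap_axial(theta_deg):
    """Unwrap a time series of axial angles into a continuous trajectory.

    Successive samples are shifted by multiples of 180 deg so that each step
    is the minimal axial difference; the result may leave [0, 180).
    """
    theta = np.asarray(theta_deg, dtype=float)
    if theta.ndim != 1:
        raise ValueError("unwrap_axial expects a 1-D series")
    out = np.empty_like(theta)
    if theta.size == 0:
        return out
    out[0] = theta[0]
    for i in range(1, theta.size):
        out[i] = out[i - 1] + axial_difference(theta[i], out[i - 1])
    return out
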