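"""Shared fixtures and rasterization helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from mitoshear.segmentation import CellMask


def rasterize_ellipse(a, b, theta_deg=0.0, shape=(256, 256), center=None):
    """Boolean mask of a filled ellipse (independent of the package's renderer)."""
    H, W = shape
    cy, cx = (H / 2.0, W / 2.0) if center is None else (center[1], center[0])
    Y, X = np.mgrid[0:H, 0:W]
    t = np.deg2rad(theta_deg)
    dx, dy = X - cx, Y - cy
    xr = dx * np.cos(t) + dy * np.sin(t)
    yr = -dx * np.sin(t) + dy * np.cos(t)
    return (xr / a) ** 2 + (yr / b) ** 2 <= 1.0


def rasterize_disk(r, shape=(256, 256), center=None):
    return rasterize_ellipse(r, r, 0.0, shape=shape, center=center)


def as_mask(bool_array, cell_id=0):
    return CellMask(pixels=bool_array, cell_id=cell_id)


@pytest.fixture(scope="session")
def small_movie():
    """A small sheared movie with divisions, shared across test modules."""
    from mitoshear.synthgen import GeneratorConfig, ShearProtocol, simulate_experiment

    protocol = ShearProtocol(amplitude_gamma=1.0, frequency_hz=0.3)
    config = GeneratorConfig(
        n_cells=6, n_frames=30, seed=123, anaphase_mean_s=350.0, anaphase_sd_s=80.0
    )
    frames, truth = simulate_experiment(protocol, config)
    return protocol, config, frames, truth


@pytest.fixture(scope="session")
def small_tracks(small_movie):
    """Tracks built from the small movie via the full pipeline stages."""
    from mitoshear.pipeline import build_tracks, segment_movie

    protocol, config, frames, truth = small_movie
    masks = segment_movie(frames)
    tracks = build_tracks(frames, masks)
    return protocol, config, truth, tracks
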