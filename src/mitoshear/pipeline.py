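"""End-to-end orchestration: simulate/read -> segment -> track -> stats.

Movies are numbered 16-bit grayscale TIFF (or PNG) sequences with a JSON
sidecar carrying physical metadata; tabular outputs are CSV, nested
summaries JSON.  Every run writes its resolved configuration next to its
outputs and logs every threshold used and every filtered or censored cell
count, because all the cohort sizes downstream depend on those filters.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import imageio.v3 as iio

from . import kinetics_stats as ks
from .angles import wrap_axial
from .segmentation import ImageFrame, detect_cells, equivalent_ellipse
from .spindle_tracking import CellTrack, TrackRecord, call_anaphase, detect_spindle, link_tracks
from .synthgen import GeneratorConfig, ShearProtocol, simulate_experiment

__all__ = [
    "RunConfig",
    "PipelineError",
    "run_pipeline",
    "read_stack",
    "write_stack",
    "write_table",
    "segment_movie",
    "build_tracks",
]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage-labelled pipeline failure."""


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run (JSON round-trippable)."""

    out_dir: str = "run"
    input_dir: str | None = None  # read a movie from here; None = simulate
    protocol: dict = field(default_factory=dict)  # ShearProtocol fields
    generator: dict = field(default_factory=dict)  # GeneratorConfig fields
    threshold_policy: str | float = "otsu"
    min_area_px: int = 200
    size_window: tuple = (0.02, 0.25)
    search_radius_frac: float = 0.5
    max_jump_px: float = 15.0
    window_deg: float = 30.0
    censor_horizon_s: float = 7200.0
    seed: int = 0
    log_level: str = "INFO"

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        d["size_window"] = tuple(d.get("size_window", (0.02, 0.25)))
        return cls(**d)


# ---------------------------------------------------------------------------
# stack I/O

_FRAME_RE = re.compile(r"(\d+)\.(tiff?|png)$", re.IGNORECASE)


def write_stack(frames, out_dir, protocol=None, config=None, extra_meta=None) -> Path:
    """Write frames as numbered 16-bit TIFFs plus a JSON metadata sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, fr in enumerate(frames):
        tifffile.imwrite(out / f"frame_{i:04d}.tif", np.asarray(fr.pixels, dtype=np.uint16))
    meta = {
        "pixel_size_um": frames[0].pixel_size_um,
        "frame_interval_s": (frames[1].time_s - frames[0].time_s) if len(frames) > 1 else 0.0,
        "channel": frames[0].channel,
        "n_frames": len(frames),
    }
    if protocol is not None:
        meta["protocol"] = dataclasses.asdict(protocol)
    if config is not None:
        meta["generator"] = dataclasses.asdict(config)
    if extra_meta:
        meta.update(extra_meta)
    (out / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return out


def read_stack(path, pixel_size_um=None, frame_interval_s=None, channel=None):
    """Read a numbered TIFF/PNG sequence (with optional sidecar) as frames.

    Frames are ordered by their numeric index; a gap in the numbering or
    mixed image sizes is an error.  Metadata comes from ``meta.json`` next
    to the images, with keyword overrides taking precedence; missing
    sidecar falls back to defaults with a logged warning.
    """
    p = Path(path)
    entries = []
    for f in sorted(p.iterdir()):
        m = _FRAME_RE.search(f.name)
        if m:
            entries.append((int(m.group(1)), f))
    if not entries:
        raise PipelineError(f"input: no numbered TIFF/PNG frames in {p}")
    entries.sort()
    indices = [i for i, _ in entries]
    expected = list(range(indices[0], indices[0] + len(indices)))
    if indices != expected:
        missing = sorted(set(expected) - set(indices))
        raise PipelineError(f"input: gap in frame numbering, missing indices {missing}")

    meta = {}
    sidecar = p / "meta.json"
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    else:
        log.warning("read_stack: no meta.json in %s, using defaults", p)
    px = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um", 1.0)
    dt = frame_interval_s if frame_interval_s is not None else meta.get("frame_interval_s", 1.0)
    chan = channel if channel is not None else meta.get("channel", "phase")

    frames = []
    shape = None
    for k, (idx, f) in enumerate(entries):
        try:
            if f.suffix.lower() in (".tif", ".tiff"):
                data = tifffile.imread(f)
            else:
                data = iio.imread(f)
        except Exception as exc:  # noqa: BLE001 - surface the frame index
            raise PipelineError(f"input: unreadable frame index {idx} ({f.name}): {exc}") from exc
        if shape is None:
            shape = data.shape
        elif data.shape != shape:
            raise PipelineError(
                f"input: mixed image sizes ({shape} vs {data.shape} at index {idx})"
            )
        frames.append(ImageFrame(pixels=data, pixel_size_um=px, time_s=k * dt, channel=chan))
    return frames


def write_table(df: pd.DataFrame, path) -> Path:
    """Canonical CSV writer (fixed float format, no index)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.6g")
    return path


# ---------------------------------------------------------------------------
# pipeline stages

def segment_movie(frames, threshold_policy="otsu", min_area_px=200):
    """Detect cells in every frame; returns per-frame lists of CellMask."""
    per_frame = []
    for i, fr in enumerate(frames):
        try:
            masks = detect_cells(fr, threshold_policy=threshold_policy, min_area_px=min_area_px)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"segmentation: failed at frame {i}: {exc}") from exc
        for m in masks:
            m.frame_index = i
        per_frame.append(masks)
    return per_frame


def build_tracks(
    frames,
    masks_per_frame,
    size_window=(0.02, 0.25),
    search_radius_frac=0.5,
    max_jump_px=15.0,
):
    """Spindle detection + linking + anaphase calling for a whole movie.

    Returns the list of tracks; each track that shows a persistent region
    split carries its onset time and division angle, and its records are
    truncated at onset (curves terminate at anaphase onset).
    """
    records_per_frame = []
    for i, (fr, masks) in enumerate(zip(frames, masks_per_frame)):
        recs = []
        for m in masks:
            ell = equivalent_ellipse(m)
            sp = detect_spindle(
                fr, m, size_window=size_window, search_radius_frac=search_radius_frac
            )
            recs.append(TrackRecord(frame_index=i, time_s=fr.time_s, mask=m, ellipse=ell, spindle=sp))
        records_per_frame.append(recs)
    tracks = link_tracks(records_per_frame, max_jump_px=max_jump_px)
    by_frame = {}
    for recs in records_per_frame:
        if recs:
            by_frame[recs[0].frame_index] = recs
    for tr in tracks:
        onset, angle = call_anaphase(tr, by_frame)
        if onset is not None:
            tr.anaphase_onset_s = onset
            tr.division_angle_deg = angle
            tr.censored = False
            tr.records = [r for r in tr.records if r.time_s < onset]
    return tracks


def tracks_to_tables(tracks, pixel_size_um: float, strain_axis_deg: float = 0.0):
    """Long-format track CSV rows plus a per-cell summary table."""
    rows, summary = [], []
    for tr in tracks:
        for rec in tr.records:
            rows.append(
                dict(
                    cell_id=tr.cell_id,
                    frame=rec.frame_index,
                    time_s=rec.time_s,
                    cx=rec.ellipse.cx,
                    cy=rec.ellipse.cy,
                    a_um=rec.ellipse.semi_major_a * pixel_size_um,
                    b_um=rec.ellipse.semi_minor_b * pixel_size_um,
                    elongation_pct=rec.ellipse.elongation_pct,
                    theta_cell_deg=rec.ellipse.theta_cell_deg,
                    theta_spin_deg=(
                        rec.spindle.theta_spin_deg if rec.spindle is not None else np.nan
                    ),
                )
            )
        division_rel = (
            wrap_axial(tr.division_angle_deg - strain_axis_deg)
            if tr.division_angle_deg is not None
            else np.nan
        )
        summary.append(
            dict(
                cell_id=tr.cell_id,
                n_records=len(tr.records),
                start_frame=tr.records[0].frame_index if tr.records else -1,
                onset_s=tr.anaphase_onset_s if tr.anaphase_onset_s is not None else np.nan,
                censored=tr.censored,
                division_angle_deg=division_rel,
            )
        )
    return pd.DataFrame(rows), pd.DataFrame(summary)


def run_pipeline(config: RunConfig) -> Path:
    """Run the full analysis and write all outputs into the run directory.

    Stages: input (simulate or read) -> segmentation -> tracking (spindle,
    linking, anaphase) -> statistics.  The run directory receives
    ``segmentation.csv``, ``tracks.csv``, ``cells.csv``, ``stats.json``,
    ``run.log`` and the resolved ``config.json``; the first fatal stage
    stops the pipeline with a stage-labelled error.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("mitoshear")
    root.addHandler(handler)
    root.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    try:
        (out / "config.json").write_text(config.to_json())

        # ---- input
        protocol = ShearProtocol(**{**config.protocol})
        if config.input_dir is None:
            gen = GeneratorConfig(**{**config.generator, "seed": config.seed})
            log.info("simulating: %d cells, %d frames, gamma=%.2f f=%.3g Hz",
                     gen.n_cells, gen.n_frames, protocol.amplitude_gamma, protocol.frequency_hz)
            frames, truth = simulate_experiment(protocol, gen)
            truth.frames.pipe(write_table, out / "truth_frames.csv")
            truth.cells.pipe(write_table, out / "truth_cells.csv")
        else:
            frames = read_stack(config.input_dir)
        if not frames:
            raise PipelineError("input: empty movie")

        # ---- segmentation
        masks_per_frame = segment_movie(
            frames, threshold_policy=config.threshold_policy, min_area_px=config.min_area_px
        )
        n_masks = sum(len(m) for m in masks_per_frame)
        log.info("segmentation: %d masks over %d frames", n_masks, len(frames))
        if n_masks == 0:
            raise PipelineError("segmentation: no cells found in any frame")

        # ---- tracking
        tracks = build_tracks(
            frames,
            masks_per_frame,
            size_window=tuple(config.size_window),
            search_radius_frac=config.search_radius_frac,
            max_jump_px=config.max_jump_px,
        )
        strain_axis = protocol.strain_axis_at(frames[-1].time_s)
        track_df, cell_df = tracks_to_tables(
            tracks, frames[0].pixel_size_um, strain_axis_deg=strain_axis
        )
        seg_rows = []
        for i, masks in enumerate(masks_per_frame):
            for m in masks:
                ell = equivalent_ellipse(m)
                seg_rows.append(
                    dict(
                        frame=i, cell_id=m.cell_id, cx=ell.cx, cy=ell.cy,
                        a_um=ell.semi_major_a * frames[0].pixel_size_um,
                        b_um=ell.semi_minor_b * frames[0].pixel_size_um,
                        theta_cell_deg=ell.theta_cell_deg,
                        elongation_pct=ell.elongation_pct,
                    )
                )
        write_table(pd.DataFrame(seg_rows), out / "segmentation.csv")
        write_table(track_df, out / "tracks.csv")
        write_table(cell_df, out / "cells.csv")
        n_censored = int(sum(tr.censored for tr in tracks))
        log.info("tracking: %d tracks, %d censored", len(tracks), n_censored)

        # ---- statistics
        founders = [tr for tr in tracks if tr.records and tr.records[0].frame_index == 0]
        div_angles = np.array(
            [
                wrap_axial(tr.division_angle_deg - strain_axis)
                for tr in founders
                if tr.division_angle_deg is not None
            ]
        )
        stats: dict = {
            "n_tracks": len(tracks),
            "n_founder_tracks": len(founders),
            "n_divided": int(div_angles.size),
            "angle_convention": "strain axis at 0 deg; zero-force direction at 90 deg",
        }
        cdf, frac_div = ks.onset_cumulative(founders, horizon_s=config.censor_horizon_s)
        stats["fraction_divided"] = frac_div
        write_table(cdf, out / "onset_cdf.csv")
        if div_angles.size:
            sample = ks.DivisionAngleSample(
                div_angles, gamma=protocol.amplitude_gamma, frequency_hz=protocol.frequency_hz
            )
            hist, frac_win = ks.division_angle_histogram(sample, window_deg=config.window_deg)
            write_table(hist, out / "division_angles.csv")
            stats["fraction_within_window"] = frac_win
            stats["window_deg"] = config.window_deg
            stats["median_reflected_angle_deg"] = float(
                np.median(ks.reflected_angles(div_angles))
            )
        (out / "stats.json").write_text(json.dumps(stats, indent=2, sort_keys=True))
        return out
    finally:
        root.removeHandler(handler)
        handler.close()
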