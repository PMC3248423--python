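"""Spindle detection, cell tracking, and anaphase calling.

The mitotic spindle appears as a bright, elongated blob around the cell
centroid and is found by thresholding the cell interior under two
constraints: the blob must lie near the centroid and its area must fall in
a configured window (fractions of the cell area).  Its orientation is the
major axis of its equivalent ellipse.  For immunofluorescence stills the
spindle axis is instead derived from the DNA channel, as the direction
perpendicular to the metaphase chromosome plate.

Detections are linked over time by greedy nearest-centroid assignment
(confined mitotic cells barely translate), and anaphase onset is called
when a cell's region splits into two comparably sized daughters that
persist; the division axis joins the daughter centroids at the first split
frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .angles import wrap_axial
from .segmentation import CellMask, EquivalentEllipse, ImageFrame, equivalent_ellipse

__all__ = [
    "SpindleDetection",
    "TrackRecord",
    "CellTrack",
    "detect_spindle",
    "spindle_from_plate",
    "link_tracks",
    "call_anaphase",
]

log = logging.getLogger(__name__)

DEFAULT_SIZE_WINDOW = (0.02, 0.25)  # blob area as a fraction of the cell area
DEFAULT_SEARCH_RADIUS_FRAC = 0.5  # of the cell semi-minor axis
DEFAULT_MAX_JUMP_PX = 15.0


@dataclass(frozen=True)
class SpindleDetection:
    """One spindle found inside a cell mask."""

    cx: float
    cy: float
    theta_spin_deg: float
    area_px: int
    frame_index: int = 0
    cell_id: int = -1


@dataclass
class TrackRecord:
    """One per-frame observation of a cell (mask + shape + spindle)."""

    frame_index: int
    time_s: float
    mask: CellMask
    ellipse: EquivalentEllipse
    spindle: SpindleDetection | None = None

    @property
    def centroid(self) -> tuple[float, float]:
        return self.ellipse.cx, self.ellipse.cy


@dataclass
class CellTrack:
    """Time-ordered records of one cell, up to (and including) anaphase.

    ``anaphase_onset_s`` is None while censored (movie ended before a
    split); ``division_angle_deg`` is the axis through the two daughter
    centroids at the first post-split frame.
    """

    cell_id: int
    records: list = field(default_factory=list)
    anaphase_onset_s: float | None = None
    censored: bool = True
    division_angle_deg: float | None = None

    def times(self) -> np.ndarray:
        return np.array([r.time_s for r in self.records])

    def theta_spin_series(self):
        """(times, angles) for records with a spindle detection."""
        t = [r.time_s for r in self.records if r.spindle is not None]
        th = [r.spindle.theta_spin_deg for r in self.records if r.spindle is not None]
        return np.asarray(t, float), np.asarray(th, float)

    def pre_anaphase_records(self) -> list:
        if self.anaphase_onset_s is None:
            return list(self.records)
        return [r for r in self.records if r.time_s < self.anaphase_onset_s]


def detect_spindle(
    frame: ImageFrame,
    mask: CellMask,
    size_window=DEFAULT_SIZE_WINDOW,
    search_radius_frac: float = DEFAULT_SEARCH_RADIUS_FRAC,
    threshold=None,
    min_contrast: float = 5.0,
) -> SpindleDetection | None:
    """Find the spindle blob inside a cell mask; missing is a value.

    Bright pixels of the eroded cell interior (2 px inward, excluding rim
    bleed) are thresholded (Otsu by default); connected blobs are kept if
    their area falls inside ``size_window`` (fractions of the cell area),
    their centroid lies within ``search_radius_frac * b`` of the cell
    centroid, and the blob stands out from the interior background by at
    least ``min_contrast`` robust standard deviations (guards against Otsu
    splitting pure noise when no spindle is present).  Returns None when no
    blob qualifies.
    """
    ell = equivalent_ellipse(mask)
    img = mask.crop_from(np.asarray(frame.pixels))
    edt = ndimage.distance_transform_edt(mask.pixels)
    interior = edt > 2.0
    vals = img[interior]
    if vals.size < 16 or np.ptp(vals) == 0:
        return None
    thr = float(threshold) if threshold is not None else float(threshold_otsu(vals))
    bright = interior & (img.astype(float) > thr)
    labels, n_lab = ndimage.label(bright)
    if n_lab == 0:
        return None
    area_cell = mask.area
    lo, hi = size_window[0] * area_cell, size_window[1] * area_cell
    radius = search_radius_frac * ell.semi_minor_b
    best = None
    for lab in range(1, n_lab + 1):
        blob = labels == lab
        area = int(blob.sum())
        if not (lo <= area <= hi):
            continue
        ys, xs = np.nonzero(blob)
        bx = xs.mean() + mask.offset[1]
        by = ys.mean() + mask.offset[0]
        if np.hypot(bx - ell.cx, by - ell.cy) > radius:
            continue
        if best is None or area > best[0]:
            best = (area, blob, bx, by)
    if best is None:
        return None
    area, blob, bx, by = best
    # robust contrast gate: blob must rise clearly above the interior noise
    med = float(np.median(vals))
    mad = float(np.median(np.abs(vals - med)))
    robust_sd = 1.4826 * mad + 1e-12
    if (float(img[blob].mean()) - med) / robust_sd < min_contrast:
        return None
    try:
        blob_ell = equivalent_ellipse(
            CellMask(blob, mask.cell_id, mask.frame_index, offset=mask.offset,
                     frame_shape=mask.frame_shape)
        )
    except ValueError:
        return None
    return SpindleDetection(
        cx=float(bx),
        cy=float(by),
        theta_spin_deg=blob_ell.theta_cell_deg,
        area_px=area,
        frame_index=mask.frame_index,
        cell_id=mask.cell_id,
    )


def spindle_from_plate(dna_frame: ImageFrame, mask: CellMask) -> float:
    """Spindle axis from a DNA still: perpendicular to the metaphase plate.

    The chromosome plate is the bright DNA bar inside the mask; its
    equivalent-ellipse major axis gives the plate angle, and the spindle
    axis is that angle + 90 deg folded into [0, 180).
    """
    img = mask.crop_from(np.asarray(dna_frame.pixels))
    vals = img[mask.pixels]
    if vals.size == 0 or np.ptp(vals) == 0:
        raise ValueError("no DNA signal inside the mask")
    thr = float(threshold_otsu(vals))
    bright = mask.pixels & (img.astype(float) > thr)
    labels, n_lab = ndimage.label(bright)
    if n_lab == 0:
        raise ValueError("no DNA blob found inside the mask")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n_lab + 1))
    blob = labels == (int(np.argmax(sizes)) + 1)
    plate = equivalent_ellipse(
        CellMask(blob, mask.cell_id, mask.frame_index, offset=mask.offset,
                 frame_shape=mask.frame_shape)
    )
    return float(wrap_axial(plate.theta_cell_deg + 90.0))


def link_tracks(frames_records, max_jump_px: float = DEFAULT_MAX_JUMP_PX, max_gap_frames: int = 1):
    """Greedy nearest-centroid linking of per-frame records into tracks.

    ``frames_records`` is a time-ordered sequence of per-frame lists of
    :class:`TrackRecord`.  Each record joins the nearest active track whose
    last record is at most ``1 + max_gap_frames`` frames old and closer
    than ``max_jump_px``; unmatched records start new tracks.  Every record
    ends up in exactly one track.
    """
    last_frame = None
    tracks: list[CellTrack] = []
    active: list[int] = []  # indices into tracks
    for recs in frames_records:
        if not recs:
            continue
        fidx = recs[0].frame_index
        if any(r.frame_index != fidx for r in recs):
            raise ValueError("records within one frame list must share a frame index")
        if last_frame is not None and fidx <= last_frame:
            raise ValueError(f"duplicate or out-of-order frame index {fidx}")
        last_frame = fidx

        active = [
            ti for ti in active
            if fidx - tracks[ti].records[-1].frame_index <= 1 + max_gap_frames
        ]
        pairs = []
        for ti in active:
            lx, ly = tracks[ti].records[-1].centroid
            for rj, rec in enumerate(recs):
                rx, ry = rec.centroid
                d = float(np.hypot(rx - lx, ry - ly))
                if d <= max_jump_px:
                    pairs.append((d, ti, rj))
        pairs.sort(key=lambda p: (p[0], p[1], p[2]))
        used_t, used_r = set(), set()
        for d, ti, rj in pairs:
            if ti in used_t or rj in used_r:
                continue
            tracks[ti].records.append(recs[rj])
            used_t.add(ti)
            used_r.add(rj)
        for rj, rec in enumerate(recs):
            if rj not in used_r:
                tracks.append(CellTrack(cell_id=len(tracks), records=[rec]))
                active.append(len(tracks) - 1)
    return tracks


def _split_candidates(records_at_frame, center, radius, min_area):
    cands = []
    for rec in records_at_frame:
        rx, ry = rec.centroid
        if np.hypot(rx - center[0], ry - center[1]) <= radius and rec.mask.area >= min_area:
            cands.append(rec)
    cands.sort(key=lambda r: -r.mask.area)
    return cands


def call_anaphase(
    track: CellTrack,
    records_by_frame: dict,
    min_area_frac: float = 0.25,
    persist_frames: int = 2,
    search_factor: float = 1.8,
):
    """Call anaphase onset for a track from region splitting.

    Onset is the first frame where at least two regions, each at least
    ``min_area_frac`` of the prior single-cell area, lie within
    ``search_factor * a`` of the prior centroid, and the split persists for
    ``persist_frames`` consecutive frames.  Returns
    ``(onset_s or None, division_angle_deg or None)``; None means censored
    (movie ended before a persistent split).  ``records_by_frame`` maps
    frame index to the list of *all* records detected in that frame.
    """
    for i in range(1, len(track.records)):
        prev = track.records[i - 1]
        radius = max(25.0, search_factor * prev.ellipse.semi_major_a)
        min_area = min_area_frac * prev.mask.area
        fidx = track.records[i].frame_index
        ok = True
        first_cands = None
        for j in range(persist_frames):
            recs = records_by_frame.get(fidx + j, [])
            cands = _split_candidates(recs, prev.centroid, radius, min_area)
            if len(cands) < 2:
                ok = False
                break
            if j == 0:
                first_cands = cands
        if not ok:
            continue
        (x1, y1), (x2, y2) = first_cands[0].centroid, first_cands[1].centroid
        angle = wrap_axial(np.rad2deg(np.arctan2(y2 - y1, x2 - x1)))
        return float(track.records[i].time_s), float(angle)
    return None, None
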