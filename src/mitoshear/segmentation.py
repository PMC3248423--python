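"""Cell detection and equivalent-ellipse shape descriptors.

Confined mitotic cells imaged with a phase-contrast objective appear as a
very bright closed rim around a darker interior.  Segmentation exploits
this: bright structures are thresholded, and each cell body is recovered as
a "hole" — a connected region of below-threshold pixels fully enclosed by
the thresholded edges.  Shape is then summarised by the *equivalent
ellipse*, the ellipse sharing the region's first and second spatial
moments.  Its axis ratio R = a/b defines the cell elongation
(R - 1) * 100 %, which is 0 for a disk and 100 % for a 2:1 ellipse, and the
major-axis angle defines the cell orientation.

Conventions: 0-based pixel indices with origin at the top-left corner;
x = column, y = row; angles in degrees measured from the +x axis toward +y
and folded into the axial range [0, 180).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .angles import orientation_relative, wrap_axial

__all__ = [
    "ImageFrame",
    "CellMask",
    "EquivalentEllipse",
    "detect_cells",
    "equivalent_ellipse",
    "orientation_relative",
]

log = logging.getLogger(__name__)

#: smallest admissible cell area, px^2 — guards against specks
DEFAULT_MIN_AREA_PX = 200


@dataclass(frozen=True)
class ImageFrame:
    """A single-channel image with physical metadata.

    Parameters
    ----------
    pixels
        2-D non-negative intensity grid (any real dtype).
    pixel_size_um
        Physical pixel size in micrometres per pixel.
    time_s
        Acquisition time in seconds.
    channel
        One of ``"phase"``, ``"myosin"`` or ``"dna"``.
    """

    pixels: np.ndarray
    pixel_size_um: float = 1.0
    time_s: float = 0.0
    channel: str = "phase"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("ImageFrame requires a 2-D pixel grid")
        if min(px.shape) < 32:
            raise ValueError(f"frame too small: {px.shape} (need at least 32x32)")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class CellMask:
    """A filled binary cell region on the frame grid.

    ``pixels`` is a boolean patch cropped to the region's bounding box
    (plus margin); ``offset`` = (y0, x0) places the patch in the frame and
    ``frame_shape`` records the full grid.  Constructing from a full-frame
    boolean array (offset (0, 0)) also works; all reported coordinates are
    frame coordinates.
    """

    pixels: np.ndarray  # bool, cropped patch
    cell_id: int = -1
    frame_index: int = 0
    offset: tuple[int, int] = (0, 0)
    frame_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.frame_shape is None:
            self.frame_shape = self.pixels.shape

    @property
    def area(self) -> int:
        return int(np.count_nonzero(self.pixels))

    @property
    def centroid(self) -> tuple[float, float]:
        """(cx, cy) centroid in frame coordinates (x = column, y = row)."""
        ys, xs = np.nonzero(self.pixels)
        return float(xs.mean()) + self.offset[1], float(ys.mean()) + self.offset[0]

    @property
    def slices(self) -> tuple[slice, slice]:
        """Frame slices covered by the cropped patch."""
        y0, x0 = self.offset
        h, w = self.pixels.shape
        return slice(y0, y0 + h), slice(x0, x0 + w)

    def crop_from(self, image: np.ndarray) -> np.ndarray:
        """Crop a full-frame image to this mask's patch window."""
        sy, sx = self.slices
        return image[sy, sx]

    def to_full(self) -> np.ndarray:
        """Expand to a full-frame boolean array."""
        full = np.zeros(self.frame_shape, dtype=bool)
        sy, sx = self.slices
        full[sy, sx] = self.pixels
        return full


@dataclass(frozen=True)
class EquivalentEllipse:
    """Ellipse with the same first and second moments as a cell region.

    Semi-axes satisfy a >= b > 0; ``theta_cell_deg`` is the major-axis
    orientation in [0, 180).  ``ratio_R`` and ``elongation_pct`` are the
    shape descriptors derived from the axes.
    """

    cx: float
    cy: float
    semi_major_a: float
    semi_minor_b: float
    theta_cell_deg: float

    @property
    def ratio_R(self) -> float:
        return self.semi_major_a / self.semi_minor_b

    @property
    def elongation_pct(self) -> float:
        return (self.ratio_R - 1.0) * 100.0

    def axes_um(self, pixel_size_um: float) -> tuple[float, float]:
        return self.semi_major_a * pixel_size_um, self.semi_minor_b * pixel_size_um


def _resolve_threshold(img: np.ndarray, threshold_policy) -> float:
    if threshold_policy is None or threshold_policy == "otsu":
        return float(threshold_otsu(img))
    return float(threshold_policy)


def detect_cells(
    frame: ImageFrame,
    threshold_policy="otsu",
    seeds=None,
    min_area_px: int = DEFAULT_MIN_AREA_PX,
    close_edges: bool = False,
    include_rim: bool = False,
):
    """Detect mitotic cells as holes enclosed by bright thresholded edges.

    Bright pixels (above Otsu's threshold, or a fixed value) form the edge
    set; the complement is labelled with 4-connectivity, components touching
    the image border are discarded as background, and the remaining
    components are the candidate cell interiors ("holes").  Each returned
    mask is hole-filled, so bright structures inside the cell (the spindle)
    are part of the mask.

    Parameters
    ----------
    threshold_policy
        ``"otsu"`` (default) or a fixed intensity value.
    seeds
        Optional list of (x, y) points; when given, the hole containing each
        seed is returned (one mask per valid seed).  Seeds falling on edges
        or background are logged and skipped.
    min_area_px
        Minimum hole area when running without seeds.
    close_edges
        Apply a 3x3 binary closing to the edge set before hole extraction
        (repairs 1-px gaps in noisy rims).
    include_rim
        Grow each mask to include its enclosing bright rim (used when the
        bright structure *is* the cell periphery, e.g. the myosin channel).

    Returns
    -------
    list of CellMask, largest first (or in seed order).
    """
    img = np.asarray(frame.pixels, dtype=float)
    thr = _resolve_threshold(img, threshold_policy)
    edges = img > thr
    if close_edges:
        edges = ndimage.binary_closing(edges, structure=np.ones((3, 3), bool))
    log.debug("detect_cells: threshold=%.4g policy=%r", thr, threshold_policy)

    # holes = 4-connected components of the complement not touching the border
    labels, n_lab = ndimage.label(~edges)  # default structure = 4-connectivity
    if n_lab == 0:
        log.warning("detect_cells: no closed edge found (frame t=%.1fs)", frame.time_s)
        return []
    border = np.unique(
        np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    )
    border = set(int(b) for b in border if b != 0)

    objects = ndimage.find_objects(labels)

    def _make_mask(lab: int, cid: int) -> CellMask:
        # crop to the component's bounding box with margin so hole filling,
        # rim growth and later distance transforms stay local
        margin = 12 if include_rim else 3
        sy, sx = objects[lab - 1]
        y0 = max(0, sy.start - margin)
        y1 = min(labels.shape[0], sy.stop + margin)
        x0 = max(0, sx.start - margin)
        x1 = min(labels.shape[1], sx.stop + margin)
        m = ndimage.binary_fill_holes(labels[y0:y1, x0:x1] == lab)
        if include_rim:
            # annex the enclosing rim: grow until the added shell is no
            # longer above-threshold, then fill
            local_edges = edges[y0:y1, x0:x1]
            grown = ndimage.binary_dilation(m, iterations=1)
            while True:
                shell = ndimage.binary_dilation(grown, iterations=1) & ~grown
                add = shell & local_edges
                if not add.any():
                    break
                grown |= add
            m = ndimage.binary_fill_holes(grown)
        return CellMask(
            pixels=m, cell_id=cid, frame_index=0, offset=(y0, x0), frame_shape=labels.shape
        )

    if seeds is not None:
        out = []
        for i, (sx, sy) in enumerate(seeds):
            xi, yi = int(round(sx)), int(round(sy))
            if not (0 <= yi < labels.shape[0] and 0 <= xi < labels.shape[1]):
                log.warning("seed %d at (%s, %s) outside frame; skipped", i, sx, sy)
                continue
            lab = int(labels[yi, xi])
            if lab == 0 or lab in border:
                log.warning("seed %d at (%s, %s) is not inside a hole; skipped", i, sx, sy)
                continue
            out.append(_make_mask(lab, i))
        return out

    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n_lab + 1))
    order = np.argsort(sizes)[::-1]
    out = []
    for k in order:
        lab = int(k) + 1
        if lab in border or sizes[k] < min_area_px:
            continue
        out.append(_make_mask(lab, len(out)))
    if not out:
        log.warning("detect_cells: no hole above min_area=%d px^2", min_area_px)
    return out


def equivalent_ellipse(mask: CellMask) -> EquivalentEllipse:
    """Compute the ellipse with the same first and second moments as a mask.

    The central second-moment (covariance) matrix of the pixel coordinates
    is diagonalised; semi-axes follow the solid-ellipse relation
    a = 2 sqrt(lambda_1), b = 2 sqrt(lambda_2), which is exact for a filled
    continuous ellipse, and the orientation is the major eigenvector angle
    folded to [0, 180).

    Raises
    ------
    ValueError
        For degenerate masks (fewer than 3 pixels, or collinear pixels).
    """
    ys, xs = np.nonzero(mask.pixels)
    n = xs.size
    if n < 3:
        raise ValueError(f"degenerate mask (cell {mask.cell_id}): {n} pixels")
    ys = ys + mask.offset[0]
    xs = xs + mask.offset[1]
    cx, cy = xs.mean(), ys.mean()
    dx, dy = xs - cx, ys - cy
    mxx = float(np.mean(dx * dx))
    myy = float(np.mean(dy * dy))
    mxy = float(np.mean(dx * dy))
    half_diff = 0.5 * (mxx - myy)
    common = np.hypot(half_diff, mxy)
    lam1 = 0.5 * (mxx + myy) + common
    lam2 = 0.5 * (mxx + myy) - common
    if lam2 <= 0:
        raise ValueError(f"degenerate (collinear) mask for cell {mask.cell_id}")
    theta = wrap_axial(np.rad2deg(0.5 * np.arctan2(2.0 * mxy, mxx - myy)))
    return EquivalentEllipse(
        cx=float(cx),
        cy=float(cy),
        semi_major_a=2.0 * float(np.sqrt(lam1)),
        semi_minor_b=2.0 * float(np.sqrt(lam2)),
        theta_cell_deg=float(theta),
    )
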