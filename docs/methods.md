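# Methods

This note records the models, conventions, parameter choices and known
limitations behind `mitoshear`. It documents what the code computes; every
number quoted here is produced by the test suite or the `analysis/`
scripts, not asserted independently.

## Coordinate and angle conventions

Images use 0-based pixel indices with the origin at the top-left corner;
x is the column and y the row. Angles are in degrees, measured from the
+x axis toward +y. Every orientation (cell axis, spindle axis, division
axis, plate normal) is *axial* — θ and θ + 180° are the same direction —
and is folded into [0°, 180°). Averages of axial data are taken on the
doubled angle (so 10° and 170° average to 0°), and the corresponding
circular standard deviation is reported. In division-angle reporting the
strain axis sits at 0°, so divisions along the zero-force direction peak
at 90° and the reflected statistic |θ − 90°| is small for aligned
divisions; every statistics output records this convention.

## Segmentation and shape

Phase-contrast mitotic cells present a very bright closed rim. Bright
pixels above a threshold (Otsu by default; a fixed value can be
configured, and the value actually used is logged) form the edge set; the
complement is labelled with 4-connectivity, components touching the image
border are background, and the remaining enclosed components — the
"holes" — are cell interiors. Each mask is hole-filled so interior bright
structures (the spindle) belong to the cell. With seed points, the hole
containing each seed is returned; otherwise holes above a minimum area
(default 200 px², a speck guard) are returned largest-first. Masks are
stored as bounding-box crops with an offset, which keeps the moment and
distance-transform computations local to each cell rather than scaling
with the field of view.

The equivalent ellipse diagonalises the central second-moment matrix of
the mask pixels; a = 2√λ₁ and b = 2√λ₂ are exact for a solid continuous
ellipse, making elongation a pure function of the mask. Discretization
accuracy on rasterized shapes: a disk of radius 50 px returns 0.0 %
elongation; an 80/40 px ellipse returns 100.5 %; orientations are
recovered within 0.1°. The computation is cross-checked in the tests
against `skimage.measure.regionprops`, which implements the same moment
relations independently.

## Spindle detection and tracking

Inside each mask, the interior (eroded 2 px to exclude rim bleed) is
thresholded; a blob qualifies as the spindle if (i) its area is within a
size window (default 2–25 % of the cell area), (ii) its centroid lies
within 0.5·b of the cell centroid, and (iii) it rises at least 5 robust
standard deviations (median/MAD) above the interior background. The last
gate is what distinguishes "no spindle present" from Otsu splitting pure
interior noise. The spec-level description thresholds within the search
radius; thresholding the whole interior and constraining the *blob
centroid* instead avoids clipping an elongated blob whose half-length
0.5·a exceeds the 0.5·b radius, while rejecting off-centre structures the
same way. A failed detection is a missing value, not an error; gaps are
retained, not interpolated.

Tracking is greedy nearest-centroid linking (confined mitotic cells
barely translate): per frame, candidate (track, detection) pairs closer
than 15 px are assigned in order of distance, with a one-frame gap
tolerance; unmatched detections start new tracks. Anaphase onset is the
first frame where at least two regions, each ≥ 25 % of the prior
single-cell area, appear within 1.8·a of the prior centroid and persist
for 2 consecutive frames (the persistence requirement suppresses
single-frame threshold flicker). The division angle joins the two
daughter centroids at the first split frame. The search radius 1.8·a is
deliberately smaller than the generator's cell spacing so a neighbour's
daughters cannot trigger a false split call. Track records terminate at
the called onset.

## Periphery myosin profile

The band is the set of mask pixels whose Euclidean distance transform is
≤ 1 µm (at least one pixel; narrower bands are rejected). Each band pixel
gets an angular position about the cell centroid — adequate for
near-elliptic cells — and is folded into [0°, 90°] about the reference
axis θ₀ (cell body or spindle; round control cells have an ill-defined
body axis, so the spindle reference, taken perpendicular to the DNA
plate, is the robust default). Intensities are divided by the mean over
the whole cell body, averaged per cell per bin first (so large cells do
not dominate), then across cells; the standard error is across cells.
Default 9 bins of 10°. Cells at or above 60 % elongation are excluded
and counted in the log. The pole/equator excess is estimated by a least
squares fit of A + B·cos 2θ to the bin means, reported as 2B/(A − B).

## Interferometric gap estimation

The two-beam reflection spectrum is periodic in ν = 1/λ with period
1/(2 n_w h). The estimator resamples the intensity uniformly in ν (4×
the input density), removes a linear trend, applies a Hann window, and
takes the dominant peak of the zero-padded (8×) power spectrum, refined
by quadratic interpolation of the log power; h = f_peak/(2 n_w). Quality
is the peak power over the median background; below the quality floor
(or if the fringe contrast is below 0.1 % of the mean intensity, the
flat-trace case) the result is a typed failure rather than a number.
Round-trip accuracy: relative error < 10⁻³ noiseless and < 5 % at a noise
standard deviation of 10 % of the fringe amplitude, for h ∈ {5, 10, 20} µm
over 400–800 nm.

## Statistics

The Mann-Whitney U statistic is U = #(a > b pairs) + ½·ties. Exact mode
enumerates all C(n+m, n) assignments of the pooled values (tie-aware,
midrank formulation; capped at n + m ≤ 20, automatic below 17) and
reports the two-sided tail probability P(|U − nm/2| ≥ |u − nm/2|); normal
mode uses the tie-corrected Gaussian with continuity correction. The
exact path is verified against a brute-force enumeration oracle and
against `scipy.stats.mannwhitneyu` in the tests.

Rotation speed is the slope of a linear fit (robust to frame noise,
unlike a two-point difference) of the unsigned angle between the
unwrapped spindle axis and the strain axis over the 0–5 min window after
a force switch, in deg/min; positive speeds mean rotation away from the
strain. No multiple-testing correction is applied by default (tests are
reported per condition); the censoring horizon for onset statistics
defaults to 2 h.

## The synthetic-data generator

The generator is the package's data source and defines its study
conditions. Steady-state elongation follows a saturating response

    E(γ, f) = E_base + E_max · γⁿ/(γ_halfⁿ + γⁿ) · f/(f_half + f)

with E_base = 10 % (non-strained cells), E_max = 45 %, γ_half = 0.4,
n = 2, f_half = 0.1 Hz — a Hill-type nonlinearity in amplitude and a
saturation above ~100 mHz in frequency, matching the qualitative shape of
the measured responses. The cell long axis relaxes toward the zero-force
direction at k_shape = 0.5 min⁻¹ and the spindle toward the cell axis at
k_align = 2 min⁻¹ (first-order relaxations; the observed adaptations are
smooth and take a few minutes, with the spindle following shape within
the 20 s frame interval). Both angles carry additive Gaussian noise
(2° per frame for the spindle, half that for the shape axis).

Two structural choices encode the biology rather than convenience:
with zero amplitude or frequency there is no preferred in-plane
direction, so orientations start uniform and the shape axis only
diffuses; and the spindle–shape coupling is gated by the (noise-free)
elongation, ramping linearly from zero at 10 % to full strength at 20 % —
round cells present no usable shape cue, which is what makes the
"no bias below 10 % elongation" behaviour reproducible. The gate uses
the deterministic elongation state so that measurement-like noise on the
recorded elongation cannot leak alignment into nominally round cells.

Anaphase onset times are log-normal (mean 3600 s, sd 2400 s), placing
~92 % of divisions inside a 2 h horizon; the division axis is the spindle
axis at the last metaphase frame, and anaphase is rendered as two
separating daughter regions (radius 0.62·r, initial centre offset just
beyond contact, growing 2 px/frame, capped to stay inside the cell's grid
slot). Cells sit on a fixed grid (spacing ≥ 90 px) so segmentation
failures cannot arise from overlap; that is a deliberate simplification.
Rendering uses uint16 levels with the rim brightest (52000), a dark
interior (6000), background 12000 and spindle 30000, plus Gaussian noise
(2 % of full scale by default). The rim ring straddles the true contour
(−0.5/+2 px), so the enclosed hole tracks the true cell area closely
(IoU ≥ 0.9 against truth on noise-free frames).

Immunofluorescence stills place the myosin signal in the same 1 µm
periphery band the analysis measures, with

    I(α) = I_base · (1 + c·(1 + cos 2(α − θ₀))/2),

so the pole exceeds the equator by exactly the configured contrast c
(c = 0.1 emulates the ~10 % measured excess); the DNA channel is a
metaphase-plate bar perpendicular to θ₀. Spectra are
I(λ) = I₀ + B·cos(4π n_w h/λ + φ) sampled uniformly in λ; at least three
fringes must fit the range or generation refuses.

Randomness: a single integer seed; per-cell substreams are derived from
(seed, cell_id) so adding cells never perturbs existing trajectories, and
per-frame noise from a separate (seed, constant, frame) stream. Identical
configuration and seed give bit-identical movies, truth tables and
pipeline outputs.

**What the generator does not emulate** — and hence what passing tests do
not demonstrate about real data: cell–cell contact and overlap, uneven
illumination and photobleaching, segmentation-confusing debris,
out-of-focus drift, 3D cell shape (the analysis is strictly 2D; the
curvature along the optical axis is not modelled), retraction fibres, and
any mechanistic model of *why* cells elongate. Parameter-recovery results
certify the measurement chain, not the biology.

## Problem sizes

The test suite exercises the tracking chain at 100 cells × 200 frames
(the cohort scale of the time-lapse experiments; ~1 min on one CPU),
myosin cohorts at the study's n = 75 control / n = 58 sheared, Monte
Carlo gap recovery over 100 seeds, and Mann-Whitney exactness over all
n, m ≤ 7 with 100 random tied samples. The `analysis/` drivers use
smaller cohorts (10–44 cells) chosen to make each script a few seconds
long while keeping every estimate comfortably inside its test tolerance.

## Known limitations

- Greedy linking has no global assignment step; it is adequate for
  near-stationary confined cells and would swap tracks for fast-moving
  ones.
- The angular position of band pixels is measured about the centroid, not
  by arc length; for elongations well beyond 60 % (excluded by the
  default filter) the two differ appreciably.
- The anaphase caller assumes daughters remain within ~1.8 cell radii of
  the parent during the persistence window.
- Background subtraction for still images is off by default (a flag
  exists); the synthetic stills have a flat background, real images may
  not.
- `estimate_gap` assumes a single dominant fringe system (two reflecting
  interfaces); multilayer stacks would need a Fresnel model, which is out
  of scope.
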