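# mitoshear

Quantitative image analysis of confined mitotic cells under dynamic shear:
cell-shape descriptors from image moments, mitotic-spindle detection and
tracking, division-angle statistics, quadrant-folded cortical myosin
profiles, and interferometric measurement of the confinement gap — driven
end to end by a synthetic-data generator that emulates the experiments, so
every stage is testable without microscope data.

## The problem

Mitotic cells confined between two parallel plates and sheared
sinusoidally (strain γ = dy/h, with dy the plate displacement and h the
plate gap) elongate along the **zero-force direction** — the in-plane axis
perpendicular to the strain — and align their mitotic spindle with the
resulting long axis, so that division becomes perpendicular to the force.
This package implements the measurements behind that phenomenology:

- **Equivalent ellipse.** A segmented cell region is summarised by the
  ellipse with the same first and second spatial moments. With covariance
  eigenvalues λ₁ ≥ λ₂, the semi-axes are a = 2√λ₁, b = 2√λ₂; the axis
  ratio R = a/b defines the *elongation* (R − 1)·100 % (0 for a disk,
  100 % for a 2:1 ellipse) and the major-axis angle θ_cell the cell
  orientation. All orientations are axial, reported in [0°, 180°).
- **Spindle and anaphase.** The spindle is the bright, centred,
  size-bounded interior blob (orientation θ_spin from its equivalent
  ellipse), or, in fixed cells, the axis perpendicular to the DNA
  metaphase plate. Tracks are greedy nearest-centroid links; anaphase
  onset is the first persistent split of a cell region into two daughters,
  and the division axis joins the daughter centroids.
- **Division statistics.** With the strain axis at 0°, aligned divisions
  peak at 90°; conditions are compared by a Mann-Whitney U test on the
  reflected angles |θ − 90°| (exact, tie-aware enumeration for small
  samples).
- **Periphery myosin profile.** Intensity in a 1 µm band under the cell
  edge, normalized per cell by the whole-body mean, folded into one
  quadrant θ−θ₀ ∈ [0°, 90°] (poles at 0°, equator at 90°) and averaged
  per cell, then across cells.
- **Plate gap from interference.** The reflected spectrum of the two
  water–glass interfaces is periodic in 1/λ with period 1/(2 n_w h),
  n_w = 1.33; the dominant fringe period gives h to sub-micrometre
  accuracy.
- **Cortex geometry.** An ellipse's pole/equator curvature ratio is
  (a/b)³ — ≈ 2.2 at 30 % elongation — so the Laplace law Δp = σC with
  uniform pressure would require about half the tension at the poles,
  opposite in trend to the ~10 % myosin excess measured there.

## Worked example

```python
from mitoshear import (render_cell, detect_cells, equivalent_ellipse,
                       detect_spindle, simulate_spectrum, estimate_gap)

frame = render_cell((128, 128, 60, 30, 20.0), spindle_params=(30, 8, 45.0),
                    noise_sd=0.02, seed=1)
mask = detect_cells(frame)[0]
ell = equivalent_ellipse(mask)
print(f"elongation {ell.elongation_pct:.1f}%  orientation {ell.theta_cell_deg:.1f} deg")
print(f"spindle at {detect_spindle(frame, mask).theta_spin_deg:.1f} deg")

est = estimate_gap(simulate_spectrum(gap_um=10.0, noise_sd=0.05, seed=0))
print(f"plate gap {est.h_um:.2f} um")
```

prints

```
elongation 101.3%  orientation 20.0 deg
spindle at 44.9 deg
plate gap 10.00 um
```

— the rendered 2:1 cell at 20° is recovered at ~100 % elongation (the
rim adds ~1 % of apparent elongation), the spindle blob drawn at 45° is
measured at 44.9°, and the 10 µm gap is recovered from a noisy spectrum.

The numbered scripts under `analysis/` run the full study on synthetic
data and write their tables to `results/`: gap recovery (`01`), the
elongation response to amplitude and frequency (`02`), spindle–shape
alignment vs elongation (`03`), force-switch re-orientation kinetics and
rotation-speed statistics (`04`), control vs sheared myosin profiles
(`05`), division-angle and anaphase-onset statistics (`06`), and the
curvature/tension table (`07`). A `mitoshear` CLI exposes the individual
stages (`simulate`, `segment`, `track`, `gap`, `run`, ...).

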