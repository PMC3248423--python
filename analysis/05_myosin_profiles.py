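#!/usr/bin/env python
"""Quadrant-folded periphery myosin intensity: control vs sheared cohorts.

Two immunofluorescence-like cohorts are generated and pushed through the
full still-image pipeline (myosin-channel segmentation, spindle axis from
the DNA metaphase plate, 1 um periphery band, quadrant folding, per-cell
normalization): a control cohort (n = 75, elongation 10 +/- 1 %, no
angular modulation) and a sheared cohort (n = 58, elongation 32 +/- 5 %,
10 % pole/equator myosin excess).  The control profile is flat; the
sheared profile shows ~10 % more signal at the poles than at the equator.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from mitoshear.myosin_profile import angular_profile, profile_contrast
from mitoshear.segmentation import detect_cells, equivalent_ellipse
from mitoshear.spindle_tracking import spindle_from_plate
from mitoshear.synthgen import GeneratorConfig, simulate_if_cohort

OUT = Path(__file__).resolve().parents[1] / "results"

COHORTS = {
    "control": dict(n=75, elongation=10.0, sd=1.0, contrast=0.0),
    "sheared": dict(n=58, elongation=32.0, sd=5.0, contrast=0.1),
}


def main(seed: int = 1) -> None:
    OUT.mkdir(exist_ok=True)
    tables = []
    for label, kw in COHORTS.items():
        cfg = GeneratorConfig(seed=seed)
        stills = simulate_if_cohort(
            kw["n"], cfg, elongation_mean_pct=kw["elongation"],
            elongation_sd_pct=kw["sd"], myosin_contrast=kw["contrast"], seed=seed,
        )
        cells = []
        for s in stills:
            masks = detect_cells(s.myosin, include_rim=True)
            if not masks:
                continue
            m = masks[0]
            theta0 = spindle_from_plate(s.dna, m)  # spindle reference, robust for round cells
            cells.append((s.myosin, m, theta0, equivalent_ellipse(m).elongation_pct))
        prof = angular_profile(cells)
        t = pd.DataFrame(
            dict(
                cohort=label,
                bin_center_deg=prof.bin_centers_deg,
                mean_norm_intensity=prof.mean_norm_intensity,
                se=prof.se,
                n_cells=prof.n_cells,
            )
        )
        tables.append(t)
        est = profile_contrast(prof)
        pole, eq = prof.mean_norm_intensity[0], prof.mean_norm_intensity[-1]
        print(f"{label}: n = {prof.n_cells}, pole/equator = {pole / eq:.3f}, "
              f"fitted pole excess = {est * 100:.1f} % (generator: {kw['contrast'] * 100:.0f} %)")
    df = pd.concat(tables, ignore_index=True)
    df.to_csv(OUT / "myosin_profiles.csv", index=False, float_format="%.6g")
    print("\ncontrol profile is flat; sheared cells carry ~10 % more myosin at the poles")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
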