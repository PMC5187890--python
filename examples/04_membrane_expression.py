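"""Quantify relative membrane expression from fluorescence line profiles.

Thirty synthetic cells with a bright membrane annulus (true expression
0.37, 1 px PSF blur, camera noise) are scored the manual way: three
lines across the membrane per cell, peak minus matched background,
divided by the maximal fluorescence; per-cell means are averaged over
the cohort.
"""

import numpy as np

from aquaflux import (
    aggregate_cells,
    extract_profile,
    generate_cell_image,
    relative_membrane_expression,
)

TRUTH = 0.37
values = {}
for cell_idx in range(30):
    image, _, gt = generate_cell_image(
        TRUTH, ring_width_px=5, blur_sd_px=1.0, noise_sd=2.0, seed=cell_idx
    )
    background = extract_profile(image, (1.0, 0.0), (1.0, 63.0)).intensities
    lines = []
    for dr in (-2.0, 0.0, 2.0):  # three parallel lines through the cell
        profile = extract_profile(image, (31.5 + dr, 0.0), (31.5 + dr, 63.0))
        lines.append(
            relative_membrane_expression(profile, gt["image_max"], background=background)
        )
    values[f"cell{cell_idx:02d}"] = lines

cohort = aggregate_cells(values)
print(f"cells scored: {cohort.n_cells} (3 lines each)")
print(f"cohort relative membrane expression = "
      f"{cohort.cohort_mean:.3f} +/- {cohort.cohort_sd:.3f}")
print(f"true value = {TRUTH}; scores are in [0, 1], where 1 means the "
      "membrane peak reaches the maximal fluorescence above background.")
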