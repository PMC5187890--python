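"""Reduce plate-reader assays: catalase activity, glutathione, DCF-ROS.

Each assay is a linear standard curve plus inverse prediction of the
unknowns, followed by the assay-specific normalization: catalase to
U/mg (1 U = 1 umol H2O2 degraded per minute), glutathione per mg of
protein, DCF fluorescence as fold change over its baseline.
"""

import numpy as np

from aquaflux import (
    catalase_activity,
    fit_standard_curve,
    generate_assay_plate,
    gsh_level,
    ros_fold_change,
)

# --- Goth catalase endpoint: standards are remaining H2O2 (mM) ---
plate = generate_assay_plate(
    "catalase", standards=[0, 15, 30, 45, 60, 75], slope=0.02, intercept=0.05,
    unknown_true=32.5, noise_sd=0.002, seed=1,
)
curve = fit_standard_curve(plate, assay="catalase")
reading = plate.loc[plate.role == "unknown", "reading"].iloc[0]
cat = catalase_activity(curve, reading, protein_mg=1.0)
print(f"catalase: remaining H2O2 = {cat.remaining_mM:.1f} mM of 65 mM after 5 min")
print(f"          activity = {cat.U_per_mg:.3f} U/mg "
      "(umol H2O2 consumed per minute per mg protein)")

# --- Tietze recycling assay for total glutathione ---
plate = generate_assay_plate(
    "gsh", standards=[0, 0.5, 1, 2, 4], slope=0.3, intercept=0.02,
    unknown_true=1.94, noise_sd=0.001, seed=2,
)
curve = fit_standard_curve(plate, assay="gsh")
reading = plate.loc[plate.role == "unknown", "reading"].iloc[0]
gsh = gsh_level(curve, reading, protein_mg=1.0)
print(f"\nGSH: {gsh.per_mg:.2f} {gsh.unit_label} (true 1.94)")

# --- DCF oxidation kinetics after an oxidant challenge ---
times = np.arange(0, 61, 10, dtype=float)
fluor = 100.0 * (1 + times / 15.0)  # fluorescence doubling every 15 min
tc = ros_fold_change(times, fluor)
for t, f in zip(tc.times_min, tc.fold):
    print(f"DCF fold at {t:4.0f} min: {f:.2f}")
print("Rising fold means intracellular ROS accumulates as peroxide enters.")
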