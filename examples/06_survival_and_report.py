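"""Acute-stress survival percentages, group comparison and report output.

Triplicate colony-count time courses are simulated for two strains under
an acute oxidant pulse; counts become percentages of each replicate's
untreated time-0 plate, strains are compared per time point by ANOVA +
unpaired t-test, and tidy CSVs plus a survival figure are written.
"""

import tempfile
from pathlib import Path

import pandas as pd

from aquaflux import (
    generate_survival_counts,
    one_way_anova,
    survival_percent,
    unpaired_t_test,
    build_report,
)

curves = {
    "control": {5.0: 0.9, 15.0: 0.75, 30.0: 0.7, 45.0: 0.75, 60.0: 0.8},
    "AQP5": {5.0: 0.6, 15.0: 0.4, 30.0: 0.5, 45.0: 0.7, 60.0: 0.8},
}
tables = []
for s_idx, (strain, curve) in enumerate(curves.items()):
    for rep in range(1, 4):
        tables.append(
            generate_survival_counts(
                300, curve, seed=100 * s_idx + rep,
                strain=strain, replicate=rep,
            )
        )
counts = pd.concat(tables, ignore_index=True)
percents = survival_percent(counts)
summary = percents.attrs["summary"]
print(summary.to_string(index=False))

print("\nper-time comparisons (control vs AQP5):")
for t in sorted(curves["control"]):
    a = percents.query("strain == 'control' and time_min == @t")["percent"]
    b = percents.query("strain == 'AQP5' and time_min == @t")["percent"]
    gate = one_way_anova([a.to_list(), b.to_list()])
    res = unpaired_t_test(a, b, labels=("control", "AQP5"))
    print(f"  t = {t:4.0f} min: ANOVA p = {gate.p_value:.3f}, "
          f"t-test p = {res.p_value:.3f} {res.stars}")

outdir = Path(tempfile.mkdtemp()) / "report"
written = build_report({"survival": percents, "summary": summary}, outdir)
print(f"\nwrote {len(written)} report files to {outdir}")
print("Lower AQP5 survival at early times reflects the extra peroxide "
      "influx through the channel; later recovery reflects adaptation.")
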