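# aquaflux

Quantitative analysis chain for yeast-based aquaporin functional
studies, with seeded synthetic-data generators standing in for the
wet-lab instruments.

Heterologous expression in an aquaporin-null *Saccharomyces cerevisiae*
strain is a classic platform for testing whether a candidate channel
transports water (and small solutes such as hydrogen peroxide). The
quantitative readouts of such a study are scattered across several
instruments — a stopped-flow fluorimeter, O₂ and H₂O₂ electrodes, an
epifluorescence microscope and a plate reader — and `aquaflux`
implements each reduction step as a tested, reusable Python function:

* **Osmotic water permeability.** A hyperosmotic sorbitol shock shrinks
  fluorophore-loaded cells; the fluorescence relaxation is fitted to a
  single exponential with rate constant *k*, and

  $$P_f = k \,\frac{V_0/A}{V_w\,\mathrm{osm}_{out}}$$

  converts it to a permeability (cm·s⁻¹) using the equivalent-sphere
  volume-to-area ratio $V_0/A = d/6$ and the molar volume of water
  $V_w$. Across temperatures, the activation energy is
  $E_a = -R \cdot \mathrm{slope}(\ln P_f\ \mathrm{vs}\ 1/T)$; values
  below ~6 kcal·mol⁻¹ indicate channel-mediated transport.
* **Peroxide-consumption kinetics.** External H₂O₂ consumed by intact
  cells decays exponentially; *k* (s⁻¹) is the slope of the semi-log
  concentration plot, identically for the direct H₂O₂ electrode and the
  catalase/O₂-release readout (the ½ stoichiometry cancels).
* **Membrane expression.** The manual line-profile score: (peak
  intensity along a line crossing the membrane − matched background) /
  maximal fluorescence, three lines per cell, ≥30 cells per cohort.
* **Plate assays.** Linear standard curves with inverse prediction for
  Bradford protein, Goth catalase (U = µmol H₂O₂ · min⁻¹, per mg
  protein), Tietze glutathione, and DCF-ROS fold-change kinetics.
* **Survival statistics.** Colony counts as a percentage of the
  untreated time-0 plate, compared by one-way ANOVA followed by
  unpaired t-tests with conventional significance stars.
* **Synthetic data.** Every input above can be generated with known
  ground truth — a nonlinear osmometer ODE for shrinkage traces,
  exponential electrode traces, annulus cell images, linear plates and
  Poisson colony counts — so each estimator is testable by parameter
  recovery.

## Worked example

`examples/01_water_permeability.py` simulates ten stopped-flow runs at
a known permeability and runs the full estimation chain:

```text
seed  1:  k = 2.025 1/s   Pf = 5.342e-03 cm/s
seed  2:  k = 2.048 1/s   Pf = 5.403e-03 cm/s
...
replicate mean Pf = (5.33 +/- 0.04) x 10^-3 cm/s
generative value  =  4.94 x 10^-3 cm/s (relative error +8.0%)
```

Each trace is a numerical solution of the osmometer ODE (1.4 →
1.75 osmol·L⁻¹ shock, 5 µm cells, 0.005 a.u. noise); the fitted rate
constants near 2 s⁻¹ convert to permeabilities a few × 10⁻³ cm·s⁻¹,
i.e. channel-level water transport. The systematic +8% offset is the
documented bias of applying the small-shock linear *k* → *P_f* relation
to a full-strength shock (see `docs/methods.md`).

The other scripts in `examples/` cover the Arrhenius fit, the electrode
kinetics and fold comparison, the line-profile membrane score, the
plate assays, and survival statistics with report output; each prints
its numbers and a one-line interpretation.

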