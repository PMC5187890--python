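# Methods

## Osmotic shrinkage: forward model and estimator

The simulator integrates the single-cell osmometer equation

    dV/dt = -Pf · A · Vw · (osm_out − osm_in(V)),
    osm_in(V) = osm_in0 · (V0 − Vb) / (V − Vb),   Vb = b·V0,

with `b` the non-osmotic volume fraction (solids and bound water,
default 0). Internal solute is conserved exactly — `osm_in(V)·(V−Vb)`
is a constant of the motion, and the test suite verifies relative drift
below 10⁻⁶. The equilibrium volume has the closed form
`V∞/V0 = b + (1−b)·osm_in0/osm_out`. Integration uses LSODA at
rtol 10⁻¹⁰, and the output is clamped to `[V∞/V0, 1]` to remove
integrator-level overshoot.

The estimator is deliberately *not* the inverse of the simulator: it is
the standard experimental procedure — a three-parameter single
exponential `F(t) = F_inf + (F0 − F_inf)·e^{−kt}` fitted by
Levenberg–Marquardt (initialized from a log-linearization of the
upper half of the decay, with bounded restarts), followed by the linear
conversion `Pf = k·(V0/A)/(Vw·osm_out)`. That relation is exact only in
the small-shock limit; the simulator therefore serves as an independent
oracle. At a 1% shock the round trip recovers `Pf` within 1% (tested).

### Known bias at full shock strength

At the default protocol (cells equilibrated at 1.4 osmol/L, equal-volume
mixing with 2.1 osmol/L sorbitol, hence osm_out = 1.75 osmol/L) the
relaxation is not exponential: the local rate rises from
`Pf·(A/V0)·Vw·osm_out` at t = 0 to `osm_out/osm_in0 = 1.25×` that value
at equilibrium. A single-exponential fit lands in between, and where it
lands depends on how much plateau is recorded: the recovered `Pf` is
+1% of truth for a 1 s window, ≈ +8% at the default 2 s window (about
four time constants, i.e. recording essentially to plateau, which is
what a stopped-flow operator does), and ≈ +12% in the infinite-window
limit. This bias is a property of the field's standard estimator, not
of the implementation; it is measured and asserted in the tests rather
than hidden.

### Defaults and units

| parameter | default | why |
|---|---|---|
| Vw | 18.05 cm³·mol⁻¹ | molar volume of water |
| R | 1.9872×10⁻³ kcal·mol⁻¹·K⁻¹ | gas constant, for Ea in kcal/mol |
| cell diameter | 5 µm | typical budding yeast equivalent sphere; always overridable, and acceptance runs pass geometry explicitly |
| osm_in0 / osm_out | 1.4 / 1.75 osmol·L⁻¹ | equal-volume mixing of 1.4 M-equilibrated cells with 2.1 M sorbitol buffer |
| dead time | 2 ms | stopped-flow mixing dead time; earlier samples are dropped |
| acquisition | 2 s at 500 Hz | ~4 relaxation time constants at channel-level Pf |
| noise | 0.005 a.u., additive Gaussian i.i.d. | photometric noise on a unit-amplitude signal |

All internal computation is in Kelvin and cgs; `fit_arrhenius` refuses
temperatures below 200 (almost certainly Celsius passed by mistake)
rather than converting silently. Fluorescence transduction is affine in
relative volume with positive gain (self-quenching of entrapped
carboxyfluorescein: shrinkage lowers the signal); gain, offset and sign
are configurable.

Aggregation order is fit-per-trace, then average the per-trace `Pf`
values (sample SD, n−1; a single replicate reports SD as NaN, never 0).

## Peroxide kinetics

The primary estimator is the field's plot-slope method: ordinary least
squares of ln C on t, `k = −slope`, after converting O₂-electrode
readings back to remaining H₂O₂ (×2; the factor cancels in the slope,
so the two readouts give identical k — tested). Points at or below a
floor (default 2% of C₀) are excluded from the log transform and
counted. A nonlinear exponential fit exists in the test suite only, as
a brute-force SSE grid oracle; the semi-log estimator agrees with it
within 3% at electrode-level noise and its median recovery error over
seeded noisy traces is below 5% at all four study-condition rate
constants. Fold changes are reported by explicit group label and never
reordered. Blank (cell-free autodegradation) subtraction is off by
default since the measurements are of intact cells.

## Line-profile membrane expression

Profiles are sampled by bilinear interpolation at unit-pixel spacing
(0-based pixel-centre coordinates). The per-line score is
`(max(profile) − mean(background)) / image_max`, clipped to [0, 1] with
clips logged; the peak is the maximum sample (no sub-pixel refinement),
matching the manual workflow. Open choices resolved here: "maximal
fluorescence" is the maximum pixel of the analysed image by default
(per-profile normalization behind a flag), and the background is a
matched cell-free line of the same length (a region mean can be passed
as a constant profile). Per-cell values average three lines; cohort
mean ± SD is over cells, never pooled lines (asserted). Cohorts under
30 cells and cells without exactly 3 lines warn but are included.

The synthetic images render an annulus whose peak is
`background + expression_true·image_max`, so the noiseless, unblurred
chain returns the truth to machine precision. Under a 1 px PSF blur the
peak attenuates (monotonically in blur — tested); with the 5 px default
ring the attenuation stays inside the ±0.05 cohort tolerance. The
generator does not emulate cytoplasmic autofluorescence, vesicular
puncta, or cell-to-cell size variation, so passing recovery tests show
the scoring arithmetic is right, not that membrane localization is
detectable in arbitrary real images.

## Plate assays

All four assays share one primitive: an OLS calibration line with
inverse prediction, flagged beyond 1.1× the standard range. Catalase
converts remaining H₂O₂ to units via
`U = (C_initial − C_remaining)·volume / time` with
`C_initial = 65 mM`, 5 min reaction and a 0.1 mL effective assay
volume (the reaction volume is not fully determined by the protocol, so
it is an explicit parameter recorded with every result). Glutathione
results carry their unit label verbatim from configuration because the
source protocol's units are internally ambiguous (µM vs nmol per mg).
DCF kinetics are reduced to fold over the pre-treatment baseline,
background-uncorrected by default.

For the power check on DCF group separation, the slower group's
fluorescence doubles every 15 min — a representative response to a
strong (10 mM-scale) oxidant pulse; with a 1.5× steeper second group,
5% reading noise and triplicates, the groups separate at 40 min in
≥95% of seeded experiments.

## Statistics

Comparisons follow the classic bench pipeline: one-way ANOVA as the
gate, then two-sided unpaired t-tests — pooled-variance Student by
default (the era-typical Prism-style choice), Welch behind a flag. No
multiple-testing correction is applied by default (Bonferroni is
available but off, documented). Stars map p < 0.05/0.01/0.001 to
*/**/***; the mapping is a pure function tested at the boundaries.
Degenerate inputs (both groups constant and equal) report p = 1 with a
note instead of NaN. Survival percentages are per (strain, replicate)
against that replicate's own untreated time-0 plate; SD is across
biological replicates. Replicate identity is a required input column,
never inferred. The t-test's type-I error is verified at 5% (±1 point)
over 2000 seeded null simulations.

## Problem sizes and determinism

Monte-Carlo suites use 200–2000 seeded repetitions depending on the
cost per draw (200 for ODE-free estimators and power checks, 500 for
Arrhenius bias and Poisson recovery, 2000 for type-I error); every
random draw flows from an explicit `numpy.random.default_rng(seed)` and
all results in the tests, examples and the acceptance script are
bit-reproducible. The acceptance script derives its per-trace seeds
from the single `--seed` argument via `numpy.random.SeedSequence`.

## Known limitations

* No solute (glycerol) permeability, channel gating dynamics, mercury
  binding kinetics, swelling protocols, or multi-exponential models.
* The image pipeline requires user-supplied lines; there is no
  segmentation or automatic membrane detection.
* Assay curves are strictly linear; saturating (e.g. enzyme-kinetic)
  calibration is out of scope.
* The chronic spot-growth assay is qualitative and only representable
  as a stored dilution-series table, not analysed.
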