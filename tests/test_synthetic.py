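"""Generator correctness: closed forms, conservation laws, reproducibility."""

import numpy as np
import pandas as pd
import pytest

from aquaflux import (
    InstrumentSpec,
    SimCellSpec,
    generate_arrhenius_series,
    generate_assay_plate,
    generate_cell_image,
    generate_decay_trace,
    generate_survival_counts,
    simulate_shrinkage_trace,
    simulate_volume_relaxation,
    volume_to_fluorescence,
)
from aquaflux.assays import fit_standard_curve
from aquaflux.constants import DEFAULT_CONSTANTS, OSM_PER_L_TO_MOL_PER_CM3


class TestVolumeRelaxation:
    def test_equilibrium_closed_form(self):
        """1.4 -> 1.75 osM with no non-osmotic volume ends at V/V0 = 0.800."""
        cell = SimCellSpec(Pf_true=5e-3, osm_in0=1.4, osm_out=1.75)
        t = np.linspace(0.0, 30.0, 200)
        v = simulate_volume_relaxation(cell, t)
        assert v[-1] == pytest.approx(0.800, abs=1e-4)
        assert cell.equilibrium_relative_volume == pytest.approx(0.8)

    def test_zero_permeability_means_no_flux(self):
        cell = SimCellSpec(Pf_true=0.0)
        v = simulate_volume_relaxation(cell, np.linspace(0, 2, 50))
        assert np.all(v == 1.0)

    def test_monotone_nonincreasing_and_bounded(self, aqp5_cell):
        t = np.linspace(0.0, 3.0, 500)
        v = simulate_volume_relaxation(aqp5_cell, t)
        assert np.all(np.diff(v) <= 1e-12)
        assert np.all(v >= aqp5_cell.equilibrium_relative_volume - 1e-9)
        assert np.all(v <= 1.0)

    def test_osmolyte_conservation(self, aqp5_cell):
        """osm_in(V) * (V - Vb) is a constant of the motion (drift < 1e-6)."""
        cell = SimCellSpec(Pf_true=4.94e-3, nonosmotic_fraction=0.3)
        t = np.linspace(0.0, 3.0, 400)
        v = simulate_volume_relaxation(cell, t)
        b = cell.nonosmotic_fraction
        osm_in = cell.osm_in0 * (1 - b) / (v - b)
        solute = osm_in * (v - b)
        drift = np.abs(solute / solute[0] - 1.0)
        assert drift.max() < 1e-6

    def test_small_shock_matches_linearized_rate(self):
        """For a 1% shock the relaxation is exponential at k = Pf*(A/V0)*Vw*osm_out."""
        from aquaflux import ShrinkageTrace, fit_single_exponential

        cell = SimCellSpec(Pf_true=4.94e-3, osm_in0=1.4, osm_out=1.4 * 1.01)
        k_lin = cell.linearized_rate_constant()
        t = np.linspace(0.002, 5.0 / k_lin, 800)
        v = simulate_volume_relaxation(cell, t)
        fit = fit_single_exponential(ShrinkageTrace(times=t, values=v))
        assert fit.k == pytest.approx(k_lin, rel=0.01)

    def test_input_validation(self):
        cell = SimCellSpec(Pf_true=1e-3)
        with pytest.raises(ValueError):
            simulate_volume_relaxation(cell, np.array([0.0, 0.5, 0.4]))
        with pytest.raises(ValueError):
            SimCellSpec(Pf_true=1e-3, osm_out=-1.0)


class TestFluorescenceTransduction:
    def test_identity_transduction(self, aqp5_cell):
        inst = InstrumentSpec(noise_sd=0.0, fluor_offset=0.0, fluor_gain=1.0)
        t = inst.sample_times()
        v = simulate_volume_relaxation(aqp5_cell, t)
        trace = volume_to_fluorescence(t, v, inst)
        assert np.allclose(trace.values, v)

    def test_seed_determinism(self, aqp5_cell):
        inst = InstrumentSpec(seed=7)
        a = simulate_shrinkage_trace(aqp5_cell, inst)
        b = simulate_shrinkage_trace(aqp5_cell, inst)
        assert np.array_equal(a.values, b.values)
        c = simulate_shrinkage_trace(aqp5_cell, InstrumentSpec(seed=8))
        assert not np.array_equal(a.values, c.values)

    def test_noise_level_calibrated(self, aqp5_cell):
        """Residual SD of a 1000-point trace matches the requested 0.005."""
        inst = InstrumentSpec(noise_sd=0.005, duration=2.0, sample_rate=500.0, seed=3)
        t = inst.sample_times()
        v = simulate_volume_relaxation(aqp5_cell, t)
        noisy = volume_to_fluorescence(t, v, inst)
        resid = noisy.values - v
        assert 0.004 < resid.std() < 0.006

    def test_dead_time_samples_dropped(self, aqp5_cell):
        inst = InstrumentSpec(dead_time=0.01, sample_rate=1000.0)
        trace = simulate_shrinkage_trace(aqp5_cell, inst)
        assert trace.times.min() >= 0.01

    def test_zero_gain_rejected(self, aqp5_cell):
        inst = InstrumentSpec(fluor_gain=0.0)
        t = np.linspace(0.01, 1, 100)
        with pytest.raises(ValueError):
            volume_to_fluorescence(t, np.full(100, 0.9), inst)


class TestArrheniusSeries:
    def test_slope_is_minus_ea_over_r(self):
        """Ea = 6.52 kcal/mol gives a ln Pf vs 1/T slope of -3281.0 K."""
        df = generate_arrhenius_series(6.52, 4.94e-3, 296.15, [282.15, 307.15])
        x = 1.0 / df["T_K"].to_numpy()
        y = np.log(df["Pf"].to_numpy())
        slope = (y[1] - y[0]) / (x[1] - x[0])
        assert slope == pytest.approx(-6.52 / 1.9872e-3, rel=1e-9)
        assert slope == pytest.approx(-3281.0, rel=1e-4)

    def test_zero_activation_energy_is_flat(self):
        df = generate_arrhenius_series(0.0, 1e-3, 296.15, [280.0, 300.0, 320.0])
        assert np.allclose(df["Pf"], 1e-3)

    def test_reference_temperature_anchors_pf(self):
        df = generate_arrhenius_series(6.52, 4.94e-3, 296.15, [296.15])
        assert df["Pf"].iloc[0] == pytest.approx(4.94e-3, rel=1e-12)
        assert df.attrs["sufficient_for_fit"] is False


class TestDecayTrace:
    def test_closed_form_h2o2(self):
        tr = generate_decay_trace(50.0, 2e-3, 500.0, 1.0, noise_sd=0.0)
        idx = np.searchsorted(tr.times, 500.0)
        assert tr.values[idx] == pytest.approx(50 * np.exp(-1), abs=1e-3)
        assert tr.values[idx] == pytest.approx(18.394, abs=1e-3)

    def test_o2_mode_half_stoichiometry(self):
        tr = generate_decay_trace(50.0, 2e-3, 500.0, 1.0, mode="o2")
        idx = np.searchsorted(tr.times, 500.0)
        assert tr.values[idx] == pytest.approx(9.197, abs=1e-3)

    def test_zero_rate_is_constant(self):
        tr = generate_decay_trace(50.0, 0.0, 100.0, 2.0)
        assert np.all(tr.values == 50.0)

    def test_noise_floor_clipping_counted(self):
        tr = generate_decay_trace(1.0, 5e-2, 200.0, 1.0, noise_sd=0.5, seed=1)
        assert tr.values.min() >= 1e-3
        assert tr.clipped_points > 0


class TestCellImage:
    def test_zero_expression_uniform_background(self):
        img, mask, gt = generate_cell_image(0.0, noise_sd=0.0, blur_sd_px=0.0)
        assert np.all(img == 20.0)

    def test_peak_construction_identity(self):
        img, mask, gt = generate_cell_image(
            0.5, background=20.0, image_max=160.0, noise_sd=0.0, blur_sd_px=0.0
        )
        assert img.max() == pytest.approx(100.0)
        assert img[mask].min() == pytest.approx(100.0)

    def test_out_of_range_expression_rejected(self):
        with pytest.raises(ValueError):
            generate_cell_image(1.5)

    def test_seeded_noise_reproducible(self):
        a, _, _ = generate_cell_image(0.4, noise_sd=2.0, seed=5)
        b, _, _ = generate_cell_image(0.4, noise_sd=2.0, seed=5)
        assert np.array_equal(a, b)


class TestAssayPlate:
    def test_noiseless_round_trip(self):
        plate = generate_assay_plate("gsh", [0, 5, 10, 20], 0.2, 0.05, 7.5)
        curve = fit_standard_curve(plate)
        reading = plate.loc[plate.role == "unknown", "reading"].iloc[0]
        assert curve.inverse_predict(reading) == pytest.approx(7.5, rel=1e-12)

    def test_intercept_shift_leaves_unknown_unchanged(self):
        a = generate_assay_plate("bradford", [0, 10, 20], 0.1, 0.0, 12.0)
        b = generate_assay_plate("bradford", [0, 10, 20], 0.1, 5.0, 12.0)
        ca, cb = fit_standard_curve(a), fit_standard_curve(b)
        ra = a.loc[a.role == "unknown", "reading"].iloc[0]
        rb = b.loc[b.role == "unknown", "reading"].iloc[0]
        assert ca.inverse_predict(ra) == pytest.approx(cb.inverse_predict(rb))

    def test_monte_carlo_recovery_within_5_percent(self):
        """1% range noise, 8 standards: unknown recovered within 5% (200 seeds)."""
        standards = np.linspace(0, 70, 8)
        truth = 33.0
        noise = 0.01 * (0.1 * 70)  # 1% of the reading range
        errors = []
        for seed in range(200):
            plate = generate_assay_plate(
                "catalase", standards, 0.1, 0.2, truth, noise_sd=noise, seed=seed
            )
            curve = fit_standard_curve(plate)
            reading = plate.loc[plate.role == "unknown", "reading"].iloc[0]
            errors.append(abs(curve.inverse_predict(reading) / truth - 1.0))
        assert np.median(errors) < 0.05
        assert np.mean(np.array(errors) < 0.05) > 0.9

    def test_too_few_standards_rejected(self):
        with pytest.raises(ValueError):
            generate_assay_plate("dcf", [0, 1], 1.0, 0.0, 0.5)


class TestSurvivalCounts:
    def test_no_dispersion_exact_counts(self):
        df = generate_survival_counts(250, {30.0: 0.5}, dispersion="none")
        assert df.loc[df.time_min == 0.0, "count"].iloc[0] == 250
        assert df.loc[df.time_min == 30.0, "count"].iloc[0] == 125

    def test_poisson_mean_recovery(self):
        """Mean recovered fraction within 2% of truth over 500 seeds."""
        frac = 0.6
        counts = [
            generate_survival_counts(300, {15.0: frac}, seed=s)
            .set_index("time_min")["count"]
            for s in range(500)
        ]
        recovered = np.mean([c[15.0] / 300 for c in counts])
        assert recovered == pytest.approx(frac, rel=0.02)

    def test_fraction_validation(self):
        with pytest.raises(ValueError):
            generate_survival_counts(100, {10.0: 1.5})
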