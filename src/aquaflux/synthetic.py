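"""Synthetic-data generators standing in for the wet-lab instruments.

Every generator draws from an explicit integer seed (no hidden global
state) and attaches a :class:`~aquaflux.containers.GroundTruth` record of
its true parameters, so each downstream estimator can be validated by
parameter recovery without any external data.

The forward model for osmotic shrinkage is the standard single-cell
osmometer ODE

    dV/dt = -Pf * A * Vw * (osm_out - osm_in(V)),
    osm_in(V) = osm_in0 * (V0 - Vb) / (V - Vb),  Vb = b * V0,

with an optional non-osmotic volume fraction ``b`` (default 0, so the
linearized single-exponential estimator is exactly nested). Internal
solute is conserved: osm_in(V) * (V - Vb) is constant along every
trajectory. In the small-shock limit the relaxation is exponential with
rate k = Pf * (A/V0) * Vw * osm_out, which is the linear k <-> Pf
relation the estimation chain inverts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.ndimage import gaussian_filter

from .constants import (
    DEFAULT_CONSTANTS,
    OSM_PER_L_TO_MOL_PER_CM3,
    UM_TO_CM,
    PhysicalConstants,
)
from .containers import DecayTrace, GroundTruth, ShrinkageTrace

__all__ = [
    "SimCellSpec",
    "InstrumentSpec",
    "simulate_volume_relaxation",
    "volume_to_fluorescence",
    "simulate_shrinkage_trace",
    "generate_arrhenius_series",
    "generate_decay_trace",
    "generate_cell_image",
    "generate_assay_plate",
    "generate_survival_counts",
]


@dataclass(frozen=True)
class SimCellSpec:
    """Ground-truth cell and shock parameters for the osmometer model.

    Defaults reproduce the standard shrinkage protocol: cells
    equilibrated in 1.4 osmol/L buffer mixed with an equal volume of
    2.1 osmol/L sorbitol buffer, giving a final external osmolarity of
    (1.4 + 2.1) / 2 = 1.75 osmol/L, and a 5 um equivalent-sphere
    diameter typical of yeast.
    """

    Pf_true: float  # cm/s
    diameter_um: float = 5.0
    nonosmotic_fraction: float = 0.0
    osm_in0: float = 1.4  # osmol/L
    osm_out: float = 1.75  # osmol/L

    def __post_init__(self) -> None:
        if self.Pf_true < 0:
            raise ValueError("Pf_true must be non-negative")
        if self.diameter_um <= 0:
            raise ValueError("diameter must be positive")
        if not 0 <= self.nonosmotic_fraction < 1:
            raise ValueError("nonosmotic_fraction must be in [0, 1)")
        if self.osm_out <= 0:
            raise ValueError("osm_out must be positive")
        if self.osm_in0 <= 0:
            raise ValueError("osm_in0 must be positive")

    @property
    def area_over_volume_cm(self) -> float:
        """A/V0 of the equivalent sphere, cm^-1 (= 6 / d)."""
        return 6.0 / (self.diameter_um * UM_TO_CM)

    @property
    def equilibrium_relative_volume(self) -> float:
        """Closed-form V_inf/V0 = b + (1 - b) * osm_in0 / osm_out."""
        b = self.nonosmotic_fraction
        return b + (1.0 - b) * self.osm_in0 / self.osm_out

    def linearized_rate_constant(
        self, constants: PhysicalConstants = DEFAULT_CONSTANTS
    ) -> float:
        """Small-shock exponential rate k = Pf * (A/V0) * Vw * osm_out, 1/s."""
        osm = self.osm_out * OSM_PER_L_TO_MOL_PER_CM3
        return self.Pf_true * self.area_over_volume_cm * constants.Vw * osm


@dataclass(frozen=True)
class InstrumentSpec:
    """Stopped-flow acquisition parameters.

    The 2 ms dead time is the interval after mixing during which no
    signal is recorded. The default 2 s acquisition window covers
    roughly four relaxation time constants of the default shrinkage
    protocol at a channel-level permeability.
    """

    dead_time: float = 0.002  # s
    duration: float = 2.0  # s
    sample_rate: float = 500.0  # Hz
    noise_sd: float = 0.005  # a.u.
    fluor_offset: float = 0.0  # a.u.
    fluor_gain: float = 1.0  # a.u. per unit relative volume
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dead_time < 0:
            raise ValueError("dead_time must be >= 0")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def sample_times(self) -> np.ndarray:
        """Acquisition grid after the dead time, seconds from mixing."""
        n = int(round(self.duration * self.sample_rate))
        t = np.arange(1, n + 1) / self.sample_rate
        return t[t >= self.dead_time]


def simulate_volume_relaxation(
    cell: SimCellSpec,
    times: np.ndarray,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> np.ndarray:
    """Integrate the osmometer ODE and return V(t)/V0 at ``times``.

    ``times`` must be strictly increasing with times[0] >= 0. The output
    is monotone non-increasing for a hyperosmotic shock and bounded
    below by the closed-form equilibrium volume.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if times[0] < 0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing and start at t >= 0")

    if cell.Pf_true == 0.0:
        return np.ones_like(times)

    b = cell.nonosmotic_fraction
    osm_out = cell.osm_out * OSM_PER_L_TO_MOL_PER_CM3
    osm_in0 = cell.osm_in0 * OSM_PER_L_TO_MOL_PER_CM3
    coef = cell.Pf_true * cell.area_over_volume_cm * constants.Vw

    v_eq = cell.equilibrium_relative_volume

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        v = y[0]
        osm_in = osm_in0 * (1.0 - b) / max(v - b, 1e-12)
        return np.array([-coef * (osm_out - osm_in)])

    sol = solve_ivp(
        rhs,
        (0.0, float(times[-1])),
        [1.0],
        t_eval=times,
        method="LSODA",
        rtol=1e-10,
        atol=1e-12,
        max_step=max(float(times[-1]) / 50.0, 1e-4),
    )
    if not sol.success:
        raise RuntimeError(f"volume relaxation integration failed: {sol.message}")
    # Clamp tiny integrator overshoot below the analytic equilibrium.
    return np.clip(sol.y[0], v_eq, 1.0)


def volume_to_fluorescence(
    times: np.ndarray,
    v_rel: np.ndarray,
    instrument: InstrumentSpec,
    ground_truth: GroundTruth | None = None,
    conditions: Mapping[str, object] | None = None,
) -> ShrinkageTrace:
    """Transduce a relative-volume series into a noisy fluorescence trace.

    F(t) = offset + gain * V(t)/V0 plus i.i.d. Gaussian noise; samples
    recorded before the instrument dead time are dropped. The affine,
    positive-gain transduction models self-quenching of the entrapped
    carboxyfluorescein: shrinkage lowers the signal proportionally.
    """
    times = np.asarray(times, dtype=float)
    v_rel = np.asarray(v_rel, dtype=float)
    if np.any(v_rel <= 0) or np.any(v_rel > 1 + 1e-9):
        raise ValueError("relative volumes must lie in (0, 1]")
    if instrument.fluor_gain == 0:
        raise ValueError("fluor_gain = 0 produces a degenerate signal")

    keep = times >= instrument.dead_time
    times, v_rel = times[keep], v_rel[keep]
    rng = np.random.default_rng(instrument.seed)
    signal = instrument.fluor_offset + instrument.fluor_gain * v_rel
    if instrument.noise_sd > 0:
        signal = signal + rng.normal(0.0, instrument.noise_sd, size=signal.shape)
    return ShrinkageTrace(
        times=times,
        values=signal,
        dead_time=instrument.dead_time,
        conditions=dict(conditions or {}),
        ground_truth=ground_truth,
    )


def simulate_shrinkage_trace(
    cell: SimCellSpec,
    instrument: InstrumentSpec,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    conditions: Mapping[str, object] | None = None,
) -> ShrinkageTrace:
    """Full forward model: osmometer ODE + fluorescence transduction."""
    times = instrument.sample_times()
    v_rel = simulate_volume_relaxation(cell, times, constants)
    gt = GroundTruth(
        {
            "Pf_true": cell.Pf_true,
            "diameter_um": cell.diameter_um,
            "osm_in0": cell.osm_in0,
            "osm_out": cell.osm_out,
            "nonosmotic_fraction": cell.nonosmotic_fraction,
            "k_linearized": cell.linearized_rate_constant(constants),
        }
    )
    return volume_to_fluorescence(times, v_rel, instrument, gt, conditions)


def generate_arrhenius_series(
    Ea_true: float,
    Pf_ref: float,
    T_ref: float,
    temperatures: Sequence[float],
    noise_sd_log: float = 0.0,
    seed: int = 0,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """Pf(T) samples obeying the Arrhenius law with known activation energy.

    ln Pf(T) = ln Pf_ref - (Ea_true / R) * (1/T - 1/T_ref), with optional
    Gaussian noise on the log scale. Temperatures are in Kelvin.

    Returns a DataFrame with columns ``T_K`` and ``Pf`` and attrs
    carrying the ground truth; a single temperature is flagged in attrs
    as insufficient for a slope fit.
    """
    temps = np.asarray(temperatures, dtype=float)
    if np.any(temps <= 0):
        raise ValueError("temperatures must be positive (Kelvin)")
    if Ea_true < 0:
        raise ValueError("Ea_true must be non-negative")
    if Pf_ref <= 0 or T_ref <= 0:
        raise ValueError("Pf_ref and T_ref must be positive")

    ln_pf = np.log(Pf_ref) - (Ea_true / constants.R_kcal) * (1.0 / temps - 1.0 / T_ref)
    if noise_sd_log > 0:
        rng = np.random.default_rng(seed)
        ln_pf = ln_pf + rng.normal(0.0, noise_sd_log, size=ln_pf.shape)
    df = pd.DataFrame({"T_K": temps, "Pf": np.exp(ln_pf)})
    df.attrs["ground_truth"] = GroundTruth(
        {"Ea_true": Ea_true, "Pf_ref": Pf_ref, "T_ref": T_ref}
    )
    df.attrs["sufficient_for_fit"] = temps.size >= 2
    return df


def generate_decay_trace(
    C0: float,
    k_true: float,
    duration: float,
    sample_rate: float,
    noise_sd: float = 0.0,
    mode: Literal["h2o2", "o2"] = "h2o2",
    seed: int = 0,
    floor: float = 1e-3,
    conditions: Mapping[str, object] | None = None,
) -> DecayTrace:
    """First-order peroxide decay C(t) = C0 * exp(-k t) plus electrode noise.

    In ``"o2"`` mode the stored series is the catalase-released oxygen
    O2(t) = C(t) / 2 (dismutation stoichiometry 2 H2O2 -> 2 H2O + O2).
    Noise draws that push a reading below ``floor`` (uM) are clipped and
    counted in ``clipped_points``.
    """
    if C0 <= 0:
        raise ValueError("C0 must be positive")
    if k_true < 0:
        raise ValueError("k_true must be >= 0")
    n = int(round(duration * sample_rate))
    times = np.arange(n + 1) / sample_rate
    conc = C0 * np.exp(-k_true * times)
    if mode == "o2":
        stored = conc / 2.0
    elif mode == "h2o2":
        stored = conc
    else:
        raise ValueError(f"unknown readout mode: {mode!r}")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        stored = stored + rng.normal(0.0, noise_sd, size=stored.shape)
    clipped = int(np.sum(stored < floor))
    stored = np.maximum(stored, floor)
    return DecayTrace(
        times=times,
        values=stored,
        mode=mode,
        C0_nominal=C0,
        conditions=dict(conditions or {}),
        ground_truth=GroundTruth({"k_true": k_true, "C0": C0, "mode": mode}),
        clipped_points=clipped,
    )


def generate_cell_image(
    expression_true: float,
    radius_px: float = 20.0,
    ring_width_px: float = 4.0,
    background: float = 20.0,
    image_max: float = 160.0,
    blur_sd_px: float = 0.0,
    noise_sd: float = 0.0,
    image_size: int = 64,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Render a cell with a bright membrane annulus on a flat background.

    The annulus peak intensity is ``background + expression_true *
    image_max``, so the line-profile expression formula
    (peak - background) / image_max applied to the noiseless, unblurred
    image returns ``expression_true`` exactly. Optional Gaussian blur
    emulates the microscope point-spread function and additive Gaussian
    noise the camera.

    Returns (image, annulus mask, ground truth). The mask marks the
    noiseless ring so tests can place profile lines without a detector.
    """
    if not 0.0 <= expression_true <= 1.0:
        raise ValueError("expression_true must be in [0, 1]")
    if not 0 < radius_px < image_size / 2:
        raise ValueError("radius_px must be positive and fit inside the image")
    if background >= image_max:
        raise ValueError("background must be below image_max")

    center = (image_size - 1) / 2.0
    yy, xx = np.mgrid[0:image_size, 0:image_size]
    r = np.hypot(xx - center, yy - center)
    mask = np.abs(r - radius_px) <= ring_width_px / 2.0

    image = np.full((image_size, image_size), float(background))
    image[mask] = background + expression_true * image_max
    if blur_sd_px > 0:
        image = gaussian_filter(image, blur_sd_px)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        image = image + rng.normal(0.0, noise_sd, size=image.shape)

    gt = GroundTruth(
        {
            "expression_true": expression_true,
            "radius_px": radius_px,
            "ring_width_px": ring_width_px,
            "background": background,
            "image_max": image_max,
            "center": (center, center),
        }
    )
    return image, mask, gt


def generate_assay_plate(
    assay: Literal["catalase", "gsh", "bradford", "dcf"],
    standards: Sequence[float],
    slope: float,
    intercept: float,
    unknown_true: float | Iterable[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Tidy plate table for a linear colorimetric/fluorometric assay.

    Readings follow reading = slope * concentration + intercept plus
    Gaussian noise, for both the standard series and the unknowns.
    Duplicate standard concentrations are allowed (replicates).

    Returns columns (well, role, concentration, reading); unknown rows
    carry NaN concentration, with the truth in ``attrs['ground_truth']``.
    """
    standards = np.asarray(standards, dtype=float)
    if standards.size < 3:
        raise ValueError("at least 3 standards are required")
    if slope == 0:
        raise ValueError("slope must be non-zero")
    unknowns = np.atleast_1d(np.asarray(unknown_true, dtype=float))

    rng = np.random.default_rng(seed)
    rows = []
    for i, conc in enumerate(standards):
        reading = slope * conc + intercept
        if noise_sd > 0:
            reading += rng.normal(0.0, noise_sd)
        rows.append((f"S{i + 1}", "standard", conc, reading))
    for i, conc in enumerate(unknowns):
        reading = slope * conc + intercept
        if noise_sd > 0:
            reading += rng.normal(0.0, noise_sd)
        rows.append((f"U{i + 1}", "unknown", np.nan, reading))
    df = pd.DataFrame(rows, columns=["well", "role", "concentration", "reading"])
    df.attrs["ground_truth"] = GroundTruth(
        {"assay": assay, "unknown_true": unknowns.tolist(), "slope": slope,
         "intercept": intercept}
    )
    return df


def generate_survival_counts(
    n0: int,
    survival_curve: Mapping[float, float],
    dispersion: Literal["poisson", "none"] = "poisson",
    seed: int = 0,
    strain: str = "strain",
    replicate: int = 1,
) -> pd.DataFrame:
    """Colony counts for an acute-stress survival time course.

    The untreated time-0 reference is reported at exactly ``n0``
    expected colonies; the count at each treated time t is
    Poisson(n0 * fraction(t)) (or the rounded mean with dispersion off).

    Returns columns (strain, replicate, time_min, count) including a
    time-0 row.
    """
    if n0 <= 0:
        raise ValueError("n0 must be positive")
    fractions = dict(survival_curve)
    if any(not 0.0 <= f <= 1.0 for f in fractions.values()):
        raise ValueError("survival fractions must be in [0, 1]")
    if 0.0 not in fractions and 0 not in fractions:
        fractions = {0.0: 1.0, **fractions}

    rng = np.random.default_rng(seed)
    rows = []
    for t in sorted(fractions):
        mean = n0 * fractions[t]
        if dispersion == "poisson":
            count = int(rng.poisson(mean))
        elif dispersion == "none":
            count = int(round(mean))
        else:
            raise ValueError(f"unknown dispersion model: {dispersion!r}")
        rows.append((strain, replicate, float(t), count))
    df = pd.DataFrame(rows, columns=["strain", "replicate", "time_min", "count"])
    df.attrs["ground_truth"] = GroundTruth(
        {"n0": n0, "survival_curve": {float(k): v for k, v in fractions.items()}}
    )
    return df
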