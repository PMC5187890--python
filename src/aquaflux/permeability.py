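"""Osmotic water permeability (Pf) and activation energy (Ea) estimation.

The estimation chain mirrors the standard stopped-flow workflow:

1. fit the recorded shrinkage signal to a single exponential
   F(t) = F_inf + (F0 - F_inf) * exp(-k t);
2. convert the rate constant to a permeability through the linear
   relation Pf = k * (V0/A) / (Vw * osm_out), with the cell modelled as
   an equivalent sphere (V0/A = d/6);
3. for temperature series, regress ln Pf on 1/T and report
   Ea = -slope * R (kcal/mol).

All geometry is carried in cgs units; osmolarities are osmol/L at the
interface and converted to mol/cm^3 internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .constants import (
    DEFAULT_CONSTANTS,
    OSM_PER_L_TO_MOL_PER_CM3,
    UM_TO_CM,
    PhysicalConstants,
)
from .containers import ShrinkageTrace

__all__ = [
    "CellGeometry",
    "ExponentialFit",
    "PermeabilityEstimate",
    "ArrheniusEstimate",
    "compute_geometry",
    "fit_single_exponential",
    "compute_pf",
    "fit_arrhenius",
    "aggregate_replicates",
]

#: Temperatures below this are assumed to be Celsius passed by mistake.
_MIN_PLAUSIBLE_KELVIN = 200.0


@dataclass(frozen=True)
class CellGeometry:
    """Equivalent-sphere geometry of a cell (or cell population mean).

    The diameter is the average of the maximum and minimum dimensions
    of the cell; V0 and A are the sphere volume (cm^3) and surface area
    (cm^2), so V0/A = d/6 in cm.
    """

    d_max_um: float
    d_min_um: float

    def __post_init__(self) -> None:
        if self.d_min_um <= 0 or self.d_max_um < self.d_min_um:
            raise ValueError("diameters must satisfy d_max >= d_min > 0")

    @property
    def d_eq_um(self) -> float:
        return (self.d_max_um + self.d_min_um) / 2.0

    @property
    def V0_cm3(self) -> float:
        d = self.d_eq_um * UM_TO_CM
        return np.pi * d**3 / 6.0

    @property
    def A_cm2(self) -> float:
        d = self.d_eq_um * UM_TO_CM
        return np.pi * d**2

    @property
    def V0_over_A_cm(self) -> float:
        return self.d_eq_um * UM_TO_CM / 6.0


def compute_geometry(d_max_um: float, d_min_um: float | None = None) -> CellGeometry:
    """Build a :class:`CellGeometry` from measured diameters (um).

    With a single argument the cell is taken as a sphere of that
    diameter.
    """
    if d_min_um is None:
        d_min_um = d_max_um
    return CellGeometry(d_max_um=d_max_um, d_min_um=d_min_um)


@dataclass
class ExponentialFit:
    """Result of the single-exponential fit to a shrinkage trace."""

    k: float  # 1/s
    F0: float
    F_inf: float
    residual_sse: float
    n_points: int
    converged: bool

    @property
    def amplitude(self) -> float:
        return self.F0 - self.F_inf

    def predict(self, times: np.ndarray) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        return self.F_inf + (self.F0 - self.F_inf) * np.exp(-self.k * times)


def _exp_model(t: np.ndarray, F0: float, F_inf: float, k: float) -> np.ndarray:
    return F_inf + (F0 - F_inf) * np.exp(-k * t)


def _initial_guess(times: np.ndarray, values: np.ndarray) -> tuple[float, float, float]:
    """Log-linearization of (F - min F) for starting values."""
    f_inf = values.min()
    shifted = values - f_inf
    # Use the upper half of the decay where the shifted signal is well
    # above the noise floor.
    thresh = 0.2 * shifted.max()
    ok = shifted > max(thresh, 1e-12)
    if ok.sum() >= 2:
        slope, intercept, *_ = stats.linregress(times[ok], np.log(shifted[ok]))
        k0 = max(-slope, 1e-6)
        f0 = f_inf + np.exp(intercept)
    else:
        k0 = 1.0 / max(times[-1] - times[0], 1e-6)
        f0 = values[0]
    return float(f0), float(f_inf), float(k0)


def fit_single_exponential(
    trace: ShrinkageTrace,
    fit_window: tuple[float, float] | None = None,
    max_restarts: int = 4,
) -> ExponentialFit:
    """Least-squares single-exponential fit of a shrinkage trace.

    All post-dead-time samples are used unless ``fit_window``
    (t_start, t_end) restricts them. At least 5 points must remain and
    the signal must not be constant. On convergence failure the fit is
    restarted from perturbed initial guesses a bounded number of times.
    """
    times, values = trace.times, trace.values
    if fit_window is not None:
        t0, t1 = fit_window
        keep = (times >= t0) & (times <= t1)
        times, values = times[keep], values[keep]
    if times.size < 5:
        raise ValueError("need at least 5 samples after trimming to fit")
    if np.ptp(values) == 0:
        raise ValueError("constant signal: degenerate exponential fit")

    f0, f_inf, k0 = _initial_guess(times, values)
    last_err: Exception | None = None
    for attempt in range(max_restarts + 1):
        scale = 2.0**attempt if attempt else 1.0
        try:
            popt, _ = optimize.curve_fit(
                _exp_model,
                times,
                values,
                p0=[f0, f_inf, k0 * scale],
                maxfev=10000,
            )
            resid = values - _exp_model(times, *popt)
            return ExponentialFit(
                k=float(popt[2]),
                F0=float(popt[0]),
                F_inf=float(popt[1]),
                residual_sse=float(resid @ resid),
                n_points=int(times.size),
                converged=True,
            )
        except RuntimeError as err:  # curve_fit non-convergence
            last_err = err
    raise RuntimeError(
        f"single-exponential fit failed after {max_restarts + 1} attempts: {last_err}"
    )


@dataclass
class PermeabilityEstimate:
    """A per-trace osmotic water permeability with its provenance."""

    Pf: float  # cm/s
    k: float  # 1/s
    geometry: CellGeometry
    osm_out: float  # osmol/L
    temperature_K: float | None = None
    conditions: dict[str, Any] = field(default_factory=dict)
    fit: ExponentialFit | None = None


def compute_pf(
    fit: ExponentialFit | float,
    geometry: CellGeometry,
    osm_out: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    temperature_K: float | None = None,
    conditions: dict[str, Any] | None = None,
) -> PermeabilityEstimate:
    """Convert a fitted rate constant to Pf (cm/s).

    Pf = k * (V0/A) / (Vw * osm_out), with osm_out in osmol/L converted
    to mol/cm^3. ``fit`` may be an :class:`ExponentialFit` or a bare
    rate constant in 1/s.
    """
    if osm_out <= 0:
        raise ValueError("osm_out must be positive")
    if geometry is None:
        raise ValueError("cell geometry is required to convert k to Pf")
    k = fit.k if isinstance(fit, ExponentialFit) else float(fit)
    osm = osm_out * OSM_PER_L_TO_MOL_PER_CM3
    pf = k * geometry.V0_over_A_cm / (constants.Vw * osm)
    return PermeabilityEstimate(
        Pf=pf,
        k=k,
        geometry=geometry,
        osm_out=osm_out,
        temperature_K=temperature_K,
        conditions=dict(conditions or {}),
        fit=fit if isinstance(fit, ExponentialFit) else None,
    )


@dataclass
class ArrheniusEstimate:
    """Activation energy from the slope of ln Pf vs 1/T."""

    Ea: float  # kcal/mol
    slope: float  # K
    intercept: float
    r_squared: float
    n_temperatures: int


def fit_arrhenius(
    data: pd.DataFrame | Sequence[tuple[float, float]],
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> ArrheniusEstimate:
    """Ordinary least squares of ln Pf on 1/T; Ea = -slope * R.

    ``data`` is a DataFrame with columns ``T_K`` and ``Pf`` or a
    sequence of (T_K, Pf) pairs. Temperatures must be in Kelvin; values
    below 200 trip an explicit unit guard (Celsius passed by mistake).
    At least 2 distinct temperatures are required; r^2 is meaningful
    from 3 up.
    """
    if isinstance(data, pd.DataFrame):
        temps = data["T_K"].to_numpy(dtype=float)
        pfs = data["Pf"].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(data), dtype=float)
        temps, pfs = arr[:, 0], arr[:, 1]
    if np.any(temps < _MIN_PLAUSIBLE_KELVIN):
        raise ValueError(
            "temperatures must be Kelvin; values below 200 look like Celsius"
        )
    if np.any(pfs <= 0):
        raise ValueError("all Pf values must be positive for the log transform")
    if np.unique(temps).size < 2:
        raise ValueError("need at least 2 distinct temperatures")

    x = 1.0 / temps
    y = np.log(pfs)
    res = stats.linregress(x, y)
    return ArrheniusEstimate(
        Ea=-res.slope * constants.R_kcal,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_temperatures=int(np.unique(temps).size),
    )


def aggregate_replicates(
    estimates: Iterable[PermeabilityEstimate],
    group_keys: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-condition mean +/- SD of Pf over replicate runs.

    Each estimate is fitted per trace first; averaging happens on the
    Pf values (never on pooled traces). ``group_keys`` name entries of
    each estimate's ``conditions`` dict to group by. The SD uses the
    n-1 denominator and is reported as NaN (not 0) for single-replicate
    groups; empty groups are dropped with a warning.
    """
    rows = []
    for est in estimates:
        row = {key: est.conditions.get(key) for key in group_keys}
        row["Pf"] = est.Pf
        row["k"] = est.k
        rows.append(row)
    if not rows:
        warnings.warn("no estimates supplied; empty aggregation", stacklevel=2)
        return pd.DataFrame(columns=[*group_keys, "Pf_mean", "Pf_sd", "n"])
    df = pd.DataFrame(rows)
    if group_keys:
        grouped = df.groupby(list(group_keys), dropna=False)["Pf"]
    else:
        grouped = df.assign(_all="all").groupby("_all")["Pf"]
    out = grouped.agg(Pf_mean="mean", Pf_sd=lambda s: s.std(ddof=1), n="count")
    return out.reset_index().drop(columns="_all", errors="ignore")
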