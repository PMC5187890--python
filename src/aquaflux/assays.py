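"""Reduction of plate-based colorimetric and fluorometric assays.

Covers the four endpoint/kinetic assays of the oxidative-stress panel:

* Bradford total protein (standard curve + inverse prediction),
* Goth catalase activity (ammonium-molybdate endpoint; U = umol H2O2
  consumed per minute, normalized per mg protein),
* Tietze enzymatic-recycling total glutathione (inverse prediction per
  mg protein; the unit label is carried verbatim from configuration),
* DCFH-DA reactive-oxygen-species kinetics (fold change of
  fluorescence over the pre-treatment baseline).

All curves are ordinary least-squares lines reading = slope * conc +
intercept; inverse prediction beyond 1.1x the standard range is flagged
as extrapolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurve",
    "CatalaseResult",
    "GshResult",
    "RosTimeCourse",
    "fit_standard_curve",
    "catalase_activity",
    "gsh_level",
    "ros_fold_change",
]

#: Slopes smaller than this (relative to the reading range) are unusable.
_MIN_RELATIVE_SLOPE = 1e-12

#: Allowed inverse-prediction overshoot beyond the standard range.
_EXTRAPOLATION_MARGIN = 1.1


@dataclass
class StandardCurve:
    """An OLS calibration line for one assay."""

    slope: float
    intercept: float
    r_squared: float
    conc_min: float
    conc_max: float
    assay: str = ""

    def predict_reading(self, conc: float | np.ndarray) -> float | np.ndarray:
        return self.slope * np.asarray(conc, dtype=float) + self.intercept

    def inverse_predict(self, reading: float) -> float:
        """Concentration at a reading; warns outside 1.1x the standard range."""
        conc = (reading - self.intercept) / self.slope
        span = self.conc_max - self.conc_min
        lo = self.conc_min - (_EXTRAPOLATION_MARGIN - 1.0) * span
        hi = self.conc_max + (_EXTRAPOLATION_MARGIN - 1.0) * span
        if not lo <= conc <= hi:
            warnings.warn(
                f"inverse prediction {conc:.4g} extrapolates beyond the standard "
                f"range [{self.conc_min:g}, {self.conc_max:g}]",
                stacklevel=2,
            )
        return float(conc)


def fit_standard_curve(
    standards: pd.DataFrame | Sequence[tuple[float, float]],
    assay: str = "",
) -> StandardCurve:
    """Fit a calibration line to (concentration, reading) standards.

    ``standards`` is a DataFrame with columns ``concentration`` and
    ``reading`` (rows with other roles are ignored) or a sequence of
    pairs. At least 3 distinct concentrations are required; replicates
    at a concentration are allowed.
    """
    if isinstance(standards, pd.DataFrame):
        df = standards
        if "role" in df.columns:
            df = df[df["role"] == "standard"]
        conc = df["concentration"].to_numpy(dtype=float)
        reading = df["reading"].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(standards), dtype=float)
        conc, reading = arr[:, 0], arr[:, 1]
    if np.unique(conc).size < 3:
        raise ValueError("need at least 3 distinct standard concentrations")
    res = stats.linregress(conc, reading)
    scale = max(np.ptp(reading), 1.0)
    if abs(res.slope) < _MIN_RELATIVE_SLOPE * scale:
        raise ValueError("standard-curve slope is indistinguishable from zero")
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        conc_min=float(conc.min()),
        conc_max=float(conc.max()),
        assay=assay,
    )


@dataclass
class CatalaseResult:
    """Catalase activity from the molybdate endpoint assay."""

    U_per_mg: float
    consumed_umol: float
    reaction_time_min: float
    protein_mg: float
    remaining_mM: float
    assay_volume_mL: float


def catalase_activity(
    curve: StandardCurve,
    reading_t5: float,
    protein_mg: float,
    C_initial_mM: float = 65.0,
    assay_volume_mL: float = 0.1,
    reaction_time_min: float = 5.0,
) -> CatalaseResult:
    """Catalase activity (U/mg) from the endpoint H2O2 reading.

    The curve maps remaining H2O2 (mM) to absorbance; one unit (U) is
    1 umol H2O2 degraded per minute, normalized per mg of lysate
    protein. consumed_umol = (C_initial - remaining) * volume (mM * mL
    = umol).
    """
    if protein_mg <= 0:
        raise ValueError("protein_mg must be positive")
    remaining = curve.inverse_predict(reading_t5)
    if remaining > C_initial_mM:
        raise ValueError(
            f"interpolated remaining H2O2 ({remaining:.3g} mM) exceeds the "
            f"initial {C_initial_mM:g} mM: negative consumption"
        )
    consumed_umol = (C_initial_mM - remaining) * assay_volume_mL
    units = consumed_umol / reaction_time_min
    return CatalaseResult(
        U_per_mg=units / protein_mg,
        consumed_umol=consumed_umol,
        reaction_time_min=reaction_time_min,
        protein_mg=protein_mg,
        remaining_mM=remaining,
        assay_volume_mL=assay_volume_mL,
    )


@dataclass
class GshResult:
    """Total glutathione normalized per mg protein."""

    per_mg: float
    raw_concentration: float
    dilution_factor: float
    protein_mg: float
    unit_label: str = "uM GSH per mg protein"


def gsh_level(
    curve: StandardCurve,
    reading: float,
    protein_mg: float,
    dilution_factor: float = 1.0,
    unit_label: str = "uM GSH per mg protein",
) -> GshResult:
    """Glutathione level by inverse prediction on the recycling-assay curve.

    conc = inverse prediction * dilution_factor, normalized per mg of
    total protein. The unit label is carried verbatim from the caller's
    configuration rather than converted.
    """
    if protein_mg <= 0:
        raise ValueError("protein_mg must be positive")
    if dilution_factor <= 0:
        raise ValueError("dilution_factor must be positive")
    raw = curve.inverse_predict(reading) * dilution_factor
    return GshResult(
        per_mg=raw / protein_mg,
        raw_concentration=raw,
        dilution_factor=dilution_factor,
        protein_mg=protein_mg,
        unit_label=unit_label,
    )


@dataclass
class RosTimeCourse:
    """A DCF fluorescence kinetic read and its fold-change series."""

    times_min: np.ndarray
    fluorescence: np.ndarray
    fold: np.ndarray

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        self.fold = np.asarray(self.fold, dtype=float)


def ros_fold_change(
    times_min: Sequence[float], fluorescence: Sequence[float]
) -> RosTimeCourse:
    """Fold change F(t)/F(0) of DCF fluorescence over its baseline.

    The first sample is the pre-treatment baseline and must be
    positive; fold(0) = 1 by construction. Readings are background
    uncorrected by default; subtract a blank before calling if desired.
    """
    times = np.asarray(times_min, dtype=float)
    fluor = np.asarray(fluorescence, dtype=float)
    if times.shape != fluor.shape or times.size == 0:
        raise ValueError("times and fluorescence must be equal-length, non-empty")
    if fluor[0] <= 0:
        raise ValueError("baseline fluorescence must be positive")
    return RosTimeCourse(times_min=times, fluorescence=fluor, fold=fluor / fluor[0])
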