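"""First-order hydrogen peroxide consumption kinetics from electrode traces.

Intact cells consume externally added H2O2; the remaining concentration
decays exponentially and the rate constant k (1/s) is read off the slope
of a semi-logarithmic plot of concentration versus time. Two readouts
are supported: the direct H2O2-specific electrode, and the oxygen
electrode, where exogenous catalase dismutates the remaining peroxide
(2 H2O2 -> 2 H2O + O2) so the O2 signal is half the H2O2 concentration.
The factor of two cancels in the log slope, making k readout-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .containers import DecayTrace

__all__ = ["RateEstimate", "fit_first_order", "compare_rates"]

#: Default exclusion floor for the log transform, as a fraction of C0.
DEFAULT_FLOOR_FRACTION = 0.02


@dataclass
class RateEstimate:
    """First-order rate constant from a semi-log fit of one trace."""

    k: float  # 1/s
    intercept_logC: float  # ln uM
    r_squared: float
    n_points: int
    mode: str
    n_below_floor: int = 0
    consuming: bool = True  # False when the fitted slope is non-negative


def fit_first_order(trace: DecayTrace, floor: float | None = None) -> RateEstimate:
    """Semi-log OLS estimate of the consumption rate constant.

    O2-electrode readings are first converted back to remaining H2O2
    (x2). Points at or below ``floor`` (uM; default 2% of the initial
    concentration) are excluded from the log fit and counted. At least
    4 points must remain. A non-negative slope is not an error - the
    estimate is returned with ``consuming=False`` so a no-consumption
    control can be reported as such.
    """
    values = trace.values * 2.0 if trace.mode == "o2" else trace.values.copy()
    c0 = trace.C0_nominal if trace.C0_nominal is not None else float(values[0])
    if floor is None:
        floor = DEFAULT_FLOOR_FRACTION * c0
    keep = values > floor
    n_below = int(np.sum(~keep))
    times, values = trace.times[keep], values[keep]
    if times.size < 4:
        raise ValueError(
            f"only {times.size} points above the floor ({floor:g} uM); need >= 4"
        )
    res = stats.linregress(times, np.log(values))
    return RateEstimate(
        k=float(-res.slope),
        intercept_logC=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=int(times.size),
        mode=trace.mode,
        n_below_floor=n_below,
        consuming=bool(res.slope < 0),
    )


def compare_rates(
    group_a: Sequence[RateEstimate | float],
    group_b: Sequence[RateEstimate | float],
    label_a: str = "A",
    label_b: str = "B",
) -> dict:
    """Fold change of group B over group A with an optional t-test.

    fold = mean(k_B) / mean(k_A). Groups are identified by explicit
    labels and never reordered. With >= 2 estimates per group an
    unpaired two-sided t-test on the k values is attached.
    """
    ka = np.array([e.k if isinstance(e, RateEstimate) else float(e) for e in group_a])
    kb = np.array([e.k if isinstance(e, RateEstimate) else float(e) for e in group_b])
    if ka.size == 0 or kb.size == 0:
        raise ValueError("both groups need at least one rate estimate")
    mean_a, mean_b = float(ka.mean()), float(kb.mean())
    if mean_a == 0:
        raise ValueError(f"mean rate of group {label_a!r} is zero; fold undefined")
    result = {
        "label_a": label_a,
        "label_b": label_b,
        "mean_a": mean_a,
        "mean_b": mean_b,
        "fold": mean_b / mean_a,
        "n_a": int(ka.size),
        "n_b": int(kb.size),
        "test": None,
    }
    if ka.size >= 2 and kb.size >= 2:
        from .stats_report import unpaired_t_test

        result["test"] = unpaired_t_test(ka, kb)
    return result
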