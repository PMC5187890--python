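import numpy as np
import pytest

from aquaflux import InstrumentSpec, SimCellSpec, compute_geometry

#: Study-condition permeabilities (cm/s) and activation energies
#: (kcal/mol) used as generative ground truth across the suite.
PF_AQP5 = 4.94e-3
PF_CONTROL = 0.41e-3
EA_AQP5 = 6.52
EA_CONTROL = 15.16


@pytest.fixture
def aqp5_cell() -> SimCellSpec:
    """Default shrinkage protocol at channel-level permeability."""
    return SimCellSpec(Pf_true=PF_AQP5)


@pytest.fixture
def instrument() -> InstrumentSpec:
    return InstrumentSpec(seed=42)


@pytest.fixture
def geometry():
    return compute_geometry(5.0)


def grid_exponential_sse(times: np.ndarray, values: np.ndarray,
                         k_grid: np.ndarray) -> float:
    """Brute-force SSE minimizer over k for F = a + b * exp(-k t).

    For each candidate k the amplitude and offset are solved by linear
    least squares; the k with smallest SSE is returned. Independent of
    the package's curve-fitting path.
    """
    best_k, best_sse = None, np.inf
    for k in k_grid:
        e = np.exp(-k * times)
        design = np.column_stack([np.ones_like(times), e])
        coef, *_ = np.linalg.lstsq(design, values, rcond=None)
        resid = values - design @ coef
        sse = float(resid @ resid)
        if sse < best_sse:
            best_k, best_sse = float(k), sse
    return best_k


def grid_decay_sse(times: np.ndarray, values: np.ndarray,
                   k_grid: np.ndarray) -> float:
    """Brute-force SSE minimizer over k for C = C0 * exp(-k t)."""
    best_k, best_sse = None, np.inf
    for k in k_grid:
        e = np.exp(-k * times)
        c0 = float(values @ e) / float(e @ e)
        resid = values - c0 * e
        sse = float(resid @ resid)
        if sse < best_sse:
            best_k, best_sse = float(k), sse
    return best_k
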