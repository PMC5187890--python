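"""Core data containers shared between the generators and the estimators."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Literal

import numpy as np


@dataclass
class GroundTruth:
    """True generative parameters attached to every synthetic artifact.

    A plain name -> value mapping (``Pf_true``, ``k_true``, ``Ea_true``,
    ``expression_true``, ``concentration_true``, ...) that travels with
    the generated data so downstream estimators can be scored by
    parameter recovery. Serialized alongside the data as JSON.
    """

    params: dict[str, Any] = field(default_factory=dict)

    def __getitem__(self, key: str) -> Any:
        return self.params[key]

    def __contains__(self, key: str) -> bool:
        return key in self.params

    def to_dict(self) -> dict[str, Any]:
        return dict(self.params)


@dataclass
class ShrinkageTrace:
    """A stopped-flow shrinkage recording.

    ``values`` is the fluorescence signal (arbitrary units) or, for
    noiseless identity transduction, the relative volume itself.
    ``times`` are seconds from mixing; samples inside the instrument
    dead time have already been dropped.
    """

    times: np.ndarray
    values: np.ndarray
    dead_time: float = 0.0
    temperature_K: float | None = None
    conditions: dict[str, Any] = field(default_factory=dict)
    ground_truth: GroundTruth | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


DecayMode = Literal["h2o2", "o2"]


@dataclass
class DecayTrace:
    """An electrode recording of peroxide consumption by intact cells.

    ``mode`` identifies the readout: ``"h2o2"`` for the direct
    H2O2-specific electrode (values are remaining H2O2, uM) and
    ``"o2"`` for the oxygen electrode, where values are the O2 that
    exogenous catalase would release from the remaining peroxide
    (2 H2O2 -> 2 H2O + O2, so O2 = H2O2 / 2).
    """

    times: np.ndarray
    values: np.ndarray
    mode: DecayMode = "h2o2"
    C0_nominal: float | None = None
    conditions: dict[str, Any] = field(default_factory=dict)
    ground_truth: GroundTruth | None = None
    clipped_points: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.mode not in ("h2o2", "o2"):
            raise ValueError(f"unknown readout mode: {self.mode!r}")

    def __len__(self) -> int:
        return self.times.size
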