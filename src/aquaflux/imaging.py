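"""Line-profile quantification of membrane expression from fluorescence images.

Reproduces the manual ImageJ workflow: a straight line is drawn across
the cell membrane, the intensity profile along it is sampled, a matched
background line from a cell-free region is averaged and subtracted from
the profile peak, and the difference is divided by the maximal
fluorescence to give a relative membrane-expression score in [0, 1].
Per-cell values are the mean of three lines; cohort statistics are
computed over cells, not over pooled lines.

Coordinates are 0-based pixel-centre (row, col), matching
``skimage.measure.profile_line``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.measure import profile_line

__all__ = [
    "LineProfile",
    "MembraneExpression",
    "extract_profile",
    "relative_membrane_expression",
    "aggregate_cells",
    "quantify_membrane",
]


@dataclass
class LineProfile:
    """Intensities sampled along a straight line across a cell membrane."""

    intensities: np.ndarray
    start: tuple[float, float]  # (row, col), 0-based pixel centres
    end: tuple[float, float]
    cell_id: str | None = None
    background: np.ndarray | None = None  # matched-length cell-free profile

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.background is not None:
            self.background = np.asarray(self.background, dtype=float)
            if self.background.shape != self.intensities.shape:
                raise ValueError("background profile must match the line length")

    @property
    def length(self) -> int:
        return self.intensities.size

    @property
    def peak(self) -> float:
        return float(self.intensities.max())


def extract_profile(
    image: np.ndarray,
    start: tuple[float, float],
    end: tuple[float, float],
    cell_id: str | None = None,
    background: np.ndarray | None = None,
) -> LineProfile:
    """Sample an image along a segment by bilinear interpolation.

    ``start`` and ``end`` are (row, col) pixel-centre coordinates; the
    profile is sampled at unit-pixel spacing. Endpoints must lie inside
    the image and the line must have non-zero length.
    """
    image = np.asarray(image, dtype=float)
    for name, (r, c) in (("start", start), ("end", end)):
        if not (0 <= r <= image.shape[0] - 1 and 0 <= c <= image.shape[1] - 1):
            raise ValueError(f"{name} point {(r, c)} outside image bounds")
    if np.hypot(end[0] - start[0], end[1] - start[1]) == 0:
        raise ValueError("zero-length profile line")
    intensities = profile_line(image, start, end, order=1, mode="reflect")
    return LineProfile(
        intensities=intensities,
        start=tuple(start),
        end=tuple(end),
        cell_id=cell_id,
        background=background,
    )


def relative_membrane_expression(
    profile: LineProfile,
    image_max: float,
    background: np.ndarray | None = None,
) -> float:
    """(peak - mean background) / maximal fluorescence, clipped to [0, 1].

    The peak is the maximum sample on the line (no sub-pixel
    refinement). ``image_max`` is the maximal-fluorescence normalizer -
    by default the pipeline uses the maximum pixel of the analysed
    image. A background mean above the peak clips to 0 with a warning.
    """
    if image_max <= 0:
        raise ValueError("image_max must be positive")
    bg = background if background is not None else profile.background
    if bg is None:
        raise ValueError("a matched background profile is required")
    bg_mean = float(np.mean(bg))
    value = (profile.peak - bg_mean) / image_max
    if value < 0:
        warnings.warn(
            f"background mean ({bg_mean:.3g}) exceeds peak ({profile.peak:.3g}); "
            "clipping expression to 0",
            stacklevel=2,
        )
        return 0.0
    return min(value, 1.0)


@dataclass
class MembraneExpression:
    """Cohort-level relative membrane expression."""

    per_line: pd.DataFrame  # columns: cell_id, value
    per_cell: pd.Series  # index: cell_id
    cohort_mean: float
    cohort_sd: float
    n_cells: int
    warnings_: list[str] = field(default_factory=list)


#: Cohort sizes below this draw a warning (the manual protocol scores
#: at least 30 cells per condition).
RECOMMENDED_MIN_CELLS = 30

#: Lines per cell in the manual protocol.
LINES_PER_CELL = 3


def aggregate_cells(per_line_values: Mapping[str, Sequence[float]] | pd.DataFrame) -> MembraneExpression:
    """Average line values per cell, then cells per cohort.

    ``per_line_values`` maps cell_id -> line values, or is a DataFrame
    with columns (cell_id, value). Cells with a number of lines other
    than three are included with a warning, as are cohorts smaller than
    30 cells. The cohort SD (n-1 denominator) is over per-cell means,
    never over pooled lines.
    """
    if isinstance(per_line_values, pd.DataFrame):
        df = per_line_values[["cell_id", "value"]].copy()
    else:
        df = pd.DataFrame(
            [
                (cell, float(v))
                for cell, values in per_line_values.items()
                for v in values
            ],
            columns=["cell_id", "value"],
        )
    if df.empty:
        raise ValueError("at least one cell is required")

    notes: list[str] = []
    counts = df.groupby("cell_id")["value"].count()
    odd = counts[counts != LINES_PER_CELL]
    for cell, n in odd.items():
        msg = f"cell {cell!r} has {n} lines (expected {LINES_PER_CELL}); included"
        warnings.warn(msg, stacklevel=2)
        notes.append(msg)

    per_cell = df.groupby("cell_id")["value"].mean()
    n_cells = int(per_cell.size)
    if n_cells < RECOMMENDED_MIN_CELLS:
        msg = f"cohort has {n_cells} cells; fewer than the recommended {RECOMMENDED_MIN_CELLS}"
        warnings.warn(msg, stacklevel=2)
        notes.append(msg)

    sd = float(per_cell.std(ddof=1)) if n_cells > 1 else float("nan")
    return MembraneExpression(
        per_line=df,
        per_cell=per_cell,
        cohort_mean=float(per_cell.mean()),
        cohort_sd=sd,
        n_cells=n_cells,
        warnings_=notes,
    )


def quantify_membrane(
    image: np.ndarray,
    lines: pd.DataFrame,
    image_max: float | None = None,
    per_profile_max: bool = False,
) -> MembraneExpression:
    """Full pipeline: profiles -> per-line values -> cohort statistics.

    ``lines`` has columns (cell_id, line_id, r0, c0, r1, c1, role) with
    role ``"cell"`` for membrane-crossing lines and ``"background"``
    for cell-free lines; each cell line is paired with the background
    line of the same line_id (or the first background line if ids do
    not match). ``image_max`` defaults to the maximum pixel of the
    analysed image; ``per_profile_max`` normalizes each line by its own
    maximum instead.
    """
    image = np.asarray(image, dtype=float)
    if image_max is None and not per_profile_max:
        image_max = float(image.max())

    bg_rows = lines[lines["role"] == "background"]
    if bg_rows.empty:
        raise ValueError("at least one background line is required")
    bg_profiles = {
        row["line_id"]: extract_profile(
            image, (row["r0"], row["c0"]), (row["r1"], row["c1"])
        ).intensities
        for _, row in bg_rows.iterrows()
    }
    default_bg = next(iter(bg_profiles.values()))

    records = []
    for _, row in lines[lines["role"] == "cell"].iterrows():
        prof = extract_profile(
            image, (row["r0"], row["c0"]), (row["r1"], row["c1"]),
            cell_id=str(row["cell_id"]),
        )
        bg = bg_profiles.get(row["line_id"], default_bg)
        if bg.size != prof.length:  # lengths may differ by a pixel on diagonals
            bg = np.resize(bg, prof.length)
        norm = prof.peak if per_profile_max else image_max
        value = relative_membrane_expression(prof, norm, background=bg)
        records.append((str(row["cell_id"]), value))
    return aggregate_cells(pd.DataFrame(records, columns=["cell_id", "value"]))
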