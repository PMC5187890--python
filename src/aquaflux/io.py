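"""Reading and writing the package's on-disk formats.

Traces go to two-column CSV (time_s, value) with a JSON sidecar for
metadata and ground truth; images to 16-bit grayscale TIFF (PNG is
accepted on read); plate tables to tidy CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile

from .containers import DecayTrace, GroundTruth, ShrinkageTrace


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_trace_csv(trace: ShrinkageTrace | DecayTrace, path: str | Path) -> Path:
    """Write a trace as (time_s, value) CSV plus a JSON metadata sidecar."""
    path = Path(path)
    pd.DataFrame({"time_s": trace.times, "value": trace.values}).to_csv(
        path, index=False
    )
    meta: dict[str, Any] = {"conditions": trace.conditions}
    if isinstance(trace, ShrinkageTrace):
        meta.update({"kind": "shrinkage", "dead_time": trace.dead_time})
        if trace.temperature_K is not None:
            meta["temperature_K"] = trace.temperature_K
    else:
        meta.update(
            {
                "kind": "decay",
                "mode": trace.mode,
                "C0_nominal": trace.C0_nominal,
                "clipped_points": trace.clipped_points,
            }
        )
    if trace.ground_truth is not None:
        meta["ground_truth"] = trace.ground_truth.to_dict()
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, default=float))
    return path


def read_trace_csv(path: str | Path) -> ShrinkageTrace | DecayTrace:
    """Read a trace CSV and its sidecar back into the matching container."""
    path = Path(path)
    df = pd.read_csv(path)
    meta: dict[str, Any] = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    gt = GroundTruth(meta["ground_truth"]) if "ground_truth" in meta else None
    times = df["time_s"].to_numpy(dtype=float)
    values = df["value"].to_numpy(dtype=float)
    if meta.get("kind") == "decay":
        return DecayTrace(
            times=times,
            values=values,
            mode=meta.get("mode", "h2o2"),
            C0_nominal=meta.get("C0_nominal"),
            conditions=meta.get("conditions", {}),
            ground_truth=gt,
            clipped_points=int(meta.get("clipped_points", 0)),
        )
    return ShrinkageTrace(
        times=times,
        values=values,
        dead_time=float(meta.get("dead_time", 0.0)),
        temperature_K=meta.get("temperature_K"),
        conditions=meta.get("conditions", {}),
        ground_truth=gt,
    )


def write_image_tiff(image: np.ndarray, path: str | Path) -> Path:
    """Write an image as 16-bit grayscale TIFF, rescaling into range."""
    path = Path(path)
    img = np.asarray(image, dtype=float)
    img = np.clip(img, 0, None)
    if img.max() > np.iinfo(np.uint16).max:
        img = img / img.max() * np.iinfo(np.uint16).max
    tifffile.imwrite(path, img.astype(np.uint16))
    return path


def read_image(path: str | Path) -> np.ndarray:
    """Read a TIFF or PNG grayscale image as a float array."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path).astype(float)
    import imageio.v3 as iio

    return np.asarray(iio.imread(path), dtype=float)
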