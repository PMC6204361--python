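"""Readers and writers: multi-page TIFF stacks, trace/Ct CSVs, JSON sidecars.

TIFF stacks are written ImageJ-style with pixel size encoded in the
resolution tags and z-spacing in the ImageJ metadata, so physical units
round-trip.  Traces travel as CSV with ``# key: value`` header comments
for the acquisition metadata (flow rate, total content, schedule).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .morphometry import ImageStack, ParticleMeasurement
from .perifusion import PerifusionTrace, RampSchedule, SamplingGrid

__all__ = [
    "write_stack_tiff",
    "read_stack_tiff",
    "write_trace_csv",
    "read_trace_csv",
    "particles_to_frame",
    "write_json",
]


def write_stack_tiff(stack: ImageStack, path: str | Path) -> Path:
    """Write a z-stack as multi-page ImageJ TIFF with physical pixel sizes."""
    path = Path(path)
    px = stack.pixel_size_um
    tifffile.imwrite(
        path,
        stack.voxels.astype(np.float32),
        imagej=True,
        resolution=(1.0 / px, 1.0 / px),
        metadata={"spacing": stack.z_step_um, "unit": "um", "axes": "ZYX"},
    )
    return path


def read_stack_tiff(
    path: str | Path,
    pixel_size_um: float | None = None,
    z_step_um: float | None = None,
) -> ImageStack:
    """Read a multi-page TIFF into an ImageStack.

    Pixel sizes are taken from the file's resolution tags and ImageJ
    metadata when present; explicit arguments override and are required
    when the file carries no calibration.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        voxels = tf.asarray()
        if voxels.ndim == 2:
            voxels = voxels[None, :, :]
        ij = tf.imagej_metadata or {}
        # resolution tags alone are ambiguous (unit defaults to NONE);
        # only trust them when the ImageJ metadata names a spatial unit
        if pixel_size_um is None and ij.get("unit") in ("um", "micron", "µm"):
            xres = tf.pages[0].tags.get("XResolution")
            if xres is not None:
                num, denom = xres.value
                if num > 0:
                    pixel_size_um = denom / num
        if z_step_um is None:
            z_step_um = ij.get("spacing")
    if pixel_size_um is None:
        raise ValueError(
            f"{path.name}: no pixel-size calibration in file; pass pixel_size_um"
        )
    return ImageStack(
        np.asarray(voxels, dtype=float), float(pixel_size_um), float(z_step_um or 1.0)
    )


def write_trace_csv(trace: PerifusionTrace, path: str | Path) -> Path:
    """Write a perifusion trace: metadata header comments + time/insulin rows."""
    path = Path(path)
    sched = trace.schedule
    meta = {
        "flow_rate_ul_min": trace.grid.flow_rate_ul_min,
        "total_content": trace.total_content,
        "normalized": trace.normalized,
        "basal_glucose_mM": sched.basal_glucose_mM,
        "stimulus_label": sched.stimulus_label,
        "stimulus_start_min": sched.stimulus_start_min,
        "stimulus_duration_min": sched.stimulus_duration_min,
    }
    with open(path, "w") as fh:
        for key, value in meta.items():
            if value is not None:
                fh.write(f"# {key}: {value}\n")
        pd.DataFrame(
            {"time_min": trace.times, "insulin": trace.insulin}
        ).to_csv(fh, index=False)
    return path


def read_trace_csv(path: str | Path) -> PerifusionTrace:
    """Read a trace CSV written by :func:`write_trace_csv` (or bare columns)."""
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition(":")
            meta[key.strip()] = value.strip()
            body_start = i + 1
        else:
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])))
    if not {"time_min", "insulin"} <= set(df.columns):
        raise ValueError(f"{path.name}: trace CSV needs time_min and insulin columns")
    grid = SamplingGrid(
        df["time_min"].to_numpy(dtype=float),
        flow_rate_ul_min=float(meta.get("flow_rate_ul_min", 120.0)),
    )
    schedule = RampSchedule(
        basal_glucose_mM=float(meta.get("basal_glucose_mM", 2.8)),
        stimulus_label=meta.get("stimulus_label", "glucose 16.7 mM"),
        stimulus_start_min=float(meta.get("stimulus_start_min", 52.0)),
        stimulus_duration_min=float(meta.get("stimulus_duration_min", 16.0)),
    )
    total = meta.get("total_content")
    return PerifusionTrace(
        grid=grid,
        insulin=df["insulin"].to_numpy(dtype=float),
        schedule=schedule,
        total_content=float(total) if total not in (None, "", "None") else None,
        normalized=meta.get("normalized", "raw"),  # type: ignore[arg-type]
    )


def particles_to_frame(
    particles: Sequence[ParticleMeasurement], image: str | None = None
) -> pd.DataFrame:
    """Tabulate particle measurements, one row per particle."""
    df = pd.DataFrame([asdict(p) for p in particles])
    if image is not None and not df.empty:
        df.insert(0, "image", image)
    return df


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify) + "\n")
    return path


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
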