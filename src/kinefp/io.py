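"""Reading and writing the pipeline's file formats.

Movies travel as multi-page TIFF (16-bit unsigned, counts clipped at 0);
traces, ROI tables, dwell tables, fingerprints and result tables as CSV with
documented column names; configuration as YAML.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .containers import GroundTruth, IntensityTrace, MovieStack
from .imaging import ROI

__all__ = [
    "write_movie_tiff",
    "read_movie_tiff",
    "write_trace_csv",
    "read_trace_csv",
    "write_roi_csv",
    "read_roi_csv",
    "write_yaml",
    "read_yaml",
]

TRACE_COLUMNS = ("frame", "time_s", "intensity")


def write_movie_tiff(path, movie: MovieStack) -> None:
    """Write the stack as uint16 multi-page TIFF (counts clipped at 0/65535)."""
    data = np.clip(np.round(movie.data), 0, 65535).astype(np.uint16)
    tifffile.imwrite(
        str(path),
        data,
        metadata={
            "exposure_s": movie.exposure,
            "pixel_size_um": movie.pixel_size,
            "channel": movie.channel,
        },
    )


def read_movie_tiff(path, exposure: float | None = None,
                    channel: str | None = None) -> MovieStack:
    """Load a multi-page TIFF; exposure is read from metadata when present."""
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    if data.ndim == 2:
        data = data[None]
    return MovieStack(
        data=data.astype(np.float32),
        exposure=float(meta.get("exposure_s", exposure or 1.0)),
        pixel_size=float(meta.get("pixel_size_um", 1.0)),
        channel=str(meta.get("channel", channel or "ch0")),
    )


def write_trace_csv(path, trace: IntensityTrace,
                    truth: GroundTruth | None = None,
                    states: np.ndarray | None = None) -> None:
    """Trace as CSV: frame, time_s, intensity [, true_state] [, state]."""
    df = pd.DataFrame(
        {
            "frame": np.arange(trace.n_frames),
            "time_s": trace.time,
            "intensity": trace.intensity,
        }
    )
    if truth is not None:
        df["true_state"] = truth.states
    if states is not None:
        df["state"] = np.asarray(states, dtype=int)
    df.to_csv(path, index=False)


def read_trace_csv(path, exposure: float | None = None) -> IntensityTrace:
    df = pd.read_csv(path)
    if exposure is None:
        t = df["time_s"].to_numpy()
        exposure = float(t[1] - t[0]) if len(t) > 1 else 1.0
    return IntensityTrace(
        intensity=df["intensity"].to_numpy(dtype=float), exposure=exposure
    )


def write_roi_csv(path, rois: list[ROI]) -> None:
    pd.DataFrame([asdict(r) for r in rois]).to_csv(path, index=False)


def read_roi_csv(path) -> list[ROI]:
    df = pd.read_csv(path)
    return [
        ROI(row=int(r.row), col=int(r.col), peak=float(r.peak),
            channel=str(r.channel))
        for r in df.itertuples()
    ]


def write_yaml(path, obj: dict) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def read_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
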