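"""File formats: trajectory CSV, TIFF stacks, and JSON reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import FrameStack, TrajectorySet

__all__ = [
    "write_trajectories",
    "read_trajectories",
    "write_tiff_stack",
    "read_tiff_stack",
    "write_report",
]

_REQUIRED = ("cell_id", "frame", "t_s", "x_um", "y_um")


def write_trajectories(tset: TrajectorySet, path: str | Path) -> None:
    """Write a trajectory set to CSV (cell_id, frame, t_s, x_um, y_um[, true_state])."""
    df = tset.to_frame()
    extra = tset.meta.get("extra_columns")
    if extra is not None:
        df = df.merge(extra, on=["cell_id", "frame"], how="left")
    df.to_csv(path, index=False)


def read_trajectories(path: str | Path) -> TrajectorySet:
    """Read a trajectory CSV; unknown columns are preserved in the metadata.

    Raises a schema error naming the first missing required column.
    """
    df = pd.read_csv(path)
    for col in _REQUIRED:
        if col not in df.columns:
            raise ValueError(f"trajectory file {path}: missing column {col!r}")
    known = set(_REQUIRED) | {"true_state"}
    extras = [c for c in df.columns if c not in known]
    tset = TrajectorySet.from_frame(df)
    if extras:
        tset.meta["extra_columns"] = df[["cell_id", "frame", *extras]].copy()
    tset.meta["source"] = str(path)
    return tset


def write_tiff_stack(stack: FrameStack, path: str | Path) -> None:
    """Write frames as a 16-bit multi-page TIFF (values clipped to uint16)."""
    data = np.clip(np.round(stack.frames), 0, 65535).astype(np.uint16)
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        metadata={"fps": stack.fps, "pixel_size_um": stack.pixel_size},
    )


def read_tiff_stack(
    path: str | Path, fps: float | None = None, pixel_size: float | None = None
) -> FrameStack:
    """Read a multi-page TIFF as a FrameStack.

    Acquisition metadata written by :func:`write_tiff_stack` is used
    unless overridden.
    """
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if data.ndim == 2:
        data = data[None]
    return FrameStack(
        frames=data.astype(float),
        fps=fps if fps is not None else float(meta.get("fps", 10.0)),
        pixel_size=(
            pixel_size if pixel_size is not None
            else float(meta.get("pixel_size_um", 0.65))
        ),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dataclass_fields__"):
        return _jsonable(
            {k: getattr(obj, k) for k in obj.__dataclass_fields__}
        )
    return obj


def write_report(report: dict, path: str | Path) -> None:
    """Serialize a run report to JSON deterministically (sorted keys)."""
    Path(path).write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True))
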