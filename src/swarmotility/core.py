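"""Core trajectory containers shared across the package."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = ["Trajectory", "TrajectorySet", "FrameStack", "RUN", "TUMBLE"]

# Per-frame motility state labels.
RUN = 0
TUMBLE = 1


@dataclass
class Trajectory:
    """Time-stamped planar positions of one cell.

    ``t`` is in seconds and strictly increasing; ``x``/``y`` are in μm.
    ``true_state`` (optional) carries simulator ground-truth run/tumble
    labels; it is absent for trajectories reconstructed from images.
    """

    cell_id: int
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    true_state: np.ndarray | None = None
    true_motile: bool | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.shape == self.x.shape == self.y.shape):
            raise ValueError("t, x, y must have identical shapes")
        if self.t.size >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("time must be strictly increasing")
        if self.true_state is not None:
            self.true_state = np.asarray(self.true_state, dtype=int)
            if self.true_state.shape != self.t.shape:
                raise ValueError("true_state must align with samples")

    def __len__(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        """Elapsed time between first and last sample, s."""
        if self.t.size == 0:
            return 0.0
        return float(self.t[-1] - self.t[0])

    @property
    def dt(self) -> float:
        """Median sampling interval, s."""
        if self.t.size < 2:
            raise ValueError("need >= 2 samples to define dt")
        return float(np.median(np.diff(self.t)))

    def displacements(self) -> np.ndarray:
        """Frame-to-frame displacement vectors, shape (n-1, 2), μm."""
        return np.column_stack([np.diff(self.x), np.diff(self.y)])


@dataclass
class TrajectorySet:
    """An ordered collection of trajectories plus provenance metadata."""

    trajectories: list[Trajectory] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self) -> Iterator[Trajectory]:
        return iter(self.trajectories)

    def __getitem__(self, i: int) -> Trajectory:
        return self.trajectories[i]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (cell_id, frame, t_s, x_um, y_um[, true_state])."""
        rows = []
        for traj in self.trajectories:
            df = pd.DataFrame(
                {
                    "cell_id": traj.cell_id,
                    "frame": np.arange(len(traj)),
                    "t_s": traj.t,
                    "x_um": traj.x,
                    "y_um": traj.y,
                }
            )
            if traj.true_state is not None:
                df["true_state"] = traj.true_state
            rows.append(df)
        if not rows:
            return pd.DataFrame(
                columns=["cell_id", "frame", "t_s", "x_um", "y_um"]
            )
        return pd.concat(rows, ignore_index=True)

    def durations(self) -> np.ndarray:
        return np.array([tr.duration for tr in self.trajectories])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, meta: dict | None = None) -> "TrajectorySet":
        """Rebuild a set from the long-format table."""
        required = {"cell_id", "t_s", "x_um", "y_um"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing required column(s): {sorted(missing)}")
        trajs = []
        for cid, g in df.groupby("cell_id", sort=True):
            g = g.sort_values("t_s")
            state = (
                g["true_state"].to_numpy()
                if "true_state" in g.columns and g["true_state"].notna().all()
                else None
            )
            trajs.append(
                Trajectory(
                    cell_id=int(cid),
                    t=g["t_s"].to_numpy(),
                    x=g["x_um"].to_numpy(),
                    y=g["y_um"].to_numpy(),
                    true_state=state,
                )
            )
        return cls(trajectories=trajs, meta=meta or {})


@dataclass
class FrameStack:
    """A stack of 2D intensity frames with acquisition metadata.

    ``frames`` has shape (n_frames, height, width); ``fps`` is the frame
    rate and ``pixel_size`` the lateral sampling in μm/px.  ``meta`` may
    carry simulator ground truth (per-frame true centers).
    """

    frames: np.ndarray
    fps: float = 10.0
    pixel_size: float = 0.65
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, h, w) array")
        if self.fps <= 0 or self.pixel_size <= 0:
            raise ValueError("fps and pixel_size must be > 0")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]
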