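"""Per-cell motility statistics from planar trajectories.

The measurement chain mirrors the tracking-based assay: a trajectory is
first classified motile or non-motile by its MSD-derived diffusion
coefficient (Brownian cells fall well below the 10 μm²/s threshold);
motile trajectories are segmented into runs and tumbles, from which the
tumble bias (fraction of frames spent tumbling) and the tumble-excluded
swimming speed derive.  Population summaries weight each cell by its
trajectory duration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import RUN, TUMBLE, Trajectory, TrajectorySet

__all__ = [
    "RunTumbleSegmentation",
    "MotilitySummary",
    "diffusion_coefficient",
    "classify_motile",
    "segment_tumbles",
    "tumble_bias",
    "swim_speed",
    "analyze_trajectory",
    "analyze_population",
    "population_summary",
    "weighted_median",
    "MOTILE_D_THRESHOLD",
]

# Diffusion-coefficient threshold separating swimmers from Brownian cells.
MOTILE_D_THRESHOLD = 10.0  # μm²/s


@dataclass
class RunTumbleSegmentation:
    """Per-frame run/tumble labels for one trajectory."""

    labels: np.ndarray  # RUN/TUMBLE per frame
    dt: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)

    @property
    def tumble_count(self) -> int:
        """Number of distinct tumble episodes."""
        lab = self.labels == TUMBLE
        return int(np.sum(lab[1:] & ~lab[:-1]) + (1 if lab.size and lab[0] else 0))

    @property
    def run_durations(self) -> np.ndarray:
        """Durations of maximal RUN stretches, s."""
        lab = self.labels == RUN
        if lab.size == 0:
            return np.array([])
        change = np.flatnonzero(np.diff(lab.astype(int)) != 0)
        starts = np.concatenate([[0], change + 1])
        ends = np.concatenate([change + 1, [lab.size]])
        lens = (ends - starts)[lab[starts]]
        return lens * self.dt


@dataclass
class MotilitySummary:
    """Per-cell motility metrics; ``weight`` is the trajectory duration."""

    cell_id: int
    diffusion_coefficient: float
    is_motile: bool
    weight: float
    tumble_bias: float = float("nan")
    mean_speed: float = float("nan")


def diffusion_coefficient(
    traj: Trajectory, lag_window: tuple[float, float] = (2.0, 10.0)
) -> float:
    """Diffusion coefficient from the MSD slope (2D: MSD = 4Dτ).

    The MSD is averaged over all pair separations for each lag in
    ``lag_window`` (seconds) and fitted by least squares through the
    origin; the slope over 4 is D in μm²/s.
    """
    if traj.duration < 5.0:
        raise ValueError("trajectory shorter than 5 s")
    dt = traj.dt
    lags = np.arange(max(1, int(round(lag_window[0] / dt))),
                     int(round(lag_window[1] / dt)) + 1)
    lags = lags[lags < len(traj)]
    if lags.size == 0:
        raise ValueError("too few samples for the requested lag window")
    taus = lags * dt
    msd = np.empty(lags.size)
    for i, k in enumerate(lags):
        ddx = traj.x[k:] - traj.x[:-k]
        ddy = traj.y[k:] - traj.y[:-k]
        msd[i] = np.mean(ddx**2 + ddy**2)
    # OLS through the origin
    slope = float(np.sum(msd * taus) / np.sum(taus**2))
    return slope / 4.0


def classify_motile(D: float, threshold: float = MOTILE_D_THRESHOLD) -> bool:
    """Motile iff D >= threshold (boundary inclusive)."""
    return D >= threshold


def segment_tumbles(
    traj: Trajectory,
    alpha: float = 0.18,
    speed_percentile: float = 80.0,
    omega_min: float | None = None,
    merge_gap: float = 0.2,
) -> RunTumbleSegmentation:
    """Label each frame RUN or TUMBLE.

    A frame is a tumble candidate when its instantaneous speed drops
    below ``alpha`` times a per-trajectory run-speed reference (the
    ``speed_percentile``-th percentile of frame speeds, which tracks
    the full run speed regardless of how much time the cell spends
    tumbling or recovering).  Tumble episodes separated by runs shorter
    than ``merge_gap`` seconds are merged (hysteresis).

    ``omega_min`` optionally adds a turn-rate criterion (rad/s, flagging
    high-turn frames slower than the reference).  It is off by default:
    when tumbles are near-stationary the displacement heading is
    noise-dominated and the criterion double-counts episode boundaries.

    The defaults were calibrated against simulator ground truth so that
    the recovered population tumble bias is unbiased across
    TB ∈ [0.02, 0.2]; ``alpha`` is deliberately low because the
    post-tumble speed recovery (~0.5 s) otherwise masquerades as extra
    tumbling.
    """
    n = len(traj)
    if n < 3 or traj.duration < 1.0:
        raise ValueError("need at least 1 s of samples to segment")
    dt = traj.dt
    disp = traj.displacements()
    speed = np.hypot(disp[:, 0], disp[:, 1]) / dt  # length n-1

    ref = np.percentile(speed, speed_percentile)
    flag = speed < alpha * ref
    if omega_min is not None:
        heading = np.arctan2(disp[:, 1], disp[:, 0])
        dthe = np.angle(np.exp(1j * np.diff(heading)))  # wrapped to (-π, π]
        turn_rate = np.zeros(speed.size)
        turn_rate[1:] = np.abs(dthe) / dt
        flag |= (turn_rate > omega_min) & (speed < ref)

    # hysteresis: merge tumble episodes separated by short run gaps
    gap_frames = int(round(merge_gap / dt))
    if gap_frames >= 1 and flag.any():
        idx = np.flatnonzero(flag)
        gaps = np.diff(idx)
        for j, g in enumerate(gaps):
            if 1 < g <= gap_frames:
                flag[idx[j] : idx[j + 1]] = True

    labels = np.full(n, RUN)
    labels[:-1][flag] = TUMBLE
    labels[-1] = labels[-2]
    return RunTumbleSegmentation(labels=labels, dt=dt)


def tumble_bias(seg: RunTumbleSegmentation) -> float:
    """Fraction of frames labeled TUMBLE."""
    if seg.labels.size == 0:
        raise ValueError("empty segmentation")
    return float(np.mean(seg.labels == TUMBLE))


def swim_speed(
    traj: Trajectory,
    seg: RunTumbleSegmentation,
    exclude_recovery: float = 0.5,
    min_speed_fraction: float = 0.8,
    speed_percentile: float = 80.0,
) -> float:
    """Tumble-excluded mean swimming speed, μm/s.

    Averages frame-to-frame displacement over RUN frames, additionally
    skipping (i) ``exclude_recovery`` seconds after each tumble episode,
    where the cell is still accelerating back to full speed, (ii) the
    single frame preceding each episode, whose displacement partially
    overlaps the tumble, and (iii) frames slower than
    ``min_speed_fraction`` of the per-trajectory run-speed reference,
    which belong to short tumbles or recovery stretches the segmenter
    cannot resolve at the frame rate.  Without these exclusions the
    ~0.5 s post-tumble recovery biases the estimate low by 1–2 μm/s.
    """
    n = len(traj)
    disp = traj.displacements()
    dt = seg.dt
    speed = np.hypot(disp[:, 0], disp[:, 1]) / dt
    run_iv = seg.labels[:-1] == RUN  # interval i spans frames i..i+1
    if not run_iv.any():
        raise ValueError("no RUN frames: cannot compute swimming speed")
    keep = run_iv.copy()
    if exclude_recovery > 0:
        n_excl = int(round(exclude_recovery / dt))
        tumble_iv = ~run_iv
        starts = np.flatnonzero(tumble_iv & ~np.roll(tumble_iv, 1))
        ends = np.flatnonzero(tumble_iv[:-1] & ~tumble_iv[1:])  # last frame of episode
        for e in ends:
            keep[e + 1 : e + 1 + n_excl] = False
        for s in starts:
            if s > 0:
                keep[s - 1] = False
    if min_speed_fraction > 0:
        ref = np.percentile(speed, speed_percentile)
        keep &= speed >= min_speed_fraction * ref
    if not keep.any():
        keep = run_iv  # trajectory dominated by recovery: fall back
    return float(np.mean(speed[keep]))


def analyze_trajectory(
    traj: Trajectory,
    motile_threshold: float = MOTILE_D_THRESHOLD,
    **segment_kwargs,
) -> MotilitySummary:
    """Full per-cell analysis: D, motile classification, TB, speed."""
    D = diffusion_coefficient(traj)
    motile = classify_motile(D, motile_threshold)
    summary = MotilitySummary(
        cell_id=traj.cell_id,
        diffusion_coefficient=D,
        is_motile=motile,
        weight=traj.duration,
    )
    if motile:
        seg = segment_tumbles(traj, **segment_kwargs)
        summary.tumble_bias = tumble_bias(seg)
        summary.mean_speed = swim_speed(traj, seg)
    return summary


def analyze_population(
    tset: TrajectorySet, min_duration: float = 5.0, **kwargs
) -> list[MotilitySummary]:
    """Analyze every trajectory of at least ``min_duration`` seconds."""
    return [
        analyze_trajectory(tr, **kwargs)
        for tr in tset
        if tr.duration >= min_duration
    ]


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weight-CDF median with linear interpolation."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0:
        raise ValueError("empty sample")
    if np.any(weights <= 0):
        raise ValueError("weights must be > 0")
    order = np.argsort(values)
    v = values[order]
    w = weights[order]
    cdf = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, cdf, v))


def population_summary(summaries: list[MotilitySummary]) -> dict:
    """Duration-weighted population statistics over motile cells."""
    motile = [s for s in summaries if s.is_motile]
    if not motile:
        raise ValueError("no motile cells in population")
    tb = np.array([s.tumble_bias for s in motile])
    sp = np.array([s.mean_speed for s in motile])
    w = np.array([s.weight for s in motile])
    return {
        "n_total": len(summaries),
        "n_motile": len(motile),
        "motile_fraction": len(motile) / len(summaries),
        "tumble_bias_weighted_mean": float(np.average(tb, weights=w)),
        "tumble_bias_weighted_median": weighted_median(tb, w),
        "speed_weighted_mean": float(np.average(sp, weights=w)),
        "speed_weighted_median": weighted_median(sp, w),
        "tumble_bias_values": tb,
        "speed_values": sp,
        "weights": w,
    }
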