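"""Cell detection and trajectory linking from phase-contrast-like stacks.

The chain mirrors a standard single-particle-tracking pipeline:
(1) the pixelwise temporal mean is subtracted as background;
(2) candidate spots (local intensity maxima) are refined to subpixel
centers by the radial-symmetry-center construction and thresholded by
Benjamini–Hochberg FDR control against a background-noise null;
(3) detections are linked frame-to-frame by minimum-cost bipartite
assignment under a motion model blending constant velocity with random
reorientation, with one-frame gap closing;
(4) trajectories shorter than a minimum duration are discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, maximum_filter, uniform_filter
from scipy.optimize import linear_sum_assignment

from .core import FrameStack, Trajectory, TrajectorySet

__all__ = [
    "compute_background",
    "subtract_background",
    "detect_cells",
    "radial_symmetry_center",
    "link_trajectories",
    "filter_short",
    "track",
]


def compute_background(stack: FrameStack) -> np.ndarray:
    """Pixelwise mean intensity over all frames."""
    if len(stack) < 2:
        raise ValueError("need >= 2 frames to estimate background")
    return stack.frames.mean(axis=0)


def subtract_background(stack: FrameStack) -> FrameStack:
    """Subtract the temporal-mean background, clipping at zero."""
    bg = compute_background(stack)
    residual = np.clip(stack.frames - bg, 0.0, None)
    return FrameStack(
        frames=residual, fps=stack.fps, pixel_size=stack.pixel_size,
        meta=dict(stack.meta),
    )


def radial_symmetry_center(window: np.ndarray) -> tuple[float, float]:
    """Subpixel center of a radially symmetric spot.

    Image gradients are evaluated on the half-pixel dual grid from
    diagonal differences; for a radially symmetric intensity profile
    every gradient vector points through the center, so the center is
    the least-squares intersection of the gradient lines, weighted by
    squared gradient magnitude.  Returns (x, y) in the window's pixel
    coordinates.
    """
    I = np.asarray(window, dtype=float)
    h, w = I.shape
    if h < 3 or w < 3:
        raise ValueError("window too small")
    # diagonal derivatives on the dual grid (midpoints between pixels)
    A = I[1:, 1:] - I[:-1, :-1]  # along (+x, +y)
    B = I[1:, :-1] - I[:-1, 1:]  # along (-x, +y)
    # smooth lightly to stabilize directions
    A = uniform_filter(A, size=3, mode="nearest")
    B = uniform_filter(B, size=3, mode="nearest")
    gx = A - B
    gy = A + B
    mag2 = gx**2 + gy**2
    if not np.any(mag2 > 0):
        return ((w - 1) / 2.0, (h - 1) / 2.0)
    ys, xs = np.mgrid[0 : h - 1, 0 : w - 1]
    px = xs + 0.5
    py = ys + 0.5
    # unit gradient directions
    mag = np.sqrt(mag2)
    nx = np.where(mag > 0, gx / np.where(mag > 0, mag, 1.0), 0.0)
    ny = np.where(mag > 0, gy / np.where(mag > 0, mag, 1.0), 0.0)
    wgt = mag2
    # least squares: sum w (I - nn^T)(c - p) = 0
    a11 = np.sum(wgt * (1 - nx * nx))
    a12 = np.sum(wgt * (-nx * ny))
    a22 = np.sum(wgt * (1 - ny * ny))
    b1 = np.sum(wgt * ((1 - nx * nx) * px - nx * ny * py))
    b2 = np.sum(wgt * (-nx * ny * px + (1 - ny * ny) * py))
    det = a11 * a22 - a12 * a12
    if abs(det) < 1e-12:
        return ((w - 1) / 2.0, (h - 1) / 2.0)
    cx = (a22 * b1 - a12 * b2) / det
    cy = (a11 * b2 - a12 * b1) / det
    return float(cx), float(cy)


def _detect_frame(
    frame: np.ndarray,
    fdr: float,
    neighborhood: int,
    z_min: float,
    refine_half: int,
    smooth_sigma: float,
) -> list[tuple[float, float, float]]:
    """Detections (x, y, score) for one background-subtracted frame."""
    h, w = frame.shape
    # matched filter: smoothing with a PSF-sized Gaussian maximizes the
    # peak SNR of diffraction-limited spots
    sm = gaussian_filter(frame, smooth_sigma) if smooth_sigma > 0 else frame
    footprint = neighborhood
    local_max = (sm == maximum_filter(sm, size=footprint, mode="nearest"))
    med = float(np.median(sm))
    # robust noise scale from the upper quantile: insensitive to the
    # zero-clipping of background subtraction, which empties the lower tail
    sigma = float(np.quantile(sm, 0.8413)) - med
    if sigma <= 0:
        # noiseless frame: any pixel above the median is signal
        peak = float(sm.max())
        if peak <= med:
            return []
        sigma = (peak - med) * 1e-9
    z = (sm - med) / sigma
    cand = local_max & (z >= z_min)
    # filtering edge modes make border maxima unreliable
    margin = max(refine_half, int(math.ceil(2 * smooth_sigma)))
    cand[:margin, :] = cand[-margin:, :] = False
    cand[:, :margin] = cand[:, -margin:] = False
    ys, xs = np.nonzero(cand)
    if ys.size == 0:
        return []
    # p-value under the noise-only null: candidates are local maxima of a
    # smoothed (correlated) Gaussian field, whose peak heights have the
    # heavy survival ~ z^4 exp(-z^2/2) rather than a Gaussian upper tail
    # (the extra polynomial factor is the peak-density correction for a
    # smooth random field, calibrated on pure-noise frames).  Conditioning
    # on the z >= z_min proposal cut keeps null p-values uniform, which
    # Benjamini-Hochberg requires.
    zc = z[ys, xs]

    def _peak_survival(v: np.ndarray | float) -> np.ndarray | float:
        return v**4 * np.exp(-0.5 * v**2)

    pvals = np.clip(_peak_survival(zc) / _peak_survival(z_min), 0.0, 1.0)
    # Benjamini-Hochberg step-up
    order = np.argsort(pvals, kind="stable")
    m = pvals.size
    thresh = fdr * (np.arange(1, m + 1)) / m
    passed = pvals[order] <= thresh
    n_keep = int(np.max(np.nonzero(passed)[0]) + 1) if passed.any() else 0
    keep_idx = order[:n_keep]
    out = []
    for i in keep_idx:
        yy, xx = int(ys[i]), int(xs[i])
        x0, x1 = max(0, xx - refine_half), min(w, xx + refine_half + 1)
        y0, y1 = max(0, yy - refine_half), min(h, yy + refine_half + 1)
        win = sm[y0:y1, x0:x1]
        cx, cy = radial_symmetry_center(win)
        out.append((x0 + cx, y0 + cy, float(sm[yy, xx] - med)))
    return out


def detect_cells(
    stack: FrameStack,
    fdr: float = 0.05,
    neighborhood: int = 5,
    z_min: float = 2.0,
    refine_half: int = 3,
    smooth_sigma: float = 1.3,
) -> pd.DataFrame:
    """Detect subpixel cell centers in every frame of a stack.

    ``stack`` should already be background-subtracted.  Candidates are
    local maxima at least ``z_min`` robust SDs above the frame median
    within a ``neighborhood``-pixel box; they are kept by
    Benjamini–Hochberg at the given false-discovery rate using
    max-statistic null p-values, then refined by the radial-symmetry
    center.  Returns a table (frame, x_px, y_px, score); a flat frame
    yields no rows.
    """
    if not 0.0 < fdr < 1.0:
        raise ValueError(f"fdr must be in (0, 1), got {fdr}")
    rows = []
    for f in range(len(stack)):
        for x, y, s in _detect_frame(
            stack.frames[f], fdr, neighborhood, z_min, refine_half, smooth_sigma
        ):
            rows.append((f, x, y, s))
    return pd.DataFrame(rows, columns=["frame", "x_px", "y_px", "score"])


@dataclass
class _Track:
    xs: list
    ys: list
    frames: list
    misses: int = 0

    def predict(self, n_ahead: int) -> tuple[tuple[float, float], tuple[float, float]]:
        """(constant-velocity, static) position predictions n_ahead frames on."""
        x, y = self.xs[-1], self.ys[-1]
        if len(self.xs) >= 2:
            vx = self.xs[-1] - self.xs[-2]
            vy = self.ys[-1] - self.ys[-2]
            return (x + n_ahead * vx, y + n_ahead * vy), (x, y)
        return (x, y), (x, y)


def link_trajectories(
    detections: pd.DataFrame,
    fps: float = 10.0,
    pixel_size: float = 0.65,
    expected_speed_range: tuple[float, float] = (20.0, 30.0),
    max_gap: int = 1,
    gate_slack: float = 1.6,
) -> TrajectorySet:
    """Link per-frame detections into trajectories.

    The assignment cost between a live track and a detection is the
    squared distance to the nearer of two motion predictions — constant
    velocity (a swimming cell mid-run) and the current position (a
    reorienting or stalled cell).  Costs beyond a gating radius
    (``gate_slack`` × the maximum expected per-frame displacement) are
    infeasible.  Unmatched detections seed new tracks; unmatched tracks
    survive ``max_gap`` frames before closing (gap closing).  Ties are
    resolved deterministically by the Hungarian algorithm on the cost
    matrix in detection-index order.  Coordinates are converted to μm.
    """
    dt = 1.0 / fps
    gate_um = gate_slack * expected_speed_range[1] * dt
    gate_px = gate_um / pixel_size
    birth_cost = gate_px**2 * 1.05

    live: list[_Track] = []
    closed: list[_Track] = []
    if len(detections):
        n_frames = int(detections["frame"].max()) + 1
    else:
        n_frames = 0
    by_frame = dict(tuple(detections.groupby("frame"))) if len(detections) else {}

    for f in range(n_frames):
        dets = by_frame.get(f)
        if dets is None:
            px = np.empty(0)
            py = np.empty(0)
        else:
            px = dets["x_px"].to_numpy()
            py = dets["y_px"].to_numpy()
        n_t, n_d = len(live), px.size
        assigned_det = np.full(n_d, -1)
        if n_t and n_d:
            cost = np.full((n_t, n_d), np.inf)
            for i, tr in enumerate(live):
                (cvx, cvy), (sx, sy) = tr.predict(tr.misses + 1)
                d_cv = (px - cvx) ** 2 + (py - cvy) ** 2
                d_st = (px - sx) ** 2 + (py - sy) ** 2
                c = np.minimum(d_cv, d_st)
                gate2 = ((tr.misses + 1) * gate_px) ** 2
                c[c > gate2] = np.inf
                cost[i] = c
            # pad to allow births/deaths
            big = np.full((n_t + n_d, n_d + n_t), np.inf)
            big[:n_t, :n_d] = cost
            for i in range(n_t):
                big[i, n_d + i] = birth_cost  # death
            for j in range(n_d):
                big[n_t + j, j] = birth_cost  # birth
            big[n_t:, n_d:] = birth_cost * 1.01  # filler block
            finite = np.isfinite(big)
            big[~finite] = 1e12
            rows, cols = linear_sum_assignment(big)
            for r, c in zip(rows, cols):
                if r < n_t and c < n_d and cost[r, c] < birth_cost and np.isfinite(cost[r, c]):
                    tr = live[r]
                    tr.xs.append(float(px[c]))
                    tr.ys.append(float(py[c]))
                    tr.frames.append(f)
                    tr.misses = 0
                    assigned_det[c] = r
        matched_tracks = set(assigned_det[assigned_det >= 0].tolist())
        still_live = []
        for i, tr in enumerate(live):
            if i in matched_tracks:
                still_live.append(tr)
            else:
                tr.misses += 1
                if tr.misses > max_gap:
                    closed.append(tr)
                else:
                    still_live.append(tr)
        live = still_live
        for j in range(n_d):
            if assigned_det[j] < 0:
                live.append(_Track([float(px[j])], [float(py[j])], [f]))
    closed.extend(live)
    closed.sort(key=lambda tr: (tr.frames[0], tr.xs[0], tr.ys[0]))

    trajs = []
    for cid, tr in enumerate(closed):
        frames = np.asarray(tr.frames, dtype=float)
        trajs.append(
            Trajectory(
                cell_id=cid,
                t=frames * dt,
                x=np.asarray(tr.xs) * pixel_size,
                y=np.asarray(tr.ys) * pixel_size,
            )
        )
    return TrajectorySet(
        trajectories=trajs,
        meta={"fps": fps, "pixel_size": pixel_size, "n_detections": int(len(detections))},
    )


def filter_short(tset: TrajectorySet, min_duration: float = 5.0) -> TrajectorySet:
    """Keep trajectories of at least ``min_duration`` seconds."""
    if min_duration < 0:
        raise ValueError("min_duration must be >= 0")
    kept = [tr for tr in tset if tr.duration >= min_duration]
    meta = dict(tset.meta)
    meta["n_before_duration_filter"] = len(tset)
    meta["n_after_duration_filter"] = len(kept)
    return TrajectorySet(trajectories=kept, meta=meta)


def track(
    stack: FrameStack,
    fdr: float = 0.05,
    min_duration: float = 5.0,
    **link_kwargs,
) -> tuple[TrajectorySet, dict]:
    """Full tracking chain; returns (trajectories, stage-count report)."""
    residual = subtract_background(stack)
    detections = detect_cells(residual, fdr=fdr)
    tset = link_trajectories(
        detections, fps=stack.fps, pixel_size=stack.pixel_size, **link_kwargs
    )
    filtered = filter_short(tset, min_duration)
    report = {
        "n_frames": len(stack),
        "n_detections": int(len(detections)),
        "n_tracks_linked": len(tset),
        "n_tracks_kept": len(filtered),
        "fdr": fdr,
        "min_duration_s": min_duration,
    }
    return filtered, report
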