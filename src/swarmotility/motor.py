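"""Tethered-bead flagellar-motor analysis.

A polystyrene bead attached to a truncated flagellar filament orbits the
motor axis; its center coordinates, recorded at high frame rate, encode
the signed rotation of the motor.  This module extracts a signed
rotation-frequency trace (CW positive, CCW negative), counts direction
reversals, and converts CCW speed into torque through a viscous-drag
model of the bead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "BeadTrace",
    "SpeedTrace",
    "DragModel",
    "rotation_speed",
    "count_reversals",
    "torque",
    "analyze_trace",
]


@dataclass
class BeadTrace:
    """Uniformly sampled bead-center coordinates (μm) at ``fps`` frames/s."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    fps: float
    true_sign: np.ndarray | None = None  # simulator ground truth: +1 CW, -1 CCW
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.shape == self.x.shape == self.y.shape):
            raise ValueError("t, x, y must have identical shapes")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")

    def __len__(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.t.size else 0.0


@dataclass
class SpeedTrace:
    """Signed rotation-frequency series, Hz.  CW positive, CCW negative."""

    t: np.ndarray
    frequency: np.ndarray
    smoothing_window: float  # s

    def __len__(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.t.size else 0.0

    @property
    def mean_abs_frequency(self) -> float:
        return float(np.mean(np.abs(self.frequency)))


@dataclass(frozen=True)
class DragModel:
    """Viscous drag on an eccentrically rotating bead.

    The rotational drag coefficient combines rotation of the bead about
    its own axis with translation of its center on a circle of radius
    ``eccentricity``:  ξ = 8πηa³ + 6πηa·r_e².

    Defaults: water-like buffer at room temperature (η = 9.6e-4 Pa·s),
    0.75-μm-diameter bead (a = 0.375 μm), eccentricity 0.2 μm.
    """

    viscosity: float = 9.6e-4  # Pa*s
    bead_radius: float = 0.375  # μm
    eccentricity: float = 0.2  # μm

    def __post_init__(self) -> None:
        if self.viscosity <= 0 or self.bead_radius <= 0:
            raise ValueError("viscosity and bead_radius must be > 0")
        if self.eccentricity < 0:
            raise ValueError("eccentricity must be >= 0")

    @property
    def xi(self) -> float:
        """Drag coefficient in SI units, N·m·s."""
        eta = self.viscosity
        a = self.bead_radius * 1e-6
        re = self.eccentricity * 1e-6
        return 8.0 * math.pi * eta * a**3 + 6.0 * math.pi * eta * a * re**2


def _orbit_center(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Orbit center by algebraic (Kåsa) circle fit; exact for true circles.

    Falls back to the median position if the fit is degenerate (e.g. all
    points collinear).
    """
    # the closed form requires centroid-centered coordinates
    mx, my = np.mean(x), np.mean(y)
    u = x - mx
    v = y - my
    Suu = np.sum(u * u)
    Svv = np.sum(v * v)
    Suv = np.sum(u * v)
    Suuu = np.sum(u * u * u)
    Svvv = np.sum(v * v * v)
    Suvv = np.sum(u * v * v)
    Svuu = np.sum(v * u * u)
    det = Suu * Svv - Suv * Suv
    if abs(det) < 1e-12 * max(Suu, Svv, 1.0) ** 2:
        return float(mx), float(my)
    b1 = 0.5 * (Suuu + Suvv)
    b2 = 0.5 * (Svvv + Svuu)
    uc = (Svv * b1 - Suv * b2) / det
    vc = (Suu * b2 - Suv * b1) / det
    return float(mx + uc), float(my + vc)


def rotation_speed(trace: BeadTrace, smoothing_window: float = 0.008) -> SpeedTrace:
    """Signed rotation frequency from bead-center coordinates.

    The orbit center comes from a least-squares circle fit to the bead
    positions; the bead angle about it is unwrapped and differentiated
    with a local quadratic (Savitzky–Golay) filter over
    ``smoothing_window`` seconds.  In right-handed image
    coordinates CCW rotation increases the angle, so the signed
    frequency is the negated angle derivative over 2π (CW positive).
    """
    if len(trace) < max(5, int(0.1 * trace.fps)):
        raise ValueError("need at least 0.1 s of samples")
    cx, cy = _orbit_center(trace.x, trace.y)
    rx = trace.x - cx
    ry = trace.y - cy
    radius = np.hypot(rx, ry)
    if np.median(radius) <= 0:
        raise ValueError("degenerate orbit: bead does not move around a center")
    theta = np.unwrap(np.arctan2(ry, rx))
    win = int(round(smoothing_window * trace.fps))
    win = max(5, win | 1)  # odd, >= 5 samples
    dtheta_dt = savgol_filter(
        theta, window_length=win, polyorder=2, deriv=1, delta=1.0 / trace.fps,
        mode="interp",
    )
    freq = -dtheta_dt / (2.0 * math.pi)
    return SpeedTrace(t=trace.t, frequency=freq, smoothing_window=win / trace.fps)


def _sign_segments(sign: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encode a ±1 array -> (segment_signs, segment_lengths)."""
    change = np.flatnonzero(np.diff(sign) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [sign.size]])
    return sign[starts], ends - starts


def count_reversals(
    speed: SpeedTrace, debounce: float = 0.01, fps: float | None = None
) -> dict:
    """Count motor direction reversals in a signed frequency trace.

    A reversal is a zero crossing whose new sign persists for at least
    ``debounce`` seconds; shorter excursions are treated as noise and
    merged into the surrounding segment.  Returns reversals/min, the CW
    time fraction, and the raw reversal count.
    """
    n = len(speed)
    if n < 2:
        raise ValueError("speed trace too short")
    dt = (speed.t[-1] - speed.t[0]) / (n - 1)
    min_len = max(1, int(round(debounce / dt)))
    sign = np.where(speed.frequency >= 0, 1, -1)
    seg_signs, seg_lens = _sign_segments(sign)
    # Iteratively absorb sub-debounce segments into their neighbors.
    segs = list(zip(seg_signs.tolist(), seg_lens.tolist()))
    changed = True
    while changed and len(segs) > 1:
        changed = False
        # find shortest segment below threshold
        idx = min(range(len(segs)), key=lambda i: segs[i][1])
        if segs[idx][1] < min_len:
            s, L = segs.pop(idx)
            if idx > 0 and idx < len(segs) and segs[idx - 1][0] == segs[idx][0]:
                merged = (segs[idx - 1][0], segs[idx - 1][1] + L + segs[idx][1])
                segs[idx - 1] = merged
                segs.pop(idx)
            elif idx > 0:
                segs[idx - 1] = (segs[idx - 1][0], segs[idx - 1][1] + L)
            else:
                segs[0] = (segs[0][0], segs[0][1] + L)
            changed = True
    n_reversals = max(0, len(segs) - 1)
    duration = speed.duration
    cw_time = sum(L for s, L in segs if s > 0) * dt
    return {
        "n_reversals": n_reversals,
        "reversals_per_min": n_reversals / (duration / 60.0),
        "cw_fraction": cw_time / (len(speed) * dt),
    }


def torque(ccw_frequency: float, drag: DragModel | None = None) -> float:
    """Motor torque in pN·nm from the CCW rotation frequency (Hz).

    τ = 2π·f·ξ with ξ the bead drag coefficient; 1 N·m = 1e21 pN·nm.
    """
    if drag is None:
        drag = DragModel()
    if ccw_frequency < 0:
        raise ValueError("pass the unsigned CCW frequency (Hz)")
    return 2.0 * math.pi * ccw_frequency * drag.xi * 1e21


def analyze_trace(
    trace: BeadTrace,
    smoothing_window: float = 0.008,
    debounce: float = 0.01,
    drag: DragModel | None = None,
) -> dict:
    """Full per-motor summary: mean |f|, reversals/min, CW fraction, torque."""
    speed = rotation_speed(trace, smoothing_window=smoothing_window)
    rev = count_reversals(speed, debounce=debounce)
    ccw = speed.frequency[speed.frequency < 0]
    mean_ccw = float(-np.mean(ccw)) if ccw.size else 0.0
    return {
        "mean_abs_frequency_hz": speed.mean_abs_frequency,
        "mean_ccw_frequency_hz": mean_ccw,
        "reversals_per_min": rev["reversals_per_min"],
        "cw_fraction": rev["cw_fraction"],
        "torque_pn_nm": torque(mean_ccw, drag) if mean_ccw > 0 else 0.0,
    }
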