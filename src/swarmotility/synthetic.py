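"""Synthetic-data generators for every input the pipeline consumes.

The generators emulate the four experimental data streams of the study:

* pseudo-2D run-and-tumble swimming (with a Brownian non-motile
  subpopulation) sampled at the tracking frame rate, optionally
  rendered into phase-contrast-like image stacks;
* two-state CW/CCW motor telegraph processes rendered as orbiting
  bead-center coordinates at high frame rate;
* first-order protein-decay time courses with multiplicative
  (lognormal) noise, as produced by chloramphenicol-chase westerns;
* two-channel fluorescence scenes of elliptical cells with per-cell
  expression variability.

All generators are deterministic for a fixed seed, and every output
carries its ground truth (per-frame run/tumble state, motor rotation
sign, per-cell expression totals) so that downstream estimators can be
calibrated and tested without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import RUN, TUMBLE, FrameStack, Trajectory, TrajectorySet
from .blotquant import DecayCourse
from .motor import BeadTrace
from .presets import (
    DecayPreset,
    FluorScenePreset,
    MotilityPreset,
    MotorPreset,
)

__all__ = [
    "simulate_trajectory",
    "simulate_population",
    "render_frames",
    "simulate_motor_trace",
    "simulate_decay",
    "render_fluor_scene",
    "FluorScene",
]

# Internal integration substeps per sampling interval for swimming cells.
_SUBSTEPS = 5


def _simulate_motile(
    preset: MotilityPreset, duration: float, dt: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integrate one run-and-tumble cell; returns (x, y, state) at substeps."""
    h = dt / _SUBSTEPS
    n_sub = int(round(duration / dt)) * _SUBSTEPS + 1
    t_sub = np.arange(n_sub) * h

    if preset.tumble_bias_true == 0.0:
        run_mask = np.ones(n_sub, dtype=bool)
        seg_idx = np.zeros(n_sub, dtype=int)
        seg_starts = np.array([0.0])
        seg_is_run = np.array([True])
    else:
        seg_starts, seg_is_run = _run_tumble_intervals(rng, preset, duration)
        seg_idx = np.searchsorted(seg_starts, t_sub, side="right") - 1
        run_mask = seg_is_run[seg_idx]

    # Headings: rotational diffusion during runs, uniform redraw at each
    # tumble->run transition.  Heading is frozen during tumbles.
    dtheta = rng.normal(0.0, math.sqrt(2.0 * preset.rotational_diffusion * h), n_sub)
    dtheta[~run_mask] = 0.0
    base = np.cumsum(dtheta)
    theta0 = rng.uniform(0.0, 2.0 * math.pi, seg_starts.size)
    # heading resets at the start of each run segment; within a segment the
    # diffusion increments accumulate from the segment's first substep
    first_sub_of_seg = np.searchsorted(t_sub, seg_starts, side="left")
    base_at_start = base[np.clip(first_sub_of_seg, 0, n_sub - 1)]
    # a run segment inherits theta0 drawn for it; tumble segments keep the
    # (unused) frozen heading
    theta = theta0[seg_idx] + base - base_at_start[seg_idx]

    # Speed: exponential recovery toward run_speed after each tumble exit.
    time_in_seg = t_sub - seg_starts[seg_idx]
    if preset.speed_recovery_tau > 0:
        recovery = 1.0 - np.exp(-time_in_seg / preset.speed_recovery_tau)
    else:
        recovery = np.ones(n_sub)
    # cells that begin the trace mid-run start at full speed
    if seg_is_run.size and seg_is_run[0]:
        recovery[seg_idx == 0] = 1.0
    v = np.where(run_mask, preset.run_speed * recovery, 0.0)

    step = v * h
    x = np.concatenate([[0.0], np.cumsum(step * np.cos(theta))[:-1]])
    y = np.concatenate([[0.0], np.cumsum(step * np.sin(theta))[:-1]])
    state = np.where(run_mask, RUN, TUMBLE)
    return x, y, state


def _run_tumble_intervals(
    rng: np.random.Generator, preset: MotilityPreset, duration: float
) -> tuple[np.ndarray, np.ndarray]:
    """Alternating exponential run/tumble intervals covering [0, duration)."""
    starts = [0.0]
    in_run = rng.random() >= preset.tumble_bias_true
    states = [in_run]
    t = 0.0
    while True:
        mean = preset.mean_run_duration if in_run else preset.mean_tumble_duration
        t += rng.exponential(mean)
        if t >= duration:
            break
        in_run = not in_run
        starts.append(t)
        states.append(in_run)
    return np.asarray(starts), np.asarray(states, dtype=bool)


def simulate_trajectory(
    preset: MotilityPreset,
    duration: float,
    dt: float,
    seed: int | np.random.Generator,
    motile: bool = True,
    origin: tuple[float, float] = (0.0, 0.0),
) -> Trajectory:
    """Simulate one cell trajectory sampled every ``dt`` seconds.

    Motile cells alternate exponential runs and tumbles so that the
    expected fraction of time tumbling equals ``tumble_bias_true``.
    During runs the heading diffuses rotationally and the speed relaxes
    exponentially toward ``run_speed`` after each tumble; tumbles are
    stationary and exit with a fresh uniform heading.  Non-motile cells
    perform Brownian motion with diffusivity ``brownian_D``.  Reported
    positions carry isotropic Gaussian localization noise.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if duration < dt:
        raise ValueError(f"duration ({duration}) must be >= dt ({dt})")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(round(duration / dt)) + 1
    t = np.arange(n) * dt

    if motile:
        xs, ys, state_sub = _simulate_motile(preset, duration, dt, rng)
        x = xs[::_SUBSTEPS]
        y = ys[::_SUBSTEPS]
        state = state_sub[::_SUBSTEPS]
    else:
        sigma_step = math.sqrt(2.0 * preset.brownian_D * dt)
        x = np.concatenate([[0.0], np.cumsum(rng.normal(0, sigma_step, n - 1))])
        y = np.concatenate([[0.0], np.cumsum(rng.normal(0, sigma_step, n - 1))])
        state = np.full(n, RUN)

    if preset.localization_sigma > 0:
        x = x + rng.normal(0.0, preset.localization_sigma, n)
        y = y + rng.normal(0.0, preset.localization_sigma, n)
    return Trajectory(
        cell_id=0,
        t=t,
        x=x + origin[0],
        y=y + origin[1],
        true_state=state,
        true_motile=motile,
    )


def simulate_population(
    preset: MotilityPreset,
    n_cells: int,
    duration: float,
    dt: float,
    seed: int,
    arena: float | tuple[float, float] | None = None,
) -> TrajectorySet:
    """Simulate a mixed motile/non-motile population.

    A fraction ``preset.nonmotile_fraction`` of cells (rounded to the
    nearest count, assigned by a seeded shuffle) is Brownian.  Per-cell
    seeds derive deterministically from the master ``seed``.  If
    ``arena`` is given, initial positions are scattered uniformly in a
    square: side length ``arena`` μm from the origin, or the interval
    ``(lo, hi)`` μm per axis.  Otherwise all cells start at the origin.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    master = np.random.default_rng(seed)
    n_nonmotile = int(round(preset.nonmotile_fraction * n_cells))
    motile_flags = np.ones(n_cells, dtype=bool)
    motile_flags[:n_nonmotile] = False
    master.shuffle(motile_flags)
    child_seeds = master.spawn(n_cells)
    if arena is None:
        box = None
    elif np.isscalar(arena):
        box = (0.0, float(arena))
    else:
        box = (float(arena[0]), float(arena[1]))
    trajs = []
    for i in range(n_cells):
        origin = (
            tuple(master.uniform(box[0], box[1], 2)) if box is not None else (0.0, 0.0)
        )
        traj = simulate_trajectory(
            preset,
            duration,
            dt,
            seed=np.random.default_rng(child_seeds[i]),
            motile=bool(motile_flags[i]),
            origin=origin,
        )
        traj.cell_id = i
        trajs.append(traj)
    return TrajectorySet(
        trajectories=trajs,
        meta={
            "seed": seed,
            "preset": preset,
            "dt": dt,
            "duration": duration,
            "fps": 1.0 / dt,
        },
    )


def render_frames(
    tset: TrajectorySet,
    pixel_size: float = 0.65,
    psf_sigma: float = 1.3,
    snr: float = 10.0,
    frame_size: tuple[int, int] = (256, 256),
    noise_sigma: float = 10.0,
    background: float = 100.0,
    fps: float | None = None,
) -> FrameStack:
    """Render a trajectory set as a stack of spot images.

    Each cell is drawn as a 2D Gaussian of width ``psf_sigma`` px and
    peak amplitude ``snr * noise_sigma`` on a uniform background with
    additive Gaussian noise.  Positions (μm) map to pixels through
    ``pixel_size``; all positions must fall inside the frame.  The
    ground-truth per-frame centers are kept in ``meta['truth']``.
    """
    h, w = frame_size
    n_frames = max(len(tr) for tr in tset) if len(tset) else 0
    if fps is None:
        fps = float(tset.meta.get("fps", 10.0))
    offenders = []
    for tr in tset:
        px = tr.x / pixel_size
        py = tr.y / pixel_size
        if np.any(px < 0) or np.any(px > w - 1) or np.any(py < 0) or np.any(py > h - 1):
            offenders.append(tr.cell_id)
    if offenders:
        raise ValueError(f"cells out of frame after scaling: {offenders}")

    # noiseless stacks keep a finite spot amplitude (snr is then nominal)
    amp = snr * (noise_sigma if noise_sigma > 0 else 10.0)
    rng = np.random.default_rng(int(tset.meta.get("seed", 0)) + 7)
    frames = rng.normal(background, noise_sigma, (max(n_frames, 1), h, w)) if noise_sigma > 0 else np.full((max(n_frames, 1), h, w), float(background))
    truth_rows = []
    half = max(3, int(math.ceil(4 * psf_sigma)))
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    for tr in tset:
        px_all = tr.x / pixel_size
        py_all = tr.y / pixel_size
        for f in range(len(tr)):
            cx, cy = px_all[f], py_all[f]
            ix, iy = int(round(cx)), int(round(cy))
            x0, x1 = max(0, ix - half), min(w, ix + half + 1)
            y0, y1 = max(0, iy - half), min(h, iy + half + 1)
            gx = xx[(y0 - iy + half) : (y1 - iy + half), (x0 - ix + half) : (x1 - ix + half)] + ix
            gy = yy[(y0 - iy + half) : (y1 - iy + half), (x0 - ix + half) : (x1 - ix + half)] + iy
            frames[f, y0:y1, x0:x1] += amp * np.exp(
                -((gx - cx) ** 2 + (gy - cy) ** 2) / (2.0 * psf_sigma**2)
            )
            truth_rows.append((f, tr.cell_id, cx, cy))
    truth = pd.DataFrame(truth_rows, columns=["frame", "cell_id", "x_px", "y_px"])
    return FrameStack(
        frames=frames,
        fps=fps,
        pixel_size=pixel_size,
        meta={"truth": truth, "snr": snr, "noise_sigma": noise_sigma,
              "background": background, "psf_sigma": psf_sigma},
    )


def simulate_motor_trace(
    preset: MotorPreset, duration: float, seed: int | np.random.Generator
) -> BeadTrace:
    """Simulate a tethered-bead trace from a CW/CCW telegraph motor.

    The motor switches between CCW (angle increasing; the default
    low-CW-bias state) and CW with rates chosen so the expected number
    of reversals per minute equals ``reversal_rate`` and the stationary
    CW time fraction equals ``cw_bias``.  The bead center orbits at
    ``orbit_radius`` with angular speed ±2π·frequency plus Gaussian
    positional jitter.  Ground-truth per-sample rotation signs
    (+1 CW, −1 CCW) are stored on the trace.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    fps = preset.fps
    n = int(round(duration * fps)) + 1
    t = np.arange(n) / fps

    k_cc2cw, k_cw2cc = preset.switching_rates
    if preset.reversal_rate == 0:
        # locked motor: CW if cw_bias rounds to 1, else CCW
        cw0 = preset.cw_bias >= 0.5
        starts = np.array([0.0])
        is_cw = np.array([cw0])
    else:
        starts_l = [0.0]
        cw = rng.random() < preset.cw_bias
        states_l = [cw]
        tt = 0.0
        while True:
            rate = k_cw2cc if cw else k_cc2cw
            tt += rng.exponential(1.0 / rate)
            if tt >= duration:
                break
            cw = not cw
            starts_l.append(tt)
            states_l.append(cw)
        starts = np.asarray(starts_l)
        is_cw = np.asarray(states_l, dtype=bool)

    # Piecewise-linear unwrapped angle: slope +2πf_ccw during CCW
    # (right-handed convention: CCW increases the angle), −2πf_cw during CW.
    omegas = np.where(is_cw, -2.0 * math.pi * preset.cw_frequency,
                      2.0 * math.pi * preset.ccw_frequency)
    seg_ends = np.concatenate([starts[1:], [duration]])
    seg_lens = seg_ends - starts
    angle_knots = np.concatenate([[0.0], np.cumsum(omegas * seg_lens)])
    knot_times = np.concatenate([starts, [duration]])
    theta0 = rng.uniform(0.0, 2.0 * math.pi)
    theta = theta0 + np.interp(t, knot_times, angle_knots)

    x = preset.orbit_radius * np.cos(theta)
    y = preset.orbit_radius * np.sin(theta)
    if preset.center_jitter_sigma > 0:
        x = x + rng.normal(0.0, preset.center_jitter_sigma, n)
        y = y + rng.normal(0.0, preset.center_jitter_sigma, n)
    seg_idx = np.searchsorted(starts, t, side="right") - 1
    true_sign = np.where(is_cw[seg_idx], 1, -1)
    return BeadTrace(
        t=t, x=x, y=y, fps=fps, true_sign=true_sign,
        meta={"preset": preset},
    )


def simulate_decay(
    preset: DecayPreset, n_replicates: int, seed: int
) -> list[DecayCourse]:
    """Generate chase time courses I(t) = I₀·exp(−k·t)·ε with lognormal ε.

    Noise is independent across time points and replicates;
    ``lognormal_sigma`` is the log-scale SD.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    times = np.asarray(preset.sample_times, dtype=float)
    courses = []
    for rep in range(n_replicates):
        clean = preset.initial_intensity * np.exp(-preset.decay_rate * times)
        eps = (
            np.exp(rng.normal(0.0, preset.lognormal_sigma, times.size))
            if preset.lognormal_sigma > 0
            else np.ones(times.size)
        )
        courses.append(
            DecayCourse(
                replicate_id=rep,
                t=times,
                intensity=clean * eps,
                meta={"true_rate": preset.decay_rate},
            )
        )
    return courses


@dataclass
class FluorScene:
    """A rendered two-channel fluorescence scene plus ground truth.

    ``yfp``/``cherry`` are the two fluorescence channels, ``phase`` a
    cell-body reference image for segmentation, ``labels`` the
    ground-truth label mask (0 background), and ``truth`` the per-cell
    drawn expression totals.
    """

    yfp: np.ndarray
    cherry: np.ndarray
    phase: np.ndarray
    labels: np.ndarray
    truth: pd.DataFrame
    meta: dict = field(default_factory=dict)


def render_fluor_scene(
    preset: FluorScenePreset,
    seed: int,
    image_size: tuple[int, int] = (384, 384),
    shot_noise: bool = True,
    max_attempts: int = 5000,
) -> FluorScene:
    """Render non-overlapping elliptical cells in two fluorescence channels.

    Per-cell total intensities are lognormal around the channel means
    with coefficient of variation ``expression_cv`` and are spread
    uniformly over the cell pixels; a uniform background and per-cell
    autofluorescence are added, then Poisson shot noise is applied.
    """
    rng = np.random.default_rng(seed)
    h, w = image_size
    labels = np.zeros((h, w), dtype=int)
    yy, xx = np.mgrid[0:h, 0:w]

    placed = 0
    attempts = 0
    rows = []
    cv = preset.expression_cv
    log_sigma = math.sqrt(math.log(1.0 + cv**2)) if cv > 0 else 0.0

    while placed < preset.n_cells:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {preset.n_cells} non-overlapping cells in "
                f"{image_size} after {max_attempts} attempts"
            )
        area = max(20.0, rng.normal(preset.mean_area, preset.area_sd))
        aspect = rng.uniform(2.0, 4.0)  # rod-shaped cells
        b_ax = math.sqrt(area / (math.pi * aspect))
        a_ax = aspect * b_ax
        phi = rng.uniform(0.0, math.pi)
        cx = rng.uniform(a_ax + 2, w - a_ax - 2)
        cy = rng.uniform(a_ax + 2, h - a_ax - 2)
        dx = xx - cx
        dy = yy - cy
        u = dx * math.cos(phi) + dy * math.sin(phi)
        v = -dx * math.sin(phi) + dy * math.cos(phi)
        mask = (u / a_ax) ** 2 + (v / b_ax) ** 2 <= 1.0
        # forbid touching: dilate-by-margin via a slightly larger ellipse
        margin = 2.0
        near = (u / (a_ax + margin)) ** 2 + (v / (b_ax + margin)) ** 2 <= 1.0
        if np.any(labels[near] > 0):
            continue
        placed += 1
        labels[mask] = placed
        npx = int(mask.sum())

        def draw_total(mean: float) -> float:
            if mean == 0:
                return 0.0
            if log_sigma == 0:
                return mean
            mu = math.log(mean) - 0.5 * log_sigma**2
            return float(np.exp(rng.normal(mu, log_sigma)))

        yfp_tot = draw_total(preset.yfp_mean)
        cherry_tot = draw_total(preset.cherry_mean)
        rows.append((placed, npx, yfp_tot, cherry_tot))

    truth = pd.DataFrame(rows, columns=["cell_id", "area_px", "yfp_total", "cherry_total"])

    def build_channel(col: str) -> np.ndarray:
        img = np.full((h, w), float(preset.background_level))
        for cid, npx, yfp_tot, cherry_tot in truth.itertuples(index=False):
            total = yfp_tot if col == "yfp" else cherry_tot
            per_px = (total + preset.autofluorescence) / npx
            img[labels == cid] += per_px
        if shot_noise:
            img = rng.poisson(img).astype(float)
        return img

    yfp = build_channel("yfp")
    cherry = build_channel("cherry")
    phase = np.where(labels > 0, 1000.0, 100.0)
    phase = rng.normal(phase, 20.0) if shot_noise else phase
    return FluorScene(
        yfp=yfp,
        cherry=cherry,
        phase=phase,
        labels=labels,
        truth=truth,
        meta={"preset": preset, "seed": seed},
    )
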