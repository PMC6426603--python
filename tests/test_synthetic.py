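import numpy as np
import pytest

from swarmotility.core import TUMBLE
from swarmotility.presets import (
    DecayPreset,
    make_decay_preset,
    make_fluor_preset,
    make_motor_preset,
    make_preset,
)
from swarmotility.synthetic import (
    render_fluor_scene,
    render_frames,
    simulate_decay,
    simulate_motor_trace,
    simulate_population,
    simulate_trajectory,
)


class TestTrajectorySimulation:
    def test_no_tumble_no_noise_is_straight_constant_speed(self):
        p = make_preset(
            "liquid", tumble_bias_true=0.0, rotational_diffusion=0.0,
            localization_sigma=0.0,
        )
        tr = simulate_trajectory(p, 10.0, 0.1, seed=0)
        speeds = np.hypot(np.diff(tr.x), np.diff(tr.y)) / 0.1
        assert np.allclose(speeds, 21.0, atol=1e-9)
        # straight: all displacement headings identical
        headings = np.arctan2(np.diff(tr.y), np.diff(tr.x))
        assert np.allclose(headings, headings[0])

    def test_state_label_fraction_matches_tumble_bias(self):
        # law of large numbers over many cells, counted from simulator state
        p = make_preset("liquid")
        fractions = []
        for s in range(300):
            tr = simulate_trajectory(p, 100.0, 0.1, seed=s)
            fractions.append(np.mean(tr.true_state == TUMBLE))
        assert abs(np.mean(fractions) - 0.12) < 0.005

    def test_brownian_msd_slope_recovers_diffusivity(self):
        p = make_preset("liquid", brownian_D=0.4, localization_sigma=0.0)
        slopes = []
        for s in range(50):
            tr = simulate_trajectory(p, 100.0, 0.1, seed=s, motile=False)
            k = 10  # 1 s lag
            msd = np.mean(
                (tr.x[k:] - tr.x[:-k]) ** 2 + (tr.y[k:] - tr.y[:-k]) ** 2
            )
            slopes.append(msd / (4 * k * 0.1))
        assert abs(np.mean(slopes) - 0.4) < 0.05

    def test_duration_must_cover_dt(self):
        p = make_preset("liquid")
        with pytest.raises(ValueError):
            simulate_trajectory(p, 0.05, 0.1, seed=0)
        with pytest.raises(ValueError):
            simulate_trajectory(p, 10.0, -0.1, seed=0)

    def test_seed_determinism(self):
        p = make_preset("liquid")
        a = simulate_trajectory(p, 20.0, 0.1, seed=7)
        b = simulate_trajectory(p, 20.0, 0.1, seed=7)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)
        assert np.array_equal(a.true_state, b.true_state)


class TestPopulation:
    def test_nonmotile_fraction_one_gives_all_brownian(self):
        p = make_preset("liquid", nonmotile_fraction=1.0)
        ts = simulate_population(p, 20, 10.0, 0.1, seed=0)
        assert all(tr.true_motile is False for tr in ts)

    def test_ground_truth_labels_stored(self):
        p = make_preset("liquid", nonmotile_fraction=0.3)
        ts = simulate_population(p, 50, 10.0, 0.1, seed=1)
        n_nonmotile = sum(not tr.true_motile for tr in ts)
        assert n_nonmotile == 15
        assert all(tr.true_state is not None for tr in ts)

    def test_same_seed_identical_output(self):
        p = make_preset("swarm")
        a = simulate_population(p, 10, 10.0, 0.1, seed=5)
        b = simulate_population(p, 10, 10.0, 0.1, seed=5)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.x, tb.x)
            assert np.array_equal(ta.y, tb.y)


class TestRenderFrames:
    def test_brightest_pixel_at_stationary_cell(self):
        from swarmotility.core import Trajectory, TrajectorySet

        t = np.arange(5) * 0.1
        tr = Trajectory(0, t, np.full(5, 30 * 0.65), np.full(5, 40 * 0.65))
        stack = render_frames(
            TrajectorySet([tr]), noise_sigma=0.0, frame_size=(64, 64)
        )
        iy, ix = np.unravel_index(np.argmax(stack.frames[0]), (64, 64))
        assert (ix, iy) == (30, 40)

    def test_empty_set_is_pure_noise(self):
        from swarmotility.core import TrajectorySet

        stack = render_frames(TrajectorySet([]), frame_size=(32, 32),
                              background=100.0, noise_sigma=5.0)
        assert stack.frames.shape == (1, 32, 32)
        assert abs(stack.frames.mean() - 100.0) < 2.0

    def test_out_of_frame_cells_reported(self):
        p = make_preset("liquid")
        ts = simulate_population(p, 3, 5.0, 0.1, seed=0)  # starts at origin
        with pytest.raises(ValueError, match="out of frame"):
            render_frames(ts, frame_size=(32, 32))

    def test_ground_truth_metadata_present(self):
        p = make_preset("liquid")
        ts = simulate_population(p, 5, 2.0, 0.1, seed=2, arena=(60.0, 100.0))
        stack = render_frames(ts, frame_size=(256, 256))
        truth = stack.meta["truth"]
        assert set(truth.columns) == {"frame", "cell_id", "x_px", "y_px"}
        assert truth.cell_id.nunique() == 5


class TestMotorTraces:
    def test_locked_ccw_motor_constant_orbit(self):
        p = make_motor_preset(
            "liquid", reversal_rate=0.0, cw_bias=0.0, center_jitter_sigma=0.0
        )
        tr = simulate_motor_trace(p, 1.0, seed=0)
        r = np.hypot(tr.x, tr.y)
        assert np.allclose(r, p.orbit_radius, atol=1e-12)
        assert np.all(tr.true_sign == -1)

    def test_orbit_radius_from_circle_fit(self):
        p = make_motor_preset("liquid", center_jitter_sigma=0.0)
        tr = simulate_motor_trace(p, 2.0, seed=1)
        assert abs(np.hypot(tr.x, tr.y).mean() - p.orbit_radius) < 1e-9

    def test_true_reversal_count_matches_preset_rate(self):
        # mean simulator-state sign changes per minute ≈ reversal_rate
        p = make_motor_preset("liquid")
        counts = []
        master = np.random.default_rng(3)
        for child in master.spawn(200):
            tr = simulate_motor_trace(p, 60.0, child)
            counts.append(int(np.sum(np.diff(tr.true_sign) != 0)))
        mean = np.mean(counts)
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(mean - 38.0) < 3 * se + 0.5

    def test_cw_time_fraction_matches_bias(self):
        p = make_motor_preset("liquid")
        fracs = []
        master = np.random.default_rng(4)
        for child in master.spawn(100):
            tr = simulate_motor_trace(p, 60.0, child)
            fracs.append(np.mean(tr.true_sign > 0))
        assert abs(np.mean(fracs) - p.cw_bias) < 0.01


class TestDecay:
    def test_noiseless_is_exact_exponential(self):
        p = DecayPreset(decay_rate=2.7e-3, lognormal_sigma=0.0)
        (course,) = simulate_decay(p, 1, seed=0)
        expected = p.initial_intensity * np.exp(-2.7e-3 * course.t)
        assert np.allclose(course.intensity, expected)

    def test_zero_rate_is_constant(self):
        p = DecayPreset(decay_rate=0.0, lognormal_sigma=0.0)
        (course,) = simulate_decay(p, 1, seed=0)
        assert np.allclose(course.intensity, p.initial_intensity)

    def test_intensities_strictly_positive(self):
        p = make_decay_preset("liquid", lognormal_sigma=0.5)
        for course in simulate_decay(p, 10, seed=1):
            assert np.all(course.intensity > 0)


class TestFluorScene:
    def test_empty_scene_is_background_only(self):
        p = make_fluor_preset("liquid", n_cells=0)
        scene = render_fluor_scene(p, seed=0, shot_noise=False)
        assert np.all(scene.labels == 0)
        assert np.allclose(scene.yfp, p.background_level)

    def test_noiseless_totals_equal_drawn_expression(self):
        p = make_fluor_preset(
            "liquid", n_cells=10, background_level=0.0, autofluorescence=0.0
        )
        scene = render_fluor_scene(p, seed=1, shot_noise=False)
        for row in scene.truth.itertuples():
            total = scene.yfp[scene.labels == row.cell_id].sum()
            assert abs(total - row.yfp_total) / row.yfp_total < 1e-9

    def test_cells_do_not_overlap(self):
        p = make_fluor_preset("swarm", n_cells=60)
        scene = render_fluor_scene(p, seed=2)
        # labels are assigned exclusively, so count pixels per cell
        areas = np.bincount(scene.labels.ravel())[1:]
        assert (areas >= 20).all()
        assert len(areas) == 60

    def test_impossible_packing_raises(self):
        p = make_fluor_preset("liquid", n_cells=500)
        with pytest.raises(RuntimeError, match="non-overlapping"):
            render_fluor_scene(p, seed=3, image_size=(96, 96), max_attempts=600)
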