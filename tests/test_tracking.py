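import numpy as np
import pandas as pd
import pytest

from swarmotility.core import FrameStack, Trajectory, TrajectorySet
from swarmotility import tracking as trk
from swarmotility.presets import make_preset
from swarmotility.synthetic import render_frames, simulate_population


def _gaussian_spot(shape, cx, cy, amp=100.0, sigma=1.3):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return amp * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))


class TestBackground:
    def test_constant_stack_zero_residual(self):
        stack = FrameStack(np.full((5, 16, 16), 7.0))
        assert np.allclose(trk.compute_background(stack), 7.0)
        assert np.allclose(trk.subtract_background(stack).frames, 0.0)

    def test_two_frame_mean(self):
        stack = FrameStack(np.stack([np.zeros((8, 8)), np.full((8, 8), 2.0)]))
        assert np.allclose(trk.compute_background(stack), 1.0)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            trk.compute_background(FrameStack(np.zeros((1, 8, 8))))

    def test_moving_cell_survives_subtraction(self):
        frames = np.full((20, 64, 64), 50.0)
        for f in range(20):
            frames[f] += _gaussian_spot((64, 64), 5 + 2.5 * f, 32)
        res = trk.subtract_background(FrameStack(frames))
        # spot peak retained well above the flattened background
        assert res.frames[10].max() > 60.0
        assert abs(np.median(res.frames[10]) - 0.0) < 1.0


class TestDetection:
    def test_noiseless_spot_subpixel_center(self):
        frame = _gaussian_spot((64, 64), 30.25, 41.75)
        stack = FrameStack(np.stack([frame, frame]))
        det = trk.detect_cells(stack)
        row = det[det.frame == 0].iloc[0]
        # independent oracle: intensity centroid of the noiseless spot
        yy, xx = np.mgrid[0:64, 0:64]
        cx = (frame * xx).sum() / frame.sum()
        cy = (frame * yy).sum() / frame.sum()
        assert abs(row.x_px - cx) < 0.1 and abs(row.y_px - cy) < 0.1
        assert abs(row.x_px - 30.25) < 0.1 and abs(row.y_px - 41.75) < 0.1

    def test_flat_frame_yields_no_detections(self):
        det = trk.detect_cells(FrameStack(np.zeros((3, 32, 32))))
        assert len(det) == 0

    def test_fdr_validated(self):
        with pytest.raises(ValueError):
            trk.detect_cells(FrameStack(np.zeros((2, 8, 8))), fdr=1.5)

    def test_pure_noise_fdp_controlled(self):
        # false-discovery proportion on noise-only frames stays within
        # 1.5x the nominal rate (every detection on pure noise is false)
        fdps = []
        for s in range(100):
            frame = np.random.default_rng(s).normal(0.0, 10.0, (128, 128))
            n = len(trk._detect_frame(frame, 0.05, 5, 2.0, 3, 1.3))
            fdps.append(1.0 if n > 0 else 0.0)
        assert np.mean(fdps) <= 1.5 * 0.05

    def test_rendered_scene_recall_and_precision(self):
        preset = make_preset("liquid")
        ts = simulate_population(preset, 200, 2.0, 0.1, seed=7,
                                 arena=(120.0, 420.0))
        stack = render_frames(ts, snr=5.0, frame_size=(832, 832))
        det = trk.detect_cells(trk.subtract_background(stack))
        truth = stack.meta["truth"]
        recalls, precisions = [], []
        for f in range(len(stack)):
            tt = truth[truth.frame == f][["x_px", "y_px"]].to_numpy()
            dd = det[det.frame == f][["x_px", "y_px"]].to_numpy()
            hit = sum(
                1 for x, y in tt
                if len(dd) and np.hypot(dd[:, 0] - x, dd[:, 1] - y).min() < 2
            )
            fp = sum(
                1 for x, y in dd
                if np.hypot(tt[:, 0] - x, tt[:, 1] - y).min() > 2
            )
            recalls.append(hit / len(tt))
            precisions.append(1 - fp / max(len(dd), 1))
        assert np.mean(recalls) > 0.95
        assert np.mean(precisions) > 0.95


class TestLinking:
    @staticmethod
    def _detections_from_tracks(tracks):
        rows = []
        for xs, ys in tracks:
            for f, (x, y) in enumerate(zip(xs, ys)):
                if x is not None:
                    rows.append((f, x, y, 1.0))
        return pd.DataFrame(rows, columns=["frame", "x_px", "y_px", "score"])

    def test_two_parallel_tracks_never_swap(self):
        a = ([10 + 3 * f for f in range(10)], [10] * 10)
        b = ([10 + 3 * f for f in range(10)], [40] * 10)
        det = self._detections_from_tracks([a, b])
        tset = trk.link_trajectories(det, fps=10, pixel_size=0.65)
        assert len(tset) == 2
        ys = sorted(round(float(tr.y[0] / 0.65)) for tr in tset)
        assert ys == [10, 40]
        for tr in tset:
            assert np.allclose(tr.y, tr.y[0])

    def test_one_frame_gap_is_closed(self):
        xs = [10 + 3 * f for f in range(10)]
        xs[5] = None  # missed detection
        det = self._detections_from_tracks([(xs, [20] * 10)])
        tset = trk.link_trajectories(det, fps=10, pixel_size=0.65)
        assert len(tset) == 1
        assert len(tset[0]) == 9  # spans the gap without the missing frame

    def test_input_order_permutation_invariance(self):
        rng = np.random.default_rng(0)
        tracks = [
            ([20 + 60 * i + 2.5 * f for f in range(8)],
             [30 + 10 * i + 0.5 * f for f in range(8)])
            for i in range(4)
        ]
        det = self._detections_from_tracks(tracks)
        shuffled = (
            det.sample(frac=1, random_state=1)
            .sort_values("frame", kind="stable")
            .reset_index(drop=True)
        )
        a = trk.link_trajectories(det, fps=10, pixel_size=0.65)
        b = trk.link_trajectories(shuffled, fps=10, pixel_size=0.65)
        key = lambda tr: (round(float(tr.x[0]), 6), round(float(tr.y[0]), 6))
        xa = {key(tr): tr.x.tolist() for tr in a}
        xb = {key(tr): tr.x.tolist() for tr in b}
        assert xa == xb

    def test_linking_identity_on_simulated_cells(self):
        # >= 99% of frame-to-frame links agree with ground-truth identities
        preset = make_preset("liquid")
        ts = simulate_population(preset, 50, 3.0, 0.1, seed=11,
                                 arena=(120.0, 320.0))
        stack = render_frames(ts, snr=8.0, frame_size=(680, 680))
        tset, _ = trk.track(stack, min_duration=2.0)
        truth = stack.meta["truth"]
        by_frame = {f: g for f, g in truth.groupby("frame")}
        correct = total = 0
        for tr in tset:
            frames = (tr.t * stack.fps).round().astype(int)
            ids = []
            for fi, x, y in zip(frames, tr.x / 0.65, tr.y / 0.65):
                tt = by_frame[fi]
                d = np.hypot(tt.x_px - x, tt.y_px - y).to_numpy()
                ids.append(int(tt.cell_id.iloc[int(np.argmin(d))])
                           if d.min() < 3 else -1)
            ids = np.asarray(ids)
            ok = (ids[1:] == ids[:-1]) & (ids[1:] >= 0)
            correct += int(ok.sum())
            total += ids.size - 1
        assert correct / total >= 0.99


class TestFilterShort:
    def test_duration_threshold(self):
        def traj(cid, dur):
            t = np.arange(0, dur + 0.05, 0.1)
            return Trajectory(cid, t, np.zeros_like(t), np.zeros_like(t))

        tset = TrajectorySet([traj(0, 3.0), traj(1, 5.0), traj(2, 80.0)])
        kept = trk.filter_short(tset, 5.0)
        assert len(kept) == 2
        assert kept.meta["n_before_duration_filter"] == 3

    def test_zero_threshold_is_identity(self):
        t = np.arange(5) * 0.1
        tset = TrajectorySet([Trajectory(0, t, t, t)])
        assert len(trk.filter_short(tset, 0.0)) == 1

    def test_survivor_count_matches_enumeration(self, rng):
        tsets = []
        durations = rng.exponential(6.0, 300)
        trajs = []
        for i, d in enumerate(durations):
            n = max(2, int(d / 0.1))
            t = np.arange(n) * 0.1
            trajs.append(Trajectory(i, t, np.zeros(n), np.zeros(n)))
        tset = TrajectorySet(trajs)
        kept = trk.filter_short(tset, 5.0)
        brute = sum(1 for tr in trajs if tr.t[-1] - tr.t[0] >= 5.0)
        assert len(kept) == brute


class TestPipelineIdentity:
    def test_noiseless_cells_recovered_exactly(self):
        # detect+link on noiseless rendered cells: k tracks, <0.2 px RMS
        rng = np.random.default_rng(0)
        trajs = []
        nf = 51
        for i in range(9):
            t = np.arange(nf) * 0.1
            x0, y0 = 40 + (i % 3) * 60, 40 + (i // 3) * 60
            ang = rng.uniform(0, 2 * np.pi)
            w = 2 * np.pi / (nf * 0.1) * 2
            trajs.append(
                Trajectory(
                    i, t,
                    (x0 + 12 * np.cos(w * t + ang)) * 0.65,
                    (y0 + 12 * np.sin(w * t + ang)) * 0.65,
                )
            )
        ts = TrajectorySet(trajs, meta={"fps": 10.0})
        stack = render_frames(ts, noise_sigma=0.0, frame_size=(256, 256))
        tset, _ = trk.track(stack, min_duration=1.0)
        assert len(tset) == 9
        for tr in tset:
            rms = min(
                np.sqrt(np.mean((o.x - tr.x) ** 2 + (o.y - tr.y) ** 2)) / 0.65
                for o in trajs
                if len(o) == len(tr)
            )
            assert rms < 0.2
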