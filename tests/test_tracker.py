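import math

import numpy as np
import pandas as pd
import pytest

from wormbench.tracker import (
    Blob,
    FrameSequence,
    TrackerConfig,
    Trajectory,
    background_model,
    derive_kinematics,
    detect_blobs,
    frame_difference,
    orientation_from_moments,
    segment_body,
    select_worm,
    track,
    track_frames,
    unwrap_orientation,
)


def frame(level=200, shape=(120, 120)):
    return np.full(shape, level, dtype=np.uint8)


def stamp_disc(img, center, radius, level=60):
    rr, cc = np.mgrid[: img.shape[0], : img.shape[1]]
    img[(rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2] = level
    return img


class TestFrameDifference:
    def test_identical_frames_empty(self):
        f = frame()
        assert not frame_difference(f, f).any()

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            frame_difference(frame(shape=(10, 10)), frame(shape=(12, 12)))

    def test_translated_disc_crescents_bound_displacement(self):
        # geometric oracle: the motion region of a disc translated by d spans
        # from the old disc's leading edge to the new disc's leading edge
        f0 = stamp_disc(frame(), (60, 40), 10)
        f1 = stamp_disc(frame(), (60, 50), 10)
        motion = frame_difference(f1, f0)
        assert motion.any()
        rows, cols = np.nonzero(motion)
        assert cols.min() >= 40 - 10 - 1
        assert cols.max() <= 50 + 10 + 1
        # two crescent lobes: set pixels exist on both sides of the overlap
        assert (cols < 45).any() and (cols > 45).any()

    def test_noise_floor_oracle(self, rng):
        # analytic oracle: P(|N(0, sd*sqrt(2))| > thr) = p per pixel; opening
        # with a 5-px cross keeps at most ~5*p^5 of pixels (erosion requires
        # 5 independent exceedances, dilation regrows each survivor <= 5x)
        from scipy.stats import norm

        sd = 3.0
        f0 = np.clip(rng.normal(200, sd, (400, 400)), 0, 255).astype(np.uint8)
        f1 = np.clip(rng.normal(200, sd, (400, 400)), 0, 255).astype(np.uint8)
        motion = frame_difference(f1, f0)
        p = 2 * norm.sf(5.5, scale=sd * math.sqrt(2))
        assert motion.mean() < 5 * p**5
        # and the floor is far below any real worm signature (~0.8% of pixels)
        assert motion.mean() < 0.002


class TestDetectBlobs:
    def test_empty_image(self):
        assert detect_blobs(np.zeros((50, 50), dtype=bool)) == []

    def test_square_blob_closed_form(self):
        img = np.zeros((60, 60), dtype=bool)
        k = 7
        img[10 : 10 + k, 20 : 20 + k] = True
        (blob,) = detect_blobs(img)
        assert blob.area == k * k
        assert blob.centroid == (10 + (k - 1) / 2, 20 + (k - 1) / 2)

    def test_min_area_filter(self):
        img = np.zeros((50, 50), dtype=bool)
        img[5:8, 5:8] = True  # 9 px < default 20
        assert detect_blobs(img) == []

    def test_moments_match_brute_force_on_random_shapes(self, rng):
        # oracle: plain python double-loop over pixels
        for _ in range(100):
            img = np.zeros((40, 40), dtype=bool)
            r0, c0 = rng.integers(5, 20, 2)
            h, w = rng.integers(5, 15, 2)
            img[r0 : r0 + h, c0 : c0 + w] = rng.random((h, w)) < 0.7
            blobs = detect_blobs(img, TrackerConfig(min_blob_area_px=1))
            for blob in blobs:
                rows, cols = blob.pixels
                n = sr = sc = 0
                for r, c in zip(rows.tolist(), cols.tolist()):
                    n += 1
                    sr += r
                    sc += c
                rbar, cbar = sr / n, sc / n
                mu20 = mu02 = mu11 = 0.0
                for r, c in zip(rows.tolist(), cols.tolist()):
                    mu20 += (c - cbar) ** 2
                    mu02 += (r - rbar) ** 2
                    mu11 += (c - cbar) * (r - rbar)
                assert blob.area == n
                assert blob.centroid == pytest.approx((rbar, cbar))
                assert blob.mu20 == pytest.approx(mu20)
                assert blob.mu02 == pytest.approx(mu02)
                assert blob.mu11 == pytest.approx(mu11)

    def test_eight_connectivity(self):
        img = np.zeros((30, 30), dtype=bool)
        img[10:15, 10:15] = True
        img[15:20, 15:20] = True  # touches diagonally
        blobs = detect_blobs(img, TrackerConfig(min_blob_area_px=1))
        assert len(blobs) == 1


class TestSelectWorm:
    def blob_at(self, r, c, area=25):
        k = int(math.isqrt(area))
        rows, cols = np.mgrid[r : r + k, c : c + k]
        return Blob.from_pixels(rows.ravel(), cols.ravel())

    def test_single_blob_selected(self):
        b = self.blob_at(10, 10)
        assert select_worm([b], None) is b

    def test_largest_without_history(self):
        small = self.blob_at(5, 5, area=25)
        large = self.blob_at(30, 30, area=100)
        assert select_worm([small, large], None) is large

    def test_nearest_to_previous_even_if_smaller(self):
        near_small = self.blob_at(12, 12, area=25)
        far_large = self.blob_at(80, 80, area=100)
        chosen = select_worm([near_small, far_large], (13.0, 13.0), max_jump_px=30)
        assert chosen is near_small

    def test_none_when_outside_max_jump(self):
        b = self.blob_at(90, 90)
        assert select_worm([b], (0.0, 0.0), max_jump_px=30) is None

    def test_empty_returns_none(self):
        assert select_worm([], (0.0, 0.0)) is None


class TestSegmentBody:
    def test_background_equals_frame_empty(self):
        f = frame()
        assert not segment_body(f, f.astype(float)).any()

    def test_rendered_worm_area_within_15pct(self):
        from wormbench.wormsim import CameraModel, Environment, make_worm, render_frame

        env = Environment((-2000, -2000, 2000, 2000), grid_um_per_px=10.0)
        worm = make_worm((0, 0), 0.7, env=env)
        cam = CameraModel(image_shape=(600, 600), um_per_px=5.0, noise_sd=0.0)
        f, truth = render_frame(worm, None, cam)
        bg = np.full(cam.image_shape, cam.background_level)
        mask = segment_body(f, bg)
        assert mask.sum() == pytest.approx(truth["area_px"], rel=0.15)

    def test_lever_is_single_component(self):
        from wormbench.scenarios import hinge_replay_scenario

        scn = hinge_replay_scenario(seed=0)
        f, _ = next(iter([(fr, tr) for _, fr, tr in scn.sim.iter_frames(0.2)]))
        bg = np.full(scn.camera.image_shape, scn.camera.background_level)
        mask = segment_body(f, bg)
        from scipy.ndimage import label

        _, n = label(mask)
        assert n == 1


class TestOrientation:
    def rect_mask(self, angle_deg, shape=(200, 200), length=120, width=20):
        import shapely
        from shapely import affinity
        from shapely.geometry import box

        poly = affinity.rotate(
            box(-width / 2, -length / 2, width / 2, length / 2), -angle_deg, origin=(0, 0)
        )
        rr, cc = np.mgrid[: shape[0], : shape[1]]
        x = cc - shape[1] / 2
        y = shape[0] / 2 - rr
        return shapely.contains_xy(poly, x.ravel(), y.ravel()).reshape(shape)

    def test_vertical_rectangle_zero(self):
        assert orientation_from_moments(self.rect_mask(0.0)) == pytest.approx(0.0, abs=1e-6)

    def test_rotated_30_degrees(self):
        # analytic oracle: a rigid rectangle rotated by t has principal axis t
        assert orientation_from_moments(self.rect_mask(30.0)) == pytest.approx(30.0, abs=0.5)

    @pytest.mark.parametrize("angle", [-60.0, -10.0, 10.0, 45.0, 80.0])
    def test_angles_recovered(self, angle):
        assert orientation_from_moments(self.rect_mask(angle)) == pytest.approx(angle, abs=0.5)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            orientation_from_moments(np.zeros((10, 10), dtype=bool))

    def test_degenerate_isotropic_mask_raises(self):
        mask = np.zeros((21, 21), dtype=bool)
        mask[8:13, 8:13] = True  # square: isotropic second moments
        with pytest.raises(ValueError, match="degenerate"):
            orientation_from_moments(mask)

    def test_unwrap_avoids_180_flips(self):
        seq = [85.0, 89.0, -88.0, -85.0]  # crossing the 90° wrap
        out = unwrap_orientation(seq)
        assert np.all(np.abs(np.diff(out)) < 10)

    def test_orientation_rmse_on_rotating_shape(self):
        angles = np.linspace(5, 40, 30)
        rec = unwrap_orientation([orientation_from_moments(self.rect_mask(a)) for a in angles])
        rmse = float(np.sqrt(np.mean((rec - angles) ** 2)))
        assert rmse < 1.0


class TestKinematics:
    def make_traj(self, xs, ys, dt=0.1):
        n = len(xs)
        df = pd.DataFrame(
            {
                "time_s": np.arange(n) * dt,
                "x_um": xs,
                "y_um": ys,
                "area_px": 100,
                "valid": True,
            }
        )
        return Trajectory(df, um_per_px=5.0)

    def test_stationary_track(self):
        traj = derive_kinematics(self.make_traj(np.full(20, 3.0), np.full(20, -2.0)))
        v = traj.valid()
        assert np.allclose(v["speed_um_s"], 0.0)
        assert np.allclose(v["accel_um_s2"], 0.0)

    def test_uniform_linear_motion(self):
        v = 200.0
        t = np.arange(50) * 0.1
        traj = derive_kinematics(self.make_traj(v * t, np.zeros_like(t)))
        speeds = traj.valid()["speed_um_s"]
        assert np.allclose(speeds, v, rtol=0.01)

    def test_window_larger_than_track_raises(self):
        with pytest.raises(ValueError, match="window"):
            derive_kinematics(self.make_traj(np.arange(5.0), np.arange(5.0)), window=11)

    def test_too_few_valid_frames_raises(self):
        traj = self.make_traj(np.arange(2.0), np.arange(2.0))
        with pytest.raises(ValueError):
            derive_kinematics(traj)

    def test_simulator_max_speed_within_5pct(self):
        # ground-truth oracle: the simulator's commanded peak speed
        from wormbench.scenarios import open_frame_scenario

        scn = open_frame_scenario(seed=21, peak_speed_um_s=330.0)
        truths = []

        def gen():
            for t, f, tr in scn.sim.iter_frames(40.0):
                truths.append(tr)
                yield t, f

        traj = derive_kinematics(track_frames(gen(), scn.camera.um_per_px), window=13)
        tdf = pd.DataFrame(truths)
        truth_speed = np.hypot(
            np.gradient(tdf.x_um, tdf.time_s), np.gradient(tdf.y_um, tdf.time_s)
        )
        assert traj.max_speed() == pytest.approx(truth_speed.max(), rel=0.05)


class TestPipeline:
    def render_sequence(self, seed=0, duration=5.0):
        from wormbench.scenarios import open_frame_scenario

        scn = open_frame_scenario(seed=seed)
        frames, times, truth = scn.sim.run(duration)
        return FrameSequence(frames=frames, times=times, um_per_px=scn.camera.um_per_px), truth

    def test_pipeline_pure(self):
        seq, _ = self.render_sequence(seed=31)
        t1 = track(seq)
        t2 = track(seq)
        pd.testing.assert_frame_equal(t1.data, t2.data)

    def test_centroid_rmse_below_quarter_body_width(self):
        seq, truth = self.render_sequence(seed=32, duration=20.0)
        traj = track(seq, derive=False)
        m = traj.valid().merge(truth, on="time_s", suffixes=("_trk", "_gt"))
        rmse = np.sqrt(
            ((m.x_um_trk - m.x_um_gt) ** 2 + (m.y_um_trk - m.y_um_gt) ** 2).mean()
        )
        assert rmse < 60.0 / 4

    def test_distractor_crossing_keeps_target(self):
        # two-worm scene: the tracked worm stays on the target when the
        # distractor remains farther than max_jump
        from wormbench.wormsim import CameraModel, Environment, _Renderer, make_worm, step

        env = Environment((-3000, -3000, 3000, 3000), grid_um_per_px=10.0)
        cam = CameraModel(image_shape=(900, 900), um_per_px=7.0, noise_sd=2.0)
        target = make_worm((-1500, 1200), 0.0, env=env, base_speed=300.0, turn_noise_rad_sqrt_s=0.05)
        distractor = make_worm((1500, -1200), math.pi, env=env, base_speed=300.0, turn_noise_rad_sqrt_s=0.05)
        renderer = _Renderer(cam)
        rng = np.random.default_rng(7)
        frames = []
        for i in range(80):
            img = np.full(cam.image_shape, cam.background_level, dtype=np.float32)
            for w in (target, distractor):
                rr, cc = renderer.worm_mask(w)
                img[rr, cc] = cam.worm_level
            img += rng.normal(0, cam.noise_sd, img.shape)
            frames.append(np.clip(img, 0, 255).astype(np.uint8))
            step(target, env, 0.1, rng)
            step(distractor, env, 0.1, rng)
        seq = FrameSequence(frames=frames, times=np.arange(80) * 0.1, um_per_px=cam.um_per_px)
        traj = track(seq, derive=False)
        v = traj.valid()
        # the largest-area tie-break may land on either worm at frame 1, but
        # the track must never jump across: y stays on one side throughout
        assert (v["y_um"] > 300).all() or (v["y_um"] < -300).all()


class TestFrameSequence:
    def test_times_strictly_increasing(self):
        with pytest.raises(ValueError):
            FrameSequence([frame(), frame()], [0.0, 0.0], 5.0)

    def test_uniform_shape_required(self):
        with pytest.raises(ValueError):
            FrameSequence([frame(shape=(10, 10)), frame(shape=(12, 12))], [0.0, 0.1], 5.0)
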