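"""Canned simulator scenarios: open frame, pillar array, rippled channel,
hinge-lever replay and T-maze runs.

These wire together pattern geometry, the environment, a worm and a camera
so the tracker and closed-loop driver can be exercised end to end with
ground truth available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from shapely.geometry import box

from .patterns import CorrugatedChannel, Frame, PillarArray, TMaze
from .wormsim import CameraModel, Environment, HingePin, Simulation, make_worm

__all__ = [
    "confinement_gain_for",
    "open_frame_scenario",
    "pillar_scenario",
    "channel_scenario",
    "hinge_replay_scenario",
    "tmaze_scenario",
    "SCENARIOS",
]

# Default speed modulation: a slow swell between 10% and 100% of peak speed,
# starting at the peak, so the per-stage maximum is well defined, reached
# early and repeatedly, and survives trajectory smoothing.
def default_speed_modulation(period_s: float = 20.0):
    def mod(t: float) -> float:
        return 0.55 + 0.45 * math.cos(2 * math.pi * t / period_s)

    return mod


def confinement_gain_for(
    open_speed_um_s: float,
    confined_speed_um_s: float,
    clearance_threshold_um: float = 150.0,
):
    """Phenomenological confinement-speed coupling.

    Gain is 1 in open space and ``confined/open`` when the mean free lateral
    clearance drops below the threshold, so peak speeds in open and confined
    stages can be dialed in directly.
    """
    ratio = confined_speed_um_s / open_speed_um_s

    def gain(clearance_um: float) -> float:
        return ratio if clearance_um < clearance_threshold_um else 1.0

    return gain


@dataclass
class Scenario:
    sim: Simulation
    env: Environment
    camera: CameraModel
    label: str
    extras: dict


def _camera_for(env: Environment, um_per_px: float, frame_rate: float, **kw) -> CameraModel:
    return CameraModel.for_bounds(env.bounds, um_per_px=um_per_px, frame_rate=frame_rate, **kw)


def open_frame_scenario(
    seed: int = 0,
    peak_speed_um_s: float = 330.0,
    frame_w_um: float = 5000.0,
    frame_h_um: float = 3000.0,
    wall_um: float = 150.0,
    um_per_px: float = 5.0,
    frame_rate: float = 10.0,
    confined_peak_um_s: float | None = None,
) -> Scenario:
    """Worm swimming inside an open rectangular frame (first confinement stage)."""
    spec = Frame(outer_w=frame_w_um, outer_h=frame_h_um, wall_thickness=wall_um)
    margin = 200.0
    bounds = (
        -frame_w_um / 2 - margin,
        -frame_h_um / 2 - margin,
        frame_w_um / 2 + margin,
        frame_h_um / 2 + margin,
    )
    env = Environment.from_geometry(spec.geometry(), bounds, grid_um_per_px=um_per_px)
    gain = confinement_gain_for(peak_speed_um_s, confined_peak_um_s or peak_speed_um_s)
    worm = make_worm(
        (0.0, 0.0),
        heading=0.0,
        env=env,
        base_speed=peak_speed_um_s,
        confinement_gain=gain,
        speed_modulation=default_speed_modulation(),
        # low turning noise keeps peak-speed windows straight so the tracked
        # centroid speed faithfully reaches the commanded maximum
        turn_noise_rad_sqrt_s=0.15,
    )
    cam = _camera_for(env, um_per_px, frame_rate)
    return Scenario(Simulation(env, worm, cam, seed=seed), env, cam, "open_frame", {"spec": spec})


def pillar_scenario(
    seed: int = 0,
    peak_speed_um_s: float = 330.0,
    confined_peak_um_s: float | None = None,
    diameter_um: float = 100.0,
    pitch_um: float = 200.0,
    um_per_px: float = 5.0,
    frame_rate: float = 10.0,
) -> Scenario:
    """Micropillar array inside a frame (second confinement stage)."""
    frame = Frame(outer_w=5000.0, outer_h=3000.0, wall_thickness=150.0)
    pillars = PillarArray(diameter=diameter_um, pitch=pitch_um, region=frame.interior_bounds())
    geom = frame.geometry().union(pillars.geometry())
    margin = 200.0
    bounds = (-2500 - margin, -1500 - margin, 2500 + margin, 1500 + margin)
    env = Environment.from_geometry(geom, bounds, grid_um_per_px=um_per_px)
    gain = confinement_gain_for(peak_speed_um_s, confined_peak_um_s or peak_speed_um_s)
    # start in a lumen spot between pillars
    worm = make_worm(
        (pitch_um / 2, pitch_um / 2),
        heading=0.0,
        env=env,
        base_speed=peak_speed_um_s,
        confinement_gain=gain,
        speed_modulation=default_speed_modulation(),
        turn_noise_rad_sqrt_s=0.4,
        undulation_amplitude=20.0,
    )
    cam = _camera_for(env, um_per_px, frame_rate)
    return Scenario(Simulation(env, worm, cam, seed=seed), env, cam, "pillars", {"spec": pillars})


def channel_scenario(
    seed: int = 0,
    peak_speed_um_s: float = 890.0,
    open_peak_um_s: float = 330.0,
    length_um: float = 4000.0,
    width_um: float = 200.0,
    ripple_amplitude_um: float = 20.0,
    ripple_period_um: float = 500.0,
    um_per_px: float = 5.0,
    frame_rate: float = 10.0,
) -> Scenario:
    """Rippled microchannel (final confinement stage); peak speed is the
    confined value via the clearance-gain schedule."""
    spec = CorrugatedChannel(
        length=length_um,
        width=width_um,
        ripple_amplitude=ripple_amplitude_um,
        ripple_period=ripple_period_um,
        wall_thickness=150.0,
    )
    margin = 150.0
    half_h = width_um / 2 + ripple_amplitude_um + spec.wall_thickness
    bounds = (
        -length_um / 2 - spec.wall_thickness - margin,
        -half_h - margin,
        length_um / 2 + spec.wall_thickness + margin,
        half_h + margin,
    )
    env = Environment.from_geometry(spec.geometry(), bounds, grid_um_per_px=um_per_px, guide_axis=(1.0, 0.0))
    gain = confinement_gain_for(open_peak_um_s, peak_speed_um_s)
    worm = make_worm(
        (-length_um / 2 + 1200.0, 0.0),
        heading=0.0,
        env=env,
        base_speed=open_peak_um_s,
        confinement_gain=gain,
        speed_modulation=default_speed_modulation(),
        turn_noise_rad_sqrt_s=0.1,
        # confined amplitude is small enough that the wall clamp rarely
        # engages, keeping the rendered-centroid wobble symmetric
        undulation_amplitude=min(20.0, width_um / 2 - 50.0),
        # the guide axis already steers along the channel; anticipatory
        # avoidance would only add speed-cancelling heading waggle
        wall_avoidance=False,
    )
    cam = _camera_for(env, um_per_px, frame_rate)
    return Scenario(Simulation(env, worm, cam, seed=seed), env, cam, "channel", {"spec": spec})


def hinge_replay_scenario(
    seed: int = 0,
    theta_start_deg: float = 6.0,
    theta_end_deg: float = 27.0,
    duration_s: float = 6.0,
    lever_length_um: float = 500.0,
    lever_width_um: float = 80.0,
    um_per_px: float = 5.0,
    frame_rate: float = 10.0,
) -> Scenario:
    """Rigid lever rotating about an anchored pin on a scripted angle schedule."""
    pin = (0.0, 0.0)
    lever = box(-lever_width_um / 2, 0.0, lever_width_um / 2, lever_length_um)

    def schedule(t: float) -> float:
        f = min(max(t / duration_s, 0.0), 1.0)
        return theta_start_deg + f * (theta_end_deg - theta_start_deg)

    hinge = HingePin(pin_center=pin, lever_polygon=lever, angle_deg=theta_start_deg, schedule=schedule)
    half = lever_length_um + 150.0
    bounds = (-half, -half, half, half)
    env = Environment(bounds, grid_um_per_px=um_per_px, hinges=[hinge])
    cam = _camera_for(env, um_per_px, frame_rate)
    sim = Simulation(env, None, cam, seed=seed)
    return Scenario(sim, env, cam, "hinge", {"hinge": hinge, "duration_s": duration_s})


def tmaze_scenario(
    seed: int = 0,
    side: str | None = None,
    stem_len_um: float = 1200.0,
    arm_len_um: float = 2000.0,
    channel_width_um: float = 300.0,
    wall_um: float = 150.0,
    terminal_radius_um: float = 350.0,
    um_per_px: float = 5.0,
    frame_rate: float = 5.0,
    food_side: str | None = None,
    peak_speed_um_s: float = 300.0,
) -> Scenario:
    """Worm navigating a T-maze to a terminal; ``side`` forces the choice
    (None draws it from the seed), ``food_side`` adds a food site."""
    rng = np.random.default_rng(seed)
    if side is None:
        side = "left" if rng.random() < 0.5 else "right"
    spec = TMaze(
        stem_len=stem_len_um,
        arm_len=arm_len_um,
        channel_width=channel_width_um,
        wall_thickness=wall_um,
        terminal_radius=terminal_radius_um,
    )
    left, right = spec.terminal_centers()
    target = left if side == "left" else right
    margin = 150.0
    bounds = (
        -arm_len_um / 2 - terminal_radius_um - wall_um - margin,
        -stem_len_um - wall_um - margin,
        arm_len_um / 2 + terminal_radius_um + wall_um + margin,
        terminal_radius_um + wall_um + margin,
    )
    food = []
    if food_side is not None:
        food = [((left if food_side == "left" else right), 1.0)]
    env = Environment.from_geometry(spec.geometry(), bounds, grid_um_per_px=um_per_px, food_sites=food)
    body_length = 800.0
    entrance = spec.entrance_point()
    # head placed so the straight body fits inside the stem lumen
    worm = make_worm(
        (entrance[0], entrance[1] + body_length + 100.0),
        heading=math.pi / 2,
        env=env,
        body_length=body_length,
        body_width=60.0,
        base_speed=peak_speed_um_s,
        turn_noise_rad_sqrt_s=0.05,
        undulation_amplitude=25.0,
        waypoints=[(0.0, 0.0), ((target[0] + 0.0) / 2, 0.0), target],
        waypoint_tolerance=80.0,
    )
    cam = _camera_for(env, um_per_px, frame_rate)
    sim = Simulation(env, worm, cam, seed=seed)
    return Scenario(sim, env, cam, "tmaze", {"spec": spec, "truth_side": side})


def confinement_replay(
    seed: int = 0,
    duration_s: float = 200.0,
    open_peak_um_s: float = 330.0,
    confined_peak_um_s: float = 890.0,
    smooth_window: int = 13,
) -> dict:
    """Replay the staged-confinement experiment: open frame then rippled channel.

    Both stages are rendered at 10 fps / 5 μm/px, tracked with the full
    frame-differencing pipeline, and the per-stage maximum smoothed centroid
    speed is recovered.  Peak speeds use a boxcar smoother (1.3 s window):
    wide enough to reject the ~2 Hz undulation wobble of the body-mask
    centroid, and free of the polynomial-fit derivative overshoot that a
    Savitzky-Golay filter exhibits at hard wall stops.  Returns recovered
    maxima and the confined/open percent ratio.
    """
    from .assays import percent_of_baseline
    from .tracker import derive_kinematics, track_frames

    out = {}
    stages = {
        "open": open_frame_scenario(seed=seed, peak_speed_um_s=open_peak_um_s),
        "channel": channel_scenario(
            seed=seed + 1, peak_speed_um_s=confined_peak_um_s, open_peak_um_s=open_peak_um_s
        ),
    }
    for label, scn in stages.items():
        frames = ((t, f) for t, f, _ in scn.sim.iter_frames(duration_s))
        traj = derive_kinematics(
            track_frames(frames, scn.camera.um_per_px),
            window=smooth_window,
            smoother="boxcar",
        )
        out[f"{label}_max_um_s"] = traj.max_speed()
    out["percent_of_open"] = percent_of_baseline(out["channel_max_um_s"], out["open_max_um_s"])
    return out


def hinge_replay(seed: int = 0, duration_s: float = 6.0, **kw) -> dict:
    """Render the scripted lever rotation and recover angles by image moments."""
    from .tracker import orientation_from_moments, segment_body, unwrap_orientation

    scn = hinge_replay_scenario(seed=seed, duration_s=duration_s, **kw)
    # the scene is lever-on-background only: a flat background model suffices
    bg = np.full(scn.camera.image_shape, scn.camera.background_level, dtype=float)
    angles, truth_angles, times = [], [], []
    # run two frames past the schedule end so the final pose is captured
    for t, frame, truth in scn.sim.iter_frames(duration_s + 2.0 / scn.camera.frame_rate):
        mask = segment_body(frame, bg)
        angles.append(orientation_from_moments(mask))
        truth_angles.append(truth["theta_deg"])
        times.append(t)
    unwrapped = unwrap_orientation(angles)
    return {
        "times": np.asarray(times),
        "angles_deg": unwrapped,
        "truth_deg": np.asarray(truth_angles),
        "final_angle_deg": float(unwrapped[-1]),
    }


def run_maze_assay(seed: int = 0, duration_s: float = 40.0, **kw):
    """Simulate one T-maze run and classify it with the 80%-body rule.

    Returns ``(outcome, decision_time, truth_side)``; the background model is
    the median of the first 10 frames (worm still near the stem).
    """
    from .assays import MazeRegions, maze_classify
    from .tracker import background_model, segment_body

    scn = tmaze_scenario(seed=seed, **kw)
    spec = scn.extras["spec"]
    maze = MazeRegions(*spec.terminal_centers(), spec.terminal_radius)
    gen = scn.sim.iter_frames(duration_s)
    buf = []
    for _, frame, _ in gen:
        buf.append(frame)
        if len(buf) >= 10:
            break
    bg = background_model(buf, k=10)

    def masks():
        for i, frame in enumerate(buf):
            yield i / scn.camera.frame_rate, segment_body(frame, bg)
        for t, frame, _ in gen:
            yield t, segment_body(frame, bg)

    outcome, t_dec = maze_classify(masks(), maze, scn.camera)
    return outcome, t_dec, scn.extras["truth_side"]


SCENARIOS = {
    "open_frame": open_frame_scenario,
    "pillars": pillar_scenario,
    "channel": channel_scenario,
    "hinge": hinge_replay_scenario,
    "tmaze": tmaze_scenario,
}
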