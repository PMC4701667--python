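"""Ground-truthed synthetic worm videos.

A kinematic (non-physical) worm model: the body centerline trails the head
along its path (follow-the-leader), an undulatory traveling wave is applied
as a lateral offset at render time, and obstacle collisions are resolved by
pushing points back into free space along the distance-field gradient.
Confinement couples to speed through a user-set gain on obstacle clearance.

All positions are world μm (y-up).  Rendering maps to a camera pixel grid
(y-down) with a dark worm on a light background, semi-opaque obstacles and
additive Gaussian noise.  Every simulation is deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon
from shapely import affinity

from .patterns import WorldOccupancy, rasterize_geometry

__all__ = [
    "WormState",
    "Environment",
    "HingePin",
    "CameraModel",
    "Simulation",
    "make_worm",
    "step",
    "hinge_step",
    "render_frame",
    "render",
]


# ---------------------------------------------------------------------------
# Environment
# ---------------------------------------------------------------------------


class Environment:
    """World-frame obstacle set with arena bounds, hinges and food sites.

    Obstacles are immutable except via :meth:`add_obstacles` (exposure
    events).  A Euclidean distance field over the occupancy grid supports
    clearance queries and collision push-out; arena bounds count as
    obstacles.
    """

    def __init__(
        self,
        bounds: tuple[float, float, float, float],
        occupancy: WorldOccupancy | None = None,
        grid_um_per_px: float = 5.0,
        hinges: Sequence["HingePin"] = (),
        food_sites: Sequence[tuple[tuple[float, float], float]] = (),
        guide_axis: tuple[float, float] | None = None,
    ):
        self.bounds = bounds
        if occupancy is None:
            occupancy = WorldOccupancy.empty(bounds, grid_um_per_px)
        self.occupancy = occupancy
        self.hinges = list(hinges)
        self.food_sites = list(food_sites)
        self.guide_axis = guide_axis
        self._dist: np.ndarray | None = None
        self._signed: np.ndarray | None = None
        self.version = 0

    @classmethod
    def from_geometry(
        cls,
        geom: shapely.Geometry,
        bounds: tuple[float, float, float, float],
        grid_um_per_px: float = 5.0,
        **kw,
    ) -> "Environment":
        occ = rasterize_geometry(geom, grid_um_per_px, bounds)
        return cls(bounds, occupancy=occ, **kw)

    def add_obstacles(self, occ: WorldOccupancy) -> None:
        self.occupancy.union_inplace(occ)
        self._dist = None
        self._signed = None
        self.version += 1

    def _distance_field(self) -> np.ndarray:
        """Distance (μm) from each free pixel to the nearest obstacle/border."""
        if self._dist is None:
            from scipy.ndimage import distance_transform_edt

            free = ~self.occupancy.grid
            padded = np.zeros((free.shape[0] + 2, free.shape[1] + 2), dtype=bool)
            padded[1:-1, 1:-1] = free  # border ring = obstacle (arena bounds)
            d = distance_transform_edt(padded)[1:-1, 1:-1]
            self._dist = d * self.occupancy.um_per_px
        return self._dist

    def _signed_field(self) -> np.ndarray:
        """Signed clearance: positive in free space, negative inside obstacles.

        Unlike the plain distance field (flat zero inside obstacles), this has
        a usable gradient everywhere, so embedded points can be walked out.
        """
        if self._signed is None:
            from scipy.ndimage import distance_transform_edt

            d_out = self._distance_field()
            d_in = distance_transform_edt(self.occupancy.grid) * self.occupancy.um_per_px
            self._signed = d_out - d_in
        return self._signed

    def clearance_at(self, x: float, y: float) -> float:
        d = self._distance_field()
        row, col = self.occupancy.world_to_index(x, y)
        row = int(np.clip(row, 0, d.shape[0] - 1))
        col = int(np.clip(col, 0, d.shape[1] - 1))
        return float(d[row, col])

    def clearance_at_many(self, points: np.ndarray) -> np.ndarray:
        d = self._distance_field()
        row, col = self.occupancy.world_to_index(points[:, 0], points[:, 1])
        row = np.clip(row, 0, d.shape[0] - 1)
        col = np.clip(col, 0, d.shape[1] - 1)
        return d[row, col]

    def push_free(self, point: np.ndarray, min_clearance: float, max_iter: int | None = None) -> np.ndarray:
        """Move a point along the signed-clearance gradient until clearance is met."""
        d = self._signed_field()
        occ = self.occupancy
        p = np.array(point, dtype=float)
        res = occ.um_per_px
        if max_iter is None:
            # enough steps to escape from the deepest embedding plus the margin
            max_iter = int((min_clearance - d.min()) / res) + 20
        for _ in range(max_iter):
            row, col = occ.world_to_index(p[0], p[1])
            row = int(np.clip(row, 1, d.shape[0] - 2))
            col = int(np.clip(col, 1, d.shape[1] - 2))
            if d[row, col] >= min_clearance:
                break
            # ascend the distance field (gradient in world coords: y up = -row)
            gx = (d[row, col + 1] - d[row, col - 1]) / (2 * res)
            gy = (d[row - 1, col] - d[row + 1, col]) / (2 * res)
            norm = math.hypot(gx, gy)
            if norm < 1e-9:
                # flat (deep inside obstacle plateau or saddle): nudge toward center
                cx = occ.x0 + (occ.grid.shape[1] // 2) * res
                cy = occ.y0 - (occ.grid.shape[0] // 2) * res
                gx, gy = cx - p[0], cy - p[1]
                norm = math.hypot(gx, gy) or 1.0
            p += np.array([gx, gy]) / norm * res
        return p


# ---------------------------------------------------------------------------
# Hinge-pin mechanism
# ---------------------------------------------------------------------------


@dataclass
class HingePin:
    """Free-floating rigid lever rotating about an anchored pin.

    ``lever_polygon`` is given at angle 0 (long axis vertical); the current
    pose is the polygon rotated ``angle_deg`` clockwise about ``pin_center``.
    ``schedule`` (optional) scripts the angle as a function of time and
    overrides contact dynamics.
    """

    pin_center: tuple[float, float]
    lever_polygon: Polygon
    angle_deg: float = 0.0
    contact_gain_deg_s: float = 3.0
    contact_range_um: float = 40.0
    schedule: Callable[[float], float] | None = None

    def posed_polygon(self) -> Polygon:
        # world frame is y-up; negative rotation = clockwise on screen
        return affinity.rotate(self.lever_polygon, -self.angle_deg, origin=self.pin_center)


def hinge_step(hinge: HingePin, state: "WormState | None", dt: float, t: float | None = None) -> HingePin:
    """Advance the hinge: scripted schedule, or contact-driven rotation.

    When the worm body contacts the lever, the angle increments by
    ``contact_gain_deg_s * dt`` (monotone within a contact bout); without
    contact the angle is unchanged.
    """
    if hinge.schedule is not None and t is not None:
        hinge.angle_deg = float(hinge.schedule(t))
        return hinge
    if state is None:
        return hinge
    poly = hinge.posed_polygon()
    pts = shapely.points(state.centerline())
    dmin = float(shapely.distance(poly, pts).min())
    if dmin <= state.body_width / 2 + hinge.contact_range_um:
        hinge.angle_deg += hinge.contact_gain_deg_s * dt
    return hinge


# ---------------------------------------------------------------------------
# Worm state and stepping
# ---------------------------------------------------------------------------


@dataclass
class WormState:
    """Kinematic worm: a head path trail plus undulation parameters.

    ``path`` holds recent head positions, head first; the centerline is the
    arc-length resampling of this trail to ``body_length``.  The rendered
    undulation is a traveling lateral wave around the centerline, so the
    commanded speed is the along-path speed of the body axis.
    """

    path: np.ndarray  # (M, 2), head first
    heading: float  # rad
    body_length: float = 1000.0
    body_width: float = 60.0
    n_points: int = 21
    undulation_amplitude: float = 40.0
    undulation_wavelength: float = 500.0
    undulation_frequency: float = 2.0
    phase: float = 0.0
    base_speed: float = 300.0
    confinement_gain: Callable[[float], float] | None = None
    speed_modulation: Callable[[float], float] | None = None
    turn_noise_rad_sqrt_s: float = 0.3
    wall_avoidance: bool = True
    food_bias_rad_s: float = 0.0
    waypoints: list[tuple[float, float]] = field(default_factory=list)
    waypoint_tolerance: float = 100.0
    time: float = 0.0

    def head(self) -> np.ndarray:
        return self.path[0]

    def centerline(self) -> np.ndarray:
        """N points at uniform arc-length spacing along the trail (head first)."""
        return _resample_polyline(self.path, self.body_length, self.n_points)

    def centroid(self) -> np.ndarray:
        return self.centerline().mean(axis=0)

    def current_speed(self, clearance: float) -> float:
        gain = self.confinement_gain(clearance) if self.confinement_gain else 1.0
        mod = self.speed_modulation(self.time) if self.speed_modulation else 1.0
        return self.base_speed * gain * mod


def _resample_polyline(path: np.ndarray, length: float, n: int) -> np.ndarray:
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    want = np.linspace(0.0, length, n)
    want = np.clip(want, 0.0, cum[-1] if cum[-1] > 0 else 0.0)
    if cum[-1] == 0:
        return np.repeat(path[:1], n, axis=0)
    xs = np.interp(want, cum, path[:, 0])
    ys = np.interp(want, cum, path[:, 1])
    return np.column_stack([xs, ys])


def make_worm(
    head: tuple[float, float],
    heading: float,
    env: Environment | None = None,
    **kw,
) -> WormState:
    """Create a straight worm with its head at ``head`` pointing ``heading``.

    Raises if any body point starts inside an obstacle (when ``env`` given).
    """
    length = kw.get("body_length", 1000.0)
    n = kw.get("n_points", 21)
    d = np.array([math.cos(heading), math.sin(heading)])
    pts = np.array(head, dtype=float) - np.outer(np.linspace(0, length * 1.05, 4 * n), d)
    state = WormState(path=pts, heading=heading, **kw)
    if env is not None:
        cl = state.centerline()
        required = state.body_width / 2
        for p in cl:
            if env.clearance_at(p[0], p[1]) < required:
                raise ValueError(f"worm initialized inside/too close to an obstacle at {tuple(p)}")
    return state


def step(state: WormState, env: Environment, dt: float, rng: np.random.Generator) -> WormState:
    """Advance the worm by ``dt`` seconds (mutates and returns ``state``).

    Head advances along heading at ``base_speed × confinement_gain(clearance)``
    (optionally time-modulated); heading receives turning noise plus optional
    food-site / guide-axis / waypoint bias; collisions are resolved by
    pushing back into free space, and a blocked head reverses direction.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    cx, cy = state.centroid()
    clearance = env.clearance_at(cx, cy)
    speed = state.current_speed(clearance)

    # heading bias terms
    if state.waypoints:
        wx, wy = state.waypoints[0]
        hx, hy = state.head()
        if math.hypot(wx - hx, wy - hy) < state.waypoint_tolerance:
            state.waypoints.pop(0)
        if state.waypoints:
            wx, wy = state.waypoints[0]
            target = math.atan2(wy - hy, wx - hx)
            state.heading += _angdiff(target, state.heading) * min(1.0, 5.0 * dt)
    elif state.food_bias_rad_s > 0 and env.food_sites:
        hx, hy = state.head()
        (fx, fy), _strength = min(
            env.food_sites, key=lambda fs: math.hypot(fs[0][0] - hx, fs[0][1] - hy)
        )
        target = math.atan2(fy - hy, fx - hx)
        state.heading += _angdiff(target, state.heading) * min(1.0, state.food_bias_rad_s * dt)
    elif env.guide_axis is not None:
        gx, gy = env.guide_axis
        axis = math.atan2(gy, gx)
        # relax toward whichever axis direction is closer (channel tangent)
        d1, d2 = _angdiff(axis, state.heading), _angdiff(axis + math.pi, state.heading)
        state.heading += (d1 if abs(d1) < abs(d2) else d2) * min(1.0, 2.0 * dt)

    state.heading += float(rng.normal(0.0, state.turn_noise_rad_sqrt_s * math.sqrt(dt)))

    required = state.body_width / 2 + 1.5 * env.occupancy.um_per_px
    head = state.head().copy()

    if state.wall_avoidance and speed > 0:
        # anticipatory steering: probe ahead and veer toward open space
        # before contact, so walls redirect rather than brake the worm
        look = max(state.body_width, speed * 0.5)
        d = np.array([math.cos(state.heading), math.sin(state.heading)])
        cf = env.clearance_at(*(head + look * d))
        threshold = required + 0.5 * look
        if cf < threshold:
            dl = np.array([math.cos(state.heading + 0.5), math.sin(state.heading + 0.5)])
            dr = np.array([math.cos(state.heading - 0.5), math.sin(state.heading - 0.5)])
            cl_side = env.clearance_at(*(head + look * dl))
            cr_side = env.clearance_at(*(head + look * dr))
            urgency = min(1.0, (threshold - cf) / (0.5 * look))
            state.heading += (1.0 if cl_side >= cr_side else -1.0) * 4.0 * urgency * dt
    step_len = speed * dt
    if step_len > 0:
        proposed = head + step_len * np.array([math.cos(state.heading), math.sin(state.heading)])
        resolved = env.push_free(proposed, required)
        moved = float(np.linalg.norm(resolved - head))
        if moved < 0.3 * step_len:
            # blocked: reverse along the body
            state.heading += math.pi + float(rng.normal(0.0, 0.2))
            state.heading = math.atan2(math.sin(state.heading), math.cos(state.heading))
        else:
            # keep heading aligned with realized motion (sliding along walls)
            state.heading = math.atan2(resolved[1] - head[1], resolved[0] - head[0])
            if moved > 1e-9:
                state.path = np.vstack([resolved[None, :], state.path])
        _trim_path(state)

    state.time += dt
    state.phase += 2 * math.pi * state.undulation_frequency * dt
    return state


def _angdiff(a: float, b: float) -> float:
    return math.atan2(math.sin(a - b), math.cos(a - b))


def _trim_path(state: WormState, margin: float = 1.2) -> None:
    seg = np.linalg.norm(np.diff(state.path, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    keep = int(np.searchsorted(cum, state.body_length * margin)) + 2
    state.path = state.path[: max(keep, 2)]


def undulated_centerline(
    state: WormState,
    spacing_um: float = 2.0,
    env: Environment | None = None,
) -> np.ndarray:
    """Dense body centerline with the traveling-wave lateral offset applied.

    When ``env`` is given, the lateral amplitude is clamped per body point so
    the rendered tube never reaches into obstacles (the wave flattens where
    the body hugs a wall).
    """
    n = max(int(state.body_length / spacing_um) + 1, 8)
    base = _resample_polyline(state.path, state.body_length, n)
    tang = np.gradient(base, axis=0)
    norm = np.linalg.norm(tang, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    tang /= norm
    normal = np.column_stack([-tang[:, 1], tang[:, 0]])
    s = np.linspace(0.0, state.body_length, n)
    amp = state.undulation_amplitude * np.sin(
        2 * math.pi * s / state.undulation_wavelength - state.phase
    )
    # taper to zero at head and tail so endpoints stay on the spine
    taper = np.minimum(1.0, np.minimum(s, s[-1] - s) / (0.15 * state.body_length))
    offsets = amp * taper
    if env is not None:
        margin = state.body_width / 2 + 1.5 * env.occupancy.um_per_px
        allowed = np.maximum(env.clearance_at_many(base) - margin, 0.0)
        offsets = np.clip(offsets, -allowed, allowed)
    return base + normal * offsets[:, None]


# ---------------------------------------------------------------------------
# Camera and rendering
# ---------------------------------------------------------------------------


@dataclass
class CameraModel:
    """Pixel grid of the virtual camera (y-down; world window centred on ``center``)."""

    image_shape: tuple[int, int] = (480, 640)
    um_per_px: float = 5.0
    frame_rate: float = 10.0
    center: tuple[float, float] = (0.0, 0.0)
    background_level: float = 200.0
    worm_level: float = 60.0
    obstacle_level: float = 150.0
    noise_sd: float = 3.0

    def __post_init__(self) -> None:
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be > 0")
        for lvl in (self.background_level, self.worm_level, self.obstacle_level):
            if not (0 <= lvl <= 255):
                raise ValueError("intensity levels must be in [0, 255]")
        if self.worm_level >= self.background_level:
            raise ValueError("worm must be darker than background")

    @classmethod
    def for_bounds(cls, bounds: tuple[float, float, float, float], um_per_px: float = 5.0, margin_um: float = 100.0, **kw) -> "CameraModel":
        xmin, ymin, xmax, ymax = bounds
        w = int(math.ceil((xmax - xmin + 2 * margin_um) / um_per_px))
        h = int(math.ceil((ymax - ymin + 2 * margin_um) / um_per_px))
        return cls(
            image_shape=(h, w),
            um_per_px=um_per_px,
            center=((xmin + xmax) / 2, (ymin + ymax) / 2),
            **kw,
        )

    def world_to_px(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        h, w = self.image_shape
        col = (np.asarray(x) - self.center[0]) / self.um_per_px + (w - 1) / 2
        row = (self.center[1] - np.asarray(y)) / self.um_per_px + (h - 1) / 2
        return row, col

    def px_to_world(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        h, w = self.image_shape
        x = self.center[0] + (np.asarray(col) - (w - 1) / 2) * self.um_per_px
        y = self.center[1] - (np.asarray(row) - (h - 1) / 2) * self.um_per_px
        return x, y

    def pixel_grid_world(self) -> tuple[np.ndarray, np.ndarray]:
        h, w = self.image_shape
        x, _ = self.px_to_world(np.zeros(w), np.arange(w))
        _, y = self.px_to_world(np.arange(h), np.zeros(h))
        return x, y


class _Renderer:
    """Caches the static obstacle image and the worm disc stamp per camera/env."""

    def __init__(self, camera: CameraModel):
        self.camera = camera
        self._base: np.ndarray | None = None
        self._base_version = -1
        self._disc: tuple[np.ndarray, np.ndarray] | None = None
        self._disc_radius_px = -1

    def base_image(self, env: Environment | None) -> np.ndarray:
        if env is None:
            return np.full(self.camera.image_shape, self.camera.background_level, dtype=np.float32)
        if self._base is None or env.version != self._base_version:
            img = np.full(self.camera.image_shape, self.camera.background_level, dtype=np.float32)
            xs, ys = self.camera.pixel_grid_world()
            occ = env.occupancy.contains_xy(
                np.repeat(xs[None, :], len(ys), axis=0).ravel(),
                np.repeat(ys[:, None], len(xs), axis=1).ravel(),
            ).reshape(self.camera.image_shape)
            img[occ] = self.camera.obstacle_level
            self._base = img
            self._base_version = env.version
        return self._base

    def disc_offsets(self, radius_px: float) -> tuple[np.ndarray, np.ndarray]:
        r = int(math.ceil(radius_px))
        if self._disc is None or r != self._disc_radius_px:
            dr, dc = np.mgrid[-r : r + 1, -r : r + 1]
            keep = dr**2 + dc**2 <= radius_px**2
            self._disc = (dr[keep], dc[keep])
            self._disc_radius_px = r
        return self._disc

    def worm_mask(self, state: WormState, env: Environment | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Pixel (rows, cols) covered by the worm tube in this pose."""
        cam = self.camera
        pts = undulated_centerline(state, spacing_um=cam.um_per_px * 0.5, env=env)
        row, col = cam.world_to_px(pts[:, 0], pts[:, 1])
        # -0.5 px compensates the dilation from stamping at rounded centres
        radius_px = max(state.body_width / 2 / cam.um_per_px - 0.5, 1.0)
        dr, dc = self.disc_offsets(radius_px)
        rr = (np.rint(row).astype(int)[:, None] + dr[None, :]).ravel()
        cc = (np.rint(col).astype(int)[:, None] + dc[None, :]).ravel()
        h, w = cam.image_shape
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        lin = np.unique(rr[ok] * w + cc[ok])
        return lin // w, lin % w

    def hinge_mask(self, hinge: HingePin) -> tuple[np.ndarray, np.ndarray]:
        poly = hinge.posed_polygon()
        cam = self.camera
        gx0, gy0, gx1, gy1 = poly.bounds
        r0, _ = cam.world_to_px(0, gy1)
        r1, _ = cam.world_to_px(0, gy0)
        _, c0 = cam.world_to_px(gx0, 0)
        _, c1 = cam.world_to_px(gx1, 0)
        h, w = cam.image_shape
        rows = np.arange(max(0, int(r0) - 1), min(h, int(r1) + 2))
        cols = np.arange(max(0, int(c0) - 1), min(w, int(c1) + 2))
        if len(rows) == 0 or len(cols) == 0:
            return np.array([], dtype=int), np.array([], dtype=int)
        x, y = cam.px_to_world(
            np.repeat(rows, len(cols)), np.tile(cols, len(rows))
        )
        shapely.prepare(poly)
        inside = shapely.contains_xy(poly, x, y)
        rr = np.repeat(rows, len(cols))[inside]
        cc = np.tile(cols, len(rows))[inside]
        return rr, cc


def render_frame(
    state: WormState | None,
    env: Environment | None,
    camera: CameraModel,
    rng: np.random.Generator | None = None,
    renderer: _Renderer | None = None,
) -> tuple[np.ndarray, dict]:
    """Render one 8-bit grayscale frame plus its ground-truth record."""
    r = renderer or _Renderer(camera)
    img = r.base_image(env).copy()
    truth: dict = {}
    if env is not None:
        for i, hinge in enumerate(env.hinges):
            rr, cc = r.hinge_mask(hinge)
            img[rr, cc] = camera.worm_level  # lever rendered as dark cured gel
            truth[f"theta_deg_{i}" if i else "theta_deg"] = hinge.angle_deg
    if state is not None:
        rr, cc = r.worm_mask(state, env)
        img[rr, cc] = camera.worm_level
        cx, cy = state.centroid()
        truth.update(x_um=float(cx), y_um=float(cy), area_px=int(len(rr)))
    if rng is not None and camera.noise_sd > 0:
        img += rng.normal(0.0, camera.noise_sd, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8), truth


def render(
    states: Sequence[WormState] | Sequence[None],
    times: Sequence[float],
    env: Environment | None,
    camera: CameraModel,
    rng: np.random.Generator | None = None,
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Render a time series of worm poses; returns frames and the truth table."""
    r = _Renderer(camera)
    frames, rows = [], []
    for t, s in zip(times, states):
        frame, truth = render_frame(s, env, camera, rng, renderer=r)
        truth["time_s"] = float(t)
        frames.append(frame)
        rows.append(truth)
    return frames, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Simulation driver
# ---------------------------------------------------------------------------


class Simulation:
    """Steps the worm/hinges and renders frames at the camera frame rate.

    Physics is substepped so a fast worm cannot tunnel through thin walls.
    ``iter_frames`` streams ``(t, frame, truth)`` without storing the video.
    """

    def __init__(
        self,
        env: Environment,
        worm: WormState | None,
        camera: CameraModel,
        seed: int = 0,
        physics_substeps: int = 5,
    ):
        self.env = env
        self.worm = worm
        self.camera = camera
        self.rng = np.random.default_rng(seed)
        self.physics_substeps = physics_substeps
        self._renderer = _Renderer(camera)
        self.time = 0.0

    def advance(self, dt: float) -> None:
        sub = dt / self.physics_substeps
        for _ in range(self.physics_substeps):
            if self.worm is not None:
                step(self.worm, self.env, sub, self.rng)
            self.time += sub
            # scripted hinges are evaluated at the post-step time so the next
            # rendered frame shows the schedule at exactly its timestamp
            for hinge in self.env.hinges:
                hinge_step(hinge, self.worm, sub, t=self.time)

    def iter_frames(self, duration: float) -> Iterator[tuple[float, np.ndarray, dict]]:
        dt = 1.0 / self.camera.frame_rate
        n = int(round(duration * self.camera.frame_rate))
        for i in range(n):
            t = self.time
            frame, truth = render_frame(self.worm, self.env, self.camera, self.rng, self._renderer)
            truth["time_s"] = float(t)
            yield t, frame, truth
            self.advance(dt)

    def run(self, duration: float) -> tuple[list[np.ndarray], np.ndarray, pd.DataFrame]:
        frames, times, rows = [], [], []
        for t, frame, truth in self.iter_frames(duration):
            frames.append(frame)
            times.append(t)
            rows.append(truth)
        return frames, np.asarray(times), pd.DataFrame(rows)
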