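"""Closed-loop virtual experiment driver.

Couples the tracking pipeline to trigger-based pattern projection inside the
simulator: each frame is rendered, tracked, and evaluated against trigger
rules; fired rules schedule exposures whose geometry becomes collidable only
after the cure completes.  The full event history is recorded in an ordered,
replayable log.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import shapely

from . import exposure as exposure_rules
from .patterns import PatternSpec, MaskBitmap, WorldOccupancy, rasterize_geometry, StrokeStream, stroke_to_mask_updates
from .tracker import TrackerConfig, Trajectory, frame_difference, detect_blobs, select_worm
from .wormsim import Environment, Simulation, WormState

__all__ = [
    "Expose",
    "AtTime",
    "WormInRegion",
    "Manual",
    "TriggerRule",
    "LogEvent",
    "ExperimentLog",
    "validate_rules",
    "run",
    "freehand_session",
    "DEFAULT_CURE_DELAY_S",
]

# it takes about one second for the exposed gel to finish polymerizing
DEFAULT_CURE_DELAY_S = 1.0
MIN_EXPOSURE_S = 0.05


@dataclass
class Expose:
    """Exposure action: project a pattern (or prebuilt mask) for a duration."""

    pattern: PatternSpec | MaskBitmap
    exposure_time: float = 1.0

    def __post_init__(self) -> None:
        if self.exposure_time < MIN_EXPOSURE_S:
            raise ValueError(f"exposure_time must be >= {MIN_EXPOSURE_S} s (shutter floor)")


@dataclass
class AtTime:
    t: float


@dataclass
class WormInRegion:
    region: shapely.Geometry
    dwell_s: float = 0.0


@dataclass
class Manual:
    event_id: str


@dataclass
class TriggerRule:
    condition: AtTime | WormInRegion | Manual
    action: Expose
    once: bool = True
    label: str = ""
    fired: bool = field(default=False, init=False)
    _dwell: float = field(default=0.0, init=False)


@dataclass
class LogEvent:
    t: float
    kind: str  # frame | exposure_start | cure_complete | trigger_fired | rejection
    payload: dict = field(default_factory=dict)


@dataclass
class ExperimentLog:
    events: list[LogEvent] = field(default_factory=list)

    def add(self, t: float, kind: str, **payload) -> None:
        self.events.append(LogEvent(float(t), kind, payload))

    def of_kind(self, kind: str) -> list[LogEvent]:
        return [e for e in self.events if e.kind == kind]

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for e in self.events:
                fh.write(json.dumps({"t": e.t, "kind": e.kind, **e.payload}) + "\n")


def validate_rules(
    rules: Sequence[TriggerRule],
    ctx: exposure_rules.FabricationContext,
    objective: float,
    env: Environment,
    table=None,
) -> None:
    """Check every rule before the run; raises on invalid rules.

    Pattern actions must pass the fabrication design rules; region conditions
    must reference a non-empty region intersecting the arena.
    """
    xmin, ymin, xmax, ymax = env.bounds
    arena = shapely.box(xmin, ymin, xmax, ymax)
    for i, rule in enumerate(rules):
        name = rule.label or f"rule[{i}]"
        if isinstance(rule.condition, WormInRegion):
            region = rule.condition.region
            if region is None or region.is_empty or not region.intersects(arena):
                raise ValueError(f"{name}: region is unknown/empty or outside the arena")
        if isinstance(rule.action.pattern, PatternSpec):
            report = exposure_rules.validate_feature(rule.action.pattern, ctx, objective, table)
            if not report:
                raise ValueError(f"{name}: pattern fails design rules: {report.reasons}")


def _pattern_occupancy(pattern: PatternSpec | MaskBitmap, env: Environment) -> WorldOccupancy:
    res = env.occupancy.um_per_px
    if isinstance(pattern, MaskBitmap):
        occ = WorldOccupancy.empty(env.bounds, res)
        pts = pattern.set_pixel_world_coords()
        if len(pts):
            row, col = occ.world_to_index(pts[:, 0], pts[:, 1])
            ok = (row >= 0) & (row < occ.grid.shape[0]) & (col >= 0) & (col < occ.grid.shape[1])
            occ.grid[row[ok], col[ok]] = True
        return occ
    return rasterize_geometry(pattern.geometry(), res, env.bounds)


def _push_worm_free(worm: WormState, env: Environment) -> bool:
    """After a cure, relocate any embedded body points to the nearest lumen.

    The body polyline is densified (~10 μm spacing) before pushing so no
    interpolated segment is left cutting through freshly cured material.
    """
    from .wormsim import _resample_polyline

    n = max(int(worm.body_length / 10.0), worm.n_points)
    cl = _resample_polyline(worm.path, worm.body_length, n)
    required = worm.body_width / 2 + 1.5 * env.occupancy.um_per_px
    moved = False
    out = []
    for p in cl:
        if env.clearance_at(p[0], p[1]) < required:
            p = env.push_free(p, required)
            moved = True
        out.append(p)
    if moved:
        worm.path = np.asarray(out)
    return moved


def run(
    sim: Simulation,
    rules: Sequence[TriggerRule],
    duration: float,
    ctx: exposure_rules.FabricationContext | None = None,
    objective: float = 5.0,
    tracker_config: TrackerConfig | None = None,
    cure_delay_s: float = DEFAULT_CURE_DELAY_S,
    manual_events: dict[str, float] | None = None,
    store_frames: bool = False,
) -> tuple[ExperimentLog, list[np.ndarray], Trajectory]:
    """Observe -> decide -> pattern loop.

    Per frame: render, track (frame differencing on consecutive frames),
    evaluate rules against the *tracked* worm position, schedule exposures.
    Newly cured geometry becomes collidable only at its cure_complete event;
    a worm overlapping a curing footprint is pushed to the nearest free
    lumen.  Requires the diffusion wait to be satisfied at t=0.
    """
    ctx = ctx or exposure_rules.FabricationContext()
    if not exposure_rules.adhesion_check(ctx):
        raise ValueError(
            f"diffusion wait not satisfied ({ctx.diffusion_time_elapsed_s} s elapsed); "
            "cured features would not adhere"
        )
    validate_rules(rules, ctx, objective, sim.env)
    manual_events = manual_events or {}
    cfg = tracker_config or TrackerConfig()
    log = ExperimentLog()
    frames: list[np.ndarray] = []
    rows: list[dict] = []
    pending: list[tuple[float, PatternSpec | MaskBitmap, str]] = []  # (cure_t, pattern, label)

    cam = sim.camera
    dt = 1.0 / cam.frame_rate
    prev_frame: np.ndarray | None = None
    prev_centroid = None
    tracked_world: tuple[float, float] | None = None

    n = int(round(duration * cam.frame_rate))
    for i in range(n):
        t = sim.time

        # cure completions strictly before anything at this frame time
        still_pending = []
        for cure_t, pattern, label in pending:
            if cure_t <= t:
                occ = _pattern_occupancy(pattern, sim.env)
                sim.env.add_obstacles(occ)
                relocated = sim.worm is not None and _push_worm_free(sim.worm, sim.env)
                log.add(cure_t, "cure_complete", label=label, worm_relocated=bool(relocated))
            else:
                still_pending.append((cure_t, pattern, label))
        pending = still_pending

        from .wormsim import render_frame

        frame, truth = render_frame(sim.worm, sim.env, cam, sim.rng, sim._renderer)
        log.add(t, "frame", index=i)
        if store_frames:
            frames.append(frame)

        # incremental tracking
        if prev_frame is not None:
            motion = frame_difference(frame, prev_frame, cfg)
            blobs = detect_blobs(motion, cfg)
            max_jump_px = cfg.max_jump_body_lengths * cfg.body_length_um / cam.um_per_px
            worm_blob = select_worm(blobs, prev_centroid, max_jump_px=max_jump_px)
            if worm_blob is not None:
                r, c = worm_blob.centroid
                x, y = cam.px_to_world(r, c)
                tracked_world = (float(x), float(y))
                prev_centroid = worm_blob.centroid
                rows.append({"time_s": t, "x_um": x, "y_um": y, "area_px": worm_blob.area, "valid": True})
            else:
                rows.append(
                    {
                        "time_s": t,
                        "x_um": tracked_world[0] if tracked_world else np.nan,
                        "y_um": tracked_world[1] if tracked_world else np.nan,
                        "area_px": 0,
                        "valid": False,
                    }
                )
        else:
            rows.append({"time_s": t, "x_um": np.nan, "y_um": np.nan, "area_px": 0, "valid": False})
        prev_frame = frame

        # rule evaluation on tracker output
        for rule in rules:
            if rule.once and rule.fired:
                continue
            fire = False
            cond = rule.condition
            if isinstance(cond, AtTime):
                fire = t >= cond.t
            elif isinstance(cond, Manual):
                et = manual_events.get(cond.event_id)
                fire = et is not None and t >= et
            elif isinstance(cond, WormInRegion):
                if tracked_world is not None and shapely.contains_xy(
                    cond.region, tracked_world[0], tracked_world[1]
                ):
                    rule._dwell += dt
                else:
                    rule._dwell = 0.0
                fire = rule._dwell >= cond.dwell_s
            if fire:
                rule.fired = True
                log.add(t, "trigger_fired", label=rule.label)
                log.add(t, "exposure_start", label=rule.label, exposure_time=rule.action.exposure_time)
                cure_t = t + rule.action.exposure_time + cure_delay_s
                pending.append((cure_t, rule.action.pattern, rule.label))

        sim.advance(dt)

    traj = Trajectory(pd.DataFrame(rows), cam.um_per_px)
    return log, frames, traj


def freehand_session(
    stream: StrokeStream,
    sim: Simulation,
    transform,
    duration: float | None = None,
    cure_time_s: float = DEFAULT_CURE_DELAY_S,
) -> ExperimentLog:
    """Replay a tablet stroke stream into the simulated environment.

    Each stamp becomes an obstacle at ``t_event + latency + cure_time``; the
    environment is mutated in place so reachability analyses can follow the
    progressive confinement.
    """
    updates = stroke_to_mask_updates(stream, transform)
    log = ExperimentLog()
    if not updates and duration is None:
        return log
    schedule = [(tp + cure_time_s, mask) for tp, mask in updates]
    end = duration if duration is not None else (schedule[-1][0] + 1.0 if schedule else 1.0)
    cam = sim.camera
    dt = 1.0 / cam.frame_rate
    i = 0
    n = int(math.ceil(end / dt)) + 1
    for k in range(n):
        t = sim.time
        while i < len(schedule) and schedule[i][0] <= t:
            cure_t, mask = schedule[i]
            occ = _pattern_occupancy(mask, sim.env)
            sim.env.add_obstacles(occ)
            if sim.worm is not None:
                _push_worm_free(sim.worm, sim.env)
            log.add(cure_t, "cure_complete", label=f"stroke[{i}]")
            i += 1
        log.add(t, "frame", index=k)
        sim.advance(dt)
    return log


def reachable_free_area_um2(env: Environment, point: tuple[float, float]) -> float:
    """Flood-fill area (μm²) of the free-space component containing ``point``."""
    from scipy.ndimage import label

    free = ~env.occupancy.grid
    labels, _ = label(free)
    row, col = env.occupancy.world_to_index(point[0], point[1])
    row = int(np.clip(row, 0, labels.shape[0] - 1))
    col = int(np.clip(col, 0, labels.shape[1] - 1))
    lab = labels[row, col]
    if lab == 0:
        return 0.0
    return float((labels == lab).sum()) * env.occupancy.um_per_px**2
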