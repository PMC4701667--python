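"""Video worm-tracking pipeline.

Frame differencing isolates motion, connected-component blob detection
proposes worm locations, raw image moments give the centroid, and second
central moments give a principal-axis orientation for rigid features
(hinge lever).  Positions are smoothed with a local polynomial
(Savitzky-Golay) fit before velocity and acceleration are derived, and all
outputs are reported in μm and seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FrameSequence",
    "Blob",
    "TrackerConfig",
    "Trajectory",
    "frame_difference",
    "detect_blobs",
    "select_worm",
    "segment_body",
    "background_model",
    "orientation_from_moments",
    "unwrap_orientation",
    "derive_kinematics",
    "track_frames",
    "track",
]


@dataclass
class FrameSequence:
    """Ordered grayscale frames with timestamps and pixel size."""

    frames: list[np.ndarray]
    times: np.ndarray
    um_per_px: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.frames) != len(self.times):
            raise ValueError("frames and times must have equal length")
        if len(self.frames) > 1:
            shapes = {f.shape for f in self.frames}
            if len(shapes) > 1:
                raise ValueError(f"non-uniform frame shapes: {shapes}")
            if not np.all(np.diff(self.times) > 0):
                raise ValueError("times must be strictly increasing")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be > 0")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[tuple[float, np.ndarray]]:
        return iter(zip(self.times, self.frames))


@dataclass
class Blob:
    """Connected motion component with raw and second central moments."""

    pixels: tuple[np.ndarray, np.ndarray]  # (rows, cols)
    area: int
    centroid: tuple[float, float]  # (row, col)
    mu20: float
    mu02: float
    mu11: float

    @classmethod
    def from_pixels(cls, rows: np.ndarray, cols: np.ndarray) -> "Blob":
        r = rows.astype(float)
        c = cols.astype(float)
        rbar, cbar = r.mean(), c.mean()
        return cls(
            pixels=(rows, cols),
            area=int(len(rows)),
            centroid=(float(rbar), float(cbar)),
            mu20=float(((c - cbar) ** 2).sum()),
            mu02=float(((r - rbar) ** 2).sum()),
            mu11=float(((c - cbar) * (r - rbar)).sum()),
        )


@dataclass
class TrackerConfig:
    """Every engineering free parameter of the pipeline, config-overridable."""

    diff_threshold: float | None = None  # None = Otsu on |diff| histogram
    diff_threshold_floor: float = 5.0
    opening_radius_px: int = 1
    min_blob_area_px: int = 20
    body_length_um: float = 1000.0
    body_width_um: float = 60.0
    max_jump_body_lengths: float = 2.0
    body_threshold: float = 30.0
    background_frames: int = 10
    refine_with_body: bool = True
    smooth_window: int = 5
    smooth_polyorder: int = 2


# ---------------------------------------------------------------------------
# Frame differencing and blob detection
# ---------------------------------------------------------------------------


def frame_difference(
    f_t: np.ndarray,
    f_prev: np.ndarray,
    config: TrackerConfig | None = None,
) -> np.ndarray:
    """Binary motion image from two consecutive frames.

    ``|f_t - f_prev|`` is thresholded (Otsu by default, floored at 5 gray
    levels) and cleaned by a morphological opening with a 1-px-radius
    element to drop speckle.
    """
    from scipy.ndimage import binary_opening
    from skimage.filters import threshold_otsu
    from skimage.morphology import disk

    cfg = config or TrackerConfig()
    if f_t.shape != f_prev.shape:
        raise ValueError(f"frame shapes differ: {f_t.shape} vs {f_prev.shape}")
    diff = np.abs(f_t.astype(np.int16) - f_prev.astype(np.int16)).astype(np.uint8)
    if cfg.diff_threshold is not None:
        thr = cfg.diff_threshold
    else:
        if diff.max() == diff.min():
            thr = cfg.diff_threshold_floor
        else:
            thr = max(float(threshold_otsu(diff)), cfg.diff_threshold_floor)
    motion = diff > thr
    if cfg.opening_radius_px > 0 and motion.any():
        motion = binary_opening(motion, structure=disk(cfg.opening_radius_px))
    return motion


def detect_blobs(motion: np.ndarray, config: TrackerConfig | None = None) -> list[Blob]:
    """8-connected components of a binary image with area >= min_blob_area."""
    from scipy.ndimage import label

    cfg = config or TrackerConfig()
    if motion.dtype != bool:
        motion = motion.astype(bool)
    labels, n = label(motion, structure=np.ones((3, 3), dtype=int))
    blobs = []
    for i in range(1, n + 1):
        rows, cols = np.nonzero(labels == i)
        if len(rows) >= cfg.min_blob_area_px:
            blobs.append(Blob.from_pixels(rows, cols))
    return blobs


def select_worm(
    blobs: Sequence[Blob],
    previous_centroid: tuple[float, float] | None,
    max_jump_px: float | None = None,
) -> Blob | None:
    """Pick the worm blob: nearest to the previous centroid within
    ``max_jump_px``, else the largest-area blob; None when nothing qualifies."""
    if not blobs:
        return None
    if previous_centroid is not None:
        def dist(b: Blob) -> float:
            return math.hypot(
                b.centroid[0] - previous_centroid[0], b.centroid[1] - previous_centroid[1]
            )

        nearest = min(blobs, key=dist)
        if max_jump_px is None or dist(nearest) <= max_jump_px:
            return nearest
        return None
    return max(blobs, key=lambda b: b.area)


# ---------------------------------------------------------------------------
# Body segmentation and orientation
# ---------------------------------------------------------------------------


def background_model(frames: Sequence[np.ndarray], k: int = 10) -> np.ndarray:
    """Median of the first ``k`` frames (a still can be passed through as-is)."""
    stack = np.stack(list(frames)[:k]).astype(float)
    return np.median(stack, axis=0)


def segment_body(
    frame: np.ndarray,
    background: np.ndarray,
    config: TrackerConfig | None = None,
) -> np.ndarray:
    """Dark-object mask: ``background - frame > body_threshold``, largest component."""
    from scipy.ndimage import label

    cfg = config or TrackerConfig()
    dark = (background.astype(float) - frame.astype(float)) > cfg.body_threshold
    if not dark.any():
        return np.zeros_like(dark)
    labels, n = label(dark, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return np.zeros_like(dark)
    sizes = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < cfg.min_blob_area_px:
        return np.zeros_like(dark)
    return labels == best


def orientation_from_moments(mask: np.ndarray) -> float:
    """Principal-axis angle in degrees from the vertical image axis.

    Positive when the top of the axis tilts toward +col; returned in
    (-90, 90].  Raises on a degenerate (isotropic) mask where the axis is
    undefined.
    """
    rows, cols = np.nonzero(mask)
    if len(rows) == 0:
        raise ValueError("empty mask: orientation undefined")
    # math frame: x = col, y = -row (y up)
    x = cols.astype(float)
    y = -rows.astype(float)
    xbar, ybar = x.mean(), y.mean()
    mu20 = ((x - xbar) ** 2).mean()
    mu02 = ((y - ybar) ** 2).mean()
    mu11 = ((x - xbar) * (y - ybar)).mean()
    if math.isclose(mu20, mu02, rel_tol=1e-12, abs_tol=1e-12) and abs(mu11) < 1e-12:
        raise ValueError("degenerate (isotropic) mask: orientation undefined")
    phi = 0.5 * math.degrees(math.atan2(2 * mu11, mu20 - mu02))  # from +x axis
    theta = 90.0 - phi
    while theta > 90.0:
        theta -= 180.0
    while theta <= -90.0:
        theta += 180.0
    return theta


def unwrap_orientation(angles_deg: Sequence[float]) -> np.ndarray:
    """Resolve the 180-degree principal-axis ambiguity along a time series."""
    out = np.asarray(angles_deg, dtype=float).copy()
    for i in range(1, len(out)):
        while out[i] - out[i - 1] > 90.0:
            out[i] -= 180.0
        while out[i] - out[i - 1] < -90.0:
            out[i] += 180.0
    return out


def refine_centroid_with_body(
    frame: np.ndarray,
    background: np.ndarray,
    blob: Blob,
    config: TrackerConfig | None = None,
    um_per_px: float = 1.0,
) -> tuple[tuple[float, float], int] | None:
    """Re-centre a motion blob on the segmented dark body.

    The motion image of a long undulating worm is a pair of crescents whose
    centroid wanders along the body; the centroid of the dark body pixels in
    a local window around the blob is far more stable.  Returns
    ((row, col), area) or None when no dark component is found.
    """
    from scipy.ndimage import label

    cfg = config or TrackerConfig()
    half = int(cfg.body_length_um / um_per_px)
    r0 = max(0, int(blob.centroid[0]) - half)
    r1 = min(frame.shape[0], int(blob.centroid[0]) + half + 1)
    c0 = max(0, int(blob.centroid[1]) - half)
    c1 = min(frame.shape[1], int(blob.centroid[1]) + half + 1)
    win = np.s_[r0:r1, c0:c1]
    dark = (background[win].astype(float) - frame[win].astype(float)) > cfg.body_threshold
    if not dark.any():
        return None
    labels, n = label(dark, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return None
    # prefer the component overlapping the motion blob, else the largest
    blob_rows = np.clip(blob.pixels[0] - r0, 0, labels.shape[0] - 1)
    blob_cols = np.clip(blob.pixels[1] - c0, 0, labels.shape[1] - 1)
    hits = labels[blob_rows, blob_cols]
    hits = hits[hits > 0]
    if len(hits):
        best = int(np.bincount(hits).argmax())
    else:
        best = int(np.argmax(np.bincount(labels.ravel())[1:])) + 1
    rows, cols = np.nonzero(labels == best)
    if len(rows) < cfg.min_blob_area_px:
        return None
    return ((float(rows.mean()) + r0, float(cols.mean()) + c0), int(len(rows)))


# ---------------------------------------------------------------------------
# Trajectory and kinematics
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Per-frame track in world units with derived kinematics.

    ``data`` columns: time_s, x_um, y_um, area_px, valid and, after
    :func:`derive_kinematics`, vx_um_s, vy_um_s, speed_um_s, accel_um_s2.
    """

    data: pd.DataFrame
    um_per_px: float

    SCHEMA = [
        "time_s",
        "x_um",
        "y_um",
        "area_px",
        "valid",
        "vx_um_s",
        "vy_um_s",
        "speed_um_s",
        "accel_um_s2",
    ]

    def valid(self) -> pd.DataFrame:
        return self.data[self.data["valid"]]

    def max_speed(self) -> float:
        v = self.valid()
        if "speed_um_s" not in v or v["speed_um_s"].dropna().empty:
            raise ValueError("no derived speeds; run derive_kinematics first")
        return float(v["speed_um_s"].max())


def derive_kinematics(
    traj: Trajectory,
    window: int | None = None,
    polyorder: int | None = None,
    smoother: str = "savgol",
) -> Trajectory:
    """Smooth positions and differentiate for velocity/acceleration.

    The default smoother is a local polynomial (Savitzky-Golay) fit; a
    ``"boxcar"`` moving average is available for peak-speed measurements,
    since its central-difference derivative is a mean of local slopes and
    cannot overshoot at sharp velocity changes (e.g. a wall stop), unlike a
    fitted polynomial.  Central differences on the smoothed positions;
    endpoints one-sided (``np.gradient``).  Valid frames only.
    """
    from scipy.ndimage import uniform_filter1d
    from scipy.signal import savgol_filter

    cfg = TrackerConfig()
    window = window or cfg.smooth_window
    polyorder = polyorder if polyorder is not None else cfg.smooth_polyorder
    df = traj.data.copy()
    valid = df["valid"].to_numpy()
    if valid.sum() < 3:
        raise ValueError("need at least 3 valid frames to derive kinematics")
    if window > valid.sum():
        raise ValueError(f"smoothing window {window} exceeds {valid.sum()} valid frames")
    if window % 2 == 0:
        window += 1

    t = df.loc[valid, "time_s"].to_numpy()
    x = df.loc[valid, "x_um"].to_numpy()
    y = df.loc[valid, "y_um"].to_numpy()
    if smoother == "boxcar":
        xs = uniform_filter1d(x, window, mode="nearest")
        ys = uniform_filter1d(y, window, mode="nearest")
    elif smoother != "savgol":
        raise ValueError(f"unknown smoother {smoother!r}")
    elif window > polyorder + 1:
        xs = savgol_filter(x, window, polyorder, mode="interp")
        ys = savgol_filter(y, window, polyorder, mode="interp")
    else:
        xs, ys = x, y
    vx = np.gradient(xs, t)
    vy = np.gradient(ys, t)
    speed = np.hypot(vx, vy)
    ax = np.gradient(vx, t)
    ay = np.gradient(vy, t)
    accel = np.hypot(ax, ay)

    for col in ("vx_um_s", "vy_um_s", "speed_um_s", "accel_um_s2"):
        df[col] = np.nan
    df.loc[valid, "vx_um_s"] = vx
    df.loc[valid, "vy_um_s"] = vy
    df.loc[valid, "speed_um_s"] = speed
    df.loc[valid, "accel_um_s2"] = accel
    return Trajectory(df, traj.um_per_px)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def track_frames(
    timed_frames: Iterable[tuple[float, np.ndarray]],
    um_per_px: float,
    config: TrackerConfig | None = None,
    origin_world: tuple[float, float] | None = None,
    image_shape: tuple[int, int] | None = None,
) -> Trajectory:
    """Streaming tracking over ``(time, frame)`` pairs.

    Centroids are converted to world μm.  By default world (0, 0) is the
    image centre (matching the simulator camera); pass ``origin_world`` as
    the world coordinate of pixel (0, 0) to override.  Frames with no
    qualifying blob carry the previous position with ``valid=False``.
    """
    cfg = config or TrackerConfig()
    rows: list[dict] = []
    state = {
        "prev_frame": None,
        "prev_centroid": None,
        "shape": image_shape,
        "last_pos": (np.nan, np.nan),
        "last_area": 0,
        "background": None,
        "area_ref": 0.0,  # running max refined body area, for partial-body gating
    }

    def emit_invalid(t: float) -> None:
        rows.append(
            {
                "time_s": t,
                "x_um": state["last_pos"][0],
                "y_um": state["last_pos"][1],
                "area_px": state["last_area"],
                "valid": False,
            }
        )

    def process(t: float, frame: np.ndarray) -> None:
        if state["shape"] is None:
            state["shape"] = frame.shape
        if state["background"] is None:
            state["background"] = frame.astype(float).copy()
        else:
            np.maximum(state["background"], frame, out=state["background"])
        prev = state["prev_frame"]
        state["prev_frame"] = frame
        if prev is None:
            emit_invalid(t)
            return
        motion = frame_difference(frame, prev, cfg)
        blobs = detect_blobs(motion, cfg)
        # 2 body lengths per frame interval is far above any plausible worm move
        max_jump_px = cfg.max_jump_body_lengths * cfg.body_length_um / um_per_px
        worm = select_worm(blobs, state["prev_centroid"], max_jump_px=max_jump_px)
        if worm is None:
            emit_invalid(t)
            return
        centroid_px, area = worm.centroid, worm.area
        if cfg.refine_with_body:
            refined = refine_centroid_with_body(frame, state["background"], worm, cfg, um_per_px)
            if refined is None:
                emit_invalid(t)
                return
            centroid_px, area = refined
            # occluded / half-formed bodies (e.g. background not yet clean)
            # produce shrunken masks whose centroid is biased: flag them
            expected_area = cfg.body_length_um * cfg.body_width_um / um_per_px**2
            if area < 0.5 * max(state["area_ref"], expected_area):
                state["prev_centroid"] = centroid_px
                emit_invalid(t)
                return
            state["area_ref"] = max(state["area_ref"], float(area))
        r, c = centroid_px
        shape = state["shape"]
        if origin_world is None:
            x = (c - (shape[1] - 1) / 2) * um_per_px
            y = ((shape[0] - 1) / 2 - r) * um_per_px
        else:
            x = origin_world[0] + c * um_per_px
            y = origin_world[1] - r * um_per_px
        rows.append({"time_s": t, "x_um": x, "y_um": y, "area_px": area, "valid": True})
        state["prev_centroid"] = centroid_px
        state["last_pos"], state["last_area"] = ((x, y), area)

    stream = iter(timed_frames)
    if cfg.refine_with_body and cfg.background_frames > 1:
        # warm-up: median background over the first k frames suppresses the
        # worm's initial imprint before the running max takes over
        warmup: list[tuple[float, np.ndarray]] = []
        for item in stream:
            warmup.append(item)
            if len(warmup) >= cfg.background_frames:
                break
        if warmup:
            state["background"] = np.median(
                np.stack([f for _, f in warmup]).astype(float), axis=0
            )
        for t, frame in warmup:
            process(t, frame)
    for t, frame in stream:
        process(t, frame)

    df = pd.DataFrame(rows)
    return Trajectory(df, um_per_px)


def track(
    seq: FrameSequence,
    config: TrackerConfig | None = None,
    derive: bool = True,
    **kw,
) -> Trajectory:
    """Track a full FrameSequence and (by default) derive kinematics."""
    traj = track_frames(iter(seq), seq.um_per_px, config, **kw)
    if derive:
        traj = derive_kinematics(traj)
    return traj
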