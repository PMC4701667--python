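"""Mask generation for a DMD projector.

Compiles parametric assay geometries and freehand stroke input into binary
DMD mask bitmaps, with coordinate transforms between the sample (world)
plane and the DMD pixel grid, multi-exposure stitching into a world-frame
occupancy grid, and a single-kernel optical blur / dose model.

Conventions (used everywhere in this package):

* World coordinates are in micrometres, y-up, origin at the centre of the
  projected field (plus any stage offset).
* DMD / image coordinates are 0-based ``(row, col)``, y-down, with pixel
  centres at integer indices.
* Masks are strictly binary: a pixel is set iff its centre lies inside the
  exposed (solid / cured) region of the pattern.  For confinement patterns
  the exposed region is the wall or pillar material, not the lumen.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import LineString, Point, Polygon, box
from shapely.ops import unary_union

__all__ = [
    "OutOfFieldError",
    "PatternExtentError",
    "GridMismatchError",
    "ProjectionTransform",
    "PatternSpec",
    "Frame",
    "PillarArray",
    "TMaze",
    "Spiral",
    "CorrugatedChannel",
    "Disk",
    "PolygonSpec",
    "StrokeStream",
    "MaskBitmap",
    "WorldOccupancy",
    "world_to_dmd",
    "dmd_to_world",
    "rasterize",
    "rasterize_geometry",
    "stroke_to_mask_updates",
    "stitch",
    "apply_optical_blur",
    "cured_footprint",
    "fit_corner_radius",
    "DEFAULT_BLUR_SIGMA_UM",
]


class OutOfFieldError(ValueError):
    """A world point maps outside the projected DMD field."""


class PatternExtentError(ValueError):
    """A pattern extends beyond the projected field and stitching was not requested."""


class GridMismatchError(ValueError):
    """Masks on inconsistent pixel grids combined without resample permission."""


# μm per DMD pixel at the sample plane for a nominal 27.5 μm effective
# mirror pitch; the 5X field then spans ~5.6 mm across 1024 mirrors.
_PITCH_UM = 27.5


@dataclass(frozen=True)
class ProjectionTransform:
    """Affine map between the sample plane (μm) and the DMD pixel grid."""

    objective_magnification: float
    sample_um_per_dmd_px: float
    dmd_shape: tuple[int, int] = (768, 1024)
    world_offset: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.sample_um_per_dmd_px <= 0:
            raise ValueError("sample_um_per_dmd_px must be > 0")
        if self.dmd_shape[0] <= 0 or self.dmd_shape[1] <= 0:
            raise ValueError("dmd_shape components must be > 0")

    @classmethod
    def for_objective(
        cls,
        magnification: float,
        dmd_shape: tuple[int, int] = (768, 1024),
        world_offset: tuple[float, float] = (0.0, 0.0),
    ) -> "ProjectionTransform":
        return cls(
            objective_magnification=magnification,
            sample_um_per_dmd_px=_PITCH_UM / magnification,
            dmd_shape=dmd_shape,
            world_offset=world_offset,
        )

    @property
    def center_pixel(self) -> tuple[int, int]:
        return (self.dmd_shape[0] // 2, self.dmd_shape[1] // 2)

    @property
    def field_extent_um(self) -> tuple[float, float]:
        """(width, height) of the projected field in μm."""
        return (
            self.dmd_shape[1] * self.sample_um_per_dmd_px,
            self.dmd_shape[0] * self.sample_um_per_dmd_px,
        )

    def field_bounds(self) -> tuple[float, float, float, float]:
        """World (xmin, ymin, xmax, ymax) covered by pixel centres."""
        s = self.sample_um_per_dmd_px
        r0, c0 = self.center_pixel
        rows, cols = self.dmd_shape
        ox, oy = self.world_offset
        xmin = ox + (0 - c0) * s
        xmax = ox + (cols - 1 - c0) * s
        ymax = oy + (r0 - 0) * s
        ymin = oy + (r0 - (rows - 1)) * s
        return (xmin, ymin, xmax, ymax)

    def col_world_x(self) -> np.ndarray:
        s = self.sample_um_per_dmd_px
        return self.world_offset[0] + (np.arange(self.dmd_shape[1]) - self.center_pixel[1]) * s

    def row_world_y(self) -> np.ndarray:
        s = self.sample_um_per_dmd_px
        return self.world_offset[1] - (np.arange(self.dmd_shape[0]) - self.center_pixel[0]) * s


def world_to_dmd(point: Sequence[float], transform: ProjectionTransform) -> tuple[float, float]:
    """Map a world point (μm) to continuous DMD ``(row, col)`` coordinates.

    Raises :class:`OutOfFieldError` if the point falls outside the field.
    """
    s = transform.sample_um_per_dmd_px
    r0, c0 = transform.center_pixel
    ox, oy = transform.world_offset
    col = c0 + (point[0] - ox) / s
    row = r0 - (point[1] - oy) / s
    rows, cols = transform.dmd_shape
    if not (-0.5 <= row <= rows - 0.5 and -0.5 <= col <= cols - 0.5):
        raise OutOfFieldError(
            f"world point {tuple(point)} maps to DMD ({row:.1f}, {col:.1f}), "
            f"outside shape {transform.dmd_shape}"
        )
    return (row, col)


def dmd_to_world(rowcol: Sequence[float], transform: ProjectionTransform) -> tuple[float, float]:
    """Inverse of :func:`world_to_dmd` (exact for in-field points)."""
    s = transform.sample_um_per_dmd_px
    r0, c0 = transform.center_pixel
    ox, oy = transform.world_offset
    x = ox + (rowcol[1] - c0) * s
    y = oy - (rowcol[0] - r0) * s
    return (x, y)


# ---------------------------------------------------------------------------
# Pattern specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatternSpec:
    """Base class for parametric assay geometries (all lengths in μm, world frame).

    Subclasses implement :meth:`geometry` returning the exposed (cured solid)
    region as a shapely geometry, plus width queries used by the design-rule
    validator: :meth:`raised_widths` (solid feature widths) and
    :meth:`channel_widths` (negative / lumen widths).
    """

    def geometry(self) -> shapely.Geometry:
        raise NotImplementedError

    def raised_widths(self) -> list[tuple[str, float]]:
        return []

    def channel_widths(self) -> list[tuple[str, float]]:
        return []


def _positive(name: str, value: float) -> None:
    if value <= 0:
        raise ValueError(f"{name} must be > 0, got {value}")


@dataclass(frozen=True)
class Frame(PatternSpec):
    """Rectangular enclosure: exposed region is the wall ring."""

    outer_w: float
    outer_h: float
    wall_thickness: float
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        _positive("outer_w", self.outer_w)
        _positive("outer_h", self.outer_h)
        _positive("wall_thickness", self.wall_thickness)
        if 2 * self.wall_thickness >= min(self.outer_w, self.outer_h):
            raise ValueError("wall_thickness too large for frame size")

    def interior_bounds(self) -> tuple[float, float, float, float]:
        cx, cy = self.center
        hw = self.outer_w / 2 - self.wall_thickness
        hh = self.outer_h / 2 - self.wall_thickness
        return (cx - hw, cy - hh, cx + hw, cy + hh)

    def geometry(self) -> shapely.Geometry:
        cx, cy = self.center
        outer = box(cx - self.outer_w / 2, cy - self.outer_h / 2, cx + self.outer_w / 2, cy + self.outer_h / 2)
        return outer.difference(box(*self.interior_bounds()))

    def raised_widths(self) -> list[tuple[str, float]]:
        return [("frame wall", self.wall_thickness)]

    def channel_widths(self) -> list[tuple[str, float]]:
        x0, y0, x1, y1 = self.interior_bounds()
        return [("frame interior", min(x1 - x0, y1 - y0))]


@dataclass(frozen=True)
class PillarArray(PatternSpec):
    """Square lattice of circular pillars filling ``region`` (xmin, ymin, xmax, ymax).

    Only pillars that fit entirely inside the region are placed; the lattice
    is centred within the region.
    """

    diameter: float
    pitch: float
    region: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        _positive("diameter", self.diameter)
        _positive("pitch", self.pitch)
        if self.pitch < self.diameter:
            raise ValueError("pillar pitch must be >= diameter (centre-to-centre)")

    def centers(self) -> np.ndarray:
        """Lattice anchored at (xmin + r, ymin + r); pillars fit entirely inside."""
        xmin, ymin, xmax, ymax = self.region
        r = self.diameter / 2
        nx = int(math.floor((xmax - xmin - self.diameter) / self.pitch)) + 1
        ny = int(math.floor((ymax - ymin - self.diameter) / self.pitch)) + 1
        if (xmax - xmin) < self.diameter or (ymax - ymin) < self.diameter:
            return np.empty((0, 2))
        xs = xmin + r + self.pitch * np.arange(nx)
        ys = ymin + r + self.pitch * np.arange(ny)
        gx, gy = np.meshgrid(xs, ys)
        return np.column_stack([gx.ravel(), gy.ravel()])

    def geometry(self) -> shapely.Geometry:
        pts = self.centers()
        if len(pts) == 0:
            return Polygon()
        return unary_union([Point(x, y).buffer(self.diameter / 2, quad_segs=64) for x, y in pts])

    def raised_widths(self) -> list[tuple[str, float]]:
        return [("pillar", self.diameter)]

    def channel_widths(self) -> list[tuple[str, float]]:
        return [("pillar gap", self.pitch - self.diameter)] if self.pitch > self.diameter else []


@dataclass(frozen=True)
class TMaze(PatternSpec):
    """T-shaped maze: vertical stem meeting a horizontal arm with circular terminals.

    The exposed region is the wall material surrounding the T-shaped lumen.
    The stem runs from the entrance at the bottom up to the arm; terminals
    are circular lumen regions at both arm ends.
    """

    stem_len: float
    arm_len: float
    channel_width: float
    wall_thickness: float
    terminal_radius: float
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        for name in ("stem_len", "arm_len", "channel_width", "wall_thickness", "terminal_radius"):
            _positive(name, getattr(self, name))

    def terminal_centers(self) -> tuple[tuple[float, float], tuple[float, float]]:
        cx, cy = self.center
        return ((cx - self.arm_len / 2, cy), (cx + self.arm_len / 2, cy))

    def entrance_point(self) -> tuple[float, float]:
        cx, cy = self.center
        return (cx, cy - self.stem_len)

    def lumen(self) -> shapely.Geometry:
        cx, cy = self.center
        w = self.channel_width
        stem = box(cx - w / 2, cy - self.stem_len, cx + w / 2, cy + w / 2)
        arm = box(cx - self.arm_len / 2, cy - w / 2, cx + self.arm_len / 2, cy + w / 2)
        left, right = self.terminal_centers()
        discs = [Point(p).buffer(self.terminal_radius, quad_segs=64) for p in (left, right)]
        return unary_union([stem, arm] + discs)

    def geometry(self) -> shapely.Geometry:
        lumen = self.lumen()
        return lumen.buffer(self.wall_thickness, quad_segs=16).difference(lumen)

    def raised_widths(self) -> list[tuple[str, float]]:
        return [("maze wall", self.wall_thickness)]

    def channel_widths(self) -> list[tuple[str, float]]:
        return [("maze channel", self.channel_width)]


@dataclass(frozen=True)
class Spiral(PatternSpec):
    """Archimedean spiral wall leaving a ``channel_width`` lumen between turns."""

    turns: float
    channel_width: float
    wall_thickness: float
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        _positive("turns", self.turns)
        _positive("channel_width", self.channel_width)
        _positive("wall_thickness", self.wall_thickness)

    def centerline(self) -> LineString:
        pitch = self.channel_width + self.wall_thickness
        b = pitch / (2 * math.pi)
        a = self.channel_width  # inner clearance before the first turn
        phi = np.linspace(0, 2 * math.pi * self.turns, max(64, int(self.turns * 128)))
        r = a + b * phi
        cx, cy = self.center
        return LineString(np.column_stack([cx + r * np.cos(phi), cy + r * np.sin(phi)]))

    def geometry(self) -> shapely.Geometry:
        return self.centerline().buffer(self.wall_thickness / 2, quad_segs=16)

    def raised_widths(self) -> list[tuple[str, float]]:
        return [("spiral wall", self.wall_thickness)]

    def channel_widths(self) -> list[tuple[str, float]]:
        return [("spiral channel", self.channel_width)]


@dataclass(frozen=True)
class CorrugatedChannel(PatternSpec):
    """Rippled microchannel: sinusoidal lumen of ``width`` with closed ends.

    The centreline runs along x with ``y = ripple_amplitude * sin(2πx/ripple_period)``.
    The exposed region is the wall band (round end caps close the channel).
    """

    length: float
    width: float
    ripple_amplitude: float
    ripple_period: float
    wall_thickness: float = 100.0
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        for name in ("length", "width", "ripple_period", "wall_thickness"):
            _positive(name, getattr(self, name))
        if self.ripple_amplitude < 0:
            raise ValueError("ripple_amplitude must be >= 0")

    def centerline(self) -> LineString:
        cx, cy = self.center
        n = max(64, int(self.length / self.ripple_period * 32))
        xs = np.linspace(-self.length / 2, self.length / 2, n)
        ys = self.ripple_amplitude * np.sin(2 * math.pi * xs / self.ripple_period)
        return LineString(np.column_stack([cx + xs, cy + ys]))

    def lumen(self) -> shapely.Geometry:
        return self.centerline().buffer(self.width / 2, cap_style="round", quad_segs=16)

    def geometry(self) -> shapely.Geometry:
        line = self.centerline()
        outer = line.buffer(self.width / 2 + self.wall_thickness, cap_style="round", quad_segs=16)
        return outer.difference(self.lumen())

    def raised_widths(self) -> list[tuple[str, float]]:
        return [("channel wall", self.wall_thickness)]

    def channel_widths(self) -> list[tuple[str, float]]:
        return [("channel lumen", self.width)]


@dataclass(frozen=True)
class Disk(PatternSpec):
    center: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        _positive("radius", self.radius)

    def geometry(self) -> shapely.Geometry:
        return Point(self.center).buffer(self.radius, quad_segs=64)

    def raised_widths(self) -> list[tuple[str, float]]:
        return [("disk", 2 * self.radius)]


@dataclass(frozen=True)
class PolygonSpec(PatternSpec):
    """Arbitrary exposed polygon; an empty vertex list is an empty pattern."""

    vertices: tuple[tuple[float, float], ...] = ()

    def geometry(self) -> shapely.Geometry:
        if len(self.vertices) == 0:
            return Polygon()
        if len(self.vertices) < 3:
            raise ValueError("polygon needs at least 3 vertices")
        return Polygon(self.vertices)

    def raised_widths(self) -> list[tuple[str, float]]:
        geom = self.geometry()
        if geom.is_empty:
            return []
        # width proxy: diameter of largest inscribed circle
        r = shapely.maximum_inscribed_circle(geom).length
        return [("polygon", 2 * r)]


# ---------------------------------------------------------------------------
# Bitmaps and rasterization
# ---------------------------------------------------------------------------


@dataclass
class MaskBitmap:
    """Binary DMD-plane raster plus its projection transform."""

    pixels: np.ndarray
    transform: ProjectionTransform
    exposure_time: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.shape != tuple(self.transform.dmd_shape):
            raise ValueError(
                f"pixels shape {self.pixels.shape} != dmd_shape {self.transform.dmd_shape}"
            )

    def union(self, other: "MaskBitmap") -> "MaskBitmap":
        if other.transform != self.transform:
            raise GridMismatchError("cannot union masks with different transforms")
        return MaskBitmap(self.pixels | other.pixels, self.transform, self.exposure_time)

    def set_pixel_world_coords(self) -> np.ndarray:
        """World (x, y) μm of every set pixel centre, shape (n, 2)."""
        rr, cc = np.nonzero(self.pixels)
        xs = self.transform.col_world_x()[cc]
        ys = self.transform.row_world_y()[rr]
        return np.column_stack([xs, ys])


def rasterize(
    spec: PatternSpec,
    transform: ProjectionTransform,
    exposure_time: float = 1.0,
    allow_clip: bool = False,
) -> MaskBitmap:
    """Rasterize a pattern spec onto the DMD grid (pixel-centre sampling).

    Deterministic: the same (spec, transform) always yields bit-identical
    pixels.  Raises :class:`PatternExtentError` if the pattern extends beyond
    the projected field, unless ``allow_clip`` (stitching workflows).
    """
    geom = spec.geometry()
    pixels = np.zeros(transform.dmd_shape, dtype=bool)
    if geom.is_empty:
        return MaskBitmap(pixels, transform, exposure_time)

    fx0, fy0, fx1, fy1 = transform.field_bounds()
    gx0, gy0, gx1, gy1 = geom.bounds
    s = transform.sample_um_per_dmd_px
    if not allow_clip and (gx0 < fx0 - s / 2 or gy0 < fy0 - s / 2 or gx1 > fx1 + s / 2 or gy1 > fy1 + s / 2):
        raise PatternExtentError(
            f"pattern bounds {geom.bounds} exceed field {transform.field_bounds()}; "
            "pass allow_clip=True to stitch multiple exposures"
        )

    xs = transform.col_world_x()
    ys = transform.row_world_y()
    cmask = (xs >= gx0 - s) & (xs <= gx1 + s)
    rmask = (ys >= gy0 - s) & (ys <= gy1 + s)
    cols = np.nonzero(cmask)[0]
    rows = np.nonzero(rmask)[0]
    if len(cols) == 0 or len(rows) == 0:
        return MaskBitmap(pixels, transform, exposure_time)
    gx, gy = np.meshgrid(xs[cols], ys[rows])
    shapely.prepare(geom)
    inside = shapely.contains_xy(geom, gx.ravel(), gy.ravel()).reshape(gx.shape)
    pixels[np.ix_(rows, cols)] = inside
    return MaskBitmap(pixels, transform, exposure_time)


def rasterize_geometry(
    geom: shapely.Geometry,
    um_per_px: float,
    bounds: tuple[float, float, float, float],
) -> "WorldOccupancy":
    """Rasterize world-frame geometry directly onto a world occupancy grid."""
    occ = WorldOccupancy.empty(bounds, um_per_px)
    if geom.is_empty:
        return occ
    shapely.prepare(geom)
    gx, gy = np.meshgrid(occ.col_x(), occ.row_y())
    occ.grid[:] = shapely.contains_xy(geom, gx.ravel(), gy.ravel()).reshape(gx.shape)
    return occ


# ---------------------------------------------------------------------------
# Freehand strokes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StrokeStream:
    """Time-ordered tablet pen events.

    ``events`` is a sequence of ``(x_tablet, y_tablet, t_seconds)`` in tablet
    units (treated as μm on the tablet surface).  The drawing is reduced by
    ``scale_reduction`` end-to-end from tablet to sample plane and projected
    ``latency`` seconds after each pen event.
    """

    events: tuple[tuple[float, float, float], ...]
    brush_radius_tablet: float = 1000.0
    scale_reduction: float = 50.0
    latency: float = 0.25

    def __post_init__(self) -> None:
        _positive("scale_reduction", self.scale_reduction)
        _positive("brush_radius_tablet", self.brush_radius_tablet)
        ts = [e[2] for e in self.events]
        if any(t1 < t0 for t0, t1 in zip(ts, ts[1:])):
            raise ValueError("stroke event times must be non-decreasing")


def stroke_to_mask_updates(
    stream: StrokeStream,
    transform: ProjectionTransform,
) -> list[tuple[float, MaskBitmap]]:
    """Convert pen events into latency-delayed incremental mask stamps.

    Each pen event produces a disc stamp of world radius
    ``brush_radius_tablet / scale_reduction`` at the scaled pen location,
    projected at ``t_event + latency``.  Consecutive events farther apart
    than one brush radius are connected by stamped segments (tablets
    subsample fast strokes).  Events mapping outside the projected field are
    skipped with a warning.
    """
    updates: list[tuple[float, MaskBitmap]] = []
    r_world = stream.brush_radius_tablet / stream.scale_reduction
    prev_world: tuple[float, float] | None = None
    for (tx, ty, t) in stream.events:
        wx, wy = tx / stream.scale_reduction, ty / stream.scale_reduction
        centers = [(wx, wy)]
        if prev_world is not None:
            dist = math.hypot(wx - prev_world[0], wy - prev_world[1])
            if dist > r_world:
                n = int(math.ceil(dist / r_world))
                for i in range(1, n):
                    f = i / n
                    centers.insert(
                        -1,
                        (prev_world[0] + f * (wx - prev_world[0]), prev_world[1] + f * (wy - prev_world[1])),
                    )
        prev_world = (wx, wy)
        try:
            world_to_dmd((wx, wy), transform)
        except OutOfFieldError:
            warnings.warn(f"pen event at t={t} maps outside the field; skipped")
            continue
        geom = unary_union([Point(c).buffer(r_world, quad_segs=32) for c in centers])
        stamp = rasterize_stamp(geom, transform)
        updates.append((t + stream.latency, MaskBitmap(stamp, transform)))
    return updates


def rasterize_stamp(geom: shapely.Geometry, transform: ProjectionTransform) -> np.ndarray:
    """Rasterize arbitrary world geometry to a DMD boolean array, clipping to field."""
    pixels = np.zeros(transform.dmd_shape, dtype=bool)
    if geom.is_empty:
        return pixels
    xs = transform.col_world_x()
    ys = transform.row_world_y()
    gx0, gy0, gx1, gy1 = geom.bounds
    s = transform.sample_um_per_dmd_px
    cols = np.nonzero((xs >= gx0 - s) & (xs <= gx1 + s))[0]
    rows = np.nonzero((ys >= gy0 - s) & (ys <= gy1 + s))[0]
    if len(cols) == 0 or len(rows) == 0:
        return pixels
    gx, gy = np.meshgrid(xs[cols], ys[rows])
    shapely.prepare(geom)
    pixels[np.ix_(rows, cols)] = shapely.contains_xy(geom, gx.ravel(), gy.ravel()).reshape(gx.shape)
    return pixels


# ---------------------------------------------------------------------------
# Stitching: world-frame occupancy
# ---------------------------------------------------------------------------


@dataclass
class WorldOccupancy:
    """Boolean obstacle/exposure grid in world coordinates.

    Row 0 is the top of the raster (maximum y); ``world_x = x0 + col * res``
    and ``world_y = y0 - row * res`` at pixel centres.
    """

    grid: np.ndarray
    x0: float
    y0: float
    um_per_px: float

    @classmethod
    def empty(cls, bounds: tuple[float, float, float, float], um_per_px: float) -> "WorldOccupancy":
        xmin, ymin, xmax, ymax = bounds
        ncols = int(math.ceil((xmax - xmin) / um_per_px)) + 1
        nrows = int(math.ceil((ymax - ymin) / um_per_px)) + 1
        return cls(np.zeros((nrows, ncols), dtype=bool), xmin, ymax, um_per_px)

    def col_x(self) -> np.ndarray:
        return self.x0 + np.arange(self.grid.shape[1]) * self.um_per_px

    def row_y(self) -> np.ndarray:
        return self.y0 - np.arange(self.grid.shape[0]) * self.um_per_px

    def world_to_index(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        col = np.rint((np.asarray(x) - self.x0) / self.um_per_px).astype(int)
        row = np.rint((self.y0 - np.asarray(y)) / self.um_per_px).astype(int)
        return row, col

    def contains_xy(self, x, y) -> np.ndarray:
        """True where (x, y) falls on a set (occupied) pixel; False off-grid."""
        row, col = self.world_to_index(x, y)
        row = np.atleast_1d(row)
        col = np.atleast_1d(col)
        ok = (row >= 0) & (row < self.grid.shape[0]) & (col >= 0) & (col < self.grid.shape[1])
        out = np.zeros(row.shape, dtype=bool)
        out[ok] = self.grid[row[ok], col[ok]]
        return out

    def area_um2(self) -> float:
        return float(self.grid.sum()) * self.um_per_px**2

    def union_inplace(self, other: "WorldOccupancy") -> None:
        if not math.isclose(other.um_per_px, self.um_per_px):
            raise GridMismatchError("occupancy grids have different resolutions")
        rr, cc = np.nonzero(other.grid)
        x = other.x0 + cc * other.um_per_px
        y = other.y0 - rr * other.um_per_px
        row, col = self.world_to_index(x, y)
        ok = (row >= 0) & (row < self.grid.shape[0]) & (col >= 0) & (col < self.grid.shape[1])
        self.grid[row[ok], col[ok]] = True


def stitch(
    masks: Iterable[tuple[MaskBitmap, tuple[float, float]]],
    resample: bool = False,
    um_per_px: float | None = None,
) -> WorldOccupancy:
    """Union multiple exposures (mask + stage offset μm) into one world grid.

    All transforms must share ``sample_um_per_dmd_px`` unless ``resample``
    is set, in which case set pixels are snapped to a stated common grid
    (``um_per_px``, default the finest input resolution).  The union is
    idempotent: overlapping exposures do not accumulate.
    """
    masks = list(masks)
    if not masks:
        raise ValueError("no masks to stitch")
    resolutions = {m.transform.sample_um_per_dmd_px for m, _ in masks}
    if len(resolutions) > 1 and not resample:
        raise GridMismatchError(
            f"masks use inconsistent pixel grids {sorted(resolutions)}; pass resample=True"
        )
    res = um_per_px if um_per_px is not None else min(resolutions)

    # world extents over all set pixels (fall back to field bounds for empties)
    pts = []
    for m, (dx, dy) in masks:
        p = m.set_pixel_world_coords()
        if len(p):
            pts.append(p + [dx, dy])
    if not pts:
        fb = masks[0][0].transform.field_bounds()
        return WorldOccupancy.empty(fb, res)
    allpts = np.vstack(pts)
    xmin, ymin = allpts.min(axis=0)
    xmax, ymax = allpts.max(axis=0)
    occ = WorldOccupancy.empty((xmin - res, ymin - res, xmax + res, ymax + res), res)
    for m, (dx, dy) in masks:
        p = m.set_pixel_world_coords()
        if not len(p):
            continue
        row, col = occ.world_to_index(p[:, 0] + dx, p[:, 1] + dy)
        occ.grid[row, col] = True
    return occ


# ---------------------------------------------------------------------------
# Optical blur / dose model
# ---------------------------------------------------------------------------

# Isotropic Gaussian kernel sigma (μm) per objective; the 5X value is a
# one-time derived fit chosen so a right-angle wall corner rounds to a
# fitted radius of 10 μm at the 0.5 dose level; other objectives scale
# inversely with magnification.
_SIGMA_5X_UM = 5.28
DEFAULT_BLUR_SIGMA_UM: dict[float, float] = {
    2: _SIGMA_5X_UM * 5 / 2,
    5: _SIGMA_5X_UM,
    20: _SIGMA_5X_UM * 5 / 20,
    50: _SIGMA_5X_UM * 5 / 50,
}


def apply_optical_blur(
    mask: MaskBitmap,
    objective: float | None = None,
    sigma_um: float | None = None,
) -> np.ndarray:
    """Smooth a binary mask into a grayscale dose image in [0, 1].

    ``sigma_um`` overrides the per-objective default kernel width.
    Thresholding the dose at 0.5 yields the predicted cured footprint
    (:func:`cured_footprint`); right-angle corners round to a finite radius.
    """
    from scipy.ndimage import gaussian_filter

    if sigma_um is None:
        mag = objective if objective is not None else mask.transform.objective_magnification
        try:
            sigma_um = DEFAULT_BLUR_SIGMA_UM[mag]
        except KeyError:
            raise KeyError(
                f"no default blur kernel for objective {mag}X; "
                f"available: {sorted(DEFAULT_BLUR_SIGMA_UM)} (or pass sigma_um)"
            ) from None
    sigma_px = sigma_um / mask.transform.sample_um_per_dmd_px
    if sigma_px <= 0:
        return mask.pixels.astype(float)
    return gaussian_filter(mask.pixels.astype(float), sigma_px, mode="constant")


def cured_footprint(dose: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Predicted cured region: dose >= threshold."""
    return dose >= threshold


def fit_corner_radius(
    dose: np.ndarray,
    transform: ProjectionTransform,
    corner_world: tuple[float, float],
    sigma_um: float,
    threshold: float = 0.5,
) -> float:
    """Fit a circle to the 0.5-level contour arc near a right-angle corner.

    Contour points within ~2.5 kernel widths of ``corner_world`` (where the
    contour departs from both straight edges) are fitted with an algebraic
    least-squares circle; the radius is returned in μm.
    """
    from skimage.measure import find_contours

    contours = find_contours(dose, threshold)
    if not contours:
        raise ValueError("no contour at the requested dose level")
    pts_img = np.vstack(contours)  # (row, col) float
    s = transform.sample_um_per_dmd_px
    r0, c0 = transform.center_pixel
    ox, oy = transform.world_offset
    x = ox + (pts_img[:, 1] - c0) * s
    y = oy - (pts_img[:, 0] - r0) * s
    d = np.hypot(x - corner_world[0], y - corner_world[1])
    near = d <= 2.5 * sigma_um
    if near.sum() < 5:
        raise ValueError("too few contour points near the corner to fit a circle")
    return _kasa_circle_radius(x[near], y[near])


def _kasa_circle_radius(x: np.ndarray, y: np.ndarray) -> float:
    """Algebraic (Kåsa) least-squares circle fit; returns the radius."""
    A = np.column_stack([x, y, np.ones_like(x)])
    b = x**2 + y**2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy = sol[0] / 2, sol[1] / 2
    return float(math.sqrt(sol[2] + cx**2 + cy**2))
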