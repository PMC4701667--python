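"""Empirical exposure/resolution calibration and fabrication design rules.

The calibration table stores measured anchors of line-pair resolution and
optimal exposure time per (objective, feature height).  The default table
ships only text-anchored values; additional anchors can be loaded from a
JSON calibration file.  Exposure falls back to an inverse-height parametric
model ``t = k / h`` when fewer than two anchors exist for an objective.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np

from .patterns import PatternSpec

__all__ = [
    "Anchor",
    "CalibrationTable",
    "FabricationContext",
    "ValidationReport",
    "UnknownObjectiveError",
    "resolution_lookup",
    "optimal_exposure",
    "validate_feature",
    "adhesion_check",
    "default_table",
    "MIN_RAISED_FEATURE_WIDTH_UM",
    "MIN_RAISED_ASPECT",
    "DIFFUSION_WAIT_S",
    "MIN_SHUTTER_S",
]

MIN_RAISED_FEATURE_WIDTH_UM = 50.0
MIN_RAISED_ASPECT = 2.0  # height:width at the minimum raised width
DIFFUSION_WAIT_S = 300.0
MIN_SHUTTER_S = 0.05


class UnknownObjectiveError(KeyError):
    pass


@dataclass(frozen=True)
class Anchor:
    objective: float
    feature_height_um: float
    line_pair_resolution_um: float | None = None
    optimal_exposure_s: float | None = None

    def __post_init__(self) -> None:
        if self.feature_height_um <= 0:
            raise ValueError("feature height must be > 0")
        if self.line_pair_resolution_um is not None and self.line_pair_resolution_um <= 0:
            raise ValueError("resolution must be > 0")
        if self.optimal_exposure_s is not None and self.optimal_exposure_s <= 0:
            raise ValueError("exposure must be > 0")


@dataclass
class CalibrationTable:
    """(objective, height) -> (resolution, exposure) anchors plus design-rule constants."""

    anchors: list[Anchor] = field(default_factory=list)
    min_raised_feature_width_um: float = MIN_RAISED_FEATURE_WIDTH_UM
    min_raised_aspect: float = MIN_RAISED_ASPECT
    diffusion_wait_s: float = DIFFUSION_WAIT_S
    min_shutter_s: float = MIN_SHUTTER_S
    # inverse-model constant per objective for the exposure fallback t = k/h;
    # default 100 μm·s reproduces a 1 s exposure for a 100 μm deep feature.
    exposure_k_um_s: dict[float, float] = field(default_factory=dict)
    default_exposure_k_um_s: float = 100.0

    def objectives(self) -> list[float]:
        return sorted({a.objective for a in self.anchors})

    def _require_objective(self, objective: float) -> None:
        if objective not in {a.objective for a in self.anchors} and objective not in self.exposure_k_um_s:
            raise UnknownObjectiveError(
                f"unknown objective {objective}X; calibrated objectives: {self.objectives()}"
            )

    def _anchors_for(self, objective: float, attr: str) -> list[tuple[float, float]]:
        pts = [
            (a.feature_height_um, getattr(a, attr))
            for a in self.anchors
            if a.objective == objective and getattr(a, attr) is not None
        ]
        return sorted(pts)

    # -- lookups -----------------------------------------------------------

    def resolution_lookup(self, objective: float, height_um: float) -> float:
        """Line-pair resolution (μm) at the given objective and feature height.

        Exact at anchors; log-log linear interpolation between anchors of the
        same objective; clamped (with a warning) outside the anchored range.
        """
        if height_um <= 0:
            raise ValueError("height must be > 0")
        self._require_objective(objective)
        pts = self._anchors_for(objective, "line_pair_resolution_um")
        if not pts:
            raise UnknownObjectiveError(
                f"no resolution anchors for objective {objective}X; "
                f"calibrated objectives: {self.objectives()}"
            )
        heights = np.array([p[0] for p in pts])
        values = np.array([p[1] for p in pts])
        for h, v in pts:
            if math.isclose(h, height_um):
                return float(v)
        if height_um < heights[0] or height_um > heights[-1]:
            warnings.warn(
                f"height {height_um} μm outside anchored range "
                f"[{heights[0]}, {heights[-1]}] for {objective}X; clamping"
            )
            return float(values[0] if height_um < heights[0] else values[-1])
        hi = int(np.searchsorted(heights, height_um))
        if values[hi - 1] == values[hi]:
            # flat regime (e.g. the 10-100 μm thick-film band): exact value
            return float(values[hi])
        return float(
            np.exp(np.interp(np.log(height_um), np.log(heights), np.log(values)))
        )

    def optimal_exposure(self, objective: float, height_um: float) -> float:
        """Optimal exposure time (s): anchored log-log interpolation or ``k/h``.

        Monotone non-increasing in height; never below the mechanical shutter
        floor (0.05 s).
        """
        if height_um <= 0:
            raise ValueError("height must be > 0")
        self._require_objective(objective)
        pts = self._anchors_for(objective, "optimal_exposure_s")
        if len(pts) >= 2:
            heights = np.array([p[0] for p in pts])
            values = np.array([p[1] for p in pts])
            if height_um <= heights[0]:
                t = float(values[0])
            elif height_um >= heights[-1]:
                t = float(values[-1])
            else:
                t = float(np.exp(np.interp(np.log(height_um), np.log(heights), np.log(values))))
        else:
            k = self.exposure_k_um_s.get(objective, self.default_exposure_k_um_s)
            t = k / height_um
        return max(t, self.min_shutter_s)

    def check_monotone(self) -> list[str]:
        """Validate the inverse exposure/height relationship; returns violations."""
        problems = []
        for obj in self.objectives():
            pts = self._anchors_for(obj, "optimal_exposure_s")
            for (h0, t0), (h1, t1) in zip(pts, pts[1:]):
                if t1 > t0:
                    problems.append(
                        f"{obj}X: exposure increases with height ({h0}→{h1} μm: {t0}→{t1} s)"
                    )
        return problems

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "anchors": [
                {
                    "objective": a.objective,
                    "feature_height_um": a.feature_height_um,
                    "line_pair_resolution_um": a.line_pair_resolution_um,
                    "optimal_exposure_s": a.optimal_exposure_s,
                }
                for a in self.anchors
            ],
            "constants": {
                "min_raised_feature_width_um": self.min_raised_feature_width_um,
                "min_raised_aspect": self.min_raised_aspect,
                "diffusion_wait_s": self.diffusion_wait_s,
                "min_shutter_s": self.min_shutter_s,
                "default_exposure_k_um_s": self.default_exposure_k_um_s,
            },
            "exposure_k_um_s": {str(k): v for k, v in self.exposure_k_um_s.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationTable":
        consts = d.get("constants", {})
        return cls(
            anchors=[Anchor(**a) for a in d.get("anchors", [])],
            min_raised_feature_width_um=consts.get("min_raised_feature_width_um", MIN_RAISED_FEATURE_WIDTH_UM),
            min_raised_aspect=consts.get("min_raised_aspect", MIN_RAISED_ASPECT),
            diffusion_wait_s=consts.get("diffusion_wait_s", DIFFUSION_WAIT_S),
            min_shutter_s=consts.get("min_shutter_s", MIN_SHUTTER_S),
            exposure_k_um_s={float(k): v for k, v in d.get("exposure_k_um_s", {}).items()},
            default_exposure_k_um_s=consts.get("default_exposure_k_um_s", 100.0),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationTable":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def default_table() -> CalibrationTable:
    """The shipped calibration table (text-anchored measurements only).

    Thick-film (10–100 μm) line-pair resolution: ~3 μm at 50X, ~23 μm at 5X.
    Thin-film (1 μm): 0.7 μm at 50X, 1 μm at 20X.  The thick-film regime is
    represented by identical anchors at 10 and 100 μm so any in-regime query
    returns the regime value.
    """
    return CalibrationTable(
        anchors=[
            Anchor(50, 1.0, line_pair_resolution_um=0.7),
            Anchor(50, 10.0, line_pair_resolution_um=3.0),
            Anchor(50, 100.0, line_pair_resolution_um=3.0),
            Anchor(20, 1.0, line_pair_resolution_um=1.0),
            Anchor(5, 10.0, line_pair_resolution_um=23.0),
            Anchor(5, 100.0, line_pair_resolution_um=23.0),
        ],
    )


# module-level conveniences over the default table --------------------------

_DEFAULT = default_table()


def resolution_lookup(objective: float, height_um: float, table: CalibrationTable | None = None) -> float:
    return (table or _DEFAULT).resolution_lookup(objective, height_um)


def optimal_exposure(objective: float, height_um: float, table: CalibrationTable | None = None) -> float:
    return (table or _DEFAULT).optimal_exposure(objective, height_um)


# ---------------------------------------------------------------------------
# Fabrication context and design-rule validation
# ---------------------------------------------------------------------------


@dataclass
class FabricationContext:
    """State of one fabrication step on the plate."""

    gap_height_um: float = 100.0
    feature_height_um: float | None = None  # defaults to gap_height_um
    diffusion_time_elapsed_s: float = DIFFUSION_WAIT_S
    polymer_fraction: float = 0.20
    exposure_time_s: float = 1.0

    def __post_init__(self) -> None:
        if self.gap_height_um < 0 or self.diffusion_time_elapsed_s < 0 or self.exposure_time_s < 0:
            raise ValueError("context values must be >= 0")
        if not (0 < self.polymer_fraction <= 1):
            raise ValueError("polymer_fraction must be in (0, 1]")
        if self.feature_height_um is None:
            self.feature_height_um = self.gap_height_um


@dataclass
class ValidationReport:
    accepted: bool
    reasons: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.accepted


def validate_feature(
    spec: PatternSpec,
    ctx: FabricationContext,
    objective: float,
    table: CalibrationTable | None = None,
) -> ValidationReport:
    """Check a pattern spec against the fabrication design rules.

    Rejects raised (positive) solid widths below the 50 μm adhesion minimum,
    negative channel widths below the line-pair resolution at this objective
    and height, degenerate (non-positive) channel widths, and feature heights
    exceeding the bead-defined cover gap.  Every violating primitive is
    listed; the report is accept/reject with reasons.
    """
    tbl = table or _DEFAULT
    height = ctx.feature_height_um
    reasons: list[str] = []

    if height is not None and height > ctx.gap_height_um:
        reasons.append(
            f"feature height {height} μm exceeds cover gap {ctx.gap_height_um} μm (gap-limited)"
        )

    for name, width in spec.raised_widths():
        if width < tbl.min_raised_feature_width_um:
            reasons.append(
                f"raised feature '{name}' width {width} μm is below the "
                f"{tbl.min_raised_feature_width_um} μm adhesion minimum"
            )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = tbl.resolution_lookup(objective, height) if height else None
    for name, width in spec.channel_widths():
        if width <= 0:
            reasons.append(f"channel '{name}' has degenerate width {width} μm")
        elif res is not None and width < res:
            reasons.append(
                f"channel '{name}' width {width} μm is below the line-pair "
                f"resolution {res:.3g} μm at {objective}X / {height} μm"
            )

    return ValidationReport(accepted=not reasons, reasons=reasons)


def adhesion_check(ctx: FabricationContext, table: CalibrationTable | None = None) -> bool:
    """True iff enough interfacial diffusion has elapsed for the cured gel to bond."""
    tbl = table or _DEFAULT
    return ctx.diffusion_time_elapsed_s >= tbl.diffusion_wait_s
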