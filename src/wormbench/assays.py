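"""Assay-level statistics.

Per-configuration speed summaries, maze endpoint classification with the
80%-of-body rule and escape exclusion, exact binomial choice tests with
Clopper-Pearson intervals, and Kaplan-Meier survival with censoring plus a
two-group log-rank test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .tracker import Trajectory

__all__ = [
    "ConfigurationWindow",
    "MazeOutcome",
    "MazeRegions",
    "SurvivalRecord",
    "ChoiceTally",
    "speed_summary",
    "percent_of_baseline",
    "maze_classify",
    "choice_test",
    "kaplan_meier",
    "logrank_test",
    "KaplanMeierResult",
]

BODY_FRACTION_THRESHOLD = 0.80


# ---------------------------------------------------------------------------
# Speed summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfigurationWindow:
    """A labelled time interval of one assay configuration."""

    label: str
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError(f"window '{self.label}' has non-positive duration")


def speed_summary(
    traj: Trajectory,
    windows: Sequence[ConfigurationWindow],
) -> pd.DataFrame:
    """Five-number speed summary per configuration window.

    Quartiles use linear interpolation; max is over valid smoothed speeds.
    Raises if a window holds fewer than 3 valid frames, naming the window.
    """
    for w0, w1 in zip(windows, windows[1:]):
        if w1.t_start < w0.t_end:
            raise ValueError(f"windows '{w0.label}' and '{w1.label}' overlap")
    df = traj.valid()
    if "speed_um_s" not in df:
        raise ValueError("trajectory has no derived speeds; run derive_kinematics")
    rows = []
    for w in windows:
        sel = df[(df["time_s"] >= w.t_start) & (df["time_s"] < w.t_end)]
        speeds = sel["speed_um_s"].dropna().to_numpy()
        if len(speeds) < 3:
            raise ValueError(f"window '{w.label}' has {len(speeds)} valid frames (< 3)")
        q1, med, q3 = np.percentile(speeds, [25, 50, 75], method="linear")
        rows.append(
            {
                "label": w.label,
                "n": len(speeds),
                "min": float(speeds.min()),
                "q1": float(q1),
                "median": float(med),
                "q3": float(q3),
                "max": float(speeds.max()),
            }
        )
    return pd.DataFrame(rows)


def percent_of_baseline(max_confined: float, max_open: float) -> float:
    """Ratio-of-maxima convention: 100 * confined / open (890/330 ≈ 270%)."""
    if max_open <= 0:
        raise ValueError("baseline maximum must be > 0")
    return 100.0 * max_confined / max_open


# ---------------------------------------------------------------------------
# Maze classification
# ---------------------------------------------------------------------------


class MazeOutcome(str, Enum):
    LEFT = "LEFT"
    RIGHT = "RIGHT"
    ESCAPED = "ESCAPED"
    INCOMPLETE = "INCOMPLETE"


@dataclass
class MazeRegions:
    """Maze scoring geometry in world μm.

    ``allowed_region`` (optional) is an occupancy-style membership test for
    pixels that are legitimately inside the maze; bodies outside it (or
    touching the image border) for ``escape_frames`` consecutive frames are
    scored as escaped.
    """

    left_center: tuple[float, float]
    right_center: tuple[float, float]
    terminal_radius: float
    body_fraction_threshold: float = BODY_FRACTION_THRESHOLD
    escape_frames: int = 5
    border_margin_px: int = 2
    allowed_region: object | None = None  # has .contains_xy(x, y) -> bool array

    def __post_init__(self) -> None:
        if not (0 < self.body_fraction_threshold <= 1):
            raise ValueError("body_fraction_threshold must be in (0, 1]")
        d = math.hypot(
            self.left_center[0] - self.right_center[0],
            self.left_center[1] - self.right_center[1],
        )
        if d < 2 * self.terminal_radius:
            raise ValueError("terminal regions must be disjoint")


def maze_classify(
    masks: Iterable[tuple[float, np.ndarray]],
    maze: MazeRegions,
    camera,
) -> tuple[MazeOutcome, float | None]:
    """Classify a maze run from a series of (time, body mask) frames.

    The first frame where >= ``body_fraction_threshold`` of body pixels lie
    inside a terminal disc decides LEFT/RIGHT.  A body overlapping the frame
    border or leaving the allowed region for ``escape_frames`` consecutive
    frames decides ESCAPED.  Otherwise INCOMPLETE.  Returns (outcome,
    decision time or None).
    """
    n_frames = 0
    out_streak = 0
    for t, mask in masks:
        n_frames += 1
        rows, cols = np.nonzero(mask)
        if len(rows) == 0:
            continue
        x, y = camera.px_to_world(rows, cols)
        total = len(rows)
        for center, outcome in (
            (maze.left_center, MazeOutcome.LEFT),
            (maze.right_center, MazeOutcome.RIGHT),
        ):
            inside = (x - center[0]) ** 2 + (y - center[1]) ** 2 <= maze.terminal_radius**2
            if inside.sum() / total >= maze.body_fraction_threshold:
                return outcome, float(t)
        h, w = mask.shape
        m = maze.border_margin_px
        on_border = (
            (rows < m).any() or (rows >= h - m).any() or (cols < m).any() or (cols >= w - m).any()
        )
        outside = False
        if maze.allowed_region is not None:
            outside = (~np.asarray(maze.allowed_region.contains_xy(x, y))).mean() > 0.5
        if on_border or outside:
            out_streak += 1
            if out_streak >= maze.escape_frames:
                return MazeOutcome.ESCAPED, float(t)
        else:
            out_streak = 0
    if n_frames == 0:
        raise ValueError("empty mask series")
    return MazeOutcome.INCOMPLETE, None


# ---------------------------------------------------------------------------
# Choice test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChoiceTally:
    n_left: int
    n_right: int
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if min(self.n_left, self.n_right, self.n_excluded) < 0:
            raise ValueError("counts must be >= 0")


def choice_test(tally: ChoiceTally, confidence: float = 0.95) -> dict:
    """Exact two-sided binomial test of left/right proportion against 0.5.

    Returns proportion left, the exact p-value (sum of outcome probabilities
    <= the observed one), the Clopper-Pearson confidence interval, and the
    excluded (escaper) count, which is reported but never tested.
    """
    from scipy.stats import binomtest

    n = tally.n_left + tally.n_right
    if n < 1:
        raise ValueError("no decided worms to test")
    res = binomtest(tally.n_left, n, 0.5, alternative="two-sided")
    ci = res.proportion_ci(confidence_level=confidence, method="exact")
    return {
        "n_left": tally.n_left,
        "n_right": tally.n_right,
        "n_excluded": tally.n_excluded,
        "proportion_left": tally.n_left / n,
        "p_value": float(res.pvalue),
        "ci_low": float(ci.low),
        "ci_high": float(ci.high),
        "confidence": confidence,
    }


# ---------------------------------------------------------------------------
# Survival analysis
# ---------------------------------------------------------------------------

CENSOR_REASONS = {
    "internally_hatched_eggs",
    "desiccation",
    "extruded_gonad",
    "edge_crawling",
    "other",
}


@dataclass(frozen=True)
class SurvivalRecord:
    """One animal: day 0 is the first day of adulthood; lifespan is the event day."""

    id: str
    event_day: float
    status: str  # "died" | "censored"
    censor_reason: str | None = None
    entry_day: float = 0.0

    def __post_init__(self) -> None:
        if self.event_day < 0:
            raise ValueError("event day must be >= 0")
        if self.status not in ("died", "censored"):
            raise ValueError("status must be 'died' or 'censored'")
        if self.status == "censored" and self.censor_reason is None:
            raise ValueError("censored records need a censor_reason")
        if self.status == "died" and self.censor_reason is not None:
            raise ValueError("died records must not carry a censor_reason")


@dataclass
class KaplanMeierResult:
    days: np.ndarray  # event days (deaths)
    survival: np.ndarray  # S(day) just after each event day
    median: float | None
    n_events: int
    n_censored: int
    at_risk: np.ndarray = field(default_factory=lambda: np.array([]))

    def step_function(self) -> "callable":
        def S(t: float) -> float:
            idx = np.searchsorted(self.days, t, side="right") - 1
            return 1.0 if idx < 0 else float(self.survival[idx])

        return S


def kaplan_meier(records: Sequence[SurvivalRecord]) -> KaplanMeierResult:
    """Product-limit estimator with right censoring.

    Censored subjects remain at risk through their censor day (ties with
    deaths at the same day are handled deaths-first, the standard
    convention).  The median is the first day where S <= 0.5 and is None
    (undefined) when the curve never reaches 0.5.
    """
    if not records:
        raise ValueError("need at least one record")
    times = np.array([r.event_day for r in records], dtype=float)
    died = np.array([r.status == "died" for r in records])
    death_days = np.unique(times[died])
    s = 1.0
    surv, at_risk_list = [], []
    for d in death_days:
        at_risk = int((times >= d).sum())
        deaths = int((died & (times == d)).sum())
        s *= 1.0 - deaths / at_risk
        surv.append(s)
        at_risk_list.append(at_risk)
    surv_arr = np.asarray(surv)
    median = None
    below = np.nonzero(surv_arr <= 0.5)[0]
    if len(below):
        median = float(death_days[below[0]])
    return KaplanMeierResult(
        days=death_days,
        survival=surv_arr,
        median=median,
        n_events=int(died.sum()),
        n_censored=int((~died).sum()),
        at_risk=np.asarray(at_risk_list),
    )


def logrank_test(
    group_a: Sequence[SurvivalRecord],
    group_b: Sequence[SurvivalRecord],
) -> dict:
    """Two-group log-rank test (chi-square, 1 df)."""
    from scipy.stats import chi2

    ta = np.array([r.event_day for r in group_a], dtype=float)
    da = np.array([r.status == "died" for r in group_a])
    tb = np.array([r.event_day for r in group_b], dtype=float)
    db = np.array([r.status == "died" for r in group_b])
    event_days = np.unique(np.concatenate([ta[da], tb[db]]))
    o_minus_e = 0.0
    var = 0.0
    for d in event_days:
        n1 = int((ta >= d).sum())
        n2 = int((tb >= d).sum())
        d1 = int((da & (ta == d)).sum())
        d2 = int((db & (tb == d)).sum())
        n = n1 + n2
        dd = d1 + d2
        if n < 2 or dd == 0:
            continue
        e1 = dd * n1 / n
        o_minus_e += d1 - e1
        var += dd * (n1 / n) * (n2 / n) * (n - dd) / (n - 1) if n > 1 else 0.0
    if var == 0:
        return {"chi2": 0.0, "p_value": 1.0}
    stat = o_minus_e**2 / var
    return {"chi2": float(stat), "p_value": float(chi2.sf(stat, df=1))}
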