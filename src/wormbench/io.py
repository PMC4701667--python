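"""Shared I/O: frame stacks, trajectory/summary tables, mask export, manifests.

The canonical internal image type is 8-bit grayscale; 16-bit inputs are
rescaled with a warning and color inputs are converted by luminance.
CSV schemas are versioned via a leading ``# schema:`` comment line.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import __version__
from .patterns import MaskBitmap
from .tracker import FrameSequence, Trajectory

__all__ = [
    "RunConfig",
    "read_frames",
    "write_frames",
    "write_mask_png",
    "write_mask_pbm",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "read_survival_csv",
    "read_stroke_csv",
    "write_outputs",
    "to_gray_u8",
]

TRAJECTORY_SCHEMA = "trajectory-v1"
TRAJECTORY_COLUMNS = ["time_s", "x_um", "y_um", "valid", "speed_um_s", "accel_um_s2"]


@dataclass
class RunConfig:
    """Run-level configuration; unknown keys are rejected on load."""

    seed: int = 0
    um_per_px: float = 5.0
    frame_rate: float = 10.0
    calibration_file: str | None = None
    out_dir: str = "out"
    log_level: str = "INFO"
    tracker: dict = field(default_factory=dict)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}; known: {sorted(known)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "um_per_px": self.um_per_px,
            "frame_rate": self.frame_rate,
            "calibration_file": self.calibration_file,
            "out_dir": self.out_dir,
            "log_level": self.log_level,
            "tracker": self.tracker,
        }

    def hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def to_gray_u8(img: np.ndarray) -> np.ndarray:
    """Convert any frame to 8-bit grayscale (luminance for color, rescale for 16-bit)."""
    if img.ndim == 3:
        # Rec. 601 luminance
        img = img[..., :3] @ np.array([0.299, 0.587, 0.114])
    if img.dtype == np.uint16:
        warnings.warn("16-bit input rescaled to 8-bit")
        img = img.astype(float) / 257.0
    if img.dtype != np.uint8:
        img = np.clip(np.asarray(img, dtype=float), 0, 255)
    return img.astype(np.uint8)


def write_frames(seq: FrameSequence, out_dir: str | Path) -> Path:
    """Write a numbered PNG stack plus a frames.csv manifest (filename, time_s)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = []
    for i, (t, frame) in enumerate(seq):
        name = f"frame_{i:06d}.png"
        iio.imwrite(out / name, to_gray_u8(frame))
        names.append({"filename": name, "time_s": float(t)})
    manifest = pd.DataFrame(names)
    with open(out / "frames.csv", "w") as fh:
        fh.write(f"# schema: frames-v1 um_per_px={seq.um_per_px}\n")
        manifest.to_csv(fh, index=False)
    return out


def read_frames(
    path: str | Path,
    um_per_px: float | None = None,
    frame_rate: float | None = None,
) -> FrameSequence:
    """Read an image-stack directory (with frames.csv), a TIFF stack, or a video.

    Times come from the manifest when present, else from ``frame_rate``.
    """
    p = Path(path)
    if p.is_dir():
        manifest = p / "frames.csv"
        if manifest.exists():
            header = manifest.read_text().splitlines()[0]
            if um_per_px is None and "um_per_px=" in header:
                um_per_px = float(header.split("um_per_px=")[1].split()[0])
            df = pd.read_csv(manifest, comment="#")
            frames = [to_gray_u8(iio.imread(p / fn)) for fn in df["filename"]]
            times = df["time_s"].to_numpy()
        else:
            files = sorted(p.glob("*.png")) + sorted(p.glob("*.tif")) + sorted(p.glob("*.tiff"))
            if not files:
                raise FileNotFoundError(f"no frames.csv and no image files in {p}")
            if frame_rate is None:
                raise ValueError("no frames.csv manifest: pass frame_rate to derive times")
            frames = [to_gray_u8(iio.imread(f)) for f in files]
            times = np.arange(len(frames)) / frame_rate
    else:
        # single container: multi-page TIFF or common video format
        arr = iio.imread(p)
        if arr.ndim == 2:
            arr = arr[None]
        frames = [to_gray_u8(a) for a in arr]
        if frame_rate is None:
            raise ValueError("container input: pass frame_rate to derive times")
        times = np.arange(len(frames)) / frame_rate
    if um_per_px is None:
        raise ValueError("um_per_px is required (not recorded in the input)")
    return FrameSequence(frames=frames, times=np.asarray(times, dtype=float), um_per_px=um_per_px)


def write_mask_png(mask: MaskBitmap, path: str | Path) -> None:
    iio.imwrite(Path(path), (mask.pixels.astype(np.uint8) * 255))


def write_mask_pbm(mask: MaskBitmap, path: str | Path) -> None:
    """Plain (P1) PBM; 1 = exposed pixel."""
    rows, cols = mask.pixels.shape
    lines = [f"P1\n{cols} {rows}\n"]
    for r in mask.pixels.astype(int):
        lines.append(" ".join(map(str, r)) + "\n")
    Path(path).write_text("".join(lines))


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    df = traj.data.copy()
    for col in TRAJECTORY_COLUMNS:
        if col not in df:
            df[col] = np.nan
    with open(path, "w") as fh:
        fh.write(f"# schema: {TRAJECTORY_SCHEMA} um_per_px={traj.um_per_px}\n")
        df[TRAJECTORY_COLUMNS].to_csv(fh, index=False)


def read_trajectory_csv(path: str | Path) -> Trajectory:
    header = Path(path).read_text().splitlines()[0]
    um_per_px = float(header.split("um_per_px=")[1].split()[0]) if "um_per_px=" in header else 1.0
    df = pd.read_csv(path, comment="#")
    return Trajectory(df, um_per_px)


def read_survival_csv(path: str | Path):
    """Read survival records: columns id, day, status[, reason]."""
    from .assays import SurvivalRecord

    df = pd.read_csv(path, comment="#")
    records = []
    for _, row in df.iterrows():
        records.append(
            SurvivalRecord(
                id=str(row["id"]),
                event_day=float(row["day"]),
                status=str(row["status"]),
                censor_reason=(str(row["reason"]) if "reason" in df.columns and pd.notna(row.get("reason")) else None),
            )
        )
    return records


def read_stroke_csv(path: str | Path, **kw):
    """Read tablet pen events: columns x, y, t."""
    from .patterns import StrokeStream

    df = pd.read_csv(path, comment="#")
    events = tuple((float(r.x), float(r.y), float(r.t)) for r in df.itertuples())
    return StrokeStream(events=events, **kw)


def write_outputs(
    artifacts: dict[str, object],
    out_dir: str | Path,
    config: RunConfig | None = None,
    force: bool = False,
) -> dict:
    """Write named artifacts and a manifest recording config hash, seed and version.

    Artifact types are dispatched on value type: Trajectory, MaskBitmap,
    FrameSequence, DataFrame, dict (JSON).  Raises on filename collision
    unless ``force``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, obj in artifacts.items():
        dest = out / name
        if dest.exists() and not force:
            raise FileExistsError(f"{dest} exists; pass force=True to overwrite")
        if isinstance(obj, Trajectory):
            write_trajectory_csv(obj, dest)
        elif isinstance(obj, MaskBitmap):
            if dest.suffix == ".pbm":
                write_mask_pbm(obj, dest)
            else:
                write_mask_png(obj, dest)
        elif isinstance(obj, FrameSequence):
            write_frames(obj, dest)
        elif isinstance(obj, pd.DataFrame):
            obj.to_csv(dest, index=False)
        elif isinstance(obj, dict):
            dest.write_text(json.dumps(obj, indent=2, default=str))
        else:
            raise TypeError(f"cannot write artifact {name!r} of type {type(obj)}")
        written.append(name)
    manifest = {
        "version": __version__,
        "seed": config.seed if config else None,
        "config_hash": config.hash() if config else None,
        "files": written,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
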