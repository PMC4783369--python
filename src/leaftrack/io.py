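"""Readers, writers and run configuration.

Everything between pipeline stages is a headered UTF-8 CSV with ISO-8601
timestamps, so each stage can be re-run from its upstream files alone.
Images are read with imageio (PNG/TIFF/JPEG), converted to single-channel
luminance in [0, 1]; timestamps are parsed from filenames by a configurable
pattern (default: an ISO-8601-like substring).
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .tracking import Frame, FrameSequence, TrackPoint
from .trajectory import DisplacementSeries

__all__ = ["RunConfig", "read_image_sequence", "write_image_sequence",
           "tracking_to_frame", "tracking_to_dataframe",
           "displacement_to_dataframe", "dataframe_to_displacement"]

# default: 20140422T101500 or 2014-04-22T10:15:00 style substrings
DEFAULT_TS_PATTERN = (r"(\d{4})-?(\d{2})-?(\d{2})[T_ -]?"
                      r"(\d{2}):?(\d{2}):?(\d{2})")

IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}

# ITU-R BT.601 luminance weights for RGB -> grayscale
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class RunConfig:
    """One analysis run: paths, seeding and the analysis constants.

    Defaults follow the method's standard operating values: cc threshold
    0.5, checkerboard square 45.5 mm, hourly LER intervals, response anchor
    i = 0 degC, alpha = 0.05.
    """
    image_dir: str = "images"
    calibration_image: str = "checkerboard.png"
    environment_csv: str = "environment.csv"
    output_dir: str = "output"
    timestamp_pattern: str = DEFAULT_TS_PATTERN
    # tracking
    cc_min: float = 0.5
    template_size_px: int = 43
    search_half_extent_px: tuple[float, float] | None = None
    max_consecutive_lost: int = 50
    subpixel_method: str = "fourier"
    # calibration
    grid_dims: tuple[int, int] = (7, 10)
    square_size_mm: float = 45.5
    # analysis
    interval_hours: float = 1.0
    intercept_degc: float = 0.0
    alpha: float = 0.05
    growth_direction: str = "up"
    temperature_channel: str = "temp_c"
    # seeding: bead_id -> (x_px, y_px); genotype and reference assignment
    bead_seeds: dict[str, tuple[float, float]] = field(default_factory=dict)
    reference_beads: list[str] = field(default_factory=list)
    genotype_map: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    def save(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["bead_seeds"] = {k: list(v) for k, v in d["bead_seeds"].items()}
        if d["search_half_extent_px"] is not None:
            d["search_half_extent_px"] = list(d["search_half_extent_px"])
        d["grid_dims"] = list(d["grid_dims"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["bead_seeds"] = {k: tuple(v)
                           for k, v in (d.get("bead_seeds") or {}).items()}
        if d.get("search_half_extent_px") is not None:
            d["search_half_extent_px"] = tuple(d["search_half_extent_px"])
        d["grid_dims"] = tuple(d["grid_dims"])
        return cls(**d)


def _load_gray(path: Path) -> np.ndarray:
    raw = np.asarray(iio.imread(path))
    img = raw[..., :3] @ _LUMA if raw.ndim == 3 else raw.astype(float)
    if np.issubdtype(raw.dtype, np.integer):
        img = img / np.iinfo(raw.dtype).max
    return np.asarray(img, dtype=float)


def read_image_sequence(directory: str | Path,
                        timestamp_pattern: str = DEFAULT_TS_PATTERN,
                        ) -> FrameSequence:
    """Load a directory of grayscale time-lapse images, sorted by the
    timestamps parsed from their filenames.

    RGB inputs are converted to luminance (ITU-R BT.601 weights); integer
    images are scaled to [0, 1].  Unparseable filenames and duplicate
    timestamps raise with the offending names listed.
    """
    directory = Path(directory)
    paths = sorted(p for p in directory.iterdir()
                   if p.suffix.lower() in IMAGE_SUFFIXES)
    if not paths:
        raise FileNotFoundError(f"no images found in {directory}")
    rx = re.compile(timestamp_pattern)
    stamped: list[tuple[datetime, Path]] = []
    bad: list[str] = []
    for p in paths:
        m = rx.search(p.name)
        if not m:
            bad.append(p.name)
            continue
        ts = datetime(*(int(g) for g in m.groups()))
        stamped.append((ts, p))
    if bad:
        raise ValueError("filenames without parseable timestamps: "
                         + ", ".join(bad))
    stamped.sort(key=lambda tp: tp[0])
    seen: dict[datetime, str] = {}
    for ts, p in stamped:
        if ts in seen:
            raise ValueError(f"duplicate timestamp {ts.isoformat()} in "
                             f"{seen[ts]} and {p.name}")
        seen[ts] = p.name
    frames = [Frame(_load_gray(p), ts, i)
              for i, (ts, p) in enumerate(stamped)]
    return FrameSequence(frames)


def write_image_sequence(frames, directory: str | Path,
                         prefix: str = "frame") -> list[Path]:
    """Write frames as 16-bit grayscale PNGs named by their timestamps."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = []
    for f in frames:
        name = f"{prefix}_{f.timestamp.strftime('%Y%m%dT%H%M%S')}.png"
        arr = np.clip(f.pixels, 0.0, 1.0)
        iio.imwrite(directory / name,
                    (arr * np.iinfo(np.uint16).max).astype(np.uint16))
        out.append(directory / name)
    return out


def tracking_to_dataframe(tracks: Mapping[str, Sequence[TrackPoint]],
                          timestamps: Sequence[datetime]) -> pd.DataFrame:
    """Flatten track points into the tracking CSV layout:
    bead_id, frame_index, timestamp, x_px, y_px, cc, lost."""
    rows = []
    for bid, points in tracks.items():
        for tp in points:
            x, y = (tp.position_px if tp.position_px is not None
                    else (np.nan, np.nan))
            rows.append((bid, tp.frame_index, timestamps[tp.frame_index],
                         x, y, tp.cc, tp.lost))
    return pd.DataFrame(rows, columns=["bead_id", "frame_index", "timestamp",
                                       "x_px", "y_px", "cc", "lost"])


def tracking_to_frame(df: pd.DataFrame,
                      bead_id: str) -> tuple[np.ndarray, np.ndarray]:
    """Positions (n, 2) and timestamps of one bead from a tracking table
    (lost frames become NaN rows)."""
    sub = df[df["bead_id"] == bead_id].sort_values("frame_index")
    pos = sub[["x_px", "y_px"]].to_numpy(dtype=float)
    pos[sub["lost"].to_numpy(bool)] = np.nan
    return pos, sub["timestamp"].to_numpy()


def displacement_to_dataframe(series: Sequence[DisplacementSeries],
                              ) -> pd.DataFrame:
    """Displacement CSV layout: bead_id, timestamp, raw_mm, reference_mm,
    corrected_mm, missing.  For uncorrected series raw == corrected and
    reference is 0."""
    rows = []
    for s in series:
        ref = (s.reference_mm if s.reference_mm is not None
               else np.zeros(len(s.displacement_mm)))
        raw = s.displacement_mm + ref
        for i in range(len(s.displacement_mm)):
            rows.append((s.bead_id, s.timestamps[i], raw[i], ref[i],
                         s.displacement_mm[i], bool(s.missing[i])))
    return pd.DataFrame(rows, columns=["bead_id", "timestamp", "raw_mm",
                                       "reference_mm", "corrected_mm",
                                       "missing"])


def dataframe_to_displacement(df: pd.DataFrame, bead_id: str,
                              column: str = "corrected_mm",
                              ) -> DisplacementSeries:
    sub = df[df["bead_id"] == bead_id].sort_values("timestamp")
    disp = sub[column].to_numpy(dtype=float)
    missing = sub["missing"].to_numpy(bool) | ~np.isfinite(disp)
    disp = np.where(missing, np.nan, disp)
    return DisplacementSeries(bead_id=bead_id,
                              timestamps=sub["timestamp"].to_numpy(),
                              displacement_mm=disp, missing=missing)
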