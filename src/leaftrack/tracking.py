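"""Sub-pixel bead tracking by normalized cross-correlation.

Each white marker bead is located in every frame of a time-lapse sequence by
matching a fixed template (cut from the seeding frame) against a search
region by zero-normalized cross-correlation (ZNCC), then refining the integer
peak to sub-pixel precision.  ZNCC is invariant to affine intensity changes,
so day/night illumination shifts do not depress the correlation coefficient.

A localization with correlation below ``cc_min`` (default 0.5) is marked
*lost*: its position is excluded from all downstream displacement series and
the tracker re-attempts localization in the next frame with a widened search
region.

Coordinates: image origin top-left, x rightward, y downward, 0-based, pixel
centers at integer coordinates.  Metric conversion happens only in the
calibration module.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from typing import Iterator, Literal, Sequence

import numpy as np
from skimage.feature import match_template as _zncc_map
from skimage.registration import phase_cross_correlation

__all__ = [
    "Frame", "FrameSequence", "BeadTemplate", "SearchRegion", "TrackPoint",
    "SearchPolicy", "SubpixelOffset", "BoundaryError", "ConfigurationError",
    "extract_template", "match_template", "refine_subpixel", "track_sequence",
]

DEFAULT_CC_MIN = 0.5


class BoundaryError(ValueError):
    """A requested window falls (partly) outside the frame."""


class ConfigurationError(ValueError):
    """Search region / template combination cannot be evaluated."""


@dataclass(frozen=True)
class Frame:
    """One grayscale image of the sequence, intensities in [0, 1]."""
    pixels: np.ndarray
    timestamp: datetime
    index: int = 0

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("frame pixels must be a non-empty 2-D array")


class FrameSequence:
    """Ordered frames with strictly increasing timestamps."""

    def __init__(self, frames: Sequence[Frame]):
        frames = list(frames)
        ts = [f.timestamp for f in frames]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("timestamps must be strictly increasing")
        self.frames = [
            Frame(f.pixels, f.timestamp, i) for i, f in enumerate(frames)
        ]

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]


@dataclass(frozen=True)
class BeadTemplate:
    """Fixed appearance template for one bead, cut from the seeding frame.

    ``anchor`` is the (x, y) offset of the bead center within the patch; for
    templates cut by :func:`extract_template` it is the geometric center.
    """
    patch: np.ndarray
    anchor: tuple[float, float]
    bead_id: str
    is_reference: bool = False

    def __post_init__(self) -> None:
        h, w = self.patch.shape
        ax, ay = self.anchor
        if not (0 <= ax <= w - 1 and 0 <= ay <= h - 1):
            raise ValueError("anchor outside patch bounds")


@dataclass(frozen=True)
class SearchRegion:
    """Rectangular search window: ``center`` (x, y) px and half-extents."""
    center: tuple[float, float]
    half_extent: tuple[float, float]


@dataclass(frozen=True)
class TrackPoint:
    bead_id: str
    frame_index: int
    position_px: tuple[float, float] | None
    cc: float
    lost: bool
    abandoned: bool = False

    def __post_init__(self) -> None:
        if self.lost and self.position_px is not None:
            raise ValueError("lost point must not carry a position")


@dataclass(frozen=True)
class SubpixelOffset:
    dx: float
    dy: float
    degenerate: bool = False
    clamped: bool = False


@dataclass
class SearchPolicy:
    """How the search region follows a bead.

    Half-extents default to 1x the template width horizontally and 2x
    vertically (motion is rail-constrained and vertical).  After each
    consecutive lost frame the region is widened by ``widen_factor`` up to
    ``widen_cap`` times the base extent.
    """
    half_extent: tuple[float, float] | None = None
    widen_factor: float = 1.5
    widen_cap: float = 4.0
    max_consecutive_lost: int = 50

    def extent_for(self, template: BeadTemplate,
                   consecutive_lost: int) -> tuple[float, float]:
        if self.half_extent is None:
            w = template.patch.shape[1]
            hx, hy = 1.0 * w, 2.0 * w
        else:
            hx, hy = self.half_extent
        scale = min(self.widen_factor ** consecutive_lost, self.widen_cap)
        return hx * scale, hy * scale


def extract_template(frame: Frame, center: tuple[int, int], size: int,
                     bead_id: str = "", is_reference: bool = False,
                     ) -> BeadTemplate:
    """Cut an odd-sized square patch centered on ``center`` (x, y).

    The anchor is the geometric center of the patch, so a bead seeded at an
    integer pixel position has its center on a pixel center.
    """
    if size % 2 != 1 or size < 3:
        raise ValueError("template size must be odd and >= 3")
    cx, cy = int(round(center[0])), int(round(center[1]))
    h = size // 2
    H, W = frame.pixels.shape
    if cx - h < 0 or cy - h < 0 or cx + h >= W or cy + h >= H:
        raise BoundaryError(
            f"template window at ({cx},{cy}) size {size} exceeds frame "
            f"{W}x{H}")
    patch = frame.pixels[cy - h:cy + h + 1, cx - h:cx + h + 1].copy()
    return BeadTemplate(patch=patch, anchor=(float(h), float(h)),
                        bead_id=bead_id, is_reference=is_reference)


def _clip_region(region: SearchRegion, shape: tuple[int, int],
                 tmpl_shape: tuple[int, int]) -> tuple[int, int, int, int]:
    """Return (x0, y0, x1, y1) of the region clipped to the frame such that
    at least one full template placement fits; raise otherwise."""
    H, W = shape
    th, tw = tmpl_shape
    cx, cy = region.center
    hx, hy = region.half_extent
    x0 = max(int(np.floor(cx - hx)), 0)
    y0 = max(int(np.floor(cy - hy)), 0)
    x1 = min(int(np.ceil(cx + hx)), W - 1)
    y1 = min(int(np.ceil(cy + hy)), H - 1)
    if x1 - x0 + 1 < tw or y1 - y0 + 1 < th:
        raise ConfigurationError(
            "search region too small to evaluate a full template placement")
    return x0, y0, x1, y1


def match_template(frame: Frame, template: BeadTemplate,
                   region: SearchRegion,
                   method: Literal["fourier", "parabolic"] = "fourier",
                   upsample_factor: int = 200,
                   ) -> tuple[tuple[float, float], float]:
    """Locate ``template`` inside ``region`` of ``frame``.

    Returns the sub-pixel bead position (x, y) maximizing the ZNCC, and the
    correlation coefficient at the integer peak.  ``method`` selects the
    sub-pixel refinement: upsampled Fourier cross-correlation (default) or a
    paraboloid fit to the 3x3 ZNCC neighborhood.

    Integer-peak ties are broken toward the region center (the last valid
    position), then lexicographically by (y, x).
    """
    th, tw = template.patch.shape
    x0, y0, x1, y1 = _clip_region(region, frame.pixels.shape, (th, tw))
    crop = frame.pixels[y0:y1 + 1, x0:x1 + 1]
    cc = _zncc_map(crop, template.patch, pad_input=False)
    cc = np.nan_to_num(cc, nan=-1.0, posinf=-1.0, neginf=-1.0)

    peak = float(cc.max())
    candidates = np.argwhere(cc >= peak - 1e-12)
    if len(candidates) > 1:
        # position of the bead center for each candidate placement
        centers = candidates[:, ::-1] + np.array([x0, y0]) + template.anchor
        d2 = ((centers - np.asarray(region.center)) ** 2).sum(axis=1)
        best = d2 == d2.min()
        candidates = candidates[best]
        candidates = candidates[np.lexsort((candidates[:, 1],
                                            candidates[:, 0]))]
    py, px = (int(candidates[0][0]), int(candidates[0][1]))

    if method == "parabolic":
        if 1 <= py < cc.shape[0] - 1 and 1 <= px < cc.shape[1] - 1:
            off = refine_subpixel(cc[py - 1:py + 2, px - 1:px + 2])
            dx, dy = off.dx, off.dy
        else:
            dx = dy = 0.0
    else:
        win = crop[py:py + th, px:px + tw]
        shift, _, _ = phase_cross_correlation(
            template.patch, win, upsample_factor=upsample_factor,
            normalization=None)
        # shift is (row, col) displacement of win relative to template
        dy = float(np.clip(-shift[0], -1.0, 1.0))
        dx = float(np.clip(-shift[1], -1.0, 1.0))

    ax, ay = template.anchor
    pos = (x0 + px + dx + ax, y0 + py + dy + ay)
    return pos, peak


def refine_subpixel(cc_patch: np.ndarray) -> SubpixelOffset:
    """Paraboloid (2-D quadratic) sub-pixel peak refinement on a 3x3 patch.

    The center value must be the patch maximum.  Offsets are clamped to
    [-0.5, 0.5] per axis (flagged when clamping occurred); a flat patch
    returns (0, 0) with the degeneracy flag set.
    """
    c = np.asarray(cc_patch, dtype=float)
    if c.shape != (3, 3):
        raise ValueError("refine_subpixel expects a 3x3 patch")
    if c[1, 1] < c.max() - 1e-12:
        raise ValueError("center of the 3x3 patch is not the maximum")
    if np.ptp(c) < 1e-15:
        return SubpixelOffset(0.0, 0.0, degenerate=True)

    denom_x = 2.0 * (2.0 * c[1, 1] - c[1, 0] - c[1, 2])
    denom_y = 2.0 * (2.0 * c[1, 1] - c[0, 1] - c[2, 1])
    dx = (c[1, 2] - c[1, 0]) / denom_x if abs(denom_x) > 1e-15 else 0.0
    dy = (c[2, 1] - c[0, 1]) / denom_y if abs(denom_y) > 1e-15 else 0.0
    clamped = abs(dx) > 0.5 or abs(dy) > 0.5
    dx = float(np.clip(dx, -0.5, 0.5))
    dy = float(np.clip(dy, -0.5, 0.5))
    return SubpixelOffset(dx, dy, clamped=clamped)


def track_sequence(frames: FrameSequence | Sequence[Frame] | Iterator[Frame],
                   templates: Sequence[BeadTemplate],
                   cc_min: float = DEFAULT_CC_MIN,
                   search: SearchPolicy | None = None,
                   method: Literal["fourier", "parabolic"] = "fourier",
                   seeds: dict[str, tuple[float, float]] | None = None,
                   ) -> dict[str, list[TrackPoint]]:
    """Track every template through the sequence.

    Each bead is seeded at its template anchor position in frame 0 (or an
    explicit ``seeds`` entry).  Per frame, the search region is recentred on
    the last valid position; a match with cc below ``cc_min`` is marked lost
    and the region widens for the next frame.  A bead lost for more than
    ``search.max_consecutive_lost`` consecutive frames is flagged abandoned
    (its remaining points are emitted as lost/abandoned).
    """
    if isinstance(frames, Sequence) and not isinstance(frames, FrameSequence):
        frames = FrameSequence(frames)   # validates timestamps up front
    search = search or SearchPolicy()
    results: dict[str, list[TrackPoint]] = {t.bead_id: [] for t in templates}
    last_valid: dict[str, tuple[float, float]] = {}
    consec_lost: dict[str, int] = {t.bead_id: 0 for t in templates}
    abandoned: dict[str, bool] = {t.bead_id: False for t in templates}

    for tmpl in templates:
        if seeds is None or tmpl.bead_id not in seeds:
            raise ValueError(
                f"no seed position provided for bead {tmpl.bead_id!r}")
        last_valid[tmpl.bead_id] = seeds[tmpl.bead_id]

    prev_ts = None
    for frame in frames:
        if prev_ts is not None and frame.timestamp <= prev_ts:
            raise ValueError("timestamps must be strictly increasing")
        prev_ts = frame.timestamp
        for tmpl in templates:
            bid = tmpl.bead_id
            if abandoned[bid]:
                results[bid].append(TrackPoint(bid, frame.index, None, -1.0,
                                               lost=True, abandoned=True))
                continue
            extent = search.extent_for(tmpl, consec_lost[bid])
            region = SearchRegion(center=last_valid[bid], half_extent=extent)
            try:
                pos, cc = match_template(frame, tmpl, region, method=method)
            except ConfigurationError:
                pos, cc = None, -1.0
            if pos is not None and cc >= cc_min:
                results[bid].append(
                    TrackPoint(bid, frame.index, pos, cc, lost=False))
                last_valid[bid] = pos
                consec_lost[bid] = 0
            else:
                consec_lost[bid] += 1
                if consec_lost[bid] > search.max_consecutive_lost:
                    abandoned[bid] = True
                results[bid].append(
                    TrackPoint(bid, frame.index, None, cc, lost=True,
                               abandoned=abandoned[bid]))
    return results
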