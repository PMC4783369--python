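"""Displacement along a bead's constrained path, and drift correction.

Beads ride in vertical u-rails, so their metric positions over a run lie on
a smooth, nearly straight curve.  A second-order polynomial is fitted to all
valid positions of each bead; every position is orthogonally projected onto
that curve and displacement is measured as the signed arc length along the
curve from the first valid projection.  Projecting onto the fitted path
suppresses the transverse component of localization noise.

Rig drift (thread stretching with moisture/temperature, wind-induced panel
movement) is common to all beads; the mean displacement of the reference
beads (threads anchored to the ground, not to leaves) is subtracted from
each leaf bead's series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = ["PathModel", "DisplacementSeries", "PathFitError",
           "fit_path", "arc_displacement", "subtract_reference"]


class PathFitError(RuntimeError):
    pass


@dataclass(frozen=True)
class PathModel:
    """Quadratic bead path: transverse = c0 + c1*u + c2*u**2.

    ``axis`` names the independent coordinate u ('y' for the usual vertical
    rail motion, i.e. x as a function of y); ``u_range`` is the observed
    parameter interval.
    """
    axis: Literal["x", "y"]
    coeffs: tuple[float, float, float]       # (c0, c1, c2)
    u_range: tuple[float, float]

    def transverse(self, u: np.ndarray) -> np.ndarray:
        c0, c1, c2 = self.coeffs
        return c0 + c1 * u + c2 * u * u

    def point(self, u: np.ndarray) -> np.ndarray:
        """(x, y) point(s) on the curve at parameter u."""
        t = self.transverse(np.asarray(u, float))
        if self.axis == "x":
            return np.stack([np.asarray(u, float), t], axis=-1)
        return np.stack([t, np.asarray(u, float)], axis=-1)

    def arc_length(self, u: np.ndarray) -> np.ndarray:
        """Closed-form arc length from u = 0 along the curve.

        With slope t(u) = c1 + 2*c2*u the antiderivative of
        sqrt(1 + t^2) du is (t*sqrt(1+t^2) + asinh(t)) / (4*c2).
        """
        _, c1, c2 = self.coeffs
        u = np.asarray(u, float)
        if abs(c2) < 1e-15:
            return np.sqrt(1.0 + c1 * c1) * u
        t = c1 + 2.0 * c2 * u
        t0 = c1
        F = lambda s: (s * np.sqrt(1.0 + s * s) + np.arcsinh(s)) / (4.0 * c2)
        return F(t) - F(t0)


@dataclass
class DisplacementSeries:
    """Per-frame cumulative displacement of one bead, growth-positive mm.

    ``displacement_mm`` is NaN where ``missing`` is set (lost track points or
    failed projections); the first valid frame has displacement 0.
    """
    bead_id: str
    timestamps: np.ndarray        # datetime64[ns] or float seconds, (n,)
    displacement_mm: np.ndarray   # (n,) float, NaN where missing
    missing: np.ndarray           # (n,) bool
    reference_mm: np.ndarray | None = None   # drift that was subtracted
    is_reference: bool = False

    def __post_init__(self) -> None:
        self.displacement_mm = np.asarray(self.displacement_mm, float)
        self.missing = np.asarray(self.missing, bool)

    @property
    def valid(self) -> np.ndarray:
        return ~self.missing

    def _t_seconds(self) -> np.ndarray:
        t = np.asarray(self.timestamps)
        if np.issubdtype(t.dtype, np.datetime64):
            return t.astype("datetime64[ns]").astype("int64") / 1e9
        return t.astype(float)


def fit_path(points_mm: np.ndarray) -> PathModel:
    """Least-squares quadratic through all valid positions of one bead.

    The independent axis is the coordinate with the larger range (the motion
    axis); the transverse coordinate is modeled as a quadratic function of
    it, so the curve is single-valued over the observed range.
    """
    p = np.asarray(points_mm, float)
    p = p[np.isfinite(p).all(axis=1)]
    if len(p) < 3:
        raise PathFitError(f"need >= 3 valid points, got {len(p)}")
    rx, ry = np.ptp(p[:, 0]), np.ptp(p[:, 1])
    if max(rx, ry) <= 0:
        raise PathFitError("zero spread along both axes")
    if rx >= ry:
        axis, u, v = "x", p[:, 0], p[:, 1]
    else:
        axis, u, v = "y", p[:, 1], p[:, 0]
    # centered fit for conditioning, then expand back
    u0 = u.mean()
    c2, c1, c0 = np.polyfit(u - u0, v, 2)
    c0 = c0 - c1 * u0 + c2 * u0 * u0
    c1 = c1 - 2.0 * c2 * u0
    return PathModel(axis=axis, coeffs=(float(c0), float(c1), float(c2)),
                     u_range=(float(u.min()), float(u.max())))


def _project_u(model: PathModel, pt: np.ndarray,
               u_prev: float | None) -> float:
    """Parameter of the orthogonal projection of ``pt`` onto the curve.

    Solves the cubic stationarity condition analytically; among real roots
    the one closest to the point wins, with ties broken toward the previous
    frame's projection, and the result is clamped to the observed parameter
    range extended by 5% + 1 mm.
    """
    c0, c1, c2 = model.coeffs
    if model.axis == "x":
        u0, v0 = pt[0], pt[1]
    else:
        u0, v0 = pt[1], pt[0]
    d0 = c0 - v0
    # (u - u0) + (c2 u^2 + c1 u + d0)(2 c2 u + c1) = 0, as cubic coeffs
    a3 = 2.0 * c2 * c2
    a2 = 3.0 * c1 * c2
    a1 = c1 * c1 + 2.0 * c2 * d0 + 1.0
    a0 = c1 * d0 - u0
    if abs(a3) < 1e-18 and abs(a2) < 1e-18:
        u_star = np.array([-a0 / a1])
    else:
        roots = np.roots([a3, a2, a1, a0])
        real = roots[np.abs(roots.imag) < 1e-8 * (1 + np.abs(roots))].real
        if len(real) == 0:
            real = roots.real
        u_star = real
    cand = model.point(u_star)
    d2 = ((cand - np.array([pt[0], pt[1]])) ** 2).sum(axis=-1)
    best = np.flatnonzero(d2 <= d2.min() + 1e-12)
    if len(best) > 1 and u_prev is not None:
        best = best[np.argmin(np.abs(u_star[best] - u_prev))]
    else:
        best = best[0]
    lo, hi = model.u_range
    ext = 0.05 * (hi - lo) + 1.0
    return float(np.clip(u_star[best], lo - ext, hi + ext))


def _growth_sign(model: PathModel,
                 growth_direction: Literal["up", "down"]) -> float:
    """Sign that makes the configured growth direction (decreasing image y
    for 'up') positive along increasing arc-length parameter."""
    _, c1, c2 = model.coeffs
    if model.axis == "y":
        dy_du = 1.0
    else:
        umid = 0.5 * (model.u_range[0] + model.u_range[1])
        dy_du = c1 + 2.0 * c2 * umid
    s = -np.sign(dy_du) if dy_du != 0 else 1.0
    return float(s if growth_direction == "up" else -s)


def arc_displacement(model: PathModel, points_mm: np.ndarray,
                     timestamps: np.ndarray | None = None,
                     bead_id: str = "",
                     growth_direction: Literal["up", "down"] = "up",
                     is_reference: bool = False) -> DisplacementSeries:
    """Signed arc-length displacement of each position along the fitted path.

    Each point is orthogonally projected onto the curve; displacement is the
    arc length from the first valid point's projection, signed so that the
    configured growth direction (default: upward on the panel, decreasing y)
    is positive.  Non-finite input positions propagate as missing.
    """
    p = np.atleast_2d(np.asarray(points_mm, float))
    n = len(p)
    if timestamps is None:
        timestamps = np.arange(n, dtype=float)
    missing = ~np.isfinite(p).all(axis=1)
    u = np.full(n, np.nan)
    u_prev: float | None = None
    for i in range(n):
        if missing[i]:
            continue
        u[i] = _project_u(model, p[i], u_prev)
        u_prev = u[i]
    s = np.full(n, np.nan)
    valid = ~missing
    if valid.any():
        sign = _growth_sign(model, growth_direction)
        arc = model.arc_length(u[valid])
        s[valid] = sign * (arc - arc[0])
    return DisplacementSeries(bead_id=bead_id, timestamps=np.asarray(timestamps),
                              displacement_mm=s, missing=missing,
                              is_reference=is_reference)


def _interp_series(series: DisplacementSeries,
                   t_target_s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate a displacement series at target times (seconds).

    Outside the series' valid coverage the nearest-in-time value is used and
    the point is flagged as extrapolated."""
    t = series._t_seconds()[series.valid]
    d = series.displacement_mm[series.valid]
    if len(t) == 0:
        return np.full_like(t_target_s, np.nan, dtype=float), \
            np.ones(len(t_target_s), bool)
    vals = np.interp(t_target_s, t, d)
    extrap = (t_target_s < t[0]) | (t_target_s > t[-1])
    return vals, extrap


def subtract_reference(series: DisplacementSeries,
                       refs: Sequence[DisplacementSeries],
                       warn_fraction: float = 0.10,
                       ) -> tuple[DisplacementSeries, list[str]]:
    """Remove common rig drift: corrected = raw - mean reference drift.

    The references are linearly interpolated in time (nearest value beyond
    their coverage, flagged) and averaged; the mean is re-zeroed at the
    series' first valid frame so the corrected series still starts at 0.
    Returns the corrected series and a list of warning strings.
    """
    if len(refs) == 0:
        raise ValueError("at least one reference series is required")
    warnings: list[str] = []
    t_s = series._t_seconds()
    ref_vals = np.zeros((len(refs), len(t_s)))
    ref_extrap = np.zeros((len(refs), len(t_s)), bool)
    for i, r in enumerate(refs):
        ref_vals[i], ref_extrap[i] = _interp_series(r, t_s)
    mean_ref = ref_vals.mean(axis=0)
    uncovered = ref_extrap.all(axis=0)
    frac = uncovered[series.valid].mean() if series.valid.any() else 1.0
    if frac > warn_fraction:
        warnings.append(
            f"{series.bead_id}: {frac:.0%} of frames outside all reference "
            "coverage; nearest-in-time reference values used there")

    # re-zero the drift at the bead's first valid frame
    first = int(np.flatnonzero(series.valid)[0]) if series.valid.any() else 0
    drift = mean_ref - mean_ref[first]
    corrected = series.displacement_mm - drift
    corrected[series.missing] = np.nan
    return DisplacementSeries(
        bead_id=series.bead_id, timestamps=series.timestamps,
        displacement_mm=corrected, missing=series.missing.copy(),
        reference_mm=drift, is_reference=series.is_reference), warnings
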