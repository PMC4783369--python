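"""Low-level analytic rendering primitives.

Discs are rasterized by exact pixel coverage (area of circle-pixel
intersection), so the intensity centroid of a rendered bead equals the
requested sub-pixel position up to floating-point error.  This is what makes
rendered scenes usable as ground truth for tracking accuracy at the
hundredth-of-a-pixel level.

Pixel convention: 0-based, origin top-left, x rightward, y downward, pixel
centers at integer coordinates; pixel (i, j) covers the square
[j-0.5, j+0.5] x [i-0.5, i+0.5].
"""

from __future__ import annotations

import numpy as np

__all__ = ["disc_coverage", "draw_disc"]


def _half_disc_cumulative(x: np.ndarray, radius: float) -> np.ndarray:
    """Integral of sqrt(r^2 - t^2) dt from -r to x (x clipped to [-r, r])."""
    t = np.clip(x, -radius, radius)
    g = 0.5 * (t * np.sqrt(np.maximum(radius**2 - t**2, 0.0))
               + radius**2 * np.arcsin(np.clip(t / radius, -1.0, 1.0)))
    g_lo = -0.25 * np.pi * radius**2  # value at t = -r
    return g - g_lo


def _corner_area(x: np.ndarray, y: np.ndarray, radius: float) -> np.ndarray:
    """Area of {X <= x, Y <= y} intersected with the disc of given radius
    centered at the origin.  Closed form; vectorized over x, y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r2 = radius * radius
    s = np.sqrt(np.maximum(r2 - y * y, 0.0))
    H = _half_disc_cumulative

    # y >= 0 branch
    a_pos = (H(x, radius)
             + H(np.minimum(x, -s), radius)
             + np.maximum(H(x, radius) - H(s, radius), 0.0)
             + y * np.clip(np.minimum(x, s) + s, 0.0, None))

    # y < 0 branch (zero when y <= -radius)
    xm = np.minimum(x, s)
    a_neg = np.where(
        (y > -radius) & (xm > -s),
        y * (xm + s) + H(xm, radius) - H(-s, radius),
        0.0,
    )
    return np.where(y >= 0.0, a_pos, a_neg)


def disc_coverage(shape: tuple[int, int], center_xy: tuple[float, float],
                  radius: float) -> np.ndarray:
    """Fraction of each pixel covered by a disc, exact per-pixel area.

    Parameters
    ----------
    shape : (height, width) of the output array.
    center_xy : disc center (x, y) in pixel coordinates.
    radius : disc radius in pixels.

    Returns
    -------
    Array of ``shape`` with values in [0, 1]; only pixels inside the disc's
    bounding box are touched, the rest are 0.
    """
    h, w = shape
    cx, cy = center_xy
    out = np.zeros((h, w), dtype=float)
    x0 = max(int(np.floor(cx - radius - 1)), 0)
    x1 = min(int(np.ceil(cx + radius + 1)), w - 1)
    y0 = max(int(np.floor(cy - radius - 1)), 0)
    y1 = min(int(np.ceil(cy + radius + 1)), h - 1)
    if x1 < x0 or y1 < y0:
        return out
    xs = np.arange(x0, x1 + 1, dtype=float) - cx
    ys = np.arange(y0, y1 + 1, dtype=float) - cy
    X, Y = np.meshgrid(xs, ys)
    area = (_corner_area(X + 0.5, Y + 0.5, radius)
            - _corner_area(X - 0.5, Y + 0.5, radius)
            - _corner_area(X + 0.5, Y - 0.5, radius)
            + _corner_area(X - 0.5, Y - 0.5, radius))
    out[y0:y1 + 1, x0:x1 + 1] = area
    return out


def draw_disc(image: np.ndarray, center_xy: tuple[float, float],
              radius: float, intensity: float) -> None:
    """Additively composite a disc of the given intensity onto ``image``
    (in place), weighting by exact pixel coverage."""
    cov = disc_coverage(image.shape, center_xy, radius)
    np.add(image, intensity * cov, out=image)
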