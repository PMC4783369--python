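"""Metric rectification from a single checkerboard view.

A checkerboard of known square size (default 45.5 mm) photographed in the
plane of the beads defines the mapping between image pixels and metric panel
coordinates.  A single planar view cannot constrain full camera intrinsics,
so the model is deliberately minimal: a plane-to-plane projective transform
(homography) composed with one radial distortion coefficient about the image
center.  That captures perspective and barrel/pincushion distortion on a
planar target, which is all the bead positions need.

The closed-form direction of the model is mm -> px (project, then distort);
``apply_rectification`` inverts it numerically per point, so the round trip
is the identity to high precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from skimage.feature import corner_subpix, match_template as _zncc_map
from skimage.feature import peak_local_max

from .tracking import Frame

__all__ = [
    "CheckerboardObservation", "RectificationModel",
    "DetectionError", "RectificationFitError",
    "detect_corners", "fit_rectification", "apply_rectification",
]

DEFAULT_SQUARE_MM = 45.5


class DetectionError(RuntimeError):
    """Checkerboard not found or wrong corner count."""


class RectificationFitError(RuntimeError):
    """Degenerate corner configuration."""


@dataclass(frozen=True)
class CheckerboardObservation:
    """Detected inner corners, row-major in board coordinates.

    corners_px[r * cols + c] is the sub-pixel image position (x, y) of the
    inner corner at board row r, column c; the top-left board corner comes
    first and x increases rightward in the image.
    """
    corners_px: np.ndarray          # (N, 2) float
    grid_dims: tuple[int, int]      # (rows, cols) of inner corners
    square_size_mm: float = DEFAULT_SQUARE_MM

    def __post_init__(self) -> None:
        r, c = self.grid_dims
        if self.corners_px.shape != (r * c, 2):
            raise ValueError("corner count does not match grid_dims")

    @property
    def grid_mm(self) -> np.ndarray:
        """Ideal metric positions of the corners: (col*s, row*s), row-major,
        origin at the top-left inner corner."""
        r, c = self.grid_dims
        jj, ii = np.meshgrid(np.arange(c), np.arange(r))
        return np.column_stack([jj.ravel(), ii.ravel()]) * self.square_size_mm


def _checker_kernel(half: int) -> np.ndarray:
    """2x2 checker (saddle) template of side 2*half."""
    q = np.ones((half, half))
    return np.block([[q, -q], [-q, q]])


def detect_corners(image: Frame | np.ndarray, grid_dims: tuple[int, int],
                   square_size_mm: float = DEFAULT_SQUARE_MM,
                   approx_square_px: float | None = None,
                   ) -> CheckerboardObservation:
    """Find the rows x cols inner corners of a checkerboard at sub-pixel
    precision, ordered row-major with the top-left board corner first.

    Candidate corners are the strongest |ZNCC| peaks of a 2x2 checker
    (saddle) kernel; each is refined with :func:`skimage.feature.corner_subpix`.
    Ordering assumes the board is roughly axis-aligned in the image (rows
    separated in y), which holds for a panel-mounted camera.
    """
    img = image.pixels if isinstance(image, Frame) else np.asarray(image, float)
    rows, cols = grid_dims
    n_expected = rows * cols
    if approx_square_px is None:
        approx_square_px = min(img.shape[0] / (rows + 1),
                               img.shape[1] / (cols + 1))
    half = max(int(round(0.30 * approx_square_px)), 3)
    kernel = _checker_kernel(half)
    if kernel.shape[0] >= min(img.shape) or img.std() < 1e-12:
        raise DetectionError("image too small or featureless: found 0 corners")

    resp = np.abs(_zncc_map(img, kernel, pad_input=True))
    min_dist = max(int(0.5 * approx_square_px), 3)
    peaks = peak_local_max(resp, min_distance=min_dist, threshold_abs=0.55,
                           num_peaks=n_expected, exclude_border=half)
    if len(peaks) != n_expected:
        raise DetectionError(
            f"expected {n_expected} corners, found {len(peaks)}")

    win = max(int(round(0.35 * approx_square_px)), 4)
    refined = corner_subpix(img, peaks.astype(float), window_size=2 * win + 1)
    bad = ~np.isfinite(refined).all(axis=1)
    refined[bad] = peaks[bad]
    corners = refined[:, ::-1]  # (row, col) -> (x, y)

    # order into a row-major grid: sort by y, split into rows, sort each by x
    order = np.argsort(corners[:, 1], kind="stable")
    corners = corners[order]
    grid = corners.reshape(rows, cols, 2)
    row_y_spread = np.ptp(grid[:, :, 1], axis=1)
    row_gaps = np.diff(grid[:, :, 1].mean(axis=1))
    if len(row_gaps) and (row_y_spread.max() > 0.8 * row_gaps.min()):
        raise DetectionError(
            "could not organize corners into rows (board too rotated?)")
    for r in range(rows):
        grid[r] = grid[r][np.argsort(grid[r, :, 0], kind="stable")]
    return CheckerboardObservation(grid.reshape(-1, 2), grid_dims,
                                   square_size_mm)


def _homography_dlt(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Least-squares homography mapping src -> dst (both (N, 2)), via the
    normalized direct linear transform."""
    def normalize(p):
        m = p.mean(axis=0)
        s = np.sqrt(2.0) / max(np.mean(np.linalg.norm(p - m, axis=1)), 1e-12)
        T = np.array([[s, 0, -s * m[0]], [0, s, -s * m[1]], [0, 0, 1.0]])
        ph = np.column_stack([p, np.ones(len(p))]) @ T.T
        return ph[:, :2], T

    s_n, Ts = normalize(src)
    d_n, Td = normalize(dst)
    n = len(src)
    A = np.zeros((2 * n, 9))
    A[0::2, 0:2] = s_n
    A[0::2, 2] = 1.0
    A[0::2, 6:8] = -s_n * d_n[:, [0]]
    A[0::2, 8] = -d_n[:, 0]
    A[1::2, 3:5] = s_n
    A[1::2, 5] = 1.0
    A[1::2, 6:8] = -s_n * d_n[:, [1]]
    A[1::2, 8] = -d_n[:, 1]
    _, sv, Vt = np.linalg.svd(A)
    if sv[-2] < 1e-10 * sv[0]:
        raise RectificationFitError("degenerate (collinear) corner set")
    H = Vt[-1].reshape(3, 3)
    H = np.linalg.inv(Td) @ H @ Ts
    return H / H[2, 2]


@dataclass
class RectificationModel:
    """Invertible pixel <-> metric mapping for the panel plane.

    ``homography`` maps metric (mm) homogeneous coordinates to undistorted
    pixel coordinates; ``k1`` is the radial distortion coefficient applied
    about ``center_px`` with radii normalized by ``radius_norm_px``.
    """
    homography: np.ndarray              # (3, 3), mm -> undistorted px
    k1: float
    center_px: tuple[float, float]
    radius_norm_px: float
    rms_residual_mm: float = float("nan")
    pixel_scale_mm_per_px: float = float("nan")
    calibrated_bbox_px: tuple[float, float, float, float] | None = None

    # -- forward: mm -> px -------------------------------------------------
    def project_mm_to_px(self, points_mm: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points_mm, float))
        ph = np.column_stack([p, np.ones(len(p))]) @ self.homography.T
        px_u = ph[:, :2] / ph[:, [2]]
        return self._distort(px_u)

    def _distort(self, px_u: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center_px)
        d = px_u - c
        r2 = (d ** 2).sum(axis=1) / self.radius_norm_px ** 2
        return c + d * (1.0 + self.k1 * r2)[:, None]

    def _undistort(self, px_d: np.ndarray, iters: int = 40) -> np.ndarray:
        """Invert the radial map by fixed-point iteration (mild k1)."""
        c = np.asarray(self.center_px)
        d = px_d - c
        u = d.copy()
        for _ in range(iters):
            r2 = (u ** 2).sum(axis=1) / self.radius_norm_px ** 2
            u_new = d / (1.0 + self.k1 * r2)[:, None]
            if np.max(np.abs(u_new - u)) < 1e-12:
                u = u_new
                break
            u = u_new
        return c + u

    # -- inverse: px -> mm -------------------------------------------------
    def map_px_to_mm(self, points_px: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points_px, float))
        px_u = self._undistort(p)
        Hinv = np.linalg.inv(self.homography)
        ph = np.column_stack([px_u, np.ones(len(px_u))]) @ Hinv.T
        return ph[:, :2] / ph[:, [2]]

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "homography": self.homography.tolist(),
            "k1": self.k1,
            "center_px": list(self.center_px),
            "radius_norm_px": self.radius_norm_px,
            "rms_residual_mm": self.rms_residual_mm,
            "pixel_scale_mm_per_px": self.pixel_scale_mm_per_px,
            "calibrated_bbox_px": (list(self.calibrated_bbox_px)
                                   if self.calibrated_bbox_px else None),
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RectificationModel":
        d = json.loads(text)
        return cls(homography=np.array(d["homography"]), k1=d["k1"],
                   center_px=tuple(d["center_px"]),
                   radius_norm_px=d["radius_norm_px"],
                   rms_residual_mm=d["rms_residual_mm"],
                   pixel_scale_mm_per_px=d["pixel_scale_mm_per_px"],
                   calibrated_bbox_px=(tuple(d["calibrated_bbox_px"])
                                       if d["calibrated_bbox_px"] else None))


def fit_rectification(obs: CheckerboardObservation,
                      radial: bool = True,
                      center_px: tuple[float, float] | None = None,
                      ) -> RectificationModel:
    """Fit the projective(+radial) model to detected corners.

    The homography is initialized by the normalized DLT with k1 = 0; with
    ``radial`` the nine parameters are then refined jointly by nonlinear
    least squares on pixel reprojection residuals.  The reported RMS residual
    is measured in mm, after mapping the observed corners to the panel plane.
    """
    mm = obs.grid_mm
    px = np.asarray(obs.corners_px, float)
    if len(px) < 4:
        raise RectificationFitError("need at least 4 corners")
    if center_px is None:
        center_px = tuple(px.mean(axis=0))
    radius_norm = float(max(np.linalg.norm(px - np.asarray(center_px),
                                           axis=1).max(), 1.0))

    H0 = _homography_dlt(mm, px)
    model = RectificationModel(H0, 0.0, center_px, radius_norm)

    if radial:
        def pack(H, k):
            return np.concatenate([H.ravel()[:8], [k]])

        def unpack(theta):
            H = np.append(theta[:8], 1.0).reshape(3, 3)
            return H, theta[8]

        def resid(theta):
            H, k = unpack(theta)
            m = RectificationModel(H, k, center_px, radius_norm)
            return (m.project_mm_to_px(mm) - px).ravel()

        sol = least_squares(resid, pack(H0, 0.0), method="lm", xtol=1e-14,
                            ftol=1e-14)
        H, k = unpack(sol.x)
        model = RectificationModel(H, float(k), center_px, radius_norm)

    mapped = model.map_px_to_mm(px)
    model.rms_residual_mm = float(
        np.sqrt(np.mean(((mapped - mm) ** 2).sum(axis=1) / 2.0)))

    # local scale at the board center: mean singular value of the Jacobian
    c_mm = mm.mean(axis=0)
    eps = 1.0
    j = np.column_stack([
        (model.project_mm_to_px(c_mm + [eps, 0])
         - model.project_mm_to_px(c_mm - [eps, 0])).ravel() / (2 * eps),
        (model.project_mm_to_px(c_mm + [0, eps])
         - model.project_mm_to_px(c_mm - [0, eps])).ravel() / (2 * eps),
    ])
    model.pixel_scale_mm_per_px = float(1.0 / np.mean(np.linalg.svd(
        j, compute_uv=False)))
    model.calibrated_bbox_px = (float(px[:, 0].min()), float(px[:, 1].min()),
                                float(px[:, 0].max()), float(px[:, 1].max()))
    return model


def apply_rectification(model: RectificationModel, points_px: np.ndarray,
                        margin_frac: float = 0.10,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Map pixel positions to metric panel coordinates.

    Returns (points_mm, extrapolated) where ``extrapolated`` flags points
    outside the calibrated corner bounding box expanded by ``margin_frac``.
    """
    p = np.atleast_2d(np.asarray(points_px, float))
    mm = model.map_px_to_mm(p)
    if model.calibrated_bbox_px is not None:
        x0, y0, x1, y1 = model.calibrated_bbox_px
        mx = margin_frac * (x1 - x0)
        my = margin_frac * (y1 - y0)
        extrap = ((p[:, 0] < x0 - mx) | (p[:, 0] > x1 + mx)
                  | (p[:, 1] < y0 - my) | (p[:, 1] > y1 + my))
    else:
        extrap = np.zeros(len(p), dtype=bool)
    return mm, extrap
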