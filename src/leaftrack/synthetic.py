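"""Ground-truthed synthetic rig: temperature, growth, and rendered frames.

Emulates the field setup the analysis is designed for: white beads
(default diameter 20 mm) riding vertical u-rails on a black 100 x 60 cm
panel, imaged at 2.1 px/mm every 120 s; leaf elongation draws a bead upward
against a 20 g counterweight.  The simulator produces everything the
pipeline consumes -- image sequences with day/night illumination, sensor
noise and optional radial lens distortion, a checkerboard calibration image
with exact corner ground truth, an environment series, and per-bead true
displacements -- so the whole measurement chain can be verified with no
camera.

All randomness flows from a single seed; identical seeds give identical
bundles.  Discs are rasterized by exact analytic pixel coverage
(:mod:`leaftrack.render`), so the rendered centroid equals the requested
sub-pixel position and tracking accuracy can be judged against exact truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .render import disc_coverage
from .tracking import Frame

__all__ = [
    "RigConfig", "GrowthParams", "SceneSpec",
    "VerificationBundle", "ExperimentBundle", "PanelCapacityError",
    "simulate_temperature", "simulate_elongation",
    "net_tensile_force", "net_virtual_weight_g",
    "render_frame", "render_checkerboard",
    "generate_verification_sequence", "generate_experiment",
]

GRAVITY_M_S2 = 9.81


class PanelCapacityError(ValueError):
    pass


@dataclass(frozen=True)
class RigConfig:
    """Geometry and mechanics of one measurement panel."""
    panel_size_mm: tuple[float, float] = (1000.0, 600.0)   # (width, height)
    pixel_scale_px_per_mm: float = 2.1
    bead_diameter_mm: float = 20.0
    n_positions: int = 23
    n_reference: int = 3
    counterweight_g: float = 20.0
    bead_mass_g: float = 6.0
    roller_resistance_g: float = 1.0
    frame_interval_s: float = 120.0

    def __post_init__(self) -> None:
        if self.n_reference >= self.n_positions:
            raise ValueError("n_reference must be < n_positions")
        if self.pixel_scale_px_per_mm <= 0:
            raise ValueError("pixel scale must be positive")

    @property
    def image_shape(self) -> tuple[int, int]:
        w, h = self.panel_size_mm
        s = self.pixel_scale_px_per_mm
        return (int(round(h * s)) + 1, int(round(w * s)) + 1)

    @property
    def bead_radius_px(self) -> float:
        return 0.5 * self.bead_diameter_mm * self.pixel_scale_px_per_mm


@dataclass(frozen=True)
class GrowthParams:
    """Generative temperature-response of one genotype.

    Instantaneous LER = a * max(T - t_base, 0) + noise, truncated at zero
    (leaves do not shrink); length is the cumulative integral.
    """
    a_mm_per_h_per_degc: float
    t_base_degc: float = 0.0
    ler_noise_sd_mm_per_h: float = 0.0

    def __post_init__(self) -> None:
        if self.a_mm_per_h_per_degc < 0 or self.ler_noise_sd_mm_per_h < 0:
            raise ValueError("slope and noise sd must be non-negative")


@dataclass(frozen=True)
class SceneSpec:
    """Illumination, noise, lens distortion and common-mode drift."""
    background: float = 0.06
    bead_intensity: float = 0.85
    day_start_hour: float = 6.0
    day_end_hour: float = 19.0
    night_contrast: float = 0.5          # contrast scale factor at night
    noise_sd_day: float = 0.01
    noise_sd_night: float = 0.03
    distortion_k1: float = 0.0           # radial coefficient, image center
    drift_amp_mm: tuple[float, float] = (0.0, 0.0)
    drift_period_h: tuple[float, float] = (16.0, 6.3)
    drift_phase: tuple[float, float] = (0.0, 1.3)

    def is_day(self, when: datetime) -> bool:
        h = when.hour + when.minute / 60.0 + when.second / 3600.0
        return self.day_start_hour <= h < self.day_end_hour

    def noise_sd(self, when: datetime) -> float:
        return self.noise_sd_day if self.is_day(when) else self.noise_sd_night

    def contrast(self, when: datetime) -> float:
        return 1.0 if self.is_day(when) else self.night_contrast

    def drift_mm(self, hours: float | np.ndarray) -> float | np.ndarray:
        """Smooth low-frequency common-mode drift (thread stretch / wind
        surrogate): sum of two sinusoids, applied equally to all beads."""
        a1, a2 = self.drift_amp_mm
        p1, p2 = self.drift_period_h
        f1, f2 = self.drift_phase
        t = np.asarray(hours, float)
        d = (a1 * np.sin(2 * np.pi * t / p1 + f1)
             + a2 * np.sin(2 * np.pi * t / p2 + f2))
        return float(d) if np.isscalar(hours) else d


# ---------------------------------------------------------------------------
# environment and growth
# ---------------------------------------------------------------------------

def simulate_temperature(days: float, t_min: float, t_max: float,
                         sample_s: float = 120.0, noise_sd: float = 0.0,
                         seed: int | None = None,
                         start: datetime | None = None) -> pd.DataFrame:
    """Diurnal temperature course: a 24 h sinusoid between t_min and t_max
    (minimum at 05:00, maximum at 17:00) plus Gaussian noise.

    Returns a DataFrame with columns ``timestamp`` and ``temp_c``.
    """
    if t_max < t_min:
        raise ValueError("t_max must be >= t_min")
    if sample_s <= 0:
        raise ValueError("sample_s must be positive")
    start = start or datetime(2014, 4, 22, 0, 0, 0)
    n = int(round(days * 86400.0 / sample_s))
    t_s = np.arange(n) * sample_s
    hour = (start.hour + start.minute / 60.0) + t_s / 3600.0
    mean = 0.5 * (t_min + t_max)
    amp = 0.5 * (t_max - t_min)
    temp = mean - amp * np.cos(2 * np.pi * (hour - 5.0) / 24.0)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        temp = temp + rng.normal(0.0, noise_sd, n)
    ts = pd.to_datetime(start) + pd.to_timedelta(t_s, unit="s")
    return pd.DataFrame({"timestamp": ts, "temp_c": temp})


def simulate_elongation(env: pd.DataFrame, params: GrowthParams,
                        seed: int | None = None,
                        temp_column: str = "temp_c",
                        truncate: bool = True) -> pd.DataFrame:
    """Temperature-driven leaf length over the span of ``env``.

    Instantaneous LER (mm/h) is evaluated at each environment sample and
    held over the sample interval; length is the cumulative integral,
    starting at 0.  Returns columns timestamp, ler_mm_h, length_mm.
    """
    t_s = _to_seconds(env["timestamp"].to_numpy())
    temp = env[temp_column].to_numpy(dtype=float)
    ler = params.a_mm_per_h_per_degc * np.maximum(
        temp - params.t_base_degc, 0.0)
    if params.ler_noise_sd_mm_per_h > 0:
        rng = np.random.default_rng(seed)
        ler = ler + rng.normal(0.0, params.ler_noise_sd_mm_per_h, len(ler))
    if truncate:
        ler = np.maximum(ler, 0.0)
    dt_h = np.diff(t_s, append=t_s[-1] + (t_s[-1] - t_s[-2] if len(t_s) > 1
                                          else 3600.0)) / 3600.0
    length = np.concatenate([[0.0], np.cumsum(ler[:-1] * dt_h[:-1])])
    return pd.DataFrame({"timestamp": env["timestamp"],
                         "ler_mm_h": ler, "length_mm": length})


def net_virtual_weight_g(counterweight_g: float = 20.0,
                         bead_g: float = 6.0,
                         roller_g: float = 1.0) -> float:
    """Net mass pulling on the leaf, g (counterweight minus bead and roller
    resistance)."""
    net = counterweight_g - bead_g - roller_g
    if net < 0:
        raise ValueError("net mass is negative: counterweight too light")
    return net


def net_tensile_force(counterweight_g: float = 20.0, bead_g: float = 6.0,
                      roller_g: float = 1.0,
                      g_m_s2: float = GRAVITY_M_S2) -> float:
    """Tensile force exerted on the extending leaf, N (2 decimals)."""
    net_kg = net_virtual_weight_g(counterweight_g, bead_g, roller_g) / 1000.0
    return round(net_kg * g_m_s2, 2)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _distort_px(points_px: np.ndarray, k1: float,
                shape: tuple[int, int]) -> np.ndarray:
    """Radial distortion about the image center; radii normalized by the
    half-diagonal so k1 is the fractional shift at the image corner."""
    if k1 == 0.0:
        return np.asarray(points_px, float)
    h, w = shape
    c = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    norm2 = (c ** 2).sum()
    d = np.atleast_2d(points_px) - c
    r2 = (d ** 2).sum(axis=1) / norm2
    return c + d * (1.0 + k1 * r2)[:, None]


def _undistort_px(points_px: np.ndarray, k1: float, shape: tuple[int, int],
                  iters: int = 25) -> np.ndarray:
    if k1 == 0.0:
        return np.asarray(points_px, float)
    h, w = shape
    c = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    norm2 = (c ** 2).sum()
    d = np.atleast_2d(points_px) - c
    u = d.copy()
    for _ in range(iters):
        r2 = (u ** 2).sum(axis=1) / norm2
        u_new = d / (1.0 + k1 * r2)[:, None]
        if np.max(np.abs(u_new - u)) < 1e-10:
            u = u_new
            break
        u = u_new
    return c + u


def bead_position_px(rig: RigConfig, scene: SceneSpec,
                     points_mm: np.ndarray) -> np.ndarray:
    """True image position of bead centers: metric panel position scaled to
    pixels, then radially distorted per the scene's lens."""
    p = np.atleast_2d(np.asarray(points_mm, float)) * rig.pixel_scale_px_per_mm
    return _distort_px(p, scene.distortion_k1, rig.image_shape)


def render_frame(bead_positions_mm: np.ndarray, rig: RigConfig,
                 scene: SceneSpec, when: datetime,
                 rng: np.random.Generator | None = None,
                 index: int = 0) -> Frame:
    """Render one panel frame: anti-aliased white discs on dark background,
    day/night contrast, additive Gaussian sensor noise, optional distortion.
    """
    shape = rig.image_shape
    pos = np.atleast_2d(np.asarray(bead_positions_mm, float))
    w_mm, h_mm = rig.panel_size_mm
    for b, (x, y) in enumerate(pos):
        if not (0 <= x <= w_mm and 0 <= y <= h_mm):
            raise ValueError(f"bead {b} at ({x:.1f}, {y:.1f}) mm is off the "
                             f"panel {w_mm:.0f}x{h_mm:.0f} mm")
    img = np.full(shape, scene.background, dtype=float)
    contrast = scene.contrast(when)
    amplitude = (scene.bead_intensity - scene.background) * contrast
    for p_px in bead_position_px(rig, scene, pos):
        cov = disc_coverage(shape, (p_px[0], p_px[1]), rig.bead_radius_px)
        img += amplitude * cov
    sd = scene.noise_sd(when)
    if sd > 0 and rng is not None:
        img += rng.normal(0.0, sd, shape)
    return Frame(pixels=img.astype(np.float32), timestamp=when, index=index)


def _even_coverage(x: np.ndarray, width: float) -> np.ndarray:
    """Measure of [0, x] lying in even-indexed cells of the given width."""
    x = np.clip(x, 0.0, None)
    period = 2.0 * width
    return width * np.floor(x / period) + np.clip(x % period, 0.0, width)


def render_checkerboard(rig: RigConfig, grid_dims: tuple[int, int] = (7, 10),
                        square_size_mm: float = 45.5,
                        distortion_k1: float = 0.0,
                        light: float = 0.90, dark: float = 0.08,
                        noise_sd: float = 0.0,
                        seed: int | None = None,
                        supersample: int = 4,
                        ) -> tuple[Frame, np.ndarray, np.ndarray]:
    """Calibration image of a checkerboard centered on the panel.

    Returns (frame, corners_px, corners_mm): the rendered board, the exact
    image positions of the rows x cols inner corners after distortion
    (row-major, top-left first), and their ideal metric grid coordinates
    with origin at the top-left inner corner.

    Without distortion the board is rasterized by exact analytic pixel
    coverage; with distortion a ``supersample``^2 grid per pixel is used.
    """
    rows, cols = grid_dims
    s = square_size_mm * rig.pixel_scale_px_per_mm     # square edge, px
    board_w = (cols + 1) * s
    board_h = (rows + 1) * s
    shape = rig.image_shape
    H, W = shape
    if board_w > W or board_h > H:
        raise ValueError("checkerboard exceeds the panel")
    bx0 = (W - 1 - board_w) / 2.0
    by0 = (H - 1 - board_h) / 2.0

    # exact inner-corner ground truth
    jj, ii = np.meshgrid(np.arange(1, cols + 1), np.arange(1, rows + 1))
    corners_u = np.column_stack([bx0 + jj.ravel() * s, by0 + ii.ravel() * s])
    corners_px = _distort_px(corners_u, distortion_k1, shape)
    corners_mm = (np.column_stack([jj.ravel(), ii.ravel()]) - 1.0) \
        * square_size_mm

    if distortion_k1 == 0.0:
        xs = np.arange(W, dtype=float)
        ys = np.arange(H, dtype=float)

        def axis_cov(coord, origin, extent):
            a = np.clip(coord - 0.5 - origin, 0.0, extent)
            b = np.clip(coord + 0.5 - origin, 0.0, extent)
            inside = b - a                      # pixel length inside board
            even = _even_coverage(b, s) - _even_coverage(a, s)
            frac_even = np.where(inside > 0, even / np.maximum(inside, 1e-12),
                                 0.0)
            return inside, frac_even

        inx, ex = axis_cov(xs, bx0, board_w)
        iny, ey = axis_cov(ys, by0, board_h)
        dark_frac = ex[None, :] * ey[:, None] \
            + (1 - ex)[None, :] * (1 - ey)[:, None]
        val_in = dark * dark_frac + light * (1.0 - dark_frac)
        inside = iny[:, None] * inx[None, :]
        img = val_in * inside + light * (1.0 - inside)
    else:
        img = np.full(shape, light)
        # supersample in distorted image space, undistort, evaluate parity
        off = (np.arange(supersample) + 0.5) / supersample - 0.5
        pad = int(abs(distortion_k1)
                  * np.hypot((W - 1) / 2, (H - 1) / 2)) + 4
        y_lo = max(int(by0) - pad, 0)
        y_hi = min(int(by0 + board_h) + pad, H - 1)
        x_lo = max(int(bx0) - pad, 0)
        x_hi = min(int(bx0 + board_w) + pad, W - 1)
        xs = np.arange(x_lo, x_hi + 1, dtype=float)
        for y_chunk in np.array_split(np.arange(y_lo, y_hi + 1),
                                      max((y_hi - y_lo) // 64, 1)):
            acc = np.zeros((len(y_chunk), len(xs)))
            for oy in off:
                for ox in off:
                    X, Y = np.meshgrid(xs + ox, y_chunk + oy)
                    pts = np.column_stack([X.ravel(), Y.ravel()])
                    u = _undistort_px(pts, distortion_k1, shape)
                    ui = np.floor((u[:, 0] - bx0) / s)
                    vi = np.floor((u[:, 1] - by0) / s)
                    on_board = ((ui >= 0) & (ui <= cols)
                                & (vi >= 0) & (vi <= rows))
                    is_dark = ((ui + vi) % 2 == 0) & on_board
                    val = np.where(on_board,
                                   np.where(is_dark, dark, light), light)
                    acc += val.reshape(len(y_chunk), len(xs))
            img[y_chunk[0]:y_chunk[-1] + 1, x_lo:x_hi + 1] = \
                acc / supersample ** 2

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, shape)
    frame = Frame(pixels=img.astype(np.float32),
                  timestamp=datetime(2014, 4, 22, 12, 0, 0), index=0)
    return frame, corners_px, corners_mm


# ---------------------------------------------------------------------------
# full bundles
# ---------------------------------------------------------------------------

def _to_seconds(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t)
    if np.issubdtype(t.dtype, np.datetime64):
        return t.astype("datetime64[ns]").astype("int64") / 1e9
    return t.astype(float)


def _rail_x_mm(rig: RigConfig, n: int, margin_mm: float = 60.0) -> np.ndarray:
    w = rig.panel_size_mm[0]
    return np.linspace(margin_mm, w - margin_mm, n)


@dataclass
class VerificationBundle:
    """Calliper-style verification run: exact 1 mm steps at every position."""
    rig: RigConfig
    scene: SceneSpec
    timestamps: list[datetime]
    positions_mm: np.ndarray            # (n_frames, n_beads, 2) ground truth
    bead_ids: list[str]
    moving_ids: list[str]
    reference_ids: list[str]
    step_mm: float
    seed: int | None = None

    @property
    def n_frames(self) -> int:
        return len(self.timestamps)

    def truth(self) -> pd.DataFrame:
        rows = []
        for k, ts in enumerate(self.timestamps):
            for b, bid in enumerate(self.bead_ids):
                disp = (k * self.step_mm
                        if bid in self.moving_ids else 0.0)
                rows.append((bid, k, ts, disp))
        return pd.DataFrame(rows, columns=["bead_id", "frame_index",
                                           "timestamp",
                                           "true_displacement_mm"])

    def seeds_px(self) -> dict[str, tuple[float, float]]:
        p0 = bead_position_px(self.rig, self.scene, self.positions_mm[0])
        return {bid: (float(x), float(y))
                for bid, (x, y) in zip(self.bead_ids, p0)}

    def frames(self) -> Iterator[Frame]:
        rng = np.random.default_rng(self.seed)
        for k, ts in enumerate(self.timestamps):
            yield render_frame(self.positions_mm[k], self.rig, self.scene,
                               ts, rng=rng, index=k)


def generate_verification_sequence(rig: RigConfig | None = None,
                                   n_steps: int = 10, step_mm: float = 1.0,
                                   scene: SceneSpec | None = None,
                                   seed: int | None = 0,
                                   start: datetime | None = None,
                                   ) -> VerificationBundle:
    """Simulated analogue of the calliper accuracy check: at each of the
    rig's measurement positions a bead moves upward in exact ``step_mm``
    increments, one step per frame, while static reference beads stay put.
    """
    rig = rig or RigConfig()
    scene = scene or SceneSpec()
    start = start or datetime(2014, 4, 22, 10, 0, 0)
    w_mm, h_mm = rig.panel_size_mm
    total = n_steps * step_mm
    if total > h_mm - 160.0:
        raise ValueError("steps exceed panel height")

    mov_x = _rail_x_mm(rig, rig.n_positions)
    ref_x = _rail_x_mm(rig, rig.n_reference, margin_mm=140.0)
    y_mov = h_mm - 80.0
    y_ref = h_mm - 220.0
    moving_ids = [f"pos{i + 1:02d}" for i in range(rig.n_positions)]
    reference_ids = [f"ref{i + 1}" for i in range(rig.n_reference)]
    bead_ids = moving_ids + reference_ids

    n_frames = n_steps + 1
    pos = np.zeros((n_frames, len(bead_ids), 2))
    for k in range(n_frames):
        pos[k, :rig.n_positions, 0] = mov_x
        pos[k, :rig.n_positions, 1] = y_mov - k * step_mm
        pos[k, rig.n_positions:, 0] = ref_x
        pos[k, rig.n_positions:, 1] = y_ref
    timestamps = [start + timedelta(seconds=k * rig.frame_interval_s)
                  for k in range(n_frames)]
    return VerificationBundle(rig=rig, scene=scene, timestamps=timestamps,
                              positions_mm=pos, bead_ids=bead_ids,
                              moving_ids=moving_ids,
                              reference_ids=reference_ids,
                              step_mm=step_mm, seed=seed)


@dataclass
class ExperimentBundle:
    """Self-contained synthetic growth study: frames, environment, truth."""
    rig: RigConfig
    scene: SceneSpec
    env: pd.DataFrame                       # timestamp, temp_c
    timestamps: list[datetime]
    positions_mm: np.ndarray                # (n_frames, n_beads, 2)
    bead_ids: list[str]
    genotype_map: dict[str, str]            # leaf bead_id -> genotype
    reference_ids: list[str]
    truth_length: pd.DataFrame              # bead_id, timestamp, length_mm
    drift_mm: np.ndarray                    # (n_frames,) common-mode drift
    seed: int | None = None

    def seeds_px(self) -> dict[str, tuple[float, float]]:
        p0 = bead_position_px(self.rig, self.scene, self.positions_mm[0])
        return {bid: (float(x), float(y))
                for bid, (x, y) in zip(self.bead_ids, p0)}

    def frames(self) -> Iterator[Frame]:
        rng = np.random.default_rng(self.seed)
        for k, ts in enumerate(self.timestamps):
            yield render_frame(self.positions_mm[k], self.rig, self.scene,
                               ts, rng=rng, index=k)


def generate_experiment(rig: RigConfig | None = None,
                        genotypes: Mapping[str, GrowthParams] | None = None,
                        n_leaves: int = 7,
                        days: float = 2.0,
                        t_min: float = 2.0, t_max: float = 16.0,
                        scene: SceneSpec | None = None,
                        seed: int = 0,
                        start: datetime | None = None,
                        ) -> ExperimentBundle:
    """Generate a complete synthetic growth study on one panel.

    ``n_leaves`` replicate leaves per genotype are assigned to rails left to
    right; the rig's reference positions hold static-thread beads that see
    only the common-mode drift.  Leaf bead vertical position is
    start - true length - drift; temperatures follow a diurnal sinusoid.
    """
    rig = rig or RigConfig()
    scene = scene or SceneSpec()
    genotypes = genotypes or {"gtA": GrowthParams(0.08)}
    start = start or datetime(2014, 4, 22, 0, 0, 0)

    n_leaf_beads = n_leaves * len(genotypes)
    capacity = rig.n_positions - rig.n_reference
    if n_leaf_beads > capacity:
        import math
        need = math.ceil(n_leaf_beads / capacity)
        raise PanelCapacityError(
            f"{n_leaf_beads} leaves exceed the {capacity} leaf positions of "
            f"one panel; use {need} panels (or a rig with more positions)")

    rng = np.random.default_rng(seed)
    env = simulate_temperature(days, t_min, t_max,
                               sample_s=rig.frame_interval_s,
                               noise_sd=0.2, seed=int(rng.integers(2**31)),
                               start=start)
    n_frames = len(env)
    timestamps = [ts.to_pydatetime() for ts in pd.to_datetime(env["timestamp"])]
    hours = _to_seconds(env["timestamp"].to_numpy())
    hours = (hours - hours[0]) / 3600.0
    drift = np.asarray(scene.drift_mm(hours), float)

    leaf_ids, genotype_map, lengths = [], {}, []
    truth_rows = []
    for gname, gp in genotypes.items():
        for rep in range(n_leaves):
            bid = f"{gname}-L{rep + 1:02d}"
            leaf_ids.append(bid)
            genotype_map[bid] = gname
            growth = simulate_elongation(
                env, gp, seed=int(rng.integers(2**31)))
            lengths.append(growth["length_mm"].to_numpy())
            truth_rows.append(pd.DataFrame({
                "bead_id": bid, "timestamp": env["timestamp"],
                "length_mm": growth["length_mm"],
                "ler_mm_h": growth["ler_mm_h"]}))
    reference_ids = [f"ref{i + 1}" for i in range(rig.n_reference)]
    bead_ids = leaf_ids + reference_ids

    w_mm, h_mm = rig.panel_size_mm
    rail_x = _rail_x_mm(rig, rig.n_positions)
    # leaves on the first rails, references on the last ones (as on the
    # field panels, where three rails hold ground-anchored threads)
    x_leaf = rail_x[:n_leaf_beads]
    x_ref = rail_x[-rig.n_reference:]
    max_len = max(float(np.max(l)) for l in lengths)
    y0_leaf = h_mm - 60.0
    if max_len + 60.0 > h_mm - 60.0:
        raise ValueError(
            f"simulated growth ({max_len:.0f} mm) exceeds panel height")
    y0_ref = h_mm - 60.0

    pos = np.zeros((n_frames, len(bead_ids), 2))
    for b, bid in enumerate(leaf_ids):
        pos[:, b, 0] = x_leaf[b]
        pos[:, b, 1] = y0_leaf - lengths[b] - drift
    for r in range(rig.n_reference):
        pos[:, n_leaf_beads + r, 0] = x_ref[r]
        pos[:, n_leaf_beads + r, 1] = y0_ref - drift

    return ExperimentBundle(
        rig=rig, scene=scene, env=env, timestamps=timestamps,
        positions_mm=pos, bead_ids=bead_ids, genotype_map=genotype_map,
        reference_ids=reference_ids,
        truth_length=pd.concat(truth_rows, ignore_index=True),
        drift_mm=drift, seed=int(rng.integers(2**31)))
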