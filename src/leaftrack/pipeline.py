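"""End-to-end stage drivers: render/track/rectify/measure/analyse.

These functions chain the library modules into the standard runs a user (or
the command line) performs: calibrating from a checkerboard, tracking an
image sequence, turning tracks into drift-corrected displacement series, and
the built-in verification and growth-study analyses on synthetic scenes.
Every stage consumes and produces plain tables, so each is re-runnable from
its upstream CSVs alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import synthetic
from .calibration import (RectificationModel, apply_rectification,
                          detect_corners, fit_rectification)
from .growth_stats import (align_environment, compute_ler, fit_response,
                           genotype_anova, tukey_letters,
                           estimate_base_temperature_from_data)
from .synthetic import (ExperimentBundle, RigConfig, SceneSpec,
                        generate_verification_sequence, render_checkerboard,
                        simulate_temperature)
from .tracking import (BeadTemplate, Frame, extract_template,
                       track_sequence)
from .trajectory import (DisplacementSeries, arc_displacement, fit_path,
                         subtract_reference)

__all__ = [
    "seed_templates", "calibrate_from_image", "tracks_to_displacements",
    "run_verification", "tracking_quality", "base_temperature_replicates",
    "run_growth_study", "VerificationResult", "GrowthStudyResult",
]

def seed_templates(frame0: Frame,
                   seeds_px: Mapping[str, tuple[float, float]],
                   size: int = 43,
                   reference_ids: Sequence[str] = (),
                   ) -> list[BeadTemplate]:
    """Cut one fixed template per bead from the seeding frame."""
    return [
        extract_template(frame0, (round(x), round(y)), size, bead_id=bid,
                         is_reference=bid in set(reference_ids))
        for bid, (x, y) in seeds_px.items()
    ]


def calibrate_from_image(image: Frame, grid_dims: tuple[int, int],
                         square_size_mm: float = 45.5,
                         radial: bool = True) -> RectificationModel:
    """Detect checkerboard corners and fit the rectification model."""
    obs = detect_corners(image, grid_dims, square_size_mm)
    return fit_rectification(obs, radial=radial)


def tracks_to_displacements(tracking_df: pd.DataFrame,
                            model: RectificationModel,
                            reference_ids: Sequence[str],
                            growth_direction: str = "up",
                            ) -> tuple[dict[str, DisplacementSeries],
                                       list[str]]:
    """Rectify tracked positions and measure drift-corrected displacement.

    Returns per-bead corrected series (references keep their raw series) and
    accumulated warnings.  Static beads whose positions have too little
    spread for a path fit fall back to Euclidean frame-to-frame displacement
    along the straight line through their mean position (vertical rail).
    """
    from .io import tracking_to_frame

    warnings: list[str] = []
    raw: dict[str, DisplacementSeries] = {}
    for bid in tracking_df["bead_id"].unique():
        pos_px, ts = tracking_to_frame(tracking_df, bid)
        mm = np.full_like(pos_px, np.nan)
        ok = np.isfinite(pos_px).all(axis=1)
        if ok.any():
            mm[ok], _ = apply_rectification(model, pos_px[ok])
        is_ref = bid in set(reference_ids)
        try:
            path = fit_path(mm)
            series = arc_displacement(path, mm, timestamps=ts, bead_id=bid,
                                      growth_direction=growth_direction,
                                      is_reference=is_ref)
        except Exception:
            series = _euclidean_displacement(mm, ts, bid, growth_direction,
                                             is_ref)
        raw[bid] = series

    refs = [raw[b] for b in reference_ids if b in raw]
    out: dict[str, DisplacementSeries] = {}
    for bid, series in raw.items():
        if series.is_reference or not refs:
            out[bid] = series
            continue
        corrected, w = subtract_reference(series, refs)
        warnings.extend(w)
        out[bid] = corrected
    return out, warnings


def _euclidean_displacement(points_mm: np.ndarray, timestamps, bead_id: str,
                            growth_direction: str,
                            is_reference: bool) -> DisplacementSeries:
    """Cumulative signed displacement for (near-)static beads, where a
    quadratic path is degenerate: vertical motion component accumulates
    with up positive, so noise does not rectify into spurious growth."""
    p = np.atleast_2d(np.asarray(points_mm, float))
    missing = ~np.isfinite(p).all(axis=1)
    disp = np.full(len(p), np.nan)
    sign = -1.0 if growth_direction == "up" else 1.0
    valid_idx = np.flatnonzero(~missing)
    if len(valid_idx):
        pv = p[valid_idx]
        steps = sign * np.diff(pv[:, 1])
        disp[valid_idx] = np.concatenate([[0.0], np.cumsum(steps)])
    return DisplacementSeries(bead_id=bead_id,
                              timestamps=np.asarray(timestamps),
                              displacement_mm=disp, missing=missing,
                              is_reference=is_reference)


# ---------------------------------------------------------------------------
# verification analogue of the calliper accuracy experiment
# ---------------------------------------------------------------------------

@dataclass
class VerificationResult:
    """Accuracy of the simulated stepwise-displacement experiment."""
    r_squared_per_position: dict[str, float]
    mean_abs_step_error_mm: float
    static_mean_abs_displacement_mm: float
    mean_cc: float
    n_steps_measured: int
    n_static_steps: int
    warnings: list[str]

    @property
    def min_r_squared(self) -> float:
        return min(self.r_squared_per_position.values())


def run_verification(rig: RigConfig | None = None,
                     scene: SceneSpec | None = None,
                     n_steps: int = 10, step_mm: float = 1.0,
                     seed: int = 0,
                     template_size: int = 43) -> VerificationResult:
    """Render the stepwise verification scene, run the full measurement
    chain, and score it against the exact ground truth.

    Per moving position: linear R^2 of measured vs true displacement and the
    absolute errors of the individual steps (|measured step - step_mm|).
    Static reference beads are scored by their mean absolute frame-to-frame
    apparent displacement (the resolution limit of the method).
    """
    rig = rig or RigConfig()
    scene = scene or SceneSpec()
    bundle = generate_verification_sequence(rig, n_steps=n_steps,
                                            step_mm=step_mm, scene=scene,
                                            seed=seed)
    grid = _grid_for_rig(rig)
    cal_frame, _, _ = render_checkerboard(
        rig, grid, distortion_k1=scene.distortion_k1,
        noise_sd=min(scene.noise_sd_day, 0.005), seed=seed)
    model = calibrate_from_image(cal_frame, grid)

    frames = bundle.frames()
    first = next(frames)
    seeds = bundle.seeds_px()
    templates = seed_templates(first, seeds, template_size,
                               bundle.reference_ids)

    def chain():
        yield first
        yield from frames

    tracks = track_sequence(chain(), templates, seeds=seeds)
    from .io import tracking_to_dataframe, tracking_to_frame
    tdf = tracking_to_dataframe(tracks, bundle.timestamps)
    ccs = tdf.loc[~tdf["lost"], "cc"]

    truth = bundle.truth()
    r2 = {}
    step_errors = []
    for bid in bundle.moving_ids:
        pos_px, ts = tracking_to_frame(tdf, bid)
        mm, _ = apply_rectification(model, pos_px)
        path = fit_path(mm)
        series = arc_displacement(path, mm, timestamps=ts, bead_id=bid)
        true_d = truth.loc[truth["bead_id"] == bid,
                           "true_displacement_mm"].to_numpy()
        meas = series.displacement_mm
        res = stats.linregress(true_d, meas)
        r2[bid] = float(res.rvalue ** 2)
        step_errors.extend(np.abs(np.diff(meas) - step_mm))

    static_steps = []
    for bid in bundle.reference_ids:
        pos_px, _ = tracking_to_frame(tdf, bid)
        mm, _ = apply_rectification(model, pos_px)
        ok = np.isfinite(mm).all(axis=1)
        d = np.linalg.norm(np.diff(mm[ok], axis=0), axis=1)
        static_steps.extend(d)

    return VerificationResult(
        r_squared_per_position=r2,
        mean_abs_step_error_mm=float(np.mean(step_errors)),
        static_mean_abs_displacement_mm=float(np.mean(static_steps)),
        mean_cc=float(ccs.mean()),
        n_steps_measured=len(step_errors),
        n_static_steps=len(static_steps),
        warnings=[])


# ---------------------------------------------------------------------------
# tracking-quality probe (day / night regimes)
# ---------------------------------------------------------------------------

def tracking_quality(regime: str = "day", n_frames: int = 200,
                     seed: int = 0, n_beads: int = 5,
                     rig: RigConfig | None = None,
                     scene: SceneSpec | None = None) -> tuple[float, int]:
    """Mean correlation coefficient over a rendered sequence with slow bead
    motion.  Returns (mean cc over non-lost points, number of points).

    The day regime uses full contrast and low noise; the night regime uses
    the scene's night contrast and elevated noise (NIR illumination look).
    """
    rig = rig or RigConfig(panel_size_mm=(400.0, 300.0), n_positions=5,
                           n_reference=1)
    scene = scene or SceneSpec()
    from datetime import datetime, timedelta
    start = (datetime(2014, 4, 22, 10, 0, 0) if regime == "day"
             else datetime(2014, 4, 22, 22, 0, 0))

    xs = np.linspace(60.0, rig.panel_size_mm[0] - 60.0, n_beads)
    y0 = rig.panel_size_mm[1] - 60.0
    speed_mm_per_frame = 0.05          # slow continuous upward motion
    timestamps = [start + timedelta(seconds=k * rig.frame_interval_s)
                  for k in range(n_frames)]
    # freeze the regime: all frames within day or night hours
    assert all(scene.is_day(t) == (regime == "day") for t in timestamps[:1])

    rng = np.random.default_rng(seed)

    def frames():
        for k, ts in enumerate(timestamps):
            pos = np.column_stack([
                xs, np.full(n_beads, y0 - k * speed_mm_per_frame)])
            yield synthetic.render_frame(pos, rig, scene, ts, rng=rng,
                                         index=k)

    gen = frames()
    first = next(gen)
    seeds = {f"b{i}": (float(x * rig.pixel_scale_px_per_mm),
                       float(y0 * rig.pixel_scale_px_per_mm))
             for i, x in enumerate(xs)}
    templates = seed_templates(first, seeds, 43)

    def chain():
        yield first
        yield from gen

    tracks = track_sequence(chain(), templates, seeds=seeds)
    ccs = [tp.cc for pts in tracks.values() for tp in pts if not tp.lost]
    return float(np.mean(ccs)), len(ccs)


# ---------------------------------------------------------------------------
# base-temperature recovery replicates
# ---------------------------------------------------------------------------

def base_temperature_replicates(n_runs: int = 100, seed: int = 0,
                                days: float = 7.0,
                                t_min: float = -2.0, t_max: float = 20.0,
                                a_true: float = 0.08,
                                t_base: float = 0.0,
                                noise_sd: float = 0.05) -> np.ndarray:
    """Estimated x-intercepts from repeated simulated hourly LER data.

    Each replicate simulates a diurnal temperature course, generates hourly
    LER = a * max(T - t_base, 0) + noise, fits a free-intercept regression
    and records the x-intercept (base-temperature estimate).
    """
    rng = np.random.default_rng(seed)
    out = np.empty(n_runs)
    for r in range(n_runs):
        env = simulate_temperature(days, t_min, t_max, sample_s=3600.0,
                                   noise_sd=0.0)
        temp = env["temp_c"].to_numpy()
        ler = a_true * np.maximum(temp - t_base, 0.0) \
            + rng.normal(0.0, noise_sd, len(temp))
        out[r], _ = estimate_base_temperature_from_data(ler, temp)
    return out


# ---------------------------------------------------------------------------
# full growth study (render -> track -> rectify -> arc -> LER -> stats)
# ---------------------------------------------------------------------------

@dataclass
class GrowthStudyResult:
    slopes_per_leaf: pd.DataFrame     # bead_id, genotype, a, r_squared, n
    slopes_by_genotype: dict[str, np.ndarray]
    f_statistic: float
    p_value: float
    letters: dict[str, str]
    ler_table: pd.DataFrame
    warnings: list[str]


def run_growth_study(bundle: ExperimentBundle,
                     interval_hours: float = 1.0,
                     intercept_degc: float = 0.0,
                     alpha: float = 0.05,
                     template_size: int = 43,
                     model: RectificationModel | None = None,
                     ) -> GrowthStudyResult:
    """Run the complete measurement chain on a synthetic growth study and
    compare genotype temperature sensitivities."""
    from .io import tracking_to_dataframe

    rig, scene = bundle.rig, bundle.scene
    if model is None:
        grid = _grid_for_rig(rig)
        cal_frame, _, _ = render_checkerboard(
            rig, grid, distortion_k1=scene.distortion_k1,
            noise_sd=0.005, seed=bundle.seed)
        model = calibrate_from_image(cal_frame, grid)

    gen = bundle.frames()
    first = next(gen)
    seeds = bundle.seeds_px()
    templates = seed_templates(first, seeds, template_size,
                               bundle.reference_ids)

    def chain():
        yield first
        yield from gen

    tracks = track_sequence(chain(), templates, seeds=seeds)
    tdf = tracking_to_dataframe(tracks, bundle.timestamps)
    series, warnings = tracks_to_displacements(tdf, model,
                                               bundle.reference_ids)

    slopes_rows = []
    ler_tables = []
    for bid, genotype in bundle.genotype_map.items():
        ler = compute_ler(series[bid], interval_hours=interval_hours)
        if len(ler.table) == 0:
            warnings.append(f"{bid}: no LER intervals")
            continue
        aligned = align_environment(bundle.env, ler.table)
        temp = aligned["temp_c"].to_numpy()
        keep = ler.valid & np.isfinite(temp)
        fit = fit_response(ler.ler[keep], temp[keep], mode="fixed",
                           i=intercept_degc)
        slopes_rows.append((bid, genotype, fit.a, fit.r_squared, fit.n))
        t = ler.table.copy()
        t.insert(0, "bead_id", bid)
        t["temp_c"] = temp
        ler_tables.append(t)

    slopes = pd.DataFrame(slopes_rows, columns=["bead_id", "genotype", "a",
                                                "r_squared", "n"])
    groups = {g: sub["a"].to_numpy()
              for g, sub in slopes.groupby("genotype")}
    f_stat, p_val = genotype_anova(groups)
    comparison = tukey_letters(groups, alpha=alpha)
    return GrowthStudyResult(
        slopes_per_leaf=slopes, slopes_by_genotype=groups,
        f_statistic=f_stat, p_value=p_val, letters=comparison.letters,
        ler_table=pd.concat(ler_tables, ignore_index=True),
        warnings=warnings)


def _grid_for_rig(rig: RigConfig,
                  square_size_mm: float = 45.5) -> tuple[int, int]:
    """Largest inner-corner grid whose board fits the rig's panel with a
    margin."""
    w, h = rig.panel_size_mm
    cols = max(int(w / square_size_mm) - 2, 3)
    rows = max(int(h / square_size_mm) - 2, 3)
    return rows, cols
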