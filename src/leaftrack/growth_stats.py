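"""Leaf elongation rates and their temperature response.

Leaf elongation rate (LER, mm h^-1) is the displacement increment per
clock-aligned interval (default 1 h).  Above the base temperature T_b the
response of LER to temperature is modeled as linear,

    LER = a * (T - i),

where ``a`` (mm h^-1 degC^-1) is the genotype's temperature sensitivity and
``i`` the temperature-axis anchor.  The anchor is fixed at i = 0 degC by
default, since the measured cereal species extrapolate to zero growth within
a fraction of a degree of 0 degC; a free-intercept fit estimates the base
temperature as the x-intercept instead.  The thermal-time correction
``LER - a*T`` removes the linear temperature effect from observed rates.

Genotype comparison: per-leaf slopes feed a one-way ANOVA and Tukey-Kramer
HSD post-hoc tests summarized as a compact letter display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .trajectory import DisplacementSeries

__all__ = [
    "LERSeries", "ResponseFit", "GenotypeComparison", "TemperatureResponse",
    "compute_ler", "align_environment", "fit_response",
    "thermal_time_residuals", "estimate_base_temperature",
    "genotype_anova", "tukey_letters",
]


# ---------------------------------------------------------------------------
# LER computation
# ---------------------------------------------------------------------------

@dataclass
class LERSeries:
    """Hourly (or configured-interval) elongation rates for one bead."""
    bead_id: str
    table: pd.DataFrame   # columns: start, end, ler_mm_h, coverage, missing

    @property
    def ler(self) -> np.ndarray:
        return self.table["ler_mm_h"].to_numpy()

    @property
    def valid(self) -> np.ndarray:
        return ~self.table["missing"].to_numpy()


def _to_seconds(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t)
    if np.issubdtype(t.dtype, np.datetime64):
        return t.astype("datetime64[ns]").astype("int64") / 1e9
    return t.astype(float)


def compute_ler(series: DisplacementSeries,
                interval_hours: float = 1.0,
                min_coverage: float = 0.5) -> LERSeries:
    """Elongation rate per clock-aligned interval, Delta L / Delta t.

    Interval boundaries start at the first valid frame's timestamp floored
    to a whole interval; boundary displacements are linearly interpolated
    between the nearest valid frames.  Intervals with less than
    ``min_coverage`` of the expected frames present are flagged missing.
    """
    dt_s = interval_hours * 3600.0
    t = _to_seconds(series.timestamps)
    valid = series.valid
    cols = ["start", "end", "ler_mm_h", "coverage", "missing"]
    if valid.sum() < 2:
        return LERSeries(series.bead_id, pd.DataFrame(columns=cols))
    tv, dv = t[valid], series.displacement_mm[valid]
    t0 = np.floor(tv[0] / dt_s) * dt_s
    n_int = int(np.ceil((tv[-1] - t0) / dt_s))
    if n_int < 1:
        return LERSeries(series.bead_id, pd.DataFrame(columns=cols))
    edges = t0 + dt_s * np.arange(n_int + 1)
    # boundary displacement defined only inside the valid time span
    d_edge = np.interp(edges, tv, dv, left=np.nan, right=np.nan)
    d_edge[(edges < tv[0]) | (edges > tv[-1])] = np.nan

    frame_dt = np.median(np.diff(t)) if len(t) > 1 else dt_s
    expected = max(dt_s / frame_dt, 1.0)
    rows = []
    is_dt = np.issubdtype(np.asarray(series.timestamps).dtype, np.datetime64)
    for k in range(n_int):
        a, b = edges[k], edges[k + 1]
        n_valid = int(((tv >= a) & (tv < b)).sum())
        coverage = min(n_valid / expected, 1.0)
        ler = (d_edge[k + 1] - d_edge[k]) / interval_hours
        missing = (not np.isfinite(ler)) or coverage < min_coverage
        start = (np.datetime64(int(a * 1e9), "ns") if is_dt else a)
        end = (np.datetime64(int(b * 1e9), "ns") if is_dt else b)
        rows.append((start, end, ler if np.isfinite(ler) else np.nan,
                     coverage, missing))
    return LERSeries(series.bead_id, pd.DataFrame(rows, columns=cols))


def align_environment(env: pd.DataFrame, intervals: pd.DataFrame,
                      time_column: str = "timestamp") -> pd.DataFrame:
    """Average environment channels over the LER intervals.

    ``env`` holds a timestamp column plus numeric channels; ``intervals``
    provides 'start'/'end'.  Channels are the arithmetic mean of in-interval
    samples; intervals without samples come out NaN.
    """
    t = _to_seconds(env[time_column].to_numpy())
    if len(intervals) == 0:
        raise ValueError("no intervals to align to")
    starts = _to_seconds(intervals["start"].to_numpy())
    ends = _to_seconds(intervals["end"].to_numpy())
    if t.min() >= ends.max() or t.max() <= starts.min():
        raise ValueError("environment series does not overlap the intervals")
    channels = [c for c in env.columns if c != time_column]
    out = {c: np.full(len(starts), np.nan) for c in channels}
    order = np.argsort(t)
    t_sorted = t[order]
    for c in channels:
        v = env[c].to_numpy(dtype=float)[order]
        csum = np.concatenate([[0.0], np.nancumsum(v)])
        cnt = np.concatenate([[0], np.cumsum(np.isfinite(v))])
        # boundary samples count toward both adjacent intervals, keeping the
        # interval mean symmetric about the interval midpoint
        i0 = np.searchsorted(t_sorted, starts, side="left")
        i1 = np.searchsorted(t_sorted, ends, side="right")
        n = cnt[i1] - cnt[i0]
        with np.errstate(invalid="ignore", divide="ignore"):
            out[c] = np.where(n > 0, (csum[i1] - csum[i0]) / np.maximum(n, 1),
                              np.nan)
    res = intervals[["start", "end"]].copy()
    for c in channels:
        res[c] = out[c]
    return res


# ---------------------------------------------------------------------------
# Temperature-response model (statsmodels-style model / results pair)
# ---------------------------------------------------------------------------

@dataclass
class ResponseFit:
    """Results of a temperature-response fit.

    mode 'fixed': LER = a * (T - i) with the anchor i held fixed (default
    0 degC); mode 'free': ordinary least squares LER = intercept + a * T,
    with the x-intercept (base-temperature estimate) -intercept/a.
    """
    mode: Literal["fixed", "free"]
    a: float
    i: float                      # temperature-axis anchor (fixed mode)
    r_squared: float
    n: int
    se_a: float
    intercept: float = 0.0        # LER at T = 0 (free mode)
    se_intercept: float = float("nan")
    cov_a_intercept: float = float("nan")

    @property
    def x_intercept(self) -> float:
        if self.mode == "fixed":
            return self.i
        return -self.intercept / self.a

    def summary(self) -> str:
        lines = [
            "Temperature response of leaf elongation rate",
            "-" * 46,
            f"mode:              {self.mode}",
            f"n observations:    {self.n}",
            f"slope a:           {self.a:.4f} mm/h/degC (SE {self.se_a:.4f})",
        ]
        if self.mode == "fixed":
            lines.append(f"anchor i:          {self.i:.2f} degC (fixed)")
        else:
            lines.append(f"intercept:         {self.intercept:.4f} mm/h "
                         f"(SE {self.se_intercept:.4f})")
            tb, se = estimate_base_temperature(self)
            lines.append(f"x-intercept (T_b): {tb:.3f} degC (SE {se:.3f})")
        lines.append(f"R^2:               {self.r_squared:.4f}")
        return "\n".join(lines)


class TemperatureResponse:
    """Linear LER-temperature model, fitted by least squares.

    Parameters
    ----------
    ler, temp : paired observations (missing values dropped pairwise).
    mode : 'fixed' anchors the line at (i, 0); 'free' fits both parameters.
    i : temperature-axis anchor for fixed mode, degC.
    """

    def __init__(self, ler: Sequence[float], temp: Sequence[float],
                 mode: Literal["fixed", "free"] = "fixed", i: float = 0.0):
        ler = np.asarray(ler, float)
        temp = np.asarray(temp, float)
        if ler.shape != temp.shape:
            raise ValueError("ler and temp must have the same length")
        keep = np.isfinite(ler) & np.isfinite(temp)
        self.ler, self.temp = ler[keep], temp[keep]
        self.mode = mode
        self.i = float(i)
        n_min = 1 if mode == "fixed" else 2
        if len(self.ler) < n_min:
            raise ValueError(f"need >= {n_min} paired observations")

    def fit(self) -> ResponseFit:
        if self.mode == "fixed":
            x = self.temp - self.i
            res = sm.OLS(self.ler, x[:, None]).fit()
            return ResponseFit(mode="fixed", a=float(res.params[0]), i=self.i,
                               r_squared=float(res.rsquared),
                               n=len(self.ler), se_a=float(res.bse[0]))
        if np.ptp(self.temp) <= 0:
            raise ValueError("zero temperature variance in free mode")
        X = sm.add_constant(self.temp)
        res = sm.OLS(self.ler, X).fit()
        cov = res.cov_params()
        return ResponseFit(mode="free", a=float(res.params[1]), i=np.nan,
                           r_squared=float(res.rsquared), n=len(self.ler),
                           se_a=float(res.bse[1]),
                           intercept=float(res.params[0]),
                           se_intercept=float(res.bse[0]),
                           cov_a_intercept=float(np.asarray(cov)[0, 1]))


def fit_response(ler: Sequence[float], temp: Sequence[float],
                 mode: Literal["fixed", "free"] = "fixed",
                 i: float = 0.0) -> ResponseFit:
    """Convenience wrapper: fit the linear LER-temperature response."""
    return TemperatureResponse(ler, temp, mode=mode, i=i).fit()


def thermal_time_residuals(ler: Sequence[float], temp: Sequence[float],
                           a: float) -> np.ndarray:
    """Thermal-time-corrected rates LER - a*T (NaNs propagate)."""
    return np.asarray(ler, float) - a * np.asarray(temp, float)


def estimate_base_temperature(fit: ResponseFit) -> tuple[float, float]:
    """Base temperature T_b = -intercept/slope from a free-mode fit, with a
    delta-method standard error."""
    if fit.mode != "free":
        raise ValueError("base temperature requires a free-intercept fit")
    if abs(fit.a) < 1e-12:
        raise ZeroDivisionError("slope is ~0; x-intercept undefined")
    tb = -fit.intercept / fit.a
    var = (fit.se_intercept ** 2 / fit.a ** 2
           + fit.intercept ** 2 * fit.se_a ** 2 / fit.a ** 4
           - 2.0 * fit.intercept * fit.cov_a_intercept / fit.a ** 3)
    return float(tb), float(np.sqrt(max(var, 0.0)))


def estimate_base_temperature_from_data(
        ler: Sequence[float], temp: Sequence[float],
        max_iter: int = 25, tol: float = 1e-3,
        min_points: int = 10) -> tuple[float, float]:
    """Base temperature as the x-intercept of a free linear fit restricted
    to the supra-base range, found self-consistently.

    Growth is zero below the base temperature, so observations on that flat
    arm bias a straight-line fit through the whole range.  Starting from a
    fit on all data, temperatures below the current x-intercept estimate are
    excluded and the line refitted until the estimate stabilizes; the true
    base temperature is a fixed point of this map.  Returns (T_b, SE) from
    the final fit.
    """
    ler = np.asarray(ler, float)
    temp = np.asarray(temp, float)
    thr = -np.inf
    tb = np.nan
    for _ in range(max_iter):
        keep = temp > thr
        if keep.sum() < min_points:
            break
        fit = TemperatureResponse(ler[keep], temp[keep], mode="free").fit()
        tb_new, se = estimate_base_temperature(fit)
        if np.isfinite(tb) and abs(tb_new - tb) < tol:
            tb = tb_new
            break
        tb = tb_new
        thr = tb
    return float(tb), float(se)


# ---------------------------------------------------------------------------
# Genotype comparison: one-way ANOVA + Tukey-Kramer HSD letters
# ---------------------------------------------------------------------------

@dataclass
class GenotypeComparison:
    """One-way ANOVA over per-leaf slopes plus Tukey-Kramer letter groups."""
    groups: dict[str, np.ndarray]
    f_statistic: float
    p_value: float
    alpha: float
    letters: dict[str, str]
    significant: pd.DataFrame = field(repr=False)   # boolean pair matrix
    ms_within: float = float("nan")
    df_within: int = 0

    def summary(self) -> str:
        lines = [
            "Genotype comparison of temperature sensitivity (slope a)",
            "-" * 58,
            f"one-way ANOVA: F = {self.f_statistic:.3f}, "
            f"p = {self.p_value:.4g}",
            f"Tukey-Kramer HSD at alpha = {self.alpha:g}:",
        ]
        for g in sorted(self.groups,
                        key=lambda g: -np.mean(self.groups[g])):
            v = self.groups[g]
            lines.append(f"  {g:<12s} mean a = {np.mean(v):.4f}  n = "
                         f"{len(v):<3d} group {self.letters[g]}")
        return "\n".join(lines)


def genotype_anova(groups: Mapping[str, Sequence[float]],
                   ) -> tuple[float, float]:
    """One-way fixed-effects ANOVA over the per-genotype slope samples.

    Returns (F, p).  If all observations are identical (zero residual
    variance, equal means) the degenerate case is reported as F = 0, p = 1.
    """
    arrays = {k: np.asarray(v, float) for k, v in groups.items()}
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    for name, v in arrays.items():
        if len(v) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
    allv = np.concatenate(list(arrays.values()))
    grand = allv.mean()
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in arrays.values())
    ss_between = sum(len(v) * (v.mean() - grand) ** 2
                     for v in arrays.values())
    if ss_within < 1e-300:
        if ss_between < 1e-300:
            return 0.0, 1.0
        return float("inf"), 0.0
    df_b = len(arrays) - 1
    df_w = len(allv) - len(arrays)
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return float(f), p


def _cld_insert_absorb(names: list[str],
                       sig: np.ndarray) -> list[frozenset[str]]:
    """Compact letter display via the insert-and-absorb algorithm.

    Starts from one column holding every treatment; each significant pair
    splits the columns containing both; subset columns are absorbed.  Groups
    sharing a letter are exactly those never separated by a rejection.
    """
    columns: list[frozenset[str]] = [frozenset(names)]
    k = len(names)
    for a in range(k):
        for b in range(a + 1, k):
            if not sig[a, b]:
                continue
            na, nb = names[a], names[b]
            new_cols: list[frozenset[str]] = []
            for col in columns:
                if na in col and nb in col:
                    new_cols.extend([col - {na}, col - {nb}])
                else:
                    new_cols.append(col)
            # absorb: drop duplicates and strict subsets
            uniq = sorted(set(new_cols), key=len, reverse=True)
            columns = [c for idx, c in enumerate(uniq)
                       if c and not any(c < other for other in uniq)]
    return columns  # letter assignment done by caller (needs group means)


def tukey_letters(groups: Mapping[str, Sequence[float]],
                  alpha: float = 0.05) -> GenotypeComparison:
    """All-pairs Tukey-Kramer HSD with a compact letter display.

    Pair (i, j) differs significantly when |mean_i - mean_j| exceeds
    q(1-alpha; k, df) * sqrt(MSW/2 * (1/n_i + 1/n_j)); the Kramer form
    handles unequal group sizes.  Letters are assigned so that groups
    sharing a letter are not significantly different.
    """
    arrays = {k: np.asarray(v, float) for k, v in groups.items()}
    names = list(arrays)
    k = len(names)
    if k == 1:
        only = names[0]
        return GenotypeComparison(arrays, float("nan"), float("nan"), alpha,
                                  {only: "a"},
                                  pd.DataFrame([[False]], index=names,
                                               columns=names))
    f_stat, p_val = genotype_anova(arrays)
    ns = np.array([len(arrays[g]) for g in names])
    means = np.array([arrays[g].mean() for g in names])
    df_w = int(ns.sum() - k)
    msw = sum(((arrays[g] - arrays[g].mean()) ** 2).sum()
              for g in names) / df_w
    sig = np.zeros((k, k), bool)
    if msw > 0:
        q_crit = stats.studentized_range.ppf(1.0 - alpha, k, df_w)
        for a in range(k):
            for b in range(a + 1, k):
                crit = q_crit * np.sqrt(msw / 2.0
                                        * (1.0 / ns[a] + 1.0 / ns[b]))
                sig[a, b] = sig[b, a] = abs(means[a] - means[b]) > crit
    else:
        for a in range(k):
            for b in range(a + 1, k):
                sig[a, b] = sig[b, a] = means[a] != means[b]

    columns = _cld_insert_absorb(names, sig)
    # assign letters: order columns by their best member mean, descending
    mean_of = dict(zip(names, means))
    columns = sorted(columns,
                     key=lambda col: -max(mean_of[g] for g in col))
    letters: dict[str, list[str]] = {g: [] for g in names}
    for idx, col in enumerate(columns):
        letter = chr(ord("a") + idx)
        for g in col:
            letters[g].append(letter)
    letter_map = {g: "".join(sorted(v)) for g, v in letters.items()}
    sig_df = pd.DataFrame(sig, index=names, columns=names)
    return GenotypeComparison(arrays, f_stat, p_val, alpha, letter_map,
                              sig_df, ms_within=float(msw), df_within=df_w)
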