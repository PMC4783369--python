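"""LER computation, temperature-response fits, ANOVA and Tukey letters."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from leaftrack.growth_stats import (TemperatureResponse, align_environment,
                                    compute_ler, estimate_base_temperature,
                                    estimate_base_temperature_from_data,
                                    fit_response, genotype_anova,
                                    thermal_time_residuals, tukey_letters)
from leaftrack.trajectory import DisplacementSeries


def disp_series(disp, dt_s=120.0, t0_s=0.0):
    disp = np.asarray(disp, float)
    t = t0_s + np.arange(len(disp)) * dt_s
    return DisplacementSeries(bead_id="b", timestamps=t,
                              displacement_mm=disp,
                              missing=~np.isfinite(disp))


# ---------------------------------------------------------------------------
# compute_ler
# ---------------------------------------------------------------------------

def test_linear_motion_gives_unit_ler():
    t = np.arange(0, 3 * 3600 + 1, 120, dtype=float)
    s = disp_series(t / 3600.0)
    ler = compute_ler(s)
    assert len(ler.table) == 3
    assert np.allclose(ler.ler, 1.0)
    assert not ler.table["missing"].any()


def test_static_bead_gives_zero_ler():
    t = np.arange(0, 2 * 3600 + 1, 120, dtype=float)
    s = disp_series(np.zeros(len(t)))
    assert np.allclose(compute_ler(s).ler, 0.0)


def test_ler_conserves_total_displacement():
    """Telescoping identity: sum(LER * dt) equals the displacement between
    the first and last interval boundaries on a gap-free series."""
    rng = np.random.default_rng(1)
    n = 10 * 30 + 1                       # 10 hours at 120 s
    disp = np.cumsum(rng.uniform(0, 0.01, n))
    s = disp_series(disp)
    ler = compute_ler(s)
    total = np.nansum(ler.ler * 1.0)
    t = np.arange(n) * 120.0
    d0 = np.interp(0.0, t, disp)
    d1 = np.interp(10 * 3600.0, t, disp)
    assert total == pytest.approx(d1 - d0, abs=1e-10)


def test_low_coverage_interval_flagged():
    t = np.arange(0, 2 * 3600 + 1, 120, dtype=float)
    disp = t / 3600.0
    # drop 80% of the second hour's frames
    keep = (t < 3600.0) | (t % 600.0 == 0)
    s = disp_series(np.where(keep, disp, np.nan))
    ler = compute_ler(s)
    assert bool(ler.table["missing"].iloc[1])


def test_short_series_empty_result():
    s = disp_series([0.0, 0.1], dt_s=60.0)
    assert len(compute_ler(s).table) >= 0   # no crash, possibly one interval


# ---------------------------------------------------------------------------
# align_environment
# ---------------------------------------------------------------------------

def intervals_df(n, dt_s=3600.0):
    start = np.arange(n) * dt_s
    return pd.DataFrame({"start": start, "end": start + dt_s})


def test_constant_channel_mean_constant():
    env = pd.DataFrame({"timestamp": np.arange(0, 7200, 120, dtype=float),
                        "temp_c": 10.0})
    out = align_environment(env, intervals_df(2))
    assert np.allclose(out["temp_c"], 10.0)


def test_linear_ramp_mean_is_midpoint():
    t = np.arange(0, 3600, 10, dtype=float)
    env = pd.DataFrame({"timestamp": t, "temp_c": t / 3600.0 * 8.0})
    out = align_environment(env, intervals_df(1))
    # mean of a linear function over the interval = value at the midpoint
    assert out["temp_c"].iloc[0] == pytest.approx(4.0, abs=0.02)


def test_sinusoid_matches_analytic_integral():
    t = np.arange(0, 24 * 3600 + 1, 120, dtype=float)
    temp = 10.0 + 5.0 * np.sin(2 * np.pi * t / 86400.0)
    env = pd.DataFrame({"timestamp": t, "temp_c": temp})
    out = align_environment(env, intervals_df(24))
    for k in range(24):
        a, b = k * 3600.0, (k + 1) * 3600.0
        analytic = 10.0 + 5.0 * (np.cos(2 * np.pi * a / 86400.0)
                                 - np.cos(2 * np.pi * b / 86400.0)) \
            * 86400.0 / (2 * np.pi * 3600.0)
        assert out["temp_c"].iloc[k] == pytest.approx(analytic, abs=0.01)


def test_no_overlap_raises():
    env = pd.DataFrame({"timestamp": [1e6, 1e6 + 60], "temp_c": [1.0, 2.0]})
    with pytest.raises(ValueError):
        align_environment(env, intervals_df(2))


# ---------------------------------------------------------------------------
# fit_response / base temperature
# ---------------------------------------------------------------------------

def test_exact_line_through_origin():
    T = np.linspace(1, 20, 40)
    fit = fit_response(0.1 * T, T, mode="fixed", i=0.0)
    assert fit.a == pytest.approx(0.1, abs=1e-12)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-12)


def test_fixed_intercept_closed_form():
    # a = sum(T*L) / sum(T^2) = 1.4 / 14 = 0.1
    fit = fit_response([0.1, 0.2, 0.3], [1.0, 2.0, 3.0], mode="fixed")
    assert fit.a == pytest.approx(1.4 / 14.0, abs=1e-12)


def test_free_fit_slope_coverage_monte_carlo():
    """Simulated LER = 0.08*max(T,0) + noise: the slope estimate lands
    within 3 SE of truth in >= 95 of 100 seeded runs."""
    from leaftrack.synthetic import simulate_temperature
    env = simulate_temperature(7, 2.0, 20.0, sample_s=3600.0)
    T = env["temp_c"].to_numpy()
    hits = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        ler = 0.08 * np.maximum(T, 0.0) + rng.normal(0, 0.05, len(T))
        fit = fit_response(ler, T, mode="free")
        if abs(fit.a - 0.08) < 3 * fit.se_a:
            hits += 1
    assert hits >= 95


def test_fixed_equals_free_when_intercept_truly_zero():
    rng = np.random.default_rng(2)
    T = np.linspace(0.0, 20.0, 200)
    ler = 0.09 * T + rng.normal(0, 1e-9, len(T))
    fixed = fit_response(ler, T, mode="fixed", i=0.0)
    free = fit_response(ler, T, mode="free")
    assert fixed.a == pytest.approx(free.a, abs=1e-6)


def test_zero_temperature_variance_free_mode_raises():
    with pytest.raises(ValueError):
        fit_response([0.1, 0.2], [5.0, 5.0], mode="free")


def test_thermal_time_residuals_zero_on_exact_model():
    T = np.linspace(0, 15, 50)
    r = thermal_time_residuals(0.07 * T, T, 0.07)
    assert np.allclose(r, 0.0, atol=1e-14)


def test_through_origin_residual_orthogonality():
    rng = np.random.default_rng(4)
    T = rng.uniform(0, 20, 300)
    ler = 0.08 * T + rng.normal(0, 0.05, 300)
    a = fit_response(ler, T, mode="fixed", i=0.0).a
    r = thermal_time_residuals(ler, T, a)
    assert abs(np.sum(T * r)) < 1e-10


def test_saturating_response_residual_sign_pattern():
    T = np.linspace(0, 20, 400)
    ler = np.minimum(0.1 * T, 1.2)       # linear then plateau at 12 degC
    a = fit_response(ler, T, mode="fixed", i=0.0).a
    r = thermal_time_residuals(ler, T, a)
    assert r[T > 18].mean() < 0          # plateau: below the fitted line
    assert r[(T > 8) & (T < 12)].mean() > 0


def test_base_temperature_exact_lines():
    T = np.linspace(3, 20, 50)
    fit0 = fit_response(0.1 * T, T, mode="free")
    tb0, _ = estimate_base_temperature(fit0)
    assert tb0 == pytest.approx(0.0, abs=1e-9)
    fit2 = fit_response(0.1 * (T - 2.0), T, mode="free")
    tb2, _ = estimate_base_temperature(fit2)
    assert tb2 == pytest.approx(2.0, abs=1e-9)


def test_base_temperature_zero_slope_undefined():
    T = np.linspace(0, 10, 20)
    fit = fit_response(np.full(20, 0.5), T, mode="free")
    with pytest.raises(ZeroDivisionError):
        estimate_base_temperature(fit)


def test_self_consistent_estimator_removes_hinge_bias():
    """Data from a hinge at 2 degC including sub-base observations: the
    plain fit is biased, the supra-base-restricted estimate is not."""
    from leaftrack.synthetic import simulate_temperature
    env = simulate_temperature(7, -2.0, 20.0, sample_s=3600.0)
    T = env["temp_c"].to_numpy()
    ler = 0.08 * np.maximum(T - 2.0, 0.0)
    plain, _ = estimate_base_temperature(fit_response(ler, T, mode="free"))
    selfc, _ = estimate_base_temperature_from_data(ler, T)
    assert abs(plain - 2.0) > 0.3
    assert selfc == pytest.approx(2.0, abs=0.05)


# ---------------------------------------------------------------------------
# ANOVA and Tukey-Kramer letters
# ---------------------------------------------------------------------------

def test_anova_hand_computed_sums_of_squares():
    # groups {0,1}, {2,3}: SS_between = 4, SS_within = 1, F = 8
    f, p = genotype_anova({"g1": [0.0, 1.0], "g2": [2.0, 3.0]})
    assert f == pytest.approx(8.0, abs=1e-12)
    assert p == pytest.approx(float(stats.f.sf(8.0, 1, 2)), abs=1e-12)


def test_anova_matches_scipy_oracle():
    rng = np.random.default_rng(5)
    groups = {f"g{i}": rng.normal(i * 0.1, 1.0, 8) for i in range(4)}
    f, p = genotype_anova(groups)
    f2, p2 = stats.f_oneway(*groups.values())
    assert f == pytest.approx(f2, rel=1e-10)
    assert p == pytest.approx(p2, rel=1e-10)


def test_anova_degenerate_identical_groups():
    f, p = genotype_anova({"g1": [1.0, 1.0], "g2": [1.0, 1.0]})
    assert f == 0.0 and p == 1.0


def test_anova_small_group_raises_with_name():
    with pytest.raises(ValueError, match="g2"):
        genotype_anova({"g1": [0.0, 1.0], "g2": [1.0]})


def test_anova_type_one_error_calibrated():
    """Under the null (equal means), rejection rate at alpha = 0.05 over
    1000 simulated datasets stays within [0.035, 0.065]."""
    rng = np.random.default_rng(6)
    rejections = 0
    for _ in range(1000):
        groups = {f"g{i}": rng.normal(0.08, 0.02, 7) for i in range(3)}
        _, p = genotype_anova(groups)
        rejections += p < 0.05
    assert 0.035 <= rejections / 1000 <= 0.065


def test_identical_groups_share_letter():
    rng = np.random.default_rng(7)
    base = rng.normal(0.08, 0.01, 7)
    comp = tukey_letters({"g1": base, "g2": base, "g3": base})
    assert set(comp.letters.values()) == {"a"}


def test_well_separated_groups_distinct_letters():
    comp = tukey_letters({"lo": [0.0, 0.01, 0.02, 0.01],
                          "hi": [5.0, 5.01, 5.02, 5.01]})
    assert comp.letters["hi"] == "a" and comp.letters["lo"] == "b"


def test_pairwise_decisions_match_direct_formula():
    """Three unequal-size groups: each pairwise call equals the direct
    studentized-range evaluation |mi - mj| > q * sqrt(MSW/2 (1/ni+1/nj))."""
    rng = np.random.default_rng(8)
    groups = {"a": rng.normal(0.06, 0.01, 7),
              "b": rng.normal(0.08, 0.01, 5),
              "c": rng.normal(0.10, 0.01, 9)}
    comp = tukey_letters(groups, alpha=0.05)
    names = list(groups)
    arrays = {k: np.asarray(v) for k, v in groups.items()}
    df = sum(len(v) for v in arrays.values()) - 3
    msw = sum(((v - v.mean()) ** 2).sum() for v in arrays.values()) / df
    q = stats.studentized_range.ppf(0.95, 3, df)
    for i, gi in enumerate(names):
        for gj in names[i + 1:]:
            crit = q * np.sqrt(msw / 2 * (1 / len(arrays[gi])
                                          + 1 / len(arrays[gj])))
            expected = abs(arrays[gi].mean() - arrays[gj].mean()) > crit
            assert bool(comp.significant.loc[gi, gj]) == expected


def test_letters_match_statsmodels_tukeyhsd():
    """Independent cross-check: pairwise rejections agree with
    statsmodels' Tukey HSD implementation."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd
    rng = np.random.default_rng(9)
    groups = {"a": rng.normal(0.06, 0.02, 7),
              "b": rng.normal(0.09, 0.02, 7),
              "c": rng.normal(0.10, 0.02, 7)}
    comp = tukey_letters(groups)
    data = np.concatenate(list(groups.values()))
    labels = sum(([g] * len(v) for g, v in groups.items()), [])
    res = pairwise_tukeyhsd(data, labels, alpha=0.05)
    sm_pairs = {(r[0], r[1]): bool(r[-1])
                for r in res.summary().data[1:]}
    for (g1, g2), reject in sm_pairs.items():
        assert bool(comp.significant.loc[g1, g2]) == reject


def test_letter_display_transitive_consistent():
    """Groups share a letter iff no pairwise rejection separates them."""
    rng = np.random.default_rng(10)
    groups = {f"g{i}": rng.normal(0.05 + 0.012 * i, 0.015, 6)
              for i in range(5)}
    comp = tukey_letters(groups)
    for gi in groups:
        for gj in groups:
            if gi == gj:
                continue
            shared = set(comp.letters[gi]) & set(comp.letters[gj])
            if comp.significant.loc[gi, gj]:
                assert not shared
            else:
                assert shared


def test_single_group_single_letter():
    comp = tukey_letters({"only": [0.1, 0.2, 0.3]})
    assert comp.letters == {"only": "a"}
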