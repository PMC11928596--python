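"""Rolling early-warning indicators: formula oracles, contracts, trends."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from soilews import (
    DetrendSpec,
    MonthlyTimeSeries,
    ScenarioConfig,
    detrend,
    ews_suite,
    generate_pixel_series,
    kendall_tau,
    lag1_autocorrelation,
    rolling_sd,
    rolling_skewness,
    sensitivity_grid,
)


def _series(values):
    return MonthlyTimeSeries(np.asarray(values, dtype=float))


# ---------------------------------------------------------------- detrending

def test_linear_detrend_of_exact_line_is_zero():
    y = 0.3 * np.arange(50) - 2.0
    resid = detrend(_series(y), DetrendSpec("linear"))
    assert np.allclose(resid.values, 0.0, atol=1e-10)


def test_first_difference_of_constant_is_zero_and_shorter():
    resid = detrend(_series(np.full(30, 0.7)), DetrendSpec("first_difference"))
    assert resid.n == 29
    assert np.allclose(resid.values, 0.0)


def test_gaussian_kernel_residuals_have_small_mean(rng):
    n, noise_sd = 400, 0.5
    y = 0.01 * np.arange(n) + rng.normal(0, noise_sd, n)
    resid = detrend(_series(y), DetrendSpec("gaussian_kernel", 0.1))
    assert abs(resid.values.mean()) < noise_sd / np.sqrt(n) * 3


def test_loess_detrend_removes_slow_curvature(rng):
    n = 200
    t = np.arange(n)
    y = 0.5 * np.sin(t / 60.0) + rng.normal(0, 0.05, n)
    resid = detrend(_series(y), DetrendSpec("loess", 0.3))
    assert abs(resid.values.mean()) < 0.02


def test_too_small_bandwidth_rejected():
    with pytest.raises(ValueError, match="bandwidth"):
        detrend(_series(np.arange(20.0)), DetrendSpec("gaussian_kernel", 0.01))


def test_unknown_method_rejected():
    with pytest.raises(ValueError):
        DetrendSpec("spline")


# ---------------------------------------------------------------- indicators

def test_alternating_signs_give_perfect_anticorrelation():
    assert lag1_autocorrelation([1, -1, 1, -1, 1, -1]) == pytest.approx(-1.0)


def test_ar1_estimate_recovers_coefficient(rng):
    phi, n = 0.8, 10_000
    z = np.empty(n)
    z[0] = rng.normal()
    eps = rng.normal(size=n)
    for t in range(1, n):
        z[t] = phi * z[t - 1] + eps[t]
    assert lag1_autocorrelation(z) == pytest.approx(phi, abs=0.05)


def test_constant_window_is_flagged_not_raised():
    assert np.isnan(lag1_autocorrelation([2.0, 2.0, 2.0]))
    assert np.isnan(rolling_skewness([1.0, 1.0, 1.0]))
    assert rolling_sd([3.0, 3.0]) == 0.0


def test_sd_textbook_case_and_consistency(rng):
    assert rolling_sd([1.0, 2.0, 3.0]) == pytest.approx(1.0)
    big = rng.normal(0, 2.0, 10_000)
    assert rolling_sd(big) == pytest.approx(2.0, abs=0.05)


def test_skewness_matches_direct_moment_arithmetic():
    z = np.array([0.0, 0.0, 1.0])
    mu = z.mean()
    m2 = np.mean((z - mu) ** 2)
    m3 = np.mean((z - mu) ** 3)
    assert rolling_skewness(z) == pytest.approx(m3 / m2**1.5, abs=1e-14)
    assert rolling_skewness([-1.0, 0.0, 1.0]) == pytest.approx(0.0, abs=1e-14)


@given(st.lists(st.floats(-10, 10), min_size=3, max_size=30))
@settings(max_examples=100, deadline=None)
def test_skewness_is_odd_under_sign_flip(values):
    z = np.asarray(values)
    if np.var(z) < 1e-12:  # near-degenerate windows are flagged, not compared
        return
    assert rolling_skewness(-z) == pytest.approx(-rolling_skewness(z), abs=1e-9)


def test_minimum_window_contracts():
    with pytest.raises(ValueError):
        lag1_autocorrelation([1.0, 2.0])
    with pytest.raises(ValueError):
        rolling_sd([1.0])
    with pytest.raises(ValueError):
        rolling_skewness([1.0, 2.0])


# ---------------------------------------------------------------- kendall tau

def test_monotone_sequences_have_extreme_tau():
    tau, p = kendall_tau(np.arange(10), np.arange(10) ** 2)
    assert tau == pytest.approx(1.0)
    tau_rev, _ = kendall_tau(np.arange(10), -(np.arange(10) ** 2.0))
    assert tau_rev == pytest.approx(-1.0)


def test_tau_matches_exhaustive_pair_count():
    x = np.arange(4)
    y = np.array([3.0, 1.0, 4.0, 2.0])
    conc = disc = 0
    for i in range(4):
        for j in range(i + 1, 4):
            s = np.sign(x[j] - x[i]) * np.sign(y[j] - y[i])
            conc += s > 0
            disc += s < 0
    tau, _ = kendall_tau(x, y)
    assert tau == pytest.approx((conc - disc) / 6.0)


def test_tau_antisymmetric_under_reversal(rng):
    y = rng.normal(size=25)
    tau_fwd, _ = kendall_tau(np.arange(25), y)
    tau_rev, _ = kendall_tau(np.arange(25), y[::-1])
    assert tau_fwd == pytest.approx(-tau_rev, abs=1e-12)


def test_tau_length_mismatch_rejected():
    with pytest.raises(ValueError):
        kendall_tau([1, 2, 3], [1, 2])


# ---------------------------------------------------------------- suite

def test_window_arithmetic_96_months():
    rng = np.random.default_rng(0)
    ser = _series(rng.normal(size=96))
    res = ews_suite(ser, DetrendSpec("linear"), window_frac=0.75)
    assert res.window_len == 72
    assert len(res.indicators["ar1"]) == 25
    assert res.window_end_month[0] == 72
    assert res.window_end_month[-1] == 96


def test_window_frac_bounds_enforced():
    ser = _series(np.random.default_rng(0).normal(size=96))
    with pytest.raises(ValueError):
        ews_suite(ser, window_frac=0.1)
    with pytest.raises(ValueError):
        ews_suite(ser, window_frac=0.9)


def test_indicator_values_respect_ranges(rng):
    ser = _series(rng.normal(size=120))
    res = ews_suite(ser)
    assert np.all(res.indicators["ar1"] >= -1.0) and np.all(res.indicators["ar1"] <= 1.0)
    assert np.all(res.indicators["sd"] >= 0.0)
    for name in ("ar1", "sd", "skewness"):
        tau, p = res.taus[name]
        assert -1.0 <= tau <= 1.0
        assert 0.0 <= p <= 1.0


def test_suite_indicators_match_bruteforce_per_window(rng):
    """Vectorised rolling path equals the scalar estimators window by window."""
    ser = _series(rng.normal(size=60))
    spec = DetrendSpec("linear")
    res = ews_suite(ser, spec, window_frac=0.5)
    resid = detrend(ser, spec).values
    w = res.window_len
    for k in range(len(res.indicators["ar1"])):
        win = resid[k : k + w]
        assert res.indicators["ar1"][k] == pytest.approx(lag1_autocorrelation(win), abs=1e-12)
        assert res.indicators["sd"][k] == pytest.approx(rolling_sd(win), abs=1e-12)
        assert res.indicators["skewness"][k] == pytest.approx(rolling_skewness(win), abs=1e-12)


def test_csd_ramp_raises_ar1_trend_vs_stationary_null():
    """Eroded-ramp pixels show a clearly higher ar1 tau than stationary ones."""
    n = 240
    cfg = ScenarioConfig(n_months=n, break_month=n, season_amplitude=0.0)
    rng = np.random.default_rng(21)
    ramp_taus, null_taus = [], []
    for _ in range(30):
        ser = generate_pixel_series(cfg, "eroded", rng).subset(n - 1)
        ramp_taus.append(ews_suite(ser).taus["ar1"][0])
        ser0 = generate_pixel_series(cfg, "non-eroded", rng).subset(n - 1)
        null_taus.append(ews_suite(ser0).taus["ar1"][0])
    assert np.median(ramp_taus) > np.median(null_taus) + 0.3
    assert abs(np.median(null_taus)) < 0.25


def test_sensitivity_grid_shape_and_consistency(rng):
    ser = _series(rng.normal(size=96))
    specs = [DetrendSpec("linear"), DetrendSpec("gaussian_kernel", 0.1)]
    fracs = (0.25, 0.5)
    grid = sensitivity_grid(ser, specs, fracs)
    assert len(grid) == len(specs) * len(fracs) * 3
    single = sensitivity_grid(ser, [DetrendSpec("linear")], (0.5,))
    suite = ews_suite(ser, DetrendSpec("linear"), 0.5)
    row = single[single.indicator == "ar1"].iloc[0]
    assert row.tau == pytest.approx(suite.taus["ar1"][0])


def test_sensitivity_grid_all_positive_ar1_tau_on_strong_ramp():
    n = 240
    cfg = ScenarioConfig(n_months=n, break_month=n, season_amplitude=0.0, seed=0)
    rng = np.random.default_rng(4)
    ser = generate_pixel_series(cfg, "eroded", rng).subset(n - 1)
    grid = sensitivity_grid(
        ser,
        [DetrendSpec("gaussian_kernel", 0.1), DetrendSpec("linear")],
        (0.375, 0.5, 0.625),
    )
    ar1_rows = grid[grid.indicator == "ar1"]
    assert (ar1_rows.tau > 0).all()


def test_empty_grid_rejected(rng):
    with pytest.raises(ValueError):
        sensitivity_grid(_series(rng.normal(size=50)), [], ())
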