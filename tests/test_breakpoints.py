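"""Breakpoint detection: decomposition, exact cases, brute-force RSS oracle."""

import numpy as np
import pytest

from soilews import (
    MonthlyTimeSeries,
    ScenarioConfig,
    detect_largest_break,
    generate_pixel_series,
    truncate_pre_break,
)
from soilews.breakpoints import decompose, fill_short_gaps


def _series(values, start=(2003, 1)):
    return MonthlyTimeSeries(np.asarray(values, dtype=float), start=start)


def _seasonal(n, amp=0.3, phase=0.0):
    t = np.arange(1, n + 1)
    return amp * np.sin(2 * np.pi * t / 12.0 + phase)


class TestDecompose:
    def test_pure_sinusoid_lands_in_seasonal_component(self):
        y = _seasonal(120)
        trend, seasonal, remainder = decompose(_series(y))
        assert np.allclose(seasonal, y, atol=1e-8)
        assert abs(np.polyfit(np.arange(120), trend, 1)[0]) < 1e-8
        assert np.allclose(remainder, 0.0, atol=1e-8)

    def test_pure_ramp_lands_in_trend_component(self):
        y = 0.01 * np.arange(120) - 0.3
        trend, seasonal, remainder = decompose(_series(y))
        assert np.allclose(trend, y, atol=1e-8)
        assert np.allclose(seasonal, 0.0, atol=1e-8)

    def test_components_recover_known_mixture(self, rng):
        noise_sd = 0.05
        t = np.arange(120)
        true_trend = 0.002 * t + 0.1
        true_season = _seasonal(120, amp=0.2, phase=0.4)
        y = true_trend + true_season + rng.normal(0, noise_sd, 120)
        trend, seasonal, _ = decompose(_series(y))
        assert np.sqrt(np.mean((trend - true_trend) ** 2)) < noise_sd
        assert np.sqrt(np.mean((seasonal - true_season) ** 2)) < noise_sd

    def test_components_sum_to_input(self, rng):
        y = rng.normal(size=60)
        trend, seasonal, remainder = decompose(_series(y))
        assert np.allclose(trend + seasonal + remainder, y, atol=1e-10)

    def test_all_masked_rejected(self):
        ser = MonthlyTimeSeries(np.full(48, np.nan))
        with pytest.raises(ValueError):
            decompose(ser)


class TestGapFilling:
    def test_short_gap_interpolated(self):
        vals = np.arange(48, dtype=float)
        mask = np.zeros(48, dtype=bool)
        mask[10:12] = True
        filled, usable = fill_short_gaps(vals, mask)
        assert usable
        assert filled[10] == pytest.approx(10.0)

    def test_long_gap_flags_series_unusable(self):
        vals = np.arange(48, dtype=float)
        mask = np.zeros(48, dtype=bool)
        mask[10:15] = True
        _, usable = fill_short_gaps(vals, mask)
        assert not usable


class TestDetect:
    def test_noise_free_step_located_exactly(self):
        n, h, b = 240, 0.3, 121
        y = np.zeros(n)
        y[b - 1 :] += h  # months >= 121 shifted
        y += _seasonal(n, amp=0.2)
        res = detect_largest_break(_series(y), seed=0)
        assert res is not None
        assert res.break_month == b
        assert res.break_year == 2013
        assert res.magnitude == pytest.approx(h, abs=1e-8)

    def test_magnitude_equals_segment_mean_difference_for_pure_step(self):
        y = np.zeros(240)
        y[120:] += -0.25
        res = detect_largest_break(_series(y), seed=0)
        assert res.magnitude == pytest.approx(-0.25, abs=1e-8)

    def test_shift_invariance(self, rng):
        cfg = ScenarioConfig()
        ser = generate_pixel_series(cfg, "eroded", rng, break_sign=1.0)
        res_a = detect_largest_break(ser, seed=77)
        res_b = detect_largest_break(
            MonthlyTimeSeries(ser.values + 5.0, start=ser.start), seed=77
        )
        assert (res_a is None) == (res_b is None)
        if res_a is not None:
            assert res_a.break_month == res_b.break_month
            assert res_a.magnitude == pytest.approx(res_b.magnitude, abs=1e-8)

    def test_selected_break_minimizes_rss_vs_brute_force(self, rng):
        """Exhaustive oracle: refit every candidate with lstsq on a short series."""
        n, ms = 60, 6
        y = rng.normal(size=n)
        y[35:] += 2.0
        t = np.arange(1, n + 1, dtype=float)

        def seg_rss(i, j):
            A = np.column_stack([np.ones(j - i), t[i:j]])
            _, res, *_ = np.linalg.lstsq(A, y[i:j], rcond=None)
            return res[0] if res.size else np.sum(
                (y[i:j] - A @ np.linalg.lstsq(A, y[i:j], rcond=None)[0]) ** 2
            )

        oracle = {b: seg_rss(0, b) + seg_rss(b, n) for b in range(ms, n - ms + 1)}
        best_oracle = min(oracle, key=oracle.get)

        from soilews.breakpoints import _segment_rss

        cands = np.arange(ms, n - ms + 1)
        _, rss = _segment_rss(y, cands)
        assert np.allclose(rss[0], [oracle[b] for b in cands], atol=1e-8)
        assert cands[np.argmin(rss[0])] == best_oracle

    def test_stationary_series_rarely_flags_a_break(self):
        """Monte-Carlo under the null at 95% confidence."""
        cfg = ScenarioConfig()
        rng = np.random.default_rng(5)
        false_pos = 0
        n_rep = 60
        for _ in range(n_rep):
            ser = generate_pixel_series(cfg, "non-eroded", rng)
            res = detect_largest_break(ser, seed=int(rng.integers(2**31)))
            false_pos += res is not None
        assert false_pos / n_rep <= 0.10

    def test_planted_break_recovered_in_noisy_pixels(self):
        cfg = ScenarioConfig()
        rng = np.random.default_rng(8)
        hits = 0
        n_rep = 40
        for _ in range(n_rep):
            ser = generate_pixel_series(cfg, "eroded", rng, break_sign=1.0)
            res = detect_largest_break(ser, seed=int(rng.integers(2**31)))
            if res is not None and abs(res.break_month - cfg.break_month) <= 3:
                hits += 1
        assert hits / n_rep >= 0.8

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            detect_largest_break(_series(np.zeros(20)), min_segment=12)

    def test_perfectly_linear_series_yields_no_break(self):
        y = 0.001 * np.arange(240) + _seasonal(240)
        assert detect_largest_break(_series(y), seed=0) is None


class TestTruncate:
    def _result_at(self, month):
        y = np.zeros(240)
        y[month - 1 :] += 1.0
        return detect_largest_break(_series(y), seed=0)

    def test_two_year_exclusion_arithmetic(self):
        ser = _series(np.zeros(240))
        res = self._result_at(121)
        sub = truncate_pre_break(ser, res, exclusion=24)
        assert sub.n == 96
        assert str(sub.calendar[-1]) == "2010-12"

    def test_zero_exclusion_ends_month_before_break(self):
        ser = _series(np.zeros(240))
        sub = truncate_pre_break(ser, self._result_at(121), exclusion=0)
        assert sub.n == 120

    def test_refuses_without_significant_break(self):
        with pytest.raises(ValueError, match="no significant break"):
            truncate_pre_break(_series(np.zeros(240)), None)

    def test_refuses_when_break_too_early(self):
        res = self._result_at(20)
        if res is not None:
            with pytest.raises(ValueError):
                truncate_pre_break(_series(np.zeros(240)), res, exclusion=24)
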