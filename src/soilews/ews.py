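"""Temporal early-warning signals: rolling AR(1), SD, skewness + Kendall trends.

Critical slowing down predicts that a system approaching a regime shift
recovers more slowly from perturbations, which shows up in its residual
time series as rising lag-1 autocorrelation and, typically, rising variance
and drifting skewness. The workflow is the standard one:

1. detrend the (de-seasoned, pre-break-truncated) series,
2. slide a window of ``window_frac`` x series length in 1-month steps,
3. inside each window compute lag-1 autocorrelation, standard deviation
   (n-1 denominator) and moment skewness,
4. summarise each indicator's drift as the Kendall tau of indicator value
   against window end time.

A sensitivity grid over detrending methods, bandwidths and window sizes
covers the arbitrariness of those choices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import MonthlyTimeSeries

__all__ = [
    "DetrendSpec",
    "EwsResult",
    "detrend",
    "lag1_autocorrelation",
    "rolling_sd",
    "rolling_skewness",
    "kendall_tau",
    "ews_suite",
    "sensitivity_grid",
    "INDICATORS",
]

INDICATORS = ("ar1", "sd", "skewness")
DETREND_METHODS = ("gaussian_kernel", "loess", "linear", "first_difference")


@dataclass(frozen=True)
class DetrendSpec:
    """How to remove slow trend before rolling-window analysis.

    method:
        ``gaussian_kernel`` (residuals of a Gaussian-kernel smooth),
        ``loess`` (residuals of a LOWESS fit), ``linear`` (residuals of an
        OLS line) or ``first_difference`` (successive differences; the
        output is one sample shorter).
    bandwidth:
        Kernel sigma / LOWESS span as a fraction of series length
        (kernel and loess only). Default 0.1.
    """

    method: str = "gaussian_kernel"
    bandwidth: float = 0.1

    def __post_init__(self) -> None:
        if self.method not in DETREND_METHODS:
            raise ValueError(f"unknown detrend method {self.method!r}")
        if self.method in ("gaussian_kernel", "loess") and not (0.0 < self.bandwidth < 1.0):
            raise ValueError("bandwidth must be a fraction of series length in (0, 1)")


def detrend(series: MonthlyTimeSeries, spec: DetrendSpec) -> MonthlyTimeSeries:
    """Residual series after removing slow trend per ``spec``.

    ``first_difference`` returns successive differences (length n-1, calendar
    advanced one month); the other methods return input minus smooth at the
    original length.
    """
    n = series.n
    if n < 4:
        raise ValueError("need at least 4 points to detrend")
    if series.mask.any():
        raise ValueError("detrend expects a gap-free series; fill or truncate first")
    y = series.values

    if spec.method == "first_difference":
        resid = np.diff(y)
        cal = series.calendar[1]
        return MonthlyTimeSeries(resid, start=(cal.year, cal.month))

    if spec.method == "linear":
        t = np.arange(n, dtype=float)
        smooth = np.polyval(np.polyfit(t, y, 1), t)
    elif spec.method == "gaussian_kernel":
        sigma = spec.bandwidth * n
        if sigma * 6 < 3:  # kernel support must cover >= 3 points
            raise ValueError("bandwidth too small: kernel covers fewer than 3 points")
        smooth = ndimage.gaussian_filter1d(y, sigma=sigma, mode="nearest")
    else:  # loess
        frac = spec.bandwidth
        if frac * n < 3:
            raise ValueError("bandwidth too small: LOWESS span covers fewer than 3 points")
        t = np.arange(n, dtype=float)
        smooth = lowess(y, t, frac=frac, return_sorted=False)
    return MonthlyTimeSeries(y - smooth, start=series.start)


def lag1_autocorrelation(window) -> float:
    """Lag-1 autocorrelation of one window.

    Sample version of the autocovariance-over-variance form: mean
    cross-product of deviations one step apart divided by the (biased)
    sample variance. NaN (flagged) for zero-variance windows.
    """
    z = np.asarray(window, dtype=float)
    if z.size < 3:
        raise ValueError("need at least 3 values for lag-1 autocorrelation")
    mu = z.mean()
    var = np.mean((z - mu) ** 2)
    if var == 0:
        return float("nan")
    num = np.mean((z[:-1] - mu) * (z[1:] - mu))
    return float(num / var)


def rolling_sd(window) -> float:
    """Sample standard deviation with the n-1 denominator."""
    z = np.asarray(window, dtype=float)
    if z.size < 2:
        raise ValueError("need at least 2 values for a standard deviation")
    return float(np.std(z, ddof=1))


def rolling_skewness(window) -> float:
    """Moment skewness m3 / m2^(3/2); NaN for zero-variance windows."""
    z = np.asarray(window, dtype=float)
    if z.size < 3:
        raise ValueError("need at least 3 values for skewness")
    mu = z.mean()
    m2 = np.mean((z - mu) ** 2)
    if m2 == 0:
        return float("nan")
    m3 = np.mean((z - mu) ** 3)
    return float(m3 / m2**1.5)


def kendall_tau(x, y) -> tuple[float, float]:
    """Kendall tau-b with two-sided p.

    Exact p by enumeration over permutations for n <= 8 without ties;
    tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs for Kendall tau")
    no_ties = np.unique(x).size == x.size and np.unique(y).size == y.size
    method = "exact" if (x.size <= 8 and no_ties) else "asymptotic"
    res = stats.kendalltau(x, y, method=method)
    return float(res.statistic), float(res.pvalue)


def _rolling_windows(values: np.ndarray, width: int) -> np.ndarray:
    return np.lib.stride_tricks.sliding_window_view(values, width)


@dataclass
class EwsResult:
    """Rolling indicator series and their Kendall trends for one pixel series."""

    window_frac: float
    window_len: int
    window_end_month: np.ndarray  # 1-based month of each window's last sample
    indicators: dict = field(default_factory=dict)  # name -> np.ndarray
    taus: dict = field(default_factory=dict)  # name -> (tau, p)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"window_end_month": self.window_end_month})
        for name in INDICATORS:
            df[name] = self.indicators[name]
        return df


def ews_suite(
    series: MonthlyTimeSeries,
    spec: DetrendSpec | None = None,
    window_frac: float = 0.5,
) -> EwsResult:
    """Detrend, roll the three indicators, and attach their Kendall taus.

    ``window_frac`` (fraction of series length, 0.25..0.75) sets the window
    width; windows advance one month and each indicator value is stamped at
    its window's end month, the convention compatible with early warning.
    The caller is expected to pass a series already truncated two years
    before any significant break.
    """
    spec = spec or DetrendSpec()
    if not (0.25 <= window_frac <= 0.75):
        raise ValueError("window_frac must be in [0.25, 0.75]")
    resid = detrend(series, spec)
    width = int(round(window_frac * resid.n))
    if width < 3:
        raise ValueError("window shorter than 3 points")

    wins = _rolling_windows(resid.values, width)
    mu = wins.mean(axis=1, keepdims=True)
    dev = wins - mu
    m2 = np.mean(dev**2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        # mean over the width-1 lag pairs, over the biased window variance
        ar1 = np.mean(dev[:, :-1] * dev[:, 1:], axis=1) / m2
        sd = np.sqrt(np.sum(dev**2, axis=1) / (width - 1))
        sk = np.mean(dev**3, axis=1) / m2**1.5
    ar1 = np.where(m2 == 0, np.nan, ar1)
    sk = np.where(m2 == 0, np.nan, sk)

    # window ends, in 1-based months of the *original* series calendar
    offset = series.n - resid.n  # 1 for first_difference, else 0
    end_months = np.arange(width, resid.n + 1) + offset

    result = EwsResult(
        window_frac=window_frac,
        window_len=width,
        window_end_month=end_months,
        indicators={"ar1": ar1, "sd": sd, "skewness": sk},
    )
    for name, vals in result.indicators.items():
        ok = np.isfinite(vals)
        if ok.sum() >= 3:
            result.taus[name] = kendall_tau(end_months[ok], vals[ok])
        else:
            result.taus[name] = (float("nan"), float("nan"))
    return result


def sensitivity_grid(
    series: MonthlyTimeSeries,
    specs=None,
    window_fracs=(0.25, 0.375, 0.5, 0.625, 0.75),
) -> pd.DataFrame:
    """Kendall taus for every (detrend spec) x (window fraction) combination.

    Returns a tidy DataFrame with one row per grid cell per indicator:
    columns method, bandwidth, window_frac, indicator, tau, p.
    """
    if specs is None:
        specs = [
            DetrendSpec("gaussian_kernel", bw) for bw in (0.05, 0.1, 0.2)
        ] + [DetrendSpec("linear"), DetrendSpec("first_difference")]
    specs = list(specs)
    window_fracs = list(window_fracs)
    if not specs or not window_fracs:
        raise ValueError("sensitivity grid must not be empty")
    rows = []
    for spec in specs:
        for wf in window_fracs:
            res = ews_suite(series, spec, wf)
            for name in INDICATORS:
                tau, p = res.taus[name]
                rows.append(
                    {
                        "method": spec.method,
                        "bandwidth": spec.bandwidth,
                        "window_frac": wf,
                        "indicator": name,
                        "tau": tau,
                        "p": p,
                    }
                )
    return pd.DataFrame(rows)
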