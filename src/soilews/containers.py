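"""Core in-memory containers shared across the pipeline.

The analysis operates on two shapes of data:

* per-pixel monthly index series (:class:`MonthlyTimeSeries`), the unit of
  breakpoint detection and rolling-window early-warning analysis, and
* time x rows x cols stacks of one spectral index (:class:`IndexCube`),
  the unit of map-level (spatial) analysis.

Both carry an explicit monthly calendar so month arithmetic (break months,
two-year exclusion windows) is never done on bare array positions alone.
Missing observations are masked, never dropped, so the calendar stays
gap-free.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "MonthlyTimeSeries",
    "IndexCube",
    "IconaLayers",
    "DEFAULT_ORIGIN",
]

#: Default calendar origin: January 2003, month index 1.
DEFAULT_ORIGIN = (2003, 1)


def _monthly_calendar(start: tuple[int, int], n: int) -> pd.PeriodIndex:
    year, month = start
    return pd.period_range(start=pd.Period(year=year, month=month, freq="M"), periods=n, freq="M")


@dataclass
class MonthlyTimeSeries:
    """One pixel's index values on a fixed monthly calendar.

    Parameters
    ----------
    values:
        Index values, one per month, ``float`` array of shape ``(n,)``.
    start:
        ``(year, month)`` of the first sample. Month indices used throughout
        the package are 1-based relative to this origin.
    mask:
        Boolean array, ``True`` where the observation is missing. Missing
        values keep their calendar slot.
    """

    values: np.ndarray
    start: tuple[int, int] = DEFAULT_ORIGIN
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("MonthlyTimeSeries values must be 1-D")
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape must match values shape")
            self.mask = self.mask | ~np.isfinite(self.values)

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def calendar(self) -> pd.PeriodIndex:
        return _monthly_calendar(self.start, self.n)

    @property
    def month_index(self) -> np.ndarray:
        """1-based month positions, shape ``(n,)``."""
        return np.arange(1, self.n + 1)

    def valid_values(self) -> np.ndarray:
        return self.values[~self.mask]

    def subset(self, stop_month: int, start_month: int = 1) -> "MonthlyTimeSeries":
        """Sub-series covering 1-based months ``start_month .. stop_month`` inclusive."""
        if not (1 <= start_month <= stop_month <= self.n):
            raise ValueError(
                f"invalid month range [{start_month}, {stop_month}] for series of length {self.n}"
            )
        cal = self.calendar[start_month - 1]
        return MonthlyTimeSeries(
            values=self.values[start_month - 1 : stop_month].copy(),
            start=(cal.year, cal.month),
            mask=self.mask[start_month - 1 : stop_month].copy(),
        )

    def to_series(self) -> pd.Series:
        vals = self.values.copy()
        vals[self.mask] = np.nan
        return pd.Series(vals, index=self.calendar)


@dataclass
class IndexCube:
    """A time x rows x cols stack of one spectral index.

    ``transform`` is a 6-element affine ``(a, b, c, d, e, f)`` mapping
    column/row to x/y as ``x = a*col + b*row + c``, ``y = d*col + e*row + f``
    (the GDAL/rasterio convention). ``crs`` is an opaque tag (e.g. an EPSG
    string); the package never reprojects.
    """

    values: np.ndarray
    index_name: str
    start: tuple[int, int] = DEFAULT_ORIGIN
    mask: np.ndarray | None = None
    transform: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0, -1.0, 0.0)
    crs: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("IndexCube values must be 3-D (time, rows, cols)")
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape must match values shape")
            self.mask = self.mask | ~np.isfinite(self.values)
        self.transform = tuple(float(v) for v in self.transform)

    @property
    def n_months(self) -> int:
        return self.values.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[1], self.values.shape[2]

    @property
    def calendar(self) -> pd.PeriodIndex:
        return _monthly_calendar(self.start, self.n_months)

    def pixel(self, row: int, col: int) -> MonthlyTimeSeries:
        """Extract one pixel as a :class:`MonthlyTimeSeries` (0-based row/col)."""
        return MonthlyTimeSeries(
            values=self.values[:, row, col].copy(),
            start=self.start,
            mask=self.mask[:, row, col].copy(),
        )

    def time_reversed(self) -> "IndexCube":
        return replace(self, values=self.values[::-1].copy(), mask=self.mask[::-1].copy())


@dataclass
class IconaLayers:
    """Co-registered ancillary rasters feeding the ICONA hazard classification.

    slope_pct : slope in percent, >= 0
    litho_class : lithofacies resistance class 1 (most resistant) .. 5
    landuse_class : land-use class 1..6
    cover_pct : vegetation cover in percent, 0..100
    mask : True where a cell is excluded (water, nodata, ...)
    """

    slope_pct: np.ndarray
    litho_class: np.ndarray
    landuse_class: np.ndarray
    cover_pct: np.ndarray
    mask: np.ndarray | None = None
    transform: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0, -1.0, 0.0)
    crs: str = ""

    def __post_init__(self) -> None:
        self.slope_pct = np.asarray(self.slope_pct, dtype=float)
        self.litho_class = np.asarray(self.litho_class, dtype=int)
        self.landuse_class = np.asarray(self.landuse_class, dtype=int)
        self.cover_pct = np.asarray(self.cover_pct, dtype=float)
        shapes = {
            self.slope_pct.shape,
            self.litho_class.shape,
            self.landuse_class.shape,
            self.cover_pct.shape,
        }
        if len(shapes) != 1:
            raise ValueError(f"ICONA layers are not co-registered: shapes {sorted(shapes)}")
        if self.mask is None:
            self.mask = np.zeros(self.slope_pct.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.slope_pct.shape:
                raise ValueError("mask shape must match layer shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.slope_pct.shape
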