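"""Spectral indices: NDVI, NDSI and TGSI from surface-reflectance bands.

All three are normalized band ratios bounded in [-1, 1]:

* NDVI = (NIR - R) / (NIR + R) — vegetation vigour
* NDSI = (R - NIR) / (R + NIR) — soil salinity (the algebraic negation of NDVI)
* TGSI = (R - B) / (R + B + G) — topsoil grain size

Zero-denominator pixels (water, deep shadow) become missing values rather
than errors so cube computation never aborts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import DEFAULT_ORIGIN, IndexCube

__all__ = ["BandStack", "ndvi", "ndsi", "tgsi", "compute_cube", "INDEX_NAMES"]

INDEX_NAMES = ("NDVI", "NDSI", "TGSI")


@dataclass
class BandStack:
    """Co-registered surface-reflectance rasters for one month.

    Reflectances are unitless and >= 0. ``mask`` is True where a cell is
    nodata; masked cells propagate to every derived index.
    """

    R: np.ndarray
    G: np.ndarray
    B: np.ndarray
    NIR: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.NIR = np.asarray(self.NIR, dtype=float)
        shapes = {self.R.shape, self.G.shape, self.B.shape, self.NIR.shape}
        if len(shapes) != 1:
            raise ValueError(f"bands are not co-registered: shapes {sorted(shapes)}")
        if self.mask is None:
            self.mask = np.zeros(self.R.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.R.shape:
                raise ValueError("mask shape must match band shape")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.R.shape


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """num/den with zero denominators mapped to NaN, not warnings/errors."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    out = np.full(np.broadcast_shapes(num.shape, den.shape), np.nan)
    ok = den != 0
    np.divide(num, den, out=out, where=ok)
    return out


def ndvi(nir, red):
    """(NIR - R) / (NIR + R); NaN where NIR + R == 0."""
    nir = np.asarray(nir, dtype=float)
    red = np.asarray(red, dtype=float)
    return _safe_ratio(nir - red, nir + red)


def ndsi(red, nir):
    """(R - NIR) / (R + NIR); NaN where R + NIR == 0.

    Identically ``-ndvi(nir, red)``.
    """
    red = np.asarray(red, dtype=float)
    nir = np.asarray(nir, dtype=float)
    return _safe_ratio(red - nir, red + nir)


def tgsi(red, green, blue):
    """(R - B) / (R + B + G); NaN where the denominator is zero."""
    red = np.asarray(red, dtype=float)
    green = np.asarray(green, dtype=float)
    blue = np.asarray(blue, dtype=float)
    return _safe_ratio(red - blue, red + blue + green)


def compute_index(bands: BandStack, index_name: str) -> np.ndarray:
    """Pixel-wise index for one month; masked cells become NaN."""
    name = index_name.upper()
    if name == "NDVI":
        vals = ndvi(bands.NIR, bands.R)
    elif name == "NDSI":
        vals = ndsi(bands.R, bands.NIR)
    elif name == "TGSI":
        vals = tgsi(bands.R, bands.G, bands.B)
    else:
        raise ValueError(f"unknown index {index_name!r}; expected one of {INDEX_NAMES}")
    vals = np.where(bands.mask, np.nan, vals)
    return vals


def compute_cube(
    bands_by_month,
    index_name: str,
    start: tuple[int, int] = DEFAULT_ORIGIN,
    transform: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0, -1.0, 0.0),
    crs: str = "",
) -> IndexCube:
    """Stack per-month pixel-wise indices into an :class:`IndexCube`.

    Parameters
    ----------
    bands_by_month:
        Sequence of :class:`BandStack`, one per month, in calendar order.
    index_name:
        One of ``NDVI``, ``NDSI``, ``TGSI``.
    start:
        ``(year, month)`` of the first stack.
    """
    bands_by_month = list(bands_by_month)
    if not bands_by_month:
        raise ValueError("need at least one month of bands")
    shape0 = bands_by_month[0].shape
    for i, b in enumerate(bands_by_month):
        if b.shape != shape0:
            raise ValueError(f"grid mismatch at month {i + 1}: {b.shape} != {shape0}")
    values = np.stack([compute_index(b, index_name) for b in bands_by_month])
    return IndexCube(
        values=values,
        index_name=index_name.upper(),
        start=start,
        transform=transform,
        crs=crs,
    )
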