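"""Synthetic monthly scenes with planted regime shifts and CSD ramps.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage is testable without satellite data:

* 240 monthly steps (January 2003 origin) of three index cubes
  (NDVI, NDSI, TGSI), values clipped to [-1, 1];
* two pixel strata: an *eroded* stratum whose NDVI drops and NDSI jumps
  abruptly at ``break_month``, preceded by a critical-slowing-down ramp of
  the AR(1) noise coefficient from ``phi_start`` to ``phi_end``, and a
  stationary *non-eroded* stratum; TGSI carries no planted change in either
  stratum (its role downstream is the no-signal control);
* harmonic seasonality (period 12) plus Gaussian AR(1) noise. ``noise_sd``
  is the *stationary* (marginal) standard deviation of the noise —
  innovations are scaled by sqrt(1 - phi^2) — so the planted step height
  stays interpretable in index units while phi ramps;
* ancillary rasters (slope %, lithofacies, land use, cover %) drawn so the
  ICONA classification labels eroded pixels severe (hazard 4-5) and
  non-eroded pixels low (hazard 1-2).

After the break the AR coefficient returns to ``phi_start``: the system has
settled into its new state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import DEFAULT_ORIGIN, IndexCube, IconaLayers, MonthlyTimeSeries

__all__ = ["ScenarioConfig", "SyntheticScene", "generate_pixel_series", "generate_scene"]

STRATA = ("eroded", "non-eroded")

#: Index-specific baseline level and break-step sign: vegetation loss drives
#: NDVI down, salinization drives NDSI up, TGSI stays put.
INDEX_PROFILES = {
    "NDVI": {"baseline": 0.30, "break_sign": -1.0, "csd": True},
    "NDSI": {"baseline": 0.00, "break_sign": +1.0, "csd": True},
    "TGSI": {"baseline": 0.05, "break_sign": 0.0, "csd": False},
}


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one synthetic scene.

    Defaults reflect the emulated record: 240 months from January 2003 with
    the abrupt change at month 121 (January 2013), a 50/50 split of eroded
    and non-eroded pixels, a step of three noise standard deviations, and a
    pre-break AR(1) ramp from 0.2 to 0.9.
    """

    n_months: int = 240
    grid_rows: int = 20
    grid_cols: int = 20
    eroded_fraction: float = 0.5
    break_month: int = 121  # 1-based; January 2013 on the default calendar
    break_magnitude: float = 0.15  # index units; sign applied per index
    break_slope_change: float = 0.0  # optional trend-slope change, index units/month
    phi_start: float = 0.2
    phi_end: float = 0.9
    season_amplitude: float = 0.1
    noise_sd: float = 0.05
    start: tuple[int, int] = DEFAULT_ORIGIN
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_months < 24:
            raise ValueError("n_months must be >= 24")
        if not (1 < self.break_month <= self.n_months):
            raise ValueError("break_month must satisfy 1 < break_month <= n_months")
        if not (0.0 <= self.eroded_fraction <= 1.0):
            raise ValueError("eroded_fraction must be in [0, 1]")
        if not (abs(self.phi_start) < 1 and abs(self.phi_end) < 1):
            raise ValueError("AR coefficients must satisfy |phi| < 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid must contain at least one pixel")


@dataclass
class SyntheticScene:
    """One generated scene: index cubes, ancillary rasters, and ground truth."""

    config: ScenarioConfig
    index_cubes: dict  # name -> IndexCube
    layers: IconaLayers
    truth_labels: np.ndarray  # bool raster, True = eroded stratum
    truth_break_month: np.ndarray  # int raster, planted break month; 0 = none


def _phi_path(config: ScenarioConfig, stratum: str) -> np.ndarray:
    """Per-month AR(1) coefficient for one pixel of the given stratum."""
    n = config.n_months
    phi = np.full(n, config.phi_start, dtype=float)
    if stratum == "eroded":
        b = config.break_month
        ramp_len = b - 1
        if ramp_len > 1:
            phi[:ramp_len] = np.linspace(config.phi_start, config.phi_end, ramp_len)
        # post-break: back to the stationary coefficient (new stable state)
    return phi


def _ar1_noise(phi: np.ndarray, sd: float, n_series: int, rng: np.random.Generator) -> np.ndarray:
    """(n_series, n_months) AR(1) noise with marginal sd ``sd`` under a
    time-varying coefficient path ``phi``."""
    n = phi.size
    out = np.empty((n_series, n))
    if sd == 0:
        out.fill(0.0)
        return out
    w = rng.standard_normal((n_series, n))
    out[:, 0] = sd * w[:, 0]
    innov = sd * np.sqrt(1.0 - phi**2)
    for t in range(1, n):
        out[:, t] = phi[t] * out[:, t - 1] + innov[t] * w[:, t]
    return out


def _stratum_values(
    config: ScenarioConfig,
    stratum: str,
    n_series: int,
    rng: np.random.Generator,
    baseline: float = 0.0,
    break_sign: float = 1.0,
    csd: bool = True,
) -> np.ndarray:
    """(n_series, n_months) raw series for one stratum of one index."""
    if stratum not in STRATA:
        raise ValueError(f"unknown stratum {stratum!r}; expected one of {STRATA}")
    n = config.n_months
    t = np.arange(1, n + 1, dtype=float)
    season = config.season_amplitude * np.sin(2.0 * np.pi * t / 12.0)
    phi = _phi_path(config, stratum) if csd else _phi_path(config, "non-eroded")
    noise = _ar1_noise(phi, config.noise_sd, n_series, rng)
    values = baseline + season + noise
    if stratum == "eroded" and break_sign != 0.0:
        post = t >= config.break_month
        step = break_sign * (
            config.break_magnitude + config.break_slope_change * (t - config.break_month)
        )
        values[:, post] += step[post]
    return np.clip(values, -1.0, 1.0)


def generate_pixel_series(
    config: ScenarioConfig,
    stratum: str,
    rng: np.random.Generator,
    baseline: float = 0.0,
    break_sign: float = 1.0,
) -> MonthlyTimeSeries:
    """One pixel's monthly index series.

    Eroded pixels get the pre-break AR(1) ramp plus the planted step at
    ``break_month`` (signed by ``break_sign``); non-eroded pixels are
    stationary with no step.
    """
    values = _stratum_values(config, stratum, 1, rng, baseline, break_sign, csd=True)[0]
    return MonthlyTimeSeries(values, start=config.start)


def generate_scene(config: ScenarioConfig) -> SyntheticScene:
    """Generate a full scene, reproducibly from ``config.seed``."""
    rows, cols = config.grid_rows, config.grid_cols
    n_pix = rows * cols
    rng = np.random.default_rng(config.seed)

    n_eroded = int(round(config.eroded_fraction * n_pix))
    eroded_flat = rng.choice(n_pix, size=n_eroded, replace=False)
    truth = np.zeros(n_pix, dtype=bool)
    truth[eroded_flat] = True
    truth = truth.reshape(rows, cols)

    transform = (30.0, 0.0, 0.0, 0.0, -30.0, 0.0)  # 30 m pixels
    crs = "EPSG:32640"

    cubes = {}
    for name, profile in INDEX_PROFILES.items():
        values = np.empty((config.n_months, n_pix))
        er = _stratum_values(
            config, "eroded", n_eroded, rng,
            baseline=profile["baseline"], break_sign=profile["break_sign"],
            csd=profile["csd"],
        )
        non = _stratum_values(
            config, "non-eroded", n_pix - n_eroded, rng,
            baseline=profile["baseline"], break_sign=profile["break_sign"],
            csd=profile["csd"],
        )
        values[:, truth.ravel()] = er.T
        values[:, ~truth.ravel()] = non.T
        cubes[name] = IndexCube(
            values=values.reshape(config.n_months, rows, cols),
            index_name=name,
            start=config.start,
            transform=transform,
            crs=crs,
        )

    # Ancillary layers: eroded pixels steep / weak / bare / sparse, so the
    # ICONA composition lands them in hazard classes 4-5; non-eroded the
    # opposite (hazard 1).
    slope = np.where(truth, rng.uniform(36.0, 60.0, truth.shape), rng.uniform(0.0, 2.9, truth.shape))
    litho = np.where(truth, 5, 1)
    landuse = np.where(
        truth,
        rng.choice([1, 5], size=truth.shape),  # Dry Farming / Bare Land
        rng.choice([4, 6], size=truth.shape),  # Rangeland / Rock Outcrops
    )
    cover = np.where(truth, rng.uniform(0.0, 24.9, truth.shape), rng.uniform(75.5, 100.0, truth.shape))
    layers = IconaLayers(
        slope_pct=slope, litho_class=litho, landuse_class=landuse, cover_pct=cover,
        transform=transform, crs=crs,
    )

    truth_break = np.where(truth, config.break_month, 0).astype(int)
    return SyntheticScene(
        config=config,
        index_cubes=cubes,
        layers=layers,
        truth_labels=truth,
        truth_break_month=truth_break,
    )
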