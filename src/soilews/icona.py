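"""ICONA erosion-hazard classification.

The ICONA model is a GIS overlay scheme that combines four ancillary layers
into a 5-class erosion-hazard map through three lookup tables:

1. slope percent -> slope class 1-5; lithofacies class 1-5 (1 = most
   resistant rock, 5 = unconsolidated sediment); (slope, litho) -> soil
   erodibility level EN < EB < EM < EA < EX,
2. land-use class x vegetation-cover class -> soil protection level
   MA > A > M > B > MB (very high .. very low conservation),
3. (protection, erodibility) -> hazard class 1 (shallow) .. 5 (very high).

The matrices live in an editable YAML config (``data/icona_tables.yaml``);
one published row of the protection matrix is typeset ambiguously, so users
can substitute their own reading without touching code. Protection levels
are kept symbolic rather than numbered because the published class-number
prose and table row order disagree.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .containers import IconaLayers

__all__ = [
    "ERODIBILITY_SYMBOLS",
    "PROTECTION_SYMBOLS",
    "LAND_USE_NAMES",
    "IconaTables",
    "load_tables",
    "classify_slope",
    "classify_cover",
    "erodibility_class",
    "protection_level",
    "hazard_class",
    "icona_map",
    "IconaResult",
]

#: Erodibility symbols in increasing susceptibility order; rank = position + 1.
ERODIBILITY_SYMBOLS = ("EN", "EB", "EM", "EA", "EX")
#: Protection symbols from very high to very low conservation.
PROTECTION_SYMBOLS = ("MA", "A", "M", "B", "MB")
#: Land-use classes 1..6 in published order.
LAND_USE_NAMES = (
    "Dry Farming",
    "Irrigated Farming",
    "Sand Areas",
    "Rangeland",
    "Bare Land",
    "Rock Outcrops",
)

ERODIBILITY_RANK = {s: i + 1 for i, s in enumerate(ERODIBILITY_SYMBOLS)}
ERODIBILITY_FROM_RANK = {i + 1: s for i, s in enumerate(ERODIBILITY_SYMBOLS)}
PROTECTION_ORDER = {s: i + 1 for i, s in enumerate(PROTECTION_SYMBOLS)}  # 1 = MA


@dataclass(frozen=True)
class IconaTables:
    """The three lookup matrices plus the slope/cover bin edges.

    ``erodibility`` is a 5x5 array of erodibility ranks indexed by
    (slope_class - 1, litho_class - 1); ``protection`` a 6x4 array of
    protection-symbol indices (0 = MA .. 4 = MB) indexed by
    (landuse_class - 1, cover_class - 1); ``hazard`` a 5x5 array of hazard
    classes indexed by (protection index, erodibility rank - 1).
    """

    slope_bins_pct: tuple[float, ...]
    cover_bins_pct: tuple[float, ...]
    erodibility: np.ndarray
    protection: np.ndarray
    hazard: np.ndarray

    def content_hash(self) -> str:
        """Stable hash of the matrices, logged so non-default parses are traceable."""
        payload = json.dumps(
            {
                "slope_bins_pct": list(self.slope_bins_pct),
                "cover_bins_pct": list(self.cover_bins_pct),
                "erodibility": self.erodibility.tolist(),
                "protection": self.protection.tolist(),
                "hazard": self.hazard.tolist(),
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_tables(path=None) -> IconaTables:
    """Load lookup matrices from YAML; default = the packaged tables."""
    if path is None:
        text = resources.files("soilews").joinpath("data/icona_tables.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)

    ero = np.zeros((5, 5), dtype=int)
    for slope_cls in range(1, 6):
        row = raw["erodibility"][slope_cls]
        if len(row) != 5:
            raise ValueError(f"erodibility row {slope_cls} must have 5 cells")
        ero[slope_cls - 1] = [ERODIBILITY_RANK[s] for s in row]

    prot = np.zeros((6, 4), dtype=int)
    for i, name in enumerate(LAND_USE_NAMES):
        row = raw["protection"][name]
        if len(row) != 4:
            raise ValueError(f"protection row {name!r} must have 4 cells")
        prot[i] = [PROTECTION_SYMBOLS.index(s) for s in row]

    haz = np.zeros((5, 5), dtype=int)
    for i, sym in enumerate(PROTECTION_SYMBOLS):
        row = raw["hazard"][sym]
        if len(row) != 5:
            raise ValueError(f"hazard row {sym} must have 5 cells")
        haz[i] = row
    if not np.isin(haz, range(1, 6)).all():
        raise ValueError("hazard classes must be in 1..5")

    return IconaTables(
        slope_bins_pct=tuple(float(v) for v in raw["slope_bins_pct"]),
        cover_bins_pct=tuple(float(v) for v in raw["cover_bins_pct"]),
        erodibility=ero,
        protection=prot,
        hazard=haz,
    )


_DEFAULT_TABLES: IconaTables | None = None


def default_tables() -> IconaTables:
    global _DEFAULT_TABLES
    if _DEFAULT_TABLES is None:
        _DEFAULT_TABLES = load_tables()
    return _DEFAULT_TABLES


def classify_slope(slope_pct, tables: IconaTables | None = None):
    """Slope percent -> slope class 1..5.

    Bins are half-open [lo, hi) with the top bin unbounded: [0,3), [3,12),
    [12,20), [20,35), [35,inf). Scalar in, scalar out; array in, array out.
    """
    tables = tables or default_tables()
    slope = np.asarray(slope_pct, dtype=float)
    if np.any(slope < 0):
        raise ValueError("slope percent must be >= 0")
    cls = np.digitize(slope, tables.slope_bins_pct[1:], right=False) + 1
    return cls if cls.ndim else int(cls)


def classify_cover(cover_pct, tables: IconaTables | None = None):
    """Vegetation-cover percent -> cover class 1..4.

    Bins [0,25), [25,50), [50,75), [75,100]; values outside [0, 100] raise.
    """
    tables = tables or default_tables()
    cover = np.asarray(cover_pct, dtype=float)
    if np.any((cover < 0) | (cover > 100)):
        raise ValueError("cover percent must be in [0, 100]")
    cls = np.digitize(cover, tables.cover_bins_pct[1:], right=False) + 1
    return cls if cls.ndim else int(cls)


def _check_range(arr, lo, hi, what):
    arr = np.asarray(arr, dtype=int)
    if np.any((arr < lo) | (arr > hi)):
        raise ValueError(f"{what} must be in {lo}..{hi}")
    return arr


def erodibility_class(slope_class, litho_class, tables: IconaTables | None = None):
    """(slope class 1..5, lithofacies class 1..5) -> erodibility rank 1..5.

    Rank 1=EN (very low) .. 5=EX (very high); use
    :data:`ERODIBILITY_FROM_RANK` for the symbol.
    """
    tables = tables or default_tables()
    s = _check_range(slope_class, 1, 5, "slope class")
    g = _check_range(litho_class, 1, 5, "lithofacies class")
    out = tables.erodibility[s - 1, g - 1]
    return out if out.ndim else int(out)


def protection_level(landuse_class, cover_class, tables: IconaTables | None = None):
    """(land-use class 1..6, cover class 1..4) -> protection symbol.

    Scalar inputs return the symbol string; arrays return the 0-based symbol
    index into :data:`PROTECTION_SYMBOLS` (vectorised form for map algebra).
    """
    tables = tables or default_tables()
    lu = _check_range(landuse_class, 1, 6, "land-use class")
    cov = _check_range(cover_class, 1, 4, "cover class")
    idx = tables.protection[lu - 1, cov - 1]
    if idx.ndim:
        return idx
    return PROTECTION_SYMBOLS[int(idx)]


def hazard_class(protection, erodibility, tables: IconaTables | None = None):
    """(protection level, erodibility rank 1..5) -> hazard class 1..5.

    ``protection`` may be a symbol string (scalar) or an array of 0-based
    symbol indices as returned by the vectorised :func:`protection_level`.
    """
    tables = tables or default_tables()
    if isinstance(protection, str):
        if protection not in PROTECTION_SYMBOLS:
            raise ValueError(f"unknown protection symbol {protection!r}")
        p = np.asarray(PROTECTION_SYMBOLS.index(protection))
    else:
        p = _check_range(protection, 0, 4, "protection index")
    e = _check_range(erodibility, 1, 5, "erodibility rank")
    out = tables.hazard[p, e - 1]
    return out if out.ndim else int(out)


@dataclass
class IconaResult:
    """Hazard map plus the intermediate class rasters and class-area summary."""

    hazard: np.ndarray  # int class 1..5; 0 where masked
    erodibility: np.ndarray  # rank 1..5; 0 where masked
    protection: np.ndarray  # 0-based symbol index; -1 where masked
    mask: np.ndarray
    class_areas: pd.DataFrame  # columns: hazard_class, n_pixels, percent
    tables_hash: str


def icona_map(layers: IconaLayers, tables: IconaTables | None = None) -> IconaResult:
    """Apply the full ICONA composition per pixel and summarise class areas.

    Masked cells are excluded from the summary; percentages over unmasked
    cells sum to 100.
    """
    tables = tables or default_tables()
    mask = layers.mask.copy()

    slope_cls = classify_slope(np.where(mask, 0.0, layers.slope_pct), tables)
    cover_cls = classify_cover(np.where(mask, 0.0, layers.cover_pct), tables)
    litho = np.where(mask, 1, layers.litho_class)
    landuse = np.where(mask, 1, layers.landuse_class)

    ero = erodibility_class(slope_cls, litho, tables)
    prot = protection_level(landuse, cover_cls, tables)
    haz = hazard_class(prot, ero, tables)

    haz = np.where(mask, 0, haz)
    ero = np.where(mask, 0, ero)
    prot = np.where(mask, -1, prot)

    valid = ~mask
    n_valid = int(valid.sum())
    rows = []
    if n_valid:
        for cls in range(1, 6):
            n = int(((haz == cls) & valid).sum())
            rows.append(
                {"hazard_class": cls, "n_pixels": n, "percent": 100.0 * n / n_valid}
            )
    summary = pd.DataFrame(rows, columns=["hazard_class", "n_pixels", "percent"])

    return IconaResult(
        hazard=haz,
        erodibility=ero,
        protection=prot,
        mask=mask,
        class_areas=summary,
        tables_hash=tables.content_hash(),
    )
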