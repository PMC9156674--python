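"""Burned-area mapping from seasonal composites and time-since-fire mosaics.

Fire detection follows the differenced Normalized Burn Ratio (dNBR) approach
on seasonal surface-reflectance composites. Early dry-season fires are mapped
from the difference between the March--May (MAM) and June--August (JJA)
composites; late dry-season fires from JJA versus September--November (SON).
For each season the all-year mean dNBR is subtracted cellwise to increase
contrast and remove static landscape features, and cells whose mean-adjusted
anomaly exceeds a cutoff (default 0.75 dNBR units, strictly greater) are
classed as burnt. Per-cell time since fire, long-unburnt (> 5 yr) patch
mosaics, and annual regime summaries are derived from the resulting stack of
boolean burn masks.

Grids are plain numpy arrays (row-major, cell (0, 0) at the raster origin)
with georeferencing carried by a :class:`GridSpec`; rasters are serialized as
ESRI ASCII grids and analysis masks as GeoJSON polygons rasterized by the
center-point rule.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import shape as _geojson_shape
from shapely.geometry.base import BaseGeometry
import shapely

logger = logging.getLogger(__name__)

#: Composite window pairs defining the two fire seasons (pre-window, post-window).
SEASON_WINDOWS: dict[str, tuple[str, str]] = {
    "early": ("MAM", "JJA"),
    "late": ("JJA", "SON"),
}
WINDOWS = ("MAM", "JJA", "SON")
SEASONS = ("early", "late")

#: Default dNBR-anomaly cutoff for fire presence (strictly greater than).
DEFAULT_CUTOFF = 0.75
#: Minimum years of prior record before time-since-fire is reported.
TSF_SPINUP_YEARS = 5
#: Patch age threshold (TSF strictly greater than this) for "long unburnt".
LONG_UNBURNT_MIN_AGE = 5
#: Default patch connectivity (queen's case, matching common landscape-metrics defaults).
DEFAULT_CONNECTIVITY = 8

ASCII_NODATA = -9999.0


# ---------------------------------------------------------------------------
# georeferencing and raster I/O
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Georeferencing of a row-major grid.

    ``origin_x``/``origin_y`` locate the *outer corner* of cell (0, 0)
    (upper-left, y decreasing down rows), ``cell_size`` is in meters.
    """

    nrows: int
    ncols: int
    cell_size: float
    origin_x: float = 0.0
    origin_y: float = 0.0
    crs: str = "local"

    def __post_init__(self) -> None:
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def cell_area_ha(self) -> float:
        return self.cell_size**2 / 1e4

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every cell center, each shaped (nrows, ncols)."""
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        x = self.origin_x + (cols + 0.5) * self.cell_size
        y = self.origin_y - (rows + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def bounds(self) -> tuple[float, float, float, float]:
        """(minx, miny, maxx, maxy) of the grid extent."""
        return (
            self.origin_x,
            self.origin_y - self.nrows * self.cell_size,
            self.origin_x + self.ncols * self.cell_size,
            self.origin_y,
        )


def rasterize_polygon(geom: BaseGeometry, grid: GridSpec) -> np.ndarray:
    """Boolean mask of cells whose *center* falls inside ``geom`` (center-point rule)."""
    xs, ys = grid.cell_centers()
    return shapely.contains_xy(geom, xs.ravel(), ys.ravel()).reshape(grid.shape)


def read_geojson_mask(path: str, grid: GridSpec) -> np.ndarray:
    """Rasterize the (first) polygon feature of a GeoJSON file onto ``grid``."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        geoms = [_geojson_shape(f["geometry"]) for f in gj["features"]]
        geom = shapely.union_all(geoms)
    elif gj.get("type") == "Feature":
        geom = _geojson_shape(gj["geometry"])
    else:
        geom = _geojson_shape(gj)
    return rasterize_polygon(geom, grid)


def write_ascii_grid(path: str, values: np.ndarray, grid: GridSpec) -> None:
    """Write a single-band raster as an ESRI ASCII grid (NaN -> nodata)."""
    arr = np.asarray(values, dtype=float)
    if arr.shape != grid.shape:
        raise ValueError("array shape does not match grid")
    out = np.where(np.isnan(arr), ASCII_NODATA, arr)
    header = (
        f"ncols {grid.ncols}\n"
        f"nrows {grid.nrows}\n"
        f"xllcorner {grid.origin_x}\n"
        f"yllcorner {grid.origin_y - grid.nrows * grid.cell_size}\n"
        f"cellsize {grid.cell_size}\n"
        f"NODATA_value {ASCII_NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.6g")


def read_ascii_grid(path: str, crs: str = "local") -> tuple[np.ndarray, GridSpec]:
    """Read an ESRI ASCII grid; nodata cells become NaN."""
    hdr: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines[:6]:
        key, val = line.split()
        hdr[key.lower()] = float(val)
    arr = np.loadtxt(lines[6:])
    arr = np.atleast_2d(arr)
    nodata = hdr.get("nodata_value", ASCII_NODATA)
    arr = np.where(arr == nodata, np.nan, arr)
    nrows, ncols = int(hdr["nrows"]), int(hdr["ncols"])
    grid = GridSpec(
        nrows=nrows,
        ncols=ncols,
        cell_size=hdr["cellsize"],
        origin_x=hdr["xllcorner"],
        origin_y=hdr["yllcorner"] + nrows * hdr["cellsize"],
        crs=crs,
    )
    return arr, grid


# ---------------------------------------------------------------------------
# composites and dNBR
# ---------------------------------------------------------------------------

@dataclass
class SeasonalComposite:
    """One season-window x year reflectance snapshot (NIR and SWIR bands).

    Reflectances are floats in [0, 1]; NaN marks nodata.
    """

    year: int
    window: str
    nir: np.ndarray
    swir: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        if self.window not in WINDOWS:
            raise ValueError(f"unknown season window {self.window!r}")
        self.nir = np.asarray(self.nir, dtype=float)
        self.swir = np.asarray(self.swir, dtype=float)
        if self.nir.shape != self.swir.shape:
            raise ValueError("NIR and SWIR grids must share shape")
        if self.nir.shape != self.grid.shape:
            raise ValueError("band shape does not match grid spec")


@dataclass
class DnbrAnomaly:
    """Mean-adjusted dNBR for one (year, season)."""

    year: int
    season: str
    values: np.ndarray


def compute_nbr(composite: SeasonalComposite) -> np.ndarray:
    """Normalized Burn Ratio (NIR - SWIR)/(NIR + SWIR); NaN where undefined."""
    nir, swir = composite.nir, composite.swir
    denom = nir + swir
    with np.errstate(invalid="ignore", divide="ignore"):
        nbr = (nir - swir) / denom
    nbr = np.where(denom == 0, np.nan, nbr)
    return nbr


def seasonal_dnbr(
    pre: SeasonalComposite, post: SeasonalComposite
) -> tuple[np.ndarray, str]:
    """dNBR = NBR(pre-window) - NBR(post-window) for one year's season pair.

    Returns the dNBR grid and the season label ('early' for MAM->JJA,
    'late' for JJA->SON).
    """
    if pre.year != post.year:
        raise ValueError(f"window pair spans years {pre.year} and {post.year}")
    for season, (w_pre, w_post) in SEASON_WINDOWS.items():
        if pre.window == w_pre and post.window == w_post:
            return compute_nbr(pre) - compute_nbr(post), season
    raise ValueError(
        f"({pre.window}, {post.window}) is not a valid season window pair"
    )


def mean_adjust(dnbr_by_year: dict[int, np.ndarray], season: str) -> list[DnbrAnomaly]:
    """Subtract the all-year mean dNBR of one season from each year, cellwise.

    Removes static landscape features (any per-cell constant present in every
    year cancels). Requires at least two years.
    """
    if len(dnbr_by_year) < 2:
        raise ValueError("mean adjustment requires at least 2 years per season")
    stack = np.stack([dnbr_by_year[y] for y in sorted(dnbr_by_year)])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
    return [
        DnbrAnomaly(year=y, season=season, values=dnbr_by_year[y] - mean)
        for y in sorted(dnbr_by_year)
    ]


def threshold_burns(anomaly: DnbrAnomaly | np.ndarray, cutoff: float = DEFAULT_CUTOFF) -> np.ndarray:
    """Boolean burn mask: anomaly strictly greater than ``cutoff``; NaN -> unburnt."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    values = anomaly.values if isinstance(anomaly, DnbrAnomaly) else np.asarray(anomaly)
    with np.errstate(invalid="ignore"):
        return np.greater(values, cutoff, where=~np.isnan(values), out=np.zeros(values.shape, dtype=bool))


# ---------------------------------------------------------------------------
# fire-history stack, time since fire, patches
# ---------------------------------------------------------------------------

@dataclass
class TsfGrid:
    """Per-cell years since the last detected burn at ``year``.

    ``censored`` marks cells with no burn on record; there ``values`` holds the
    years of record k (interpreted as TSF >= k).
    """

    year: int
    values: np.ndarray
    censored: np.ndarray


@dataclass
class FireHistoryStack:
    """Per-(year, season) boolean burn masks plus the analysis mask."""

    burns: dict[tuple[int, str], np.ndarray]
    mask: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        for key, m in self.burns.items():
            if m.shape != self.mask.shape:
                raise ValueError(f"burn mask {key} shape mismatch")
            self.burns[key] = np.asarray(m, dtype=bool)

    @property
    def years(self) -> list[int]:
        return sorted({y for (y, _s) in self.burns})

    def annual_burn(self, year: int) -> np.ndarray:
        """Union of the early and late masks for one year."""
        out = np.zeros(self.mask.shape, dtype=bool)
        for season in SEASONS:
            m = self.burns.get((year, season))
            if m is not None:
                out |= m
        return out


def time_since_fire(stack: FireHistoryStack, query_year: int) -> TsfGrid:
    """Years since the most recent burn (any season) up to and including ``query_year``.

    Only defined once at least :data:`TSF_SPINUP_YEARS` years of history
    precede the query. Cells never seen burning are censored at the record
    length.
    """
    years = stack.years
    if not years:
        raise ValueError("empty fire-history stack")
    first = years[0]
    if query_year < first + TSF_SPINUP_YEARS:
        raise ValueError(
            f"query year {query_year} precedes the {TSF_SPINUP_YEARS}-year spin-up "
            f"(record starts {first})"
        )
    last_burn = np.full(stack.mask.shape, -1, dtype=int)
    for y in years:
        if y > query_year:
            break
        burnt = stack.annual_burn(y)
        last_burn[burnt] = y
    censored = last_burn < 0
    record_len = query_year - first + 1
    values = np.where(censored, record_len, query_year - last_burn)
    return TsfGrid(year=query_year, values=values, censored=censored)


@dataclass
class Patch:
    patch_id: int
    cell_count: int
    area_ha: float


@dataclass
class PatchSet:
    """Disjoint connected components of long-unburnt cells inside the mask."""

    patches: list[Patch]
    connectivity: int
    year: int
    labels: np.ndarray = field(repr=False)

    @property
    def total_area_ha(self) -> float:
        return sum(p.area_ha for p in self.patches)

    @property
    def mean_patch_ha(self) -> float:
        if not self.patches:
            return float("nan")
        return float(np.mean([p.area_ha for p in self.patches]))


def long_unburnt_patches(
    tsf: TsfGrid,
    mask: np.ndarray,
    grid: GridSpec,
    min_age: int = LONG_UNBURNT_MIN_AGE,
    connectivity: int = DEFAULT_CONNECTIVITY,
) -> PatchSet:
    """Connected patches of cells with TSF > ``min_age`` inside the mask.

    Censored (never-burnt) cells qualify once the record itself exceeds
    ``min_age`` years, which their censored value (>= record length) encodes.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty analysis mask")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    eligible = (tsf.values > min_age) & mask
    structure = ndimage.generate_binary_structure(2, 1 if connectivity == 4 else 2)
    labels, n = ndimage.label(eligible, structure=structure)
    counts = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    patches = [
        Patch(patch_id=i + 1, cell_count=int(c), area_ha=float(c) * grid.cell_area_ha)
        for i, c in enumerate(counts)
    ]
    return PatchSet(patches=patches, connectivity=connectivity, year=tsf.year, labels=labels)


# ---------------------------------------------------------------------------
# end-to-end mapping and regime summaries
# ---------------------------------------------------------------------------

def map_fire_history(
    composites: list[SeasonalComposite],
    mask: np.ndarray,
    cutoff: float = DEFAULT_CUTOFF,
    threshold_on: str = "anomaly",
) -> FireHistoryStack:
    """Run the full dNBR pipeline: pair windows, difference, mean-adjust, threshold.

    ``threshold_on`` selects whether the cutoff applies to the mean-adjusted
    anomaly (default, following the stated pipeline order) or to raw dNBR.
    """
    if threshold_on not in ("anomaly", "raw"):
        raise ValueError("threshold_on must be 'anomaly' or 'raw'")
    by_key = {(c.year, c.window): c for c in composites}
    grid = composites[0].grid
    burns: dict[tuple[int, str], np.ndarray] = {}
    for season, (w_pre, w_post) in SEASON_WINDOWS.items():
        dnbr_by_year: dict[int, np.ndarray] = {}
        for (year, window), comp in by_key.items():
            if window != w_pre:
                continue
            post = by_key.get((year, w_post))
            if post is None:
                logger.warning("year %d lacks %s composite; season %s skipped", year, w_post, season)
                continue
            dnbr_by_year[year], _ = seasonal_dnbr(comp, post)
        if not dnbr_by_year:
            continue
        if threshold_on == "anomaly":
            anomalies = mean_adjust(dnbr_by_year, season)
        else:
            anomalies = [
                DnbrAnomaly(year=y, season=season, values=v)
                for y, v in sorted(dnbr_by_year.items())
            ]
        for anom in anomalies:
            burns[(anom.year, season)] = threshold_burns(anom, cutoff) & np.asarray(mask, bool)
    return FireHistoryStack(burns=burns, mask=np.asarray(mask, bool), grid=grid)


def summarize_regime(
    stack: FireHistoryStack,
    min_age: int = LONG_UNBURNT_MIN_AGE,
    connectivity: int = DEFAULT_CONNECTIVITY,
) -> pd.DataFrame:
    """Annual regime table over mask cells.

    Columns: year, p_early, p_late, p_total (union of seasons), mean_tsf,
    p_long_unburnt, mean_patch_ha. TSF-derived columns are NaN during the
    spin-up years; censored cells enter mean_tsf at their record length
    (a lower bound).
    """
    mask = stack.mask
    n_mask = int(mask.sum())
    if n_mask == 0:
        raise ValueError("empty analysis mask")
    rows = []
    first = stack.years[0]
    for year in stack.years:
        p = {}
        for season in SEASONS:
            m = stack.burns.get((year, season), np.zeros_like(mask))
            p[season] = float((m & mask).sum()) / n_mask
        p_total = float((stack.annual_burn(year) & mask).sum()) / n_mask
        mean_tsf = p_lu = mean_patch = float("nan")
        if year >= first + TSF_SPINUP_YEARS:
            tsf = time_since_fire(stack, year)
            mean_tsf = float(tsf.values[mask].mean())
            eligible = (tsf.values > min_age) & mask
            p_lu = float(eligible.sum()) / n_mask
            if eligible.any():
                ps = long_unburnt_patches(tsf, mask, stack.grid, min_age, connectivity)
                mean_patch = ps.mean_patch_ha
        rows.append(
            {
                "year": year,
                "p_early": p["early"],
                "p_late": p["late"],
                "p_total": p_total,
                "mean_tsf": mean_tsf,
                "p_long_unburnt": p_lu,
                "mean_patch_ha": mean_patch,
            }
        )
    return pd.DataFrame(rows)
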