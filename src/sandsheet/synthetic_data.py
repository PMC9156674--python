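"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator is a pure function of its scenario (including the scenario
seed): running it twice yields bit-identical output. One master
``numpy.random.SeedSequence`` per scenario is split into named child streams
(one per independent source of randomness), so adding a stream never
perturbs the others.

The generators emulate the *shape* of the field and satellite data — seasonal
composite stacks containing burn scars of known footprint and season over
static landscape features, Thomas-process grove/singleton stem maps,
size-class-specific Bernoulli survival chains, ring-width series consistent
with known establishment years, and regional fuel samples with unequal
medians and unequal upper-tail spread — not their physics. Reflectance is
constructed directly from target NBR values; there is no radiative transfer,
topography, or fire spread.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Point, box
from shapely.geometry.base import BaseGeometry

from .fire_history import (
    GridSpec,
    SeasonalComposite,
    rasterize_polygon,
)
from .growth_dating import age_at_height, round_half_up, PITH_ESTIMATOR_RINGS
from .demography import SCHEME_A_CLASSES, SCHEME_B_CLASSES

#: Baseline NBR of unburnt vegetation in synthetic composites.
BASE_NBR = 0.5


def _streams(seed: int, names: tuple[str, ...]) -> dict[str, np.random.Generator]:
    """Split one scenario seed into named, order-stable child generators."""
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


# ---------------------------------------------------------------------------
# fire landscapes
# ---------------------------------------------------------------------------

@dataclass
class FireEvent:
    """One burn scar: footprint polygon, calendar year, season, dNBR amplitude."""

    year: int
    season: str  # 'early' or 'late'
    footprint: BaseGeometry
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.season not in ("early", "late"):
            raise ValueError("season must be 'early' or 'late'")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")


def disc(x: float, y: float, radius_m: float) -> BaseGeometry:
    """Convenience circular footprint."""
    return Point(x, y).buffer(radius_m)


@dataclass
class FireScenario:
    """A multi-year landscape with known burn scars.

    ``static_sd`` controls a smooth random field added identically to every
    year's dNBR (static landscape features such as drainage lines); mean
    adjustment downstream must remove it exactly. ``noise_sd`` is i.i.d.
    per-cell, per-composite-pair noise in dNBR units.
    """

    nrows: int = 100
    ncols: int = 100
    cell_size: float = 30.0
    year_start: int = 1990
    year_end: int = 2020
    events: list[FireEvent] = dataclass_field(default_factory=list)
    static_sd: float = 0.05
    static_field: np.ndarray | None = None
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.year_end - self.year_start + 1 < 2:
            raise ValueError("scenario must span at least 2 years")
        if self.noise_sd < 0 or self.static_sd < 0:
            raise ValueError("noise levels must be non-negative")
        grid = self.grid
        minx, miny, maxx, maxy = grid.bounds()
        extent = box(minx, miny, maxx, maxy)
        for ev in self.events:
            if not (self.year_start <= ev.year <= self.year_end):
                raise ValueError(f"event year {ev.year} outside scenario span")
            if not extent.covers(ev.footprint):
                raise ValueError("fire footprint extends outside the grid")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(
            nrows=self.nrows,
            ncols=self.ncols,
            cell_size=self.cell_size,
            origin_x=0.0,
            origin_y=self.nrows * self.cell_size,
        )

    @property
    def years(self) -> range:
        return range(self.year_start, self.year_end + 1)


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sd: float) -> np.ndarray:
    """Smooth zero-mean random field with marginal standard deviation ``sd``."""
    if sd == 0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, sigma=3.0, mode="reflect")
    smooth -= smooth.mean()
    s = smooth.std()
    return smooth * (sd / s) if s > 0 else smooth


def gen_fire_landscape(
    scenario: FireScenario,
) -> tuple[list[SeasonalComposite], dict[tuple[int, str], np.ndarray]]:
    """Seasonal composite stack plus true per-(year, season) burn masks.

    For each year three composites (MAM, JJA, SON) are built so that the
    seasonal dNBR (pre minus post window) equals fire amplitude inside true
    footprints, plus the static field, plus noise. NBR is inverted to NIR and
    SWIR bands with NIR + SWIR = 1.
    """
    grid = scenario.grid
    rngs = _streams(scenario.seed, ("static", "noise"))
    static = (
        np.asarray(scenario.static_field, dtype=float)
        if scenario.static_field is not None
        else _smooth_field(rngs["static"], grid.shape, scenario.static_sd)
    )
    truth: dict[tuple[int, str], np.ndarray] = {
        (y, s): np.zeros(grid.shape, dtype=bool)
        for y in scenario.years
        for s in ("early", "late")
    }
    signal: dict[tuple[int, str], np.ndarray] = {
        key: np.zeros(grid.shape) for key in truth
    }
    for ev in scenario.events:
        mask = rasterize_polygon(ev.footprint, grid)
        truth[(ev.year, ev.season)] |= mask
        signal[(ev.year, ev.season)] += ev.amplitude * mask

    composites: list[SeasonalComposite] = []
    noise_rng = rngs["noise"]
    for year in scenario.years:
        dnbr_early = signal[(year, "early")] + static
        dnbr_late = signal[(year, "late")] + static
        if scenario.noise_sd > 0:
            dnbr_early = dnbr_early + noise_rng.normal(0, scenario.noise_sd, grid.shape)
            dnbr_late = dnbr_late + noise_rng.normal(0, scenario.noise_sd, grid.shape)
        nbr = {"MAM": np.full(grid.shape, BASE_NBR)}
        nbr["JJA"] = nbr["MAM"] - dnbr_early
        nbr["SON"] = nbr["JJA"] - dnbr_late
        for window, values in nbr.items():
            composites.append(
                SeasonalComposite(
                    year=year,
                    window=window,
                    nir=(1.0 + values) / 2.0,
                    swir=(1.0 - values) / 2.0,
                    grid=grid,
                )
            )
    return composites, truth


# ---------------------------------------------------------------------------
# tree populations (Thomas cluster process)
# ---------------------------------------------------------------------------

#: Dimension ranges (height m, D1.0 cm) drawn uniformly per scheme-A class.
_CLASS_DIMS = {
    "seedling": ((0.01, 0.0999), None),
    "sapling": ((0.1, 2.199), None),
    "small": ((2.2, 8.0), (1.0, 9.999)),
    "medium": ((4.0, 12.0), (10.0, 19.999)),
    "large": ((8.0, 16.0), (20.0, 29.999)),
    "very_large": ((10.0, 20.0), (30.0, 60.0)),
}


@dataclass
class PopulationScenario:
    """Grove/singleton stem map generator settings (Thomas cluster process)."""

    domain: BaseGeometry
    parent_intensity_ha: float = 2.0
    mean_offspring: float = 10.0
    dispersal_scale_m: float = 8.0
    singleton_intensity_ha: float = 1.0
    class_mixture: tuple[float, ...] = (0.25, 0.25, 0.2, 0.15, 0.1, 0.05)
    dead_proportion: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.domain.is_empty or self.domain.area == 0:
            raise ValueError("domain polygon is empty")
        if min(self.parent_intensity_ha, self.singleton_intensity_ha, self.mean_offspring) < 0:
            raise ValueError("intensities must be non-negative")
        if not 0 <= self.dead_proportion <= 1:
            raise ValueError("dead proportion must lie in [0, 1]")
        if len(self.class_mixture) != len(SCHEME_A_CLASSES):
            raise ValueError(f"mixture needs {len(SCHEME_A_CLASSES)} proportions")
        if abs(sum(self.class_mixture) - 1.0) > 1e-9:
            raise ValueError("mixture proportions must sum to 1")


def _poisson_points(
    rng: np.random.Generator, domain: BaseGeometry, intensity_ha: float
) -> np.ndarray:
    """Homogeneous Poisson points inside ``domain`` (rejection from the bbox)."""
    import shapely

    minx, miny, maxx, maxy = domain.bounds
    bbox_area_ha = (maxx - minx) * (maxy - miny) / 1e4
    n = rng.poisson(intensity_ha * bbox_area_ha)
    if n == 0:
        return np.empty((0, 2))
    pts = np.column_stack(
        [rng.uniform(minx, maxx, n), rng.uniform(miny, maxy, n)]
    )
    inside = shapely.contains_xy(domain, pts[:, 0], pts[:, 1])
    return pts[inside]


def gen_tree_population(scenario: PopulationScenario) -> pd.DataFrame:
    """Stem map: clustered grove stems plus independent singletons.

    Parents follow a homogeneous Poisson process; each parent spawns a
    Poisson number of offspring displaced by isotropic Gaussian jumps
    (offspring falling outside the domain are dropped, as are the parents
    themselves — parents are latent cluster centers). Singletons are an
    independent Poisson process. Columns: tag, x, y, origin, size_class,
    height_m, d1p0_cm, status.
    """
    import shapely

    rngs = _streams(
        scenario.seed, ("parents", "offspring", "singletons", "marks")
    )
    parents = _poisson_points(rngs["parents"], scenario.domain, scenario.parent_intensity_ha)
    off_rng = rngs["offspring"]
    stems: list[tuple[float, float, str]] = []
    for px, py in parents:
        k = off_rng.poisson(scenario.mean_offspring)
        if k == 0:
            continue
        jumps = off_rng.normal(0.0, scenario.dispersal_scale_m, size=(k, 2))
        pts = np.array([px, py]) + jumps
        inside = shapely.contains_xy(scenario.domain, pts[:, 0], pts[:, 1])
        stems.extend((float(x), float(y), "grove") for x, y in pts[inside])
    singles = _poisson_points(rngs["singletons"], scenario.domain, scenario.singleton_intensity_ha)
    stems.extend((float(x), float(y), "singleton") for x, y in singles)

    mark_rng = rngs["marks"]
    n = len(stems)
    classes = mark_rng.choice(
        len(SCHEME_A_CLASSES), size=n, p=np.asarray(scenario.class_mixture)
    )
    rows = []
    for i, ((x, y, origin), ci) in enumerate(zip(stems, classes)):
        cls = SCHEME_A_CLASSES[ci]
        (h_lo, h_hi), d_range = _CLASS_DIMS[cls]
        height = float(mark_rng.uniform(h_lo, h_hi))
        d1p0 = float(mark_rng.uniform(*d_range)) if d_range else np.nan
        dead = bool(mark_rng.random() < scenario.dead_proportion)
        rows.append(
            {
                "tag": f"T{i:05d}",
                "x": x,
                "y": y,
                "origin": origin,
                "size_class": cls,
                "height_m": height,
                "d1p0_cm": d1p0,
                "status": "dead" if dead else "live",
            }
        )
    columns = ["tag", "x", "y", "origin", "size_class", "height_m", "d1p0_cm", "status"]
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# survival histories
# ---------------------------------------------------------------------------

@dataclass
class SurvivalScenario:
    """Per-size-class annual survival truth for the longitudinal study.

    Defaults mirror the longitudinal design: tagging in 2006, relocations
    through 2019, six classes with the published tagging counts.
    """

    annual_survival: dict[str, float] = dataclass_field(
        default_factory=lambda: {
            "juvenile": 0.70,
            "very_small": 0.95,
            "small": 0.97,
            "medium": 0.975,
            "large": 0.988,
            "very_large": 0.959,
        }
    )
    census_years: tuple[int, ...] = (2006, 2007, 2008, 2009, 2016, 2019)
    initial_counts: dict[str, int] = dataclass_field(
        default_factory=lambda: {
            "juvenile": 385,
            "very_small": 52,
            "small": 94,
            "medium": 166,
            "large": 175,
            "very_large": 220,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for cls, p in self.annual_survival.items():
            if not 0 <= p <= 1:
                raise ValueError(f"survival probability for {cls} outside [0, 1]")
        if list(self.census_years) != sorted(set(self.census_years)):
            raise ValueError("census years must be strictly increasing")
        if len(self.census_years) < 2:
            raise ValueError("need at least two censuses")


def gen_survival_histories(scenario: SurvivalScenario) -> pd.DataFrame:
    """Tagged-tree census table from per-class annual Bernoulli survival chains.

    Death is absorbing: each tagged tree survives each year independently
    with its class probability until it dies. Columns: tag, size_class, and
    one status_<year> column ('live'/'dead') per census year.
    """
    rng = _streams(scenario.seed, ("survival",))["survival"]
    start = scenario.census_years[0]
    horizon = scenario.census_years[-1] - start
    rows = []
    i = 0
    for cls in SCHEME_B_CLASSES:
        n0 = scenario.initial_counts.get(cls, 0)
        p = scenario.annual_survival.get(cls, 1.0)
        if n0 == 0:
            continue
        # death year offset: first failed annual Bernoulli trial (inf = survived)
        draws = rng.random((n0, horizon))
        died = draws >= p
        death_offset = np.where(died.any(axis=1), died.argmax(axis=1) + 1, horizon + 1)
        for d in death_offset:
            row = {"tag": f"S{i:05d}", "size_class": cls}
            for cy in scenario.census_years:
                row[f"status_{cy}"] = "live" if (cy - start) < d else "dead"
            rows.append(row)
            i += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ring-width series
# ---------------------------------------------------------------------------

@dataclass
class TreeRingSpec:
    """Ground truth for one synthetic dated sample."""

    tag: str
    establishment_year: int
    sample_height_cm: float = 100.0
    sample_type: str = "core"
    pith_offset: int = 0
    segment: str = "all"


@dataclass
class RingScenario:
    """Settings for synthetic cross-dated ring-width series."""

    trees: list[TreeRingSpec]
    end_year: int = 2015
    mean_ring_width_mm: float = 1.5
    ring_width_cv: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_ring_width_mm <= 0:
            raise ValueError("mean ring width must be positive")
        if self.ring_width_cv < 0:
            raise ValueError("ring width variability must be non-negative")
        for t in self.trees:
            if t.pith_offset < 0:
                raise ValueError("pith offset must be non-negative")
            if t.establishment_year > self.end_year:
                raise ValueError("establishment after series end")


def gen_ring_series(
    scenario: RingScenario,
) -> tuple[dict[str, tuple[int, np.ndarray]], pd.DataFrame]:
    """Dated ring series plus a metadata sidecar, consistent with known truth.

    The first dated ring year of each series is
    establishment + round(seedling age at sample height) + pith offset, so the
    dating pipeline's establishment estimate inverts the construction exactly.
    The sidecar distance-to-pith is backed out of the generated inner-ring
    widths so that the pith estimator recovers the specified offset.
    """
    rng = _streams(scenario.seed, ("widths",))["widths"]
    series: dict[str, tuple[int, np.ndarray]] = {}
    meta_rows = []
    for tree in scenario.trees:
        height_corr = round_half_up(age_at_height(tree.sample_height_cm))
        first_ring_year = tree.establishment_year + height_corr + tree.pith_offset
        n_rings = scenario.end_year - first_ring_year + 1
        if n_rings < max(1, PITH_ESTIMATOR_RINGS if tree.pith_offset else 1):
            raise ValueError(
                f"tree {tree.tag}: implied ring count {n_rings} too small "
                f"(establishment {tree.establishment_year}, corrections "
                f"{height_corr}+{tree.pith_offset})"
            )
        sigma = scenario.ring_width_cv
        widths = scenario.mean_ring_width_mm * np.exp(
            rng.normal(-0.5 * sigma**2, sigma, n_rings)
        )
        widths = np.round(widths, 2)  # .rwl carries 0.01 mm precision
        widths[widths < 0.01] = 0.01
        inner_mean = widths[:PITH_ESTIMATOR_RINGS].mean() if tree.pith_offset else 0.0
        distance = tree.pith_offset * inner_mean
        series[tree.tag] = (first_ring_year, widths)
        meta_rows.append(
            {
                "series_id": tree.tag,
                "sample_height_cm": tree.sample_height_cm,
                "sample_type": tree.sample_type,
                "distance_to_pith_mm": distance,
                "segment": tree.segment,
            }
        )
    return series, pd.DataFrame(meta_rows)


# ---------------------------------------------------------------------------
# fuel samples
# ---------------------------------------------------------------------------

@dataclass
class RegionFuel:
    """One region's dry-load distribution: lognormal with given median and spread."""

    name: str
    median_dry_g_m2: float
    upper_tail_sigma: float  # lognormal sigma; larger = heavier upper tail

    def __post_init__(self) -> None:
        if self.median_dry_g_m2 < 0:
            raise ValueError("median load must be non-negative")
        if self.upper_tail_sigma < 0:
            raise ValueError("tail scale must be non-negative")


@dataclass
class FuelScenario:
    """Regional fuel-sampling design: segments x quadrats per region.

    Defaults echo the field design: two regions with unequal medians and
    unequal upper-tail spread, eight 0.25 m^2 quadrats per 100-m segment.
    """

    regions: list[RegionFuel] = dataclass_field(
        default_factory=lambda: [
            RegionFuel("Dukaladjarranj", 70.0, 0.4),
            RegionFuel("Kakadu", 110.0, 0.8),
        ]
    )
    segments_per_region: int = 20
    quadrats_per_segment: int = 8
    quadrat_area_m2: float = 0.25
    moisture_beta: tuple[float, float] = (2.0, 6.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.quadrat_area_m2 <= 0:
            raise ValueError("quadrat area must be positive")
        if self.segments_per_region < 1 or self.quadrats_per_segment < 1:
            raise ValueError("need at least one segment and quadrat")


def gen_fuel_samples(scenario: FuelScenario) -> pd.DataFrame:
    """Quadrat table with known per-region dry-load medians and tail spread.

    Dry loads are lognormal (median = exp(mu)); moisture fractions are Beta
    draws in [0, 1); fresh weight back-computes as dry weight / (1 -
    moisture) so the dry-load conversion downstream recovers the truth
    exactly. Columns: region, segment, quadrat, area_m2, fresh_weight_g,
    moisture_fraction.
    """
    rng = _streams(scenario.seed, ("fuel",))["fuel"]
    rows = []
    a, b = scenario.moisture_beta
    for region in scenario.regions:
        n = scenario.segments_per_region * scenario.quadrats_per_segment
        dry = region.median_dry_g_m2 * np.exp(
            rng.normal(0.0, region.upper_tail_sigma, n)
        )
        moisture = np.minimum(rng.beta(a, b, n), 0.999)
        dry_weight_g = dry * scenario.quadrat_area_m2
        fresh = dry_weight_g / (1.0 - moisture)
        for i in range(n):
            rows.append(
                {
                    "region": region.name,
                    "segment": f"{region.name[:3]}-{i // scenario.quadrats_per_segment:03d}",
                    "quadrat": i % scenario.quadrats_per_segment,
                    "area_m2": scenario.quadrat_area_m2,
                    "fresh_weight_g": float(fresh[i]),
                    "moisture_fraction": float(moisture[i]),
                }
            )
    return pd.DataFrame(rows)
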