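"""Stand structure, stand status, and longitudinal survival of C. intratropica.

Two size-class schemes are in use, reflecting the two field designs:

* scheme A (transect structure surveys): seedling (< 0.1 m tall), sapling
  (0.1-2.2 m), then by diameter at 1 m (D1.0): small (< 10 cm), medium
  (10-20), large (20-30), very large (>= 30);
* scheme B (longitudinal tagged-tree study): juvenile (< 1.5 m tall), then
  by D1.0: very small (< 5 cm), small (5-10), medium (10-20), large (20-30),
  very large (>= 30).

All interval boundaries are lower-inclusive / upper-exclusive (a 10.0 cm stem
is "medium"), which resolves the overlap in the printed ranges.

Annualized survival over a monitoring interval of y years is
(N2/N1)^(1/y) x 100, with N1 live individuals at the start and N2 at the end;
missing individuals are assumed dead. Class membership is frozen at the
tagging census, so per-class survival refers to the class a tree was in when
tagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .growth_dating import age_at_height

#: Mean radial diameter growth rate used for indicative ages (mm per year).
DIAMETER_GROWTH_MM_YR = 2.5
#: Sampling band half-widths (m from transect midline) per broad class group.
BAND_HALF_WIDTH_M = {"seedling": 2.0, "sapling": 25.0, "tree": 25.0}

SCHEME_A_CLASSES = ("seedling", "sapling", "small", "medium", "large", "very_large")
SCHEME_B_CLASSES = ("juvenile", "very_small", "small", "medium", "large", "very_large")

#: D1.0 (cm) class edges shared by both schemes for established trees.
_DIAMETER_EDGES = ((10.0, "small"), (20.0, "medium"), (30.0, "large"))


def _diameter_class(d1_0: float, small_label: str = "small", lowest_edge: float | None = None):
    if d1_0 >= 30.0:
        return "very_large"
    if d1_0 >= 20.0:
        return "large"
    if d1_0 >= 10.0:
        return "medium"
    if lowest_edge is not None and d1_0 < lowest_edge:
        return None  # caller handles the sub-threshold class
    return small_label


def assign_size_class(
    height_m: float | None,
    d1_0_cm: float | None,
    scheme: str = "A",
) -> str:
    """Deterministic size-class label under scheme 'A' or 'B'.

    Height decides the juvenile classes; D1.0 decides the rest and is
    required for stems above the scheme's height threshold.
    """
    if scheme == "A":
        if height_m is not None and height_m < 2.2:
            return "seedling" if height_m < 0.1 else "sapling"
        if d1_0_cm is None:
            raise ValueError("stem >= 2.2 m tall requires D1.0 under scheme A")
        return _diameter_class(d1_0_cm)
    if scheme == "B":
        if height_m is not None and height_m < 1.5:
            return "juvenile"
        if d1_0_cm is None:
            raise ValueError("stem >= 1.5 m tall requires D1.0 under scheme B")
        cls = _diameter_class(d1_0_cm, lowest_edge=5.0)
        return "very_small" if cls is None else cls
    raise ValueError(f"unknown scheme {scheme!r}")


# ---------------------------------------------------------------------------
# transect densities
# ---------------------------------------------------------------------------

def _band_group(size_class: str) -> str:
    if size_class == "seedling":
        return "seedling"
    if size_class == "sapling":
        return "sapling"
    return "tree"


def segment_densities(
    stem_map: pd.DataFrame,
    segments: pd.DataFrame,
    band_half_width_m: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-size-class stem densities (ha^-1): mean and SE across segments.

    ``stem_map`` needs columns segment, dist_m (distance from the transect
    midline), size_class, status ('live'/'dead'); ``segments`` needs columns
    segment and length_m. Each class is scaled by its own sampled band area:
    seedlings are counted only within 2 m of the midline, saplings and trees
    within 25 m (configurable). Segments are the replicated unit for the SE.
    """
    bands = dict(BAND_HALF_WIDTH_M)
    if band_half_width_m:
        bands.update(band_half_width_m)
    if (segments["length_m"] <= 0).any():
        raise ValueError("zero- or negative-length segment")
    seg_ids = segments["segment"].tolist()
    rows = []
    for size_class in sorted(stem_map["size_class"].unique()) if len(stem_map) else []:
        half = bands[_band_group(size_class)]
        for status in ("live", "dead"):
            sub = stem_map[
                (stem_map["size_class"] == size_class)
                & (stem_map["status"] == status)
                & (stem_map["dist_m"].abs() <= half)
            ]
            counts = sub.groupby("segment").size().reindex(seg_ids, fill_value=0)
            area_ha = segments.set_index("segment")["length_m"] * 2 * half / 1e4
            dens = counts / area_ha
            se = float(dens.std(ddof=1) / np.sqrt(len(dens))) if len(dens) > 1 else 0.0
            rows.append(
                {
                    "size_class": size_class,
                    "status": status,
                    "mean_density_ha": float(dens.mean()),
                    "se_density_ha": se,
                    "n_segments": len(dens),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def annualized_survival(n1: float, n2: float, years: float) -> float:
    """Annualized survival percentage (N2/N1)^(1/y) x 100, one decimal.

    N1 must be positive, N2 cannot exceed N1, and the interval must be
    positive. Missing individuals should already be counted as dead.
    """
    if n1 <= 0:
        raise ValueError("N1 must be positive")
    if n2 > n1:
        raise ValueError("N2 cannot exceed N1")
    if n2 < 0:
        raise ValueError("N2 must be non-negative")
    if years <= 0:
        raise ValueError("interval must be positive")
    return round((n2 / n1) ** (1.0 / years) * 100.0, 1)


def survival_by_class(
    census: pd.DataFrame, start_year: int, end_year: int
) -> pd.DataFrame:
    """Raw and annualized percent survival per size class between two censuses.

    ``census`` needs a size_class column (class at tagging; membership is
    frozen there) and status_<year> columns with values 'live'/'dead'/'missing'.
    Missing individuals count as dead.
    """
    if end_year <= start_year:
        raise ValueError("end census must postdate start census")
    s_col, e_col = f"status_{start_year}", f"status_{end_year}"
    for col in (s_col, e_col):
        if col not in census.columns:
            raise ValueError(f"census table lacks column {col}")
    alive_start = census[census[s_col] == "live"]
    rows = []
    y = end_year - start_year
    for cls, grp in alive_start.groupby("size_class", sort=False):
        n1 = len(grp)
        n2 = int((grp[e_col] == "live").sum())
        rows.append(
            {
                "size_class": cls,
                "n_start": n1,
                "n_end": n2,
                "raw_survival_pct": round(100.0 * n2 / n1, 1),
                "annualized_survival_pct": annualized_survival(n1, n2, y),
            }
        )
    order = {c: i for i, c in enumerate(SCHEME_B_CLASSES)}
    rows.sort(key=lambda r: order.get(r["size_class"], 99))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stand status
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StandStatusRule:
    """Numeric thresholds operationalizing the qualitative stand categories.

    The published categories (healthy, degraded, recovering, singleton, new)
    are verbal; these defaults make them reproducible and every threshold is
    explicit in the result.
    """

    healthy_min_live: int = 3
    healthy_min_classes: int = 3
    singleton_max_stems: int = 2
    singleton_max_juveniles: int = 2
    recovering_min_juveniles: int = 3


@dataclass
class StandStatus:
    segment: str
    status: str
    rule: StandStatusRule = field(repr=False, default_factory=StandStatusRule)


def classify_stand_status(
    segment: str,
    live_counts: dict[str, int],
    dead_counts: dict[str, int],
    rule: StandStatusRule | None = None,
    scheme_classes: tuple[str, ...] = SCHEME_A_CLASSES,
) -> StandStatus:
    """Assign one status per transect segment from per-class live/dead counts.

    Precedence: absent (no stems) -> new (juveniles only) -> singleton (1-2
    established stems, majority live, few juveniles) -> healthy (several live
    stems spanning several classes, live > dead) -> recovering (dead >= live
    among established stems but juveniles present) -> degraded (fallback).
    """
    rule = rule or StandStatusRule()
    juvenile_classes = {c for c in scheme_classes if c in ("seedling", "sapling", "juvenile")}
    tree_classes = [c for c in scheme_classes if c not in juvenile_classes]
    live_juv = sum(live_counts.get(c, 0) for c in juvenile_classes)
    live_trees = sum(live_counts.get(c, 0) for c in tree_classes)
    dead_trees = sum(dead_counts.get(c, 0) for c in tree_classes)
    total_stems = live_juv + live_trees + dead_trees

    if total_stems == 0:
        status = "absent"
    elif live_trees + dead_trees == 0:
        status = "new"
    elif (
        live_trees + dead_trees <= rule.singleton_max_stems
        and live_trees > dead_trees
        and live_juv <= rule.singleton_max_juveniles
    ):
        status = "singleton"
    elif (
        live_trees >= rule.healthy_min_live
        and sum(1 for c in tree_classes if live_counts.get(c, 0) > 0) >= rule.healthy_min_classes
        and live_trees > dead_trees
    ):
        status = "healthy"
    elif dead_trees >= live_trees and live_juv >= rule.recovering_min_juveniles:
        status = "recovering"
    else:
        status = "degraded"
    return StandStatus(segment=segment, status=status, rule=rule)


# ---------------------------------------------------------------------------
# indicative ages
# ---------------------------------------------------------------------------

def indicative_age(d1_0_cm: float, rate_mm_yr: float = DIAMETER_GROWTH_MM_YR) -> float:
    """Indicative tree age (years) from D1.0, unrounded.

    Diameter growth at ``rate_mm_yr`` accounts for the years above 1 m; the
    seedling time to reach 1 m comes from the height-age curve.
    """
    if rate_mm_yr <= 0:
        raise ValueError("growth rate must be positive")
    if d1_0_cm < 0:
        raise ValueError("diameter must be non-negative")
    return (d1_0_cm * 10.0) / rate_mm_yr + age_at_height(100.0)


def indicative_age_decade(d1_0_cm: float, rate_mm_yr: float = DIAMETER_GROWTH_MM_YR) -> int:
    """Indicative age rounded to the nearest decade (the age-class boundary form)."""
    age = indicative_age(d1_0_cm, rate_mm_yr)
    return int(np.floor(age / 10.0 + 0.5)) * 10
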