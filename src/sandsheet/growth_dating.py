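"""Establishment dating of Callitris intratropica from dated ring-width series.

Cores and stem sections are rarely taken at ground level and rarely intersect
the pith, so a dated series underestimates tree age in two ways. Two
corrections recover the establishment (germination) year:

* a pith offset — the number of innermost rings missed by the sample,
  estimated as distance-to-pith divided by the mean width of the five
  innermost measured rings;
* a height–age correction — the years a seedling needs to grow to the
  sampling height, from the empirical curve ``age = -2.1 + 2.024 * sqrt(h)``
  (h in cm, age in years, clamped at zero below the curve's root at ~1.08 cm).
  The curve derives from an ordinary least-squares regression of annual
  height increment on initial height in tagged juveniles.

establishment year = innermost dated ring year - pith offset - round(height-age).

The module consumes *dated* series (cross-dating is done upstream); calendar
years in the input are trusted. Tucson decadal .rwl is the interchange format.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Height-age curve coefficients: age = HEIGHT_AGE_A + HEIGHT_AGE_B * sqrt(height_cm).
HEIGHT_AGE_A = -2.1
HEIGHT_AGE_B = 2.024
#: Number of innermost rings averaged by the pith estimator.
PITH_ESTIMATOR_RINGS = 5
#: Decade bins start at the calendar decade [1750, 1760), ...
DECADE_ORIGIN = 1750


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero.

    Shared by the dating pipeline and the synthetic ring generator so that
    establishment-year round trips are exact.
    """
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


# ---------------------------------------------------------------------------
# height-increment regression and height-age curve
# ---------------------------------------------------------------------------

@dataclass
class HeightIncrementObs:
    """One juvenile's annual height increment over one measurement interval."""

    tag: str
    interval: int
    initial_height_cm: float
    increment_cm: float


@dataclass
class HeightIncrementFit:
    intercept: float
    slope: float
    r_squared: float
    delta_aic: float  # AIC(intercept-only) - AIC(model); positive favors the slope
    n: int


def _gaussian_aic(rss: float, n: int, k: int) -> float:
    # k counts mean parameters plus the residual variance
    sigma2 = max(rss / n, 1e-300)
    return n * math.log(2 * math.pi * sigma2) + n + 2 * k


def fit_height_increment_model(obs: list[HeightIncrementObs]) -> HeightIncrementFit:
    """OLS of annual height increment on initial height, with AIC support.

    delta_aic compares against the intercept-only model under a Gaussian
    likelihood (parameter counts include the residual variance).
    """
    if len(obs) < 3:
        raise ValueError("need at least 3 increment observations")
    x = np.array([o.initial_height_cm for o in obs], dtype=float)
    y = np.array([o.increment_cm for o in obs], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("initial heights are constant; slope is unidentifiable")
    n = len(x)
    X = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    aic_model = _gaussian_aic(rss, n, k=3)
    aic_null = _gaussian_aic(tss, n, k=2)
    return HeightIncrementFit(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        r_squared=r2,
        delta_aic=aic_null - aic_model,
        n=n,
    )


def age_at_height(height_cm: float) -> float:
    """Years for a seedling to reach ``height_cm``, clamped at 0 (unrounded).

    Evaluates age = -2.1 + 2.024 * sqrt(height); negative ages (below the
    curve root near 1.08 cm) are physically meaningless and clamp to zero.
    """
    if height_cm < 0:
        raise ValueError("height must be non-negative")
    return max(0.0, HEIGHT_AGE_A + HEIGHT_AGE_B * math.sqrt(height_cm))


# ---------------------------------------------------------------------------
# pith offset and establishment year
# ---------------------------------------------------------------------------

@dataclass
class DatedRingSample:
    """A cross-dated ring-width series with sampling metadata.

    ``ring_widths_mm`` runs from the innermost (oldest) to outermost ring;
    ``first_ring_year`` is the calendar year of the innermost dated ring.
    """

    series_id: str
    first_ring_year: int
    ring_widths_mm: np.ndarray
    sample_height_cm: float
    sample_type: str = "core"  # 'core' or 'section'
    distance_to_pith_mm: float = 0.0
    segment: str | None = None

    def __post_init__(self) -> None:
        self.ring_widths_mm = np.asarray(self.ring_widths_mm, dtype=float)
        if self.ring_widths_mm.size == 0:
            raise ValueError("series has no rings")
        if (self.ring_widths_mm <= 0).any():
            raise ValueError("ring widths must be positive")
        if self.sample_type not in ("core", "section"):
            raise ValueError("sample_type must be 'core' or 'section'")

    @property
    def last_ring_year(self) -> int:
        return self.first_ring_year + self.ring_widths_mm.size - 1


def pith_offset(inner_widths_mm: np.ndarray, distance_to_pith_mm: float) -> int:
    """Missing inner rings: distance to pith over the mean of the 5 innermost rings.

    With fewer than five measured rings the mean of all available rings is
    used and a degraded-mode warning is logged.
    """
    if distance_to_pith_mm < 0:
        raise ValueError("distance to pith must be non-negative")
    w = np.asarray(inner_widths_mm, dtype=float)
    if w.size == 0:
        raise ValueError("no ring widths supplied")
    if w.size < PITH_ESTIMATOR_RINGS:
        logger.warning(
            "pith estimator: only %d rings available (wanted %d); using all",
            w.size,
            PITH_ESTIMATOR_RINGS,
        )
        mean_w = float(w.mean())
    else:
        mean_w = float(w[:PITH_ESTIMATOR_RINGS].mean())
    return max(0, round_half_up(distance_to_pith_mm / mean_w))


def establishment_year(sample: DatedRingSample) -> int:
    """Establishment (germination) year of the tree behind one dated sample.

    innermost ring year, minus the pith offset, minus the rounded seedling
    time to reach the sampling height.
    """
    offset = pith_offset(sample.ring_widths_mm, sample.distance_to_pith_mm)
    height_corr = round_half_up(age_at_height(sample.sample_height_cm))
    year = sample.first_ring_year - offset - height_corr
    if year > sample.last_ring_year:
        raise ValueError("establishment year postdates the series end (inconsistent sample)")
    return year


@dataclass
class EstablishmentTable:
    """Per-tree establishment years with decadal bins per transect segment."""

    per_tree: pd.DataFrame  # series_id, segment, establishment_year, decade
    decade_counts: pd.DataFrame  # index: segment, columns: decade start years
    record_limits: pd.Series  # per-segment earliest innermost ring year


def bin_establishment(samples: list[DatedRingSample]) -> EstablishmentTable:
    """Decadal establishment counts per 100-m segment, with record limits.

    Decades are closed-open calendar decades [1750, 1760), [1760, 1770), ...;
    the per-segment record limit is the earliest innermost dated ring year
    among that segment's samples.
    """
    rows = []
    for s in samples:
        est = establishment_year(s)
        if est < 1000:
            raise ValueError(f"establishment year {est} before 1000 CE: parse artifact?")
        rows.append(
            {
                "series_id": s.series_id,
                "segment": s.segment if s.segment is not None else "all",
                "establishment_year": est,
                "decade": (est // 10) * 10,
                "first_ring_year": s.first_ring_year,
            }
        )
    per_tree = pd.DataFrame(rows)
    counts = (
        per_tree.groupby(["segment", "decade"]).size().unstack(fill_value=0).sort_index(axis=1)
    )
    limits = per_tree.groupby("segment")["first_ring_year"].min()
    return EstablishmentTable(
        per_tree=per_tree.drop(columns="first_ring_year"),
        decade_counts=counts,
        record_limits=limits,
    )


# ---------------------------------------------------------------------------
# Tucson decadal .rwl interchange
# ---------------------------------------------------------------------------

def write_rwl(path: str, series: dict[str, tuple[int, np.ndarray]]) -> None:
    """Write ring-width series as Tucson decadal .rwl (0.01 mm units, 999 stop)."""
    with open(path, "w") as fh:
        for sid, (first_year, widths) in series.items():
            vals = np.round(np.asarray(widths, dtype=float) * 100).astype(int).tolist()
            vals.append(999)  # stop marker occupies the slot after the last ring
            i = 0
            while i < len(vals):
                y = first_year + i
                n = min((y // 10) * 10 + 9 - y + 1, len(vals) - i)
                fields = "".join(f"{v:6d}" for v in vals[i : i + n])
                fh.write(f"{sid:<8.8s}{y:4d}{fields}\n")
                i += n


def read_rwl(path: str) -> dict[str, tuple[int, np.ndarray]]:
    """Read Tucson decadal .rwl; returns {series_id: (first_year, widths_mm)}.

    The stop-marker dialect is auto-detected per series: 999 implies 0.01 mm
    units, -9999 implies 0.001 mm; the detected dialect is logged.
    """
    raw: dict[str, list[tuple[int, list[int]]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            sid = line[:8].strip()
            rest = line[8:].split()
            if not rest:
                continue
            year = int(rest[0])
            vals = [int(v) for v in rest[1:]]
            raw.setdefault(sid, []).append((year, vals))
    out: dict[str, tuple[int, np.ndarray]] = {}
    for sid, rows in raw.items():
        rows.sort()
        flat: list[int] = []
        first_year = None
        stop = None
        for year, vals in rows:
            for i, v in enumerate(vals):
                if v == 999 and stop is None:
                    stop = 999
                    break
                if v == -9999:
                    stop = -9999
                    break
                if first_year is None:
                    first_year = year + i
                flat.append(v)
            if stop is not None:
                break
        if first_year is None:
            continue
        scale = 0.01 if stop in (999, None) else 0.001
        logger.info("series %s: %s stop marker, %.3f mm units", sid, stop, scale)
        out[sid] = (first_year, np.array(flat, dtype=float) * scale)
    return out


def read_samples(rwl_path: str, meta: pd.DataFrame) -> list[DatedRingSample]:
    """Join an .rwl file with its metadata sidecar into DatedRingSample objects.

    ``meta`` needs columns series_id, sample_height_cm, sample_type,
    distance_to_pith_mm and optionally segment.
    """
    series = read_rwl(rwl_path)
    meta = meta.set_index("series_id")
    samples = []
    for sid, (first_year, widths) in series.items():
        if sid not in meta.index:
            logger.warning("series %s has no metadata row; skipped", sid)
            continue
        row = meta.loc[sid]
        samples.append(
            DatedRingSample(
                series_id=sid,
                first_ring_year=first_year,
                ring_widths_mm=widths,
                sample_height_cm=float(row["sample_height_cm"]),
                sample_type=str(row["sample_type"]),
                distance_to_pith_mm=float(row.get("distance_to_pith_mm", 0.0)),
                segment=str(row["segment"]) if "segment" in row else None,
            )
        )
    return samples
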