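# Methods

This note documents the models, parameter choices, numerical conventions,
and known limitations of `sandsheet`. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Burned-area mapping

NBR is computed as (NIR − SWIR)/(NIR + SWIR) on surface reflectance in
[0, 1]; cells where NIR + SWIR = 0 or either band is nodata propagate NaN
and are treated as unburnt by the thresholding step. Seasonal dNBR is
NBR(pre-window) − NBR(post-window) with the window pairs early: MAM→JJA and
late: JJA→SON (the three-month composite calendar; the alternative
March–June / July–October season definition that sometimes appears in
figure-level summaries is not used). For each season, the all-year mean
dNBR is subtracted cellwise before thresholding: any per-cell constant
present in every year — a drainage line, a rocky outcrop — cancels exactly,
which is the purpose of the adjustment. A consequence worth knowing: a cell
that burns in k of N record years retains only amplitude × (1 − k/N) of its
signal in the anomaly, so frequently reburnt cells sit closer to the cutoff
than raw dNBR would suggest.

The fire-presence cutoff is 0.75 dNBR units, strictly greater-than, applied
to the mean-adjusted anomaly by default (`threshold_on="anomaly"`); applying
it to raw dNBR instead is a config switch (`"raw"`), since the pipeline
order admits either reading.

Time since fire is reported only once five years of prior record exist
(spin-up), matching the practice of reconstructing TSF only where history is
deep enough to be meaningful. Never-burnt cells are censored and carry the
record length k as a "≥ k" lower bound; they count as long-unburnt once
k > 5, and they enter the mean-TSF summary at value k (a conservative lower
bound — documented, not interpolated). Long-unburnt patches are connected
components of TSF > 5 cells inside the analysis mask; connectivity defaults
to 8-neighbor (queen), matching common landscape-metrics defaults, with a
4-neighbor switch. Patch areas come from the cell size (areas in ha); masks
are cell-aligned with the center-point rasterization rule throughout.

Rasters are numpy arrays with a `GridSpec` (origin, cell size, CRS label),
serialized as ESRI ASCII grids; analysis polygons are GeoJSON handled with
shapely. This keeps the whole pipeline in plain-text formats.

## Regime statistics

Each regime variable is compared pre/post-intervention with OLS on a
two-level period indicator, which is algebraically the pooled-variance
two-sample t-test (slope = difference of period means; t with n − 2 df).
Years are the replicate unit — annual values enter individually, not as
period means. The commencement year itself is post (commencement-year
burning is intervention burning). The long-unburnt proportion uses
thresholds lagged five years (2011 Dukaladjarranj, 2012 Kakadu), because the
long-unburnt class cannot respond faster than its own age definition.
Transforms: asin√p for proportions (applied as-is at 0 and 1, where the
transform is defined; no continuity correction) and log for mean patch size,
with a named error on non-positive values. No autocorrelation adjustment is
made — the model is deliberately the plain linear model on annual values.

## Demography

Size classes are lower-inclusive / upper-exclusive everywhere (a 10.0 cm
stem is medium, a 30.0 cm stem is very large), which resolves the overlap in
conventionally printed ranges ("10–20", "20–30"). The transect scheme (A)
splits juveniles at 0.1 m and 2.2 m of height; the longitudinal scheme (B)
uses a single 1.5 m juvenile threshold and adds a very-small (< 5 cm D1.0)
class. The two schemes agree for established trees with D1.0 ≥ 10 cm, which
the suite checks.

Segment densities scale each class by its own sampled band (seedlings 2 m
either side of the midline, saplings and trees 25 m; configurable), and the
standard error is across 100-m segments — segments, not transects, are the
replicated unit. Annualized survival is (N₂/N₁)^(1/y) × 100, reported to one
decimal; missing individuals are dead; class membership is frozen at the
tagging census (no promotion), so per-class survival describes the cohort as
tagged.

The stand-status categories are verbal in origin; the classifier ships
explicit numeric defaults (precedence absent → new → singleton → healthy →
recovering → degraded, with thresholds: healthy needs ≥ 3 live established
stems spanning ≥ 3 classes and live > dead; singleton allows ≤ 2 established
stems, majority live, ≤ 2 juveniles; recovering needs ≥ 3 juveniles under
dead-dominance). Every threshold is config-exposed and recorded in each
result object, because an operational rule is the only reproducible form of
a qualitative definition.

Indicative ages assume 2.5 mm yr⁻¹ diameter growth at 1 m plus the seedling
time to reach 1 m from the height–age curve (18.14 yr unrounded), rounded to
the nearest decade only at the end: 10 cm → 58.1 → 60 yr, 30 cm → 138.1 →
140 yr.

## Establishment dating

The height-increment regression is OLS of annual increment on initial
height; ΔAIC against the intercept-only model uses the Gaussian likelihood
with parameter counts including the residual variance (k = 3 vs 2). The
height–age curve age = −2.1 + 2.024·√h is implemented as printed and clamped
at zero below its root (≈ 1.08 cm), because negative ages are meaningless.
Its derivation from the increment regression is not re-derived here; note
that the printed increment-regression slope (0.773) is dimensionally
inconsistent with the printed mean increments (4–6 cm yr⁻¹ at ~30 cm initial
height), which imply ≈ 0.0773 — the module fits whatever the data yield and
hard-codes neither; the synthetic generator uses 0.0773 as its truth.

The pith offset is round(distance-to-pith / mean width of the five innermost
rings); with fewer than five rings all available rings are used and a
degraded-mode warning is logged. Establishment year = innermost dated ring
year − pith offset − round(height correction). Rounding is half-up and
happens exactly once, at composition time, with the same convention in the
synthetic generator — this makes the generator/dating round trip exact, and
the suite relies on that exactness. Decade bins are closed-open calendar
decades ([1900, 1910), …); per-segment record limits are the earliest
innermost ring year among the segment's samples. Cross-dating is consumed,
not performed: calendar years in the input `.rwl` are trusted. The Tucson
reader auto-detects the 999 (0.01 mm) vs −9999 (0.001 mm) stop-marker
dialect and logs it.

## Fuel statistics

Dry load is fresh weight × (1 − moisture)/area, with the default 0.25 m²
quadrat. Quantile regression minimizes the check loss; the fit is delegated
to statsmodels' QuantReg (IRLS), with the degenerate all-equal-response case
short-circuited. Confidence intervals use a seeded case-resampling bootstrap
(percentile method, default B = 2000) — chosen over rank inversion for
transparency; B and the seed are parameters. AIC uses the asymmetric-Laplace
working likelihood with scale profiled out, AIC = 2k + 2n·log(V/n) with V
the minimized check loss and k the coefficient count; AIC for quantile
regression is not uniquely defined, so the formula is documented rather than
assumed universal. ΔAIC = AIC(null) − AIC(region), positive favoring the
region model. Region enters as a single fixed effect; plot/segment grouping
is not modeled.

## Patch dynamics

Patches are independent Markov chains on six states; entries of the
transition matrix are monotone functions of the annual patch burn
probability f (inflows to degraded/absent nondecreasing in f, inflows to
healthy/recovering/new nonincreasing). The shipped default templates are a
demonstration parameterization only — no published numbers anchor them, and
results from them should be read qualitatively (direction and monotonicity,
not magnitudes). The stationary distribution is computed by damped power
iteration (π ← ½π + ½πP, tolerance 1e−12); damping removes periodicity
without changing fixed points, and for chains with an absorbing reachable
state the limit concentrates there and is flagged. Spatial contagion between
patches is deliberately absent (the conceptual model is patch-level); a
neighbor-coupling extension would change the interface, not just parameters,
and is out of scope.

## Synthetic-data generators

All generators split one scenario seed into named child streams via
`numpy.random.SeedSequence.spawn`, so each consumer of randomness is
insulated from the others and every output is a pure function of the
scenario.

Fire landscapes are constructed in dNBR space (fire amplitude inside
footprints + static smooth field + white noise) and inverted to NIR/SWIR
with NIR + SWIR = 1; footprints rasterize by the center-point rule. Defaults
follow the study conditions: a 1990–2020 record, 30 m cells, dNBR fire
amplitude 1.0 against the 0.75 cutoff, static-feature and noise standard
deviations of 0.05. Over a 31-year record the mean adjustment shaves at most
1/31 of a once-burnt cell's amplitude, leaving a ≳ 4σ margin above the
cutoff at noise 0.05 — the basis of the recall property the suite checks.

Stem maps come from a Thomas cluster process (Poisson parents, Poisson
offspring with isotropic Gaussian dispersal) plus an independent Poisson
singleton process — the simplest process producing the grove/singleton
dichotomy. Survival histories are per-class Bernoulli chains with absorbing
death, with default class sizes matching the longitudinal tagging design
(385/52/94/166/175/220 across the six classes, censuses 2006–2019). Ring
series place the first dated ring at establishment + rounded height
correction + pith offset, and back-compute the sidecar distance-to-pith from
the generated inner-ring widths so the pith estimator inverts exactly. Fuel
loads are lognormal per region — median and sigma are the two stated
controls (unequal medians, unequal upper-tail spread); defaults use medians
70 and 110 g m⁻² with sigmas 0.4 and 0.8, echoing the direction and rough
magnitude of the published regional contrast; moisture is Beta(2, 6)
(mean 0.25).

What the generators do **not** emulate: reflectance physics, clouds, sensor
noise structure, fire spread and partial burns within footprints, size-class
transitions over time, climate signal in ring widths, or spatial correlation
in fuel loads. Passing tests therefore demonstrate the correctness of the
algorithms under the stated statistical conditions, not robustness to the
full messiness of field data.

## Problem sizes

The test suite and acceptance checks use desk-scale problem sizes chosen to
make sampling error negligible relative to the tested tolerances: 200 random
20×20 stacks for the TSF/patch oracles, 10⁵ individuals for the survival
inversion (±0.1 pp), ~500 quadrats per region for median-shift recovery,
161–201-point grids for the check-loss oracle on n ≤ 12 instances, and
500-patch / 300-year / 10-seed sweeps for the occupancy monotonicity check.
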