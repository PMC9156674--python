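# sandsheet

Fire-regime reconstruction and *Callitris intratropica* demography for
monsoon-tropics sand sheet savannas.

In the savannas of the Arnhem Plateau (northern Australia), the Gondwanan
conifer *C. intratropica* is a bio-indicator of fire-regime health: it
persists as closed-canopy groves that exclude grass and fire, while isolated
trees and juveniles are killed by intense grass fires. Changes in fire
management — the breakdown of traditional Aboriginal patch burning and its
partial replacement by institutional early-dry-season burning — leave
signatures in satellite burn histories, stand structure, tagged-tree
survival, tree-ring establishment dates, and grass fuel loads. `sandsheet`
implements the full analysis chain connecting those data streams, plus
synthetic-data generators with known ground truth so every stage is testable
without any field or satellite download.

## What it computes

**Burned-area mapping** (`fire_history`). From seasonal surface-reflectance
composites, NBR = (NIR − SWIR)/(NIR + SWIR); early dry-season fires from the
March–May vs June–August difference, late fires from June–August vs
September–November; the all-year mean seasonal dNBR is subtracted to remove
static landscape features; cells with mean-adjusted dNBR > 0.75 are classed
as burnt. Derived products: per-cell time since fire (TSF, censored where no
burn is on record), long-unburnt (TSF > 5 yr) patch mosaics via connected
components, and annual regime summaries (proportions burnt early/late/total,
mean TSF, long-unburnt proportion and mean patch size).

**Regime statistics** (`regime_stats`). Pre/post-intervention comparison of
each annual regime variable with an OLS linear model on a period indicator
(≡ pooled two-sample t-test), splitting at the management-commencement year
(Dukaladjarranj 2006, Kakadu 2007; lagged to 2011/2012 for the long-unburnt
proportion). Proportions are arcsine-square-root transformed
(asin√p); mean patch size is log-transformed.

**Demography** (`demography`). Size-class assignment under the transect and
longitudinal schemes, per-segment stem densities with class-specific sampling
bands, an operationalized stand-status classifier (healthy / degraded /
recovering / singleton / new), indicative ages from D1.0 at 2.5 mm yr⁻¹, and
annualized survival

    S = (N₂/N₁)^(1/y) × 100

over a y-year monitoring interval (missing individuals counted dead).

**Establishment dating** (`growth_dating`). From cross-dated ring series:
pith offset = distance-to-pith / mean width of the five innermost rings;
seedling height–age curve age = −2.1 + 2.024·√height (cm → years);
establishment year = innermost ring year − pith offset − rounded height
correction; decadal establishment bins per transect segment with per-segment
record limits. Tucson `.rwl` read/write included.

**Fuel loads** (`fuel_stats`). Dry load = fresh × (1 − moisture)/area;
regional comparison by quantile regression at τ = 0.90 and 0.50 (check-loss
minimization), bootstrap confidence intervals, and asymmetric-Laplace AIC
model comparison against the intercept-only model.

**Patch dynamics** (`patch_dynamics`). A Markov state-transition simulator of
the grove mosaic (healthy ↔ degraded → singleton/absent, recovery and new
cohorts when fire is rare) driven by an annual patch burn probability f, with
stationary-distribution analysis. No published transition probabilities
exist; the default parameterization is for qualitative exploration only.

**Synthetic data** (`synthetic_data`). Seeded generators for every input:
composite stacks with known burn footprints over static features and noise,
Thomas-process grove/singleton stem maps, per-class Bernoulli survival
chains, ring series consistent with known establishment years, and regional
fuel samples with unequal medians and tail spread.

## Worked example

```python
import numpy as np
from sandsheet import synthetic_data as sd, fire_history as fh, demography as dm

events = [sd.FireEvent(y, "late", sd.disc(1500, 1500, 600), 1.0) for y in (1995, 2000, 2004)] + \
         [sd.FireEvent(y, "early", sd.disc(800, 2400, 500), 1.0) for y in (2008, 2013, 2018)]
sc = sd.FireScenario(nrows=100, ncols=100, year_start=1990, year_end=2020,
                     events=events, noise_sd=0.02, seed=42)
comps, truth = sd.gen_fire_landscape(sc)
stack = fh.map_fire_history(comps, np.ones(sc.grid.shape, bool))
print(fh.summarize_regime(stack).query("year in (1995, 2008, 2020)").round(3))
```

```
 year  p_early  p_late  p_total  mean_tsf  p_long_unburnt  mean_patch_ha
 1995    0.000   0.126    0.126     5.242           0.874         786.24
 2008    0.087   0.000    0.087    15.443           0.786         707.58
 2020    0.000   0.000    0.000    26.569           0.913         821.34
```

The mapped proportions match the constructed scars exactly (the late scar
covers 12.6% of the grid, the early scar 8.7%), mean TSF grows by one each
fire-free year, and the long-unburnt share recovers after the regime switches
from repeated late fires to sparser early fires. Testing the late-season
proportion across the 2006 split:

```python
from sandsheet import regime_stats as rs
res = rs.fit_period_model(fh.summarize_regime(stack).set_index("year")["p_late"],
                          rs.get_scheme("Dukaladjarranj"), "p_late",
                          transform="arcsine_sqrt")
# slope=-0.068, t=-1.80, p=0.0824 (n_pre=16, n_post=15)
```

The slope is the post-minus-pre difference on the arcsine-√ scale — late-season
burning declined after 2006 in this scenario, short of the 0.05 level at n=31
years. Longitudinal survival from the synthetic census (true per-class annual
survival rates are recovered within binomial error; e.g. large trees,
generated at 98.8%, estimate at 99.0% from n=175):

```python
census = sd.gen_survival_histories(sd.SurvivalScenario(seed=42))
print(dm.survival_by_class(census, 2006, 2019))
```

```
size_class  n_start  n_end  raw_survival_pct  annualized_survival_pct
  juvenile      385      5               1.3                     71.6
     large      175    154              88.0                     99.0
...
```

A command-line interface mirrors the stages
(`sandsheet synth|firehist|regime|demog|dendro|fuel|mosaic --help`).

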