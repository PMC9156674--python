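"""Pre/post fire-management comparison of annual regime summaries.

Annual values of each regime variable (mean time since fire, mean long-unburnt
patch size, proportions burnt) are split into pre- and post-intervention
periods at a site-specific threshold year (management commenced 2006 at
Dukaladjarranj, 2007 in Kakadu National Park; the commencement year itself
counts as post). The proportion-long-unburnt variable responds with a delay,
so its split is lagged five years (2011 and 2012 respectively).

Each variable is compared with an ordinary least-squares linear model of the
(possibly transformed) annual value on a two-level period indicator, which is
algebraically the equal-variance two-sample t-test. Proportions are
arcsine-square-root transformed; mean patch size is log-transformed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Lag (years) applied to the long-unburnt threshold year.
LONG_UNBURNT_LAG_YEARS = 5
#: Variables whose period split uses the lagged threshold.
LAGGED_VARIABLES = ("p_long_unburnt", "proportion_long_unburnt", "long_unburnt")


@dataclass(frozen=True)
class InterventionScheme:
    """Site-specific pre/post split: threshold year and its 5-year lagged form."""

    site: str
    threshold_year: int
    lagged_threshold_year: int

    def __post_init__(self) -> None:
        if self.lagged_threshold_year != self.threshold_year + LONG_UNBURNT_LAG_YEARS:
            raise ValueError(
                f"lagged threshold must be threshold + {LONG_UNBURNT_LAG_YEARS}"
            )


SCHEMES: dict[str, InterventionScheme] = {
    "Dukaladjarranj": InterventionScheme("Dukaladjarranj", 2006, 2011),
    "Kakadu": InterventionScheme("Kakadu", 2007, 2012),
}


def get_scheme(site: str) -> InterventionScheme:
    try:
        return SCHEMES[site]
    except KeyError:
        raise ValueError(f"unknown site {site!r}; known: {sorted(SCHEMES)}") from None


def _uses_lag(variable: str) -> bool:
    return any(key in variable for key in LAGGED_VARIABLES)


def classify_period(year: int, scheme: InterventionScheme, variable: str) -> str:
    """'pre' or 'post' for one annual value of one variable.

    Post means year >= the applicable threshold; the long-unburnt variable
    uses the lagged threshold.
    """
    threshold = scheme.lagged_threshold_year if _uses_lag(variable) else scheme.threshold_year
    return "post" if year >= threshold else "pre"


def arcsine_sqrt(p: float | np.ndarray) -> float | np.ndarray:
    """Variance-stabilizing transform asin(sqrt(p)) for proportions in [0, 1]."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return float(out) if np.isscalar(p) else out


TRANSFORMS = {
    "identity": lambda v: np.asarray(v, dtype=float),
    "log": None,  # handled specially to name the error
    "arcsine_sqrt": arcsine_sqrt,
}


class NonPositiveLogError(ValueError):
    """Raised when a log transform meets a non-positive value."""


def _apply_transform(values: np.ndarray, transform: str) -> np.ndarray:
    if transform == "identity":
        return np.asarray(values, dtype=float)
    if transform == "log":
        arr = np.asarray(values, dtype=float)
        if np.any(arr <= 0):
            raise NonPositiveLogError("log transform requires strictly positive values")
        return np.log(arr)
    if transform == "arcsine_sqrt":
        return arcsine_sqrt(np.asarray(values, dtype=float))
    raise ValueError(f"unknown transform {transform!r}")


@dataclass
class PeriodModelResult:
    variable: str
    transform: str
    mean_pre: float
    mean_post: float
    slope: float  # post minus pre, on the transformed scale
    se: float
    t: float
    p_value: float
    n_pre: int
    n_post: int


def fit_period_model(
    values_by_year: pd.Series | dict[int, float],
    scheme: InterventionScheme,
    variable: str,
    transform: str = "identity",
) -> PeriodModelResult:
    """OLS of the transformed annual value on a pre/post period indicator.

    Equivalent to the pooled-variance two-sample t-test; the slope is the
    post-minus-pre difference on the transformed scale, with its standard
    error, t statistic (n - 2 df) and two-sided p-value.
    """
    series = pd.Series(values_by_year).dropna().sort_index()
    periods = np.array([classify_period(int(y), scheme, variable) for y in series.index])
    y = _apply_transform(series.to_numpy(), transform)
    if not np.all(np.isfinite(y)):
        raise ValueError("transformed values must be finite")
    pre, post = y[periods == "pre"], y[periods == "post"]
    if len(pre) < 2 or len(post) < 2:
        raise ValueError("each period needs at least 2 years of data")
    n = len(y)
    slope = float(post.mean() - pre.mean())
    rss = float(((pre - pre.mean()) ** 2).sum() + ((post - post.mean()) ** 2).sum())
    sigma2 = rss / (n - 2)
    se = math.sqrt(sigma2 * (1.0 / len(pre) + 1.0 / len(post)))
    if se == 0.0:
        t_stat = 0.0 if slope == 0 else math.inf * np.sign(slope)
        p_value = 1.0 if slope == 0 else 0.0
    else:
        t_stat = slope / se
        p_value = 2.0 * stats.t.sf(abs(t_stat), df=n - 2)
    return PeriodModelResult(
        variable=variable,
        transform=transform,
        mean_pre=float(pre.mean()),
        mean_post=float(post.mean()),
        slope=slope,
        se=se,
        t=t_stat,
        p_value=p_value,
        n_pre=len(pre),
        n_post=len(post),
    )


#: Default transform per regime-summary column.
DEFAULT_VARIABLE_TRANSFORMS = {
    "mean_tsf": "identity",
    "mean_patch_ha": "log",
    "p_total": "arcsine_sqrt",
    "p_early": "arcsine_sqrt",
    "p_late": "arcsine_sqrt",
    "p_long_unburnt": "arcsine_sqrt",
}


def compare_regime(summary: pd.DataFrame, site: str) -> pd.DataFrame:
    """Fit the period model for every standard regime variable in a summary table.

    ``summary`` is the annual table from fire_history.summarize_regime
    (columns year, p_early, p_late, p_total, mean_tsf, p_long_unburnt,
    mean_patch_ha). Returns one row per variable.
    """
    scheme = get_scheme(site)
    rows = []
    for variable, transform in DEFAULT_VARIABLE_TRANSFORMS.items():
        if variable not in summary.columns:
            continue
        series = summary.set_index("year")[variable]
        try:
            res = fit_period_model(series, scheme, variable, transform)
        except (ValueError, NonPositiveLogError):
            continue
        rows.append(
            {
                "variable": res.variable,
                "transform": res.transform,
                "slope": res.slope,
                "se": res.se,
                "t": res.t,
                "p": res.p_value,
                "n_pre": res.n_pre,
                "n_post": res.n_post,
            }
        )
    return pd.DataFrame(rows)
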