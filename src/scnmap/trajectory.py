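"""Age-trajectory analyses of ROI volumes.

Two analyses are provided, mirroring how lifespan hippocampal volumetry is
usually summarized:

* a quadratic ordinary-least-squares fit ``value ~ c0 + c1*age + c2*age^2``,
  reported with R² and the overall F-test (volumes typically rise slightly
  into middle age and then decline, hence the quadratic);
* a sliding-window dispersion statistic: for each integer age ``t`` the
  sample variance of values among subjects aged within ``t ± 2`` years,
  itself fit with the same quadratic model to detect U-shaped (high at both
  ends of life) dispersion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateDesignError

__all__ = [
    "TrajectoryFit",
    "VarianceSeries",
    "fit_quadratic",
    "sliding_window_variance",
    "fit_variance_trajectory",
]


@dataclass
class TrajectoryFit:
    """Result of a quadratic OLS fit of a value against age.

    Attributes
    ----------
    coeffs
        (c0, c1, c2) of value ~ c0 + c1*age + c2*age².
    r_squared
        1 - RSS/TSS.
    f_stat, p_value
        Overall regression F statistic with (2, n-3) degrees of freedom and
        its p-value.
    coef_se, coef_pvalues
        Per-coefficient standard errors and two-sided t-test p-values
        (intercept, linear, quadratic).
    n
        Number of observations.
    """

    coeffs: tuple[float, float, float]
    r_squared: float
    f_stat: float
    p_value: float
    coef_se: tuple[float, float, float]
    coef_pvalues: tuple[float, float, float]
    n: int


@dataclass
class VarianceSeries:
    """Sliding-window variance of ROI values across age.

    ``variances[i]`` is the sample variance (n-1 denominator) of values for
    subjects with age in ``[ages[i]-halfwidth, ages[i]+halfwidth]``;
    ``counts[i]`` is the number of subjects in that window.  Ages whose
    window holds fewer than the minimum count are omitted.
    """

    ages: np.ndarray
    variances: np.ndarray
    counts: np.ndarray
    halfwidth: float = 2.0


def fit_quadratic(ages, values) -> TrajectoryFit:
    """OLS fit of ``values ~ 1 + age + age²``.

    Requires n >= 4 and at least three distinct ages (otherwise the design
    is rank deficient and a :class:`DegenerateDesignError` is raised).
    """
    import statsmodels.api as sm

    ages = np.asarray(ages, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    if ages.shape != values.shape or ages.ndim != 1:
        raise ValueError("ages and values must be 1D arrays of equal length")
    n = len(ages)
    if n < 4:
        raise DegenerateDesignError(f"need at least 4 observations, got {n}")
    if len(np.unique(ages)) <= 2:
        raise DegenerateDesignError(
            "quadratic fit needs at least 3 distinct ages"
        )
    X = np.column_stack([np.ones(n), ages, ages**2])
    res = sm.OLS(values, X).fit()
    fvalue = float(res.fvalue)
    f_pvalue = float(res.f_pvalue)
    if math.isnan(fvalue):  # perfect fit: RSS == 0
        fvalue, f_pvalue = float("inf"), 0.0
    return TrajectoryFit(
        coeffs=tuple(res.params),
        r_squared=float(res.rsquared),
        f_stat=fvalue,
        p_value=f_pvalue,
        coef_se=tuple(res.bse),
        coef_pvalues=tuple(res.pvalues),
        n=n,
    )


def sliding_window_variance(
    ages, values, halfwidth: float = 2.0, min_window_n: int = 3
) -> VarianceSeries:
    """Sample variance of values in the age window [t-halfwidth, t+halfwidth].

    Evaluated at every integer t from min(ages) to max(ages), both window
    ends inclusive; windows with fewer than ``min_window_n`` subjects are
    omitted from the series.
    """
    if halfwidth < 0:
        raise ValueError(f"halfwidth must be non-negative, got {halfwidth}")
    ages = np.asarray(ages, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    if ages.shape != values.shape or ages.ndim != 1:
        raise ValueError("ages and values must be 1D arrays of equal length")
    if len(ages) < min_window_n:
        raise ValueError(
            f"need at least min_window_n={min_window_n} subjects, got {len(ages)}"
        )
    t_grid = np.arange(math.ceil(ages.min()), math.floor(ages.max()) + 1)
    out_t, out_var, out_n = [], [], []
    for t in t_grid:
        sel = (ages >= t - halfwidth) & (ages <= t + halfwidth)
        k = int(sel.sum())
        if k < min_window_n:
            continue
        out_t.append(t)
        out_var.append(float(np.var(values[sel], ddof=1)))
        out_n.append(k)
    return VarianceSeries(
        ages=np.asarray(out_t, dtype=np.float64),
        variances=np.asarray(out_var, dtype=np.float64),
        counts=np.asarray(out_n, dtype=np.int64),
        halfwidth=float(halfwidth),
    )


def fit_variance_trajectory(series: VarianceSeries, weighted: bool = False) -> TrajectoryFit:
    """Quadratic fit of window variance against evaluation age.

    Unweighted by default even though window counts differ; pass
    ``weighted=True`` to weight each window by its subject count.
    """
    if len(series.ages) < 4:
        raise DegenerateDesignError(
            f"need at least 4 evaluation ages, got {len(series.ages)}"
        )
    if not weighted:
        return fit_quadratic(series.ages, series.variances)
    import statsmodels.api as sm

    n = len(series.ages)
    X = np.column_stack([np.ones(n), series.ages, series.ages**2])
    res = sm.WLS(series.variances, X, weights=series.counts).fit()
    return TrajectoryFit(
        coeffs=tuple(res.params),
        r_squared=float(res.rsquared),
        f_stat=float(res.fvalue),
        p_value=float(res.f_pvalue),
        coef_se=tuple(res.bse),
        coef_pvalues=tuple(res.pvalues),
        n=n,
    )
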