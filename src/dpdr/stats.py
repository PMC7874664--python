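"""Method-agreement and cohort statistics.

Pearson correlation with ordinary least-squares regression, Bland-Altman
agreement (mean difference +/- 2 SD limits, with a difference-on-mean
regression for proportional error), the pooled-variance unpaired t test, and
complication-rate tabulation by risk band. SDs use the n-1 denominator
throughout; limits of agreement are mean +/- 2 SD exactly (not 1.96 SD); all
tests are two-tailed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as _st

__all__ = [
    "RegressionResult",
    "AgreementReport",
    "RateTable",
    "pearson_regression",
    "bland_altman",
    "compare_methods",
    "unpaired_t_test",
    "complication_rates",
]


@dataclass
class RegressionResult:
    n: int
    pearson_r: float
    r_squared: float
    slope: float
    intercept: float
    p_value: float


@dataclass
class AgreementReport:
    n: int
    pearson_r: float
    r_squared: float
    slope: float
    intercept: float
    mean_difference: float
    sd_difference: float
    loa_low: float
    loa_high: float
    pct_within_2sd: float
    prop_error_slope: float
    prop_error_intercept: float
    p_value: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RateTable:
    """Event rates per risk band, plus the overall rate.

    ``bands`` maps band label -> (n_patients, n_events, rate_pct); empty
    bands are absent rather than reported as zero.
    """

    bands: dict[str, tuple[int, int, float]]
    overall_n: int
    overall_events: int
    overall_rate_pct: float


def _as_1d(x) -> np.ndarray:
    a = np.asarray(x, float).ravel()
    if np.isnan(a).any():
        raise ValueError("input contains NaN")
    return a


def pearson_regression(x, y) -> RegressionResult:
    """Pearson r (with two-tailed p) and the OLS line of y on x."""
    x, y = _as_1d(x), _as_1d(y)
    if len(x) != len(y):
        raise ValueError("x and y lengths differ")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; regression undefined")
    res = _st.linregress(x, y)
    return RegressionResult(
        n=len(x),
        pearson_r=float(res.rvalue),
        r_squared=float(res.rvalue**2),
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_value=float(res.pvalue),
    )


def bland_altman(a, b) -> AgreementReport:
    """Agreement between two methods measuring the same quantity.

    Differences are ``a - b``; limits of agreement are the mean difference
    +/- 2 sample SDs, and proportional error is the OLS of the differences on
    the pairwise means ``(a + b) / 2``. Correlation/regression of ``b`` on
    ``a`` is included so one report covers the whole method comparison.
    """
    a, b = _as_1d(a), _as_1d(b)
    if len(a) != len(b):
        raise ValueError("paired inputs must have equal length")
    if len(a) < 3:
        raise ValueError("need n >= 3 pairs")
    d = a - b
    m = (a + b) / 2.0
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    loa_low, loa_high = mean_d - 2 * sd_d, mean_d + 2 * sd_d
    within = float(100.0 * np.mean(np.abs(d - mean_d) <= 2 * sd_d))
    if np.ptp(m) > 0:
        prop = _st.linregress(m, d)
        prop_slope, prop_int = float(prop.slope), float(prop.intercept)
    else:  # all pairwise means identical: no proportional trend estimable
        prop_slope, prop_int = float("nan"), mean_d
    if np.ptp(a) > 0:
        reg = pearson_regression(a, b)
        r, r2, slope, intercept, p = reg.pearson_r, reg.r_squared, reg.slope, reg.intercept, reg.p_value
    else:
        r = r2 = slope = intercept = p = float("nan")
    return AgreementReport(
        n=len(a),
        pearson_r=r,
        r_squared=r2,
        slope=slope,
        intercept=intercept,
        mean_difference=mean_d,
        sd_difference=sd_d,
        loa_low=loa_low,
        loa_high=loa_high,
        pct_within_2sd=within,
        prop_error_slope=prop_slope,
        prop_error_intercept=prop_int,
        p_value=p,
    )


#: alias: the full report is the method comparison
compare_methods = bland_altman


def unpaired_t_test(group_a, group_b) -> tuple[float, float]:
    """Classic pooled-variance two-sample t statistic and two-tailed p.

    Two identical degenerate groups (zero pooled variance, equal means) are
    reported as t = 0, p = 1 rather than NaN.
    """
    a, b = _as_1d(group_a), _as_1d(group_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf") if a.mean() > b.mean() else float("-inf"), 0.0
    t, p = _st.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def complication_rates(
    df: pd.DataFrame,
    band_col: str,
    event_col: str,
    band_order: list[str] | None = None,
) -> RateTable:
    """Per-band and overall complication rates (percent).

    ``df`` needs a band-label column and a boolean event column. Bands with
    no patients are omitted. Rates keep full precision here; round only for
    display.
    """
    if band_col not in df or event_col not in df:
        raise KeyError(f"columns {band_col!r} and {event_col!r} required")
    events = df[event_col].astype(bool)
    labels = band_order if band_order is not None else sorted(df[band_col].unique())
    bands: dict[str, tuple[int, int, float]] = {}
    for lab in labels:
        sel = df[band_col] == lab
        n = int(sel.sum())
        if n == 0:
            continue
        k = int(events[sel].sum())
        bands[lab] = (n, k, 100.0 * k / n)
    n_all = int(len(df))
    if n_all == 0:
        raise ValueError("empty cohort")
    k_all = int(events.sum())
    return RateTable(
        bands=bands, overall_n=n_all, overall_events=k_all, overall_rate_pct=100.0 * k_all / n_all
    )
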