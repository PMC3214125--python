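"""Manual-vs-automated comparison: OLS regression of paired counts.

Validation of an automated counter against a human reader is summarized
by ordinary least squares of automated on manual counts: a slope near 1
and intercept near 0 with high r^2 indicate the two methods agree, and
the mean per-image difference quantifies any systematic over- or
under-count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .batch import BatchReport

__all__ = ["RegressionSummary", "ComparisonResult", "linear_regression", "compare_counts"]


@dataclass(frozen=True)
class RegressionSummary:
    n: int
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    ci95_slope: tuple[float, float]
    ci95_intercept: tuple[float, float]


@dataclass(frozen=True)
class ComparisonResult:
    regression: RegressionSummary
    differences: pd.DataFrame   # filename, automated, manual, difference
    mean_difference: float      # mean(automated - manual)


def linear_regression(x, y) -> RegressionSummary:
    """OLS fit y = slope*x + intercept with slope t-test and 95% CIs.

    The p-value is the two-sided t-test of the slope against zero on
    n - 2 degrees of freedom; for simple linear regression it coincides
    with the regression F-test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"x and y must be equal-length 1-D arrays, got {x.shape} and {y.shape}")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 points for regression, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance; the regression is undefined")

    fit = stats.linregress(x, y)
    tcrit = stats.t.ppf(0.975, n - 2)
    return RegressionSummary(
        n=n,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        ci95_slope=(
            float(fit.slope - tcrit * fit.stderr),
            float(fit.slope + tcrit * fit.stderr),
        ),
        ci95_intercept=(
            float(fit.intercept - tcrit * fit.intercept_stderr),
            float(fit.intercept + tcrit * fit.intercept_stderr),
        ),
    )


def compare_counts(automated: BatchReport | pd.DataFrame, manual) -> ComparisonResult:
    """Pair automated and manual counts by filename and regress them.

    ``manual`` is an iterable of (filename, count) pairs or a DataFrame
    with columns filename, count.  Returns the regression of automated
    on manual plus per-image differences (automated - manual).
    """
    if isinstance(automated, BatchReport):
        auto_df = automated.to_dataframe()[["filename", "total_count"]]
    else:
        auto_df = automated[["filename", "total_count"]].copy()
    if isinstance(manual, pd.DataFrame):
        man_df = manual[["filename", "count"]].copy()
    else:
        man_df = pd.DataFrame(list(manual), columns=["filename", "count"])

    auto_names = set(auto_df["filename"])
    man_names = set(man_df["filename"])
    if auto_names != man_names:
        only_auto = sorted(auto_names - man_names)
        only_man = sorted(man_names - auto_names)
        raise ValueError(
            "filename sets differ between automated and manual counts; "
            f"only automated: {only_auto}; only manual: {only_man}"
        )

    merged = auto_df.merge(man_df, on="filename").sort_values("filename", ignore_index=True)
    merged = merged.rename(columns={"total_count": "automated", "count": "manual"})
    merged["difference"] = merged["automated"] - merged["manual"]
    regression = linear_regression(merged["manual"], merged["automated"])
    return ComparisonResult(
        regression=regression,
        differences=merged,
        mean_difference=float(merged["difference"].mean()),
    )
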