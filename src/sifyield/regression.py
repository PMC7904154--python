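"""Group-binned ordinary least squares and Pearson correlation.

Capacity (Vcmax or Jmax) is always the response and the optical quantity
(SIF, SIF yield or APAR) the predictor. Records are binned into time
groups by acquisition date; each group gets its own fit plus one pooled
all-data fit.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

__all__ = [
    "RegressionResult",
    "GroupScheme",
    "DEFAULT_GROUP_SCHEME",
    "linear_fit",
    "pearson_cc",
    "grouped_regression",
    "results_to_frame",
]

POOLED = "all"
P_SIGNIFICANT = 0.05


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    rmse: float
    pearson_cc: float
    p_value_slope: float
    n: int
    group: str = ""
    x_name: str = "x"
    y_name: str = "y"

    @property
    def significant(self) -> bool:
        return self.p_value_slope < P_SIGNIFICANT


def _as_date(d) -> _dt.date:
    if isinstance(d, _dt.date):
        return d
    return _dt.date.fromisoformat(str(d))


@dataclass(frozen=True)
class GroupScheme:
    """Mapping from acquisition date to time-proximity group label."""

    mapping: dict

    def group_of(self, date) -> str:
        date = _as_date(date)
        try:
            return self.mapping[date]
        except KeyError:
            raise KeyError(f"date {date.isoformat()} is not mapped to any group") from None

    @classmethod
    def from_lists(cls, groups: dict) -> "GroupScheme":
        mapping = {}
        for label, dates in groups.items():
            for d in dates:
                d = _as_date(d)
                if d in mapping:
                    raise ValueError(f"date {d} mapped to both {mapping[d]} and {label}")
                mapping[d] = label
        return cls(mapping)


#: The campaign's time-proximity bins.
DEFAULT_GROUP_SCHEME = GroupScheme.from_lists({
    "group1": ["2017-07-06", "2017-07-07", "2017-07-12"],
    "group2": ["2017-07-31", "2017-08-18"],
    "group3": ["2018-07-24", "2018-07-25"],
})


def linear_fit(x, y, group: str = "", x_name: str = "x",
               y_name: str = "y") -> RegressionResult:
    """OLS of y on x with R2, in-sample RMSE and a two-sided slope t-test."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need n >= 3 observations, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    res = _stats.linregress(x, y)
    yhat = res.intercept + res.slope * x
    resid = y - yhat
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    cc = float(res.rvalue) if ss_tot > 0 else 0.0
    pval = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
    return RegressionResult(slope=float(res.slope), intercept=float(res.intercept),
                            r_squared=max(r2, 0.0), rmse=rmse, pearson_cc=cc,
                            p_value_slope=pval, n=n, group=group,
                            x_name=x_name, y_name=y_name)


def pearson_cc(x, y) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    return float(_stats.pearsonr(x, y).statistic)


def grouped_regression(records: pd.DataFrame, scheme: GroupScheme,
                       x_var: str, y_var: str,
                       date_column: str = "date") -> dict[str, RegressionResult]:
    """Per-group OLS plus a pooled all-data fit.

    ``records`` needs columns ``date_column``, ``x_var`` and ``y_var``; rows
    with missing values in either variable are dropped (callers log them).
    """
    for col in (date_column, x_var, y_var):
        if col not in records.columns:
            raise KeyError(f"records lack column {col!r}")
    df = records.dropna(subset=[x_var, y_var]).copy()
    df["_group"] = [scheme.group_of(d) for d in df[date_column]]
    out: dict[str, RegressionResult] = {}
    for label, sub in df.groupby("_group", sort=True):
        out[label] = linear_fit(sub[x_var].to_numpy(), sub[y_var].to_numpy(),
                                group=label, x_name=x_var, y_name=y_var)
    out[POOLED] = linear_fit(df[x_var].to_numpy(), df[y_var].to_numpy(),
                             group=POOLED, x_name=x_var, y_name=y_var)
    return out


def results_to_frame(results: dict[str, RegressionResult]) -> pd.DataFrame:
    rows = [{
        "group": r.group, "x": r.x_name, "y": r.y_name, "n": r.n,
        "slope": r.slope, "intercept": r.intercept, "r_squared": r.r_squared,
        "rmse": r.rmse, "pearson_cc": r.pearson_cc,
        "p_value_slope": r.p_value_slope, "significant": r.significant,
    } for r in results.values()]
    return pd.DataFrame(rows)
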