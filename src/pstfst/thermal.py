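"""Temperature-regime characterization from hourly in-situ series.

Works on tidy hourly records (site, depth, timestamp, temp_c), the layout of
multi-year coastal mooring archives.  Provides the daily climatology
(per-julian-day mean +/- SD of daily means), warm-period (July-October)
distribution statistics, extreme-tail statistics above a quantile, and a
Kruskal-Wallis comparison between thermal regimes with Dunn pairwise
post-hocs under a Sidak family-wise adjustment.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["read_temperature", "validate_series", "daily_climatology",
           "warm_period", "warm_period_stats", "extreme_tail_stats",
           "kruskal_dunn"]

SERIES_COLUMNS = ["site", "depth", "timestamp", "temp_c"]

#: warm period: July 1 00:00 through October 31 23:59, inclusive
WARM_MONTHS = (7, 8, 9, 10)


def validate_series(series: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("timestamp", "temp_c") if c not in series.columns]
    if missing:
        raise ValueError(f"series lacks required columns: {missing}")
    out = series.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"])
    keys = [c for c in ("site", "depth") if c in out.columns]
    if keys:
        for _, grp in out.groupby(keys):
            if not grp["timestamp"].is_monotonic_increasing:
                raise ValueError("timestamps not increasing within a "
                                 "site x depth series")
    t = out["temp_c"].to_numpy(dtype=float)
    if np.any((t < -2) | (t > 35)):
        warnings.warn("temperature records outside the plausible "
                      "(-2, 35) degC range")
    return out


def read_temperature(path) -> pd.DataFrame:
    return validate_series(pd.read_csv(path))


def _julian_day(ts: pd.Series) -> np.ndarray:
    """Day-of-year with Feb 29 folded into day 59, so years align on 365."""
    doy = ts.dt.dayofyear.to_numpy().copy()
    leap = ts.dt.is_leap_year.to_numpy()
    after_feb28 = doy >= 60
    doy[leap & after_feb28] -= 1
    doy[leap & (ts.dt.month.to_numpy() == 2) & (ts.dt.day.to_numpy() == 29)] \
        = 59
    return doy


def daily_climatology(series: pd.DataFrame) -> pd.DataFrame:
    """Per-julian-day mean and SD of the daily mean temperature across years.

    Daily means are computed first; julian days with no record in any year
    are flagged (``n_years`` 0, NaN statistics).
    """
    s = validate_series(series)
    s = s.assign(date=s["timestamp"].dt.normalize())
    daily = s.groupby("date", as_index=False)["temp_c"].mean()
    daily["jday"] = _julian_day(pd.to_datetime(daily["date"]))
    grp = daily.groupby("jday")["temp_c"]
    out = pd.DataFrame({"mean": grp.mean(), "sd": grp.std(ddof=1),
                        "n_years": grp.size()})
    out = out.reindex(range(1, 366))
    out["n_years"] = out["n_years"].fillna(0).astype(int)
    out.index.name = "jday"
    return out


def warm_period(series: pd.DataFrame) -> pd.DataFrame:
    """Hourly records inside July 1 - October 31, all years pooled."""
    s = validate_series(series)
    return s[s["timestamp"].dt.month.isin(WARM_MONTHS)]


def _box_stats(values: np.ndarray) -> pd.Series:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return pd.Series({"median": med, "q1": q1, "q3": q3, "iqr": q3 - q1,
                      "min": values.min(), "max": values.max(),
                      "mean": values.mean(), "n": len(values)})


def warm_period_stats(series: pd.DataFrame) -> pd.Series:
    """Median, quartiles, IQR, min, max of warm-period hourly records."""
    w = warm_period(series)
    if w.empty:
        raise ValueError("no warm-period records")
    return _box_stats(w["temp_c"].to_numpy(dtype=float))


def extreme_tail_stats(series: pd.DataFrame, q: float = 0.90) -> pd.Series:
    """Boxplot statistics of warm-period records at or above the q-quantile.

    The quantile (linear interpolation) is computed on the pooled warm-period
    records; the retained tail is every record >= it.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    w = warm_period(series)
    if w.empty:
        raise ValueError("no warm-period records")
    vals = w["temp_c"].to_numpy(dtype=float)
    thr = np.quantile(vals, q)
    tail = vals[vals >= thr]
    out = _box_stats(tail)
    out["threshold"] = thr
    return out


def kruskal_dunn(groups: dict, alpha: float = 0.05) -> tuple[float, pd.DataFrame]:
    """Global Kruskal-Wallis p plus Dunn pairwise z-tests, Sidak-adjusted.

    ``groups`` maps label -> 1-D array of warm-period records (>=3 groups,
    each >=5 records).  The pairwise adjustment is p_adj = 1 - (1 - p)^m
    with m the number of pairs.
    """
    labels = list(groups)
    if len(labels) < 3:
        raise ValueError(">=3 groups required")
    arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    if any(len(a) < 5 for a in arrays):
        raise ValueError("every group needs >=5 records")
    _, kw_p = stats.kruskal(*arrays)

    pooled = np.concatenate(arrays)
    n_tot = len(pooled)
    ranks = stats.rankdata(pooled)
    # tie correction for the rank variance
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12 * (n_tot - 1))
    var_unit = n_tot * (n_tot + 1) / 12 - tie_term
    mean_rank, sizes = {}, {}
    start = 0
    for lab, arr in zip(labels, arrays):
        mean_rank[lab] = ranks[start:start + len(arr)].mean()
        sizes[lab] = len(arr)
        start += len(arr)

    pairs = list(itertools.combinations(labels, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        se = np.sqrt(var_unit * (1 / sizes[a] + 1 / sizes[b]))
        z = (mean_rank[a] - mean_rank[b]) / se
        p = 2 * stats.norm.sf(abs(z))
        p_adj = 1 - (1 - p) ** m
        rows.append({"group_a": a, "group_b": b, "z": z, "p": p,
                     "p_adj": p_adj, "significant": p_adj < alpha})
    return float(kw_p), pd.DataFrame(rows)
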