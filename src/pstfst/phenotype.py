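"""Necrosis response summaries for common-garden thermotolerance panels.

A necrosis panel is a tidy long-format table, one row per colony-day, with
columns: colony, population, locality, depth, set (Control | Treatment),
tank, day, necrosis (% of the colony showing dead tissue or denuded axis,
0-100).  A colony counts as "affected" when its necrosis is strictly > 0.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["read_necrosis", "write_necrosis", "validate_panel",
           "percent_affected", "mean_se_daily", "stopping_day",
           "final_day_mean_necrosis"]

PANEL_COLUMNS = ["colony", "population", "locality", "depth", "set",
                 "tank", "day", "necrosis"]


def validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Schema and sanity checks; returns the panel unchanged.

    Control colonies with non-zero necrosis draw a warning (in a valid study
    they remain healthy), out-of-range necrosis is an error.
    """
    missing = [c for c in ("colony", "day", "necrosis")
               if c not in panel.columns]
    if missing:
        raise ValueError(f"panel lacks required columns: {missing}")
    nec = panel["necrosis"].to_numpy(dtype=float)
    if np.any((nec < 0) | (nec > 100)):
        raise ValueError("necrosis outside [0, 100]")
    if panel.duplicated(["colony", "day"]).any():
        raise ValueError("more than one record per colony x day")
    if "set" in panel.columns:
        ctrl = panel[panel["set"] == "Control"]
        if (ctrl["necrosis"] > 0).any():
            warnings.warn("Control colonies with necrosis > 0 present")
    return panel


def read_necrosis(path) -> pd.DataFrame:
    return validate_panel(pd.read_csv(path))


def write_necrosis(panel: pd.DataFrame, path) -> None:
    validate_panel(panel).to_csv(path, index=False)


def _treatment(panel: pd.DataFrame) -> pd.DataFrame:
    if "set" in panel.columns:
        return panel[panel["set"] == "Treatment"]
    return panel


def percent_affected(panel: pd.DataFrame, day: int,
                     by: str = "all") -> float | pd.Series:
    """Percentage of Treatment colonies with necrosis > 0 on the given day.

    ``by="population"`` returns a per-population Series; ``by="all"`` pools
    every colony.
    """
    df = _treatment(panel)
    df = df[df["day"] == day]
    if df.empty:
        raise ValueError(f"no records at day {day}")
    affected = df["necrosis"] > 0
    if by == "all":
        return float(100.0 * affected.mean())
    out = df.assign(_aff=affected).groupby(by)["_aff"].mean() * 100
    if (df.groupby(by).size() == 0).any():
        raise ValueError("empty group")
    return out


def mean_se_daily(panel: pd.DataFrame, statistic: str = "affected",
                  by: str = "population") -> pd.DataFrame:
    """Per-day mean +/- SE across populations of an affected-% or
    mean-necrosis summary (SE = sd / sqrt(number of populations))."""
    df = _treatment(panel)
    if df[by].nunique() < 2:
        raise ValueError("SE across populations needs >=2 populations")
    if statistic == "affected":
        per_pop = (df.assign(_v=df["necrosis"] > 0)
                   .groupby(["day", by])["_v"].mean() * 100)
    elif statistic == "mean-necrosis":
        per_pop = df.groupby(["day", by])["necrosis"].mean()
    else:
        raise ValueError("statistic must be 'affected' or 'mean-necrosis'")
    grp = per_pop.groupby(level="day")
    out = pd.DataFrame({"mean": grp.mean(),
                        "se": grp.std(ddof=1) / np.sqrt(grp.size())})
    return out


def stopping_day(panel: pd.DataFrame, threshold: float = 95.0):
    """First day on which at least ``threshold`` % of colonies are affected;
    None if the panel never reaches it."""
    if not 0 < threshold <= 100:
        raise ValueError("threshold must be in (0, 100]")
    df = _treatment(panel)
    for day in sorted(df["day"].unique()):
        if percent_affected(panel, day) >= threshold:
            return int(day)
    return None


def final_day_mean_necrosis(panel: pd.DataFrame, pool_map=None,
                            pool_column=None) -> pd.Series:
    """Mean necrosis per genetic pool on the last experiment day.

    The last day is the maximum day present.  ``pool_map`` merges sampled
    populations into genetic pools before averaging (pooled mean over all
    member colonies, i.e. the size-weighted mean of the merged populations).
    """
    df = _treatment(panel)
    last = df["day"].max()
    df = df[df["day"] == last].copy()
    col = pool_column or ("pool" if "pool" in df.columns else "population")
    labels = df[col].astype(str)
    if pool_map is not None:
        labels = labels.map(lambda p: str(pool_map.get(p, p)))
    out = df.assign(_pool=labels.to_numpy()).groupby("_pool")["necrosis"].mean()
    out.index.name = "pool"
    return out
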