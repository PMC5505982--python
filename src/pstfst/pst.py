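"""P_ST estimation from PERMANOVA mean squares.

P_ST is the phenotypic analog of Q_ST computed from total variance
components: P_ST = c * sigma2_GB / (c * sigma2_GB + 2 * h2 * sigma2_GW),
with the between-pool component extracted from one-way mean squares as
sigma2_GB = (MS_B - MS_W) / n0 (negative estimates set to zero) and n0 the
weighted average sample size for unbalanced designs.  Under the null
assumption that the trait's genetic architecture is constant across pools,
c / h2 = 1.

Point estimates and 95% CIs come from a bootstrap of the multivariate
response (colonies resampled with replacement, stratified within genetic
pool), one PERMANOVA per replicate: the point estimate is the bootstrap
median and the CI the 25th/975th order statistics for 1000 replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import as_generator, child_seed
from .containers import DivergenceMatrix
from .permanova import (DistanceMatrix, PermanovaResult, necrosis_distance,
                        permanova_oneway)

__all__ = [
    "VarianceComponents", "PstEstimate", "n0_weighted",
    "variance_components", "pst_point", "pst_bootstrap", "pairwise_pst",
    "divergence_table",
]


@dataclass
class VarianceComponents:
    ms_between: float
    ms_within: float
    n0: float
    a: int
    n_i: np.ndarray
    sigma2_gb: float
    sigma2_gw: float
    flags: tuple = ()


@dataclass
class PstEstimate:
    scope: object
    c_over_h2: float
    pst: float
    ci_low: float
    ci_high: float
    n_boot: int
    n_perm_inner: int
    samples: np.ndarray | None = None


def n0_weighted(n_i) -> float:
    """Weighted average sample size: (1/(a-1)) (sum n_i - sum n_i^2 / sum n_i).

    Equals n when all a pools have equal size n, and never exceeds max(n_i).
    """
    n_i = np.asarray(n_i, dtype=float)
    a = len(n_i)
    if a < 2:
        raise ValueError(">=2 pools required for n0")
    if (n_i < 1).any():
        raise ValueError("pool sizes must be >= 1")
    s = n_i.sum()
    return float((s - (n_i ** 2).sum() / s) / (a - 1))


def variance_components(res: PermanovaResult) -> VarianceComponents:
    """Extract sigma2_GB and sigma2_GW from a one-way PERMANOVA result."""
    if res.group_sizes is None or len(res.group_sizes) == 0:
        raise ValueError("PermanovaResult lacks group sizes")
    n_i = res.group_sizes.to_numpy(dtype=float)
    n0 = n0_weighted(n_i)
    ms_b, ms_w = res.ms_between, res.ms_within
    gb = (ms_b - ms_w) / n0
    flags = ("negative_sigma2_gb_clamped",) if gb < 0 else ()
    return VarianceComponents(ms_b, ms_w, n0, len(n_i), n_i,
                              max(gb, 0.0), ms_w, flags)


def pst_point(vc: VarianceComponents, c_over_h2: float = 1.0) -> float:
    """P_ST = r sigma2_GB / (r sigma2_GB + 2 sigma2_GW), r = c/h2.

    Returns 0 when both variance components are zero (degenerate data).
    """
    if c_over_h2 <= 0:
        raise ValueError("c_over_h2 must be > 0")
    gb, gw = vc.sigma2_gb, vc.sigma2_gw
    if gb < 0 or gw < 0:
        raise ValueError("variance components must be non-negative")
    denom = c_over_h2 * gb + 2 * gw
    if denom == 0:
        return 0.0
    return float(c_over_h2 * gb / denom)


# ---------------------------------------------------------------------------
# fast mean squares straight from the day-vectors (Euclidean identity)
# ---------------------------------------------------------------------------

def _ms_from_matrix(x: np.ndarray, codes: np.ndarray, sizes: np.ndarray):
    """One-way (MS_B, MS_W) from raw coordinates; identical to the
    distance-based partition for Euclidean distances."""
    n, _ = x.shape
    a = len(sizes)
    ss_w = 0.0
    for g in range(a):
        xg = x[codes == g]
        ss_w += ((xg - xg.mean(axis=0)) ** 2).sum()
    ss_t = ((x - x.mean(axis=0)) ** 2).sum()
    return (ss_t - ss_w) / (a - 1), ss_w / (n - a)


def _panel_matrix(panel: pd.DataFrame, days, pool_map=None,
                  pool_column=None):
    """Treatment colonies as (X, pool labels, colony ids)."""
    df = panel
    if "set" in df.columns:
        df = df[df["set"] == "Treatment"]
    sub = df[df["day"].isin(days)]
    wide = sub.pivot_table(index="colony", columns="day", values="necrosis",
                           aggfunc="first")
    missing = [d for d in days if d not in wide.columns]
    if missing:
        raise ValueError(f"no records at day(s) {missing}")
    wide = wide[list(days)].dropna()
    meta = df.drop_duplicates("colony").set_index("colony")
    col = pool_column or ("pool" if "pool" in meta.columns else "population")
    pools = meta.loc[wide.index, col].astype(str)
    if pool_map is not None:
        pools = pools.map(lambda p: str(pool_map.get(p, p)))
    return wide.to_numpy(dtype=float), pools.to_numpy(dtype=object), \
        wide.index.to_numpy()


def pst_bootstrap(panel: pd.DataFrame, days=(10, 20, 30), scope="global",
                  pool_map=None, pool_column=None, n_boot: int = 1000,
                  n_perm_inner: int = 100, c_over_h2: float = 1.0,
                  seed=None, fast: bool = True,
                  keep_samples: bool = False) -> PstEstimate:
    """Bootstrap P_ST point estimate (median) and 95% CI.

    Each replicate resamples colonies with replacement stratified within
    genetic pool (preserving the n_i), runs a one-way PERMANOVA on the
    replicate, and converts its mean squares to a P_ST.  For exactly 1000
    replicates the CI bounds are the 25th and 975th sorted values; otherwise
    percentile interpolation is used.  ``fast=True`` computes the mean
    squares directly from the day-vectors (the Euclidean identity makes the
    inner permutations irrelevant to the MS); ``fast=False`` runs the full
    permutation PERMANOVA per replicate, with identical mean squares.
    """
    x, pools, _ = _panel_matrix(panel, days, pool_map, pool_column)
    if scope != "global":
        a, b = scope
        m = np.isin(pools, [str(a), str(b)])
        x, pools = x[m], pools[m]
    levels, codes = np.unique(pools, return_inverse=True)
    sizes = np.bincount(codes)
    if len(levels) < 2:
        raise ValueError(">=2 genetic pools required")
    if (sizes < 3).any():
        raise ValueError("every pool needs >=3 colonies for the bootstrap")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable CI bounds")
    rng = as_generator(seed if isinstance(seed, np.random.Generator)
                       else child_seed(seed, 51))

    vals = np.empty(n_boot)
    group_idx = [np.flatnonzero(codes == g) for g in range(len(levels))]
    codes_r = np.repeat(np.arange(len(levels)), sizes)
    pools_r = np.repeat(levels, sizes)
    for rep in range(n_boot):
        take = np.concatenate([gi[rng.integers(0, len(gi), size=len(gi))]
                               for gi in group_idx])
        xr = x[take]
        if fast:
            ms_b, ms_w = _ms_from_matrix(xr, codes_r, sizes)
            n0 = n0_weighted(sizes)
            gb = max((ms_b - ms_w) / n0, 0.0)
            vc = VarianceComponents(ms_b, ms_w, n0, len(sizes),
                                    sizes.astype(float), gb, ms_w)
        else:
            from scipy.spatial.distance import pdist, squareform
            dmat = DistanceMatrix(squareform(pdist(xr)),
                                  ids=[str(i) for i in range(len(xr))])
            res = permanova_oneway(dmat, pools_r, n_perm=n_perm_inner,
                                   seed=child_seed(seed, 52, rep))
            vc = variance_components(res)
        vals[rep] = pst_point(vc, c_over_h2)

    vals.sort()
    point = float(np.median(vals))
    if n_boot == 1000:
        lo, hi = float(vals[24]), float(vals[974])
    else:
        lo, hi = (float(v) for v in np.percentile(vals, [2.5, 97.5]))
    return PstEstimate(scope, c_over_h2, point, lo, hi, n_boot, n_perm_inner,
                       vals if keep_samples else None)


def pairwise_pst(panel: pd.DataFrame, days=(10, 20, 30), pool_map=None,
                 pool_column=None, n_boot: int = 1000,
                 n_perm_inner: int = 100, c_over_h2: float = 1.0,
                 seed=None, fast: bool = True) -> DivergenceMatrix:
    """All pairwise P_ST estimates as a :class:`DivergenceMatrix`."""
    _, pools, _ = _panel_matrix(panel, days, pool_map, pool_column)
    levels = list(dict.fromkeys(pools.tolist()))
    vals, ci = {}, {}
    for i, a in enumerate(levels):
        for j in range(i + 1, len(levels)):
            b = levels[j]
            est = pst_bootstrap(panel, days=days, scope=(a, b),
                                pool_map=pool_map, pool_column=pool_column,
                                n_boot=n_boot, n_perm_inner=n_perm_inner,
                                c_over_h2=c_over_h2,
                                seed=child_seed(seed, 53, i, j), fast=fast)
            vals[(a, b)] = est.pst
            ci[(a, b)] = (est.ci_low, est.ci_high)
    return DivergenceMatrix.from_pairs(levels, vals, kind="PST", pair_ci=ci)


def divergence_table(pst_dm: DivergenceMatrix,
                     fst_dm: DivergenceMatrix) -> pd.DataFrame:
    """Pairwise P_ST and F_ST side by side with their 95% CIs."""
    if list(pst_dm.labels) != list(fst_dm.labels):
        raise ValueError("matrices must share pool labels and order")
    rows = []
    for i, j in pst_dm.pair_index():
        rows.append({
            "pair": f"{pst_dm.labels[i]} vs. {pst_dm.labels[j]}",
            "pst": pst_dm.values[i, j],
            "pst_ci_low": pst_dm.ci_low[i, j],
            "pst_ci_high": pst_dm.ci_high[i, j],
            "fst": fst_dm.values[i, j],
            "fst_ci_low": fst_dm.ci_low[i, j],
            "fst_ci_high": fst_dm.ci_high[i, j]})
    return pd.DataFrame(rows)
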