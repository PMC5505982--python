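"""Comparison of phenotypic (P_ST) and neutral genetic (F_ST) divergence.

Three complementary comparisons, mirroring the standard Q_ST-F_ST logic:

* a Mantel test correlating the two pairwise divergence matrices (a
  significant positive association with no excess of P_ST over F_ST points
  to drift rather than divergent selection);
* per-pair and global 95% CI overlap, including the divergent-selection
  signature test (P_ST interval entirely above the F_ST interval);
* a Spearman correlation between population-specific F_ST (drift intensity)
  and mean final-day necrosis (thermal-stress impact).
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import as_generator, child_seed
from .containers import DivergenceMatrix

__all__ = ["DivergenceComparison", "mantel_test", "ci_overlap_compare",
           "interval_overlap", "spearman_fst_necrosis", "compare_divergence"]


def mantel_test(m1: DivergenceMatrix, m2: DivergenceMatrix,
                n_perm: int = 1000, seed=None,
                alternative: str = "greater") -> tuple[float, float]:
    """Mantel test between two pairwise divergence matrices.

    r is the Pearson correlation over the upper-triangle entries; the p-value
    permutes pool labels (simultaneous row/column permutation of one matrix).
    One-sided positive association by default (the stated hypothesis when
    comparing P_ST to F_ST); ``alternative="two-sided"`` uses |r|.
    """
    if list(m1.labels) != list(m2.labels):
        raise ValueError("matrices must share pool labels and order")
    k = m1.n_pools
    if k < 4:
        raise ValueError(">=4 pools required for a Mantel test")
    iu = np.triu_indices(k, k=1)
    v1, v2 = m1.values[iu], m2.values[iu]
    if np.ptp(v1) == 0 or np.ptp(v2) == 0:
        raise ValueError("a matrix is constant across pairs; r undefined")
    r_obs = float(np.corrcoef(v1, v2)[0, 1])
    rng = as_generator(seed if isinstance(seed, np.random.Generator)
                       else child_seed(seed, 61))
    count = 0
    b = m2.values
    for _ in range(n_perm):
        perm = rng.permutation(k)
        v2p = b[np.ix_(perm, perm)][iu]
        rp = np.corrcoef(v1, v2p)[0, 1]
        if alternative == "two-sided":
            hit = abs(rp) >= abs(r_obs) - 1e-12
        else:
            hit = rp >= r_obs - 1e-12
        count += bool(hit)
    p = (1 + count) / (1 + n_perm)
    return r_obs, float(p)


def interval_overlap(lo1, hi1, lo2, hi2) -> bool:
    """Closed-interval intersection (touching endpoints count as overlap)."""
    return bool(max(lo1, lo2) <= min(hi1, hi2))


def ci_overlap_compare(pst_dm: DivergenceMatrix,
                       fst_dm: DivergenceMatrix) -> pd.DataFrame:
    """Per-pair 95% CI comparison between P_ST and F_ST.

    Columns: ``overlap`` (closed-interval intersection non-empty) and
    ``pst_above`` (P_ST CI entirely above the F_ST CI, the divergent-
    selection signature).
    """
    if list(pst_dm.labels) != list(fst_dm.labels):
        raise ValueError("matrices must share pool labels and order")
    for dm, name in ((pst_dm, "PST"), (fst_dm, "FST")):
        if dm.ci_low is None or dm.ci_high is None:
            raise ValueError(f"{name} matrix lacks CIs")
    rows = []
    for i, j in pst_dm.pair_index():
        pl, ph = pst_dm.ci_low[i, j], pst_dm.ci_high[i, j]
        fl, fh = fst_dm.ci_low[i, j], fst_dm.ci_high[i, j]
        if not all(np.isfinite(v) for v in (pl, ph, fl, fh)):
            raise ValueError(
                f"missing CI for pair {pst_dm.labels[i]} vs. "
                f"{pst_dm.labels[j]}")
        rows.append({"pool_a": pst_dm.labels[i], "pool_b": pst_dm.labels[j],
                     "overlap": interval_overlap(pl, ph, fl, fh),
                     "pst_above": bool(pl > fh)})
    return pd.DataFrame(rows)


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float,
                      alternative: str) -> float:
    """Exact permutation p for Spearman rho over all n! pairings."""
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    count = total = 0
    for perm in itertools.permutations(range(n)):
        rp = np.corrcoef(rx, ry[list(perm)])[0, 1]
        total += 1
        if alternative == "greater":
            count += rp >= rho_obs - 1e-12
        elif alternative == "less":
            count += rp <= rho_obs + 1e-12
        else:
            count += abs(rp) >= abs(rho_obs) - 1e-12
    return count / total


def spearman_fst_necrosis(pop_fst, final_necrosis,
                          alternative: str = "two-sided"
                          ) -> tuple[float, float]:
    """Spearman correlation of population-specific F_ST vs final-day necrosis.

    Both arguments map genetic pool -> value (dict or Series); pools must
    match.  Average ranks are used for ties; the p-value is the exact
    permutation p over all pairings for n <= 8 pools, else the large-sample
    approximation.
    """
    f = pd.Series(pop_fst)
    nec = pd.Series(final_necrosis)
    if set(f.index) != set(nec.index):
        raise ValueError("pool labels differ between the two inputs")
    nec = nec.loc[f.index]
    if f.nunique() == 1 or nec.nunique() == 1:
        raise ValueError("constant vector; rho undefined")
    if len(f) < 5:
        raise ValueError(">=5 pools required for a meaningful p-value")
    rho = float(stats.spearmanr(f, nec).statistic)
    if len(f) <= 8:
        p = _spearman_exact_p(f.to_numpy(), nec.to_numpy(), rho, alternative)
    else:
        res = stats.spearmanr(f, nec,
                              alternative=alternative.replace("-", "_")
                              if alternative != "two-sided" else "two-sided")
        p = float(res.pvalue)
    return rho, float(p)


class DivergenceComparison:
    """Bundle of all phenotype-vs-neutral comparisons with a CSV export."""

    def __init__(self, mantel_r, mantel_p, n_perm, pair_table,
                 global_overlap=None, spearman_rho=None, spearman_p=None):
        if not -1 <= mantel_r <= 1:
            raise ValueError("mantel r outside [-1, 1]")
        self.mantel_r = mantel_r
        self.mantel_p = mantel_p
        self.n_perm = n_perm
        self.pair_table = pair_table
        self.global_overlap = global_overlap
        self.spearman_rho = spearman_rho
        self.spearman_p = spearman_p

    def to_frame(self) -> pd.DataFrame:
        rows = self.pair_table.copy()
        summary = {"pool_a": "(summary)", "pool_b": "",
                   "overlap": bool(rows["overlap"].all()),
                   "pst_above": bool(rows["pst_above"].any()),
                   "mantel_r": self.mantel_r, "mantel_p": self.mantel_p}
        if self.spearman_rho is not None:
            summary["spearman_rho"] = self.spearman_rho
            summary["spearman_p"] = self.spearman_p
        return pd.concat([rows, pd.DataFrame([summary])], ignore_index=True)


def compare_divergence(pst_dm: DivergenceMatrix, fst_dm: DivergenceMatrix,
                       n_perm: int = 1000, seed=None,
                       global_pst=None, global_fst=None,
                       pop_fst=None, final_necrosis=None
                       ) -> DivergenceComparison:
    """Run the full comparison: Mantel, CI overlap, optional global overlap
    and the population-specific-F_ST vs final-necrosis Spearman test."""
    r, p = mantel_test(pst_dm, fst_dm, n_perm=n_perm, seed=seed)
    pairs = ci_overlap_compare(pst_dm, fst_dm)
    glob = None
    if global_pst is not None and global_fst is not None:
        glob = interval_overlap(global_pst.ci_low, global_pst.ci_high,
                                global_fst.ci_low, global_fst.ci_high)
    rho = sp = None
    if pop_fst is not None and final_necrosis is not None:
        rho, sp = spearman_fst_necrosis(pop_fst, final_necrosis)
    return DivergenceComparison(r, p, n_perm, pairs, glob, rho, sp)
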