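"""Distance-based multivariate ANOVA (PERMANOVA).

Implements the Anderson (2001) sum-of-squares partition directly from a
distance matrix: one-way and two-way crossed designs, permutation p-values,
and pairwise post-hoc tests.  The one-way mean squares are the raw material
for P_ST variance components, so every result carries the full term table
(df, SS, MS, pseudo-F, permutation p) and the group sizes.

Distances live in :class:`skbio.stats.distance.DistanceMatrix`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix

from ._utils import as_generator, child_seed

__all__ = [
    "DistanceMatrix", "PermanovaResult", "necrosis_distance",
    "permanova_oneway", "permanova_twoway", "pairwise_posthoc",
]


@dataclass
class PermanovaResult:
    """ANOVA-style term table plus design bookkeeping.

    ``terms`` is indexed by term name (factors, interaction, ``Residual``,
    ``Total``) with columns df, SS, MS, pseudo_F, p_perm.
    """

    terms: pd.DataFrame
    group_sizes: pd.Series
    n_perm: int
    method: str = "one-way"

    @property
    def ms_between(self) -> float:
        return float(self.terms["MS"].iloc[0])

    @property
    def ms_within(self) -> float:
        return float(self.terms.loc["Residual", "MS"])

    def to_csv(self, path) -> None:
        self.terms.to_csv(path, index_label="term")


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def necrosis_distance(panel: pd.DataFrame, days=(10, 20, 30),
                      value: str = "necrosis") -> DistanceMatrix:
    """Euclidean distances between colonies on their day-vector of necrosis.

    Control colonies are excluded (the response of interest is the heated
    treatment); every Treatment colony must have a record on each requested
    day.
    """
    df = panel
    if "set" in df.columns:
        df = df[df["set"] == "Treatment"]
    df = df[df["day"].isin(days)]
    wide = df.pivot_table(index="colony", columns="day", values=value,
                          aggfunc="first")
    missing = [d for d in days if d not in wide.columns]
    if missing:
        raise ValueError(f"no records at day(s) {missing}")
    wide = wide[list(days)]
    bad = wide.index[wide.isna().any(axis=1)].tolist()
    if bad:
        raise ValueError(f"colonies missing a requested day: {bad}")
    mat = squareform(pdist(wide.to_numpy(), metric="euclidean"))
    return DistanceMatrix(mat, ids=[str(c) for c in wide.index])


def colony_groups(panel: pd.DataFrame, dm: DistanceMatrix,
                  column: str = "population") -> np.ndarray:
    """Group label per distance-matrix id, read from the panel metadata."""
    meta = (panel.drop_duplicates("colony").set_index("colony")[column])
    meta.index = meta.index.map(str)
    return meta.loc[list(dm.ids)].to_numpy()


# ---------------------------------------------------------------------------
# one-way
# ---------------------------------------------------------------------------

def _oneway_ss(d2: np.ndarray, codes: np.ndarray, sizes: np.ndarray):
    n = len(codes)
    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    for gcode, ng in enumerate(sizes):
        m = codes == gcode
        ss_within += d2[np.ix_(m, m)].sum() / (2 * ng)
    return ss_total, ss_total - ss_within, ss_within


def permanova_oneway(dm: DistanceMatrix, groups, n_perm: int = 9999,
                     seed=None, name: str = "groups") -> PermanovaResult:
    """One-way PERMANOVA: pseudo-F = MS_between / MS_within, p by permutation
    of group labels over observations, with +1 smoothing so p is never 0.
    """
    groups = np.asarray(groups, dtype=object)
    d2 = np.asarray(dm.data, dtype=float) ** 2
    n = d2.shape[0]
    if len(groups) != n:
        raise ValueError("one group label per observation required")
    levels, codes = np.unique(groups, return_inverse=True)
    sizes = np.bincount(codes)
    if len(levels) < 2:
        raise ValueError(">=2 groups required")
    if (sizes < 2).any():
        small = levels[sizes < 2].tolist()
        raise ValueError(f"groups of size 1 not allowed: {small}")
    if n_perm < 99:
        warnings.warn("n_perm < 99 gives a very coarse p-value")

    a = len(levels)
    ss_t, ss_b, ss_w = _oneway_ss(d2, codes, sizes)
    df_b, df_w = a - 1, n - a
    ms_b, ms_w = ss_b / df_b, ss_w / df_w
    if ss_t <= 1e-12:
        f_obs, p = np.nan, 1.0
    else:
        f_obs = ms_b / ms_w if ms_w > 0 else np.inf
        rng = as_generator(seed if isinstance(seed, np.random.Generator)
                           else child_seed(seed, 41))
        count = 0
        chunk = max(1, min(n_perm, 2_000_000 // max(n * a, 1)))
        done = 0
        while done < n_perm:
            b = min(chunk, n_perm - done)
            perm_codes = np.empty((b, n), dtype=np.int64)
            for k in range(b):
                perm_codes[k] = rng.permutation(codes)
            ss_w_perm = np.zeros(b)
            for gcode, ng in enumerate(sizes):
                m = perm_codes == gcode            # (b, n)
                ss_w_perm += ((m @ d2) * m).sum(axis=1) / (2 * ng)
            ss_b_perm = ss_t - ss_w_perm
            with np.errstate(divide="ignore", invalid="ignore"):
                f_perm = (ss_b_perm / df_b) / (ss_w_perm / df_w)
            f_perm[ss_w_perm <= 0] = np.inf
            count += int((f_perm >= f_obs - 1e-12).sum())
            done += b
        p = (1 + count) / (1 + n_perm)

    terms = pd.DataFrame(
        {"df": [df_b, df_w, n - 1],
         "SS": [ss_b, ss_w, ss_t],
         "MS": [ms_b, ms_w, np.nan],
         "pseudo_F": [f_obs, np.nan, np.nan],
         "p_perm": [p, np.nan, np.nan]},
        index=[name, "Residual", "Total"])
    return PermanovaResult(terms, pd.Series(sizes, index=levels),
                           n_perm, "one-way")


# ---------------------------------------------------------------------------
# two-way crossed
# ---------------------------------------------------------------------------

def _hat(x: np.ndarray) -> np.ndarray:
    return x @ np.linalg.pinv(x.T @ x) @ x.T


def _rank(x: np.ndarray) -> int:
    return int(np.linalg.matrix_rank(x))


def _dummies(labels: np.ndarray) -> np.ndarray:
    return pd.get_dummies(pd.Series(labels)).to_numpy(dtype=float)


def permanova_twoway(dm: DistanceMatrix, factor_a, factor_b,
                     n_perm: int = 9999, seed=None,
                     names=("A", "B", "AxB")) -> PermanovaResult:
    """Two-way crossed PERMANOVA with a sequential Euclidean partition.

    Main-effect p-values come from unrestricted permutation of observations;
    the interaction p comes from permutation of residuals under the
    main-effects-only model (Freedman-Lane).  Every cell of the crossed
    design must be non-empty, and the two factors must not be confounded.
    """
    fa = np.asarray(factor_a, dtype=object)
    fb = np.asarray(factor_b, dtype=object)
    d2 = np.asarray(dm.data, dtype=float) ** 2
    n = d2.shape[0]
    if len(fa) != n or len(fb) != n:
        raise ValueError("factor length must match distance matrix")
    cells = pd.crosstab(pd.Series(fa), pd.Series(fb))
    if (cells == 0).any().any():
        raise ValueError("empty cell in the crossed design")

    j = np.eye(n) - np.ones((n, n)) / n
    gower = -0.5 * j @ d2 @ j

    one = np.ones((n, 1))
    xa = np.hstack([one, _dummies(fa)])
    xab = np.hstack([xa, _dummies(fb)])
    inter = _dummies(np.array([f"{x}\x1f{y}" for x, y in zip(fa, fb)],
                              dtype=object))
    xfull = np.hstack([xab, inter])
    r0, ra, rab, rfull = 1, _rank(xa), _rank(xab), _rank(xfull)
    df_a, df_b_, df_i = ra - r0, rab - ra, rfull - rab
    if df_b_ == 0:
        raise ValueError("factor B is confounded with factor A")
    if df_i == 0:
        raise ValueError("interaction confounded with main effects")
    df_res = n - rfull
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")

    h0 = np.ones((n, n)) / n
    ha, hab, hfull = _hat(xa), _hat(xab), _hat(xfull)
    m_a, m_b, m_i = ha - h0, hab - ha, hfull - hab
    m_res = np.eye(n) - hfull

    def tr(m, gmat):
        return float((m * gmat).sum())  # tr(M G), both symmetric-compatible

    ss = {"A": tr(m_a, gower), "B": tr(m_b, gower), "I": tr(m_i, gower),
          "res": tr(m_res, gower), "tot": float(np.trace(gower))}
    ms = {"A": ss["A"] / df_a, "B": ss["B"] / df_b_, "I": ss["I"] / df_i,
          "res": ss["res"] / df_res}
    f_obs = {k: (ms[k] / ms["res"] if ms["res"] > 0 else np.inf)
             for k in ("A", "B", "I")}

    rng = as_generator(seed if isinstance(seed, np.random.Generator)
                       else child_seed(seed, 42))
    counts = {"A": 0, "B": 0, "I": 0}
    g_res = (np.eye(n) - hab) @ gower @ (np.eye(n) - hab)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = gower[np.ix_(perm, perm)]
        den = tr(m_res, gp) / df_res
        for key, m, dfk in (("A", m_a, df_a), ("B", m_b, df_b_)):
            fp = (tr(m, gp) / dfk) / den if den > 0 else np.inf
            if fp >= f_obs[key] - 1e-12:
                counts[key] += 1
        gp_i = g_res[np.ix_(perm, perm)]
        den_i = tr(m_res, gp_i) / df_res
        fp_i = (tr(m_i, gp_i) / df_i) / den_i if den_i > 0 else np.inf
        if fp_i >= f_obs["I"] - 1e-12:
            counts["I"] += 1
    p = {k: (1 + counts[k]) / (1 + n_perm) for k in counts}

    na, nb, ni = names
    terms = pd.DataFrame(
        {"df": [df_a, df_b_, df_i, df_res, n - 1],
         "SS": [ss["A"], ss["B"], ss["I"], ss["res"], ss["tot"]],
         "MS": [ms["A"], ms["B"], ms["I"], ms["res"], np.nan],
         "pseudo_F": [f_obs["A"], f_obs["B"], f_obs["I"], np.nan, np.nan],
         "p_perm": [p["A"], p["B"], p["I"], np.nan, np.nan]},
        index=[na, nb, ni, "Residual", "Total"])
    sizes = pd.Series(fa).astype(str).str.cat(pd.Series(fb).astype(str),
                                              sep=":").value_counts()
    return PermanovaResult(terms, sizes, n_perm, "two-way")


# ---------------------------------------------------------------------------
# pairwise post-hoc
# ---------------------------------------------------------------------------

def pairwise_posthoc(dm: DistanceMatrix, groups, n_perm: int = 9999,
                     seed=None, adjust: str | None = None) -> pd.DataFrame:
    """Pairwise PERMANOVA t-tests (t = sqrt(pseudo-F)) on each pair's
    sub-matrix.  Unadjusted by default; ``adjust="sidak"`` applies a
    family-wise Sidak correction.
    """
    groups = np.asarray(groups, dtype=object)
    levels = list(dict.fromkeys(groups.tolist()))
    rows = []
    data = np.asarray(dm.data)
    ids = np.asarray(dm.ids)
    for i, a in enumerate(levels):
        for jdx in range(i + 1, len(levels)):
            b = levels[jdx]
            m = np.isin(groups, [a, b])
            sub = DistanceMatrix(data[np.ix_(m, m)], ids=ids[m].tolist())
            res = permanova_oneway(sub, groups[m], n_perm=n_perm,
                                   seed=child_seed(seed, 43, i, jdx))
            f = res.terms["pseudo_F"].iloc[0]
            rows.append({"pool_a": a, "pool_b": b,
                         "t": float(np.sqrt(f)) if np.isfinite(f) else f,
                         "p": float(res.terms["p_perm"].iloc[0])})
    out = pd.DataFrame(rows)
    if adjust == "sidak":
        m_pairs = len(out)
        out["p_adj"] = 1 - (1 - out["p"]) ** m_pairs
    return out
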