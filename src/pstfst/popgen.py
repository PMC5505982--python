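"""Microsatellite genotype model and neutral-divergence estimators.

The data model is a diploid multiallelic genotype table with sampled-population
labels and an optional merge of non-differentiated populations into genetic
pools.  On top of it sit:

* Genepop text I/O (2- or 3-digit allele encoding);
* per-pool allele frequency tables;
* Monte-Carlo exact tests of genotypic differentiation, with Fisher combination
  across loci and transitive-closure pool merging;
* the Weir & Cockerham (1984) theta estimator of F_ST (ratio of summed
  variance components over alleles and loci) with percentile bootstrap CIs
  over loci;
* an EM estimator of null-allele frequency under Hardy-Weinberg with one
  unobservable allele (missing genotypes treated as null homozygotes);
* a hierarchical Bayesian population-specific F_ST (pool frequencies drawn
  from a Dirichlet around an ancestral frequency with concentration
  (1 - F_i) / F_i), sampled by Metropolis-within-Gibbs on a collapsed
  Dirichlet-multinomial likelihood.

Missing data are handled complete-case per locus throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from ._utils import as_generator, child_seed
from .containers import DivergenceMatrix, FstEstimate

#: sentinel for a missing allele call (never 0: Genepop's 0 is decoded on read)
MISSING = -1


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Diploid multiallelic calls for individuals at named loci.

    ``calls`` has shape (n_individuals, n_loci, 2) with positive integer
    allele codes, or :data:`MISSING` in both slots for a missing genotype.
    Allele order within a call is not meaningful; calls are stored sorted.
    ``pool_of`` maps each individual to its sampled population;
    ``pool_merge`` maps sampled populations to genetic pools and is the
    identity until :func:`merge_genetic_pools` runs.
    """

    individuals: list
    loci: list
    calls: np.ndarray
    pools: np.ndarray
    pool_merge: dict = field(default_factory=dict)

    def __post_init__(self):
        self.individuals = list(self.individuals)
        self.loci = list(self.loci)
        self.calls = np.asarray(self.calls, dtype=np.int32)
        n, L = len(self.individuals), len(self.loci)
        if self.calls.shape != (n, L, 2):
            raise ValueError(f"calls shape {self.calls.shape} != ({n}, {L}, 2)")
        self.pools = np.asarray(self.pools, dtype=object)
        if self.pools.shape != (n,):
            raise ValueError("one pool label per individual required")
        bad = (self.calls == 0).any()
        if bad:
            raise ValueError("allele code 0 is not allowed; use MISSING (-1)")
        # canonical order within each call; keep missing as (-1, -1)
        self.calls = np.sort(self.calls, axis=2)
        miss = self.calls[:, :, 0] == MISSING
        self.calls[miss] = MISSING
        if not self.pool_merge:
            self.pool_merge = {p: p for p in self.sampled_pools}

    # -- labels -------------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def sampled_pools(self) -> list:
        seen = dict.fromkeys(self.pools.tolist())
        return list(seen)

    @property
    def genetic_pool_of(self) -> np.ndarray:
        """Genetic-pool label per individual (after any merge)."""
        return np.array([self.pool_merge.get(p, p) for p in self.pools],
                        dtype=object)

    @property
    def genetic_pools(self) -> list:
        seen = dict.fromkeys(self.genetic_pool_of.tolist())
        return list(seen)

    def with_merge(self, mapping: dict) -> "GenotypeMatrix":
        full = {p: mapping.get(p, p) for p in self.sampled_pools}
        return replace(self, pool_merge=full)

    def subset_pools(self, pools, level: str = "genetic") -> "GenotypeMatrix":
        labels = self.genetic_pool_of if level == "genetic" else self.pools
        mask = np.isin(labels, list(pools))
        return GenotypeMatrix(
            [ind for ind, m in zip(self.individuals, mask) if m],
            self.loci, self.calls[mask], self.pools[mask],
            dict(self.pool_merge))

    def missing_mask(self) -> np.ndarray:
        """(n, L) boolean, True where the genotype is missing."""
        return self.calls[:, :, 0] == MISSING


# ---------------------------------------------------------------------------
# Genepop I/O
# ---------------------------------------------------------------------------

_POOL_TAG = "pools:"


def write_genepop(g: GenotypeMatrix, path, digits: int = 3,
                  title: str | None = None) -> None:
    """Write Genepop text with the given allele digit width (2 or 3)."""
    if digits not in (2, 3):
        raise ValueError("digits must be 2 or 3")
    if (g.calls[g.calls > 0] >= 10 ** digits).any():
        raise ValueError(f"allele code does not fit in {digits} digits")
    pools_line = ";".join(str(p) for p in g.sampled_pools)
    head = title or "pstfst genotype export"
    lines = [f"{head} {_POOL_TAG}{pools_line}"]
    lines.extend(str(l) for l in g.loci)
    for pool in g.sampled_pools:
        lines.append("pop")
        for i in np.flatnonzero(g.pools == pool):
            toks = []
            for l in range(g.n_loci):
                a, b = g.calls[i, l]
                a = 0 if a == MISSING else a
                b = 0 if b == MISSING else b
                toks.append(f"{a:0{digits}d}{b:0{digits}d}")
            lines.append(f"{g.individuals[i]} , " + " ".join(toks))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


class GenepopParseError(ValueError):
    pass


def read_genepop(path) -> GenotypeMatrix:
    """Parse a Genepop file (2- or 3-digit dialect, ``pop`` separators).

    Missing genotypes encoded with allele 0 (``0000`` / ``000000`` or a
    half-missing call) become :data:`MISSING`.  Pool names are recovered from
    a ``pools:`` tag in the title line when present, else ``pop_1..N``.
    """
    with open(path) as fh:
        raw = [ln.rstrip("\n") for ln in fh]
    lines = [(i + 1, ln) for i, ln in enumerate(raw) if ln.strip()]
    if len(lines) < 3:
        raise GenepopParseError("file too short to be Genepop")
    title = lines[0][1]
    pool_names = None
    if _POOL_TAG in title:
        pool_names = [p for p in
                      title.split(_POOL_TAG, 1)[1].strip().split(";") if p]

    loci: list[str] = []
    k = 1
    while k < len(lines) and lines[k][1].strip().lower() != "pop":
        # locus names: one per line, or comma-separated on one line
        loci.extend(t.strip() for t in lines[k][1].split(",") if t.strip())
        k += 1
    if not loci:
        raise GenepopParseError(f"line {lines[k][0] if k < len(lines) else '?'}:"
                                " no locus names before first 'pop'")

    blocks: list[list[tuple[int, str]]] = []
    for lineno, ln in lines[k:]:
        if ln.strip().lower() == "pop":
            blocks.append([])
        else:
            if not blocks:
                raise GenepopParseError(f"line {lineno}: data before 'pop'")
            blocks[-1].append((lineno, ln))
    if any(len(b) == 0 for b in blocks):
        raise GenepopParseError("empty pop block")

    inds, calls, pools = [], [], []
    digits = None
    for b, block in enumerate(blocks):
        pname = (pool_names[b] if pool_names and b < len(pool_names)
                 else f"pop_{b + 1}")
        for lineno, ln in block:
            if "," not in ln:
                raise GenepopParseError(f"line {lineno}: missing comma after id")
            ident, rest = ln.split(",", 1)
            toks = rest.split()
            if len(toks) != len(loci):
                raise GenepopParseError(
                    f"line {lineno}: {len(toks)} genotypes for "
                    f"{len(loci)} loci")
            row = np.empty((len(loci), 2), dtype=np.int32)
            for l, tok in enumerate(toks):
                if len(tok) not in (4, 6) or not tok.isdigit():
                    raise GenepopParseError(
                        f"line {lineno}: bad genotype token {tok!r}")
                w = len(tok) // 2
                if digits is None:
                    digits = w
                elif digits != w:
                    raise GenepopParseError(
                        f"line {lineno}: inconsistent allele digit width")
                a, c = int(tok[:w]), int(tok[w:])
                if a == 0 or c == 0:
                    a = c = MISSING
                row[l] = (a, c)
            inds.append(ident.strip())
            calls.append(row)
            pools.append(pname)
    return GenotypeMatrix(inds, loci, np.stack(calls), np.array(pools))


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

def _locus_counts(g: GenotypeMatrix, locus: int, pool_labels: np.ndarray,
                  pools: list):
    """Allele copy counts and one-copy (heterozygote-for-allele) counts.

    Returns (alleles, counts[r, A], het_counts[r, A], n_ind[r]) for the given
    locus, complete-case.
    """
    c = g.calls[:, locus, :]
    ok = c[:, 0] != MISSING
    alleles = np.unique(c[ok])
    A = len(alleles)
    code = {a: i for i, a in enumerate(alleles)}
    r = len(pools)
    counts = np.zeros((r, A))
    het = np.zeros((r, A))
    n_ind = np.zeros(r, dtype=int)
    for pi, pool in enumerate(pools):
        sel = ok & (pool_labels == pool)
        n_ind[pi] = sel.sum()
        for a, b in c[sel]:
            ia, ib = code[a], code[b]
            counts[pi, ia] += 1
            counts[pi, ib] += 1
            if ia != ib:
                het[pi, ia] += 1
                het[pi, ib] += 1
    return alleles, counts, het, n_ind


def allele_frequencies(g: GenotypeMatrix, level: str = "genetic"
                       ) -> pd.DataFrame:
    """Tidy per-pool x locus allele frequency table (complete-case per locus).

    Pool x locus combinations with zero non-missing calls are flagged absent
    (``n_calls`` 0, frequency NaN) so downstream estimators can skip them.
    """
    labels = g.genetic_pool_of if level == "genetic" else g.pools
    pools = list(dict.fromkeys(labels.tolist()))
    rows = []
    for l, locus in enumerate(g.loci):
        alleles, counts, _, n_ind = _locus_counts(g, l, labels, pools)
        for pi, pool in enumerate(pools):
            tot = counts[pi].sum()
            if tot == 0:
                rows.append({"pool": pool, "locus": locus, "allele": np.nan,
                             "count": 0, "freq": np.nan, "n_calls": 0})
                continue
            for ai, a in enumerate(alleles):
                rows.append({"pool": pool, "locus": locus, "allele": int(a),
                             "count": int(counts[pi, ai]),
                             "freq": counts[pi, ai] / tot,
                             "n_calls": int(n_ind[pi])})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# exact genotypic differentiation and pool merging
# ---------------------------------------------------------------------------

@dataclass
class ExactTestResult:
    pool_a: object
    pool_b: object
    per_locus: pd.Series        # p-value per tested locus
    combined_p: float           # Fisher's method across loci
    skipped: list               # monomorphic loci
    n_mc: int


def _genotype_categories(calls: np.ndarray) -> np.ndarray:
    """Integer genotype category per individual (rows of sorted call pairs)."""
    _, codes = np.unique(calls, axis=0, return_inverse=True)
    return codes


def exact_differentiation_test(g: GenotypeMatrix, pool_a, pool_b,
                               n_mc: int = 9999, seed=None,
                               level: str = "sampled") -> ExactTestResult:
    """Monte-Carlo exact test of genotypic differentiation between two pools.

    Per locus, the genotype x pool contingency table is tested against the
    fixed-margins (multivariate hypergeometric) null; the statistic is the
    table probability, and the p-value is the +1-smoothed proportion of
    sampled tables as or less probable than the observed one.  Loci are
    combined by Fisher's method.
    """
    if n_mc < 999:
        raise ValueError("n_mc must be >= 999")
    labels = g.pools if level == "sampled" else g.genetic_pool_of
    for p in (pool_a, pool_b):
        if p not in labels:
            raise ValueError(f"pool {p!r} not present")
    rng = as_generator(seed)
    pvals, skipped = {}, []
    for l, locus in enumerate(g.loci):
        sel = np.isin(labels, [pool_a, pool_b]) & (g.calls[:, l, 0] != MISSING)
        calls = g.calls[sel, l, :]
        in_a = labels[sel] == pool_a
        if len(np.unique(calls)) < 2 or in_a.all() or not in_a.any():
            skipped.append(locus)
            continue
        cats = _genotype_categories(calls)
        n_cat = cats.max() + 1
        if n_cat < 2:
            skipped.append(locus)
            continue
        row_tot = np.bincount(cats, minlength=n_cat)
        obs_a = np.bincount(cats[in_a], minlength=n_cat)
        # log table probability up to a margin-only constant
        stat_obs = -(gammaln(obs_a + 1) + gammaln(row_tot - obs_a + 1)).sum()
        draws = rng.multivariate_hypergeometric(row_tot, int(in_a.sum()),
                                                size=n_mc)
        stat = -(gammaln(draws + 1)
                 + gammaln(row_tot[None, :] - draws + 1)).sum(axis=1)
        pvals[locus] = (1 + int((stat <= stat_obs + 1e-9).sum())) / (1 + n_mc)
    if skipped:
        warnings.warn(f"monomorphic loci skipped: {skipped}")
    if not pvals:
        raise ValueError("all loci monomorphic; exact test impossible")
    per_locus = pd.Series(pvals, name="p")
    x = -2.0 * np.log(per_locus.to_numpy()).sum()
    combined = float(chi2.sf(x, 2 * len(per_locus)))
    return ExactTestResult(pool_a, pool_b, per_locus,
                           max(combined, np.finfo(float).tiny),
                           skipped, n_mc)


def components_from_pvalues(pools: list, pvalues: dict, alpha: float) -> dict:
    """Connected components of the non-significant graph (transitive closure).

    ``pvalues`` maps unordered pool pairs to combined p-values; pairs with
    p > alpha are joined.  Returns pool -> merged-pool label, where a merged
    label is the '+'-join of its members in input order.
    """
    parent = {p: p for p in pools}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (a, b), p in pvalues.items():
        if p > alpha:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra
    groups: dict = {}
    for p in pools:
        groups.setdefault(find(p), []).append(p)
    mapping = {}
    for members in groups.values():
        label = members[0] if len(members) == 1 else "+".join(
            str(m) for m in members)
        for m in members:
            mapping[m] = label
    return mapping


def merge_genetic_pools(g: GenotypeMatrix, alpha: float = 0.001,
                        n_mc: int = 9999, seed=None) -> dict:
    """Merge sampled populations that are not significantly differentiated.

    All pairs are tested; pairs with Fisher-combined p > alpha are joined,
    and merging is the transitive closure of the resulting graph.
    """
    pools = g.sampled_pools
    if len(pools) < 2:
        raise ValueError(">=2 sampled populations required")
    pvalues = {}
    for i, a in enumerate(pools):
        for b in pools[i + 1:]:
            res = exact_differentiation_test(
                g, a, b, n_mc=n_mc, seed=child_seed(seed, 11, i, pools.index(b)))
            pvalues[(a, b)] = res.combined_p
    return components_from_pvalues(pools, pvalues, alpha)


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------

def _wc_locus_components(counts, het, n_ind):
    """Per-allele (a, b, c) variance components for one locus.

    ``counts``: allele copy counts (r x A); ``het``: per-allele one-copy
    individual counts (r x A); ``n_ind``: individuals with data per pool.
    Pools without data at the locus must be excluded beforehand.
    """
    n_i = n_ind.astype(float)
    r = len(n_i)
    nbar = n_i.mean()
    if r < 2 or nbar == 0:
        return 0.0, 0.0
    p_i = counts / (2 * n_i[:, None])
    h_i = het / n_i[:, None]
    nc = (r * nbar - (n_i ** 2).sum() / (r * nbar)) / (r - 1)
    pbar = (n_i[:, None] * p_i).sum(axis=0) / (r * nbar)
    s2 = (n_i[:, None] * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n_i[:, None] * h_i).sum(axis=0) / (r * nbar)
    if nbar <= 1 or nc == 0:
        return 0.0, 0.0
    inner = pbar * (1 - pbar) - (r - 1) / r * s2
    a = (nbar / nc) * (s2 - (inner - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return float(a.sum()), float((a + b + c).sum())


def _per_locus_components(g: GenotypeMatrix, pools):
    labels = g.genetic_pool_of
    nums, dens = [], []
    for l in range(g.n_loci):
        _, counts, het, n_ind = _locus_counts(g, l, labels, pools)
        have = n_ind > 0
        if have.sum() < 2:
            nums.append(np.nan)
            dens.append(np.nan)
            continue
        num, den = _wc_locus_components(counts[have], het[have], n_ind[have])
        nums.append(num)
        dens.append(den)
    return np.array(nums), np.array(dens)


def _theta_from_components(nums, dens):
    ok = np.isfinite(nums)
    if not ok.any() or dens[ok].sum() == 0:
        return np.nan
    return nums[ok].sum() / dens[ok].sum()


def wc_theta(g: GenotypeMatrix, scope="global", n_boot: int = 1000,
             seed=None):
    """Multi-locus Weir-Cockerham theta with bootstrap-over-loci 95% CI.

    ``scope``: ``"global"`` (one estimate over all genetic pools),
    ``"pairwise"`` (a :class:`DivergenceMatrix` over all pool pairs) or a
    ``(poolA, poolB)`` tuple.  Variance components are summed over alleles
    and loci (ratio of sums); the CI is the percentile bootstrap over loci.
    """
    pools = g.genetic_pools
    if len(pools) < 2:
        raise ValueError(">=2 genetic pools required")
    sizes = pd.Series(g.genetic_pool_of).value_counts()
    if (sizes < 2).any():
        raise ValueError("every genetic pool needs >=2 individuals")

    if scope == "pairwise":
        vals, ci = {}, {}
        for i, a in enumerate(pools):
            for b in pools[i + 1:]:
                est = wc_theta(g, scope=(a, b), n_boot=n_boot,
                               seed=child_seed(seed, 7, i, pools.index(b)))
                vals[(a, b)] = est.theta
                ci[(a, b)] = (est.ci_low, est.ci_high)
        return DivergenceMatrix.from_pairs(pools, vals, kind="FST",
                                           pair_ci=ci)

    if scope != "global":
        a, b = scope
        g = g.subset_pools([a, b])
        pools = [a, b]
    nums, dens = _per_locus_components(g, pools)
    theta = _theta_from_components(nums, dens)
    if np.isnan(theta):
        raise ValueError("no informative locus for theta")
    flags = ()
    ok = np.flatnonzero(np.isfinite(nums) & (dens != 0))
    if len(ok) < 2 or n_boot <= 0:
        lo = hi = np.nan
        if len(ok) < 2:
            flags = ("ci_unavailable_single_locus",)
        n_boot_eff = 0
    else:
        rng = as_generator(child_seed(seed, 8) if not isinstance(
            seed, np.random.Generator) else seed)
        idx = rng.integers(0, len(ok), size=(n_boot, len(ok)))
        bn = nums[ok][idx].sum(axis=1)
        bd = dens[ok][idx].sum(axis=1)
        bt = np.divide(bn, bd, out=np.full(n_boot, np.nan), where=bd != 0)
        bt = bt[np.isfinite(bt)]
        lo, hi = np.percentile(bt, [2.5, 97.5])
        n_boot_eff = n_boot
    theta = min(theta, 1.0)
    sc = "global" if scope == "global" else ("pair",) + tuple(scope)
    return FstEstimate(sc, float(theta), float(lo), float(hi),
                       n_boot_eff, flags)


# ---------------------------------------------------------------------------
# null-allele EM
# ---------------------------------------------------------------------------

def null_allele_em(g: GenotypeMatrix, min_calls: int = 5,
                   max_iter: int = 2000, tol: float = 1e-10) -> pd.DataFrame:
    """EM estimate of null-allele frequency per genetic pool x locus.

    Model: Hardy-Weinberg with one unobservable allele; apparent homozygotes
    may be visible/null heterozygotes and missing genotypes are treated as
    null homozygotes.  Returns a tidy frame with columns pool, locus,
    null_freq, n_calls, flag.
    """
    labels = g.genetic_pool_of
    rows = []
    for l, locus in enumerate(g.loci):
        c = g.calls[:, l, :]
        for pool in g.genetic_pools:
            inpool = labels == pool
            calls = c[inpool]
            ok = calls[:, 0] != MISSING
            n_miss = int((~ok).sum())
            obs = calls[ok]
            n_obs = len(obs)
            if n_obs < min_calls:
                rows.append({"pool": pool, "locus": locus,
                             "null_freq": np.nan, "n_calls": n_obs,
                             "flag": "insufficient_calls"})
                continue
            alleles = np.unique(obs)
            if len(alleles) < 2 and n_miss == 0:
                rows.append({"pool": pool, "locus": locus, "null_freq": 0.0,
                             "n_calls": n_obs, "flag": "monomorphic"})
                continue
            code = {a: i for i, a in enumerate(alleles)}
            k = len(alleles)
            hom = np.zeros(k)          # apparent homozygote counts per allele
            allele_het = np.zeros(k)   # copies carried in true heterozygotes
            for a, b in obs:
                if a == b:
                    hom[code[a]] += 1
                else:
                    allele_het[code[a]] += 1
                    allele_het[code[b]] += 1
            n_tot = n_obs + n_miss
            p = np.full(k, 0.9 / k)
            p0 = 0.1
            for _ in range(max_iter):
                f = p / np.maximum(p + 2 * p0, 1e-300)  # P(true hom | apparent)
                cnt = allele_het + hom * (1 + f)
                cnt0 = (hom * (1 - f)).sum() + 2 * n_miss
                tot = cnt.sum() + cnt0
                p_new = cnt / tot
                p0_new = cnt0 / tot
                if abs(p0_new - p0) + np.abs(p_new - p).sum() < tol:
                    p, p0 = p_new, p0_new
                    break
                p, p0 = p_new, p0_new
            rows.append({"pool": pool, "locus": locus,
                         "null_freq": float(min(p0, 1 - 1e-12)),
                         "n_calls": n_obs, "flag": ""})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# population-specific F_ST (hierarchical Bayesian)
# ---------------------------------------------------------------------------

@dataclass
class PopSpecificFst:
    estimates: list          # FstEstimate per genetic pool, scope ("pop", lab)
    rhat: pd.Series          # split-chain diagnostic per pool
    converged: bool
    samples: np.ndarray      # (n_pools, n_kept) posterior F draws
    pools: list

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"pool": [e.scope[1] for e in self.estimates],
             "fst": [e.theta for e in self.estimates],
             "ci_low": [e.ci_low for e in self.estimates],
             "ci_high": [e.ci_high for e in self.estimates],
             "rhat": self.rhat.to_numpy()})


def _dm_loglik(theta: float, p: np.ndarray, n: np.ndarray) -> float:
    """Collapsed Dirichlet-multinomial log-likelihood for one pool x locus."""
    N = n.sum()
    ap = theta * p
    return float(gammaln(theta) - gammaln(theta + N)
                 + (gammaln(ap + n) - gammaln(ap)).sum())


def population_specific_fst(g: GenotypeMatrix, n_iter: int = 50_000,
                            burn_in: int = 10_000, thin: int = 10,
                            seed=None, rhat_threshold: float = 1.1
                            ) -> PopSpecificFst:
    """Posterior median and 95% credible interval of per-pool F_ST.

    Hierarchical model: pool allele frequencies at each locus are Dirichlet
    around a shared ancestral frequency with concentration
    theta_i = (1 - F_i) / F_i; pool frequencies are integrated out, leaving a
    Dirichlet-multinomial likelihood for the observed allele counts.  F_i has
    a uniform (0, 1) prior; ancestral frequencies have a flat Dirichlet prior.
    Sampling is Metropolis-within-Gibbs (logit random walk on F_i, Dirichlet
    proposal on each locus's ancestral frequency).  A split-chain diagnostic
    (Gelman-Rubin on chain halves) is reported per pool.
    """
    pools = g.genetic_pools
    r = len(pools)
    if r < 3:
        raise ValueError(">=3 genetic pools required to separate ancestral "
                         "frequencies from pool effects")
    if burn_in >= n_iter:
        raise ValueError("burn_in must be < n_iter")
    labels = g.genetic_pool_of
    counts = []   # per locus: (r x A) allele copy counts
    for l in range(g.n_loci):
        _, cnt, _, n_ind = _locus_counts(g, l, labels, pools)
        if (n_ind > 0).sum() >= 2 and cnt.sum() > 0:
            counts.append(cnt)
    L = len(counts)
    if L == 0:
        raise ValueError("no informative locus")
    rng = as_generator(child_seed(seed, 21) if not isinstance(
        seed, np.random.Generator) else seed)

    F = np.full(r, 0.1)
    anc = [c.sum(axis=0) + 1.0 for c in counts]
    anc = [a / a.sum() for a in anc]
    ll = np.zeros((r, L))
    for i in range(r):
        th = (1 - F[i]) / F[i]
        for l in range(L):
            ll[i, l] = _dm_loglik(th, anc[l], counts[l][i])

    step = 0.35
    conc = 200.0
    kept = []
    n_kept = (n_iter - burn_in) // thin
    for it in range(n_iter):
        # F_i updates: logit random walk, uniform prior => logit Jacobian
        z = np.log(F / (1 - F))
        zp = z + step * rng.standard_normal(r)
        Fp = 1 / (1 + np.exp(-zp))
        for i in range(r):
            th = (1 - Fp[i]) / Fp[i]
            newll = np.array([_dm_loglik(th, anc[l], counts[l][i])
                              for l in range(L)])
            logr = (newll.sum() - ll[i].sum()
                    + np.log(Fp[i] * (1 - Fp[i]))
                    - np.log(F[i] * (1 - F[i])))
            if np.log(rng.random()) < logr:
                F[i] = Fp[i]
                ll[i] = newll
        # ancestral frequency updates per locus
        for l in range(L):
            cur = anc[l]
            alpha_fwd = conc * cur + 0.05
            prop = rng.dirichlet(alpha_fwd)
            prop = np.maximum(prop, 1e-9)
            prop /= prop.sum()
            alpha_rev = conc * prop + 0.05
            th_all = (1 - F) / F
            newll = np.array([_dm_loglik(th_all[i], prop, counts[l][i])
                              for i in range(r)])
            logq_fwd = (gammaln(alpha_fwd.sum()) - gammaln(alpha_fwd).sum()
                        + ((alpha_fwd - 1) * np.log(prop)).sum())
            logq_rev = (gammaln(alpha_rev.sum()) - gammaln(alpha_rev).sum()
                        + ((alpha_rev - 1) * np.log(cur)).sum())
            logr = newll.sum() - ll[:, l].sum() + logq_rev - logq_fwd
            if np.log(rng.random()) < logr:
                anc[l] = prop
                ll[:, l] = newll
        if it >= burn_in and (it - burn_in) % thin == 0:
            kept.append(F.copy())
    samples = np.array(kept).T  # (r, n_kept)

    half = samples.shape[1] // 2
    rhat = np.empty(r)
    for i in range(r):
        a, b = samples[i, :half], samples[i, half:2 * half]
        w = 0.5 * (a.var(ddof=1) + b.var(ddof=1))
        m = half
        bvar = m * ((a.mean() - samples[i, :2 * half].mean()) ** 2
                    + (b.mean() - samples[i, :2 * half].mean()) ** 2)
        var_plus = (m - 1) / m * w + bvar / m
        rhat[i] = np.sqrt(var_plus / w) if w > 0 else np.inf
    converged = bool(np.all(rhat < rhat_threshold))
    if not converged:
        warnings.warn("population-specific F_ST chains may not have "
                      f"converged (max split-Rhat {rhat.max():.3f})")
    estimates = []
    for i, pool in enumerate(pools):
        med = float(np.median(samples[i]))
        lo, hi = np.percentile(samples[i], [2.5, 97.5])
        flags = () if converged else ("nonconverged",)
        estimates.append(FstEstimate(("pop", pool), med, float(lo),
                                     float(hi), samples.shape[1], flags))
    return PopSpecificFst(estimates, pd.Series(rhat, index=pools),
                          converged, samples, pools)
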