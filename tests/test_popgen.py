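"""Allele frequencies, Weir-Cockerham theta, exact tests, merging, null EM."""

import numpy as np
import pandas as pd
import pytest

from pstfst.popgen import (GenotypeMatrix, allele_frequencies,
                           components_from_pvalues,
                           exact_differentiation_test, merge_genetic_pools,
                           null_allele_em, wc_theta)
from pstfst.simulate import SimConfig, gen_genotypes, inject_null_alleles


def make_matrix(pools_calls, loci=None):
    """pools_calls: dict pool -> list of per-locus call pairs per ind."""
    inds, calls, pools = [], [], []
    for pool, rows in pools_calls.items():
        for k, row in enumerate(rows):
            inds.append(f"{pool}_{k}")
            calls.append(row)
            pools.append(pool)
    calls = np.asarray(calls)
    loci = loci or [f"L{j}" for j in range(calls.shape[1])]
    return GenotypeMatrix(inds, loci, calls, np.array(pools, dtype=object))


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

class TestAlleleFrequencies:
    def test_fixed_pool(self):
        g = make_matrix({"p1": [[(1, 1)], [(1, 1)]], "p2": [[(2, 2)],
                                                            [(1, 2)]]})
        f = allele_frequencies(g)
        p1 = f[(f.pool == "p1") & (f["count"] > 0)]
        assert p1["freq"].tolist() == [1.0]

    def test_three_of_four(self):
        g = make_matrix({"p1": [[(1, 1)], [(1, 2)]], "p2": [[(2, 2)],
                                                            [(2, 2)]]})
        f = allele_frequencies(g)
        p1 = f[f.pool == "p1"].set_index("allele")["freq"]
        assert p1[1] == 0.75 and p1[2] == 0.25

    def test_sums_to_one_per_pool_locus(self, default_genotypes):
        f = allele_frequencies(default_genotypes)
        sums = f.groupby(["pool", "locus"])["freq"].sum()
        assert np.allclose(sums, 1.0)


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------

def wc_theta_oracle(g):
    """Independent textbook computation: explicit per-allele a, b, c with
    plain loops, summed as a ratio of sums over alleles and loci."""
    num = den = 0.0
    pools = g.sampled_pools
    r = len(pools)
    for l in range(g.n_loci):
        calls = g.calls[:, l, :]
        ok = calls[:, 0] > 0
        alleles = sorted(set(calls[ok].ravel()))
        n_i = np.array([float(((g.pools == p) & ok).sum()) for p in pools])
        nbar = n_i.mean()
        nc = (r * nbar - (n_i ** 2).sum() / (r * nbar)) / (r - 1)
        for al in alleles:
            p_i, h_i = [], []
            for p in pools:
                sub = calls[(g.pools == p) & ok]
                p_i.append((sub == al).sum() / (2 * len(sub)))
                h_i.append(np.mean([(a == al) != (b == al)
                                    for a, b in sub]))
            p_i, h_i = np.array(p_i), np.array(h_i)
            pbar = (n_i * p_i).sum() / (r * nbar)
            s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
            hbar = (n_i * h_i).sum() / (r * nbar)
            a = (nbar / nc) * (s2 - (pbar * (1 - pbar)
                                     - (r - 1) / r * s2
                                     - hbar / 4) / (nbar - 1))
            b = (nbar / (nbar - 1)) * (pbar * (1 - pbar)
                                       - (r - 1) / r * s2
                                       - (2 * nbar - 1) / (4 * nbar) * hbar)
            c = hbar / 2
            num += a
            den += a + b + c
    return num / den


class TestWcTheta:
    def test_hand_worked_toy(self, toy_wc):
        est = wc_theta(toy_wc, "global", n_boot=0)
        assert est.theta == pytest.approx(0.2, abs=1e-12)
        assert est.theta == pytest.approx(wc_theta_oracle(toy_wc), abs=1e-12)
        assert "ci_unavailable_single_locus" in est.flags

    def test_matches_oracle_on_simulated_data(self, default_genotypes):
        est = wc_theta(default_genotypes, "global", n_boot=0)
        assert est.theta == pytest.approx(wc_theta_oracle(default_genotypes),
                                          abs=1e-10)

    def test_complete_fixation(self):
        g = make_matrix({"p1": [[(1, 1)]] * 5, "p2": [[(2, 2)]] * 5})
        assert wc_theta(g, "global", n_boot=0).theta == pytest.approx(1.0)

    def test_duplicated_pool_not_positive(self):
        rows = [[(1, 1)], [(1, 2)], [(2, 2)], [(1, 2)], [(1, 1)]]
        g = make_matrix({"p1": rows, "p2": rows})
        assert wc_theta(g, "global", n_boot=0).theta <= 1e-12

    def test_invariance_to_relabeling_and_reordering(self, default_genotypes):
        g = default_genotypes
        base = wc_theta(g, "global", n_boot=0).theta
        relab = g.calls.copy()
        relab[relab > 0] = 100 - relab[relab > 0]  # bijective recode
        g2 = GenotypeMatrix(g.individuals, g.loci, relab, g.pools)
        assert wc_theta(g2, "global", n_boot=0).theta == pytest.approx(
            base, abs=1e-12)
        order = np.random.default_rng(0).permutation(g.n_individuals)
        g3 = GenotypeMatrix([g.individuals[i] for i in order], g.loci,
                            g.calls[order], g.pools[order])
        assert wc_theta(g3, "global", n_boot=0).theta == pytest.approx(
            base, abs=1e-12)

    def test_pairwise_matrix_structure(self, default_genotypes):
        dm = wc_theta(default_genotypes, "pairwise", n_boot=50, seed=4)
        assert dm.n_pools == 6
        assert np.allclose(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0)
        iu = np.triu_indices(6, 1)
        assert np.isfinite(dm.ci_low[iu]).all()

    def test_ci_brackets_point_estimate(self, default_genotypes):
        est = wc_theta(default_genotypes, "global", n_boot=500, seed=1)
        assert est.ci_low <= est.theta <= est.ci_high
        assert est.theta <= 1


# ---------------------------------------------------------------------------
# exact differentiation test + merging
# ---------------------------------------------------------------------------

MIXED_A = [[(3, 4)], [(3, 3)], [(4, 4)], [(3, 4)], [(3, 3)], [(4, 4)],
           [(3, 4)], [(3, 3)], [(4, 4)], [(3, 4)]]
MIXED_B = [[(5, 6)], [(5, 5)], [(6, 6)], [(5, 6)], [(5, 5)], [(6, 6)],
           [(5, 6)], [(5, 5)], [(6, 6)], [(5, 6)]]


class TestExactTest:
    def test_identical_pools_p_one(self):
        g = make_matrix({"p1": MIXED_A, "p2": MIXED_A})
        res = exact_differentiation_test(g, "p1", "p2", n_mc=999, seed=0)
        assert res.combined_p == pytest.approx(1.0)

    def test_fixed_difference_maximal_significance(self):
        g = make_matrix({"p1": [[(1, 1), (1, 1)]] * 12,
                         "p2": [[(2, 2), (2, 2)]] * 12})
        res = exact_differentiation_test(g, "p1", "p2", n_mc=9999, seed=0)
        assert res.combined_p <= 0.001

    def test_monomorphic_locus_skipped_with_warning(self):
        g = make_matrix({"p1": [[(1, 1), (1, 2)]] * 6,
                         "p2": [[(1, 1), (2, 2)]] * 6})
        with pytest.warns(UserWarning, match="monomorphic"):
            res = exact_differentiation_test(g, "p1", "p2", n_mc=999, seed=0)
        assert res.skipped == ["L0"]
        assert list(res.per_locus.index) == ["L1"]

    def test_all_monomorphic_errors(self):
        g = make_matrix({"p1": [[(1, 1)]] * 6, "p2": [[(1, 1)]] * 6})
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="all loci monomorphic"):
                exact_differentiation_test(g, "p1", "p2", n_mc=999, seed=0)


class TestMerging:
    def test_transitive_closure_on_toy_graph(self):
        pools = ["A", "B", "C"]
        pvals = {("A", "B"): 0.5, ("B", "C"): 0.4, ("A", "C"): 1e-9}
        m = components_from_pvalues(pools, pvals, alpha=0.001)
        assert len(set(m.values())) == 1

    def test_all_significant_identity(self):
        pools = ["A", "B", "C"]
        pvals = {k: 1e-9 for k in [("A", "B"), ("B", "C"), ("A", "C")]}
        m = components_from_pvalues(pools, pvals, alpha=0.001)
        assert m == {"A": "A", "B": "B", "C": "C"}

    def test_eight_populations_merge_to_six_pools(self):
        """Two shallow/deep pairs carry identical genotype tables (same
        genetic pool sampled twice); the other four are fixed for private
        alleles.  Merging must recover exactly six genetic pools."""
        fixed = {f"C{k}": [[(k, k), (k, k)]] * 10 for k in range(1, 5)}
        both = {"M-sh": [r * 2 for r in MIXED_A],
                "M-d": [r * 2 for r in MIXED_A],
                "S-sh": [r * 2 for r in MIXED_B],
                "S-d": [r * 2 for r in MIXED_B]}
        g = make_matrix({**fixed, **both})
        mapping = merge_genetic_pools(g, alpha=0.001, n_mc=1999, seed=3)
        assert len(set(mapping.values())) == 6
        assert mapping["M-sh"] == mapping["M-d"]
        assert mapping["S-sh"] == mapping["S-d"]
        assert mapping["M-sh"] != mapping["S-sh"]
        merged = g.with_merge(mapping)
        assert len(merged.genetic_pools) == 6


# ---------------------------------------------------------------------------
# null-allele EM
# ---------------------------------------------------------------------------

class TestNullAlleleEM:
    def test_exact_hw_proportions_estimate_zero(self):
        rows = [[(1, 1)]] * 25 + [[(1, 2)]] * 50 + [[(2, 2)]] * 25
        g = make_matrix({"p1": rows})
        est = null_allele_em(g)
        assert est["null_freq"].iloc[0] < 0.01

    def test_all_homozygote_pool_positive(self):
        rows = [[(1, 1)]] * 30 + [[(2, 2)]] * 30
        g = make_matrix({"p1": rows})
        est = null_allele_em(g)
        assert est["null_freq"].iloc[0] > 0.1

    def test_monomorphic_flagged_zero(self):
        g = make_matrix({"p1": [[(1, 1)]] * 10})
        est = null_allele_em(g)
        assert est["null_freq"].iloc[0] == 0.0
        assert est["flag"].iloc[0] == "monomorphic"

    def test_insufficient_calls_flagged(self):
        g = make_matrix({"p1": [[(1, 2)]] * 3})
        est = null_allele_em(g)
        assert est["flag"].iloc[0] == "insufficient_calls"

    def test_recovers_injected_rate(self):
        cfg = SimConfig(seed=9, n_pools=1, n_per_pool=1000, n_loci=3,
                        fst_per_pool=(0.05,))
        g = inject_null_alleles(gen_genotypes(cfg), 0.2, seed=9)
        est = null_allele_em(g)
        assert np.all(np.abs(est["null_freq"] - 0.2) < 0.05)
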