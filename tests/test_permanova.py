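"""PERMANOVA: partition identities, classical-ANOVA equivalence, post-hocs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from pstfst._utils import child_seed
from pstfst.permanova import (DistanceMatrix, necrosis_distance,
                              pairwise_posthoc, permanova_oneway,
                              permanova_twoway)


def dm_from(x):
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    return DistanceMatrix(squareform(pdist(x)),
                          ids=[str(i) for i in range(len(x))])


# ---------------------------------------------------------------------------
# distances from the necrosis panel
# ---------------------------------------------------------------------------

class TestNecrosisDistance:
    def make_panel(self, vecs, sets=None):
        rows = []
        for c, v in vecs.items():
            for d, n in zip((10, 20, 30), v):
                rows.append({"colony": c, "population": "p", "day": d,
                             "necrosis": n,
                             "set": (sets or {}).get(c, "Treatment")})
        return pd.DataFrame(rows)

    def test_identical_trajectories_distance_zero(self):
        dm = necrosis_distance(self.make_panel({"a": (1, 2, 3),
                                                "b": (1, 2, 3)}))
        assert dm["a", "b"] == 0

    def test_three_four_five(self):
        dm = necrosis_distance(self.make_panel({"a": (0, 0, 0),
                                                "b": (3, 4, 0)}))
        assert dm["a", "b"] == pytest.approx(5.0)

    def test_controls_excluded(self):
        dm = necrosis_distance(self.make_panel(
            {"a": (0, 0, 0), "b": (1, 1, 1), "c": (9, 9, 9)},
            sets={"c": "Control"}))
        assert set(dm.ids) == {"a", "b"}

    def test_missing_day_lists_colonies(self):
        panel = self.make_panel({"a": (1, 2, 3), "b": (1, 2, 3)})
        panel = panel[~((panel.colony == "b") & (panel.day == 20))]
        with pytest.raises(ValueError, match="b"):
            necrosis_distance(panel)


# ---------------------------------------------------------------------------
# one-way
# ---------------------------------------------------------------------------

class TestOneWay:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_univariate_equals_classical_anova_f(self, seed):
        rng = np.random.default_rng(seed)
        y = [rng.normal(m, 1, 8) for m in (0.0, 0.4, 1.0)]
        f_classic = stats.f_oneway(*y).statistic
        groups = np.repeat(["a", "b", "c"], 8)
        res = permanova_oneway(dm_from(np.concatenate(y)), groups,
                               n_perm=99, seed=1)
        assert res.terms["pseudo_F"].iloc[0] == pytest.approx(f_classic,
                                                              rel=1e-10)

    def test_matches_skbio_pseudo_f(self):
        import skbio.stats.distance as sksd
        rng = np.random.default_rng(3)
        x = rng.normal(size=(18, 3))
        x[6:12] += 0.8
        groups = np.repeat(list("abc"), 6)
        dm = dm_from(x)
        ours = permanova_oneway(dm, groups, n_perm=99, seed=0)
        ref = sksd.permanova(dm, grouping=list(groups), permutations=99)
        assert ours.terms["pseudo_F"].iloc[0] == pytest.approx(
            ref["test statistic"], rel=1e-9)

    def test_partition_identity(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            x = rng.normal(size=(20, 4))
            groups = rng.choice(list("abcd"), 20)
            while (pd.Series(groups).value_counts() < 2).any():
                groups = rng.choice(list("abcd"), 20)
            res = permanova_oneway(dm_from(x), groups, n_perm=0, seed=0)
            ss = res.terms["SS"]
            assert ss.iloc[0] + ss.iloc[1] == pytest.approx(ss.iloc[2],
                                                            rel=1e-9)

    def test_degenerate_all_identical(self):
        dm = dm_from(np.zeros(12))
        res = permanova_oneway(dm, np.repeat(["a", "b"], 6), n_perm=99,
                               seed=0)
        assert np.isnan(res.terms["pseudo_F"].iloc[0])
        assert res.terms["p_perm"].iloc[0] == 1.0
        assert res.terms["SS"].iloc[0] == 0 == res.terms["SS"].iloc[1]

    def test_permutation_floor(self):
        x = np.concatenate([np.zeros(10), np.full(10, 50.0)])
        x += np.linspace(0, 0.1, 20)  # break exact ties
        res = permanova_oneway(dm_from(x), np.repeat(["a", "b"], 10),
                               n_perm=999, seed=5)
        assert res.terms["p_perm"].iloc[0] == pytest.approx(1 / 1000)

    def test_group_of_one_rejected(self):
        with pytest.raises(ValueError, match="size 1"):
            permanova_oneway(dm_from(np.arange(5.0)),
                             ["a", "a", "a", "a", "b"], n_perm=99)

    def test_reproducible_and_order_invariant(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=(15, 2))
        groups = np.repeat(list("abc"), 5)
        r1 = permanova_oneway(dm_from(x), groups, n_perm=199, seed=9)
        r2 = permanova_oneway(dm_from(x), groups, n_perm=199, seed=9)
        assert r1.terms.equals(r2.terms)
        order = rng.permutation(15)
        r3 = permanova_oneway(dm_from(x[order]), groups[order], n_perm=0)
        assert r3.terms["pseudo_F"].iloc[0] == pytest.approx(
            r1.terms["pseudo_F"].iloc[0], rel=1e-10)


# ---------------------------------------------------------------------------
# two-way
# ---------------------------------------------------------------------------

class TestTwoWay:
    def balanced(self, seed=0, effect_b=0.0):
        rng = np.random.default_rng(seed)
        fa = np.repeat(["l1", "l2", "l3"], 8)
        fb = np.tile(np.repeat(["sh", "dp"], 4), 3)
        y = rng.normal(size=24)
        y += np.where(fa == "l2", 0.8, 0) + np.where(fb == "dp", effect_b, 0)
        return y, fa, fb

    @pytest.mark.parametrize("seed", [0, 4])
    def test_univariate_matches_classical_twoway_anova(self, seed):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols
        y, fa, fb = self.balanced(seed, effect_b=0.5)
        res = permanova_twoway(dm_from(y), fa, fb, n_perm=49, seed=1)
        df = pd.DataFrame({"y": y, "A": fa, "B": fb})
        tab = sm.stats.anova_lm(ols("y ~ C(A) * C(B)", data=df).fit(), typ=1)
        for ours, theirs in (("A", "C(A)"), ("B", "C(B)"),
                             ("AxB", "C(A):C(B)")):
            assert res.terms.loc[ours, "pseudo_F"] == pytest.approx(
                tab.loc[theirs, "F"], rel=1e-8)

    def test_null_factor_b_p_roughly_uniform(self):
        # permutation p for an effect-free factor should not over-reject
        rej = 0
        n_rep = 120
        for rep in range(n_rep):
            y, fa, fb = self.balanced(seed=100 + rep, effect_b=0.0)
            res = permanova_twoway(dm_from(y), fa, fb, n_perm=99,
                                   seed=rep)
            rej += res.terms.loc["B", "p_perm"] <= 0.05
        lo, hi = stats.binom.interval(0.999, n_rep, 0.05)
        assert lo <= rej <= hi

    def test_duplicate_factor_rejected(self):
        y, fa, _ = self.balanced()
        # a duplicated factor is caught by the cell/rank screening
        with pytest.raises(ValueError, match="confounded|empty cell"):
            permanova_twoway(dm_from(y), fa, fa, n_perm=9)

    def test_empty_cell_rejected(self):
        y, fa, fb = self.balanced()
        fb = fb.copy()
        fb[(fa == "l1")] = "sh"  # l1 x dp becomes empty
        with pytest.raises(ValueError, match="empty cell"):
            permanova_twoway(dm_from(y), fa, fb, n_perm=9)


# ---------------------------------------------------------------------------
# pairwise post-hocs
# ---------------------------------------------------------------------------

class TestPosthoc:
    def test_pair_count(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(24, 2))
        groups = np.repeat(list("abcdef"), 4)
        out = pairwise_posthoc(dm_from(x), groups, n_perm=49, seed=0)
        assert len(out) == 15

    def test_identical_groups_t_zero(self):
        vals = np.concatenate([np.arange(6.0), np.arange(6.0)])
        groups = np.repeat(["a", "b"], 6)
        out = pairwise_posthoc(dm_from(vals), groups, n_perm=199, seed=0)
        assert out["t"].iloc[0] == pytest.approx(0.0, abs=1e-6)
        assert out["p"].iloc[0] > 0.5

    def test_consistency_with_oneway_same_seed(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(18, 2))
        x[12:] += 1.0
        groups = np.repeat(list("abc"), 6)
        out = pairwise_posthoc(dm_from(x), groups, n_perm=199, seed=31)
        # pair (a, c) is (i, j) = (0, 2) in input-order indexing
        sub = np.isin(groups, ["a", "c"])
        dm = dm_from(x)
        sub_dm = DistanceMatrix(np.asarray(dm.data)[np.ix_(sub, sub)],
                                ids=np.asarray(dm.ids)[sub].tolist())
        ref = permanova_oneway(sub_dm, groups[sub], n_perm=199,
                               seed=child_seed(31, 43, 0, 2))
        row = out[(out.pool_a == "a") & (out.pool_b == "c")].iloc[0]
        assert row["p"] == ref.terms["p_perm"].iloc[0]
        assert row["t"] == pytest.approx(
            np.sqrt(ref.terms["pseudo_F"].iloc[0]))

    def test_sidak_adjustment_option(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(16, 2))
        groups = np.repeat(list("abcd"), 4)
        out = pairwise_posthoc(dm_from(x), groups, n_perm=49, seed=0,
                               adjust="sidak")
        assert np.allclose(out["p_adj"], 1 - (1 - out["p"]) ** len(out))
        assert (out["p_adj"] >= out["p"] - 1e-12).all()
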