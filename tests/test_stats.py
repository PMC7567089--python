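"""Permutational statistics against closed-form and reference oracles."""

import numpy as np
import pytest
from scipy import stats as sps

from spongeflux.stats import (
    DesignTable,
    OneLevelFactorError,
    distinct_relabelings,
    pairwise,
    permanova,
    welch_t,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


class TestPermanova:
    def test_pseudo_f_equals_classical_anova(self, rng):
        y = rng.normal(size=15)
        g = np.repeat(["a", "b", "c"], 5)
        res = permanova(DesignTable(y, g), permutations=99, seed=0)[0]
        ref = sps.f_oneway(y[g == "a"], y[g == "b"], y[g == "c"])
        assert res.pseudo_f == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p_mc == pytest.approx(ref.pvalue, abs=1e-10)

    def test_constant_response_guarded(self):
        res = permanova(
            DesignTable(np.ones(8), np.repeat(["a", "b"], 4)), permutations=99
        )[0]
        assert np.isnan(res.pseudo_f)
        assert res.p_perm == 1.0
        assert res.p_mc == 1.0

    def test_two_groups_of_three_enumerates_ten(self, rng):
        y = rng.normal(size=6)
        res = permanova(DesignTable(y, np.repeat(["a", "b"], 3)))[0]
        assert res.unique_permutations == 10

    def test_distinct_relabeling_counts(self):
        assert distinct_relabelings([3, 3]) == 10
        assert distinct_relabelings([3, 4]) == 35
        assert distinct_relabelings([4, 4, 4]) == 5775

    def test_exhaustive_p_reproducible_and_random_seeded(self, rng):
        y = rng.normal(size=6)
        g = np.repeat(["a", "b"], 3)
        p1 = permanova(DesignTable(y, g))[0].p_perm
        p2 = permanova(DesignTable(y, g))[0].p_perm
        assert p1 == p2  # bit-exact enumeration
        ym = rng.normal(size=(12, 2))
        gm = np.repeat(["a", "b", "c"], 4)
        gb = np.tile(["x", "y"], 6)
        r1 = permanova(DesignTable(ym, gm, gb), permutations=199, seed=5)
        r2 = permanova(DesignTable(ym, gm, gb), permutations=199, seed=5)
        assert [r.p_perm for r in r1] == [r.p_perm for r in r2]

    def test_gower_identity(self, rng):
        """Raw-response and distance-matrix routes agree for Euclidean data."""
        y = rng.normal(size=(12, 3))
        g = np.repeat(["a", "b", "c"], 4)
        b = np.tile(["x", "y"], 6)
        raw = permanova(DesignTable(y, g, b), permutations=49, seed=1)
        gow = permanova(DesignTable(y, g, b), permutations=49, seed=1, method="gower")
        for r1, r2 in zip(raw, gow):
            assert r1.pseudo_f == pytest.approx(r2.pseudo_f, abs=1e-10)
            assert r1.ss == pytest.approx(r2.ss, abs=1e-9)

    def test_matches_scikit_bio_one_way(self, rng):
        from scipy.spatial import distance_matrix
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as sk_permanova

        y = rng.normal(size=(12, 4))
        g = np.repeat(["a", "b", "c"], 4)
        ours = permanova(DesignTable(y, g), permutations=99, seed=0)[0]
        sk = sk_permanova(DistanceMatrix(distance_matrix(y, y)), grouping=list(g),
                          permutations=99)
        assert ours.pseudo_f == pytest.approx(sk["test statistic"], abs=1e-10)

    def test_one_level_factor_rejected(self):
        with pytest.raises(OneLevelFactorError):
            DesignTable(np.arange(4.0), np.repeat("a", 4))

    def test_type_one_error_calibrated_under_null(self):
        """Rejection at alpha=0.05 stays near nominal for Gaussian nulls
        (3 groups x 4 observations, 1000 simulated datasets)."""
        rng = np.random.default_rng(2024)
        g = np.repeat(["a", "b", "c"], 4)
        rej_perm = rej_mc = 0
        n_sim = 1000
        for _ in range(n_sim):
            y = rng.normal(size=12)
            res = permanova(DesignTable(y, g), permutations=199, seed=rng)[0]
            rej_perm += res.p_perm <= 0.05
            rej_mc += res.p_mc <= 0.05
        assert 0.03 <= rej_perm / n_sim <= 0.07
        assert 0.03 <= rej_mc / n_sim <= 0.07


class TestPairwise:
    def test_identical_groups(self):
        y = np.tile([1.0, 2.0, 3.0], 2)
        g = np.repeat(["a", "b"], 3)
        pw = pairwise(DesignTable(y, g))
        assert pw.t[0] == pytest.approx(0.0, abs=1e-7)
        assert pw.p_mc[0] == pytest.approx(1.0, abs=1e-6)

    def test_matches_pooled_t(self, rng):
        x1 = rng.normal(size=4)
        x2 = rng.normal(size=5) + 1.0
        pw = pairwise(DesignTable(np.r_[x1, x2], np.repeat(["a", "b"], [4, 5])))
        ref = sps.ttest_ind(x1, x2, equal_var=True)
        assert abs(pw.t[0]) == pytest.approx(abs(ref.statistic), abs=1e-8)
        assert pw.p_mc[0] == pytest.approx(ref.pvalue, abs=1e-8)
        assert pw.df[0] == 7
        assert pw.unique_permutations[0] == distinct_relabelings([4, 5])

    def test_scale_invariant(self, rng):
        y = rng.normal(size=8)
        g = np.repeat(["a", "b"], 4)
        t1 = pairwise(DesignTable(y, g)).t[0]
        t2 = pairwise(DesignTable(1000.0 * y, g)).t[0]
        assert t1 == pytest.approx(t2, rel=1e-9)

    def test_small_pair_skipped(self, rng):
        y = rng.normal(size=4)
        g = np.array(["a", "a", "b", "c"])
        pw = pairwise(DesignTable(y, g))
        skipped = pw[pw.note != ""]
        assert len(skipped) == 3  # every pair involves a singleton level


class TestWelch:
    def test_identical_samples(self):
        t, df, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_equal_variance_equal_n_df(self, rng):
        x = rng.normal(size=6)
        y = x + 0.5  # identical variance by construction
        _, df, _ = welch_t(x, y)
        assert df == pytest.approx(2 * 6 - 2, abs=1e-9)

    def test_matches_reference_implementation(self):
        x = [3.1, 2.9, 3.5, 3.3, 2.8]
        y = [4.0, 4.4, 3.9, 4.6]
        t, df, p = welch_t(x, y)
        ref = sps.ttest_ind(x, y, equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)
        assert df == pytest.approx(ref.df, abs=1e-10)

    def test_degenerate_zero_variance(self):
        t, df, p = welch_t([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_p_uniform_under_null(self):
        """Two-group Gaussian null: Welch p-values are U(0,1) by KS test."""
        rng = np.random.default_rng(7)
        pvals = [
            welch_t(rng.normal(size=6), rng.normal(size=6))[2] for _ in range(1000)
        ]
        assert sps.kstest(pvals, "uniform").pvalue > 0.01
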