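import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova
from skbio.stats.distance import permdisp as skbio_permdisp

from oracles import centroid_distances_2d
from restrans.errors import DegenerateDesignError, InsufficientDataError
from restrans.stats import (
    dispersion_test,
    divergence_regression,
    permanova,
    rank_sum_test,
)


def worked_matrix():
    """2 groups of 2; within-pair d=0.1, between-pair d=1."""
    d = np.ones((4, 4))
    np.fill_diagonal(d, 0.0)
    d[0, 1] = d[1, 0] = 0.1
    d[2, 3] = d[3, 2] = 0.1
    return DistanceMatrix(d, ids=list("abcd"))


class TestPermanova:
    def test_worked_example_pseudo_f_is_199(self):
        res = permanova(worked_matrix(), ["g1", "g1", "g2", "g2"],
                        n_permutations=99, seed=0)
        # SS_total = 1.005, SS_within = 0.01 -> F = (0.995/1)/(0.01/2) = 199
        assert res.pseudo_F == pytest.approx(199.0, abs=1e-9)
        assert res.R_squared == pytest.approx(0.995 / 1.005, abs=1e-12)
        assert res.df_among == 1 and res.df_within == 2

    def test_exhaustive_p_is_one_third(self):
        res = permanova(worked_matrix(), ["g1", "g1", "g2", "g2"],
                        method="exhaustive")
        # only 3 distinct 2+2 partitions; observed F is the unique maximum
        assert res.p_value == pytest.approx(1.0 / 3.0)

    def test_sampled_p_close_to_exhaustive(self):
        res = permanova(worked_matrix(), ["g1", "g1", "g2", "g2"],
                        n_permutations=999, seed=7)
        # sampled permutations of a 4-sample design: p within MC error of 1/3
        se = np.sqrt((1 / 3) * (2 / 3) / 999)
        assert abs(res.p_value - 1 / 3) < 3 * se + 2 / 999

    def test_all_equal_distances_give_p_one(self):
        d = np.ones((6, 6)) * 0.4
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(6)])
        res = permanova(dm, ["a", "a", "a", "b", "b", "b"],
                        n_permutations=99, seed=1)
        assert res.p_value == 1.0

    def test_single_group_is_degenerate(self):
        with pytest.raises(DegenerateDesignError):
            permanova(worked_matrix(), ["g"] * 4, n_permutations=9, seed=0)

    def test_statistic_invariant_to_seed(self):
        a = permanova(worked_matrix(), ["g1", "g1", "g2", "g2"],
                      n_permutations=49, seed=1)
        b = permanova(worked_matrix(), ["g1", "g1", "g2", "g2"],
                      n_permutations=49, seed=99)
        assert a.pseudo_F == b.pseudo_F
        assert a.R_squared == b.R_squared

    def test_relabelling_invariance(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(8, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        ids = [f"s{i}" for i in range(8)]
        labels = ["a", "a", "a", "a", "b", "b", "b", "b"]
        dm = DistanceMatrix(d, ids=ids)
        perm = rng.permutation(8)
        dm2 = DistanceMatrix(d[np.ix_(perm, perm)], ids=[ids[i] for i in perm])
        r1 = permanova(dm, pd.Series(labels, index=ids), n_permutations=99, seed=5)
        r2 = permanova(dm2, pd.Series(labels, index=ids), n_permutations=99, seed=5)
        assert r1.pseudo_F == pytest.approx(r2.pseudo_F, rel=1e-12)

    def test_matches_skbio_statistic(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(12, 4))
        pts[6:] += 1.0
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(12)])
        labels = ["a"] * 6 + ["b"] * 6
        ours = permanova(dm, labels, n_permutations=999, seed=2)
        ref = skbio_permanova(dm, grouping=labels, permutations=999)
        assert ours.pseudo_F == pytest.approx(ref["test statistic"], rel=1e-9)
        assert abs(ours.p_value - ref["p-value"]) < 0.06


class TestDispersion:
    def test_zero_dispersion_group(self):
        # group a: three mutually-identical samples (distance 0)
        d = np.zeros((6, 6))
        for i in range(6):
            for j in range(6):
                if i != j and (i >= 3 or j >= 3):
                    d[i, j] = 1.0 if (i < 3) != (j < 3) else 0.6
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(6)])
        res = dispersion_test(dm, ["a"] * 3 + ["b"] * 3, n_permutations=99, seed=0)
        assert res.group_dispersions["a"] == pytest.approx(0.0, abs=1e-10)

    def test_congruent_groups_give_f_near_zero(self):
        # two groups with identical internal geometry (translated copies)
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.5, 1.5]])
        far = pts + np.array([100.0, 0.0])
        coords = np.vstack([pts, far])
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(8)])
        res = dispersion_test(dm, ["a"] * 4 + ["b"] * 4, n_permutations=99, seed=0)
        assert res.F_statistic < 1e-10
        assert res.p_value > 0.5

    def test_euclidean_embedding_matches_plane_geometry(self):
        # planted 2-D configuration: distances-to-centroid must agree with
        # direct coordinate computation
        rng = np.random.default_rng(8)
        coords = rng.normal(size=(10, 2))
        labels = np.array(["a"] * 5 + ["b"] * 5)
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(10)])
        res = dispersion_test(dm, labels, n_permutations=9, seed=0)
        want = centroid_distances_2d(coords, labels)
        assert res.group_dispersions["a"] == pytest.approx(
            want[:5].mean(), abs=1e-10)
        assert res.group_dispersions["b"] == pytest.approx(
            want[5:].mean(), abs=1e-10)

    def test_single_sample_group_is_an_error(self):
        with pytest.raises(DegenerateDesignError, match="g2"):
            dispersion_test(worked_matrix(), ["g1", "g1", "g1", "g2"],
                            n_permutations=9, seed=0)

    def test_matches_skbio_permdisp_statistic(self):
        rng = np.random.default_rng(21)
        pts = rng.normal(size=(14, 3))
        pts[7:] *= 3.0  # second group more dispersed
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(14)])
        labels = ["a"] * 7 + ["b"] * 7
        ours = dispersion_test(dm, labels, n_permutations=199, seed=3)
        ref = skbio_permdisp(dm, grouping=labels, permutations=199,
                             test="centroid")
        assert ours.F_statistic == pytest.approx(ref["test statistic"], rel=1e-6)


class TestRankSum:
    def test_fully_separated_triples(self):
        res = rank_sum_test([1, 2, 3], [4, 5, 6])
        # U = 0; exact two-sided p = 2/20 over all C(6,3) arrangements
        assert res.statistic_U == 0.0
        assert res.method == "exact"
        assert res.p_value == pytest.approx(0.1)

    def test_identical_groups_degenerate(self):
        res = rank_sum_test([2.0, 2.0], [2.0, 2.0])
        assert res.p_value == 1.0
        assert res.degenerate

    def test_swap_symmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=8), rng.normal(1.0, 1.0, size=5)
        r1 = rank_sum_test(a, b)
        r2 = rank_sum_test(b, a)
        assert r1.statistic_U == pytest.approx(8 * 5 - r2.statistic_U)
        assert r1.p_value == pytest.approx(r2.p_value)

    @pytest.mark.parametrize("alternative,scipy_alt", [
        ("two_sided", "two-sided"), ("less", "less"), ("greater", "greater"),
    ])
    def test_exact_matches_scipy(self, alternative, scipy_alt):
        rng = np.random.default_rng(5)
        a = rng.permutation(np.arange(20.0))[:8]
        b = np.setdiff1d(np.arange(20.0), a)[:7]
        ours = rank_sum_test(a, b, alternative=alternative)
        ref = sps.mannwhitneyu(a, b, alternative=scipy_alt, method="exact")
        assert ours.statistic_U == pytest.approx(ref.statistic)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_normal_approximation_matches_scipy_with_ties(self):
        rng = np.random.default_rng(6)
        a = rng.integers(0, 6, 30).astype(float)
        b = rng.integers(1, 7, 25).astype(float)
        ours = rank_sum_test(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_exact_and_normal_branches_agree(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            a = rng.normal(size=10)
            b = rng.normal(0.5, 1.0, size=10)
            exact = rank_sum_test(a, b)
            assert exact.method == "exact"
            # the asymptotic approximation on identical input stays close
            ref = sps.mannwhitneyu(a, b, alternative="two-sided",
                                   method="asymptotic")
            assert abs(exact.p_value - ref.pvalue) < 0.01

    def test_empty_input_rejected(self):
        with pytest.raises(InsufficientDataError):
            rank_sum_test([], [1.0])


def pairs_frame(t, y, pop="p1"):
    return pd.DataFrame(
        {
            "sample_a": [f"g{i}" for i in range(len(t))],
            "sample_b": [f"f{i}" for i in range(len(t))],
            "dissimilarity": y,
            "comparison_class": "within_population",
            "population_a": pop,
            "population_b": pop,
            "timepoint": t,
        }
    )


class TestDivergenceRegression:
    def test_exact_line_recovered(self):
        t = np.array([1.0, 2, 7, 14, 21, 28, 35, 42] * 3)
        y = 0.002 * t + 0.5
        res = divergence_regression(pairs_frame(t, y))[0]
        assert res.slope == pytest.approx(0.002, abs=1e-12)
        assert res.intercept == pytest.approx(0.5, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0)

    def test_time_constant_dissimilarity_gives_zero_slope(self):
        t = np.array([1.0, 2, 7, 14] * 2)
        res = divergence_regression(pairs_frame(t, np.full_like(t, 0.4)))[0]
        assert res.slope == 0.0

    def test_matches_scipy_linregress(self):
        rng = np.random.default_rng(12)
        t = np.repeat([1.0, 2, 7, 14, 21, 28, 35, 42], 5)
        y = 0.003 * t + 0.4 + rng.normal(0, 0.05, t.size)
        res = divergence_regression(pairs_frame(t, y))[0]
        ref = sps.linregress(t, y)
        assert res.slope == pytest.approx(ref.slope, abs=1e-10)
        assert res.intercept == pytest.approx(ref.intercept, abs=1e-10)
        assert res.slope_p_value == pytest.approx(ref.pvalue, rel=1e-9)
        assert res.r_squared == pytest.approx(ref.rvalue ** 2, rel=1e-9)

    def test_per_population_fits(self):
        t = np.array([1.0, 2, 7, 14] * 2)
        frame = pd.concat([
            pairs_frame(t, 0.01 * t + 0.3, pop="p1"),
            pairs_frame(t, np.full_like(t, 0.5), pop="p2"),
        ], ignore_index=True)
        fits = divergence_regression(frame, per_population=True)
        by_pop = {f.population: f for f in fits}
        assert set(by_pop) == {"pooled", "p1", "p2"}
        assert by_pop["p1"].slope == pytest.approx(0.01, abs=1e-12)
        assert by_pop["p2"].slope == pytest.approx(0.0, abs=1e-12)

    def test_single_timepoint_is_an_error(self):
        t = np.full(6, 7.0)
        with pytest.raises(InsufficientDataError):
            divergence_regression(pairs_frame(t, t * 0 + 0.5))
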