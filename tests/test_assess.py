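"""Rank-based statistics against brute-force oracles; deviation scores."""

import itertools

import numpy as np
import pytest
from scipy import stats as sstats

from emgforce.assess import (
    DeviationScore,
    dunn_bonferroni,
    friedman,
    kruskal_wallis,
    mann_whitney_u,
    welch_t,
)
from emgforce.errors import ValidationError


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def mwu_count_oracle(a, b):
    """U for group a = #{(i,j): a_i > b_j} + 0.5 #ties (scipy's convention)."""
    u = 0.0
    for x in a:
        for y in b:
            u += 1.0 if x > y else (0.5 if x == y else 0.0)
    return u


def mwu_exact_p_oracle(a, b):
    """Exact two-sided p by enumerating all group assignments (no ties)."""
    pooled = list(a) + list(b)
    n_a = len(a)
    u_obs = mwu_count_oracle(a, b)
    us = []
    for combo in itertools.combinations(range(len(pooled)), n_a):
        ga = [pooled[i] for i in combo]
        gb = [pooled[i] for i in range(len(pooled)) if i not in combo]
        us.append(mwu_count_oracle(ga, gb))
    us = np.array(us)
    mean_u = n_a * (len(pooled) - n_a) / 2.0
    dev = abs(u_obs - mean_u)
    return float(np.mean(np.abs(us - mean_u) >= dev - 1e-12))


def kw_statistic_oracle(groups):
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = sstats.rankdata(pooled)
    start, h = 0, 0.0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts ** 3 - counts) / (n ** 3 - n)
    return h / tie


def permutation_p(statistic, groups, stat_fn, n_perm=4000, seed=0):
    rng = np.random.default_rng(seed)
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        parts, start = [], 0
        for sz in sizes:
            parts.append(perm[start:start + sz])
            start += sz
        if stat_fn(parts) >= statistic - 1e-12:
            count += 1
    return count / n_perm


class TestMannWhitney:
    def test_complete_separation(self):
        cmp_ = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert cmp_.statistic == 0.0

    def test_identical_groups_p_near_one(self):
        cmp_ = mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
        assert cmp_.p_value > 0.9

    def test_u_matches_pair_counting(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.standard_normal(5)
            b = rng.standard_normal(5)
            cmp_ = mann_whitney_u(a, b)
            assert cmp_.statistic == pytest.approx(mwu_count_oracle(a, b))

    def test_exact_p_matches_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            a = rng.standard_normal(4)
            b = rng.standard_normal(4)
            cmp_ = mann_whitney_u(a, b)
            assert cmp_.extra["method"] == "exact"
            assert cmp_.p_value == pytest.approx(mwu_exact_p_oracle(a, b), abs=1e-9)

    def test_small_groups_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney_u([1, 2], [3, 4, 5])


class TestKruskalWallis:
    def test_identical_groups_h_zero(self):
        cmp_ = kruskal_wallis([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert cmp_.statistic == pytest.approx(0.0)

    def test_statistic_matches_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            groups = [rng.standard_normal(int(rng.integers(2, 6)))
                      for _ in range(3)]
            cmp_ = kruskal_wallis(groups)
            assert cmp_.statistic == pytest.approx(kw_statistic_oracle(groups))

    def test_two_group_agrees_with_mwu_asymptotics(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal(12)
        b = rng.standard_normal(12) + 0.8
        kw = kruskal_wallis([a, b])
        mw = mann_whitney_u(a, b)
        assert kw.p_value == pytest.approx(mw.p_value, abs=0.02)

    def test_small_instance_permutation_null(self):
        groups = [[1.2, 3.4, 0.2], [4.5, 5.1, 2.2], [0.1, 0.4, 0.9]]
        cmp_ = kruskal_wallis(groups)
        p_perm = permutation_p(cmp_.statistic,
                               [np.array(g, float) for g in groups],
                               kw_statistic_oracle)
        assert cmp_.p_value == pytest.approx(p_perm, abs=0.05)

    def test_all_identical_rejected(self):
        with pytest.raises(ValidationError):
            kruskal_wallis([[1.0, 1.0], [1.0, 1.0]])


class TestDunn:
    def test_adjusted_alpha_k4(self):
        rng = np.random.default_rng(4)
        groups = [rng.standard_normal(4) + i for i in range(4)]
        cmps = dunn_bonferroni(groups)
        assert len(cmps) == 6
        assert cmps[0].adjusted_alpha == pytest.approx(0.05 / 6)
        assert cmps[0].adjusted_alpha == pytest.approx(0.00833, abs=5e-5)

    def test_separated_groups_all_significant(self):
        # rank statistics saturate: even infinite separation needs enough
        # observations per group (12 here) for adjacent-pair significance
        groups = [np.arange(12) + 100 * i for i in range(3)]
        cmps = dunn_bonferroni(groups)
        assert all(c.p_value < c.adjusted_alpha for c in cmps)

    def test_identical_groups_z_zero(self):
        groups = [[1, 2, 3], [1, 2, 3], [10, 11, 12]]
        cmps = dunn_bonferroni(groups, labels=["a", "b", "c"])
        ab = next(c for c in cmps if set(c.labels) == {"a", "b"})
        assert ab.statistic == pytest.approx(0.0, abs=1e-12)

    def test_fewer_than_three_groups_rejected(self):
        with pytest.raises(ValidationError):
            dunn_bonferroni([[1, 2, 3], [4, 5, 6]])

    def test_z_matches_mean_rank_oracle(self):
        rng = np.random.default_rng(5)
        groups = [rng.standard_normal(5) for _ in range(3)]
        pooled = np.concatenate(groups)
        ranks = sstats.rankdata(pooled)
        n = len(pooled)
        mr = [ranks[i * 5:(i + 1) * 5].mean() for i in range(3)]
        se = np.sqrt(n * (n + 1) / 12.0 * (1 / 5 + 1 / 5))
        z01 = (mr[0] - mr[1]) / se
        cmps = dunn_bonferroni(groups)
        assert cmps[0].statistic == pytest.approx(z01)


class TestFriedman:
    def test_fully_tied_table_zero(self):
        x = np.ones((5, 3))
        cmp_ = friedman(x)
        assert cmp_.statistic == 0.0
        assert cmp_.p_value == 1.0

    def test_balanced_permutations_zero(self):
        # each condition gets each rank equally often -> uniform rank sums
        x = np.array([[1, 2, 3], [2, 3, 1], [3, 1, 2],
                      [1, 2, 3], [2, 3, 1], [3, 1, 2]], dtype=float)
        assert friedman(x).statistic == pytest.approx(0.0)

    def test_matches_scipy_on_tie_free_data(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((8, 4))
        ours = friedman(x)
        ref = sstats.friedmanchisquare(*(x[:, j] for j in range(4)))
        assert ours.statistic == pytest.approx(ref.statistic)
        assert ours.p_value == pytest.approx(ref.pvalue)

    def test_permutation_null_small_instance(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((5, 3))
        obs = friedman(x).statistic

        def perm_stat():
            xp = np.array([row[rng.permutation(3)] for row in x])
            return friedman(xp).statistic

        null = np.array([perm_stat() for _ in range(3000)])
        p_perm = float(np.mean(null >= obs - 1e-12))
        # chi-square approximation is coarse at n=5, k=3
        assert friedman(x).p_value == pytest.approx(p_perm, abs=0.12)

    def test_missing_cells_rejected(self):
        x = np.ones((4, 3))
        x[1, 2] = np.nan
        with pytest.raises(ValidationError):
            friedman(x)


class TestDeviationScore:
    def test_mean_aggregation_and_permutation_invariance(self):
        reps = [8.0, 10.0, 12.0, 7.5]
        a = DeviationScore("S1", "G1", reps)
        b = DeviationScore("S1", "G1", reps[::-1])
        assert a.subject_rmse == pytest.approx(np.mean(reps))
        assert a.subject_rmse == b.subject_rmse

    def test_single_repetition(self):
        s = DeviationScore("S1", "G1", [9.25])
        assert s.subject_rmse == 9.25


class TestWelch:
    def test_matches_scipy(self):
        rng = np.random.default_rng(8)
        a, b = rng.standard_normal(10), rng.standard_normal(12) + 0.4
        ours = welch_t(a, b)
        ref = sstats.ttest_ind(a, b, equal_var=False)
        assert ours.statistic == pytest.approx(ref.statistic)
        assert ours.p_value == pytest.approx(ref.pvalue)
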