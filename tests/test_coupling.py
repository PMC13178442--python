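import itertools

import numpy as np
import pytest
from scipy import stats

import countfm as cf
from countfm import ValidationError


class TestIndependentPairs:
    def test_forced_single_pair(self):
        x0, x1 = cf.independent_pairs([[1, 2]], [[3, 4]], seed=0)
        assert np.array_equal(x0, [[1, 2]]) and np.array_equal(x1, [[3, 4]])

    def test_uniform_index_distribution(self):
        b0 = np.arange(3)[:, None]
        b1 = np.arange(4)[:, None] + 10
        counts = np.zeros((3, 4))
        for seed in range(4000):
            x0, x1 = cf.independent_pairs(b0, b1, seed=seed)
            for a, b in zip(x0[:, 0], x1[:, 0] - 10):
                counts[a, b] += 1
        _, p = stats.chisquare(counts.reshape(-1))
        assert p > 0.001

    def test_seeded(self):
        b0 = np.arange(6)[:, None]
        b1 = np.arange(6)[:, None]
        a = cf.independent_pairs(b0, b1, seed=3)
        b = cf.independent_pairs(b0, b1, seed=3)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestPoissonCost:
    def test_zero_on_diagonal(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 50, (6, 3))
        c = cf.poisson_cost_matrix(x, x, eps_c=1e-3)
        assert np.allclose(np.diag(c), 0.0)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 50, (5, 3))
        b = rng.integers(0, 50, (5, 3))
        assert np.allclose(cf.poisson_cost_matrix(a, b, 1e-3),
                           cf.poisson_cost_matrix(b, a, 1e-3).T)

    def test_hand_value(self):
        # x=1, y=3, eps=1: 1*log(2/4) + 3*log(4/2) = 2 log 2
        c = cf.poisson_cost_matrix([[1]], [[3]], eps_c=1.0)
        assert np.isclose(c[0, 0], 2 * np.log(2))

    def test_eps_validation(self):
        with pytest.raises(ValidationError):
            cf.poisson_cost_matrix([[1]], [[2]], eps_c=0.0)


class TestOtCoupling:
    def test_b1(self):
        plan = cf.ot_coupling(np.array([[3.0]]))
        assert np.allclose(plan.gamma, [[1.0]])

    def test_identity_favoring(self):
        b = 5
        cost = 1.0 - np.eye(b)
        plan = cf.ot_coupling(cost)
        assert np.allclose(plan.gamma, np.eye(b) / b)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_permutations(self, seed):
        rng = np.random.default_rng(seed)
        cost = rng.integers(0, 20, (4, 4)).astype(float)
        plan = cf.ot_coupling(cost)
        brute = min(
            sum(cost[i, p[i]] for i in range(4)) / 4
            for p in itertools.permutations(range(4))
        )
        assert np.isclose(plan.objective(cost), brute)

    def test_marginals(self):
        rng = np.random.default_rng(2)
        plan = cf.ot_coupling(rng.random((7, 7)))
        assert np.allclose(plan.gamma.sum(axis=0), 1 / 7)
        assert np.allclose(plan.gamma.sum(axis=1), 1 / 7)

    def test_objective_beats_identity(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            cost = rng.random((6, 6))
            plan = cf.ot_coupling(cost)
            assert plan.objective(cost) <= np.trace(cost) / 6 + 1e-12

    def test_permuted_batches_cost_zero(self):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 30, (8, 2))
        perm = rng.permutation(8)
        cost = cf.poisson_cost_matrix(x, x[perm], 1e-3)
        plan = cf.ot_coupling(cost)
        assert plan.objective(cost) < 1e-10

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            cf.ot_coupling(np.array([[np.inf, 0.0], [0.0, 1.0]]))


class TestSamplePairs:
    def test_permutation_plan_support(self):
        x0 = np.arange(4)[:, None]
        x1 = np.arange(4)[:, None] + 100
        perm = np.array([2, 0, 3, 1])
        gamma = np.zeros((4, 4))
        gamma[np.arange(4), perm] = 0.25
        plan = cf.CouplingPlan(gamma)
        a, b = cf.sample_pairs_from_plan(plan, x0, x1, 500, seed=0)
        assert np.array_equal(b[:, 0] - 100, perm[a[:, 0]])

    def test_frequencies_converge(self):
        rng = np.random.default_rng(5)
        # random doubly-stochastic-ish plan via sinkhorn on a random matrix
        g = rng.random((4, 4))
        for _ in range(200):
            g /= g.sum(axis=1, keepdims=True) * 4
            g /= g.sum(axis=0, keepdims=True) * 4
        plan = cf.CouplingPlan(g)
        x0 = np.arange(4)[:, None]
        x1 = np.arange(4)[:, None]
        a, b = cf.sample_pairs_from_plan(plan, x0, x1, 100_000, seed=1)
        emp = np.zeros((4, 4))
        np.add.at(emp, (a[:, 0], b[:, 0]), 1)
        emp /= emp.sum()
        assert 0.5 * np.abs(emp - g).sum() < 0.02

    def test_seeded(self):
        plan = cf.CouplingPlan(np.eye(3) / 3)
        x = np.arange(3)[:, None]
        a = cf.sample_pairs_from_plan(plan, x, x, 50, seed=9)
        b = cf.sample_pairs_from_plan(plan, x, x, 50, seed=9)
        assert np.array_equal(a[0], b[0])


class TestGroupRestricted:
    def test_single_shared_label_reduces_to_plain_ot(self):
        rng = np.random.default_rng(0)
        x0 = rng.integers(0, 20, (5, 2))
        x1 = rng.integers(0, 20, (5, 2))
        labels = np.zeros(5, dtype=int)
        p0, p1, _ = cf.group_restricted_pairs(x0, labels, x1, labels, {0: {0}},
                                              seed=1)
        cost = cf.poisson_cost_matrix(x0, x1, 1e-3)
        plan = cf.ot_coupling(cost)
        a0, a1 = cf.plan_as_permutation(plan, x0, x1)
        got = sum(cf.poisson_cost_matrix(p0[i:i+1], p1[i:i+1], 1e-3)[0, 0]
                  for i in range(5))
        want = sum(cf.poisson_cost_matrix(a0[i:i+1], a1[i:i+1], 1e-3)[0, 0]
                   for i in range(5))
        assert np.isclose(got, want)

    def test_disjoint_groups_never_cross(self):
        rng = np.random.default_rng(1)
        x0 = rng.integers(0, 9, (40, 2))
        x1 = np.where(np.arange(40)[:, None] < 20, 0, 100) + rng.integers(0, 5, (40, 2))
        l0 = (np.arange(40) >= 20).astype(int)
        l1 = (np.arange(40) >= 20).astype(int)
        p0, p1, labs = cf.group_restricted_pairs(x0, l0, x1, l1, {0: {0}, 1: {1}},
                                                 seed=2)
        # group-0 targets are small counts, group-1 targets are >= 100
        assert np.all(p1[labs == 0] < 100)
        assert np.all(p1[labs == 1] >= 100)

    def test_per_group_bruteforce(self):
        rng = np.random.default_rng(3)
        x0 = rng.integers(0, 15, (9, 2))
        x1 = rng.integers(0, 15, (9, 2))
        labels = np.repeat([0, 1, 2], 3)
        p0, p1, labs = cf.group_restricted_pairs(
            x0, labels, x1, labels, {0: {0}, 1: {1}, 2: {2}}, seed=4)
        for g in range(3):
            src = x0[labels == g]
            tgt = x1[labels == g]
            cost = cf.poisson_cost_matrix(src, tgt, 1e-3)
            brute = min(
                sum(cost[i, p[i]] for i in range(3))
                for p in itertools.permutations(range(3))
            )
            sel0, sel1 = p0[labs == g], p1[labs == g]
            got = sum(cf.poisson_cost_matrix(sel0[i:i+1], sel1[i:i+1], 1e-3)[0, 0]
                      for i in range(3))
            assert np.isclose(got, brute)

    def test_missing_group_named_in_error(self):
        with pytest.raises(ValidationError, match="1"):
            cf.group_restricted_pairs([[1, 1]], [1], [[2, 2]], [0], {1: {1}})
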