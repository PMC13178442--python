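import itertools

import numpy as np
import pytest

import countfm as cf
from countfm import ValidationError


class TestWasserstein2:
    def test_identical_clouds_zero(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(20, 3))
        assert cf.wasserstein2(a, a.copy()) == pytest.approx(0.0, abs=1e-12)

    def test_single_pair_euclidean(self):
        assert cf.wasserstein2([[0, 0]], [[3, 4]]) == pytest.approx(5.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_bruteforce_assignment(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(5, 2))
        b = rng.normal(size=(5, 2))
        got = cf.wasserstein2(a, b)
        brute = min(
            np.mean([np.sum((a[i] - b[p[i]]) ** 2) for i in range(5)])
            for p in itertools.permutations(range(5))
        )
        assert got == pytest.approx(np.sqrt(brute))

    def test_metric_properties(self):
        rng = np.random.default_rng(7)
        a, b, c = (rng.normal(size=(8, 2)) for _ in range(3))
        dab = cf.wasserstein2(a, b)
        dba = cf.wasserstein2(b, a)
        assert dab == pytest.approx(dba)
        assert dab <= cf.wasserstein2(a, c) + cf.wasserstein2(c, b) + 1e-12

    def test_unequal_sizes_exact_lp(self):
        # two points vs four points placed so the optimum is computable by hand:
        # mass 1/2 at each source splits evenly onto its two nearest targets
        a = np.array([[0.0], [10.0]])
        b = np.array([[-1.0], [1.0], [9.0], [11.0]])
        # each source sends 1/4 mass to each of its two neighbors at distance 1
        assert cf.wasserstein2(a, b) == pytest.approx(1.0)

    def test_dimension_mismatch(self):
        with pytest.raises(ValidationError):
            cf.wasserstein2([[1, 2]], [[1, 2, 3]])


class TestMmdRbf2:
    def test_hand_expanded_double_sum(self):
        a = np.array([[0.0], [1.0], [2.0]])
        b = np.array([[0.5], [1.5], [4.0]])
        sigma = 1.3

        def k(u, v):
            return np.exp(-((u - v) ** 2) / (2 * sigma**2))

        m = n = 3
        taa = sum(k(a[i, 0], a[j, 0]) for i in range(m) for j in range(m) if i != j)
        tbb = sum(k(b[i, 0], b[j, 0]) for i in range(n) for j in range(n) if i != j)
        tab = sum(k(a[i, 0], b[j, 0]) for i in range(m) for j in range(n))
        want = taa / (m * (m - 1)) + tbb / (n * (n - 1)) - 2 * tab / (m * n)
        assert cf.mmd_rbf2(a, b, bandwidth=sigma) == pytest.approx(want)

    def test_huge_bandwidth_limit_zero(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(30, 2))
        b = rng.normal(3.0, 1.0, size=(30, 2))
        assert abs(cf.mmd_rbf2(a, b, bandwidth=1e9)) < 1e-12

    def test_null_fluctuation_scale(self):
        # same distribution on both sides: the unbiased estimate is centered
        # at zero with O(1/n) fluctuations
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = rng.poisson(5.0, size=(2000, 2))
            b = rng.poisson(5.0, size=(2000, 2))
            vals.append(cf.mmd_rbf2(a, b))
        vals = np.array(vals)
        assert np.abs(vals).max() < 3.0 / 2000 * 3
        assert abs(vals.mean()) < 3.0 / 2000

    def test_bad_bandwidth(self):
        with pytest.raises(ValidationError):
            cf.mmd_rbf2([[1.0], [2.0]], [[3.0], [4.0]], bandwidth=0.0)


class TestBenchmarkHarness:
    def test_oracle_model_matches_two_draw_baseline(self):
        # running the analytic-rate oracle through the full harness must land
        # at the W2 level of two independent target draws
        spec = cf.default_mixture_spec()

        def factory(seed):
            tgt = cf.sample_gamma_poisson_mixture(spec, 800, seed + 1000)
            return cf.ConditionalRateOracle(tgt.values)

        rep = cf.benchmark_simulation(seeds=[0], n_eval=800, model_factory=factory)
        a = cf.sample_gamma_poisson_mixture(spec, 800, 51)
        b = cf.sample_gamma_poisson_mixture(spec, 800, 52)
        baseline = cf.wasserstein2(a, b)
        assert rep.w2_mean < 2.0 * baseline

    def test_report_consistency(self):
        rep = cf.MetricReport(((0, 2.0, 0.1), (1, 4.0, 0.3)))
        assert rep.w2_mean == pytest.approx(3.0)
        assert rep.mmd2_mean == pytest.approx(0.2)
        assert rep.w2_std == pytest.approx(np.std([2.0, 4.0], ddof=1))


class TestConditionalMetrics:
    def _toy(self):
        rng = np.random.default_rng(0)
        real = rng.poisson([3.0, 1.0, 6.0], size=(60, 3))
        bins = np.repeat([0, 1], 30)
        return real, bins

    def test_perfect_reproduction_zero_errors(self):
        real, bins = self._toy()
        rep = cf.conditional_metrics(real, real.copy(), bins, bins.copy())
        assert rep.rmse_mu == 0.0
        assert rep.rmse_var == 0.0
        assert rep.rmse_zero == 0.0
        assert rep.cov_f == 0.0

    def test_single_bin_mean_shift(self):
        real = np.full((4, 1), 2)
        gen = np.full((4, 1), 3)
        rep = cf.conditional_metrics(real, gen, np.zeros(4, int), np.zeros(4, int))
        assert rep.rmse_mu == pytest.approx(1.0)

    def test_matches_spreadsheet_arithmetic(self):
        # 2 bins x 3 coordinates, hand-computed weighted RMSEs
        real = np.array([[0, 2, 4], [2, 2, 4], [1, 3, 5], [3, 3, 5], [1, 3, 5], [3, 3, 5]])
        bins = np.array([0, 0, 1, 1, 1, 1])
        gen = np.array([[1, 2, 5], [1, 2, 5], [2, 4, 4], [2, 4, 4], [2, 4, 4], [2, 4, 4]])
        rep = cf.conditional_metrics(real, gen, bins, bins.copy())
        # bin 0 (n=2): mu=(1,2,4), mu_hat=(1,2,5) -> sq err 1
        # bin 1 (n=4): mu=(2,3,5), mu_hat=(2,4,4) -> sq err 2
        want_mu = np.sqrt((2 * 1 + 4 * 2) / (6 * 3))
        assert rep.rmse_mu == pytest.approx(want_mu)
        # zero fractions: bin0 real (0.5,0,0) gen (0,0,0) -> 0.25;
        # bin1 real (0,0,0) gen (0,0,0) -> 0
        want_zero = np.sqrt((2 * 0.25) / (6 * 3))
        assert rep.rmse_zero == pytest.approx(want_zero)
        # variances (ddof=1): bin0 real (2,0,0) gen (0,0,0) -> 4;
        # bin1 real (4/3,0,0) gen 0 -> 16/9
        want_var = np.sqrt((2 * 4 + 4 * 16 / 9) / (6 * 3))
        assert rep.rmse_var == pytest.approx(want_var)

    def test_coordinate_permutation_invariance(self):
        real, bins = self._toy()
        rng = np.random.default_rng(1)
        gen = rng.poisson([2.0, 2.0, 5.0], size=(60, 3))
        base = cf.conditional_metrics(real, gen, bins, bins.copy())
        perm = [2, 0, 1]
        permuted = cf.conditional_metrics(real[:, perm], gen[:, perm], bins,
                                          bins.copy())
        assert permuted.rmse_mu == pytest.approx(base.rmse_mu)
        assert permuted.cov_f == pytest.approx(base.cov_f)
        assert permuted.contrast == pytest.approx(base.contrast)

    def test_small_bin_excluded_with_warning(self):
        real = np.array([[1], [2], [3]])
        bins = np.array([0, 0, 1])
        gen = np.array([[1], [2], [3], [4]])
        gbins = np.array([0, 0, 1, 1])
        with pytest.warns(UserWarning, match="excluded"):
            rep = cf.conditional_metrics(real, gen, bins, gbins)
        assert np.isfinite(rep.rmse_mu)
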