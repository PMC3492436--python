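import numpy as np
import pytest
from scipy import stats

from latsurr import (
    FBFSpec,
    Lattice,
    NullModelSpec,
    binarize_median,
    cerioli_modified_chi2,
    chi_square_binary,
    dutilleul_modified_t,
    fbf_generate,
    monte_carlo_test,
    pearson_r,
)
from latsurr.assoc_tests import _chi2_batch, _ess_correction, _pearson_batch
from latsurr.grid_io import DegenerateLatticeError


class TestPearson:
    def test_identical_lattices(self, fbf32):
        assert pearson_r(fbf32, fbf32) == pytest.approx(1.0)

    def test_negated(self, fbf32):
        assert pearson_r(fbf32, Lattice(-fbf32.values)) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        a = Lattice(np.array([[1.0, 2.0], [3.0, 4.0]]))
        b = Lattice(np.array([[1.0, 2.0], [4.0, 3.0]]))
        assert pearson_r(a, b) == pytest.approx(0.8)

    def test_errors(self, fbf32):
        with pytest.raises(ValueError):
            pearson_r(fbf32, Lattice(np.zeros((8, 8)) + 1.0))
        with pytest.raises(ValueError):
            pearson_r(fbf32, Lattice(np.ones((8, 9)) * np.arange(9)))

    def test_batch_matches_scalar(self, rng):
        A = rng.standard_normal((5, 6, 6))
        B = rng.standard_normal((5, 6, 6))
        batch = _pearson_batch(A, B)
        for i in range(5):
            assert batch[i] == pytest.approx(pearson_r(A[i], B[i]))


class TestChiSquare:
    @staticmethod
    def _from_counts(n11, n10, n01, n00):
        a = np.concatenate([np.ones(n11 + n10), np.zeros(n01 + n00)])
        b = np.concatenate([np.ones(n11), np.zeros(n10), np.ones(n01), np.zeros(n00)])
        side = int(np.sqrt(len(a)))
        return Lattice(a.reshape(side, -1)), Lattice(b.reshape(side, -1))

    def test_independent_counts_give_zero(self):
        a, b = self._from_counts(25, 25, 25, 25)
        assert chi_square_binary(a, b) == pytest.approx(0.0)

    def test_perfect_association_equals_n(self, binary32):
        assert chi_square_binary(binary32, binary32) == pytest.approx(1024.0)

    def test_hand_computed_counts(self):
        a, b = self._from_counts(30, 10, 10, 30)
        assert chi_square_binary(a, b) == pytest.approx(20.0)

    def test_degenerate_margin_rejected(self, binary32):
        with pytest.raises(ValueError, match="prevalence"):
            chi_square_binary(binary32, Lattice(np.ones((32, 32))))

    def test_batch_matches_scalar(self, rng):
        A = (rng.random((5, 8, 8)) > 0.4).astype(float)
        B = (rng.random((5, 8, 8)) > 0.6).astype(float)
        batch = _chi2_batch(A, B)
        for i in range(5):
            assert batch[i] == pytest.approx(chi_square_binary(A[i], B[i]))


class TestMonteCarlo:
    def test_result_contract(self, fbf32_pair):
        a, b = fbf32_pair
        res = monte_carlo_test(
            a, b, stat="pearson_r", null=NullModelSpec(model="reassignment"),
            n_surrogates=99, seed=5,
        )
        assert res.n_total == 100
        assert len(res.surrogate_values) == 99
        assert res.tails == "two_tailed_symmetric"
        assert res.p_value >= 1 / 100
        assert (res.p_value * res.n_total) == pytest.approx(
            round(res.p_value * res.n_total)
        )

    def test_observed_most_extreme_gives_minimum_p(self, fbf32):
        # identical lattices: |r_obs| = 1 beats every surrogate pair
        res = monte_carlo_test(
            fbf32, fbf32, stat="pearson_r",
            null=NullModelSpec(model="reassignment"), n_surrogates=499, seed=1,
        )
        assert res.p_value == pytest.approx(1 / 500)

    def test_p_invariant_to_affine_rescaling(self, fbf32_pair):
        a, b = fbf32_pair
        kw = dict(stat="pearson_r", null=NullModelSpec(model="reassignment"),
                  n_surrogates=49, seed=11)
        p1 = monte_carlo_test(a, b, **kw).p_value
        p2 = monte_carlo_test(Lattice(3.0 * a.values - 1.0), b, **kw).p_value
        assert p1 == p2

    def test_pvalues_uniform_under_exchangeable_null(self):
        # white-noise pairs with the reassignment null: exchangeability
        # makes the rank of the observed statistic uniform
        rng = np.random.default_rng(0)
        pvals = []
        for _ in range(400):
            a = rng.standard_normal((4, 4))
            b = rng.standard_normal((4, 4))
            res = monte_carlo_test(
                a, b, stat="pearson_r", null=NullModelSpec(model="reassignment"),
                n_surrogates=39, seed=rng,
            )
            pvals.append(res.p_value)
        # compare against the discrete uniform on {1/40, ..., 1}
        grid = (np.searchsorted(np.arange(1, 41) / 40, pvals, side="left") + 1) / 40
        assert stats.kstest(grid, "uniform").pvalue > 0.01

    def test_custom_statistic_callable(self, fbf32_pair):
        a, b = fbf32_pair

        def mean_abs_diff(x, y):
            return -np.mean(np.abs(x - y))

        res = monte_carlo_test(
            a, b, stat=mean_abs_diff, null=NullModelSpec(model="reassignment"),
            n_surrogates=29, seed=2,
        )
        assert res.statistic_name == "mean_abs_diff"
        assert 0 < res.p_value <= 1

    def test_too_few_surrogates_rejected(self, fbf32_pair):
        with pytest.raises(ValueError):
            monte_carlo_test(*fbf32_pair, n_surrogates=5, seed=0)


class TestDutilleul:
    def test_white_noise_effective_df_near_classical(self):
        dfs = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            a, b = rng.standard_normal((2, 10, 10))
            _, eff_df, _ = dutilleul_modified_t(a, b)
            dfs.append(eff_df)
        n = 100
        assert abs(np.mean(dfs) - (n - 2)) < 0.1 * (n - 2)

    def test_autocorrelated_fields_lose_degrees_of_freedom(self):
        n = 32 * 32
        for seed in range(5):
            a = fbf_generate(FBFSpec(beta=3.0, seed=300 + 2 * seed))
            b = fbf_generate(FBFSpec(beta=3.0, seed=301 + 2 * seed))
            _, eff_df, _ = dutilleul_modified_t(a, b)
            assert eff_df < n - 2

    def test_reduces_to_classical_t_without_autocorrelation(self):
        # with the correction term exactly zero the formulas coincide
        rng = np.random.default_rng(4)
        a, b = rng.standard_normal((2, 8, 8))
        r = pearson_r(a, b)
        n = a.size
        t_classical = r * np.sqrt((n - 2) / (1 - r ** 2))
        p_classical = 2 * stats.t.sf(abs(t_classical), n - 2)
        var_r, ess = _ess_correction(a, b, max_dist=None)
        # replicate the statistic with the no-correction variance 1/n
        eff_df = (1 + n) - 2
        t0 = r * np.sqrt(eff_df / (1 - r ** 2))
        p0 = 2 * stats.t.sf(abs(t0), eff_df)
        assert p0 == pytest.approx(p_classical, abs=2e-2)


class TestCerioli:
    def test_zero_statistic_maps_to_zero(self):
        a = np.zeros((10, 10))
        a[:, :5] = 1.0
        b = np.tile([1.0, 0.0], 50).reshape(10, 10)
        chi2 = chi_square_binary(a, b)
        adj, p = cerioli_modified_chi2(a, b)
        if chi2 == 0:
            assert adj == 0.0 and p == 1.0

    def test_independent_fields_correction_near_one(self):
        ratios = []
        for seed in range(60):
            rng = np.random.default_rng(1000 + seed)
            a = (rng.random((10, 10)) > 0.5).astype(float)
            b = (rng.random((10, 10)) > 0.5).astype(float)
            raw = chi_square_binary(a, b)
            if raw == 0:
                continue
            adj, _ = cerioli_modified_chi2(a, b)
            ratios.append(adj / raw)
        assert abs(np.mean(ratios) - 1.0) < 0.15

    def test_autocorrelation_deflates_statistic(self):
        for seed in range(5):
            a = binarize_median(fbf_generate(FBFSpec(beta=3.0, seed=400 + 2 * seed)))
            b = binarize_median(fbf_generate(FBFSpec(beta=3.0, seed=401 + 2 * seed)))
            raw = chi_square_binary(a, b)
            adj, _ = cerioli_modified_chi2(a, b)
            assert adj <= raw + 1e-9
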