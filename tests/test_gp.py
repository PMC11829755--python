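import math

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from mztseq import (
    DifferentialResult, GPHyperparams, HyperPriors,
    classify_direction, fit_gp, gp_marginal_loglik, inverse_vst, lr_test,
    matern52, vst,
)


class TestVST:
    @pytest.mark.parametrize("x", [0.0, 50.0, 100.0])
    def test_roundtrip_identity(self, x):
        m = 100.0
        y = vst(x, m)
        assert inverse_vst(y, m) == pytest.approx(x, rel=1e-9, abs=1e-9)

    def test_strictly_increasing(self, rng):
        m = 200.0
        xs = np.sort(rng.uniform(0, m, 50))
        ys = vst(xs, m)
        assert np.all(np.diff(ys) > 0)

    def test_zero_abundance_value(self):
        # log2((0 + 1) / (100 + 1000)) = log2(1/1100)
        assert vst(0.0, 100.0) == pytest.approx(math.log2(1 / 1100), abs=1e-9)
        assert vst(0.0, 100.0) == pytest.approx(-10.1033, abs=1e-3)

    def test_depends_on_gene_only_through_max(self):
        assert vst(3.0, 50.0) == vst(3.0, 50.0, alpha=1.0, beta=1000.0)
        assert vst(3.0, 50.0) != vst(3.0, 60.0)

    def test_nonpositive_max_rejected(self):
        with pytest.raises(ValueError):
            vst(1.0, 0.0)
        with pytest.raises(ValueError):
            inverse_vst(0.0, -1.0)

    def test_strict_inverse_rejects_below_infimum(self):
        lo = vst(0.0, 100.0)
        with pytest.raises(ValueError):
            inverse_vst(lo - 1.0, 100.0, strict=True)
        assert inverse_vst(lo - 1.0, 100.0) >= -1.0  # still >= -alpha


class TestMatern:
    def test_zero_lag_is_signal_variance(self):
        h = GPHyperparams(2.0, 1.5, 0.1)
        assert matern52(3.0, 3.0, h) == pytest.approx(4.0)

    def test_value_at_one_timescale(self):
        h = GPHyperparams(1.0, 2.0, 0.1)
        want = (1 + math.sqrt(5) + 5 / 3) * math.exp(-math.sqrt(5))
        assert matern52(0.0, 2.0, h) == pytest.approx(want, abs=1e-9)
        assert want == pytest.approx(0.523994, abs=1e-6)

    def test_monotone_decay_to_zero(self):
        h = GPHyperparams(1.0, 1.0, 0.1)
        r = np.linspace(0, 50, 200)
        k = matern52(r, 0.0, h)
        assert np.all(np.diff(k) < 0)
        assert k[-1] < 1e-8

    def test_positive_semidefinite_on_grids(self, rng):
        h = GPHyperparams(1.3, 0.7, 0.0001)
        t = np.sort(rng.uniform(0, 10, 12))
        K = matern52(t[:, None], t[None, :], h)
        np.testing.assert_allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() > -1e-9


class TestMarginalLoglik:
    def test_single_point_closed_form(self):
        # sigma_f^2 + sigma_n^2 = 1 -> N(0, 1) density at 0
        h = GPHyperparams(math.sqrt(0.5), 1.0, math.sqrt(0.5))
        assert gp_marginal_loglik([1.0], [0.0], h) == pytest.approx(
            -0.5 * math.log(2 * math.pi), abs=1e-12
        )

    def test_duplicate_times_rejected(self):
        h = GPHyperparams(1.0, 1.0, 0.1)
        with pytest.raises(ValueError, match="duplicate"):
            gp_marginal_loglik([1.0, 1.0], [0.0, 0.1], h)

    def test_matches_multivariate_normal_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 6))
            t = np.sort(rng.uniform(0, 10, n))
            while np.unique(t).size < n:
                t = np.sort(rng.uniform(0, 10, n))
            y = rng.standard_normal(n)
            h = GPHyperparams(*np.exp(rng.uniform(-1, 1, 3)))
            K = matern52(t[:, None], t[None, :], h) + h.sigma_n**2 * np.eye(n)
            want = multivariate_normal(np.zeros(n), K).logpdf(y)
            assert gp_marginal_loglik(t, y, h) == pytest.approx(want, abs=1e-8)

    def test_matches_sklearn_gp_regressor(self, rng):
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import ConstantKernel, Matern

        t = np.sort(rng.uniform(0, 8, 10))
        y = rng.standard_normal(10)
        h = GPHyperparams(1.4, 2.2, 0.3)
        kernel = ConstantKernel(h.sigma_f**2, "fixed") * Matern(h.tau, "fixed", nu=2.5)
        gpr = GaussianProcessRegressor(kernel=kernel, alpha=h.sigma_n**2, optimizer=None)
        gpr.fit(t[:, None], y)
        assert gp_marginal_loglik(t, y, h) == pytest.approx(
            gpr.log_marginal_likelihood(), abs=1e-8
        )


class TestFit:
    def test_constant_zero_data_gives_symmetric_ci_around_zero(self):
        t = 0.5 * np.arange(10)
        fit = fit_gp(t, np.zeros(10), seed=0)
        np.testing.assert_allclose(fit.median_transformed, 0.0, atol=1e-6)
        np.testing.assert_allclose(
            fit.median_transformed - fit.ci_low_transformed,
            fit.ci_high_transformed - fit.median_transformed,
        )

    def test_ci_ordering_preserved_through_back_transform(self, rng):
        t = 0.5 * np.arange(12)
        m = 80.0
        y = vst(rng.uniform(0, m, 12), m)
        fit = fit_gp(t, y, seed=3, gene_max=m)
        assert np.all(fit.ci_low <= fit.median + 1e-12)
        assert np.all(fit.median <= fit.ci_high + 1e-12)

    def test_same_seed_same_map(self, rng):
        t = 0.5 * np.arange(15)
        y = rng.standard_normal(15)
        f1 = fit_gp(t, y, seed=5)
        f2 = fit_gp(t, y, seed=5)
        assert f1.hyper == f2.hyper
        assert f1.loglik == f2.loglik

    def test_loglik_excludes_prior_by_default(self, rng):
        t = 0.5 * np.arange(10)
        y = rng.standard_normal(10)
        plain = fit_gp(t, y, seed=1)
        pen = fit_gp(t, y, seed=1, penalized_loglik=True)
        assert pen.loglik == pytest.approx(
            plain.loglik + HyperPriors().logpdf(plain.hyper.log_vector)
        )


class TestLRTest:
    def test_lr_identity_enforced(self):
        res = DifferentialResult("g", -10.0, -12.0, -25.0, 3.0, "increased")
        assert res.LR == 3.0
        with pytest.raises(AssertionError):
            DifferentialResult("g", -10.0, -12.0, -25.0, 4.0, "increased")

    def test_lr_symmetric_under_condition_swap(self, rng):
        t = 0.5 * np.arange(12)
        uic = rng.uniform(1, 60, 12)
        mo = rng.uniform(1, 60, 12)
        a = lr_test("g", t, uic, mo, seed=2)
        b = lr_test("g", t, mo, uic, seed=2)
        assert a.LR == pytest.approx(b.LR, abs=1e-6)

    def test_strong_divergence_gives_large_lr(self):
        t = 0.5 * np.arange(20)
        uic = 100.0 * np.exp(-t)
        mo = np.full(20, 100.0)
        res = lr_test("g", t, uic, mo, seed=0)
        assert res.LR > 10
        assert res.direction == "increased"


class TestDirection:
    def _fit_pair(self, uic_vals, mo_vals):
        t = np.arange(8, dtype=float)
        m = max(uic_vals.max(), mo_vals.max(), 1.0)
        fu = fit_gp(t, vst(uic_vals, m), seed=0, gene_max=m)
        fm = fit_gp(t, vst(mo_vals, m), seed=0, gene_max=m)
        return fu, fm

    def test_uniform_shift_up_is_increased(self):
        uic = np.linspace(10, 20, 8)
        fu, fm = self._fit_pair(uic, uic + 30)
        assert classify_direction(fu, fm) == "increased"

    def test_exact_tie_is_decreased(self):
        uic = np.linspace(10, 20, 8)
        fu, fm = self._fit_pair(uic, uic.copy())
        assert classify_direction(fu, fm) == "decreased"

    def test_net_negative_mean_is_decreased(self):
        t = np.arange(8, dtype=float)
        uic = np.full(8, 50.0)
        mo = np.concatenate([np.full(2, 60.0), np.full(6, 10.0)])
        fu, fm = self._fit_pair(uic, mo)
        assert classify_direction(fu, fm) == "decreased"

    def test_grid_mismatch_rejected(self):
        t = np.arange(8, dtype=float)
        f1 = fit_gp(t, np.zeros(8), seed=0)
        f2 = fit_gp(t[:-1], np.zeros(7), seed=0)
        with pytest.raises(ValueError, match="grid"):
            classify_direction(f1, f2)
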