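"""Log-logistic MLE, the family registry, and AIC model selection."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from t2het import (
    default_registry,
    fit_family,
    fit_loglogistic_mle,
    fit_loglogistic_mle_batch,
    loglogistic_logpdf,
    loglogistic_ppf,
    modal_best_family,
    select_best,
    summarize_region,
)
from t2het.distributions import (
    SupportError,
    aic,
    fit_all_families,
    loglogistic_cdf,
    loglogistic_pdf,
    registry_by_name,
)
from t2het.types import DistributionFit, ROISampleVector

HC_PARAMS = (4.68, 0.112)  # healthy-control hippocampus example
MCI_PARAMS = (4.71, 0.135)  # MCI hippocampus example


def _sample(mu, sigma, n, seed):
    rng = np.random.default_rng(seed)
    return loglogistic_ppf(rng.uniform(size=n), mu, sigma)


class TestLogLogisticDensity:
    def test_density_at_median_standard(self):
        # z = 0 at the median, so f = 1 / (4 sigma x)
        assert math.exp(loglogistic_logpdf(1.0, 0.0, 1.0)) == pytest.approx(0.25)

    def test_density_at_median_closed_form(self):
        mu, sigma = HC_PARAMS
        x = math.exp(mu)
        expected = 1.0 / (4.0 * sigma * x)
        assert loglogistic_pdf(x, mu, sigma) == pytest.approx(expected, rel=1e-12)

    def test_integrates_to_one(self):
        total, err = integrate.quad(
            lambda x: loglogistic_pdf(x, 4.7, 0.12), 0.0, np.inf
        )
        assert abs(total - 1.0) < 1e-8

    def test_matches_scipy_fisk(self):
        # scipy's fisk is the log-logistic with c = 1/sigma, scale = exp(mu)
        x = np.linspace(50.0, 250.0, 7)
        mu, sigma = 4.7, 0.13
        expected = stats.fisk.logpdf(x, 1.0 / sigma, scale=math.exp(mu))
        assert np.allclose(loglogistic_logpdf(x, mu, sigma), expected, rtol=1e-12)

    def test_extreme_arguments_do_not_overflow(self):
        out = loglogistic_logpdf(np.array([1e-12, 1e12]), 4.7, 0.05)
        assert np.all(np.isfinite(out))

    @pytest.mark.parametrize("bad", [-1.0, 0.0])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            loglogistic_logpdf(bad, 4.7, 0.1)
        with pytest.raises(ValueError):
            loglogistic_logpdf(100.0, 4.7, bad)

    def test_ppf_cdf_inverse_pair(self):
        u = np.linspace(0.01, 0.99, 21)
        x = loglogistic_ppf(u, *MCI_PARAMS)
        assert np.allclose(loglogistic_cdf(x, *MCI_PARAMS), u, atol=1e-12)


class TestLogLogisticMLE:
    @pytest.mark.parametrize("mu,sigma", [HC_PARAMS, MCI_PARAMS])
    def test_parameter_recovery_large_n(self, mu, sigma):
        x = _sample(mu, sigma, 100_000, seed=2024)
        mu_hat, sigma_hat, _, ok = fit_loglogistic_mle(x)
        assert ok
        assert abs(mu_hat - mu) < 0.01
        assert abs(sigma_hat - sigma) < 0.005

    def test_matches_scipy_fisk_mle(self):
        x = _sample(4.7, 0.12, 5000, seed=5)
        mu_hat, sigma_hat, ll, ok = fit_loglogistic_mle(x)
        c, _, scale = stats.fisk.fit(x, floc=0)
        assert ok
        assert mu_hat == pytest.approx(math.log(scale), abs=2e-6)
        assert sigma_hat == pytest.approx(1.0 / c, abs=2e-6)
        assert ll == pytest.approx(stats.fisk.logpdf(x, c, scale=scale).sum(), abs=1e-4)

    def test_scale_equivariance(self):
        x = _sample(4.6, 0.11, 3000, seed=9)
        mu1, s1, _, _ = fit_loglogistic_mle(x)
        mu2, s2, _, _ = fit_loglogistic_mle(2.0 * x)
        assert mu2 - mu1 == pytest.approx(math.log(2.0), abs=1e-6)
        assert s2 == pytest.approx(s1, abs=1e-6)

    def test_degenerate_zero_spread_flagged(self):
        mu_hat, sigma_hat, _, ok = fit_loglogistic_mle(np.full(50, 90.0))
        assert not ok
        assert mu_hat == pytest.approx(math.log(90.0))
        assert sigma_hat <= 1e-6

    def test_too_few_samples_raises(self):
        with pytest.raises(ValueError, match="at least"):
            fit_loglogistic_mle(np.full(5, 90.0))

    def test_nonpositive_samples_raise(self):
        with pytest.raises(ValueError, match="positive"):
            fit_loglogistic_mle(np.array([1.0] * 10 + [-2.0]))

    def test_median_identity_at_large_n(self):
        # exp(mu_hat) tracks the sample median within 2x its Monte-Carlo SE
        mu, sigma = 4.7, 0.12
        n = 10_000
        x = _sample(mu, sigma, n, seed=77)
        mu_hat, _, _, _ = fit_loglogistic_mle(x)
        med = np.median(x)
        # SE of the sample median: 1 / (2 f(med) sqrt(n))
        se_med = 1.0 / (2.0 * loglogistic_pdf(med, mu, sigma) * math.sqrt(n))
        assert abs(math.exp(mu_hat) - med) < 2.0 * se_med

    def test_consistency_rmse_shrinks_with_n(self):
        mu, sigma = 4.68, 0.112
        rng = np.random.default_rng(31)
        rmse = []
        for n in (100, 1000, 10_000):
            x = loglogistic_ppf(rng.uniform(size=(50, n)), mu, sigma)
            mu_hat, sigma_hat, _, _ = fit_loglogistic_mle_batch(x)
            rmse.append(
                (
                    math.sqrt(np.mean((mu_hat - mu) ** 2)),
                    math.sqrt(np.mean((sigma_hat - sigma) ** 2)),
                )
            )
        assert rmse[0][0] > rmse[1][0] > rmse[2][0]
        assert rmse[0][1] > rmse[1][1] > rmse[2][1]


class TestBatchMLE:
    def test_agrees_with_scalar_path(self):
        x = loglogistic_ppf(
            np.random.default_rng(3).uniform(size=(20, 400)), 4.7, 0.12
        )
        mu_b, sg_b, ll_b, conv = fit_loglogistic_mle_batch(x)
        assert conv.all()
        for i in (0, 7, 19):
            mu_s, sg_s, ll_s, ok = fit_loglogistic_mle(x[i])
            assert ok
            assert mu_b[i] == pytest.approx(mu_s, abs=1e-6)
            assert sg_b[i] == pytest.approx(sg_s, abs=1e-6)
            assert ll_b[i] == pytest.approx(ll_s, abs=1e-6)

    def test_ragged_mask_support(self):
        rng = np.random.default_rng(8)
        x = loglogistic_ppf(rng.uniform(size=(4, 300)), 4.6, 0.1)
        mask = np.ones_like(x, dtype=bool)
        mask[1, 150:] = False  # second ROI has half the voxels
        mu_b, sg_b, _, conv = fit_loglogistic_mle_batch(x, mask=mask)
        mu_s, sg_s, _, _ = fit_loglogistic_mle(x[1, :150])
        assert conv.all()
        assert mu_b[1] == pytest.approx(mu_s, abs=1e-6)
        assert sg_b[1] == pytest.approx(sg_s, abs=1e-6)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError, match="positive"):
            fit_loglogistic_mle_batch(np.array([[1.0, -1.0, 2.0]]))


class TestFamilyRegistry:
    def test_registry_has_18_families_with_loglogistic(self):
        reg = default_registry()
        names = [f.name for f in reg]
        assert len(reg) == 18
        assert len(set(names)) == 18
        assert "loglogistic" in names

    def test_normal_closed_form_mle(self):
        fam = {f.name: f for f in default_registry()}["normal"]
        fit = fit_family(np.array([1.0, 2.0, 3.0]), fam)
        assert fit.params[0] == pytest.approx(2.0)
        assert fit.params[1] == pytest.approx(math.sqrt(2.0 / 3.0))
        assert fit.aic == pytest.approx(aic(2, fit.loglik))

    def test_exponential_closed_form_mle(self):
        fam = {f.name: f for f in default_registry()}["exponential"]
        fit = fit_family(np.array([2.0, 2.0, 2.0]), fam)
        assert fit.params[0] == pytest.approx(2.0)
        # loglik = sum log(rate e^{-rate x}) = 3 (log(1/2) - 1)
        assert fit.loglik == pytest.approx(3.0 * (math.log(0.5) - 1.0), rel=1e-12)

    def test_aic_definition_recomputed_independently(self, rng):
        x = _sample(4.7, 0.12, 500, seed=13)
        fits, _ = fit_all_families(x)
        for f in fits:
            if f.converged:
                assert f.aic == pytest.approx(2 * f.n_params - 2 * f.loglik, rel=1e-12)

    def test_support_violation_raises_and_is_recorded(self):
        fam = {f.name: f for f in default_registry()}["lognormal"]
        with pytest.raises(SupportError):
            fit_family(np.array([1.0, -1.0, 2.0]), fam)
        fits, skipped = fit_all_families(np.array([1.0, -1.0, 2.0, 3.0]))
        assert "lognormal" in skipped
        assert all(f.family not in skipped for f in fits)

    def test_sample_smaller_than_param_count_raises(self):
        fam = {f.name: f for f in default_registry()}["gev"]
        with pytest.raises(ValueError, match="below parameter count"):
            fit_family(np.array([1.0, 2.0]), fam)

    @pytest.mark.parametrize("name", ["loglogistic", "gamma", "weibull"])
    def test_fitted_density_integrates_to_one(self, name):
        fam = {f.name: f for f in default_registry()}[name]
        x = _sample(4.7, 0.12, 400, seed=21)
        fit = fit_family(x, fam)
        total, _ = integrate.quad(
            lambda v: math.exp(fam.logpdf(np.array([v]), fit.params)[0]),
            0.0, np.inf, limit=200,
        )
        assert abs(total - 1.0) < 1e-6

    def test_named_registries(self):
        assert [f.name for f in registry_by_name("loglogistic")] == ["loglogistic"]
        assert len(registry_by_name("core")) == 6
        with pytest.raises(ValueError, match="unknown"):
            registry_by_name("nope")


def _fit(family, aic_value, n_params=2, converged=True):
    return DistributionFit(
        family=family, params=(0.0,), loglik=0.0, aic=aic_value,
        n=100, n_params=n_params, converged=converged,
    )


class TestSelection:
    def test_single_fit_selected(self):
        assert select_best([_fit("gamma", 50.0)]) == "gamma"

    def test_argmin_aic(self):
        fits = [_fit("a", 100.0), _fit("b", 90.0), _fit("c", 95.0)]
        assert select_best(fits) == "b"

    def test_tie_broken_by_fewer_params_then_order(self):
        fits = [_fit("a", 90.0, n_params=3), _fit("b", 90.0, n_params=2)]
        assert select_best(fits) == "b"
        fits = [_fit("a", 90.0), _fit("b", 90.0)]
        assert select_best(fits) == "a"

    def test_nonconverged_excluded(self):
        fits = [_fit("a", 10.0, converged=False), _fit("b", 99.0)]
        assert select_best(fits) == "b"
        with pytest.raises(ValueError, match="no converged"):
            select_best([_fit("a", 10.0, converged=False)])

    def test_modal_family(self):
        name, table, tie = modal_best_family(
            ["loglogistic", "loglogistic", "loglogistic", "lognormal"]
        )
        assert name == "loglogistic" and not tie
        assert table == {"loglogistic": 3, "lognormal": 1}

    def test_modal_tie_flag_and_registry_order(self):
        name, _, tie = modal_best_family(["lognormal", "loglogistic"])
        assert tie
        assert name == "loglogistic"  # earlier in the registry
        with pytest.raises(ValueError):
            modal_best_family([])


class TestSummarizeRegion:
    def _vec(self, mu, sigma, n, seed, hemi):
        return ROISampleVector(
            values=_sample(mu, sigma, n, seed), region="hippocampus",
            hemisphere=hemi, subject_id="sub-0001",
        )

    def test_identical_hemispheres_average_to_themselves(self):
        left = self._vec(4.7, 0.12, 2000, 1, "left")
        right = ROISampleVector(
            values=left.values.copy(), region="hippocampus",
            hemisphere="right", subject_id="sub-0001",
        )
        s = summarize_region(left, right)
        assert s.t2_mu == pytest.approx(s.hemispheres["left"].params[0])
        assert s.t2_sigma == pytest.approx(s.hemispheres["left"].params[1])

    def test_region_values_are_unweighted_hemisphere_means(self):
        s = summarize_region(
            self._vec(4.6, 0.10, 1500, 2, "left"),
            self._vec(4.8, 0.14, 3000, 3, "right"),
        )
        mus = [s.hemispheres[h].params[0] for h in ("left", "right")]
        sigmas = [s.hemispheres[h].params[1] for h in ("left", "right")]
        assert s.t2_mu == pytest.approx(np.mean(mus), rel=1e-12)
        assert s.t2_sigma == pytest.approx(np.mean(sigmas), rel=1e-12)

    def test_known_sigma_pair_averages_to_midpoint(self):
        # large samples: sigma_hat near 0.10 and 0.14, so the region value
        # sits near 0.12 within MLE tolerance
        s = summarize_region(
            self._vec(4.7, 0.10, 50_000, 4, "left"),
            self._vec(4.7, 0.14, 50_000, 5, "right"),
        )
        assert s.t2_sigma == pytest.approx(0.12, abs=0.002)

    def test_single_hemisphere_mode_flagged(self):
        s = summarize_region(self._vec(4.7, 0.12, 1000, 6, "left"), None)
        assert s.single_hemisphere
        assert s.t2_mu == pytest.approx(s.hemispheres["left"].params[0])

    def test_both_empty_raises(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_region(None, None)

    def test_pooled_combination(self):
        left = self._vec(4.7, 0.12, 1000, 7, "left")
        right = self._vec(4.7, 0.12, 1000, 8, "right")
        s = summarize_region(left, right, combine="pooled")
        mu_pool, sg_pool, _, _ = fit_loglogistic_mle(
            np.concatenate([left.values, right.values])
        )
        assert s.t2_mu == pytest.approx(mu_pool, rel=1e-9)
        assert s.t2_sigma == pytest.approx(sg_pool, rel=1e-9)

    def test_best_family_reported_separately(self):
        left = self._vec(4.7, 0.12, 4000, 9, "left")
        right = self._vec(4.7, 0.12, 4000, 10, "right")
        s = summarize_region(left, right, families=registry_by_name("core"))
        assert set(s.best_family) == {"left", "right"}
        assert all(v in {f.name for f in registry_by_name("core")}
                   for v in s.best_family.values())
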