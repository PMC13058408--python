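"""Standardisation, empirical-Bayes priors, HMC fitting, pooling and R2."""

import numpy as np
import pandas as pd
import pytest

from nfpredict.bayes import (FrequentistFit, McmcSettings, ModelSpec,
                             PosteriorFit, PriorSet, _summarize, bayes_r2,
                             diagnose, empirical_bayes_priors, fit_model,
                             fit_model_stack, frequentist_mle, incremental_r2,
                             pool_fits, standardize)
from tests.conftest import make_gaussian_design

TINY = McmcSettings(iterations=1200, burn_in=600, chains=4)


def weak_priors(cols, aux=(0.0, 1.0)):
    return PriorSet({c: (0.0, 2.5) for c in cols}, aux=aux)


class TestStandardize:
    def test_zscore_uses_sample_sd(self):
        d = standardize(pd.DataFrame({"x": [1.0, 2.0, 3.0]}), {"x": "metric"})
        np.testing.assert_allclose(d.table["x"], [-1.0, 0.0, 1.0])
        assert abs(d.table["x"].mean()) < 1e-10
        assert abs(d.table["x"].std(ddof=1) - 1) < 1e-10

    def test_binary_effect_coding(self):
        d = standardize(pd.DataFrame({"b": ["no", "yes", "no"]}),
                        {"b": "binary"})
        np.testing.assert_allclose(d.table["b"], [-0.5, 0.5, -0.5])

    def test_ordinal_cumulative_coding(self):
        d = standardize(pd.DataFrame({"o": [1, 2, 3]}), {"o": "ordinal"})
        # level 2 of 3: first threshold crossed, second not
        np.testing.assert_allclose(d.table.iloc[1], [0.5, -0.5])
        assert d.term_columns["o"] == ["o_ge2", "o_ge3"]

    def test_counts_left_unstandardized(self):
        d = standardize(pd.DataFrame({"y": [0, 3, 7]}), {"y": "count"})
        np.testing.assert_array_equal(d.table["y"], [0, 3, 7])

    def test_zero_variance_metric_rejected_by_name(self):
        with pytest.raises(ValueError, match="flat"):
            standardize(pd.DataFrame({"flat": [2.0, 2.0]}), {"flat": "metric"})


class TestModelSpec:
    def test_predictor_covariate_overlap_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("y", "gaussian", ("a",), covariates=("a",))

    def test_without_removes_one_predictor(self):
        spec = ModelSpec("y", "gaussian", ("a", "b"))
        assert spec.without("a").predictors == ("b",)
        with pytest.raises(ValueError):
            spec.without("zzz")


class TestEmpiricalBayesPriors:
    def test_common_scale_is_max_of_sd_and_mean_se(self):
        ff = FrequentistFit(coef={"a": (0.2, 0.3), "b": (-0.4, 0.3),
                                  "c": (0.6, 0.3)}, aux=None, converged=True)
        ps = empirical_bayes_priors(ff, {c: "fam" for c in "abc"})
        sd = np.std([0.2, -0.4, 0.6], ddof=1)
        for c in "abc":
            assert ps.coef[c][1] == pytest.approx(sd)
        # large SEs dominate when they exceed the MLE spread
        ff2 = FrequentistFit(coef={"a": (0.2, 0.9), "b": (0.25, 0.9)},
                             aux=None, converged=True)
        ps2 = empirical_bayes_priors(ff2, {"a": "fam", "b": "fam"})
        assert ps2.coef["a"][1] == pytest.approx(0.9)

    def test_scale_multiplier_doubles_every_scale(self):
        ff = FrequentistFit(coef={"a": (0.2, 0.3), "b": (-0.4, 0.3)},
                            aux=2.0, converged=True)
        base = empirical_bayes_priors(ff, {"a": "f", "b": "f"})
        doubled = base.scaled(2.0)
        for c in ("a", "b"):
            loc0, sc0 = base.location_scale(c)
            loc2, sc2 = doubled.location_scale(c)
            assert loc2 == loc0 and sc2 == pytest.approx(2 * sc0)
        assert doubled.aux_location_scale()[1] == pytest.approx(
            2 * base.aux_location_scale()[1])

    def test_single_member_family_uses_its_se(self):
        ff = FrequentistFit(coef={"a": (0.3, 0.12)}, aux=None, converged=True)
        ps = empirical_bayes_priors(ff, {"a": "solo"})
        assert ps.coef["a"] == (0.3, 0.12)

    def test_nonconverged_coefficient_falls_back_to_weak_prior(self):
        ff = FrequentistFit(coef={"a": (np.nan, np.nan), "b": (0.1, 0.2)},
                            aux=None, converged=False)
        ps = empirical_bayes_priors(ff, {"a": "f1", "b": "f2"})
        assert ps.coef["a"] == (0.0, 2.5)
        assert "a" in ps.fallbacks


class TestFitModel:
    def test_gaussian_posterior_matches_ols_oracle(self):
        design, names = make_gaussian_design(n=200, seed=1)
        spec = ModelSpec("y", "gaussian", tuple(names))
        fit = fit_model(spec, design, weak_priors(["intercept"] + names), TINY)
        X, cols = design.matrix(spec.terms)
        ols = np.linalg.lstsq(X, design.outcome("y"), rcond=None)[0]
        for i, c in enumerate(cols):
            assert fit.summary.loc[c, "mean"] == pytest.approx(ols[i],
                                                               abs=0.05)

    def test_draw_count_matches_chains_and_kept_iterations(self):
        design, names = make_gaussian_design(n=60, seed=2)
        spec = ModelSpec("y", "gaussian", tuple(names))
        fit = fit_model(spec, design, weak_priors(["intercept"] + names), TINY)
        assert fit.draws.shape == (4, 600, len(names) + 2)  # + intercept, aux

    def test_constant_outcome_rejected(self):
        tab = pd.DataFrame({"y": [1.0] * 20,
                            "x": np.random.default_rng(0).standard_normal(20)})
        d = standardize(tab, {"y": "passthrough", "x": "metric"})
        with pytest.raises(ValueError, match="constant"):
            fit_model(ModelSpec("y", "gaussian", ("x",)), d,
                      weak_priors(["intercept", "x"]), TINY)

    def test_missing_priors_rejected(self):
        design, names = make_gaussian_design(n=50, seed=3)
        with pytest.raises(ValueError, match="priors"):
            fit_model(ModelSpec("y", "gaussian", tuple(names)), design,
                      weak_priors(["intercept"]), TINY)

    def test_prior_dominance_in_small_scale_limit(self):
        design, names = make_gaussian_design(n=100, seed=4)
        spec = ModelSpec("y", "gaussian", (names[0],))
        priors = PriorSet({"intercept": (0.0, 2.5), names[0]: (1.7, 1e-3)},
                          aux=(0.0, 1.0))
        fit = fit_model(spec, design, priors, TINY)
        assert fit.summary.loc[names[0], "mean"] == pytest.approx(1.7,
                                                                  abs=0.01)

    def test_reproducibility_under_fixed_seed(self):
        design, names = make_gaussian_design(n=80, seed=5)
        spec = ModelSpec("y", "gaussian", tuple(names))
        pr = weak_priors(["intercept"] + names)
        a = fit_model(spec, design, pr, TINY)
        b = fit_model(spec, design, pr, TINY)
        pd.testing.assert_frame_equal(a.summary, b.summary)

    def test_nb_fit_on_poisson_data_concentrates_dispersion_high(self):
        rng = np.random.default_rng(6)
        n = 400
        x = rng.standard_normal(n)
        y = rng.poisson(np.exp(1.0 + 0.3 * x))
        d = standardize(pd.DataFrame({"y": y, "x": x}),
                        {"y": "count", "x": "metric"})
        fit = fit_model(ModelSpec("y", "negative_binomial", ("x",)), d,
                        weak_priors(["intercept", "x"], aux=(1.0, 2.0)), TINY)
        # Poisson limit: dispersion posterior pushed to large values
        assert fit.summary.loc["log_dispersion", "mean"] > np.log(10)

    def test_stack_fit_matches_single_fits_in_distribution(self):
        design, names = make_gaussian_design(n=120, seed=7)
        spec = ModelSpec("y", "gaussian", tuple(names))
        pr = weak_priors(["intercept"] + names)
        fits = fit_model_stack(spec, [design, design], pr, TINY)
        assert len(fits) == 2
        a, b = (f.summary["mean"] for f in fits)
        np.testing.assert_allclose(a, b, atol=0.05)


def fake_fit(draws, names=("p",)):
    spec = ModelSpec("y", "gaussian", ())
    return PosteriorFit(spec=spec, param_names=list(names),
                        coef_names=list(names), draws=draws,
                        summary=_summarize(draws, list(names)), loglik=None,
                        X=None, y=None, provenance={})


class TestDiagnose:
    def test_copied_chains_have_unit_rhat(self):
        rng = np.random.default_rng(0)
        one = rng.standard_normal((1, 2000, 1))
        v = diagnose(fake_fit(np.tile(one, (4, 1, 1))))
        assert v.max_rhat == pytest.approx(1.0, abs=0.01)

    def test_iid_draws_have_nominal_ess(self):
        rng = np.random.default_rng(1)
        v = diagnose(fake_fit(rng.standard_normal((4, 2000, 1))))
        assert v.min_ess == pytest.approx(8000, rel=0.20)
        assert v.passed

    def test_offset_chain_fails_rhat(self):
        rng = np.random.default_rng(2)
        draws = rng.standard_normal((4, 1000, 1))
        draws[0] += 10.0
        v = diagnose(fake_fit(draws))
        assert v.max_rhat > 1.1
        assert not v.passed

    def test_single_chain_is_indeterminate(self):
        rng = np.random.default_rng(3)
        v = diagnose(fake_fit(rng.standard_normal((1, 1000, 1))))
        assert v.indeterminate


class TestPoolFits:
    def _fits(self, m=3, n=120, seed=8):
        design, names = make_gaussian_design(n=n, seed=seed)
        spec = ModelSpec("y", "gaussian", tuple(names))
        pr = weak_priors(["intercept"] + names)
        return [fit_model(spec, design, pr, TINY, imputation_index=i)
                for i in range(m)]

    def test_identical_fits_pool_to_single_fit_summaries(self):
        fits = self._fits(m=1) * 3
        pooled = pool_fits(fits)
        # identical up to the ddof term in the draw SD
        pd.testing.assert_frame_equal(pooled.summary, fits[0].summary,
                                      atol=1e-3, rtol=0)
        assert pooled.provenance["pooling"] == "combine"

    def test_pooled_draw_count_is_m_times_chains(self):
        fits = self._fits(m=3)
        pooled = pool_fits(fits)
        assert pooled.draws.shape == (3 * 4, 600, fits[0].draws.shape[-1])

    def test_nonconverged_fit_triggers_rubin_path(self):
        fits = self._fits(m=3)
        bad = fits[1]
        bad.draws = bad.draws.copy()
        bad.draws[0] += 25.0  # inject a stuck, offset chain
        pooled = pool_fits(fits)
        assert pooled.provenance["pooling"] == "rubin"
        assert pooled.draws is None
        assert {"mean", "sd", "cri_lower", "cri_upper"} <= set(pooled.summary)

    def test_mismatched_specs_rejected(self):
        fits = self._fits(m=2)
        other_design, names = make_gaussian_design(n=120, coefs=(0.5,), seed=9)
        other = fit_model(ModelSpec("y", "gaussian", ("x1",)), other_design,
                          weak_priors(["intercept", "x1"]), TINY)
        with pytest.raises(ValueError):
            pool_fits([fits[0], other])


class TestBayesR2:
    def test_noiseless_saturated_fit_explains_everything(self):
        design, names = make_gaussian_design(n=150, coefs=(1.0, 0.8),
                                             sigma=1e-4, seed=10)
        fit = fit_model(ModelSpec("y", "gaussian", tuple(names)), design,
                        weak_priors(["intercept"] + names), TINY)
        _, s = bayes_r2(fit)
        assert s["mean"] > 0.99

    def test_intercept_only_model_explains_nothing(self):
        design, _ = make_gaussian_design(n=150, coefs=(0.0,), seed=11)
        fit = fit_model(ModelSpec("y", "gaussian", ()), design,
                        weak_priors(["intercept"]), TINY)
        _, s = bayes_r2(fit)
        assert s["mean"] < 0.02

    def test_known_variance_split_recovered(self):
        # var(fitted) = 1, var(noise) = 1 -> R2 = 0.5
        design, names = make_gaussian_design(n=1000, coefs=(1.0,), sigma=1.0,
                                             seed=12)
        fit = fit_model(ModelSpec("y", "gaussian", tuple(names)), design,
                        weak_priors(["intercept"] + names), TINY)
        _, s = bayes_r2(fit)
        assert 0.45 <= s["mean"] <= 0.55


class TestIncrementalR2:
    def test_null_predictor_adds_nothing(self):
        design, names = make_gaussian_design(n=500, coefs=(0.8, 0.0), seed=13)
        pr = weak_priors(["intercept"] + names)
        full = fit_model(ModelSpec("y", "gaussian", tuple(names)), design,
                         pr, TINY)
        reduced = fit_model(ModelSpec("y", "gaussian", (names[0],)), design,
                            pr, TINY)
        _, s, diag = incremental_r2(full, reduced)
        assert s["mean"] < 0.02
        assert diag["predictor"] == names[1]

    def test_strong_predictor_contribution_recovered(self):
        # x2 contributes 0.36 of total variance 1.36 + 1 -> Delta R2 ~ 0.3
        design, names = make_gaussian_design(n=1000, coefs=(1.0, 0.85),
                                             sigma=1.0, seed=14)
        pr = weak_priors(["intercept"] + names)
        full = fit_model(ModelSpec("y", "gaussian", tuple(names)), design,
                         pr, TINY)
        reduced = fit_model(ModelSpec("y", "gaussian", (names[0],)), design,
                            pr, TINY)
        _, s, _ = incremental_r2(full, reduced)
        assert 0.2 <= s["mean"] <= 0.4

    def test_identical_specs_rejected(self):
        design, names = make_gaussian_design(n=100, seed=15)
        pr = weak_priors(["intercept"] + names)
        fit = fit_model(ModelSpec("y", "gaussian", tuple(names)), design,
                        pr, TINY)
        with pytest.raises(ValueError):
            incremental_r2(fit, fit)


class TestFrequentistMle:
    def test_ols_route_recovers_coefficients(self):
        design, names = make_gaussian_design(n=300, seed=16)
        ff = frequentist_mle(ModelSpec("y", "gaussian", tuple(names)), design)
        assert ff.converged
        X, cols = design.matrix(tuple(names))
        ols = np.linalg.lstsq(X, design.outcome("y"), rcond=None)[0]
        for i, c in enumerate(cols):
            assert ff.coef[c][0] == pytest.approx(ols[i], abs=1e-6)

    def test_separation_falls_back_gracefully(self):
        # perfectly separated logit: flagged, not crashed
        tab = pd.DataFrame({"y": [0] * 10 + [1] * 10,
                            "x": list(range(10)) + list(range(20, 30))})
        d = standardize(tab, {"y": "binary_outcome", "x": "metric"})
        ff = frequentist_mle(ModelSpec("y", "bernoulli_logit", ("x",)), d)
        assert not ff.converged
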