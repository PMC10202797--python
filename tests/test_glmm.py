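"""Multilevel binomial fitting: oracles, limits, symmetries, translation."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import special, stats

from clickbias.features import build_feature_table
from clickbias.glmm import (
    LaplaceBinomialGLMM,
    ModelSpec,
    RankDeficiencyError,
    fit_glmm,
    model_concordance,
    odds_percent_change,
    per_word_effect,
    standardize_features,
    wald_inference,
)
from clickbias.synth import GeneratorConfig, generate_archive

VARS = ["positive", "negative", "length", "complexity", "platform_age"]


def synth_frame(seed, n_experiments, variables=("positive", "negative", "length"), **kw):
    config = GeneratorConfig(seed=seed, n_experiments=n_experiments, **kw)
    archive, truth = generate_archive(config)
    frame = build_feature_table(archive, truth.lexicon).frame
    std_frame, std = standardize_features(frame, list(variables))
    return std_frame, std, truth


@pytest.fixture(scope="module")
def high_info():
    """A small, information-rich instance on which the Laplace and
    quadrature evaluations of the marginal likelihood nearly coincide."""
    frame, _, _ = synth_frame(7, 9, impressions_mean=1e6, impressions_sigma=0.2)
    return frame, ModelSpec(fixed_terms=["positive", "negative", "length"])


class TestStandardize:
    def test_three_point_example(self):
        rows = pd.DataFrame({"x": [1.0, 2.0, 3.0], "experiment_id": list("abc")})
        out, std = standardize_features(rows, ["x"])
        assert list(out["x"]) == pytest.approx([-1.0, 0.0, 1.0])
        assert std.means["x"] == 2.0
        assert std.sds["x"] == 1.0

    def test_constant_column_errors_with_name(self):
        rows = pd.DataFrame({"x": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="x"):
            standardize_features(rows, ["x"])

    def test_round_trip_inverse(self):
        rng = np.random.default_rng(0)
        rows = pd.DataFrame({"x": rng.normal(5, 3, 40), "y": rng.uniform(0, 1, 40)})
        out, std = standardize_features(rows, ["x", "y"])
        back = std.inverse(out)
        assert np.allclose(back["x"], rows["x"])
        assert np.allclose(back["y"], rows["y"])
        assert np.mean(out["x"]) == pytest.approx(0.0, abs=1e-12)
        assert np.std(out["x"], ddof=1) == pytest.approx(1.0)


class TestLaplaceLoglik:
    def test_vanishing_variance_recovers_plain_binomial(self, high_info):
        frame, _ = high_info
        spec = ModelSpec(fixed_terms=[])
        prob = LaplaceBinomialGLMM(spec, frame)
        beta = np.array([special.logit(0.014)])
        plain = prob.plain_loglik(beta)
        tiny = prob.loglik(beta, np.array([np.log(1e-8)]))
        assert tiny == pytest.approx(plain, abs=1e-5)

    def test_agrees_with_quadrature_oracle(self, high_info):
        frame, spec = high_info
        prob = LaplaceBinomialGLMM(spec, frame)
        beta = np.array([special.logit(0.014), 0.01, 0.02, 0.04])
        theta = np.array([np.log(0.3)])
        assert prob.loglik(beta, theta) == pytest.approx(
            prob.agq_loglik(beta, theta), abs=1e-4
        )

    def test_zero_coefficient_covariate_leaves_value_unchanged(self, high_info):
        frame, _ = high_info
        small = ModelSpec(fixed_terms=["positive"])
        big = ModelSpec(fixed_terms=["positive", "length"])
        beta_small = np.array([-4.2, 0.01])
        beta_big = np.array([-4.2, 0.01, 0.0])
        theta = np.array([np.log(0.3)])
        ll_small = LaplaceBinomialGLMM(small, frame).loglik(beta_small, theta)
        ll_big = LaplaceBinomialGLMM(big, frame).loglik(beta_big, theta)
        assert ll_big == pytest.approx(ll_small, abs=1e-9)


class TestFitGlmm:
    def test_pooling_limit_intercept_only(self):
        # homogeneous experiments: no between-experiment heterogeneity, so
        # the intercept approaches the pooled logit and the variance ~ 0
        rng = np.random.default_rng(3)
        rows = []
        for i in range(40):
            for j in range(3):
                n = 5000
                rows.append(
                    {"experiment_id": f"e{i}", "impressions": n,
                     "clicks": rng.binomial(n, 0.014)}
                )
        frame = pd.DataFrame(rows)
        fit = fit_glmm(ModelSpec(fixed_terms=[]), frame)
        pooled = special.logit(frame["clicks"].sum() / frame["impressions"].sum())
        assert fit.coef("(Intercept)") == pytest.approx(pooled, abs=5e-3)
        # variance shrinks to the sampling-noise floor of 40 groups
        assert fit.cov_re[0, 0] < 5e-3

    def test_zero_variance_fit_matches_logistic_ml_oracle(self, high_info):
        frame, spec = high_info
        fit = fit_glmm(spec, frame, fix_variance_zero=True)
        X = np.column_stack(
            [np.ones(len(frame))] + [frame[v] for v in spec.fixed_terms]
        )
        endog = np.column_stack([frame["clicks"], frame["impressions"] - frame["clicks"]])
        oracle = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
        assert np.max(np.abs(fit.coefficients - oracle.params)) < 1e-4
        assert fit.loglik == pytest.approx(oracle.llf, abs=1e-6)

    def test_laplace_fit_matches_quadrature_fit(self, high_info):
        frame, spec = high_info
        f_lap = fit_glmm(spec, frame, method="laplace")
        f_agq = fit_glmm(spec, frame, method="agq")
        assert np.max(np.abs(f_lap.coefficients - f_agq.coefficients)) < 1e-3
        assert abs(f_lap.loglik - f_agq.loglik) < 1e-4

    def test_recovers_truth_on_seeded_archive(self):
        frame, _, truth = synth_frame(99, 400, variables=VARS)
        fit = fit_glmm(ModelSpec(fixed_terms=VARS), frame)
        assert fit.converged
        truth_map = {"(Intercept)": truth.intercept, **truth.coefficients}
        for i, term in enumerate(fit.terms):
            assert abs(fit.coefficients[i] - truth_map[term]) < 4 * fit.se[i]
        sd_hat = np.sqrt(fit.cov_re[0, 0])
        assert 0.2 < sd_hat < 0.4  # truth: 0.3

    def test_loglik_at_optimum_beats_start_and_perturbations(self, high_info):
        frame, spec = high_info
        fit = fit_glmm(spec, frame)
        prob = LaplaceBinomialGLMM(spec, frame)
        theta_hat = np.array([0.5 * np.log(fit.cov_re[0, 0])])
        ll_hat = prob.loglik(fit.coefficients, theta_hat)
        rng = np.random.default_rng(0)
        for _ in range(5):
            assert ll_hat >= prob.loglik(
                fit.coefficients + rng.normal(0, 0.01, len(fit.coefficients)), theta_hat
            )

    def test_sign_symmetry(self):
        frame, _, _ = synth_frame(21, 120)
        spec = ModelSpec(fixed_terms=["positive", "negative", "length"])
        flipped = frame.copy()
        flipped["negative"] = -flipped["negative"]
        f1 = fit_glmm(spec, frame)
        f2 = fit_glmm(spec, flipped)
        i = f1.terms.index("negative")
        assert f1.coefficients[i] == pytest.approx(-f2.coefficients[i], abs=1e-5)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-6)

    def test_affine_invariance_of_likelihood(self):
        # mapping the optimum of the standardized fit back to the raw scale
        # must reproduce the raw-data likelihood exactly
        config = GeneratorConfig(seed=21, n_experiments=120)
        archive, truth = generate_archive(config)
        raw = build_feature_table(archive, truth.lexicon).frame
        spec = ModelSpec(fixed_terms=VARS)
        std_frame, std = standardize_features(raw, VARS)
        fit = fit_glmm(spec, std_frame)
        beta = fit.coefficients.copy()
        mapped = beta.copy()
        for k, v in enumerate(VARS, start=1):
            mapped[k] = beta[k] / std.sds[v]
            mapped[0] -= beta[k] * std.means[v] / std.sds[v]
        theta = np.array([0.5 * np.log(fit.cov_re[0, 0])])
        ll_std = LaplaceBinomialGLMM(spec, std_frame).loglik(beta, theta)
        ll_raw = LaplaceBinomialGLMM(spec, raw).loglik(mapped, theta)
        assert ll_raw == pytest.approx(ll_std, abs=1e-8)
        # and the independently fitted raw model lands on the same optimum
        fit_raw = fit_glmm(spec, raw)
        assert np.max(np.abs(fit_raw.coefficients - mapped)) < 1e-3
        assert fit_raw.loglik == pytest.approx(fit.loglik, abs=1e-4)

    def test_varying_slopes_covariance_is_psd_and_recovers(self):
        config = GeneratorConfig(
            seed=31, n_experiments=250, slope_sds={"negative": 0.08, "positive": 0.08}
        )
        archive, truth = generate_archive(config)
        frame = build_feature_table(archive, truth.lexicon).frame
        std_frame, _ = standardize_features(frame, VARS)
        spec = ModelSpec(fixed_terms=VARS, random_slopes=["positive", "negative"])
        fit = fit_glmm(spec, std_frame)
        eigs = np.linalg.eigvalsh(fit.cov_re)
        assert np.all(eigs >= -1e-12)
        assert fit.cov_re.shape == (3, 3)
        assert 0.15 < np.sqrt(fit.cov_re[0, 0]) < 0.45  # intercept SD, truth 0.3

    def test_rank_deficiency_names_collinear_terms(self):
        frame, _, _ = synth_frame(5, 40)
        frame["copy"] = frame["positive"]
        with pytest.raises(RankDeficiencyError, match="copy"):
            fit_glmm(ModelSpec(fixed_terms=["positive", "copy"]), frame)

    def test_random_slope_must_be_fixed_term(self):
        with pytest.raises(ValueError):
            ModelSpec(fixed_terms=["positive"], random_slopes=["negative"])


class TestWaldInference:
    def _dummy_fit(self, est, se):
        frame, _, _ = synth_frame(5, 40)
        fit = fit_glmm(ModelSpec(fixed_terms=[]), frame)
        fit.terms = ["x"]
        fit.coefficients = np.array([est])
        fit.se = np.array([se])
        return fit

    def test_ci_closed_form(self):
        fit = self._dummy_fit(0.01, 0.005)
        tbl = wald_inference(fit, level=0.99)
        crit = stats.norm.ppf(0.995)
        assert tbl["ci_low"][0] == pytest.approx(0.01 - crit * 0.005)
        assert tbl["ci_high"][0] == pytest.approx(0.01 + crit * 0.005)

    def test_z_two_p_value(self):
        fit = self._dummy_fit(0.02, 0.01)  # z = 2
        tbl = wald_inference(fit)
        assert tbl["z"][0] == pytest.approx(2.0)
        assert tbl["p"][0] == pytest.approx(0.0455, abs=2e-4)

    def test_ci_widens_monotonically_with_level(self):
        fit = self._dummy_fit(0.01, 0.005)
        widths = [
            wald_inference(fit, level=lev)["ci_high"][0]
            - wald_inference(fit, level=lev)["ci_low"][0]
            for lev in (0.8, 0.9, 0.95, 0.99)
        ]
        assert all(a < b for a, b in zip(widths, widths[1:]))

    def test_invalid_se_marks_inference_unavailable(self):
        fit = self._dummy_fit(0.01, 0.0)
        tbl = wald_inference(fit)
        assert np.isnan(tbl["z"][0]) and np.isnan(tbl["p"][0])


class TestEffectTranslation:
    @pytest.mark.parametrize(
        "beta,expected",
        [(0.0, 0.0), (np.log(2), 100.0), (0.015, 100 * (np.exp(0.015) - 1))],
    )
    def test_odds_percent_change(self, beta, expected):
        assert odds_percent_change(beta) == pytest.approx(expected)

    def test_per_word_effect_identity_case(self):
        # when one word shifts the proportion by exactly one SD, the
        # per-word effect equals the per-SD odds change
        assert per_word_effect(0.02, sd_raw=1 / 15, mean_length=15) == pytest.approx(
            odds_percent_change(0.02)
        )
        assert per_word_effect(0.0, 0.05, 15.0) == 0.0
        with pytest.raises(ValueError):
            per_word_effect(0.01, 0.0, 15.0)

    def test_per_word_effect_refit_oracle(self):
        # refitting with the raw (unstandardized) negative proportion and
        # evaluating a 1/mean_length covariate change must reproduce the
        # translated per-word effect
        config = GeneratorConfig(seed=77, n_experiments=250)
        archive, truth = generate_archive(config)
        raw = build_feature_table(archive, truth.lexicon).frame
        std_frame, std = standardize_features(raw, VARS)
        spec = ModelSpec(fixed_terms=VARS)
        fit_std = fit_glmm(spec, std_frame)
        mean_length = float(raw["length"].mean())
        translated = per_word_effect(
            fit_std.coef("negative"), std.sds["negative"], mean_length
        )
        semi = raw.copy()
        others = [v for v in VARS if v != "negative"]
        semi, _ = standardize_features(semi, others)
        fit_raw = fit_glmm(spec, semi)
        direct = odds_percent_change(fit_raw.coef("negative") / mean_length)
        assert translated == pytest.approx(direct, rel=5e-3)


class TestConcordance:
    def test_identical_fits_fully_concordant(self):
        frame, _, _ = synth_frame(13, 150, variables=VARS)
        fit = fit_glmm(ModelSpec(fixed_terms=VARS), frame)
        report = model_concordance(fit, fit, ["positive", "negative"])
        assert report["all_concordant"] == all(
            fit.p_of(t) < 0.01 for t in ("positive", "negative")
        )

    def test_opposite_signs_flag_discordance_with_precedence_note(self):
        frame, _, _ = synth_frame(13, 150, variables=VARS)
        fit_a = fit_glmm(ModelSpec(fixed_terms=VARS), frame)
        import copy

        fit_b = copy.deepcopy(fit_a)
        fit_b.coefficients = fit_b.coefficients.copy()
        fit_b.coefficients[fit_b.terms.index("negative")] *= -1
        report = model_concordance(fit_a, fit_b, ["negative"])
        assert not report["terms"]["negative"]["concordant"]
        assert "precedence" in report["note"]

    def test_missing_term_errors(self):
        frame, _, _ = synth_frame(13, 60)
        fit = fit_glmm(ModelSpec(fixed_terms=["positive"]), frame)
        with pytest.raises(KeyError):
            model_concordance(fit, fit, ["absent"])
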