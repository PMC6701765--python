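import math

import numpy as np
import pytest

from qfpcr.glmm import (
    GlmmError,
    GlmmFit,
    GlmmSpec,
    agq_loglik,
    bootstrap_ci,
    compare_models,
    fit_glmm,
    information_criteria,
    logit_to_probability,
    predict_logit,
    standard_specs,
)
from qfpcr.tables import DiallelicObservation


def make_glmm_data(seed, n=200, n_markers=4, beta=(-1.0, 1.4, -0.05), sigma=0.7):
    """Observations with a binary label drawn from a known mixed model."""
    rng = np.random.default_rng(seed)
    u = rng.normal(0.0, sigma, n_markers)
    obs = []
    for i in range(n):
        j = int(rng.integers(n_markers))
        hr = float(rng.uniform(0.5, 2.5))
        sd = float(rng.uniform(0.0, 40.0))
        eta = beta[0] + beta[1] * hr + beta[2] * sd + u[j]
        y = rng.random() < 1.0 / (1.0 + math.exp(-eta))
        obs.append(
            DiallelicObservation(
                sample_id=str(i),
                marker=f"M{j}",
                height_ratio=hr,
                size_difference=sd,
                label="trisomic_2_1" if y else "normal_1_1",
            )
        )
    return obs


def table1_style_fit(beta):
    """A GlmmFit shell holding given coefficients (for prediction tests)."""
    terms = ("intercept", "height_ratio", "size_difference")
    return GlmmFit(
        spec=GlmmSpec(terms),
        beta=dict(zip(terms, beta)),
        sigma_b=1.0,
        conditional_modes={"D13S258": 0.5},
        logLik=0.0, deviance_resid=0.0, aic=0.0, bic=0.0,
        df_residual=0, n_obs=0, converged=True, separation_flag=True,
    )


class TestFitBasics:
    def test_glm_reduction_intercept_only(self):
        """sigma_b fixed at 0, intercept-only: closed-form Bernoulli logLik."""
        obs = make_glmm_data(3, n=120)
        y = np.array([o.label.startswith("trisomic") for o in obs], float)
        fit = fit_glmm(obs, GlmmSpec(("intercept",)), sigma_b=0.0)
        p = y.mean()
        closed = len(y) * (p * math.log(p) + (1 - p) * math.log(1 - p))
        assert fit.logLik == pytest.approx(closed, abs=1e-6)
        assert fit.beta["intercept"] == pytest.approx(math.log(p / (1 - p)), abs=1e-5)

    def test_information_criteria_identities(self):
        obs = make_glmm_data(4, n=150)
        for spec in standard_specs():
            fit = fit_glmm(obs, spec)
            k = fit.spec.n_fixed + 1
            assert fit.aic == pytest.approx(2 * k - 2 * fit.logLik, abs=1e-12)
            assert fit.bic == pytest.approx(
                k * math.log(fit.n_obs) - 2 * fit.logLik, abs=1e-12
            )
            assert fit.df_residual == fit.n_obs - k
            assert fit.logLik <= 0.0
            assert fit.sigma_b >= 0.0

    def test_single_class_rejected(self):
        obs = make_glmm_data(5, n=50)
        with pytest.raises(GlmmError, match="classes"):
            fit_glmm(obs, response=np.zeros(len(obs)))

    def test_single_level_grouping_rejected(self):
        obs = [
            DiallelicObservation(str(i), "M0", 1.0 + 0.01 * i, float(i),
                                 "trisomic_2_1" if i % 2 else "normal_1_1")
            for i in range(20)
        ]
        with pytest.raises(GlmmError, match="levels"):
            fit_glmm(obs)

    def test_separation_flagged_on_separated_data(self):
        rng = np.random.default_rng(8)
        obs = []
        for i in range(300):
            tri = i % 20 == 0
            obs.append(
                DiallelicObservation(
                    str(i), f"M{rng.integers(3)}",
                    height_ratio=2.0 + 0.1 * rng.random() if tri
                    else 1.0 + 0.1 * rng.random(),
                    size_difference=float(rng.uniform(0, 10)),
                    label="trisomic_2_1" if tri else "normal_1_1",
                )
            )
        fit = fit_glmm(obs)
        assert fit.separation_flag
        # fitted probabilities remain usable despite huge coefficients
        p = [logit_to_probability(predict_logit(fit, o)) for o in obs]
        tri_p = [x for o, x in zip(obs, p) if o.label == "trisomic_2_1"]
        norm_p = [x for o, x in zip(obs, p) if o.label == "normal_1_1"]
        assert min(tri_p) > max(norm_p)


class TestAgainstQuadratureOracle:
    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_laplace_close_to_agq(self, seed):
        obs = make_glmm_data(seed, n=150, n_markers=4)
        fit = fit_glmm(obs)
        ll_agq = agq_loglik(
            obs, fit.spec, [fit.beta[t] for t in fit.spec.fixed_terms],
            fit.sigma_b, order=50,
        )
        assert abs(fit.logLik - ll_agq) < 0.05

    def test_agq_exact_at_sigma_zero(self):
        obs = make_glmm_data(14, n=80)
        fit = fit_glmm(obs, GlmmSpec(("intercept",)), sigma_b=0.0)
        ll = agq_loglik(obs, fit.spec, [fit.beta["intercept"]], 0.0)
        assert ll == pytest.approx(fit.logLik, abs=1e-8)


class TestPrediction:
    def test_logit_arithmetic_2_1_coefficients(self):
        fit = table1_style_fit((-369.66, 221.46, -6.78))
        obs = DiallelicObservation("s", "MX", 1.0, 0.0)
        assert predict_logit(fit, obs, use_marker_effect=False) == pytest.approx(
            -148.20, abs=1e-9
        )

    def test_logit_arithmetic_1_2_coefficients(self):
        fit = table1_style_fit((326.14, -427.74, 0.44))
        obs = DiallelicObservation("s", "MX", 1.0, 0.0)
        assert predict_logit(fit, obs, use_marker_effect=False) == pytest.approx(
            -101.60, abs=1e-9
        )

    def test_zero_beta_gives_zero_logit(self):
        fit = table1_style_fit((0.0, 0.0, 0.0))
        obs = DiallelicObservation("s", "MX", 1.7, 23.0)
        assert predict_logit(fit, obs, use_marker_effect=False) == 0.0

    def test_marker_effect_added_and_unseen_warns(self):
        fit = table1_style_fit((1.0, 0.0, 0.0))
        seen = DiallelicObservation("s", "D13S258", 1.0, 0.0)
        assert predict_logit(fit, seen) == pytest.approx(1.5)
        unseen = DiallelicObservation("s", "D99S999", 1.0, 0.0)
        with pytest.warns(UserWarning, match="unseen"):
            assert predict_logit(fit, unseen) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "logit,p",
        [(0.0, 0.5), (math.log(3), 0.75), (-148.20, 0.0), (900.0, 1.0)],
    )
    def test_logistic_transform(self, logit, p):
        assert logit_to_probability(logit) == pytest.approx(p, abs=1e-12)


class TestInvariances:
    def test_order_and_relabeling_invariance(self):
        obs = make_glmm_data(21, n=150)
        fit = fit_glmm(obs)
        rng = np.random.default_rng(0)
        perm = list(obs)
        rng.shuffle(perm)
        fit_perm = fit_glmm(perm)
        assert fit_perm.logLik == pytest.approx(fit.logLik, abs=1e-6)
        renamed = [
            DiallelicObservation(o.sample_id, "Z" + o.marker, o.height_ratio,
                                 o.size_difference, o.label)
            for o in obs
        ]
        fit_ren = fit_glmm(renamed)
        assert fit_ren.logLik == pytest.approx(fit.logLik, abs=1e-6)
        for m, v in fit.conditional_modes.items():
            assert fit_ren.conditional_modes["Z" + m] == pytest.approx(v, abs=1e-4)

    def test_adding_fixed_effect_never_hurts_loglik(self):
        obs = make_glmm_data(22, n=250)
        ll_m = fit_glmm(obs, GlmmSpec(("intercept",))).logLik
        ll_hr = fit_glmm(obs, GlmmSpec(("intercept", "height_ratio"))).logLik
        ll_full = fit_glmm(obs, GlmmSpec()).logLik
        assert ll_hr >= ll_m - 1e-4
        assert ll_full >= ll_hr - 1e-4


class TestBootstrap:
    def test_seed_reproducibility_and_coverage_shape(self):
        obs = make_glmm_data(31, n=150, n_markers=3)
        fit = fit_glmm(obs)
        with pytest.warns(UserWarning, match="unstable"):
            ci1 = bootstrap_ci(fit, obs, n_boot=60, seed=5)
            ci2 = bootstrap_ci(fit, obs, n_boot=60, seed=5)
        assert ci1 == ci2
        for lo, hi in ci1.values():
            assert lo <= hi

    def test_zero_boot_rejected(self):
        obs = make_glmm_data(32, n=80)
        fit = fit_glmm(obs)
        with pytest.raises(GlmmError):
            bootstrap_ci(fit, obs, n_boot=0, seed=1)
        with pytest.raises(GlmmError, match="seed"):
            bootstrap_ci(fit, obs, n_boot=100, seed=None)


class TestCompareModels:
    def test_four_rows_and_aic_identity(self):
        obs = make_glmm_data(41, n=200)
        table = compare_models(obs)
        assert len(table) == 4
        assert list(table["model"]) == [
            "height_ratio+size_difference", "height_ratio",
            "size_difference", "marker_only",
        ]
        # AIC difference between two rows is exactly 2*dk - 2*dlogLik
        r_no_hr = table[table.model == "size_difference"].iloc[0]
        r_marker = table[table.model == "marker_only"].iloc[0]
        d_aic = r_no_hr.AIC - r_marker.AIC
        assert d_aic == pytest.approx(
            2 * 1 - 2 * (r_no_hr.logLik - r_marker.logLik), abs=1e-10
        )
        assert (table["logLik"] <= 0).all()

    def test_printed_identity_example(self):
        """k=2 and logLik -285.84 at n=9063 give the printed AIC/BIC."""
        aic, bic, df = information_criteria(-285.8434, 1, 9063)
        assert aic == pytest.approx(575.69, abs=0.01)
        assert bic == pytest.approx(589.91, abs=0.01)
        assert df == 9061

    def test_deviance_is_not_minus_two_loglik(self):
        """The comparison table's deviance column is the conditional sum of
        squared deviance residuals, which exceeds -2*logLik by the
        random-effect penalty and normalisation."""
        obs = make_glmm_data(42, n=200)
        fit = fit_glmm(obs)
        assert fit.deviance_resid < -2 * fit.logLik
        assert fit.deviance_resid > 0
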