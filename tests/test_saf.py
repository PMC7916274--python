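"""Two-part prediction, the never-smoker replay, and attributable fractions."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from same_econ import measurement as ms
from same_econ import models, saf
from same_econ.exceptions import SchemaError


def make_fit(model, coefficients, sigma_alpha=0.0, sigma_u=None, smearing=1.0):
    return models.REFit(
        model=model,
        coefficients=dict(coefficients),
        std_errors={k: 0.0 for k in coefficients},
        sigma_alpha=sigma_alpha,
        sigma_u=sigma_u,
        log_likelihood=-1.0 if model == "re_logit" else None,
        n_obs=10,
        n_individuals=5,
        converged=True,
        iterations=1,
        smearing_factor=smearing if model == "re_gls" else None,
        design_columns=tuple(coefficients),
    )


def design_frame(rows, columns):
    return pd.DataFrame(rows, columns=list(columns))


class TestPredictTwoPart:
    def test_null_model_gives_half_times_one(self):
        cols = ("const", "x")
        use_fit = make_fit("re_logit", {"const": 0.0, "x": 0.0})
        cost_fit = make_fit("re_gls", {"const": 0.0, "x": 0.0}, sigma_u=0.0)
        rows = design_frame([[1.0, 0.3], [1.0, -2.0]], cols)
        pred = saf.predict_two_part(use_fit, cost_fit, rows)
        assert np.allclose(pred["p_use"], 0.5)
        assert np.allclose(pred["cond_cost"], 1.0)
        assert np.allclose(pred["expected_cost"], 0.5)

    def test_one_row_closed_form_zero_intercept_normal_theory(self):
        cols = ("const", "x")
        gamma = {"const": 0.4, "x": -0.9}
        beta = {"const": 1.5, "x": 0.3}
        use_fit = make_fit("re_logit", gamma, sigma_alpha=0.7)
        cost_fit = make_fit("re_gls", beta, sigma_alpha=0.5, sigma_u=1.1)
        rows = design_frame([[1.0, 2.0]], cols)
        pred = saf.predict_two_part(
            use_fit, cost_fit, rows,
            retransform="normal_theory", integration="zero_intercept",
        )
        eta_u = 0.4 - 0.9 * 2.0
        eta_c = 1.5 + 0.3 * 2.0
        expected = expit(eta_u) * np.exp(eta_c + 0.5 * (0.5**2 + 1.1**2))
        assert pred["expected_cost"].iloc[0] == pytest.approx(expected, rel=1e-12)
        assert pred["expected_cost"].iloc[0] == pytest.approx(
            pred["p_use"].iloc[0] * pred["cond_cost"].iloc[0], rel=1e-15
        )

    def test_population_average_probability_matches_dense_integral(self):
        eta = np.array([-2.0, -0.3, 0.0, 1.2, 4.0])
        sigma = 0.9
        p = saf.population_average_probability(eta, sigma)
        a = np.linspace(-8 * sigma, 8 * sigma, 40001)
        phi = np.exp(-0.5 * (a / sigma) ** 2) / (np.sqrt(2 * np.pi) * sigma)
        dense = np.trapezoid(expit(eta[:, None] + a[None, :]) * phi, a, axis=1)
        np.testing.assert_allclose(p, dense, atol=1e-10)

    def test_population_average_lies_within_nodewise_bounds(self):
        """Averaging over the intercept cannot leave the node-value range."""
        eta = np.linspace(-3, 3, 11)
        sigma = 1.3
        p = saf.population_average_probability(eta, sigma)
        lo, hi = expit(eta - 8 * sigma), expit(eta + 8 * sigma)
        assert np.all(p >= lo) and np.all(p <= hi)
        # averaging shrinks extreme probabilities toward 1/2
        assert p[0] > expit(eta[0]) and p[-1] < expit(eta[-1])

    def test_design_mismatch_rejected(self):
        use_fit = make_fit("re_logit", {"const": 0.0})
        cost_fit = make_fit("re_gls", {"const": 0.0}, sigma_u=1.0)
        rows = design_frame([[1.0, 1.0]], ("const", "extra"))
        with pytest.raises(SchemaError):
            saf.predict_two_part(use_fit, cost_fit, rows)


class TestCounterfactual:
    def _cov(self, smoking, age_group):
        return pd.DataFrame(
            dict(
                smoking_status=pd.Categorical([smoking], categories=ms.SMOKING_LEVELS),
                age_group=pd.Categorical([age_group], categories=ms.AGE_GROUPS),
                sex=["male"], residency=["urban"], education=["middle_or_above"],
                marital=["partnered"], poverty=[True], insurance=["yes"],
                region=["east"],
                bmi_class=pd.Categorical(["overweight"], categories=ms.BMI_CLASSES),
                drinker=[True],
            )
        )

    def test_never_smoker_row_is_fixed_point(self):
        X = ms.build_design_matrix(self._cov("never", "65_plus"))
        assert saf.make_counterfactual(X).equals(X)

    def test_heavy_smoker_row_keeps_age_dummies(self):
        X = ms.build_design_matrix(self._cov("current_heavy", "65_plus"))
        assert X["it4"].iloc[0] == 1.0
        cf = saf.make_counterfactual(X)
        assert cf[list(ms.SMOKING_DESIGN_COLUMNS)].to_numpy().sum() == 0.0
        assert cf["age_65_plus"].iloc[0] == 1.0
        assert cf["male"].iloc[0] == 1.0

    def test_idempotent(self, default_design):
        _, design = default_design
        once = saf.make_counterfactual(design)
        twice = saf.make_counterfactual(once)
        assert once.equals(twice)


def two_service_predictions(factor=1.0):
    """Small aligned factual/hypothetical tables for ratio arithmetic."""
    factual = pd.DataFrame(
        {
            "service": ["outpatient"] * 2 + ["inpatient"] * 2,
            "expected_cost": np.array([60.0, 40.0, 30.0, 20.0]) * factor,
        }
    )
    hypothetical = pd.DataFrame(
        {
            "service": ["outpatient"] * 2 + ["inpatient"] * 2,
            "expected_cost": np.array([54.0, 36.0, 30.0, 10.0]) * factor,
        }
    )
    return factual, hypothetical


class TestComputeSAF:
    def test_ratio_arithmetic(self):
        factual, hypothetical = two_service_predictions()
        out = saf.compute_saf(factual, hypothetical)
        by = out.set_index("service")
        assert by.loc["outpatient", "saf"] == pytest.approx(0.10)
        assert by.loc["inpatient", "saf"] == pytest.approx(0.20)
        # pooled overall: (150 - 130) / 150
        assert by.loc["overall", "saf"] == pytest.approx(20.0 / 150.0)

    def test_equal_scenarios_give_zero(self):
        factual, _ = two_service_predictions()
        out = saf.compute_saf(factual, factual.copy())
        assert np.allclose(out["saf"], 0.0)

    def test_invariant_to_constant_retransformation_factor(self):
        """A common multiplicative factor on predictions cancels in the ratio."""
        f1, h1 = two_service_predictions(factor=1.0)
        f2, h2 = two_service_predictions(factor=3.7)
        out1 = saf.compute_saf(f1, h1)
        out2 = saf.compute_saf(f2, h2)
        np.testing.assert_allclose(out1["saf"], out2["saf"], rtol=1e-14)

    def test_overall_saf_between_service_extremes(self):
        factual, hypothetical = two_service_predictions()
        out = saf.compute_saf(factual, hypothetical).set_index("service")
        services = out.drop(index="overall")["saf"]
        assert services.min() <= out.loc["overall", "saf"] <= services.max()

    def test_strata_split_totals(self):
        factual, hypothetical = two_service_predictions()
        strata = pd.DataFrame({"sex": ["male", "female", "male", "female"]})
        out = saf.compute_saf(factual, hypothetical, strata)
        male_out = out[
            (out["stratum"] == "male") & (out["service"] == "outpatient")
        ]
        assert male_out["factual_total"].iloc[0] == pytest.approx(60.0)
        assert male_out["saf"].iloc[0] == pytest.approx(0.10)

    def test_misaligned_tables_rejected(self):
        factual, hypothetical = two_service_predictions()
        with pytest.raises(SchemaError):
            saf.compute_saf(factual, hypothetical.iloc[:3])

    def test_zero_factual_total_signals(self):
        factual, hypothetical = two_service_predictions()
        factual = factual.copy()
        factual["expected_cost"] = 0.0
        with pytest.raises(ZeroDivisionError):
            saf.compute_saf(factual, hypothetical)


class TestStructuralSAFProperties:
    def test_saf_zero_when_smoking_coefficients_zero(self, default_design,
                                                     outpatient_fits):
        """Zeroed smoking effects make factual and hypothetical identical."""
        _, design = default_design
        use_fit, cost_fit = outpatient_fits
        use0 = make_fit(
            "re_logit",
            {c: (0.0 if c in ms.SMOKING_DESIGN_COLUMNS else v)
             for c, v in use_fit.coefficients.items()},
            sigma_alpha=use_fit.sigma_alpha,
        )
        cost0 = make_fit(
            "re_gls",
            {c: (0.0 if c in ms.SMOKING_DESIGN_COLUMNS else v)
             for c, v in cost_fit.coefficients.items()},
            sigma_alpha=cost_fit.sigma_alpha,
            sigma_u=cost_fit.sigma_u,
            smearing=cost_fit.smearing_factor,
        )
        fact = saf.predict_two_part(use0, cost0, design)
        hyp = saf.predict_two_part(use0, cost0, saf.make_counterfactual(design))
        fact["service"] = "outpatient"
        hyp["service"] = "outpatient"
        out = saf.compute_saf(fact, hyp)
        assert np.allclose(out["saf"], 0.0, atol=1e-14)

    def test_saf_monotone_in_cost_smoking_coefficient(self, default_design,
                                                      outpatient_fits):
        _, design = default_design
        use_fit, cost_fit = outpatient_fits
        safs = []
        for bump in (0.0, 0.5, 1.0):
            coef = dict(cost_fit.coefficients)
            coef["smk_current_heavy"] = coef["smk_current_heavy"] + bump
            cost_b = make_fit(
                "re_gls", coef, sigma_alpha=cost_fit.sigma_alpha,
                sigma_u=cost_fit.sigma_u, smearing=cost_fit.smearing_factor,
            )
            fact = saf.predict_two_part(use_fit, cost_b, design)
            hyp = saf.predict_two_part(
                use_fit, cost_b, saf.make_counterfactual(design)
            )
            fact["service"] = "outpatient"
            hyp["service"] = "outpatient"
            safs.append(saf.compute_saf(fact, hyp)["saf"].iloc[0])
        assert safs[0] < safs[1] < safs[2]

    def test_smearing_equals_normal_theory_when_sigmas_forced(self, default_design,
                                                              outpatient_fits):
        """With the factors forced equal the two retransforms agree exactly."""
        _, design = default_design
        use_fit, cost_fit = outpatient_fits
        forced = make_fit(
            "re_gls", cost_fit.coefficients, sigma_alpha=cost_fit.sigma_alpha,
            sigma_u=cost_fit.sigma_u,
            smearing=float(
                np.exp(0.5 * (cost_fit.sigma_alpha**2 + cost_fit.sigma_u**2))
            ),
        )
        p1 = saf.predict_two_part(use_fit, forced, design, retransform="smearing")
        p2 = saf.predict_two_part(use_fit, forced, design, retransform="normal_theory")
        np.testing.assert_allclose(p1["expected_cost"], p2["expected_cost"], rtol=1e-12)
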