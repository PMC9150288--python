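import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from preconrisk import (
    Cohort,
    MissingnessModels,
    complete_case_weights,
    fit_missingness,
    impute_conception_time,
    rubin_pool,
    sequential_impute,
)
from preconrisk._utils import FitError
from preconrisk.conception import ConceptionModel
from preconrisk.missing import conditional_conception_masses
from preconrisk.simulate import default_cohort_params, simulate_cohort


def _intercept_only(p):
    return pd.Series({"intercept": logit(p)})


def _manual_models(p1, p2, psel=0.9):
    return MissingnessModels(
        form="product",
        stage1=_intercept_only(p1),
        stage2=_intercept_only(p2),
        selection=_intercept_only(psel),
    )


def _one_row(conceived=1):
    return pd.DataFrame({"id": [0], "conceived": [conceived]})


def test_verification_prob_is_product_of_stage_probabilities():
    models = _manual_models(0.8, 0.5)
    assert models.verification_prob(_one_row())[0] == pytest.approx(0.4)


def test_verification_prob_second_factor_vacuous_without_conception():
    models = _manual_models(0.8, 0.5)
    assert models.verification_prob(_one_row(conceived=0))[0] == pytest.approx(0.8)


def test_verification_prob_unity_at_certain_observation():
    models = _manual_models(1 - 1e-12, 1 - 1e-12)
    assert models.verification_prob(_one_row())[0] == pytest.approx(1.0, abs=1e-9)


def test_complete_case_weight_arithmetic(four_pattern_cohort):
    """Factors (0.5, 0.8, 0.5) give 1/pi_C = 5 for the complete case."""
    models = _manual_models(p1=0.5, p2=0.5, psel=0.8)
    w = complete_case_weights(models, four_pattern_cohort, truncate=None)
    assert list(w.index) == [4]  # the single known-result pregnancy
    assert w.iloc[0] == pytest.approx(5.0)


def test_complete_case_weights_require_product_form(four_pattern_cohort):
    models = MissingnessModels(form="single", single=_intercept_only(0.9))
    with pytest.raises(FitError, match="product"):
        complete_case_weights(models, four_pattern_cohort)


def test_fit_missingness_rejects_constant_r1(complete_default_cohort):
    df = complete_default_cohort.df.copy()
    df.loc[df["r1"] == 0, ["r1", "conceived", "U", "r2"]] = [1, 0, 6, 1]
    cohort = Cohort(df, 6, complete_default_cohort.schema, validate=False)
    with pytest.raises(FitError, match="no missingness variation in R1"):
        fit_missingness(cohort, form="product")


def test_fit_missingness_stage2_recovery_and_null_slopes():
    """The stage-2 observation model is generatively logistic in z', so its
    coefficients are recovered; with missingness independent of covariates
    the fitted slopes are ~0 (cross-checked against statsmodels SEs)."""
    import statsmodels.api as sm

    params = default_cohort_params(
        n=20_000,
        covariate_missing_rates={},
        stage2_obs_logit={"intercept": 1.5, "college": 0.8, "smoker": -0.9},
    )
    cohort = simulate_cohort(params, seed=31)
    models = fit_missingness(cohort, form="product")
    conc = cohort.df[(cohort.df.r1 == 1) & (cohort.df.conceived == 1)]
    X = sm.add_constant(conc[["college", "smoker"]].to_numpy())
    res = sm.GLM(conc["r2"].to_numpy(), X, family=sm.families.Binomial()).fit()
    np.testing.assert_allclose(models.stage2.to_numpy(), np.asarray(res.params), atol=1e-6)
    truth = [1.5, 0.8, -0.9]
    for est, tr, se in zip(models.stage2, truth, np.asarray(res.bse)):
        assert abs(est - tr) < 3 * se

    # null case: R varies but independently of covariates (slopes set to 0
    # while keeping the x'/z' roles declared so the fit estimates them)
    null = default_cohort_params(
        n=20_000,
        covariate_missing_rates={},
        censor_logit={"intercept": -3.0, "college": 0.0, "smoker": 0.0},
        stage2_obs_logit={"intercept": 2.0, "college": 0.0, "smoker": 0.0},
    )
    cohort0 = simulate_cohort(null, seed=32)
    models0 = fit_missingness(cohort0, form="product")
    assert abs(models0.stage1["college"]) < 0.25
    assert abs(models0.stage1["smoker"]) < 0.35
    assert abs(models0.stage2["college"]) < 0.35
    assert abs(models0.stage2["smoker"]) < 0.55


def _hazard_model(logits):
    return ConceptionModel(np.asarray(logits, dtype=float), pd.Series({"a": 0.0}), len(logits))


def test_conditional_masses_point_mass_at_no_conception():
    m = _hazard_model([-100.0] * 6)  # hazard ~0 everywhere
    masses = conditional_conception_masses(m, [0.0], u=2)
    assert masses[-1] == pytest.approx(1.0)


def test_conditional_masses_point_mass_next_cycle():
    m = _hazard_model([100.0] * 6)  # hazard ~1 at u+1
    masses = conditional_conception_masses(m, [0.0], u=2)
    assert masses[0] == pytest.approx(1.0)


def test_imputed_times_match_analytic_conditional_distribution(simple_schema):
    """Empirical frequencies of imputed conception cycles track the analytic
    conditional masses within 3-sigma multinomial bands."""
    n = 30_000
    u = 2
    df = pd.DataFrame(
        {
            "id": np.arange(n), "U": u, "conceived": 0, "r1": 0,
            "y2": np.nan, "r2": 0, "a": 0.7, "b": 1.0,
        }
    )
    cohort = Cohort(df, 6, simple_schema, validate=False)
    model = ConceptionModel(
        np.array([-1.0, -1.2, -1.4, -1.6, -1.8, -2.0]),
        pd.Series({"a": 0.3, "b": -0.2}),
        6,
    )
    draws = impute_conception_time(cohort, model, np.random.default_rng(17))
    masses = conditional_conception_masses(model, {"a": 0.7, "b": 1.0}, u)
    support = np.arange(u + 1, 8)
    for value, p in zip(support, masses):
        freq = np.mean(draws.to_numpy() == value)
        assert abs(freq - p) < 3 * np.sqrt(p * (1 - p) / n), f"cycle {value}"


def test_impute_rejects_censoring_at_tau(simple_schema):
    df = pd.DataFrame(
        {"id": [0], "U": [6], "conceived": [0], "r1": [0], "y2": [np.nan],
         "r2": [0], "a": [0.0], "b": [0.0]}
    )
    cohort = Cohort(df, 6, simple_schema, validate=False)
    with pytest.raises(ValueError, match="u>=tau"):
        impute_conception_time(cohort, _hazard_model([-1.0] * 6), np.random.default_rng(0))


def test_sequential_impute_identity_without_missingness(complete_default_cohort):
    df = complete_default_cohort.df.copy()
    keep = (df["r1"] == 1) & (df["r2"] == 1)
    full = Cohort(df.loc[keep].reset_index(drop=True), 6, complete_default_cohort.schema, validate=False)
    imputed = sequential_impute(full, M=3, seed=9)
    for c in imputed.cohorts:
        pd.testing.assert_frame_equal(c.df, full.df)


def test_sequential_impute_deterministic_under_seed(default_cohort):
    a = sequential_impute(default_cohort, M=2, seed=123)
    b = sequential_impute(default_cohort, M=2, seed=123)
    for ca, cb in zip(a.cohorts, b.cohorts):
        pd.testing.assert_frame_equal(ca.df, cb.df)
    c = sequential_impute(default_cohort, M=2, seed=124)
    assert not all(ca.df.equals(cc.df) for ca, cc in zip(a.cohorts, c.cohorts))


def test_sequential_impute_completes_everything(default_cohort):
    imputed = sequential_impute(default_cohort, M=2, seed=5)
    for c in imputed.cohorts:
        assert (c.df["r1"] == 1).all() and (c.df["r2"] == 1).all()
        assert not c.df[list(c.covariate_names)].isna().any().any()
        conc = c.df["conceived"] == 1
        assert c.df.loc[conc, "y2"].notna().all()
        assert (c.df.loc[~conc, "U"] == 6).all()
    # stage-1 view keeps observed follow-up but completed covariates
    s1 = imputed.stage1_cohort(0)
    pd.testing.assert_series_equal(s1.df["U"], default_cohort.df["U"])
    assert not s1.df[list(s1.covariate_names)].isna().any().any()


def test_rubin_pool_arithmetic():
    pooled = rubin_pool([pd.Series({"b": 1.0}), pd.Series({"b": 3.0})],
                        variances=[pd.Series({"b": 0.5}), pd.Series({"b": 1.5})])
    assert pooled.point["b"] == pytest.approx(2.0)
    assert pooled.between["b"] == pytest.approx(2.0)
    assert pooled.total["b"] == pytest.approx(1.0 + 1.5 * 2.0)


def test_rubin_pool_identical_estimates_and_permutation_invariance():
    ests = [pd.Series({"a": 0.4, "b": -1.0})] * 3
    pooled = rubin_pool(ests)
    assert pooled.between.max() == pytest.approx(0.0, abs=1e-30)
    pd.testing.assert_series_equal(pooled.point, ests[0])
    rng = np.random.default_rng(2)
    ests = [pd.Series({"a": rng.normal(), "b": rng.normal()}) for _ in range(5)]
    p1 = rubin_pool(ests)
    p2 = rubin_pool(ests[::-1])
    pd.testing.assert_series_equal(p1.point, p2.point)
    pd.testing.assert_series_equal(p1.between, p2.between)


def test_rubin_pool_rejects_nonconformable():
    with pytest.raises(ValueError, match="conformable"):
        rubin_pool([pd.Series({"a": 1.0}), pd.Series({"b": 1.0})])
    with pytest.raises(ValueError, match="at least M=2"):
        rubin_pool([pd.Series({"a": 1.0})])
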