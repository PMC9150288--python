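import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from preconrisk import Cohort, ConceptionModel, expand_person_period, fit_conception
from preconrisk._utils import FitError
from preconrisk.reference import PATIENTS, reference_conception_model
from preconrisk.simulate import default_cohort_params, simulate_cohort


def _model(g, coefs, tau=None):
    tau = tau or len(g)
    return ConceptionModel(np.asarray(g, dtype=float), pd.Series(coefs, dtype=float), tau)


def test_hazard_logit_identity():
    m = _model([0.0] * 6, {"a": 0.0})
    assert m.hazard({"a": 3.0}, 1) == pytest.approx(0.5)


def test_hazard_out_of_range():
    m = _model([0.0] * 6, {"a": 0.0})
    with pytest.raises(ValueError, match="outside"):
        m.hazard({"a": 0.0}, 7)


def test_hazard_published_patient_one_first_cycle():
    """expit(g_1 + gamma'x) at the published coefficients for patient 1."""
    cm = reference_conception_model()
    x = {k: PATIENTS[1][k] for k in cm.x_names}
    assert cm.hazard(x, 1) == pytest.approx(0.2665, abs=5e-4)


def test_hazard_monotone_in_positive_coefficient():
    cm = reference_conception_model()
    base = {k: PATIENTS[1][k] for k in cm.x_names}
    more_parous = dict(base, parous=base["parous"] + 1)
    for t in range(1, 7):
        assert cm.hazard(more_parous, t) > cm.hazard(base, t)


def test_cumulative_constant_hazard_closed_form():
    h = 0.3
    g = np.full(6, np.log(h / (1 - h)))
    m = _model(g, {"a": 0.0})
    X = np.zeros((1, 1))
    assert m.cumulative_conception(X)[0] == pytest.approx(1 - (1 - h) ** 6)


def test_recovery_formula_equivalence():
    """Sum of per-cycle masses equals one minus the survival product."""
    rng = np.random.default_rng(3)
    for _ in range(20):
        tau = int(rng.integers(2, 9))
        m = _model(rng.normal(-1, 1, tau), {"a": rng.normal(), "b": rng.normal()}, tau)
        X = rng.normal(size=(50, 2))
        masses = m.cycle_masses(X)
        np.testing.assert_allclose(
            masses.sum(axis=1), m.cumulative_conception(X), rtol=1e-10, atol=1e-12
        )


def _tiny_cohort(rng, n=15, tau=4):
    df = pd.DataFrame(
        {
            "id": np.arange(n),
            "a": rng.normal(size=n).round(2),
            "b": rng.binomial(1, 0.5, n).astype(float),
        }
    )
    u = rng.integers(1, tau + 1, n)
    d = rng.binomial(1, 0.6, n)
    d[u == tau] = rng.binomial(1, 0.5, (u == tau).sum())
    df["U"] = u
    df["conceived"] = d
    df["r1"] = np.where((d == 1) | (u == tau), 1, 0)
    df.loc[(df.r1 == 1) & (df.conceived == 0), "U"] = tau
    df["r2"] = df["r1"]
    df["y2"] = np.where((df.conceived == 1) & (df.r2 == 1), 4.0, np.nan)
    from preconrisk import CovariateSchema

    schema = CovariateSchema(x=("a", "b"), z=("a",))
    return Cohort(df, tau=tau, schema=schema)


def test_person_period_loglik_matches_direct_survival_oracle():
    """The logistic fit's log-likelihood equals the subject-by-cycle
    discrete-time survival log-likelihood evaluated at the same estimates."""
    rng = np.random.default_rng(8)
    cohort = _tiny_cohort(rng)
    ppt = expand_person_period(cohort)
    model = fit_conception(ppt, ["a", "b"], cohort.tau)

    ll = 0.0
    for _, row in cohort.df.iterrows():
        x = {"a": row["a"], "b": row["b"]}
        u, d = int(row["U"]), int(row["conceived"])
        for t in range(1, u + 1):
            h = model.hazard(x, t)
            if t == u and d == 1:
                ll += np.log(h)
            else:
                ll += np.log(1 - h)
    assert model.meta["loglik"] == pytest.approx(ll, abs=1e-8)


def test_no_events_raises():
    rng = np.random.default_rng(1)
    cohort = _tiny_cohort(rng)
    df = cohort.df.copy()
    df["conceived"] = 0
    df["U"] = cohort.tau
    df["r1"] = df["r2"] = 1
    df["y2"] = np.nan
    cohort_none = Cohort(df, cohort.tau, cohort.schema)
    with pytest.raises(FitError, match="no conception events"):
        fit_conception(expand_person_period(cohort_none), ["a", "b"], cohort.tau)


def test_unit_weights_match_unweighted(complete_default_cohort):
    cohort = complete_default_cohort
    ppt = expand_person_period(cohort)
    x = list(cohort.schema.x)
    m0 = fit_conception(ppt, x, cohort.tau)
    w = pd.Series(1.0, index=cohort.df["id"])
    m1 = fit_conception(ppt, x, cohort.tau, weights=w)
    np.testing.assert_allclose(m0.coefficients, m1.coefficients, atol=1e-8)
    np.testing.assert_allclose(m0.baseline_logits, m1.baseline_logits, atol=1e-8)


def test_parameter_recovery_single_large_cohort():
    """Estimates from n=5000 simulated subjects fall within 3 SEs of truth."""
    params = default_cohort_params(n=5000, covariate_missing_rates={})
    cohort = simulate_cohort(params, seed=21)
    model = fit_conception(expand_person_period(cohort), list(cohort.schema.x), cohort.tau)
    bse = model.meta["bse"]
    for name, truth in params.gamma.items():
        est = model.coefficients[name]
        assert abs(est - truth) < 3 * bse[name], f"{name}: {est} vs {truth}"
    for t in range(1, cohort.tau + 1):
        g_true = params.baseline_logits[t - 1]
        # cycle logits combine intercept and offset uncertainty; use a loose
        # 4-SE-of-intercept guard since bse covers the offset parameterization
        key = "intercept" if t == 1 else f"I(t={t})"
        assert abs(model.baseline_logits[t - 1] - g_true) < 5 * max(bse["intercept"], bse.get(key, 0))


def test_absent_cycle_carries_last_estimable_value():
    rng = np.random.default_rng(5)
    cohort = _tiny_cohort(rng, n=40, tau=4)
    df = cohort.df.copy()
    # truncate everyone to at most 3 cycles so cycle 4 has no rows
    trunc = df["U"] > 3
    df.loc[trunc, "U"] = 3
    df.loc[trunc, "conceived"] = 1  # keep records valid with U < tau
    df["r1"] = 1
    df["r2"] = 1
    df["y2"] = np.where(df.conceived == 1, 4.0, np.nan)
    df.loc[df.conceived == 0, "U"] = 4
    df.loc[df.conceived == 0, "U"] = 4
    cohort2 = Cohort(df, 4, cohort.schema)
    ppt = expand_person_period(cohort2)
    ppt = ppt[ppt["t"] <= 3]
    with pytest.warns(RuntimeWarning, match="no person-period rows"):
        model = fit_conception(ppt, ["a", "b"], 4)
    assert model.baseline_logits[3] == model.baseline_logits[2]


def test_serialization_roundtrip(tmp_path):
    cm = reference_conception_model()
    path = tmp_path / "cm.json"
    cm.to_json(path)
    back = ConceptionModel.from_json(path)
    np.testing.assert_allclose(back.baseline_logits, cm.baseline_logits)
    pd.testing.assert_series_equal(back.coefficients, cm.coefficients)
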