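"""End-to-end orchestration: selection, estimation paths, prediction, validation.

``run_analysis`` executes the full recipe behind one configuration surface:
impute (or weight) -> AIC backward selection on the stacked completed data
-> fit the two stage models per completed dataset -> Rubin-pool -> predict
risk profiles -> verification-bias-adjusted HUM -> bootstrap optimism
correction (conditioning on the selected model form by default).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import FitError
from .cohort import CLASS_ORDER, Cohort, expand_person_period
from .conception import ConceptionModel, fit_conception
from .gestation import GestationModel, fit_gestation
from .hum import DecisionConfig, hum_bootstrap_ci, hum_ipw, hum_nonparametric, optimism_correct
from .missing import (
    complete_case_weights,
    fit_missingness,
    rubin_pool,
    sequential_impute,
)
from .profiles import predict_profiles

logger = logging.getLogger("preconrisk")


def _conception_aic(df: pd.DataFrame, x_names: list[str], tau: int) -> float:
    ppt_cols = ["id", "t", "event"] + x_names
    return fit_conception(df[ppt_cols], x_names, tau).meta["aic"]


def _gestation_aic(df: pd.DataFrame, z_names: list[str]) -> float:
    return fit_gestation(df[z_names], df["y2"].to_numpy()).meta["aic"]


def backward_aic_select(
    stacked: Cohort | pd.DataFrame,
    stage: str,
    forced_in=(),
    candidates=None,
    tau: int | None = None,
) -> list[str]:
    """AIC-based backward selection on stacked completed data.

    ``stage="conception"`` evaluates the discrete-time hazard on the
    person-period expansion of the stacked rows; ``stage="gestation"``
    evaluates the multinomial model on the stacked conceivers.  At each
    step the non-forced covariate whose removal most decreases AIC is
    dropped (lexicographic tie rule); selection stops when no removal
    decreases AIC.  Forced-in covariates are never removed.
    """
    if isinstance(stacked, Cohort):
        tau = stacked.tau
        if candidates is None:
            candidates = stacked.schema.x if stage == "conception" else stacked.schema.z
        df = stacked.df
        if stage == "conception":
            work = expand_person_period(stacked)
        else:
            work = df[(df["conceived"] == 1) & df["y2"].notna()]
    else:
        if candidates is None or (stage == "conception" and tau is None):
            raise ValueError("candidates (and tau for the conception stage) are required with a raw frame")
        if stage == "conception":
            raise ValueError("pass a Cohort for conception-stage selection")
        work = stacked[(stacked["conceived"] == 1) & stacked["y2"].notna()]

    forced = [c for c in candidates if c in set(forced_in)]
    current = list(candidates)
    if not current:
        raise ValueError("no candidate covariates")

    def aic_of(names: list[str]) -> float:
        if stage == "conception":
            return _conception_aic(work, names, tau)
        return _gestation_aic(work, names)

    current_aic = aic_of(current)
    while True:
        removable = sorted(c for c in current if c not in forced)
        best_name, best_aic = None, current_aic
        for c in removable:
            trial = [k for k in current if k != c]
            if not trial:
                continue
            try:
                a = aic_of(trial)
            except FitError as err:
                logger.warning("selection: dropping %s failed (%s); kept", c, err)
                continue
            if a < best_aic:
                best_name, best_aic = c, a
        if best_name is None:
            return current
        logger.info("selection (%s): removed %s (AIC %.2f -> %.2f)", stage, best_name, current_aic, best_aic)
        current = [k for k in current if k != best_name]
        current_aic = best_aic


@dataclass
class AnalysisConfig:
    """Configuration for one end-to-end analysis run."""

    path: str = "mi"  # mi | ipw | complete_case
    M: int = 10
    B: int = 200
    seed: int = 0
    decision_weights: tuple = (1.0, 1.0, 1.0, 1.0)
    forced_in: tuple = ()
    select: bool = True
    mc_draws: int = 200_000
    optimism: bool = True
    compute_ci: bool = False
    ci_B: int = 200
    verification_form: str = "single"
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.path not in ("mi", "ipw", "complete_case"):
            raise ValueError("path must be mi, ipw, or complete_case")


def _pool_conception(models: list[ConceptionModel]) -> ConceptionModel:
    tau = models[0].tau
    ests = []
    for m in models:
        g = pd.Series(m.baseline_logits, index=[f"g{t}" for t in range(1, tau + 1)])
        ests.append(pd.concat([g, m.coefficients]))
    pooled = rubin_pool(ests).point
    g = pooled[[f"g{t}" for t in range(1, tau + 1)]].to_numpy()
    gamma = pooled[models[0].x_names]
    return ConceptionModel(g, gamma, tau, meta={"pooled_from": len(models)})


def _pool_gestation(models: list[GestationModel]) -> GestationModel:
    a2 = rubin_pool([m.alpha2 for m in models]).point
    a3 = rubin_pool([m.alpha3 for m in models]).point
    return GestationModel(a2, a3, meta={"pooled_from": len(models)})


def _fit_stage_models(
    cohort_or_completed,
    x_sel: list[str],
    z_sel: list[str],
    path: str,
    tau: int,
) -> tuple[ConceptionModel, GestationModel]:
    """Fit (and pool, for MI) the two stage models for one dataset."""
    if path == "mi":
        cms, gms = [], []
        for m, c in enumerate(cohort_or_completed.cohorts):
            # stage 1: observed follow-up with imputed covariates only
            cms.append(fit_conception(expand_person_period(cohort_or_completed.stage1_cohort(m)), x_sel, tau))
            conc = c.df[c.df["conceived"] == 1]
            gms.append(fit_gestation(conc[z_sel], conc["y2"].to_numpy()))
        return _pool_conception(cms), _pool_gestation(gms)
    cohort = cohort_or_completed
    cm = fit_conception(expand_person_period(cohort), x_sel, tau)
    df = cohort.df
    cc = df[(df["r1"] == 1) & (df["conceived"] == 1) & (df["r2"] == 1)]
    if path == "ipw":
        mm = fit_missingness(cohort, form="product")
        w = complete_case_weights(mm, cohort)
        gm = fit_gestation(cc[z_sel], cc["y2"].to_numpy(), weights=w.loc[cc["id"]].to_numpy())
    else:  # complete_case
        gm = fit_gestation(cc[z_sel], cc["y2"].to_numpy())
    return cm, gm


def _verified_profiles_by_class(
    cohort: Cohort, cm: ConceptionModel, gm: GestationModel, pi_r: pd.Series | None
):
    """Group verified subjects' profiles (and pi_R) by observed outcome class."""
    profiles, _ = predict_profiles(cm, gm, cohort)
    prof = profiles.set_index("id")
    labels = cohort.outcome_class()
    labels.index = cohort.df["id"]
    by_class, pis = [], []
    for cls in CLASS_ORDER:
        ids = labels.index[labels == cls]
        ids = [i for i in ids if i in prof.index]
        if not ids:
            raise FitError(f"no verified subjects in class {cls}")
        by_class.append(prof.loc[ids].to_numpy())
        if pi_r is not None:
            pis.append(pi_r.loc[ids].to_numpy())
    return by_class, (pis if pi_r is not None else None)


def _complete_covariate_cohort(cohort: Cohort) -> Cohort:
    cov = list(cohort.covariate_names)
    keep = ~cohort.df[cov].isna().any(axis=1)
    if not keep.all():
        logger.info("dropping %d subjects with incomplete covariates", int((~keep).sum()))
    return Cohort(cohort.df.loc[keep].reset_index(drop=True), cohort.tau, cohort.schema, validate=False)


def run_analysis(cohort: Cohort, config: AnalysisConfig) -> dict:
    """Execute the configured analysis end to end; returns a JSON-able report."""
    rng = np.random.default_rng(config.seed)
    seeds = {k: int(rng.integers(2**31)) for k in ("impute", "hum", "optimism", "ci")}
    tau = cohort.tau
    logger.info("run_analysis: path=%s n=%d tau=%d", config.path, cohort.n, tau)

    def prepare(c: Cohort):
        """Path-specific data preparation: imputations or covariate restriction."""
        if config.path == "mi":
            return sequential_impute(c, M=config.M, seed=seeds["impute"])
        return _complete_covariate_cohort(c)

    prepared = prepare(cohort)

    # --- model selection on (stacked) completed data -----------------------
    if config.path == "mi":
        stacked_df = prepared.stacked().drop(columns=["imputation"])
        stacked_df["id"] = np.arange(len(stacked_df))
        sel_cohort = Cohort(stacked_df, tau, cohort.schema, validate=False)
    else:
        sel_cohort = prepared
    if config.select:
        x_sel = backward_aic_select(sel_cohort, "conception", forced_in=config.forced_in)
        z_sel = backward_aic_select(sel_cohort, "gestation", forced_in=config.forced_in)
    else:
        x_sel = list(cohort.schema.x)
        z_sel = list(cohort.schema.z)
    logger.info("selected x=%s z=%s", x_sel, z_sel)

    # --- estimation --------------------------------------------------------
    cm, gm = _fit_stage_models(prepared, x_sel, z_sel, config.path, tau)

    # --- verification weights on covariate-complete observed data ----------
    score_cohort = _scoring_cohort(cohort, prepared, config.path)
    if config.path == "complete_case":
        pi_r = None
    else:
        mm = fit_missingness(score_cohort, form=config.verification_form)
        pi_r = pd.Series(mm.verification_prob(score_cohort.df), index=score_cohort.df["id"])

    profiles, skipped = predict_profiles(cm, gm, score_cohort)
    hum_cfg = DecisionConfig(weights=np.asarray(config.decision_weights, dtype=float))

    def score(models: tuple, data: Cohort) -> float:
        cmx, gmx = models
        if config.path == "complete_case":
            by_class, _ = _verified_profiles_by_class(data, cmx, gmx, None)
            est = hum_nonparametric(
                by_class, hum_cfg, mode="monte_carlo", mc_draws=config.mc_draws, seed=seeds["hum"]
            )
        else:
            mmx = fit_missingness(data, form=config.verification_form)
            pir = pd.Series(mmx.verification_prob(data.df), index=data.df["id"])
            by_class, pis = _verified_profiles_by_class(data, cmx, gmx, pir)
            est = hum_ipw(
                by_class, pis, hum_cfg, mode="monte_carlo", mc_draws=config.mc_draws, seed=seeds["hum"]
            )
        return est.value

    hum_initial = score((cm, gm), score_cohort)

    report: dict = {
        "config": {
            "path": config.path, "M": config.M, "B": config.B, "seed": config.seed,
            "decision_weights": list(config.decision_weights),
            "forced_in": list(config.forced_in), "select": config.select,
            "mc_draws": config.mc_draws, "verification_form": config.verification_form,
        },
        "n_subjects": cohort.n,
        "selected": {"conception": x_sel, "gestation": z_sel},
        "conception_model": cm.to_dict(),
        "gestation_model": gm.to_dict(),
        "n_profiles": int(len(profiles)),
        "n_skipped_profiles": int(len(skipped)),
        "profile_means": {
            c: float(profiles[c].mean()) for c in profiles.columns if c != "id"
        },
        "hum": {"initial": hum_initial, "mode": "monte_carlo", "mc_draws": config.mc_draws},
    }

    # --- optimism correction (conditions on the selected model form) -------
    if config.optimism:
        def fit_and_score(fit_data: Cohort, score_data: Cohort) -> float:
            fitted = _fit_stage_models(prepare(fit_data), x_sel, z_sel, config.path, tau)
            return score(fitted, _scoring_cohort(score_data, None, "refit"))

        est = optimism_correct(cohort, fit_and_score, B=config.B, seed=seeds["optimism"])
        report["hum"].update(est.optimism)

    if config.compute_ci:
        def ci_pipeline(resampled: Cohort) -> float:
            fitted = _fit_stage_models(prepare(resampled), x_sel, z_sel, config.path, tau)
            return score(fitted, _scoring_cohort(resampled, None, "refit"))

        se, ci = hum_bootstrap_ci(cohort, ci_pipeline, B=config.ci_B, seed=seeds["ci"])
        report["hum"]["se"] = se
        report["hum"]["ci"] = list(ci)

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        profiles.to_csv(out / "profiles.csv", index=False)
        (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report


def _scoring_cohort(cohort: Cohort, prepared, path: str) -> Cohort:
    """Observed-data cohort used for scoring: original R indicators with
    complete covariates (from the first imputation for the MI path,
    covariate-complete subjects otherwise)."""
    if path == "mi" and prepared is not None:
        first = prepared.cohorts[0]
        df = cohort.df.copy()
        cov = list(cohort.covariate_names)
        df[cov] = first.df[cov].to_numpy()
        return Cohort(df, cohort.tau, cohort.schema, validate=False)
    return _complete_covariate_cohort(cohort)
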