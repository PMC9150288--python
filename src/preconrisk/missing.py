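"""Two-stage missingness machinery.

The pregnancy-attempt outcome is assumed missing *sequentially at random*:
first-stage missingness (censoring prior to conception) depends on baseline
covariates ``x'`` only, and second-stage missingness (unknown gestation
result) depends on covariates ``z'`` and the first-stage outcome, never on
the gestation outcome itself.  Under this factorization the probability of
fully observing an attempt is

    pi_R = P(R2 = 1 | z', R1 = 1, Y1) * P(R1 = 1 | x'),

and the probability of being a second-stage complete case is

    pi_C = P(R2 = 1 | z', R1 = 1, Y1 = 1) * P(Y1 = 1 | x, R1 = 1) * P(R1 = 1 | x').

Two estimation paths are provided:

* inverse-probability weighting — fit the gestation model to complete
  cases weighted by ``1 / pi_C`` (weights truncated at configurable
  percentiles for stability);
* sequential multiple imputation — impute missing baseline covariates by
  chained equations, impute the conception time for first-stage-censored
  subjects from the conditional discrete-time distribution given survival
  past their censoring cycle, then impute the gestation outcome for
  selected subjects with an unknown result; repeat M times and pool with
  Rubin's rules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sklearn.linear_model import LinearRegression, LogisticRegression

from ._utils import FitError, fit_logit, predict_logit, spawn_rngs
from .cohort import Cohort, expand_person_period
from .conception import ConceptionModel, fit_conception
from .gestation import fit_gestation


@dataclass
class MissingnessModels:
    """Fitted verification / selection probability models.

    ``form="product"`` carries the three sequential factors; ``form=
    "single"`` carries one logistic model for the probability of being a
    complete record, the simplification appropriate when second-stage
    missingness is rare.
    """

    form: str
    stage1: pd.Series | None = None  # P(R1=1 | x')
    stage2: pd.Series | None = None  # P(R2=1 | z', R1=1, Y1=1)
    selection: pd.Series | None = None  # P(Y1=1 | x, R1=1)
    single: pd.Series | None = None  # P(R=1 | w)
    prob_floor: float = 1e-3

    def _floored(self, p: np.ndarray, what: str) -> np.ndarray:
        if np.any(p < self.prob_floor):
            warnings.warn(
                f"{what}: {int(np.sum(p < self.prob_floor))} probabilities below "
                f"floor {self.prob_floor}; truncated",
                RuntimeWarning,
            )
            p = np.maximum(p, self.prob_floor)
        return p

    def p_r1(self, df: pd.DataFrame) -> np.ndarray:
        return self._floored(predict_logit(self.stage1, df), "P(R1=1|x')")

    def p_r2_given_conception(self, df: pd.DataFrame) -> np.ndarray:
        return self._floored(predict_logit(self.stage2, df), "P(R2=1|z',Y1=1)")

    def p_y1(self, df: pd.DataFrame) -> np.ndarray:
        return self._floored(predict_logit(self.selection, df), "P(Y1=1|x,R1=1)")

    def verification_prob(self, df: pd.DataFrame) -> np.ndarray:
        """pi_R per row; subjects without conception have the second factor
        equal to one (their gestation outcome is undefined, not missing)."""
        if self.form == "single":
            return self._floored(predict_logit(self.single, df), "P(R=1|w)")
        p = self.p_r1(df)
        conceived = df["conceived"].to_numpy(dtype=float)
        p2 = np.where(conceived == 1, self.p_r2_given_conception(df), 1.0)
        return p * p2


def verification_prob(models: MissingnessModels, df: pd.DataFrame) -> np.ndarray:
    return models.verification_prob(df)


def fit_missingness(
    cohort: Cohort,
    form: str = "product",
    prob_floor: float = 1e-3,
) -> MissingnessModels:
    """Fit the missingness/verification models on the observed data.

    ``form="product"`` fits the three sequential factors (the stage-2
    model on conceivers with known first-stage status, where ``R2`` truly
    varies); ``form="single"`` fits one logistic model for the complete-
    record indicator on all declared covariates.
    """
    df = cohort.df
    cov = list(cohort.covariate_names)
    if df[cov].isna().any().any():
        raise FitError("missingness models require complete covariates; impute first")
    if form == "single":
        r = ((df["r1"] == 1) & (df["r2"] == 1)).to_numpy(dtype=float)
        single = fit_logit(df[cov], r, what="single verification model P(R=1|w)")
        return MissingnessModels(form="single", single=single, prob_floor=prob_floor)
    if form != "product":
        raise ValueError("form must be 'product' or 'single'")
    xp = list(cohort.schema.x_prime) or list(cohort.schema.x)
    zp = list(cohort.schema.z_prime) or list(cohort.schema.z)
    r1 = df["r1"].to_numpy(dtype=float)
    if r1.min() == r1.max():
        raise FitError("no missingness variation in R1")
    stage1 = fit_logit(df[xp], r1, what="stage-1 missingness model P(R1=1|x')")
    conc = df[(df["r1"] == 1) & (df["conceived"] == 1)]
    r2 = conc["r2"].to_numpy(dtype=float)
    if len(conc) == 0 or r2.min() == r2.max():
        raise FitError("no missingness variation in R2 among conceivers")
    stage2 = fit_logit(conc[zp], r2, what="stage-2 missingness model P(R2=1|z')")
    known = df[df["r1"] == 1]
    selection = fit_logit(
        known[list(cohort.schema.x)],
        known["conceived"].to_numpy(dtype=float),
        what="selection model P(Y1=1|x)",
    )
    return MissingnessModels(
        form="product", stage1=stage1, stage2=stage2, selection=selection, prob_floor=prob_floor
    )


def complete_case_weights(
    models: MissingnessModels,
    cohort: Cohort,
    truncate: tuple[float, float] | None = (1.0, 99.0),
) -> pd.Series:
    """Inverse-probability weights ``1 / pi_C`` for second-stage complete cases.

    Returns a Series indexed by subject id over the complete cases
    (R1 = 1, Y1 = 1, R2 = 1).  Weights are truncated at the given
    percentiles (default 1st/99th) to guard against near-zero estimated
    probabilities.
    """
    if models.form != "product":
        raise FitError("complete-case weights require the product-form models")
    df = cohort.df
    cc = (df["r1"] == 1) & (df["conceived"] == 1) & (df["r2"] == 1)
    if not cc.any():
        raise FitError("no second-stage complete cases")
    sub = df.loc[cc]
    pi_c = (
        models.p_r2_given_conception(sub) * models.p_y1(sub) * models.p_r1(sub)
    )
    w = 1.0 / pi_c
    if truncate is not None:
        lo, hi = np.percentile(w, truncate)
        w = np.clip(w, lo, hi)
    return pd.Series(w, index=sub["id"].to_numpy(), name="weight")


# ---------------------------------------------------------------------------
# Conception-time imputation


def conditional_conception_masses(model: ConceptionModel, x_row, u: int) -> np.ndarray:
    """Distribution of T1 over {u+1, ..., tau, tau+1} given T1 > u and x.

    The final mass (index tau - u) encodes "no conception by tau".
    """
    tau = model.tau
    if not 0 <= u < tau:
        raise ValueError(f"censoring cycle u={u} must satisfy 0 <= u < tau={tau}")
    if isinstance(x_row, dict):
        x_row = [x_row[name] for name in model.x_names]
    h = model.hazard_matrix(np.asarray(x_row, dtype=float).reshape(1, -1))[0]
    h_tail = h[u:]
    surv = np.cumprod(1.0 - h_tail)
    surv_before = np.concatenate([[1.0], surv[:-1]])
    masses = np.concatenate([h_tail * surv_before, [surv[-1]]])
    return masses / masses.sum()


def impute_conception_time(
    cohort: Cohort,
    aux_model: ConceptionModel,
    rng: np.random.Generator,
) -> pd.Series:
    """Draw an imputed conception cycle for every first-stage-censored subject.

    Each subject censored at ``u < tau`` receives a draw from the
    conditional discrete-time distribution of T1 given ``T1 > u`` and
    their auxiliary covariates; the value ``tau + 1`` encodes no
    conception within the window.  Reproducible under the supplied
    generator.
    """
    df = cohort.df
    censored = df[df["r1"] == 0]
    if (censored["U"] >= cohort.tau).any():
        bad = censored.loc[censored["U"] >= cohort.tau, "id"].tolist()
        raise ValueError(f"R1=0 subjects censored at u>=tau: {bad[:5]}")
    out = {}
    for _, row in censored.iterrows():
        u = int(row["U"])
        x = [row[name] for name in aux_model.x_names]
        masses = conditional_conception_masses(aux_model, x, u)
        support = np.arange(u + 1, cohort.tau + 2)
        out[row["id"]] = int(rng.choice(support, p=masses))
    return pd.Series(out, dtype=int, name="t1_imputed")


def fit_stratified_imputation_model(
    cohort: Cohort, aux_names: list[str], min_stratum: int = 30
):
    """Censoring-cycle-stratified multinomial imputation model (non-default).

    For each censoring cycle ``u`` a separate multinomial logit over
    ``t in {u+1..tau+1}`` is fit on the auxiliaries, using the subjects
    with known first-stage status still at risk after cycle ``u``.  Sparse
    strata make this fragile at realistic sample sizes, so the pooled
    discrete-time hazard model is the package default; this literal
    stratified variant is provided for sensitivity analyses.

    Returns a ``{u: (classes, sklearn model)}`` mapping.
    """
    df = cohort.df
    known = df[df["r1"] == 1]
    t1_obs = np.where(known["conceived"] == 1, known["U"], cohort.tau + 1)
    strata = {}
    for u in sorted(df.loc[df["r1"] == 0, "U"].unique()):
        at_risk = known[t1_obs > u]
        y = np.where(at_risk["conceived"] == 1, at_risk["U"], cohort.tau + 1)
        if len(at_risk) < min_stratum or len(np.unique(y)) < 2:
            raise FitError(f"stratum u={u}: too sparse for a stratified multinomial fit")
        clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=500)
        clf.fit(at_risk[aux_names].to_numpy(dtype=float), y)
        strata[int(u)] = (clf.classes_, clf)
    return strata


# ---------------------------------------------------------------------------
# Chained-equations covariate imputation


def _chained_impute(
    cov: pd.DataFrame, rng: np.random.Generator, n_iter: int = 10
) -> pd.DataFrame:
    """One stochastic chained-equations completion of a covariate frame.

    Column models are chosen by type: Bayesian-bootstrap-free proper draws
    from a linear model for continuous columns (normal noise at the
    residual scale) and Bernoulli draws from a logistic model for 0/1
    columns.  Columns without missing values are used as-is.
    """
    cov = cov.copy()
    missing_cols = [c for c in cov.columns if cov[c].isna().any()]
    if not missing_cols:
        return cov
    masks = {c: cov[c].isna() for c in missing_cols}
    binary = {
        c: set(cov[c].dropna().unique()) <= {0, 1, 0.0, 1.0} for c in missing_cols
    }
    # initialize with observed mean / mode
    for c in missing_cols:
        obs = cov[c].dropna()
        if len(obs) == 0:
            raise FitError(f"covariate {c} entirely missing")
        fill = obs.mode().iloc[0] if binary[c] else obs.mean()
        cov.loc[masks[c], c] = fill
    for _ in range(n_iter):
        for c in missing_cols:
            others = [o for o in cov.columns if o != c]
            X_obs = cov.loc[~masks[c], others].to_numpy(dtype=float)
            y_obs = cov.loc[~masks[c], c].to_numpy(dtype=float)
            X_mis = cov.loc[masks[c], others].to_numpy(dtype=float)
            if binary[c]:
                if y_obs.min() == y_obs.max():
                    cov.loc[masks[c], c] = y_obs[0]
                    continue
                mu, sd = X_obs.mean(axis=0), X_obs.std(axis=0)
                sd[sd == 0] = 1.0
                clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=500)
                clf.fit((X_obs - mu) / sd, y_obs)
                p = clf.predict_proba((X_mis - mu) / sd)[:, list(clf.classes_).index(1)]
                cov.loc[masks[c], c] = rng.binomial(1, p).astype(float)
            else:
                reg = LinearRegression().fit(X_obs, y_obs)
                resid_sd = float(np.std(y_obs - reg.predict(X_obs), ddof=1))
                draw = reg.predict(X_mis) + rng.normal(0.0, resid_sd, size=len(X_mis))
                cov.loc[masks[c], c] = draw
    return cov


@dataclass
class ImputedCohorts:
    """M completed cohorts with per-imputation seeds and diagnostics."""

    cohorts: list[Cohort]
    seeds: list[int]
    diagnostics: dict = field(default_factory=dict)
    source: Cohort | None = None

    @property
    def M(self) -> int:
        return len(self.cohorts)

    def stage1_cohort(self, m: int) -> Cohort:
        """The m-th completed covariates joined to the *observed* follow-up.

        The discrete-time conception model is fit to the observed
        ``(U, delta)`` data — censoring is handled by the person-period
        likelihood itself — so only baseline covariates are taken from the
        imputation, never the imputed conception times.
        """
        if self.source is None:
            raise ValueError("no source cohort attached")
        df = self.source.df.copy()
        cov = list(self.source.covariate_names)
        df[cov] = self.cohorts[m].df[cov].to_numpy()
        return Cohort(df, self.source.tau, self.source.schema, validate=False)

    def stacked(self) -> pd.DataFrame:
        """All completed datasets concatenated, with an ``imputation`` column."""
        frames = []
        for m, c in enumerate(self.cohorts):
            f = c.df.copy()
            f.insert(0, "imputation", m)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)


def sequential_impute(
    cohort: Cohort,
    M: int = 10,
    seed: int | None = None,
    n_chained_iter: int = 10,
) -> ImputedCohorts:
    """Sequential multiple imputation of covariates and both outcome stages.

    For each of the M replicates (independent substreams of ``seed``):

    1. missing baseline covariates are completed by chained equations;
    2. a discrete-time hazard model on the auxiliaries ``x*`` is fit to the
       completed observed data, and the conception cycle of every
       first-stage-censored subject is drawn from its conditional
       distribution given survival past the censoring cycle (mass at
       ``tau + 1`` = no conception), defining the imputed selection event;
    3. the gestation outcome of every selected subject (observed or
       imputed conception) with an unknown result is drawn from a
       multinomial model on ``z`` and the auxiliaries fit to the subjects
       with a known result.

    Completed cohorts are fully observed (``r1 = r2 = 1`` everywhere).
    """
    if M < 2:
        raise ValueError("M must be >= 2")
    rngs = spawn_rngs(seed, M)
    tau = cohort.tau
    aux = list(cohort.schema.auxiliaries)
    z_names = list(cohort.schema.z)
    y2_predictors = list(dict.fromkeys(z_names + aux))
    cov_names = list(cohort.covariate_names)
    completed: list[Cohort] = []
    diag = {"n_covariate_cells": int(cohort.df[cov_names].isna().sum().sum()),
            "n_t1_imputed": int((cohort.df["r1"] == 0).sum()),
            "n_y2_imputed_observed_conceivers": int(
                ((cohort.df["r1"] == 1) & (cohort.df["conceived"] == 1) & (cohort.df["r2"] == 0)).sum()
            )}
    for m in range(M):
        rng = rngs[m]
        df = cohort.df.copy()
        df[cov_names] = _chained_impute(df[cov_names], rng, n_chained_iter)

        work = Cohort(df, tau, cohort.schema, validate=False)
        aux_model = fit_conception(expand_person_period(work), aux, tau)
        censored_ids = df.loc[df["r1"] == 0, "id"]
        if len(censored_ids) > 0:
            t1 = impute_conception_time(work, aux_model, rng)
            for sid, t in t1.items():
                i = df.index[df["id"] == sid][0]
                if t <= tau:
                    df.loc[i, ["conceived", "U"]] = [1, t]
                else:
                    df.loc[i, ["conceived", "U"]] = [0, tau]
            df.loc[df["id"].isin(censored_ids), "r1"] = 1

        known = df[(df["conceived"] == 1) & (df["r2"] == 1) & df["y2"].notna()]
        need_y2 = df[(df["conceived"] == 1) & (df["y2"].isna())]
        if len(need_y2) > 0:
            gm = fit_gestation(known[y2_predictors], known["y2"].to_numpy())
            probs = gm.conditional_probs(need_y2)
            draws = np.array(
                [rng.choice([2, 3, 4], p=p) for p in probs], dtype=float
            )
            df.loc[need_y2.index, "y2"] = draws
        df["r2"] = 1
        df["r1"] = 1
        completed.append(Cohort(df, tau, cohort.schema, validate=True))
    return ImputedCohorts(completed, seeds=list(range(M)), diagnostics=diag, source=cohort)


@dataclass
class PooledEstimate:
    """Rubin-pooled point estimate with within/between/total variance."""

    point: pd.Series
    within: pd.Series | None
    between: pd.Series
    total: pd.Series | None
    M: int


def rubin_pool(estimates, variances=None) -> PooledEstimate:
    """Combine M coefficient vectors (and optional variances) by Rubin's rules.

    The pooled point estimate is the arithmetic mean; when per-imputation
    variances are supplied the total variance is the mean within-imputation
    variance plus ``(1 + 1/M)`` times the between-imputation variance.
    """
    frames = [pd.Series(e, dtype=float) for e in estimates]
    M = len(frames)
    if M < 2:
        raise ValueError("need at least M=2 estimates to pool")
    index = frames[0].index
    for f in frames[1:]:
        if not f.index.equals(index):
            raise ValueError("estimates are not conformable (index mismatch)")
    mat = np.vstack([f.to_numpy() for f in frames])
    point = pd.Series(mat.mean(axis=0), index=index)
    between = pd.Series(mat.var(axis=0, ddof=1), index=index)
    within = total = None
    if variances is not None:
        vs = [pd.Series(v, dtype=float) for v in variances]
        if len(vs) != M or any(not v.index.equals(index) for v in vs):
            raise ValueError("variances are not conformable with the estimates")
        within = pd.Series(np.vstack([v.to_numpy() for v in vs]).mean(axis=0), index=index)
        total = within + (1.0 + 1.0 / M) * between
    return PooledEstimate(point=point, within=within, between=between, total=total, M=M)
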