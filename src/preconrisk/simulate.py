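"""Synthetic pregnancy-attempt cohorts with known generative truth.

The generator emulates a preconception trial cohort of women with a short
history of pregnancy loss: baseline covariates, a covariate-dependent
discrete-time conception hazard over ``tau`` menstrual cycles, independent
per-cycle dropout (censoring), a three-category gestation outcome for
every conception, and sequential-MAR missingness at both outcome stages.
Cycles are abstract discrete trials; there is no day-level fecundability
or cycle-length biology.

Stage-1 missingness is generated through the dropout process itself: the
per-cycle dropout hazard is logistic in the stage-1 missingness covariates
``x'`` and independent of the conception time given those covariates, so
censoring prior to conception (R1 = 0) is sequentially at random.  Stage-2
missingness is a direct Bernoulli draw with logit linear in ``z'`` among
conceivers, never depending on the gestation outcome.

The true conception cycle, dropout cycle and gestation outcome are emitted
in a separately-named latent column block (``latent_*``) so observed-data
code cannot accidentally consume them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, softmax

from . import reference
from .cohort import Cohort, CovariateSchema


@dataclass
class SimulationParams:
    """Full generative specification of a synthetic cohort.

    ``covariates`` maps a name to a distribution tuple: ``("normal", mean,
    sd)``, ``("bernoulli", p)``, ``("randint", low, high)`` (inclusive
    integer-uniform, for cycle counts), or ``("choice", values, probs)``.
    ``baseline_logits`` is the tau-vector ``g``; ``gamma`` / ``alpha2`` /
    ``alpha3`` are named coefficient maps (``alpha*`` include an
    ``intercept`` key).  ``censor_logit`` gives the per-cycle dropout
    hazard on the logit scale (intercept plus terms in ``x'``);
    ``stage2_obs_logit`` gives logit P(R2 = 1 | z', Y1 = 1).
    """

    n: int
    tau: int
    covariates: dict[str, tuple]
    baseline_logits: np.ndarray
    gamma: dict[str, float]
    alpha2: dict[str, float]
    alpha3: dict[str, float]
    censor_logit: dict[str, float]
    stage2_obs_logit: dict[str, float]
    covariate_missing_rates: dict[str, float] = field(default_factory=dict)
    schema: CovariateSchema | None = None

    def __post_init__(self) -> None:
        self.baseline_logits = np.asarray(self.baseline_logits, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.tau < 1:
            raise ValueError("tau must be >= 1")
        if len(self.baseline_logits) != self.tau:
            raise ValueError("baseline_logits must have length tau")
        for name, spec in self.covariates.items():
            kind = spec[0]
            if kind == "normal":
                if spec[2] <= 0:
                    raise ValueError(f"{name}: sd must be positive")
            elif kind == "bernoulli":
                if not 0 < spec[1] < 1:
                    raise ValueError(f"{name}: p must lie in (0,1)")
            elif kind == "randint":
                if spec[2] < spec[1]:
                    raise ValueError(f"{name}: high < low")
            elif kind == "choice":
                probs = np.asarray(spec[2], dtype=float)
                if np.any(probs <= 0) or abs(probs.sum() - 1) > 1e-9:
                    raise ValueError(f"{name}: choice probs must be positive and sum to 1")
            else:
                raise ValueError(f"{name}: unknown distribution kind {kind!r}")
        for rate in self.covariate_missing_rates.values():
            if not 0 <= rate < 1:
                raise ValueError("covariate missing rates must lie in [0,1)")


def _lin(coefs: dict[str, float], cov: pd.DataFrame) -> np.ndarray:
    lp = np.full(len(cov), coefs.get("intercept", 0.0))
    for name, value in coefs.items():
        if name != "intercept":
            lp = lp + value * cov[name].to_numpy(dtype=float)
    return lp


def _draw_covariates(params: SimulationParams, rng: np.random.Generator) -> pd.DataFrame:
    cols = {}
    for name, spec in params.covariates.items():
        kind = spec[0]
        if kind == "normal":
            cols[name] = rng.normal(spec[1], spec[2], size=params.n)
        elif kind == "bernoulli":
            cols[name] = rng.binomial(1, spec[1], size=params.n).astype(float)
        elif kind == "randint":
            cols[name] = rng.integers(spec[1], spec[2] + 1, size=params.n).astype(float)
        elif kind == "choice":
            cols[name] = rng.choice(np.asarray(spec[1], dtype=float), p=spec[2], size=params.n)
    return pd.DataFrame(cols)


def _first_event_cycle(hazard: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """First success cycle (1-based) for per-cycle hazards, tau+1 if none.

    ``hazard`` has shape (n, tau); draws are sequential Bernoulli trials.
    """
    n, tau = hazard.shape
    u = rng.random((n, tau))
    hit = u < hazard
    first = np.argmax(hit, axis=1) + 1
    first[~hit.any(axis=1)] = tau + 1
    return first


def simulate_cohort(params: SimulationParams, seed: int | None = None) -> Cohort:
    """Generate one synthetic cohort; reproducible under ``seed``."""
    rng = np.random.default_rng(seed)
    tau = params.tau
    cov = _draw_covariates(params, rng)

    h_conc = expit(params.baseline_logits[None, :] + _lin(params.gamma, cov)[:, None])
    t1 = _first_event_cycle(h_conc, rng)

    c_haz = expit(_lin(params.censor_logit, cov))[:, None] * np.ones((1, tau))
    c = _first_event_cycle(c_haz, rng)

    u = np.minimum(np.minimum(t1, c), tau)
    delta = (t1 <= np.minimum(c, tau)).astype(int)
    r1 = ((delta == 1) | (c >= tau)).astype(int)

    # latent gestation outcome for every true conception within the window
    lp2 = _lin(params.alpha2, cov)
    lp3 = _lin(params.alpha3, cov)
    probs = softmax(np.column_stack([lp2, lp3, np.zeros(params.n)]), axis=1)
    cum = np.cumsum(probs, axis=1)
    draw = rng.random(params.n)
    y2_latent = 2 + (draw[:, None] > cum[:, :2]).sum(axis=1)  # 2/3/4
    conceived_true = t1 <= tau
    y2_latent = np.where(conceived_true, y2_latent, np.nan)

    p_r2 = expit(_lin(params.stage2_obs_logit, cov))
    r2_draw = (rng.random(params.n) < p_r2).astype(int)
    r2 = np.where((r1 == 1) & (delta == 1), r2_draw, np.where(r1 == 1, 1, 0))

    y2_obs = np.where((delta == 1) & (r2 == 1) & (r1 == 1), y2_latent, np.nan)

    df = pd.DataFrame(
        {
            "id": np.arange(params.n),
            "U": u,
            "conceived": np.where(r1 == 1, delta, 0),
            "r1": r1,
            "y2": y2_obs,
            "r2": r2,
        }
    )
    obs_cov = cov.copy()
    for name, rate in params.covariate_missing_rates.items():
        if rate > 0:
            mask = rng.random(params.n) < rate
            obs_cov.loc[mask, name] = np.nan
    df = pd.concat([df, obs_cov], axis=1)
    df["latent_t1"] = t1
    df["latent_c"] = c
    df["latent_y2"] = y2_latent

    schema = params.schema or _default_schema(params)
    return Cohort(df, tau, schema, validate=True)


def _default_schema(params: SimulationParams) -> CovariateSchema:
    gamma_names = tuple(k for k in params.gamma if k != "intercept")
    z_names = tuple(k for k in params.alpha2 if k != "intercept")
    xp = tuple(k for k in params.censor_logit if k != "intercept")
    zp = tuple(k for k in params.stage2_obs_logit if k != "intercept")
    return CovariateSchema(x=gamma_names, z=z_names, x_prime=xp, z_prime=zp)


def true_outcome_class(cohort: Cohort) -> pd.Series:
    """Four-class outcome implied by the latent block (simulator truth)."""
    df = cohort.df
    t1 = df["latent_t1"].to_numpy()
    labels = np.where(
        t1 > cohort.tau,
        "no_pregnancy",
        pd.Series(df["latent_y2"]).map({2.0: "loss", 3.0: "preterm", 4.0: "fullterm"}),
    )
    return pd.Series(labels, index=df.index, name="true_class")


def default_cohort_params(n: int = 2000, tau: int = 6, **overrides) -> SimulationParams:
    """Reference parameter set for a preconception-trial-like cohort.

    Conception and gestation coefficients are the published first- and
    second-stage model values; covariate distributions, dropout and
    stage-2 observation rates are chosen so that the four observation
    patterns occur at realistic frequencies (roughly 8% censored prior to
    conception, 29% no pregnancy within six cycles, 1% conceptions with
    unknown result, 62% with a known result) and the cohort resembles a
    trial population of women aged 18-40 with one or two prior losses.
    """
    g = np.full(tau, reference.FIRST_STAGE_INTERCEPT)
    for t, off in reference.FIRST_STAGE_CYCLE_OFFSETS.items():
        if t <= tau:
            g[t - 1] += off
    params = SimulationParams(
        n=n,
        tau=tau,
        covariates={
            "cycles_trying": ("randint", 0, 5),
            "aspirin": ("bernoulli", 0.5),
            "age": ("normal", 28.7, 4.5),
            "prev_losses": ("choice", [1.0, 2.0], [0.7, 0.3]),
            "white": ("bernoulli", 0.75),
            "college": ("bernoulli", 0.5),
            "bmi": ("normal", 26.5, 6.0),
            "parous": ("bernoulli", 0.5),
            "hypertension": ("bernoulli", 0.08),
            "smoker": ("bernoulli", 0.12),
        },
        baseline_logits=g,
        gamma=dict(reference.FIRST_STAGE_COEFS),
        alpha2=dict(reference.SECOND_STAGE_LOSS),
        alpha3=dict(reference.SECOND_STAGE_PRETERM),
        censor_logit={"intercept": -3.6, "college": 0.3, "smoker": 0.6},
        stage2_obs_logit={"intercept": 4.0, "college": 0.3, "smoker": -0.8},
        covariate_missing_rates={
            "bmi": 0.014,
            "hypertension": 0.005,
            "smoker": 0.007,
            "college": 0.007,
        },
    )
    if overrides:
        params = replace(params, **overrides)
    return params
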