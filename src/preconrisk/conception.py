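"""Discrete-time survival model for time to clinically-recognized pregnancy.

The per-cycle conception hazard is modelled on the logit scale,

    logit P(T1 = t | T1 >= t, x) = g_t + gamma' x,   t = 1..tau,

and fitted as a logistic regression on the person-period expansion
(cycle indicators ``I(t=2)..I(t=tau)`` plus the conception predictors
``x``) under working independence.  The cumulative conception probability
within the window is recovered as

    P(T1 <= tau | x) = sum_t h_t(x) prod_{j<t} (1 - h_j(x))
                     = 1 - prod_t (1 - h_t(x)).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from ._utils import FitError


@dataclass
class ConceptionModel:
    """Fitted first-stage model: per-cycle intercepts ``g`` and slopes ``gamma``.

    ``baseline_logits[t-1]`` is ``g_t`` (reference intercept at ``t=1`` plus
    the cycle offsets), and ``coefficients`` is aligned with the conception
    covariate role ``x``.
    """

    baseline_logits: np.ndarray
    coefficients: pd.Series
    tau: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.baseline_logits = np.asarray(self.baseline_logits, dtype=float)
        if len(self.baseline_logits) != self.tau:
            raise ValueError("baseline_logits must have length tau")

    @property
    def x_names(self) -> list[str]:
        return list(self.coefficients.index)

    def _linpred(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.x_names].to_numpy(dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.coefficients.to_numpy()

    def hazard(self, x, t: int) -> float:
        """Conception hazard ``P(T1 = t | T1 >= t, x)`` at cycle ``t``."""
        if not 1 <= t <= self.tau:
            raise ValueError(f"cycle t={t} outside 1..{self.tau}")
        if isinstance(x, dict):
            x = [x[name] for name in self.x_names]
        lp = self._linpred(np.asarray(x, dtype=float).reshape(1, -1))
        return float(expit(self.baseline_logits[t - 1] + lp[0]))

    def hazard_matrix(self, X) -> np.ndarray:
        """Hazards for each subject (rows) at every cycle 1..tau (columns)."""
        lp = self._linpred(X)
        return expit(self.baseline_logits[None, :] + lp[:, None])

    def cycle_masses(self, X) -> np.ndarray:
        """Per-cycle conception mass ``h_t prod_{j<t}(1 - h_j)``, shape (n, tau)."""
        h = self.hazard_matrix(X)
        surv = np.cumprod(1.0 - h, axis=1)
        surv_before = np.concatenate([np.ones((h.shape[0], 1)), surv[:, :-1]], axis=1)
        return h * surv_before

    def cumulative_conception(self, X) -> np.ndarray:
        """``P(T1 <= tau | x)`` via the complement of the survival product."""
        h = self.hazard_matrix(X)
        return 1.0 - np.prod(1.0 - h, axis=1)

    def to_dict(self) -> dict:
        return {
            "tau": self.tau,
            "baseline_logits": self.baseline_logits.tolist(),
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "meta": self.meta,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "ConceptionModel":
        return cls(
            baseline_logits=np.asarray(d["baseline_logits"], dtype=float),
            coefficients=pd.Series(d["coefficients"], dtype=float),
            tau=int(d["tau"]),
            meta=d.get("meta", {}),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ConceptionModel":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @classmethod
    def from_table(
        cls, intercept: float, cycle_offsets: dict[int, float], coefficients: dict[str, float], tau: int
    ) -> "ConceptionModel":
        """Build from the published layout: reference intercept at t=1 plus offsets."""
        g = np.full(tau, intercept)
        for t, off in cycle_offsets.items():
            g[t - 1] += off
        return cls(g, pd.Series(coefficients, dtype=float), tau)


def fit_conception(
    ppt: pd.DataFrame,
    x_names: list[str],
    tau: int,
    weights: pd.Series | dict | None = None,
) -> ConceptionModel:
    """Fit the discrete-time hazard to a person-period table.

    Parameters
    ----------
    ppt
        Person-period table with columns ``id``, ``t``, ``event`` and the
        conception predictors.
    weights
        Optional positive per-subject weights (mapping or Series indexed
        by subject id); each subject's weight multiplies all of their
        person-period likelihood contributions.
    """
    if len(ppt) == 0:
        raise FitError("empty person-period table")
    y = ppt["event"].to_numpy(dtype=float)
    if y.sum() == 0:
        raise FitError("no conception events: hazard is not estimable")
    X_cov = ppt[list(x_names)]
    if X_cov.isna().any().any():
        raise FitError("person-period covariates contain missing values")

    cycles_present = sorted(ppt["t"].unique())
    absent = [t for t in range(1, tau + 1) if t not in cycles_present]
    if absent:
        warnings.warn(
            f"cycles {absent} have no person-period rows; their baseline "
            "logit is fixed at the last estimable cycle's value",
            RuntimeWarning,
        )
    dummy_cycles = [t for t in cycles_present if t != cycles_present[0]]
    cols = {"intercept": np.ones(len(ppt))}
    for t in dummy_cycles:
        cols[f"I(t={t})"] = (ppt["t"] == t).to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=ppt.index)
    X = pd.concat([X, X_cov.astype(float)], axis=1)

    w = None
    if weights is not None:
        wmap = pd.Series(weights, dtype=float)
        w = ppt["id"].map(wmap).to_numpy(dtype=float)
        if np.any(~np.isfinite(w)) or np.any(w <= 0):
            raise FitError("per-subject weights must be positive and defined for every id")

    model = sm.GLM(y, X.to_numpy(), family=sm.families.Binomial(), var_weights=w)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=200, tol=1e-10)
    params = pd.Series(np.asarray(res.params), index=X.columns)
    if not np.all(np.isfinite(params)) or params.abs().max() > 1e2:
        raise FitError("diverging estimates suggest complete separation")

    g = np.empty(tau)
    last = params["intercept"]
    ref = cycles_present[0]
    for t in range(1, tau + 1):
        if t == ref:
            last = params["intercept"]
        elif t in dummy_cycles:
            last = params["intercept"] + params[f"I(t={t})"]
        g[t - 1] = last

    gamma = params[list(x_names)]
    meta = {
        "n_subjects": int(ppt["id"].nunique()),
        "n_periods": int(len(ppt)),
        "converged": bool(getattr(res, "converged", True)),
        "loglik": float(res.llf),
        "aic": float(res.aic),
        "bse": {k: float(v) for k, v in zip(X.columns, np.asarray(res.bse))},
    }
    return ConceptionModel(g, gamma, tau, meta)
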