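"""Shared numerical helpers: logistic fits with separation checks, seeding."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit  # noqa: F401  (re-exported)


class FitError(RuntimeError):
    """A model fit failed (non-convergence, separation, or degenerate data)."""


def spawn_rngs(seed: int | None, n: int) -> list[np.random.Generator]:
    """Independent substreams derived from a master seed.

    Replicate ``i`` always receives the same stream regardless of how many
    other substreams are drawn, so results are invariant to parallelism.
    """
    ss = np.random.SeedSequence(seed)
    return [np.random.Generator(np.random.PCG64(s)) for s in ss.spawn(n)]


def add_intercept(X: pd.DataFrame) -> pd.DataFrame:
    out = X.copy()
    out.insert(0, "intercept", 1.0)
    return out


def fit_logit(
    X: pd.DataFrame,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    what: str = "logistic model",
) -> pd.Series:
    """Weighted ML logistic regression returning named coefficients.

    Raises :class:`FitError` when the outcome has no variation, the IRLS
    iterations fail, or estimates diverge (a symptom of complete
    separation).
    """
    y = np.asarray(y, dtype=float)
    if X.isna().any().any():
        raise FitError(f"{what}: design matrix contains missing values")
    if y.min() == y.max():
        raise FitError(f"{what}: outcome has no variation (all {y.min():g})")
    Xd = add_intercept(X)
    model = sm.GLM(y, Xd.to_numpy(dtype=float), family=sm.families.Binomial(), var_weights=weights)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(maxiter=200, tol=1e-10)
        except Exception as err:  # pragma: no cover - statsmodels internals
            raise FitError(f"{what}: fit failed ({err})") from err
    params = np.asarray(res.params, dtype=float)
    if not np.all(np.isfinite(params)) or np.max(np.abs(params)) > 1e2:
        raise FitError(f"{what}: diverging estimates suggest complete separation")
    return pd.Series(params, index=Xd.columns)


def predict_logit(params: pd.Series, X: pd.DataFrame) -> np.ndarray:
    Xd = add_intercept(X[list(params.index[1:])])
    return expit(Xd.to_numpy(dtype=float) @ params.to_numpy())


def linear_predictor(coefs: dict[str, float] | pd.Series, X: pd.DataFrame) -> np.ndarray:
    """Intercept-aware dot product of named coefficients with columns of X."""
    coefs = pd.Series(coefs, dtype=float)
    lp = np.zeros(len(X))
    for name, value in coefs.items():
        if name == "intercept":
            lp += value
        else:
            lp += value * X[name].to_numpy(dtype=float)
    return lp
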