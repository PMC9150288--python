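"""Multinomial model for the clinical result of a recognized pregnancy.

Among subjects with a clinically-recognized pregnancy within the window,
the gestation outcome (2 = clinical loss, 3 = preterm birth, 4 = full-term
birth) follows a baseline-category logit model with full-term as the
reference class:

    log{ P(Y2 = k | z, Y1 = 1) / P(Y2 = 4 | z, Y1 = 1) } = alpha_k' z,  k = 2, 3.

The model is deliberately agnostic to the timing of conception: the
conception cycle is not a second-stage covariate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import softmax
from sklearn.linear_model import LogisticRegression

from ._utils import FitError
from .cohort import OUTCOME_CODES, OUTCOME_LABELS


@dataclass
class GestationModel:
    """Fitted second-stage coefficients (intercept-first, aligned with ``z``)."""

    alpha2: pd.Series  # loss vs full-term
    alpha3: pd.Series  # preterm vs full-term
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.alpha2.index) != list(self.alpha3.index):
            raise ValueError("alpha2 and alpha3 must share the same covariate alignment")
        if self.alpha2.index[0] != "intercept":
            raise ValueError("first coefficient must be the intercept")

    @property
    def z_names(self) -> list[str]:
        return list(self.alpha2.index[1:])

    def _linpreds(self, Z) -> tuple[np.ndarray, np.ndarray]:
        if isinstance(Z, pd.DataFrame):
            Z = Z[self.z_names].to_numpy(dtype=float)
        elif isinstance(Z, dict):
            Z = np.asarray([[Z[name] for name in self.z_names]], dtype=float)
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        a2 = self.alpha2.to_numpy()
        a3 = self.alpha3.to_numpy()
        lp2 = a2[0] + Z @ a2[1:]
        lp3 = a3[0] + Z @ a3[1:]
        return lp2, lp3

    def conditional_probs(self, Z) -> np.ndarray:
        """Conditional outcome probabilities ``(pi_2|1, pi_3|1, pi_4|1)``.

        ``pi_4|1 = 1/(1 + exp(a2'z) + exp(a3'z))`` and ``pi_k|1 = pi_4|1
        exp(a_k'z)``; rows are positive and sum to one.
        """
        lp2, lp3 = self._linpreds(Z)
        logits = np.column_stack([lp2, lp3, np.zeros_like(lp2)])
        return softmax(logits, axis=1)

    def to_dict(self) -> dict:
        return {
            "loss_vs_fullterm": {k: float(v) for k, v in self.alpha2.items()},
            "preterm_vs_fullterm": {k: float(v) for k, v in self.alpha3.items()},
            "meta": self.meta,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "GestationModel":
        return cls(
            alpha2=pd.Series(d["loss_vs_fullterm"], dtype=float),
            alpha3=pd.Series(d["preterm_vs_fullterm"], dtype=float),
            meta=d.get("meta", {}),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "GestationModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def multinomial_loglik(model: GestationModel, Z: pd.DataFrame, y: np.ndarray, weights=None) -> float:
    """Weighted multinomial log-likelihood of outcomes coded 2/3/4."""
    probs = model.conditional_probs(Z)
    col = np.asarray(y, dtype=int) - 2
    p = probs[np.arange(len(col)), col]
    w = np.ones(len(col)) if weights is None else np.asarray(weights, dtype=float)
    return float(np.sum(w * np.log(p)))


def fit_gestation(
    Z: pd.DataFrame,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> GestationModel:
    """ML fit of the baseline-category logit model (full-term reference).

    Parameters
    ----------
    Z
        Covariate frame for the gestation role ``z`` (conceivers with a
        known outcome).
    y
        Outcome codes in {2, 3, 4}.
    weights
        Optional positive per-subject weights multiplying log-likelihood
        contributions (the inverse-probability-weighting path).
    """
    y = np.asarray(y, dtype=int)
    if Z.isna().any().any():
        raise FitError("gestation design matrix contains missing values")
    for code, label in OUTCOME_LABELS.items():
        if not np.any(y == code):
            raise FitError(f"empty outcome class: {label}")
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if np.any(~np.isfinite(weights)) or np.any(weights <= 0):
            raise FitError("weights must be positive")

    X = Z.to_numpy(dtype=float)
    # center/scale internally so lbfgs converges at a tight gradient
    # tolerance; coefficients are mapped back to the original scale below
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=max_iter, tol=tol)
    clf.fit(Xs, y, sample_weight=weights)
    if np.max(clf.n_iter_) >= max_iter:
        raise FitError(f"multinomial fit did not converge within {max_iter} iterations")
    coef = clf.coef_ / sd[None, :]
    intercept = clf.intercept_ - (clf.coef_ * (mu / sd)[None, :]).sum(axis=1)
    if np.max(np.abs(coef)) > 1e2 or np.max(np.abs(intercept)) > 1e2:
        raise FitError("diverging estimates suggest complete separation")

    # sklearn's symmetric softmax parameterization -> full-term reference
    classes = list(clf.classes_)
    i2, i3, i4 = (classes.index(OUTCOME_CODES[k]) for k in ("loss", "preterm", "fullterm"))
    names = ["intercept"] + list(Z.columns)
    a2 = np.concatenate([[intercept[i2] - intercept[i4]], coef[i2] - coef[i4]])
    a3 = np.concatenate([[intercept[i3] - intercept[i4]], coef[i3] - coef[i4]])
    model = GestationModel(pd.Series(a2, index=names), pd.Series(a3, index=names))
    ll = multinomial_loglik(model, Z, y, weights)
    model.meta = {
        "n": int(len(y)),
        "class_counts": {label: int(np.sum(y == code)) for code, label in OUTCOME_LABELS.items()},
        "loglik": ll,
        "aic": 2 * 2 * len(names) - 2 * ll,
        "converged": True,
    }
    return model
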