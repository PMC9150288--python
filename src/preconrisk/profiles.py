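"""Composition of the two fitted stages into four-class risk profiles.

The preconception risk profile over a conception window of ``tau`` cycles is

    p(tau) = ( pi_0(tau),
               pi_2|1(tau) * pi_not0(tau),
               pi_3|1(tau) * pi_not0(tau),
               pi_4|1(tau) * pi_not0(tau) ),

where ``pi_not0 = 1 - pi_0`` is the probability of a clinically-recognized
pregnancy within the window.  Class order is fixed everywhere as
(no-pregnancy, loss, preterm, full-term).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import CLASS_ORDER, Cohort
from .conception import ConceptionModel
from .gestation import GestationModel

PROFILE_COLUMNS = tuple(f"p_{c}" for c in CLASS_ORDER)


def compose_profile(p_conceive: float, cond) -> np.ndarray:
    """Compose one risk profile from ``pi_not0`` and ``(pi_2|1, pi_3|1, pi_4|1)``."""
    cond = np.asarray(cond, dtype=float)
    if cond.shape != (3,) or np.any(cond < 0) or abs(cond.sum() - 1.0) > 1e-8:
        raise ValueError("cond must be a 3-vector of probabilities summing to 1")
    if not 0.0 <= p_conceive <= 1.0:
        raise ValueError("p_conceive must lie in [0, 1]")
    return np.concatenate([[1.0 - p_conceive], cond * p_conceive])


def predict_profiles(
    cm: ConceptionModel,
    gm: GestationModel,
    cohort: Cohort | pd.DataFrame,
) -> tuple[pd.DataFrame, list]:
    """Risk profiles for every subject with complete ``x`` and ``z`` covariates.

    Returns a frame with columns ``id, p_no_pregnancy, p_loss, p_preterm,
    p_fullterm`` and the list of subject ids skipped for missing covariate
    values (prediction requires complete baseline covariates).
    """
    df = cohort.df if isinstance(cohort, Cohort) else cohort
    needed = list(dict.fromkeys(cm.x_names + gm.z_names))
    complete = ~df[needed].isna().any(axis=1)
    skipped = df.loc[~complete, "id"].tolist()
    sub = df.loc[complete]
    if len(sub) == 0:
        return pd.DataFrame(columns=["id", *PROFILE_COLUMNS]), skipped
    p_conceive = cm.cumulative_conception(sub)
    cond = gm.conditional_probs(sub)
    mat = np.column_stack([1.0 - p_conceive, cond * p_conceive[:, None]])
    out = pd.DataFrame(mat, columns=list(PROFILE_COLUMNS))
    out.insert(0, "id", sub["id"].to_numpy())
    return out, skipped


def predict_cycle_masses(cm: ConceptionModel, cohort: Cohort | pd.DataFrame) -> pd.DataFrame:
    """Per-cycle conception masses ``h_t prod_{j<t}(1-h_j)`` per subject."""
    df = cohort.df if isinstance(cohort, Cohort) else cohort
    complete = ~df[cm.x_names].isna().any(axis=1)
    sub = df.loc[complete]
    masses = cm.cycle_masses(sub)
    out = pd.DataFrame(masses, columns=[f"mass_t{t}" for t in range(1, cm.tau + 1)])
    out.insert(0, "id", sub["id"].to_numpy())
    return out
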