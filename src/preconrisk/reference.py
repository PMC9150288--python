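"""Published coefficients and worked-example patients.

These are the final selected prediction-model coefficients from a published
preconception risk analysis of a randomized trial of women with one or two
prior pregnancy losses (conception window ``tau = 6`` menstrual cycles),
together with three hypothetical patients used as worked examples.  They
serve as fixed inputs for worked examples and as magnitude anchors for the
synthetic-cohort defaults; nothing in the package estimates them.
"""

from __future__ import annotations

import pandas as pd

from .conception import ConceptionModel
from .gestation import GestationModel

TAU = 6

#: First-stage discrete-time hazard: reference intercept at t=1, cycle
#: offsets I(t=2)..I(t=6), and covariate slopes (logit scale).
FIRST_STAGE_INTERCEPT = -0.542
FIRST_STAGE_CYCLE_OFFSETS = {2: -0.047, 3: -0.148, 4: -0.152, 5: -0.456, 6: -0.402}
FIRST_STAGE_COEFS = {
    "cycles_trying": -0.120,
    "aspirin": 0.185,
    "age": -0.026,
    "prev_losses": 0.058,
    "white": 0.444,
    "college": 0.251,
    "bmi": -0.027,
    "parous": 0.357,
}

#: Second-stage baseline-category logits (full-term reference).
SECOND_STAGE_LOSS = {
    "intercept": -3.025,
    "age": 0.041,
    "prev_losses": 0.265,
    "white": 0.012,
    "hypertension": 0.412,
}
SECOND_STAGE_PRETERM = {
    "intercept": -0.827,
    "age": -0.032,
    "prev_losses": -0.089,
    "white": -0.698,
    "hypertension": 0.741,
}

#: Single-model verification probability logit P(R = 1 | w).
VERIFICATION_COEFS = {
    "intercept": 2.050,
    "white": 0.773,
    "college": 0.474,
    "bmi": -0.024,
    "parous": 0.366,
    "smoker": -0.973,
}

#: Worked-example patients (baseline covariates at the preconception visit).
PATIENTS = {
    1: {
        "age": 28.3, "white": 1, "college": 0, "bmi": 24.4, "hypertension": 0,
        "parous": 1, "prev_losses": 1, "aspirin": 1, "cycles_trying": 1, "smoker": 0,
    },
    2: {
        "age": 23.7, "white": 0, "college": 0, "bmi": 21.1, "hypertension": 1,
        "parous": 0, "prev_losses": 1, "aspirin": 0, "cycles_trying": 2, "smoker": 0,
    },
    3: {
        "age": 39.3, "white": 0, "college": 0, "bmi": 27.2, "hypertension": 1,
        "parous": 1, "prev_losses": 1, "aspirin": 0, "cycles_trying": 4, "smoker": 0,
    },
}

#: Published risk profiles for the worked-example patients, class order
#: (no-pregnancy, loss, preterm, full-term).  Patient 2's no-pregnancy
#: entry is not reproducible from the printed first-stage coefficients
#: (direct evaluation gives ~0.50) and is excluded from numeric anchors.
PATIENT_PROFILES = {
    1: (0.212, 0.125, 0.050, 0.613),
    2: (0.443, 0.085, 0.134, 0.338),
    3: (0.643, 0.099, 0.050, 0.208),
}


def reference_conception_model() -> ConceptionModel:
    """The published first-stage model as a ready-to-use ConceptionModel."""
    return ConceptionModel.from_table(
        FIRST_STAGE_INTERCEPT, FIRST_STAGE_CYCLE_OFFSETS, FIRST_STAGE_COEFS, TAU
    )


def reference_gestation_model() -> GestationModel:
    """The published second-stage model as a ready-to-use GestationModel."""
    return GestationModel(
        alpha2=pd.Series(SECOND_STAGE_LOSS, dtype=float),
        alpha3=pd.Series(SECOND_STAGE_PRETERM, dtype=float),
    )


def patient_frame() -> pd.DataFrame:
    """The worked-example patients as a covariate frame with an ``id`` column."""
    df = pd.DataFrame.from_dict(PATIENTS, orient="index")
    df.insert(0, "id", [f"patient_{k}" for k in df.index])
    return df.reset_index(drop=True)
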