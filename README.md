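# preconrisk

Preconception prediction of pregnancy-attempt outcomes as a multistate
competing-risks problem, for biostatisticians and reproductive
epidemiologists building risk-assessment tools from prospective
time-to-pregnancy cohorts.

## The model

At a preconception visit, the eventual outcome of a pregnancy attempt over a
conception window of τ menstrual cycles is one of four competing states:
no clinically-recognized pregnancy, clinical pregnancy loss, preterm birth,
or full-term birth.  Rather than specifying transition intensities on a
single continuous timeline — biologically implausible for gestation
outcomes and incompatible with cycle-resolution conception data — the
attempt is factored into two nested stages:

1. **Conception** — a discrete-time hazard for the time to
   clinically-recognized pregnancy T₁,

       logit P(T₁ = t | T₁ ≥ t, x) = g_t + γᵀx,   t = 1…τ,

   fit as a logistic regression on the person-period expansion (one row
   per subject per at-risk cycle), which handles censoring before
   conception; the conception probability is recovered as
   π_¬0(τ) = 1 − ∏ₜ(1 − hₜ(x)).

2. **Gestation** — a multinomial logit for the result of a recognized
   pregnancy (2 = loss, 3 = preterm, 4 = full-term reference),

       log{ P(Y₂ = k | z, Y₁=1) / P(Y₂ = 4 | z, Y₁=1) } = α_kᵀz,  k = 2, 3.

The individual **risk profile** composes the stages:

    p(τ) = ( π₀(τ), π₂|₁·π_¬0, π₃|₁·π_¬0, π₄|₁·π_¬0 ).

Outcome data are typically missing at *both* stages (censoring before
conception; pregnancies with unknown result).  Under a sequential-MAR
assumption the package offers two estimation paths: **sequential multiple
imputation** (chained-equations covariates → conditional draw of the
conception cycle for censored subjects → multinomial draw of unknown
gestation outcomes; Rubin pooling over M completed datasets) and **inverse
probability weighting** (gestation model fit to complete cases weighted by
1/π^C, the inverse probability of being a complete case).

Discrimination is validated with the **Hypervolume Under the Manifold
(HUM)**: the probability that four subjects, one per outcome class, are all
correctly matched to their classes by a forced-choice rule that assigns the
four profiles to the four class vertices minimizing the (weighted) summed
Euclidean distance.  Chance level is 1/4! ≈ 0.0417.  A
verification-bias-adjusted estimator reweights verified subjects by their
inverse verification probabilities π^R, and a bootstrap optimism
correction removes the in-sample advantage of validating on the fitting
data.

A synthetic-cohort simulator with known generative truth (covariates,
hazard, censoring, gestation outcomes, two-stage MAR missingness) makes
every component testable without access to restricted trial data.

## Worked example

`examples/01_worked_example_profiles.py` composes published two-stage
coefficients (from a preconception trial of women with one or two prior
pregnancy losses, τ = 6) into risk profiles for three hypothetical
patients:

```
Preconception risk profiles over a tau=6 cycle conception window
(no pregnancy, clinical loss, preterm birth, full-term birth):

  patient_1: 0.207  0.126  0.050  0.617
  patient_2: 0.499  0.077  0.120  0.304
  patient_3: 0.637  0.101  0.050  0.211
```

Patient 1 (the median trial participant) has a 79% chance of conceiving
within six cycles and, overall, a 62% chance of a full-term birth; patient
3 (advanced maternal age) has a 64% risk of not conceiving at all, which
might prompt immediate referral to assisted reproduction.  The other
examples simulate a cohort and refit the models
(`02_simulate_and_fit.py`), contrast the MI and IPW missing-data paths
(`03_missing_data_paths.py`), and run the full pipeline through the
optimism-corrected HUM (`04_hum_validation.py`).

A thin CLI mirrors the library:

```bash
preconrisk simulate --n 2000 --seed 1 --out cohort.csv
preconrisk fit-conception --cohort cohort.csv --config roles.yaml --out conception.json
preconrisk predict --conception conception.json --gestation gestation.json \
    --cohort cohort.csv --config roles.yaml --out profiles.csv
preconrisk validate --profiles profiles.csv --outcomes outcomes.csv --out hum.json
```

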