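"""Handle two-stage outcome missingness by multiple imputation and by IPW.

On one simulated cohort, estimates the gestation model three ways —
complete-case, sequential multiple imputation with Rubin pooling, and
inverse-probability weighting by 1/pi_C — and prints the three sets of
coefficients against the truth.
"""

import numpy as np
import pandas as pd

from preconrisk import (
    complete_case_weights,
    fit_gestation,
    fit_missingness,
    rubin_pool,
    sequential_impute,
)
from preconrisk.simulate import default_cohort_params, simulate_cohort

params = default_cohort_params(n=5000, covariate_missing_rates={})
cohort = simulate_cohort(params, seed=11)
z = list(cohort.schema.z)
df = cohort.df
cc = df[(df.r1 == 1) & (df.conceived == 1) & (df.r2 == 1)]

gm_cc = fit_gestation(cc[z], cc["y2"].to_numpy())

imputed = sequential_impute(cohort, M=10, seed=23)
a2s = []
for c in imputed.cohorts:
    conc = c.df[c.df["conceived"] == 1]
    a2s.append(fit_gestation(conc[z], conc["y2"].to_numpy()).alpha2)
a2_mi = rubin_pool(a2s)

models = fit_missingness(cohort, form="product")
w = complete_case_weights(models, cohort)
gm_ipw = fit_gestation(cc[z], cc["y2"].to_numpy(), weights=w.loc[cc["id"]].to_numpy())

print(f"Cohort n={cohort.n}: {int((df.r1 == 0).sum())} censored before conception,")
print(f"{int(((df.conceived == 1) & (df.r2 == 0)).sum())} conceptions with unknown result.\n")
print("loss-vs-fullterm coefficients (alpha_2):")
print(f"{'':15s} {'truth':>8s} {'complete-case':>14s} {'MI (M=10)':>10s} {'IPW':>8s}")
for name in gm_cc.alpha2.index:
    print(
        f"  {name:13s} {params.alpha2[name]:8.3f} {gm_cc.alpha2[name]:14.3f} "
        f"{a2_mi.point[name]:10.3f} {gm_ipw.alpha2[name]:8.3f}"
    )
print(
    "\nWith sequentially-MAR missingness at both stages, the MI and IPW\n"
    "estimates agree with each other and with the truth to within sampling\n"
    "error; Rubin's between-imputation variance quantifies the extra\n"
    "uncertainty from imputing the missing selection events and outcomes."
)
print("\nBetween-imputation SD:", np.sqrt(a2_mi.between).round(4).to_dict())
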