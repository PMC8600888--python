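"""Non-linear resilience-to-QoL link and dose-response odds ratios.

Simulates a cohort whose high-QoL probability rises logistically with
the resilience total (true per-SD OR 1.6), fits the penalized-spline
logistic GAM, and estimates crude / adjusted / per-SD odds ratios across
quartile-based resilience classes.
"""

import numpy as np

from caremirt.cohort import CohortConfig, QoLLinkSpec, default_true_params, generate_cohort, total_score_moments
from caremirt.qol import fit_gam_logistic, logistic_dose_response

params = default_true_params()
center, scale = total_score_moments(params)
cohort = generate_cohort(CohortConfig(
    n_persons=382, qol_link=QoLLinkSpec(center=center, scale=scale), seed=12,
))

total = cohort.total_scores().astype(float)
gam = fit_gam_logistic(total, cohort.qol_binary)
print(f"GAM smooth EDF = {gam.edf_smooth:.2f}, "
      f"non-linearity p = {gam.lr_pvalue:.3f} "
      "(EDF near 1: this draw is compatible with a linear logit)")

classes = np.digitize(total, np.quantile(total, [0.25, 0.5, 0.75])) + 1
covars = cohort.covariates.drop(columns=["cancer_type"])
dose = logistic_dose_response(classes, total, covars, cohort.qol_binary)
print(dose.table.round(3).to_string(index=False))
print(f"\nadjusted class ORs monotone: {dose.monotone_class_ors}")
print(f"per-SD OR = {dose.per_sd_row()['or']:.2f} "
      f"(95% CI {dose.per_sd_row()['ci_low']:.2f}-{dose.per_sd_row()['ci_high']:.2f}; "
      "true value 1.6)")
# Rising class ORs and a per-SD OR near 1.6 reproduce the dose-response
# pattern the generator encodes.
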