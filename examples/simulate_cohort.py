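"""Simulate a synthetic longitudinal diabetic cohort and check its calibration.

Generates the default cohort (269 subjects, 2798 eligible GFR studies),
prints the per-sex moment table, and compares the headline means against
the cohort the generator emulates (mean aGFR ~130.4, mean CKD-EPI eGFR
~104.7, FPG-HbA1c correlation ~0.71).
"""

import numpy as np

from glygfr import calibration_report, ckd_epi_cohort, simulate_cohort

sim = simulate_cohort(seed=1)
cohort = sim.cohort
print(f"simulated {cohort.n_subjects} subjects, {cohort.n_exams} eligible exams\n")

print(calibration_report(cohort).round(2), "\n")

df = cohort.frame
agfr = df.agfr_ml_min_1p73.to_numpy()
egfr = ckd_epi_cohort(cohort).to_numpy()
print(f"corr(FPG, HbA1c)          = {np.corrcoef(df.fpg_mg_dl, df.hba1c_pct)[0, 1]:.3f}")
print(f"mean aGFR                 = {agfr.mean():.1f} mL/min/1.73m2")
print(f"mean CKD-EPI eGFR         = {egfr.mean():.1f} mL/min/1.73m2 (emergent)")
print(f"mean (aGFR - eGFR)        = {(agfr - egfr).mean():.1f} mL/min/1.73m2")
print("the positive gap shows how far creatinine-only estimation falls "
      "below measured filtration in this hyperfiltering population")
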