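"""Normative GLM Z-scoring and abnormal-node burden.

Fits age + sex GLMs on simulated controls, Z-scores a synthetic subject
whose node strengths were shifted upward, and counts parcels outside the
±2 band.
"""

import numpy as np
import pandas as pd

from longconn import abnormal_burden, fit_normative_models, generate_control_cohort, node_strength

cohort = generate_control_cohort(n=60, scale=1, seed=3)
rows, ages, sexes = [], [], []
for s in cohort.controls:
    w = cohort.connectome(s.subject_id, "control", 1).matrix
    rows.append(node_strength(w))
    ages.append(s.ages["control"])
    sexes.append(s.sex)
parc = cohort.parcellations[1]
features = pd.DataFrame(rows, columns=parc.parcel_ids)
models = fit_normative_models(features, np.asarray(ages), np.asarray(sexes))
m0 = models[parc.parcel_ids[0]]
print(f"model for {m0.feature}: intercept {m0.intercept:.1f}, "
      f"age slope {m0.age_coefficient:.2f}/y, residual SD {m0.control_residual_sd:.1f}")

# a pseudo-patient: control-like strengths inflated by 25%
subject = features.iloc[0].to_numpy() * 1.25
z = np.array([
    models[pid].zscore(v, ages[0], sexes[0]) for pid, v in zip(parc.parcel_ids, subject)
])
burden = abnormal_burden(z, threshold=2.0)
print(f"abnormal nodes: {burden.n_abnormal_total}/{len(z)} "
      f"(>{burden.threshold:+.0f}: {burden.n_above}, <-{burden.threshold:.0f}: {burden.n_below})")
# A uniform strength inflation drives many parcels above +2 while leaving
# the lower tail empty — the burden counts localise the deviation direction.
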