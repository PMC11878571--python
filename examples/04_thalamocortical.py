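"""Thalamocortical connectivity profiles and the affected-lobe z-of-z.

Sums streamline weight from each thalamus to its ipsilateral cortical
lobes (10 sums per scan), then shows the within-patient standardization
that asks whether the epilepsy-affected lobe changed more than the rest.
"""

import numpy as np

from longconn import generate_patient_pairs, thalamocortical_connectivity
from longconn.thalamic import affected_lobe_z_of_z

cohort = generate_patient_pairs(n=5, scale=1, seed=9)
parc = cohort.parcellations[1]
patient = cohort.patients[0]
early = thalamocortical_connectivity(cohort.connectome(patient.subject_id, "early", 1), parc)
late = thalamocortical_connectivity(cohort.connectome(patient.subject_id, "late", 1), parc)

print(f"patient {patient.subject_id}, affected lobe: "
      f"{patient.affected_hemisphere} {patient.affected_lobe}")
merged = early.merge(late, on=["hemisphere", "lobe"], suffixes=("_early", "_late"))
print(merged.to_string(index=False, float_format="%.0f"))

# toy z-changes: the affected lobe (index 0) rose by 3 control-SD, others ~0
deltas = np.r_[3.0, np.zeros(9)]
zz = affected_lobe_z_of_z(deltas, affected_index=0)
print(f"\nz-of-z for a 3-SD focal change: {zz.z_of_z:.2f} "
      f"(0 would mean the affected lobe changed no more than the average lobe)")
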