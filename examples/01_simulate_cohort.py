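"""Generate a synthetic head-and-neck-cancer cohort and write it to JSON.

The generator emulates the marginals of a real single-center cohort
(~80% male, ~72% ever-smokers, median age 61) with a multimodal outcome
model, so the downstream encoding/splitting/prediction stages can be run
without access to restricted patient data.
"""

import numpy as np

from oncofusion import SimConfig, generate_cohort, write_cohort

config = SimConfig(n_patients=300, seed=42)
cohort = generate_cohort(config)
write_cohort(cohort, "cohort.json")

males = np.mean([r.sex == "male" for r in cohort])
smokers = np.mean([r.smoking_status in ("former", "current") for r in cohort])
ages = [r.age_at_diagnosis for r in cohort]
recurred = np.mean([r.recurrence_days is not None for r in cohort])
died = np.mean([r.death_days is not None for r in cohort])

print(f"patients:          {len(cohort)}")
print(f"male fraction:     {males:.2f}   (generator target 0.80)")
print(f"ever-smokers:      {smokers:.2f}   (generator target 0.72)")
print(f"median age:        {np.median(ages):.0f}      (generator target 61)")
print(f"recurrence rate:   {recurred:.2f}")
print(f"death rate:        {died:.2f}")
print("wrote cohort.json — one JSON object per patient, day 0 = diagnosis")
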