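"""Kaplan-Meier overall survival and immune-density group comparison.

Overall survival uses the time from diagnosis to death, censoring
patients alive at the end of follow-up.  The Wilcoxon-Mann-Whitney test
compares CD3 density at the tumor center between patients with and
without recurrence (higher T-cell infiltration is protective in the
generator's outcome model, so recurrence cases should run lower).
"""

import numpy as np

from oncofusion import SimConfig, generate_cohort, km_estimate, mwu_test, survival_at

cohort = generate_cohort(SimConfig(n_patients=600, seed=42))

times = np.array([r.followup_days for r in cohort], float)
events = np.array([r.death_days is not None for r in cohort], int)
curve = km_estimate(times, events)
for years in (1, 3, 5):
    s = survival_at(curve, years * 365)
    print(f"{years}-year overall survival: {100 * s:5.1f}%")
print(f"events: {events.sum()} deaths, {len(events) - events.sum()} censored")

recur, no_recur = [], []
for r in cohort:
    dens = r.tma_density.get("CD3_tumor_center")
    if dens is None:
        continue
    (recur if r.recurrence_days is not None else no_recur).append(dens)
res = mwu_test(recur, no_recur)
print(f"\nCD3 density (tumor center), recurrence vs none:")
print(f"  median {np.median(recur):.0f} vs {np.median(no_recur):.0f} cells/mm^2")
print(f"  Mann-Whitney U = {res['U']:.0f}, two-sided p = {res['p_two_sided']:.2e}")
print("  (low infiltration tracks recurrence, as planted by the generator)")
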