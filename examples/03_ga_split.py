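"""Build class-balanced in- and out-of-distribution test sets with the GA.

The genome is a binary mask over complete-vector patients with a fixed
number of test bits (20% by default).  The in-distribution fitness sums
each test point's cosine distance to its nearest test neighbor (a coverage
criterion); the out-of-distribution fitness sums all pairwise test
distances (an extremity criterion).  Both subtract the class-balance
penalty alpha * sum_k |d_k − d_k,all| over the recurrence and survival
status classes.
"""

import json

import numpy as np

from oncofusion import (
    GAParams,
    SimConfig,
    assemble_vectors,
    build_recurrence_labels,
    build_survival_labels,
    generate_cohort,
    problem_from_vectors,
    run_ga,
)

cohort = generate_cohort(SimConfig(n_patients=300, seed=42))
vectors = assemble_vectors(cohort)
labels = np.column_stack([
    build_recurrence_labels(cohort).label_array(vectors.patient_ids),
    build_survival_labels(cohort).label_array(vectors.patient_ids),
])

params = GAParams(population_size=150, stagnation_limit=15,
                  max_generations=120, mutation_rate=0.3, seed=0)
for mode in ("in_distribution", "out_of_distribution"):
    problem = problem_from_vectors(vectors, labels, mode=mode)
    result = run_ga(problem, params)
    in_test = np.isin(vectors.patient_ids, result.test_ids)
    devs = []
    for k in range(labels.shape[1]):
        obs = ~np.isnan(labels[:, k])
        devs.append(abs(labels[obs & in_test, k].mean() - labels[obs, k].mean()))
    print(f"{mode}: |test| = {len(result.test_ids)}, "
          f"fitness = {result.best_fitness:.3f}, "
          f"generations = {result.n_generations}, "
          f"max class deviation = {max(devs):.3f}")
    with open(f"split_{mode}.json", "w") as fh:
        json.dump(result.to_dict(), fh, indent=1)

print("wrote split_in_distribution.json / split_out_of_distribution.json")
print("(train lists include every incomplete-vector patient)")
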