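"""Encode a cohort into multimodal patient vectors and project them to 2-D.

Each patient becomes one row: clinical/pathological encodings (binary
flags, ordinal pT/pN stages, one-hot categories), raw hematology values,
an ICD-10 bag-of-words (first four characters, minimum support 3) and the
four CD3/CD8 densities — imputed, one-hot expanded and z-scored.
"""

from collections import Counter

from oncofusion import SimConfig, assemble_vectors, generate_cohort, project_2d

cohort = generate_cohort(SimConfig(n_patients=200, seed=42))
vectors = assemble_vectors(cohort)

widths = Counter(vectors.col_modalities)
print(f"patients x features: {vectors.X.shape}")
print(f"pre-expansion dimension: {vectors.pre_expansion_dim}")
print("columns per modality:", dict(widths))
print(f"complete multimodal vectors: {vectors.complete.sum()} / {len(cohort)}")
print("(incomplete patients are later assigned to the training split)")

coords = project_2d(vectors, seed=0)
print(f"\n2-D projection: {coords.shape[0]} points, axes rescaled to [0, 1]")
print("first three patients:", coords[:3].round(3).tolist())
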