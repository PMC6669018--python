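"""Filter physicochemical descriptors and project odorants into odor space.

Generates a descriptor matrix with planted uninformative columns, applies
the three-rule filter (missing values; >90% identical; modal value >19x the
second mode), projects the survivors with correlation-matrix PCA, and
compares two sensory profiles with Spearman correlation.
"""

from olfatlas.odorspace import (
    build_sensory_profile, filter_descriptors, project_odor_space, spearman_rho,
)
from olfatlas.synthetic_data import SimulationConfig, gen_descriptor_matrix

cfg = SimulationConfig(seed=7)
matrix, truth = gen_descriptor_matrix(cfg)
reduced, removal_log = filter_descriptors(matrix)
print(f"descriptors: {matrix.shape[1]} in, {reduced.shape[1]} kept")
print("removed by rule:", removal_log["rule"].value_counts().to_dict())

space = project_odor_space(reduced, highlight=list(matrix.index[:10]))
ve = space.variance_explained
print(f"PC1 {ve[0]:.1f}%, PC2 {ve[1]:.1f}% of descriptor variance")

# two overlapping sensory profiles, as fractions of odorant sets per category
ann = {
    "o1": {"floral", "sweet"}, "o2": {"floral"}, "o3": {"sulfurous", "meaty"},
    "o4": {"cheesy", "sweaty"}, "o5": {"sweet", "fruity"},
}
vocab = ["floral", "sweet", "fruity", "sulfurous", "meaty", "cheesy", "sweaty"]
prof_a = build_sensory_profile(["o1", "o2", "o5"], ann, vocab)
prof_b = build_sensory_profile(["o1", "o5", "o3"], ann, vocab)
rho, p = spearman_rho(prof_a, prof_b)
print(f"sensory-profile Spearman rho = {rho:.3f} (p = {p:.3f})")
# rho near 1 means the two odorant sets smell alike category-by-category.
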