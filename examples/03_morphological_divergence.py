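"""Mahalanobis distances and canonical variates from specimen measurements.

Simulates specimens for four species (two pairs: one weakly, one strongly
diverged), then computes species means, the pooled within-species
covariance, pairwise squared Mahalanobis distances D2, and the DFA
projection whose full canonical space reproduces those distances.
"""

import numpy as np

from specmode import (
    SpecimenRecord,
    dfa_project,
    mahalanobis_matrix,
    pooled_within_covariance,
    summarize_species,
)

rng = np.random.default_rng(42)

# species mean traits (mm): capitulum length/width, leaf length/width
means = {
    "similar_1": [8.0, 5.0, 20.0, 2.0],
    "similar_2": [8.3, 5.1, 20.5, 2.1],   # subtle divergence
    "diverged_1": [11.0, 6.5, 28.0, 3.5],
    "diverged_2": [6.0, 3.8, 14.0, 1.4],  # strong divergence
}
specimens = []
for sp, mu in means.items():
    for i in range(20):
        vals = np.array(mu) * np.exp(rng.normal(0, 0.08, 4))
        specimens.append(SpecimenRecord(f"{sp}_s{i}", sp, *vals))

summaries = summarize_species(specimens)
pooled = pooled_within_covariance(summaries)
D = mahalanobis_matrix(summaries, pooled)

print("squared Mahalanobis distances D2 between species means:")
for i, a in enumerate(D.species_ids):
    for j in range(i + 1, len(D.species_ids)):
        b = D.species_ids[j]
        print(f"  {a:>10} vs {b:<10} D2 = {D.get(a, b):8.1f}")

proj = dfa_project(specimens, summaries)
print("\ncanonical roots (between/within variance per axis):",
      np.round(proj.eigenvalues, 2))
print("species centroids on the first two canonical axes:")
for sp, score in zip(proj.species_ids, proj.species_scores):
    print(f"  {sp:>10}: ({score[0]:7.2f}, {score[1]:7.2f})")
print("\nThe 'similar' pair sits close together (small D2) while the "
      "'diverged' pair is far apart - D2 in the tens to hundreds, the "
      "scale separating weakly from strongly differentiated species.")
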