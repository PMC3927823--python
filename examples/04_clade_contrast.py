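"""Full pipeline on a synthetic two-clade dataset: vicariant vs sympatric.

Generates a dated tree with a vicariant clade A (6 species; ranges split at
speciation, daughters born allopatric) and a sympatric clade B (4 species;
ranges inherited whole, plus adaptive trait divergence at each split), then
runs both clade contrasts: within-clade range overlap and within-clade
Mahalanobis D2, each with a pooled t and a species-label permutation null.
"""

import numpy as np

from specmode import (
    SimulationConfig,
    generate_dataset,
    mahalanobis_matrix,
    overlap_matrix,
    permutation_test,
    pooled_within_covariance,
    ranges_from_localities,
    summarize_species,
)

config = SimulationConfig(seed=1)
ds = generate_dataset(config)
print(f"tree: {len(ds.tree.tip_labels)} species "
      f"(clade A vicariant: 6, clade B sympatric: 4), "
      f"root age {ds.tree.root.age:.2f} Ma")

ranges = ranges_from_localities(ds.localities)
M = overlap_matrix(ranges)
res_overlap = permutation_test(M, ds.clades, n_permutations=9999, seed=1,
                               statistic_name="range overlap proportion")
print()
print(res_overlap.report())

summaries = summarize_species(ds.specimens)
D = mahalanobis_matrix(summaries, pooled_within_covariance(summaries))
res_morpho = permutation_test(D, ds.clades, n_permutations=9999, seed=2,
                              statistic_name="Mahalanobis D2")
print()
print(res_morpho.report())

print("\nThe vicariant clade shows near-zero within-clade overlap and low "
      "D2; the sympatric clade shows high overlap and large D2 - the "
      "signature separating geographic from adaptive speciation.")
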