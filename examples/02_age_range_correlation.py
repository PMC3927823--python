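"""Nested average of range overlaps at every node of a dated tree.

The age-range-correlation table asks whether older splits show more range
overlap than younger ones: under vicariant speciation young nodes separate
allopatric ranges and overlap accumulates only with time, so a positive
age-overlap slope is the allopatric expectation.
"""

import numpy as np

from specmode import OverlapMatrix, arc_table, tree_from_newick

tree = tree_from_newick("(((A:1,B:1):1.5,C:2.5):1.5,(D:2,E:2):2);")

ids = ["A", "B", "C", "D", "E"]
V = np.eye(5)
pairs = {("A", "B"): 0.1, ("A", "C"): 0.5, ("B", "C"): 0.3,
         ("D", "E"): 0.2, ("A", "D"): 0.9, ("A", "E"): 0.8,
         ("B", "D"): 0.7, ("B", "E"): 0.9, ("C", "D"): 0.8,
         ("C", "E"): 0.7}
for (a, b), v in pairs.items():
    V[ids.index(a), ids.index(b)] = V[ids.index(b), ids.index(a)] = v
np.fill_diagonal(V, 1.0)
M = OverlapMatrix(ids, V)

records, reg = arc_table(tree, M, regression=True)
print("node      age (Ma)  nested overlap")
for r in records:
    print(f"{r.node_id:>4} {r.age:>12.2f} {r.nested_overlap:>15.3f}")
print(f"\nOLS of overlap on age: slope {reg.slope:.3f}, "
      f"intercept {reg.intercept:.3f}, r^2 {reg.r_squared:.3f}")
print("Here the oldest node (the root) shows the highest nested overlap "
      "and the youngest cherries the lowest - the vicariance-then-"
      "secondary-contact pattern.")
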