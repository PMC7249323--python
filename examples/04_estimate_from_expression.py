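"""Full pipeline on simulated expression: estimate weights and tree,
then score a clustering.

A five-type population is simulated from a known hierarchy; W1/W0 and
the reference dendrogram are estimated from the labelled expression
matrix exactly as they would be on real data, and a deliberately
imperfect clustering (six cells of one type merged into its sibling)
is scored with every metric.
"""

import numpy as np

import hiermetrics as hm

tree = hm.ReferenceTree(
    ("T1", "T2", "T3", "T4", "T5"),
    np.array([[0, 1], [5, 2], [6, 3], [7, 4]]),
    np.array([0.25, 0.5, 0.75, 1.0]),
)
pop = hm.simulate_population(hm.SimulationConfig(tree=tree, seed=2024))

clust = hm.perturb_clustering(pop.labels, "merge_siblings", tree=tree,
                              pair=("T2", "T1"), magnitude=6)

report = hm.compute_metrics(pop.labels, clust, expr=pop.expression,
                            n_top_genes=1000)
print("estimated from", pop.expression.n_genes, "genes x",
      pop.expression.n_cells, "cells")
for name in ("RI", "ARI", "wRI", "wPPV", "wNPV", "MI", "NMI", "wMI", "wNMI"):
    print(f"  {name:>5} = {getattr(report, name):.4f}")
print("\nThe weighted scores sit above their classical counterparts: "
      "merging the two closest types is the mildest possible mistake, "
      "and the estimated hierarchy knows it.")
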