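"""A miniature ensemble study: assemble a handful of networks across the
kernel sweep, measure all ten observables and rank-correlate them.

The full study uses hundreds of networks; this example keeps the counts
tiny so it runs in about a minute.
"""

from mutunet import (build_metrics_table, cluster_metrics, generate_ensemble,
                     spearman_matrix)

logs = generate_ensemble({"small": 6}, seed=11)
table = build_metrics_table(logs, propagule_fraction=0.10, mode=1, seed=11)

print(table[["SPE", "CON", "NEST", "MOD", "RES", "ROB", "DIS",
             "INVb", "INVn", "IMP"]].round(3).to_string())

r, p = spearman_matrix(table)
print("\nSpearman r (architecture vs invasibility):")
print(f"  r(MOD, INVb) = {r.loc['MOD', 'INVb']:+.2f}")
print(f"  r(MOD, SPE)  = {r.loc['MOD', 'SPE']:+.2f}")
print(f"  r(CON, ROB)  = {r.loc['CON', 'ROB']:+.2f}")

best_k, labels, variance, _ = cluster_metrics(r, seed=11)
print(f"\nk-means on the metric MDS embedding: best k = {best_k} "
      f"({100 * variance[best_k]:.1f}% variance explained)")
print(labels.to_string())

# At full ensemble size the metrics separate into an architecture group
# (SPE, CON, MOD), a stability group (RES, ROB, DIS, INVb) and a residual
# group around nestedness and the invasion outcomes.
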