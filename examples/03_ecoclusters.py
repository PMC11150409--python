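"""Infer eco-clusters from a phylotype table and score them against truth.

Dominant phylotypes (top 10% by mean abundance, present in more than half
the sites) are screened for habitat preference with a random forest
(>= 30% out-of-bag variance explained), grouped by semi-partial Spearman
correlation + average-linkage clustering, and named by their members' modal
preferences.
"""

from sklearn.metrics import adjusted_rand_score

import necromap as nm
from necromap import synthetic as S

env = S.generate_environment(80, seed=1)
table, truth = S.generate_phylotypes(env, 100, seed=2)

dominant = nm.select_dominant_phylotypes(table)
print(f"dominant phylotypes: {len(dominant)} of {table.shape[1]}")

pref = nm.screen_habitat_preference(table, dominant, env, seed=3)
print(pref.round(1).to_string(index=False))
print("-> variance_explained is the RF out-of-bag R2 (%); only phylotypes "
      ">= 30% are kept.")

clusters = nm.cluster_phylotypes(pref, table, env)
print(f"\ninferred eco-clusters: {clusters.names}")
kept = pref.loc[pref["kept"], "phylotype"].tolist()
ari = adjusted_rand_score([truth.cluster_membership[p] for p in kept],
                          [clusters.assignments[p] for p in kept])
print(f"adjusted Rand index vs planted membership: {ari:.2f} "
      "(1.0 = perfect recovery)")

abund = nm.cluster_relative_abundance(table, clusters)
print("\nper-site cluster relative abundance (first 5 sites):")
print(abund.head().round(3))
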