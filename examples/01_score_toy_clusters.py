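"""Score a tiny hand-built set of within-complex clusters.

Builds an interaction table for three small protein complexes, groups
the interactions into clusters and prints beta (signed count purity) per
cluster plus the population MCI and sMCI.
"""

import pandas as pd

from mcindex import (GeneSetCatalog, InteractionSet, build_within_clusters,
                     score_population)

frame = pd.DataFrame(
    [
        # OST-like complex: consistently negative interactions
        ("OST1", "OST2", -0.21, 0.001), ("OST1", "OST3", -0.15, 0.004),
        ("OST2", "OST3", -0.33, 0.002),
        # ribosome-like complex: mostly positive
        ("RPL1", "RPL2", 0.12, 0.01), ("RPL1", "RPL3", 0.18, 0.02),
        ("RPL2", "RPL3", -0.09, 0.03),
        # a balanced complex
        ("MIX1", "MIX2", 0.2, 0.01), ("MIX3", "MIX4", -0.2, 0.01),
    ],
    columns=["gene_a", "gene_b", "epsilon", "p_value"],
)
interactions = InteractionSet(frame, cutoff_level="lenient",
                              pair_policy="unordered-collapsed")

catalog = GeneSetCatalog({
    "OST": {"OST1", "OST2", "OST3"},
    "RIBOSOME": {"RPL1", "RPL2", "RPL3"},
    "MIXED": {"MIX1", "MIX2", "MIX3", "MIX4"},
})

clusters = build_within_clusters(interactions, catalog, min_interactions=2)
pop = score_population(clusters)

for score in pop.per_cluster:
    print(f"{score.cluster_id:18s} n={score.weight}  "
          f"beta={score.beta:+.3f}  beta_strength={score.beta_strength:+.3f}")
print(f"\nMCI  = {pop.mci:.4f}   (count-weighted mean of |beta|; 1 = pure)")
print(f"sMCI = {pop.smci:.4f}   (same, using epsilon-magnitude purity)")
# beta = -1 for the pure-negative complex, +1/3 for the 2:1 positive one,
# and 0 for the balanced one; MCI weighs them by interaction count.
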