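"""Full signaling-network workflow on a synthetic stand-in network.

Generates a random directed network plus an annotation set planted to be
enriched outside the NFD group (the pattern reported for essential,
disease, and drug-target genes in human signaling networks), then runs the
three downstream analyses: NFD vs non-NFD group comparison, γ-threshold
sweep, and the degree-preserving rewiring null model.
"""

import numpy as np

from fblnet import (
    GeneAnnotation,
    GeneratorConfig,
    classify_nodes,
    compare_groups,
    empirical_percentile,
    gamma,
    generate_random_network,
    rewired_control,
    threshold_sweep,
)

net = generate_random_network(GeneratorConfig(n_nodes=300, n_edges=520, seed=77))
cls = classify_nodes(net)
rng = np.random.default_rng(77)

# plant "important" genes preferentially outside the NFD group
non_nfd, nfd = sorted(net.nodes - cls.is_nfd), sorted(cls.is_nfd)
annotated = frozenset(rng.choice(non_nfd, size=60, replace=False)) | frozenset(
    rng.choice(nfd, size=10, replace=False)
)
ann = GeneAnnotation({"important": annotated})

r = compare_groups(cls, net.nodes, ann, "important")
print(f"NFD group: {r.k_nfd}/{r.n_nfd} annotated ({r.prop_nfd:.3f})")
print(f"non-NFD  : {r.k_non_nfd}/{r.n_non_nfd} annotated ({r.prop_non_nfd:.3f})")
print(f"two-proportion z-test p = {r.p_value:.2e}")

sweep = threshold_sweep(gamma(net), ann)
print("\ngamma threshold sweep (first/last rows):")
print(sweep.iloc[[0, -1]].to_string(index=False))

null = rewired_control(net, ann, n_random=20, seed=7)["diff_important"]
observed = r.prop_non_nfd - r.prop_nfd
pct = empirical_percentile(observed, null.tolist())
print(f"\nobserved group difference {observed:.3f} sits at the "
      f"{100 * pct:.0f}th percentile of the rewired null "
      f"(null mean {null.mean():.3f})")

# A high percentile says the annotation tracks the real wiring's
# feedback-loop structure, not just the degree sequence.
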