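"""Classify the nodes of a small signaling motif by feedback-loop involvement.

The fixture network is a -> b <-> c -> d -> e: a linear cascade feeding a
two-node feedback loop that drives a downstream tail.
"""

from fblnet import classify_nodes, fbl_nodes, toy_network_t1

net = toy_network_t1()
cls = classify_nodes(net)

print("edges:", sorted(net.edges))
print("feedback-loop nodes:", sorted(fbl_nodes(net)))
print(cls.to_tsv(sorted(net.nodes)))

# NFU nodes (here: a) see no feedback loop upstream, so their Boolean value
# always freezes.  NFD nodes (d, e) have no loop downstream, so flipping
# them can never change the network's attractor.  b and c sit on the loop
# and are neither.
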