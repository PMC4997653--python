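"""Perturbation-sustainable probability γ: which nodes can seed lasting change?

γ(v) is the best-case probability that a single-bit flip at v keeps
propagating until it reaches a feedback loop that can recirculate it:
the maximum over downstream paths of the product of reciprocal in-degrees
along the path, zero when no loop is reachable (NFD nodes).
"""

from fblnet import classify_nodes, gamma, path_probability, toy_network_t1

net = toy_network_t1()
nfd = classify_nodes(net).is_nfd

print("per-node gamma (NFD nodes marked):")
for v, g in sorted(gamma(net).items()):
    tag = "  <- NFD" if v in nfd else ""
    print(f"  {v}: {g:.3f}{tag}")

print("single-path survival probabilities from a:")
print("  a->b     :", path_probability(net, ["a", "b"]))       # 1/deg(b) = 1/2
print("  a->b->c  :", path_probability(net, ["a", "b", "c"]))  # 1/2 * 1/1

# gamma(b)=1: b feeds c (in-degree 1, on the loop) so a flip at b reaches
# the loop with certainty.  gamma(d)=gamma(e)=0: nothing downstream of d
# can recirculate a perturbation, matching their NFD status.
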