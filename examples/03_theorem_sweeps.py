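"""Empirically verify the two structural theorems on random Boolean networks.

Theorem-style guarantees: (1) every NFU node freezes to a constant value in
every attractor; (2) flipping the initial value of a non-source NFD node
never changes the attractor.  Both hold for arbitrary update functions, so
a sweep over random networks with random truth tables, exhaustive over all
initial states, must find zero violations.
"""

from fblnet import GeneratorConfig, verify_corollary, verify_theorem1, verify_theorem2

cfg = GeneratorConfig(n_nodes=8, n_edges=14, seed=0)
print("NFU frozenness:   ", verify_theorem1(cfg, n_networks=50, seed=1).summary())
print("NFD robustness:   ", verify_theorem2(cfg, n_networks=50, seed=1).summary())

dag = GeneratorConfig(n_nodes=8, n_edges=14, acyclic=True, seed=0)
print("acyclic => fixed points:", verify_corollary(dag, n_networks=50, seed=1).summary())

# PASS means no network, node, initial-state combination violated the
# property; a single violation would indicate an implementation bug, since
# the properties are proven for all update functions and initial states.
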