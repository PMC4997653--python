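"""Synchronous Boolean dynamics of a mutual-inhibition switch.

Two genes repress each other; each updates to the negation of its input.
The 4-state space splits into two fixed points (the bistable switch
states) and one period-2 oscillation.
"""

from fblnet import (
    BooleanNetwork,
    DirectedNetwork,
    attractors_exhaustive,
    find_attractor,
)

net = DirectedNetwork.from_edges([("a", "b"), ("b", "a")])
bn = BooleanNetwork(
    net=net, inputs={"a": ("b",), "b": ("a",)}, tables={"a": (1, 0), "b": (1, 0)}
)

for s0 in [(0, 1), (0, 0)]:
    att = find_attractor(bn, s0)
    print(f"from {s0}: transient={att.transient} period={att.period} "
          f"cycle={att.states}")

print("all attractors with basin sizes:")
for attractor, basin in sorted(attractors_exhaustive(bn).items()):
    print(f"  {attractor}  basin={basin}")

# The two fixed points (0,1) and (1,0) are the switch's stable states; the
# (0,0) <-> (1,1) cycle is the synchronous-update oscillation between them.
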