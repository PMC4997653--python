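"""Synchronous Boolean network dynamics: states, trajectories, attractors.

Each node carries a Boolean value; at every discrete time step all
non-source nodes are updated simultaneously, node ``i`` reading its next
value from a truth table over the current values of its input nodes:

    v_i(t+1) = f_i(v_{i1}(t), ..., v_{ik}(t))

Source nodes (in-degree 0) have no update function; their state stays at
the initial value forever.  Every trajectory of the finite state space
eventually enters a fixed point (period 1) or a limit cycle (period p > 1)
— the *attractor*.  Two attractors are *equivalent* when one is a cyclic
rotation of the other, and a node set is *frozen* in an attractor when its
values are constant across the whole cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .network import DirectedNetwork, source_nodes

State = tuple[int, ...]

#: node-count cap for exhaustive attractor enumeration (2^N initial states)
EXHAUSTIVE_MAX_NODES = 20


@dataclass(frozen=True)
class BooleanNetwork:
    """A directed network plus one truth table per non-source node.

    ``node_order`` fixes the coordinate order of state vectors (sorted node
    identifiers by default).  For a node with inputs ``(w_1, ..., w_k)``
    (sorted by identifier), ``tables[node]`` holds 2^k output bits indexed
    by the input tuple read as a binary number, most significant bit =
    first input: row ``0b101`` is (w_1=1, w_2=0, w_3=1).
    """

    net: DirectedNetwork
    inputs: Mapping[str, tuple[str, ...]]
    tables: Mapping[str, tuple[int, ...]]
    node_order: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        order = self.node_order or tuple(sorted(self.net.nodes))
        object.__setattr__(self, "node_order", order)
        sources = source_nodes(self.net)
        for v in self.net.nodes:
            if v in sources:
                if v in self.tables:
                    raise ValueError(f"source node {v!r} must not have a truth table")
            else:
                k = len(self.inputs[v])
                if len(self.tables[v]) != 2**k:
                    raise ValueError(
                        f"node {v!r}: truth table has {len(self.tables[v])} entries, "
                        f"expected 2^{k}"
                    )

    @property
    def n(self) -> int:
        return len(self.node_order)

    @property
    def sources(self) -> frozenset[str]:
        return source_nodes(self.net)

    def index_of(self, v: str) -> int:
        return self.node_order.index(v)


@dataclass(frozen=True)
class Attractor:
    """Limit cycle of a synchronous trajectory.

    ``transient`` is the number of steps before the cycle is entered,
    ``period`` the cycle length, ``states`` the cycle in trajectory order.
    ``canonical_form`` rotates the cycle to start at its lexicographically
    smallest state, giving a hashable identity independent of entry point.
    """

    transient: int
    period: int
    states: tuple[State, ...]

    @property
    def canonical_form(self) -> tuple[State, ...]:
        i = min(range(self.period), key=lambda j: self.states[j])
        return self.states[i:] + self.states[:i]


def _compiled(bn: BooleanNetwork):
    """Per-node update plan: (is_source, input positions, table)."""
    pos = {v: i for i, v in enumerate(bn.node_order)}
    sources = bn.sources
    plan = []
    for v in bn.node_order:
        if v in sources:
            plan.append((True, (), ()))
        else:
            plan.append((False, tuple(pos[w] for w in bn.inputs[v]), bn.tables[v]))
    return plan


def step(bn: BooleanNetwork, s: State) -> State:
    """One synchronous update; source coordinates are copied unchanged."""
    if len(s) != bn.n:
        raise ValueError(f"state length {len(s)} != node count {bn.n}")
    nxt = []
    for (is_src, positions, table), cur in zip(_compiled(bn), s):
        if is_src:
            nxt.append(cur)
        else:
            idx = 0
            for p in positions:
                idx = (idx << 1) | s[p]
            nxt.append(table[idx])
    return tuple(nxt)


def trajectory(bn: BooleanNetwork, s0: State, n_steps: int) -> list[State]:
    """States v(0) ... v(n_steps) along the synchronous trajectory."""
    out = [tuple(s0)]
    for _ in range(n_steps):
        out.append(step(bn, out[-1]))
    return out


def find_attractor(bn: BooleanNetwork, s0: State) -> Attractor:
    """Iterate from ``s0`` until a state repeats; return the limit cycle.

    Termination is guaranteed: the state space has 2^N elements.
    """
    seen: dict[State, int] = {}
    path: list[State] = []
    s = tuple(s0)
    t = 0
    while s not in seen:
        seen[s] = t
        path.append(s)
        s = step(bn, s)
        t += 1
    first = seen[s]
    return Attractor(transient=first, period=t - first, states=tuple(path[first:]))


def attractors_exhaustive(
    bn: BooleanNetwork, max_nodes: int = EXHAUSTIVE_MAX_NODES
) -> dict[tuple[State, ...], int]:
    """All attractors over the full 2^N initial-state space, with basin sizes.

    Returns a map ``canonical_form -> basin size``; basin sizes sum to 2^N.
    Raises when the network exceeds ``max_nodes`` — sample initial states
    with :func:`find_attractor` instead at that scale.
    """
    if bn.n > max_nodes:
        raise ValueError(
            f"exhaustive enumeration capped at {max_nodes} nodes (got {bn.n}); "
            "use find_attractor on sampled initial states"
        )
    label = label_states(bn)
    basins: dict[tuple[State, ...], int] = {}
    for attr in label:
        basins[attr] = basins.get(attr, 0) + 1
    return basins


def label_states(bn: BooleanNetwork) -> list[tuple[State, ...]]:
    """Canonical attractor of every initial state, indexed by encoded state.

    Two initial states converge to equivalent attractors iff their labels
    are identical; this is the workhorse behind exhaustive robustness and
    frozenness sweeps.
    """
    succ = transition_map(bn)
    label: dict[int, tuple[State, ...]] = {}
    for s0 in range(2**bn.n):
        if s0 in label:
            continue
        # walk until a labeled state or a state revisited within this walk
        path: list[int] = []
        pos: dict[int, int] = {}
        s = s0
        while s not in label and s not in pos:
            pos[s] = len(path)
            path.append(s)
            s = succ[s]
        if s in label:
            attr = label[s]
        else:
            cyc = path[pos[s]:]
            states = tuple(_decode(x, bn.n) for x in cyc)
            attr = Attractor(transient=0, period=len(cyc), states=states).canonical_form
        for x in path:
            label[x] = attr
    return [label[x] for x in range(2**bn.n)]


def transition_map(bn: BooleanNetwork) -> list[int]:
    """Successor of every state, states encoded as integers (bit i = coordinate i,
    most significant bit = first node in ``node_order``)."""
    n = bn.n
    plan = _compiled(bn)
    out = []
    for x in range(2**n):
        s = _decode(x, n)
        nxt = 0
        for (is_src, positions, table), cur in zip(plan, s):
            if is_src:
                bit = cur
            else:
                idx = 0
                for p in positions:
                    idx = (idx << 1) | s[p]
                bit = table[idx]
            nxt = (nxt << 1) | bit
        out.append(nxt)
    return out


def _encode(s: State) -> int:
    x = 0
    for b in s:
        x = (x << 1) | b
    return x


def _decode(x: int, n: int) -> State:
    return tuple((x >> (n - 1 - i)) & 1 for i in range(n))


def is_frozen(
    att: Attractor, subset: Iterable[str], node_order: Sequence[str]
) -> bool:
    """True iff every node in ``subset`` holds one constant value across the cycle."""
    idx = []
    for v in subset:
        if v not in node_order:
            raise KeyError(f"unknown node {v!r}")
        idx.append(node_order.index(v))
    return all(
        len({st[i] for st in att.states}) == 1 for i in idx
    )


def attractors_equivalent(a: Attractor, b: Attractor) -> bool:
    """Equal period and state sequences matching up to a cyclic time offset."""
    return a.period == b.period and a.canonical_form == b.canonical_form


def load_functions(path: str | Path, net: DirectedNetwork) -> BooleanNetwork:
    """Read Boolean update functions from a YAML file.

    Format: one mapping per non-source node::

        node_name:
          inputs: [w1, w2]     # must equal the node's network inputs
          outputs: "0110"      # 2^k bits; row index = input tuple read as a
                               # binary number, MSB = first listed input

    Source nodes must be absent.
    """
    raw = yaml.safe_load(Path(path).read_text())
    inputs: dict[str, tuple[str, ...]] = {}
    tables: dict[str, tuple[int, ...]] = {}
    actual_inputs = {v: set() for v in net.nodes}
    for u, v in net.edges:
        actual_inputs[v].add(u)
    for v, entry in raw.items():
        if v not in net.nodes:
            raise ValueError(f"function for unknown node {v!r}")
        ins = tuple(entry["inputs"])
        if set(ins) != actual_inputs[v]:
            raise ValueError(
                f"node {v!r}: declared inputs {sorted(ins)} != network inputs "
                f"{sorted(actual_inputs[v])}"
            )
        bits = str(entry["outputs"])
        if set(bits) - {"0", "1"} or len(bits) != 2 ** len(ins):
            raise ValueError(f"node {v!r}: outputs must be a 0/1 string of length 2^k")
        inputs[v] = ins
        tables[v] = tuple(int(b) for b in bits)
    return BooleanNetwork(net=net, inputs=inputs, tables=tables)


def dump_functions(bn: BooleanNetwork, path: str | Path) -> None:
    """Write the update functions in the format read by :func:`load_functions`."""
    out = {}
    for v in sorted(bn.tables):
        out[v] = {
            "inputs": list(bn.inputs[v]),
            "outputs": "".join(str(b) for b in bn.tables[v]),
        }
    Path(path).write_text(yaml.safe_dump(out, sort_keys=True))
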