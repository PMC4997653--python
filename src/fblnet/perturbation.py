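"""Initial-state perturbation robustness and the perturbation-sustainable probability γ.

An initial-state perturbation flips one node's starting value; the network
is *robust* against it when the original and perturbed trajectories reach
equivalent attractors.  Two structural theorems govern this:

1. every NFU node is eventually frozen, from any initial state and for
   arbitrary update functions, and
2. the network is robust against any perturbation of a non-source NFD node.

Both are verified here empirically over seeded random Boolean-network
ensembles (exhaustive over all initial states at small n).

For nodes that are not NFD, the *perturbation-sustainable probability*
γ(v) estimates how likely a flip at v keeps propagating: along a downstream
path v u_1 … u_L, each hop survives with probability 1/d_i (the reciprocal
in-degree of u_i, assuming the inputs of u_i influence it evenly), and the
path sustains the effect only if it meets a feedback-loop node that can
recirculate it.  γ(v) is the maximum of that product over all downstream
paths touching an FBL-involved node; γ(v) = 0 exactly when v is NFD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx

from .boolean import (
    Attractor,
    BooleanNetwork,
    State,
    attractors_equivalent,
    find_attractor,
    label_states,
    _encode,
)
from .network import (
    BRUTEFORCE_MAX_NODES,
    DirectedNetwork,
    _simple_paths_from,
    classify_nodes,
    fbl_nodes,
    in_degrees,
)
from .synthetic import GeneratorConfig, generate_random_network, random_boolean_functions


@dataclass(frozen=True)
class RobustnessResult:
    node: str
    initial_state: State
    robust: bool
    attractor_original: Attractor
    attractor_perturbed: Attractor


@dataclass(frozen=True)
class TheoremReport:
    """Outcome of an empirical theorem sweep over random Boolean networks."""

    networks_tested: int
    states_per_network: str
    violations: tuple[tuple[int, str, State], ...] = field(default_factory=tuple)

    @property
    def passed(self) -> bool:
        return not self.violations

    def summary(self) -> str:
        status = "PASS" if self.passed else f"FAIL ({len(self.violations)} violations)"
        return (
            f"{self.networks_tested} networks, {self.states_per_network} initial "
            f"states each: {status}"
        )


def perturb_initial(s: State, v: str, node_order: tuple[str, ...]) -> State:
    """Flip the coordinate of ``v``; an involution at Hamming distance 1."""
    if v not in node_order:
        raise KeyError(f"unknown node {v!r}")
    i = node_order.index(v)
    return s[:i] + (1 - s[i],) + s[i + 1 :]


def is_robust(bn: BooleanNetwork, s0: State, v: str) -> RobustnessResult:
    """Compare the attractors reached from ``s0`` and from ``s0`` with ``v`` flipped."""
    a = find_attractor(bn, s0)
    b = find_attractor(bn, perturb_initial(s0, v, bn.node_order))
    return RobustnessResult(
        node=v,
        initial_state=tuple(s0),
        robust=attractors_equivalent(a, b),
        attractor_original=a,
        attractor_perturbed=b,
    )


def _ensemble(cfg: GeneratorConfig, n_networks: int, seed: int):
    """Yield (network index, BooleanNetwork) with per-network derived seeds."""
    for k in range(n_networks):
        net_seed = (seed * 1_000_003 + 2 * k) % (2**31)
        fn_seed = (seed * 1_000_003 + 2 * k + 1) % (2**31)
        cfg_k = GeneratorConfig(
            n_nodes=cfg.n_nodes,
            n_edges=cfg.n_edges,
            allow_self_loops=cfg.allow_self_loops,
            acyclic=cfg.acyclic,
            seed=net_seed,
        )
        net = generate_random_network(cfg_k)
        yield k, random_boolean_functions(net, seed=fn_seed)


def verify_theorem1(
    cfg: GeneratorConfig, n_networks: int = 200, seed: int = 0
) -> TheoremReport:
    """Every NFU node must be frozen in the attractor of every initial state.

    Exhaustive over all 2^N initial states (N capped by the exhaustive
    enumerator).  Any violation is an implementation bug, not a borderline
    statistic: the property is a theorem.
    """
    violations: list[tuple[int, str, State]] = []
    for k, bn in _ensemble(cfg, n_networks, seed):
        cls = classify_nodes(bn.net)
        nfu_idx = [bn.node_order.index(v) for v in sorted(cls.is_nfu)]
        labels = label_states(bn)
        seen: set[int] = set()
        for s0 in range(2**bn.n):
            attr = labels[s0]
            if id(attr) in seen:
                continue
            seen.add(id(attr))
            for v, i in zip(sorted(cls.is_nfu), nfu_idx):
                if len({st[i] for st in attr}) != 1:
                    violations.append((k, v, attr[0]))
    return TheoremReport(
        networks_tested=n_networks,
        states_per_network="exhaustive",
        violations=tuple(violations),
    )


def verify_theorem2(
    cfg: GeneratorConfig, n_networks: int = 200, seed: int = 0
) -> TheoremReport:
    """Flipping any non-source NFD node must never change the attractor.

    Uses an exhaustive labeling of the state space: robustness of the flip
    at ``v`` from state ``s`` is label(s) == label(s with v flipped), which
    is exactly attractor equivalence.
    """
    violations: list[tuple[int, str, State]] = []
    for k, bn in _ensemble(cfg, n_networks, seed):
        cls = classify_nodes(bn.net)
        targets = sorted(cls.is_nfd - cls.is_source)
        if not targets:
            continue
        labels = label_states(bn)
        n = bn.n
        for v in targets:
            bit = 1 << (n - 1 - bn.node_order.index(v))
            for s0 in range(2**n):
                if labels[s0] is not labels[s0 ^ bit] and labels[s0] != labels[s0 ^ bit]:
                    violations.append((k, v, _decode_state(s0, n)))
    return TheoremReport(
        networks_tested=n_networks,
        states_per_network="exhaustive",
        violations=tuple(violations),
    )


def verify_corollary(
    cfg: GeneratorConfig, n_networks: int = 200, seed: int = 0
) -> TheoremReport:
    """In a feedback-loop-free network every attractor is a fixed point."""
    if not cfg.acyclic:
        raise ValueError("corollary sweep requires an acyclic generator config")
    violations: list[tuple[int, str, State]] = []
    for k, bn in _ensemble(cfg, n_networks, seed):
        for attr in set(map(tuple, label_states(bn))):
            if len(attr) != 1:
                violations.append((k, "<period>", attr[0]))
    return TheoremReport(
        networks_tested=n_networks,
        states_per_network="exhaustive",
        violations=tuple(violations),
    )


def _decode_state(x: int, n: int) -> State:
    return tuple((x >> (n - 1 - i)) & 1 for i in range(n))


def path_probability(net: DirectedNetwork, path: list[str] | tuple[str, ...]) -> float:
    """Probability that a flip at the path's first node survives the whole path.

    For a downstream path v u_1 … u_L the product is Π 1/d_i over the in-
    degrees of u_1 … u_L, provided some u_i is FBL-involved (only then can
    the effect recirculate); otherwise 0.
    """
    path = list(path)
    if len(path) < 2:
        raise ValueError("a path needs length >= 1 (at least two nodes)")
    edge_ok = all((path[i], path[i + 1]) in net.edges for i in range(len(path) - 1))
    interior = path[1:-1]
    simple_ok = len(set(path[1:])) == len(path[1:]) and (
        path[0] not in interior
    )
    if not edge_ok or not simple_ok:
        raise ValueError(f"not a valid downstream path: {path}")
    fbl = fbl_nodes(net)
    if not any(u in fbl for u in path[1:]):
        return 0.0
    deg = in_degrees(net)
    prob = 1.0
    for u in path[1:]:
        prob /= deg[u]
    return prob


def gamma(net: DirectedNetwork) -> dict[str, float]:
    """Perturbation-sustainable probability of every node.

    γ(v) = max over downstream paths of v of the path survival probability.
    Extending a path past its first FBL-involved node multiplies by factors
    ≤ 1, so the maximum is attained by a path ending at an FBL-involved
    node, and the max-product search becomes a shortest-path problem on
    edge weights ln d(target) ≥ 0 (an optimal walk is automatically
    simple).  Computed for all nodes at once by multi-source Dijkstra from
    the FBL-involved nodes on the reversed graph; a node on a cycle is
    scored from its outgoing paths only (the product starts at its first
    successor).
    """
    fbl = fbl_nodes(net)
    deg = in_degrees(net)
    out: dict[str, float] = {v: 0.0 for v in net.nodes}
    if not fbl:
        return out
    rg = nx.DiGraph()
    rg.add_nodes_from(net.nodes)
    for u, v in net.edges:
        # reversed edge v->u; traversal cost = entering v in forward direction
        w = math.log(deg[v])
        if not rg.has_edge(v, u) or rg[v][u]["weight"] > w:
            rg.add_edge(v, u, weight=w)
    dist = nx.multi_source_dijkstra_path_length(rg, sources=set(fbl), weight="weight")
    for u, v in net.edges:
        if v in dist:
            cand = math.exp(-(math.log(deg[v]) + dist[v]))
            if cand > out[u]:
                out[u] = cand
    return out


def gamma_bruteforce(net: DirectedNetwork, v: str) -> float:
    """γ(v) by literal definition: enumerate every downstream path, take the max.

    Test oracle only; guarded to small networks.  Paths closing a cycle
    back to ``v`` count as downstream paths (they are feedback loops).
    """
    if net.n_nodes > BRUTEFORCE_MAX_NODES:
        raise ValueError(
            f"brute-force gamma limited to {BRUTEFORCE_MAX_NODES} nodes "
            f"(got {net.n_nodes})"
        )
    if v not in net.nodes:
        raise KeyError(f"unknown node {v!r}")
    fbl = fbl_nodes(net)
    deg = in_degrees(net)
    best = 0.0
    for path in _simple_paths_from(net, v):
        if any(u in fbl for u in path[1:]):
            prob = 1.0
            for u in path[1:]:
                prob /= deg[u]
            best = max(best, prob)
    return best
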