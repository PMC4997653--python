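"""Random network and Boolean-function generators, plus fixed toy fixtures.

These supply the ensembles used to verify the frozenness and robustness
theorems empirically (uniform random digraphs with random truth tables),
the degree-preserving rewiring null model used to show that functional
gene classes are not randomly placed with respect to feedback-loop
structure, and a small hand-checkable fixture network.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .network import DirectedNetwork, source_nodes
from .boolean import BooleanNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneratorConfig:
    """Settings for :func:`generate_random_network`."""

    n_nodes: int
    n_edges: int
    allow_self_loops: bool = False
    acyclic: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        cap = self.n_nodes * (self.n_nodes - 1)
        if self.allow_self_loops:
            cap += self.n_nodes
        if self.acyclic:
            cap = self.n_nodes * (self.n_nodes - 1) // 2
        if self.n_edges > cap:
            raise ValueError(
                f"{self.n_edges} edges infeasible for {self.n_nodes} nodes "
                f"(max {cap} under these settings)"
            )


def _node_labels(n: int) -> list[str]:
    width = len(str(n - 1)) if n > 1 else 1
    return [f"v{i:0{width}d}" for i in range(n)]


def generate_random_network(cfg: GeneratorConfig) -> DirectedNetwork:
    """Uniformly sample ``n_edges`` distinct ordered node pairs.

    With ``acyclic=True``, only pairs respecting a random topological order
    of the nodes are eligible, so the result is guaranteed to be a DAG
    (hence free of feedback loops).
    """
    rng = np.random.default_rng(cfg.seed)
    labels = _node_labels(cfg.n_nodes)
    if cfg.acyclic:
        order = rng.permutation(cfg.n_nodes)
        rank = {labels[i]: int(order[i]) for i in range(cfg.n_nodes)}
        candidates = [
            (a, b)
            for a in labels
            for b in labels
            if rank[a] < rank[b]
        ]
    else:
        candidates = [
            (a, b)
            for a in labels
            for b in labels
            if a != b or cfg.allow_self_loops
        ]
    idx = rng.choice(len(candidates), size=cfg.n_edges, replace=False)
    edges = [candidates[int(i)] for i in idx]
    return DirectedNetwork.from_edges(edges, extra_nodes=labels)


def random_boolean_functions(net: DirectedNetwork, seed: int = 0) -> BooleanNetwork:
    """Attach a uniformly random truth table to every non-source node.

    Each of the 2^k output bits is a fair coin flip.  Input ordering is the
    sorted node identifiers, recorded in the returned object.
    """
    rng = np.random.default_rng(seed)
    ins: dict[str, set[str]] = {v: set() for v in net.nodes}
    for u, v in net.edges:
        ins[v].add(u)
    sources = source_nodes(net)
    inputs: dict[str, tuple[str, ...]] = {}
    tables: dict[str, tuple[int, ...]] = {}
    for v in sorted(net.nodes):
        if v in sources:
            continue
        ordered = tuple(sorted(ins[v]))
        inputs[v] = ordered
        bits = rng.integers(0, 2, size=2 ** len(ordered))
        tables[v] = tuple(int(b) for b in bits)
    return BooleanNetwork(net=net, inputs=inputs, tables=tables)


def rewire_preserving_degrees(
    net: DirectedNetwork, n_swaps: int, seed: int = 0, max_attempt_factor: int = 100
) -> DirectedNetwork:
    """Randomize wiring by directed double-edge swaps; degrees are conserved.

    A swap replaces edges (a→b, c→d) with (a→d, c→b), rejected when it
    would create a duplicate edge or a new self-loop, so every node keeps
    its exact in- and out-degree.  Performs ``n_swaps`` successful swaps or
    gives up after ``max_attempt_factor * n_swaps`` attempts.  Edge signs
    travel with the source endpoint's new edge.
    """
    if net.n_edges < 2:
        raise ValueError("rewiring needs at least 2 edges")
    rng = np.random.default_rng(seed)
    edges = sorted(net.edges)
    edge_set = set(edges)
    sign = dict(net.sign)
    done = 0
    attempts = 0
    cap = max_attempt_factor * max(n_swaps, 1)
    while done < n_swaps and attempts < cap:
        attempts += 1
        i, j = rng.integers(0, len(edges), size=2)
        if i == j:
            continue
        a, b = edges[int(i)]
        c, d = edges[int(j)]
        if a == d or c == b:  # would create a self-loop
            continue
        if (a, d) in edge_set or (c, b) in edge_set:
            continue
        edge_set.discard((a, b))
        edge_set.discard((c, d))
        edge_set.add((a, d))
        edge_set.add((c, b))
        edges[int(i)] = (a, d)
        edges[int(j)] = (c, b)
        sa = sign.pop((a, b), "unknown")
        sc = sign.pop((c, d), "unknown")
        sign[(a, d)] = sa
        sign[(c, b)] = sc
        done += 1
    if attempts > done:
        logger.debug(
            "rewiring: %d successful swaps, %d rejected attempts", done, attempts - done
        )
    if done < n_swaps:
        logger.warning(
            "rewiring gave up after %d attempts with %d/%d swaps done",
            attempts, done, n_swaps,
        )
    return DirectedNetwork.from_edges(edge_set, extra_nodes=net.nodes, sign=sign)


def toy_network_t1() -> DirectedNetwork:
    """Five-node fixture: a → b ⇄ c → d → e.

    Hand-checkable ground truth: feedback-loop nodes {b, c}; sources {a};
    NFU = {a}; NFD = {d, e}; γ = (a: 0.5, b: 1.0, c: 0.5, d: 0, e: 0).
    """
    return DirectedNetwork.from_edges(
        [("a", "b"), ("b", "c"), ("c", "b"), ("c", "d"), ("d", "e")]
    )
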