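"""Directed network model, edge-list I/O, and feedback-loop-based node classification.

A biological signaling network is modeled as a directed graph G(V, E).  A
*feedback loop* (FBL) is a directed cycle; a node is *FBL-involved* if it
lies on at least one cycle (member of a strongly connected component of
size >= 2, or carries a self-loop, which is a length-1 cycle).  A node is

* **NFU** (no-FBL-in-upstream)  if no upstream path of the node passes
  through an FBL-involved node, and
* **NFD** (no-FBL-in-downstream) if no downstream path does.

A node lying on a cycle is itself both upstream and downstream of itself,
so it is neither NFU nor NFD.  In a fully acyclic network every node is
both.  NFU nodes freeze to values set by their upstream sources under any
synchronous Boolean dynamics, and perturbing a non-source NFD node never
changes the attractor; those dynamic consequences live in
:mod:`fblnet.boolean` and :mod:`fblnet.perturbation`.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

Sign = Literal["positive", "negative", "unknown"]

#: default mapping from SIF interaction tokens to edge signs
SIF_SIGN_TABLE: dict[str, Sign] = {
    "activates": "positive",
    "+": "positive",
    "inhibits": "negative",
    "-": "negative",
}

#: size guard for the literal-definition classifiers (simple-path enumeration)
BRUTEFORCE_MAX_NODES = 12


class ParseError(ValueError):
    """Raised for malformed edge-list input; carries the offending line number."""


@dataclass(frozen=True)
class DirectedNetwork:
    """A directed graph with opaque string node identifiers.

    Edges are set-valued (no duplicates); self-loops are permitted and count
    as length-1 feedback loops.  ``sign`` optionally annotates edges with an
    interaction sign; signs are carried through I/O and rewiring but never
    enter classification or scoring.
    """

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    sign: Mapping[tuple[str, str], Sign] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for u, v in self.edges:
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge ({u!r}, {v!r}) has an endpoint outside the node set")

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        extra_nodes: Iterable[str] = (),
        sign: Mapping[tuple[str, str], Sign] | None = None,
    ) -> "DirectedNetwork":
        edge_set = frozenset(edges)
        nodes = frozenset(itertools.chain(extra_nodes, *edge_set))
        return cls(nodes=nodes, edges=edge_set, sign=dict(sign or {}))

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class NodeClassification:
    """Per-node structural flags: source, FBL-involved, NFU, NFD."""

    is_source: frozenset[str]
    on_fbl: frozenset[str]
    is_nfu: frozenset[str]
    is_nfd: frozenset[str]

    def to_tsv(self, nodes_sorted: Iterable[str]) -> str:
        lines = ["node\tis_source\ton_fbl\tis_nfu\tis_nfd"]
        for v in nodes_sorted:
            lines.append(
                "\t".join(
                    [
                        v,
                        "1" if v in self.is_source else "0",
                        "1" if v in self.on_fbl else "0",
                        "1" if v in self.is_nfu else "0",
                        "1" if v in self.is_nfd else "0",
                    ]
                )
            )
        return "\n".join(lines) + "\n"


def read_edge_list(
    path: str | Path,
    dialect: Literal["two_column", "sif"] = "two_column",
    sign_table: Mapping[str, Sign] | None = None,
) -> DirectedNetwork:
    """Read a plain-text edge list into a :class:`DirectedNetwork`.

    ``two_column`` lines are ``source target``; ``sif`` lines are
    ``source interaction target`` with the interaction token mapped to a
    sign via ``sign_table`` (default: activates/+ -> positive,
    inhibits/- -> negative, anything else -> unknown).  Fields are
    whitespace- or tab-separated; lines starting with ``#`` and blank
    lines are skipped, except the directive ``# node: NAME`` which declares
    an isolated node (emitted by :func:`write_edge_list` so networks with
    edge-free nodes round-trip).  Duplicate edges are dropped (count logged).
    """
    path = Path(path)
    table = dict(SIF_SIGN_TABLE if sign_table is None else sign_table)
    n_fields = 2 if dialect == "two_column" else 3
    edges: set[tuple[str, str]] = set()
    sign: dict[tuple[str, str], Sign] = {}
    n_dupes = 0
    n_data_lines = 0
    isolated: set[str] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith("# node:"):
                isolated.add(line.removeprefix("# node:").strip())
                n_data_lines += 1
                continue
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != n_fields:
                raise ParseError(
                    f"{path}:{lineno}: expected {n_fields} fields for dialect "
                    f"{dialect!r}, got {len(fields)}: {line!r}"
                )
            n_data_lines += 1
            if dialect == "two_column":
                u, v = fields
                s: Sign = "unknown"
            else:
                u, interaction, v = fields
                s = table.get(interaction, "unknown")
            if (u, v) in edges:
                n_dupes += 1
            else:
                edges.add((u, v))
                sign[(u, v)] = s
    if n_data_lines == 0:
        raise ParseError(f"{path}: no edges found (empty or all-comment file)")
    if n_dupes:
        logger.info("%s: dropped %d duplicate edge(s)", path, n_dupes)
    return DirectedNetwork.from_edges(edges, extra_nodes=isolated, sign=sign)


def write_edge_list(
    net: DirectedNetwork, path: str | Path, header_comments: Iterable[str] = ()
) -> None:
    """Write a two-column edge list, with optional ``#``-prefixed header lines.

    Nodes without any edge are recorded as ``# node: NAME`` directives so
    :func:`read_edge_list` reconstructs the full node set.
    """
    touched = {x for e in net.edges for x in e}
    with Path(path).open("w") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        for v in sorted(net.nodes - touched):
            fh.write(f"# node: {v}\n")
        for u, v in sorted(net.edges):
            fh.write(f"{u}\t{v}\n")


def in_degrees(net: DirectedNetwork) -> dict[str, int]:
    """Number of distinct input nodes of each node (a self-loop counts)."""
    deg = {v: 0 for v in net.nodes}
    for _, v in net.edges:
        deg[v] += 1
    return deg


def source_nodes(net: DirectedNetwork) -> frozenset[str]:
    """Nodes of in-degree zero; their Boolean state is held at its initial value."""
    deg = in_degrees(net)
    return frozenset(v for v, d in deg.items() if d == 0)


def fbl_nodes(net: DirectedNetwork) -> frozenset[str]:
    """Nodes lying on at least one feedback loop (directed cycle).

    Computed as membership in a strongly connected component of size >= 2,
    or possession of a self-loop (a length-1 cycle).
    """
    g = net.to_networkx()
    involved: set[str] = set()
    for scc in nx.strongly_connected_components(g):
        if len(scc) >= 2:
            involved |= scc
    involved |= {u for u, v in net.edges if u == v}
    return frozenset(involved)


def reachable(
    net: DirectedNetwork, v: str, direction: Literal["upstream", "downstream"]
) -> frozenset[str]:
    """Nodes with a path to ``v`` (upstream) or from ``v`` (downstream).

    ``v`` itself is included only when it carries a self-loop (the length-1
    cycle v → v is both an upstream and a downstream path of ``v``).
    """
    if v not in net.nodes:
        raise KeyError(f"unknown node {v!r}")
    g = net.to_networkx()
    out = nx.ancestors(g, v) if direction == "upstream" else nx.descendants(g, v)
    if (v, v) in net.edges:
        out = out | {v}
    return frozenset(out)


def classify_nodes(net: DirectedNetwork) -> NodeClassification:
    """Classify every node as source / FBL-involved / NFU / NFD.

    NFU(v) holds iff no node of ``{v} ∪ ancestors(v)`` is FBL-involved;
    NFD(v) iff no node of ``{v} ∪ descendants(v)`` is.  Including ``v``
    itself makes cycle members neither NFU nor NFD, as their own loop is
    simultaneously an upstream and a downstream path.
    """
    g = net.to_networkx()
    fbl = fbl_nodes(net)

    # Condensation DAG: a node's ancestor set touches an FBL iff its SCC, or
    # an ancestor SCC, is cyclic.  One pass over the condensation handles
    # networks the size of genome-scale signaling maps.
    cond = nx.condensation(g)
    cyclic_comp = {
        c for c, data in cond.nodes(data=True)
        if len(data["members"]) >= 2 or any((m, m) in net.edges for m in data["members"])
    }
    order = list(nx.topological_sort(cond))
    fbl_up: dict[int, bool] = {}
    for c in order:
        fbl_up[c] = c in cyclic_comp or any(fbl_up[p] for p in cond.predecessors(c))
    fbl_down: dict[int, bool] = {}
    for c in reversed(order):
        fbl_down[c] = c in cyclic_comp or any(fbl_down[s] for s in cond.successors(c))

    comp_of = cond.graph["mapping"]
    nfu = frozenset(v for v in net.nodes if not fbl_up[comp_of[v]])
    nfd = frozenset(v for v in net.nodes if not fbl_down[comp_of[v]])
    return NodeClassification(
        is_source=source_nodes(net), on_fbl=fbl, is_nfu=nfu, is_nfd=nfd
    )


def _simple_paths_from(net: DirectedNetwork, start: str):
    """Yield every directed path leaving ``start``: simple paths, plus paths
    closing a cycle back to ``start`` (first node may repeat as the last)."""
    succ: dict[str, list[str]] = {v: [] for v in net.nodes}
    for u, v in net.edges:
        succ[u].append(v)

    def walk(path: list[str], visited: set[str]):
        for s in succ[path[-1]]:
            if s == start:
                yield path + [s]
            elif s not in visited:
                yield path + [s]
                yield from walk(path + [s], visited | {s})

    yield from walk([start], {start})


def classify_nodes_bruteforce(net: DirectedNetwork) -> NodeClassification:
    """Classification by the literal path definition; test oracle only.

    Enumerates every upstream/downstream path of every node and checks the
    path nodes beyond the endpoint for FBL involvement.  Guarded to
    networks of at most ``BRUTEFORCE_MAX_NODES`` nodes.
    """
    if net.n_nodes > BRUTEFORCE_MAX_NODES:
        raise ValueError(
            f"brute-force classification limited to {BRUTEFORCE_MAX_NODES} nodes "
            f"(got {net.n_nodes})"
        )
    fbl = fbl_nodes(net)
    reversed_net = DirectedNetwork.from_edges(
        ((v, u) for u, v in net.edges), extra_nodes=net.nodes
    )
    nfu: set[str] = set()
    nfd: set[str] = set()
    for v in net.nodes:
        # downstream paths v u_1 ... u_L: check u_1..u_L
        if not any(
            any(u in fbl for u in p[1:]) for p in _simple_paths_from(net, v)
        ):
            nfd.add(v)
        # upstream paths u_1 ... u_L v, enumerated as reversed-graph walks from v
        if not any(
            any(u in fbl for u in p[1:]) for p in _simple_paths_from(reversed_net, v)
        ):
            nfu.add(v)
    return NodeClassification(
        is_source=source_nodes(net),
        on_fbl=fbl,
        is_nfu=frozenset(nfu),
        is_nfd=frozenset(nfd),
    )
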