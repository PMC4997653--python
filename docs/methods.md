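# Methods

## Model

A directed graph G(V, E) carries one Boolean variable per node, updated
synchronously: `v_i(t+1) = f_i(v_{i1}(t), …, v_{ik}(t))` where the inputs
are the nodes with an edge into `v_i` and `f_i` is an arbitrary truth table
over them. Source nodes (in-degree 0) have no update function; their value
stays at the initial state forever — they model fixed external inputs.
Because the state space is finite, every trajectory enters a fixed point or
limit cycle (the attractor). Edge signs, when present in the input files,
are carried through I/O and rewiring but never enter classification,
dynamics, or scoring: all structural guarantees hold for arbitrary update
functions, so sign information adds nothing to them.

## Structural classification

A feedback loop (FBL) is a directed cycle; self-loops are length-1 FBLs. A
node is FBL-involved iff it belongs to a strongly connected component of
size ≥ 2 or carries a self-loop — equivalent to the path-based definition
and computable in linear time, which is what lets classification run on
networks with thousands of nodes. NFU/NFD status is then a reachability
question on the condensation DAG: `v` is NFU iff no component on or above
`v`'s component is cyclic, NFD iff none on or below is. A cycle member's
own loop is simultaneously an upstream and a downstream path of it, so
cycle members are neither NFU nor NFD.

A literal-definition implementation (`classify_nodes_bruteforce`,
`gamma_bruteforce`) enumerates all simple paths — including paths closing a
cycle back to their first node — and exists purely as a test oracle,
guarded to ≤ 12 nodes. The test suite and the acceptance script check
exact agreement with the fast algorithms on 100 seeded random networks.

## Dynamics and perturbations

States are bit tuples in sorted-node order; truth-table rows are indexed by
the input tuple read as a binary number with the first (alphabetically
smallest) input as the most significant bit. Attractor detection iterates
the update map recording first-visit times; the cycle is canonicalized by
rotating it to start at its lexicographically smallest state, which makes
attractor equivalence (equality up to cyclic offset) a plain equality of
canonical forms. Exhaustive enumeration over all 2^N initial states is
capped at N = 20 by default.

An initial-state perturbation flips one node's starting bit; the network is
robust against it when original and perturbed trajectories reach equivalent
attractors. The two theorem sweeps exploit a full labeling of the state
space: each of the 2^N states is labeled with its attractor's canonical
form, so "robust for all initial states" reduces to comparing labels of
states differing in one bit, and "frozen in every attractor" to scanning
each distinct label once.

## Perturbation-sustainable probability γ

Along a downstream path `v u_1 … u_L`, each hop survives with probability
`1/d_i` (in-degree of `u_i`): the flip propagates to `u_i` only if `u_i`'s
update is actually driven by the flipped input, and all `d_i` inputs are
assumed evenly influential, with a flip at some input always producing a
flipped output. A surviving flip matters only if the path touches an
FBL-involved node, which can recirculate it indefinitely; otherwise the
path probability is 0. γ(v) is the maximum path probability over all
downstream paths of v.

Since every factor is ≤ 1, extending a path past its first FBL-involved
node cannot increase the product, so the maximum is attained by a path
ending at an FBL-involved node. Taking logs turns the max-product into a
shortest-path problem with nonnegative edge weights `ln d(target)`; an
optimal walk is then automatically simple, so Dijkstra is exact. We run
one multi-source Dijkstra from all FBL-involved nodes on the reversed
graph, and score each node from its out-edges:
`γ(v) = exp(−min over (v,b) of [ln d(b) + D(b)])` where `D(b)` is the
distance from `b` to the nearest FBL-involved node. Scoring from out-edges
(rather than giving FBL members distance 0 to themselves) makes the product
start at the path's second node, so cycle members are scored by their
outgoing paths and γ ≤ 1 always holds; γ(v) = 0 exactly when no
FBL-involved node is reachable downstream, i.e. exactly for NFD nodes.
Source nodes are scored by the same formula; the CLI can exclude them.

## Synthetic generators

Random networks sample `m` distinct ordered pairs uniformly (self-loops off
by default, so cycle structure is driven by multi-node loops); the acyclic
variant samples only pairs respecting a random topological order. Random
update functions draw every truth-table output bit as a fair coin. The
theorem-sweep default — 200 networks, n = 8 nodes, m = 14 edges, exhaustive
256 initial states — keeps full coverage of the state space cheap (the
whole battery runs in seconds) while producing a healthy mix of cyclic and
acyclic structure at that density.

What the generators emulate is the *combinatorics* the guarantees quantify
over: arbitrary wiring and arbitrary update logic. They do not reproduce
the degree heterogeneity, sign composition, or modularity of real signaling
maps — the theorems hold regardless, but quantities that depend on topology
(γ distributions, group proportions) will differ on real networks, which is
why the annotation workflows accept user-supplied edge lists.

Degree-preserving rewiring performs directed double-edge swaps
((a→b, c→d) → (a→d, c→b)), rejecting moves that would duplicate an edge or
create a new self-loop (a new length-1 loop would distort the NFD control);
every node keeps its exact in- and out-degree. The default mixing effort is
10 × |E| successful swaps — a standard heuristic, configurable — with an
attempt cap of 100 × n_swaps to guarantee termination on rigid networks.
Annotations stay attached to nodes while wiring changes.

## Annotation statistics

The NFD vs non-NFD comparison uses a two-sided two-proportion z-test by
default (Fisher's exact test behind a flag); at the group sizes of interest
(hundreds of genes) both give the same qualitative answer, and a
500-replicate null calibration test checks the z-test's type-I error at
α = 0.05. The degenerate all-annotated/none-annotated case returns p = 1
rather than an undefined z-statistic. No multiple-testing correction is
applied across annotation categories. The γ-threshold sweep's default grid
is the sorted distinct observed γ values, optionally truncated at a maximum
β. Annotated genes absent from the network are dropped with a logged count.

## Numerical and design choices

* Node identifiers are case-sensitive opaque strings; no gene-symbol
  normalization. Duplicate edges in input files are dropped (count
  logged).
* Edge lists round-trip isolated nodes via a `# node: NAME` directive.
* Truth-table input ordering is sorted node identifiers, recorded in the
  serialized function files, so runs are reproducible across platforms.
* γ oracle comparisons use an absolute tolerance of 1e-12; the Dijkstra
  route and the brute-force product agree to floating-point rounding of
  `exp(Σ −ln d)` vs repeated division.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; derived per-network seeds are reduced
  mod 2^31.
* Ties among equally optimal γ paths are irrelevant: only the maximum
  value is reported.

## Limitations

* Asynchronous and probabilistic update schemes are out of scope, as are
  perturbations of the update rules themselves.
* The dynamics engine is a desk-scale enumerator (exhaustive work capped
  near 2^20 states), not a symbolic/BDD attractor tool; the structural
  classification and γ are what scale to genome-sized networks.
* γ rests on the even-influence and certain-flip assumptions above; it is
  a sustainability proxy, not an estimate of the probability that an
  attractor actually changes.
* Nodes that are neither NFU nor NFD come with no frozenness or
  robustness guarantee in either direction.
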