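"""Perturbation robustness, theorem sweeps, and the sustainability score γ."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from fblnet import (
    BooleanNetwork,
    DirectedNetwork,
    GeneratorConfig,
    classify_nodes,
    find_attractor,
    attractors_equivalent,
    gamma,
    gamma_bruteforce,
    generate_random_network,
    is_robust,
    path_probability,
    perturb_initial,
    random_boolean_functions,
    toy_network_t1,
    verify_corollary,
    verify_theorem1,
    verify_theorem2,
)


class TestPerturbInitial:
    def test_flips_exactly_one_coordinate(self):
        order = ("a", "b", "c")
        assert perturb_initial((0, 1, 0), "b", order) == (0, 0, 0)

    @given(st.lists(st.integers(0, 1), min_size=3, max_size=3))
    def test_involution(self, bits):
        order = ("a", "b", "c")
        s = tuple(bits)
        assert perturb_initial(perturb_initial(s, "c", order), "c", order) == s

    @given(st.lists(st.integers(0, 1), min_size=3, max_size=3),
           st.sampled_from(["a", "b", "c"]))
    def test_hamming_distance_one(self, bits, v):
        order = ("a", "b", "c")
        s = tuple(bits)
        assert sum(x != y for x, y in zip(s, perturb_initial(s, v, order))) == 1

    def test_unknown_node(self):
        with pytest.raises(KeyError):
            perturb_initial((0,), "zzz", ("a",))


class TestIsRobust:
    def test_mutual_negation_flip_breaks_cycle(self, mutual_negation):
        # from 00 the trajectory is the 2-cycle; flipping a gives the fixed
        # point 10 -- a different attractor
        res = is_robust(mutual_negation, (0, 0), "a")
        assert not res.robust
        assert res.attractor_original.period == 2
        assert res.attractor_perturbed.period == 1

    def test_sink_node_flip_is_robust(self):
        # e is a sink in T1, hence NFD non-source: flipping it never matters
        net = toy_network_t1()
        bn = random_boolean_functions(net, seed=11)
        for s0 in range(32):
            state = tuple((s0 >> (4 - i)) & 1 for i in range(5))
            assert is_robust(bn, state, "e").robust

    def test_flipping_a_source_can_flip_downstream_fixed_point(self):
        # source -> target with identity function: the target's frozen value
        # follows the source, so the attractors differ
        net = DirectedNetwork.from_edges([("s", "x")])
        bn = BooleanNetwork(net=net, inputs={"x": ("s",)}, tables={"x": (0, 1)})
        assert not is_robust(bn, (0, 0), "s").robust


class TestTheoremSweeps:
    CFG = GeneratorConfig(n_nodes=8, n_edges=14, seed=0)

    def test_nfu_nodes_frozen_small_ensemble(self):
        report = verify_theorem1(self.CFG, n_networks=25, seed=42)
        assert report.passed, report.violations[:5]

    def test_nfd_flips_robust_small_ensemble(self):
        report = verify_theorem2(self.CFG, n_networks=25, seed=42)
        assert report.passed, report.violations[:5]

    def test_acyclic_fixed_points_small_ensemble(self):
        cfg = GeneratorConfig(n_nodes=8, n_edges=14, acyclic=True, seed=0)
        report = verify_corollary(cfg, n_networks=25, seed=42)
        assert report.passed, report.violations[:5]

    def test_corollary_requires_acyclic_config(self):
        with pytest.raises(ValueError, match="acyclic"):
            verify_corollary(self.CFG, n_networks=1, seed=0)

    def test_full_cycle_network_vacuous(self):
        # a single big cycle has no NFU nodes; the sweep is vacuously clean
        net = DirectedNetwork.from_edges(
            [("a", "b"), ("b", "c"), ("c", "a")]
        )
        assert classify_nodes(net).is_nfu == frozenset()

    def test_robustness_matches_equivalence_definition(self):
        # spot-check: the fast label-based theorem-2 sweep agrees with the
        # direct attractor-equivalence route
        net = generate_random_network(GeneratorConfig(n_nodes=6, n_edges=10, seed=5))
        bn = random_boolean_functions(net, seed=5)
        cls = classify_nodes(net)
        for v in sorted(cls.is_nfd - cls.is_source):
            for x in range(2**6):
                s0 = tuple((x >> (5 - i)) & 1 for i in range(6))
                res = is_robust(bn, s0, v)
                assert res.robust == attractors_equivalent(
                    res.attractor_original, res.attractor_perturbed
                )
                assert res.robust


class TestPathProbability:
    def test_single_hop_to_fbl(self, t1):
        assert path_probability(t1, ["a", "b"]) == 0.5

    def test_no_fbl_on_path_gives_zero(self, t1):
        assert path_probability(t1, ["d", "e"]) == 0.0

    def test_two_hop_product(self, t1):
        assert path_probability(t1, ["a", "b", "c"]) == 0.5  # 1/2 * 1/1

    def test_invalid_path_rejected(self, t1):
        with pytest.raises(ValueError):
            path_probability(t1, ["a", "d"])
        with pytest.raises(ValueError):
            path_probability(t1, ["a"])

    def test_cycle_closing_path_allowed(self, t1):
        # b -> c -> b is a feedback loop and a downstream path of b
        assert path_probability(t1, ["b", "c", "b"]) == 0.5  # 1/1 * 1/2


class TestGamma:
    def test_t1_values(self, t1):
        assert gamma(t1) == {"a": 0.5, "b": 1.0, "c": 0.5, "d": 0.0, "e": 0.0}

    def test_nfd_nodes_score_zero(self, t1):
        cls = classify_nodes(t1)
        g = gamma(t1)
        for v in t1.nodes:
            assert (g[v] == 0.0) == (v in cls.is_nfd)

    def test_no_outgoing_edges_bruteforce_zero(self, t1):
        assert gamma_bruteforce(t1, "e") == 0.0

    def test_bruteforce_guard(self):
        net = generate_random_network(GeneratorConfig(n_nodes=13, n_edges=20, seed=0))
        with pytest.raises(ValueError, match="12 nodes"):
            gamma_bruteforce(net, "v00")

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_literal_definition(self, seed):
        """Shortest-path-on-log-weights γ equals exhaustive path enumeration."""
        net = generate_random_network(
            GeneratorConfig(n_nodes=8, n_edges=14, seed=seed)
        )
        g = gamma(net)
        for v in net.nodes:
            assert g[v] == pytest.approx(gamma_bruteforce(net, v), abs=1e-12)

    @pytest.mark.parametrize("seed", range(30))
    def test_positive_iff_not_nfd(self, seed):
        net = generate_random_network(
            GeneratorConfig(n_nodes=10, n_edges=18, seed=seed)
        )
        cls = classify_nodes(net)
        g = gamma(net)
        for v in net.nodes:
            assert (g[v] > 0) == (v not in cls.is_nfd)
            assert 0.0 <= g[v] <= 1.0

    def test_extra_in_edge_on_optimal_path_cannot_raise_gamma(self):
        # a -> b <-> c; adding d -> b doubles b's in-degree, halving the
        # only sustaining path of a
        base = toy_network_t1()
        denser = DirectedNetwork.from_edges(sorted(base.edges) + [("f", "b")])
        assert gamma(denser)["a"] == pytest.approx(1 / 3)  # b's in-degree is now 3
        assert gamma(denser)["a"] < gamma(base)["a"]

    def test_adding_edge_never_shrinks_positive_gamma_set(self):
        base = toy_network_t1()
        withextra = DirectedNetwork.from_edges(sorted(base.edges) + [("e", "b")])
        pos_base = {v for v, g in gamma(base).items() if g > 0}
        pos_extra = {v for v, g in gamma(withextra).items() if g > 0}
        assert pos_base <= pos_extra
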