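"""Structural metrics against hand-worked examples and brute-force
oracles on small digraphs."""

import numpy as np
import pytest

from causalmaps.map_model import CausalMap
from causalmaps.metrics import (
    NodeRole,
    QCThresholds,
    census,
    classify_nodes,
    cycle_census,
    degree_stats,
    density,
    diameter,
    validate,
)
from causalmaps.synthetic_data import GeneratorParams, generate_sme_map

from conftest import random_map
from oracles import brute_diameter, brute_roles, brute_simple_cycles


class TestRolesAndDensity:
    def test_chain_typology(self, chain_map):
        roles = {chain_map.concepts[c].label: r for c, r in classify_nodes(chain_map).items()}
        assert roles == {"A": NodeRole.SOURCE, "B": NodeRole.TRANSMITTER,
                         "C": NodeRole.RECEIVER}

    def test_density_examples(self):
        full = CausalMap("k3")
        for a in "ABC":
            for b in "ABC":
                if a != b:
                    full.add_edge(a, b, 1)
        assert density(full) == 1.0
        pair = CausalMap("p")
        pair.add_edge("A", "B", 1)
        assert density(pair) == 0.5

    def test_density_undefined_below_two_nodes(self):
        m = CausalMap("m")
        m.add_concept("A")
        with pytest.raises(ValueError, match="undefined"):
            density(m)

    def test_degree_stats_single_edge_and_star(self):
        m = CausalMap("m")
        m.add_edge("A", "B", 1)
        avg, mx, argmax = degree_stats(m)
        assert (avg, mx, argmax) == (1.0, 1, ["A", "B"])
        star = CausalMap("s")
        for x in "ABCDE":
            star.add_edge("H", x, 1)
        assert degree_stats(star)[1:] == (5, ["H"])


class TestDiameter:
    def test_directed_chain(self):
        m = CausalMap("m")
        for i in range(5):
            m.add_edge(f"n{i}", f"n{i+1}", 1)
        assert diameter(m) == 5

    def test_disjoint_chains_ignore_unreachable_pairs(self):
        m = CausalMap("m")
        for i in range(3):
            m.add_edge(f"a{i}", f"a{i+1}", 1)
        for i in range(5):
            m.add_edge(f"b{i}", f"b{i+1}", 1)
        assert diameter(m) == 5

    def test_zero_edges_undefined(self):
        m = CausalMap("m")
        m.add_concept("A")
        with pytest.raises(ValueError, match="undefined"):
            diameter(m)


class TestCycles:
    def test_two_cycle_sign_product(self):
        m = CausalMap("m")
        m.add_edge("A", "B", 1)
        m.add_edge("B", "A", -1)
        cc = cycle_census(m)
        assert cc.has_cycles and cc.cycles == [(("a", "b"), -1)]

    def test_dag_has_no_cycles(self, chain_map):
        cc = cycle_census(chain_map)
        assert not cc.has_cycles and cc.cycles == []

    def test_enumeration_cap_sets_partial_flag(self):
        m = CausalMap("m")
        for a in "ABCDE":
            for b in "ABCDE":
                if a != b:
                    m.add_edge(a, b, 1)
        cc = cycle_census(m, max_len=5, max_cycles=3)
        assert cc.truncated and len(cc.cycles) == 3 and cc.has_cycles


@pytest.mark.parametrize("seed", [0, 1])
def test_metrics_match_brute_force_oracles(seed):
    """Roles, diameters (both modes) and the signed simple-cycle set match
    exhaustive brute force on random digraphs of up to 8 nodes."""
    rng = np.random.default_rng(seed)
    for _ in range(60):
        m = random_map(rng)
        nodes = sorted(m.concepts)
        edges = set(m.edges)
        assert {c: r.value for c, r in classify_nodes(m).items()} == \
            brute_roles(nodes, edges)
        if edges:
            assert diameter(m, "directed") == brute_diameter(nodes, edges)
            assert diameter(m, "undirected") == brute_diameter(nodes, edges, undirected=True)
        signed = {k: e.polarity for k, e in m.edges.items()}
        got = set(cycle_census(m, max_len=8, max_cycles=100_000).cycles)
        assert got == brute_simple_cycles(signed)


class TestQC:
    def test_acyclic_star_fires_no_cycles_and_diameter(self):
        star = CausalMap("s")
        for x in "BCDE":
            star.add_edge("A", x, 1)
        crits = {f.criterion for f in validate(star)}
        assert {"cycles", "diameter"} <= crits

    def test_long_chain_passes_diameter_but_fires_cycles(self):
        m = CausalMap("m")
        for i in range(7):
            m.add_edge(f"n{i}", f"n{i+1}", 1)
        crits = {f.criterion for f in validate(m)}
        assert "diameter" not in crits and "cycles" in crits

    def test_interview_shaped_synthetic_map_passes_all_checks(self):
        m = generate_sme_map(GeneratorParams(seed=11))
        assert validate(m) == []

    def test_thresholds_are_configurable(self, chain_map):
        crits = {f.criterion for f in
                 validate(chain_map, QCThresholds(diameter_floor=1,
                                                  density_ceiling=1.0,
                                                  source_fraction_ceiling=1.0))}
        assert crits == {"cycles"}


class TestCensus:
    def test_role_partition_identity_on_random_maps(self, rng):
        for _ in range(30):
            c = census(random_map(rng))
            assert c.n_sources + c.n_receivers + c.n_transmitters + c.n_isolated == c.n_nodes
            assert 0 <= c.density <= 1

    def test_degree_concentration_example(self):
        # a hub holding 15 of 85 links -> concentration 15/85
        m = CausalMap("m")
        for i in range(15):
            m.add_edge("hub", f"h{i}", 1)
        for i in range(70):
            m.add_edge(f"x{i}", f"y{i}", 1)
        c = census(m)
        assert c.max_degree == 15 and c.n_edges == 85
        assert c.degree_concentration == pytest.approx(15 / 85)

    def test_edgeless_map(self):
        m = CausalMap("m")
        for x in "ABCD":
            m.add_concept(x)
        c = census(m)
        assert c.n_isolated == 4 and c.density == 0.0 and c.diameter is None

    def test_monotonicity_under_edge_addition(self, rng):
        for _ in range(10):
            m = random_map(rng, p=0.25)
            before = census(m)
            free = [(a, b) for a in m.concepts for b in m.concepts
                    if a != b and (a, b) not in m.edges]
            if not free:
                continue
            a, b = free[int(rng.integers(len(free)))]
            m.add_edge(a, b, 1)
            after = census(m)
            assert after.max_degree >= before.max_degree
            assert after.density >= before.density
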