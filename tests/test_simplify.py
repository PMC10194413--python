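"""Simplification: plan proposal, endpoint pruning, sign-preserving
chain contraction."""

import numpy as np
import pytest

from causalmaps.map_model import CausalMap
from causalmaps.metrics import classify_nodes, NodeRole
from causalmaps.simplify import contract_chains, propose_plan, prune_endpoints

from conftest import random_map
from oracles import brute_path_sign_products


def chain(*signed):
    """chain(('A','B',1), ('B','C',-1), ...) -> CausalMap"""
    m = CausalMap("chain")
    for s, d, sign in signed:
        m.add_edge(s, d, sign)
    return m


class TestProposePlan:
    def test_chain_candidates(self):
        plan = propose_plan(chain(("A", "B", 1), ("B", "C", 1)))
        assert plan.sources == ["A"] and plan.receivers == ["C"]
        assert plan.skippable == ["B"]

    def test_high_in_degree_not_skippable(self):
        m = chain(("A", "B", 1), ("C", "B", 1), ("B", "D", 1))
        assert propose_plan(m).skippable == []

    def test_protected_and_focal_never_skippable(self):
        m = chain(("A", "B", 1), ("B", "C", 1), ("C", "D", 1))
        m.concept("B").protected = True
        m.set_focal("C")
        assert propose_plan(m).skippable == []

    def test_approvals_validated_against_candidates(self):
        plan = propose_plan(chain(("A", "B", 1), ("B", "C", 1)))
        plan.approve_removals(["A"])
        with pytest.raises(ValueError, match="not an endpoint"):
            plan.approve_removals(["B"])
        with pytest.raises(ValueError, match="not a skippable"):
            plan.approve_contractions(["A"])


class TestPrune:
    def test_chain_head_removal_exposes_new_source(self):
        res = prune_endpoints(chain(("A", "B", 1), ("B", "C", 1)), ["A"],
                              iterative=True)
        assert res.map.n_nodes == 2 and res.map.get_edge("B", "C")
        assert res.newly_exposed == ["B"]

    def test_receiver_removal_deletes_incident_edges(self):
        m = chain(("A", "R", 1), ("B", "R", -1), ("C", "R", 1))
        res = prune_endpoints(m, ["R"])
        assert res.map.n_edges == 0 and res.map.n_nodes == 3

    def test_transmitter_removal_rejected_by_name(self):
        with pytest.raises(ValueError, match="'B' is a transmitter"):
            prune_endpoints(chain(("A", "B", 1), ("B", "C", 1)), ["B"])

    def test_protected_endpoint_rejected(self):
        m = chain(("A", "B", 1))
        m.concept("A").protected = True
        with pytest.raises(ValueError, match="protected"):
            prune_endpoints(m, ["A"])

    def test_counts_match_set_subtraction_oracle(self, rng):
        for _ in range(30):
            m = random_map(rng)
            roles = classify_nodes(m)
            legal = [m.concepts[c].label for c, r in roles.items()
                     if r in (NodeRole.SOURCE, NodeRole.RECEIVER)]
            take = legal[: int(rng.integers(0, len(legal) + 1))]
            res = prune_endpoints(m, take)
            removed = {c for c in m.concepts
                       if m.concepts[c].label in set(take)}
            expect_edges = {k for k in m.edges if not (set(k) & removed)}
            assert res.map.n_nodes == m.n_nodes - len(take)
            assert set(res.map.edges) == expect_edges


class TestContract:
    def test_sign_product_plus_minus(self):
        res = contract_chains(chain(("A", "B", 1), ("B", "C", -1)), ["B"])
        assert res.map.get_edge("A", "C").polarity == -1

    def test_two_negatives_make_a_positive(self):
        res = contract_chains(chain(("A", "B", -1), ("B", "C", -1)), ["B"])
        assert res.map.get_edge("A", "C").polarity == 1

    def test_transitive_contraction_accumulates_full_product(self):
        m = chain(("A", "B", 1), ("B", "C", 1), ("C", "D", -1))
        res = contract_chains(m, ["B", "C"])
        assert sorted(res.contracted) == ["B", "C"]
        assert res.map.get_edge("A", "D").polarity == -1
        assert res.map.n_nodes == 2

    def test_two_cycle_contraction_refused(self):
        m = chain(("A", "B", 1), ("B", "A", 1))
        res = contract_chains(m, ["B"])
        assert res.contracted == []
        assert res.skipped == [("B", "contraction would create a self-loop")]
        assert res.map.n_nodes == 2

    def test_conflicted_incident_edge_blocks_contraction(self):
        m = chain(("A", "B", 1), ("B", "C", 1))
        m.add_edge("A", "B", -1, origin="other")  # now tied -> conflicted
        res = contract_chains(m, ["B"])
        assert res.contracted == [] and "conflicted" in res.skipped[0][1]

    def test_merge_into_opposite_signed_edge_flags_conflict(self):
        m = chain(("A", "B", 1), ("B", "C", 1), ("A", "C", -1))
        res = contract_chains(m, ["B"])
        e = res.map.get_edge("A", "C")
        assert e.is_conflicted and res.conflicts == [("a", "c")]

    def test_degree_precondition_failure_reported_not_fatal(self):
        m = chain(("A", "B", 1), ("X", "B", 1), ("B", "C", 1))
        res = contract_chains(m, ["B"])
        assert res.contracted == [] and "degree precondition" in res.skipped[0][1]

    def test_non_neighbors_keep_their_degree(self, rng):
        for _ in range(20):
            m = random_map(rng)
            plan = propose_plan(m)
            if not plan.skippable:
                continue
            res = contract_chains(m, plan.skippable[:1])
            cid = res.contracted and next(
                c for c in m.concepts if m.concepts[c].label == res.contracted[0])
            if not cid:
                continue
            nbrs = {s for (s, d) in m.edges if d == cid} | \
                   {d for (s, d) in m.edges if s == cid} | {cid}
            for c in m.concepts:
                if c not in nbrs:
                    assert res.map.degree(c) == m.degree(c)

    def test_contraction_never_creates_new_reachability(self, rng):
        import networkx as nx
        for _ in range(20):
            m = random_map(rng)
            plan = propose_plan(m)
            if not plan.skippable:
                continue
            res = contract_chains(m, plan.skippable)
            g0, g1 = m.to_networkx(), res.map.to_networkx()
            for u in g1:
                reach0 = nx.descendants(g0, u)
                for v in nx.descendants(g1, u):
                    assert v in reach0


def test_path_sign_multiset_preserved_through_contraction(rng):
    """For pairs gaining a contracted edge, the sign products of the
    original paths routed through contracted concepts (enumerated by an
    independent DFS) must account for the new edge's polarity."""
    checked = 0
    for _ in range(100):
        m = random_map(rng, p=0.25)
        plan = propose_plan(m)
        if not plan.skippable:
            continue
        res = contract_chains(m, plan.skippable)
        contracted_ids = {c for c in m.concepts
                          if m.concepts[c].label in set(res.contracted)}
        signed = {k: e.polarity for k, e in m.edges.items()}
        for (u, v), e in res.map.edges.items():
            if (u, v) in m.edges and not contracted_ids:
                continue
            prods = brute_path_sign_products(signed, u, v, contracted_ids)
            if (u, v) in m.edges:
                prods.append(m.edges[(u, v)].polarity)
            if not prods:
                continue
            checked += 1
            if all(p == prods[0] for p in prods):
                assert e.polarity == prods[0]
            else:
                assert e.is_conflicted or e.polarity in (1, -1, 0)
    assert checked > 20
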