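"""Canonicalization, panel aggregation and alias suggestion."""

import numpy as np
import pytest

from causalmaps.map_model import CausalMap, Thesaurus
from causalmaps.merge import (
    aggregate,
    canonicalize,
    suggest_aliases,
    thesaurus_stats,
)

from conftest import random_map


@pytest.fixture
def racism_thesaurus():
    return Thesaurus.from_pairs(
        [("structural racism", "racism"), ("racial injustice", "racism")]
    )


class TestCanonicalize:
    def test_variant_nodes_unite_with_aliases(self, racism_thesaurus):
        m = CausalMap("m")
        m.add_edge("structural racism", "ACEs", 1)
        m.add_edge("racial injustice", "poverty", -1)
        out, rep = canonicalize(m, racism_thesaurus)
        assert out.n_nodes == 3
        c = out.concept("racism")
        assert {"structural racism", "racial injustice"} <= c.aliases
        assert rep.n_terms_resolved == 1

    def test_idempotent(self, racism_thesaurus, rng):
        m = random_map(rng)
        once, _ = canonicalize(m, racism_thesaurus)
        twice, _ = canonicalize(once, racism_thesaurus)
        assert twice.signature() == once.signature()

    def test_collapsed_self_loop_dropped_and_recorded(self, racism_thesaurus):
        m = CausalMap("m")
        m.add_edge("structural racism", "racial injustice", 1)
        out, rep = canonicalize(m, racism_thesaurus)
        assert out.n_edges == 0
        assert rep.collapsed_self_loops == [
            (("structural racism", "racial injustice"), "racism")
        ]

    def test_parallel_edges_merge_provenance(self, racism_thesaurus):
        m = CausalMap("m")
        m.add_edge("structural racism", "ACEs", 1, origin="m1")
        m.add_edge("racial injustice", "ACEs", 1, origin="m2")
        out, _ = canonicalize(m, racism_thesaurus)
        e = out.get_edge("racism", "ACEs")
        assert out.n_edges == 1 and e.n_pos == 2


class TestAggregate:
    def test_two_agreeing_maps_double_provenance(self):
        maps = []
        for mid in ("m1", "m2"):
            m = CausalMap(mid)
            m.add_edge("A", "B", 1)
            maps.append(m)
        combined, rep = aggregate(maps)
        assert combined.get_edge("A", "B").n_pos == 2
        assert rep.n_sign_conflicts == 0

    def test_majority_with_conflict_count(self):
        signs = [1, -1, 1]
        maps = []
        for i, s in enumerate(signs):
            m = CausalMap(f"m{i}")
            m.add_edge("A", "B", s)
            maps.append(m)
        combined, rep = aggregate(maps)
        e = combined.get_edge("A", "B")
        assert e.polarity == 1 and rep.n_sign_conflicts == 1

    def test_single_map_aggregation_is_canonicalization(self, rng, racism_thesaurus):
        m = random_map(rng)
        m.add_edge("structural racism", "n0", 1)
        combined, _ = aggregate([m], racism_thesaurus)
        alone, _ = canonicalize(m, racism_thesaurus)
        assert combined.signature(include_focal=False) == alone.signature(include_focal=False)

    def test_order_invariance(self, rng):
        maps = [random_map(rng, map_id=f"m{i}") for i in range(5)]
        a, _ = aggregate(maps)
        b, _ = aggregate(maps[::-1])
        assert a.signature() == b.signature()
        assert sorted(a.edges[k].provenance for k in a.edges) == \
            sorted(b.edges[k].provenance for k in b.edges)

    def test_duplicated_panel_doubles_provenance_only(self, rng):
        m = random_map(rng, map_id="m")
        single, _ = aggregate([m])
        double, _ = aggregate([m, m])
        assert set(double.edges) == set(single.edges)
        assert set(double.concepts) == set(single.concepts)
        for k in single.edges:
            assert double.edges[k].n_pos == 2 * single.edges[k].n_pos
            assert double.edges[k].n_neg == 2 * single.edges[k].n_neg

    def test_empty_panel_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            aggregate([])


class TestSuggestAliases:
    def _panel(self, labels_a, labels_b):
        a, b = CausalMap("m1"), CausalMap("m2")
        for x in labels_a:
            a.add_concept(x)
        for x in labels_b:
            b.add_concept(x)
        return [a, b]

    def test_reordered_phrasing_is_proposed(self):
        panel = self._panel(["family financial stress"], ["financial stress (family)"])
        cands = suggest_aliases(panel)
        assert cands and cands[0].label_a == "family financial stress"
        assert cands[0].similarity >= 0.8

    def test_identical_labels_excluded(self):
        cands = suggest_aliases(self._panel(["ACEs"], ["aces"]))
        assert cands == []

    def test_disjoint_vocabulary_yields_nothing(self):
        cands = suggest_aliases(self._panel(["bullying"], ["connectedness"]))
        assert cands == []

    def test_never_merges_anything(self):
        panel = self._panel(["family financial stress"], ["financial stress (family)"])
        before = [m.signature() for m in panel]
        suggest_aliases(panel)
        assert [m.signature() for m in panel] == before


def test_thesaurus_stats_counts_multi_variant_terms():
    th = Thesaurus.from_pairs([
        ("structural racism", "racism"), ("racial injustice", "racism"),
        ("being bullied", "bullying"),
        ("aces", "adverse childhood experiences"),
        ("childhood adversity", "adverse childhood experiences"),
        ("early adversity", "adverse childhood experiences"),
    ])
    n_terms, mean, counts = thesaurus_stats(th)
    assert n_terms == 2  # racism (2 variants) + ACEs (3); bullying has 1
    assert counts == [3, 2] and mean == pytest.approx(2.5)
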