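"""Thesaurus canonicalization and panel aggregation.

Different experts name the same concept differently ("structural racism",
"racial injustice" and "racism" may all denote one concept).  A curated
thesaurus maps every variant to a canonical term; :func:`canonicalize`
applies it to one map and :func:`aggregate` pools a panel of maps into a
single combined map, merging provenance and resolving sign disagreements
by majority vote (exact ties are flagged as conflicted).

:func:`suggest_aliases` ranks likely variant pairs across maps by string
similarity to assist the humans curating the thesaurus.  It never merges
anything on its own: concept equivalence is a semantic judgment that
belongs to the experts.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from difflib import SequenceMatcher
from typing import Iterable, Optional, Sequence

from .map_model import CausalEdge, CausalMap, Thesaurus, normalize_label

__all__ = [
    "MergeReport",
    "AliasCandidate",
    "canonicalize",
    "aggregate",
    "suggest_aliases",
    "thesaurus_stats",
]


@dataclass
class MergeReport:
    """What happened while combining a panel of maps.

    ``n_terms_resolved`` counts canonical terms that absorbed at least two
    distinct surface forms across the panel; ``variants_per_term`` holds
    the per-term counts of absorbed surface forms (same order as
    ``resolved_terms``).  Edges asserted with both signs anywhere in the
    panel are counted in ``n_sign_conflicts``.  Edges whose endpoints
    collapsed onto the same canonical concept are dropped and recorded in
    ``collapsed_self_loops`` as ``((src label, dst label), canonical)``.
    """

    n_maps: int = 0
    n_terms_resolved: int = 0
    resolved_terms: list[str] = field(default_factory=list)
    variants_per_term: list[int] = field(default_factory=list)
    n_sign_conflicts: int = 0
    collapsed_self_loops: list[tuple[tuple[str, str], str]] = field(default_factory=list)

    @property
    def mean_variants_per_term(self) -> float:
        if not self.variants_per_term:
            return 0.0
        return sum(self.variants_per_term) / len(self.variants_per_term)


def canonicalize(
    cmap: CausalMap, th: Optional[Thesaurus] = None
) -> tuple[CausalMap, MergeReport]:
    """Rewrite every concept label to its canonical form.

    Concepts collapsing onto the same canonical term are united (alias
    sets merged, old labels kept as aliases); parallel edges created by a
    collapse are united with provenance concatenated; edges that become
    self-loops are dropped and recorded.  Canonicalization is idempotent.
    """
    th = th or Thesaurus()
    out = CausalMap(map_id=cmap.map_id)
    report = MergeReport(n_maps=1)
    absorbed: dict[str, set[str]] = defaultdict(set)

    for c in cmap.concepts.values():
        canonical = th.resolve(c.label)
        aliases = set(c.aliases)
        if normalize_label(canonical) != c.id:
            aliases.add(c.label)
            absorbed[normalize_label(canonical)].update({c.label} | c.aliases)
        nc = out.add_concept(canonical, protected=c.protected, aliases=aliases)
        absorbed[nc.id].add(nc.label)

    for (s, d), e in cmap.edges.items():
        ns = normalize_label(th.resolve(cmap.concepts[s].label))
        nd = normalize_label(th.resolve(cmap.concepts[d].label))
        if ns == nd:
            report.collapsed_self_loops.append(
                ((cmap.concepts[s].label, cmap.concepts[d].label), out.concepts[ns].label)
            )
            continue
        existing = out.edges.get((ns, nd))
        if existing is None:
            out.edges[(ns, nd)] = CausalEdge(ns, nd, list(e.provenance), e.forced_conflicted)
        else:
            existing.provenance.extend(e.provenance)
            existing.forced_conflicted = existing.forced_conflicted or e.forced_conflicted

    if cmap.focal is not None:
        out.set_focal(th.resolve(cmap.concepts[cmap.focal].label))

    for cid, forms in absorbed.items():
        if len(forms) >= 2:
            report.resolved_terms.append(out.concepts[cid].label)
            report.variants_per_term.append(len(forms))
    report.n_terms_resolved = len(report.resolved_terms)
    report.n_sign_conflicts = sum(
        1 for e in out.edges.values() if e.n_pos > 0 and e.n_neg > 0
    )
    return out, report


def aggregate(
    maps: Sequence[CausalMap], th: Optional[Thesaurus] = None
) -> tuple[CausalMap, MergeReport]:
    """Pool a panel of maps into one combined map.

    Each map is canonicalized first; the combined concept set is the union
    of canonical concepts, and each ordered ``(src, dst)`` pair becomes a
    single edge whose provenance is the merged multiset of all assertions,
    with polarity set by the majority-vote conflict policy.  The result is
    invariant under any permutation of the panel.
    """
    if not maps:
        raise ValueError("cannot aggregate an empty panel of maps")
    th = th or Thesaurus()
    combined = CausalMap(map_id="combined")
    report = MergeReport(n_maps=len(maps))
    absorbed: dict[str, set[str]] = defaultdict(set)
    collapsed: list[tuple[tuple[str, str], str]] = []
    focal_labels: set[str] = set()

    for m in maps:
        cm, frag = canonicalize(m, th)
        collapsed.extend(frag.collapsed_self_loops)
        for c in cm.concepts.values():
            combined.add_concept(c.label, protected=c.protected, aliases=c.aliases)
            absorbed[c.id].add(c.label)
            absorbed[c.id].update(c.aliases)
        for (s, d), e in cm.edges.items():
            existing = combined.edges.get((s, d))
            if existing is None:
                combined.edges[(s, d)] = CausalEdge(s, d, list(e.provenance), e.forced_conflicted)
            else:
                existing.provenance.extend(e.provenance)
                existing.forced_conflicted = existing.forced_conflicted or e.forced_conflicted
        if cm.focal is not None:
            focal_labels.add(cm.concepts[cm.focal].label)

    if focal_labels:  # lexicographically first, so panel order never matters
        combined.set_focal(sorted(focal_labels)[0])

    # provenance order should not depend on panel order
    for e in combined.edges.values():
        e.provenance.sort()

    report.collapsed_self_loops = sorted(collapsed)
    for cid in sorted(absorbed):
        forms = absorbed[cid]
        if len(forms) >= 2:
            report.resolved_terms.append(combined.concepts[cid].label)
            report.variants_per_term.append(len(forms))
    report.n_terms_resolved = len(report.resolved_terms)
    report.n_sign_conflicts = sum(
        1 for e in combined.edges.values() if e.n_pos > 0 and e.n_neg > 0
    )
    return combined, report


@dataclass
class AliasCandidate:
    label_a: str
    label_b: str
    similarity: float
    maps_a: tuple[str, ...]
    maps_b: tuple[str, ...]


def _token_form(label: str) -> str:
    tokens = normalize_label(label).replace("(", " ").replace(")", " ").replace("-", " ").split()
    return " ".join(sorted(tokens))


def _similarity(a: str, b: str) -> float:
    raw = SequenceMatcher(None, normalize_label(a), normalize_label(b)).ratio()
    tok = SequenceMatcher(None, _token_form(a), _token_form(b)).ratio()
    return max(raw, tok)


def suggest_aliases(
    maps: Sequence[CausalMap], similarity_floor: float = 0.8
) -> list[AliasCandidate]:
    """Rank cross-map label pairs that look like variants of one concept.

    Similarity is the better of a plain normalized-string ratio and a
    token-order-insensitive ratio, so "family financial stress" and
    "financial stress (family)" score as near-duplicates.  Pairs already
    identical after normalization are excluded (they are unified anyway).
    Advisory only — the output is a triage list for human review.
    """
    if len(maps) < 2:
        raise ValueError("need at least two maps to suggest cross-map aliases")
    where: dict[str, set[str]] = defaultdict(set)
    display: dict[str, str] = {}
    for m in maps:
        for c in m.concepts.values():
            where[c.id].add(m.map_id)
            display.setdefault(c.id, c.label)
    ids = sorted(where)
    out: list[AliasCandidate] = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if where[a] == where[b] and len(where[a]) == 1:
                continue  # never co-occur across maps
            sim = _similarity(display[a], display[b])
            if sim >= similarity_floor:
                out.append(AliasCandidate(
                    display[a], display[b], round(sim, 4),
                    tuple(sorted(where[a])), tuple(sorted(where[b])),
                ))
    out.sort(key=lambda c: (-c.similarity, c.label_a, c.label_b))
    return out


def thesaurus_stats(th: Thesaurus) -> tuple[int, float, list[int]]:
    """Summary of a thesaurus: number of canonical terms that absorb at
    least two variants, the mean variant count over those terms, and the
    per-term counts."""
    per_term: dict[str, int] = defaultdict(int)
    for v, c in th.entries.items():
        per_term[normalize_label(c)] += 1
    counts = sorted((n for n in per_term.values() if n >= 2), reverse=True)
    mean = sum(counts) / len(counts) if counts else 0.0
    return len(counts), mean, counts
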