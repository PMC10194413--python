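"""Core data model for signed causal maps.

A *causal map* (also called a system map or fuzzy cognitive map skeleton) is
a directed graph whose nodes are concepts elicited from a subject-matter
expert (SME) and whose edges assert that a change in the source concept
increases (polarity ``+1``) or decreases (polarity ``-1``) the target
concept.  Edges carry *provenance*: the multiset of ``(map_id, sign)``
assertions that produced them, so that maps from several experts can be
aggregated without losing who said what.

Identity of a concept is its *normalized* label (trimmed, internal
whitespace collapsed, case-folded); the original casing is preserved for
display.  Self-loops are rejected at ingest: a one-node loop is
uninterpretable in this formalism, whereas multi-node feedback cycles are
first-class objects of study.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import networkx as nx

__all__ = [
    "normalize_label",
    "Concept",
    "CausalEdge",
    "CausalMap",
    "Thesaurus",
    "MapCensus",
    "SelfLoopWarning",
    "ThesaurusError",
    "CONFLICTED",
]

_WS = re.compile(r"\s+")

#: Polarity value of an edge whose provenance is exactly tied between + and -.
CONFLICTED = 0


def normalize_label(label: str) -> str:
    """Normalized form used for concept identity.

    Trims, collapses internal whitespace and case-folds.  Display strings
    keep their original casing; only identity comparisons use this form.
    """
    return _WS.sub(" ", label.strip()).casefold()


class SelfLoopWarning(UserWarning):
    """Raised (as a warning) when an ingested edge would be a self-loop."""


class ThesaurusError(ValueError):
    """Invalid thesaurus: redirect chains or ambiguous variants."""


@dataclass
class Concept:
    """A node of a causal map.

    Parameters
    ----------
    id
        Stable identifier; by convention the normalized label.
    label
        Canonical display string (original casing).
    aliases
        Alternative surface strings this concept has absorbed (e.g. after
        thesaurus resolution).  Never contains ``label`` itself.
    protected
        Exempt from simplification (pruning / contraction).  The focal
        problem node is always treated as protected.
    """

    id: str
    label: str
    aliases: set[str] = field(default_factory=set)
    protected: bool = False

    def __post_init__(self) -> None:
        if not self.label.strip():
            raise ValueError("concept label must be non-empty")
        self.aliases.discard(self.label)


@dataclass
class CausalEdge:
    """A directed signed causal link with provenance.

    ``polarity`` is derived from the provenance multiset by majority vote:
    ``+1`` if more positive than negative assertions, ``-1`` for the
    converse, and ``CONFLICTED`` (0) on an exact tie.  Conflicted edges are
    retained in the map but excluded from sign-dependent operations such as
    chain contraction.
    """

    src: str
    dst: str
    provenance: list[tuple[str, int]] = field(default_factory=list)
    #: set when a sign-preserving contraction merged into an existing edge
    #: of the opposite sign; forces the conflicted state regardless of the
    #: provenance majority, so the disagreement is surfaced, not overwritten.
    forced_conflicted: bool = False

    def __post_init__(self) -> None:
        if self.src == self.dst:
            raise ValueError(f"self-loop on concept {self.src!r}")
        for _, s in self.provenance:
            if s not in (1, -1):
                raise ValueError(f"provenance sign must be +1/-1, got {s!r}")

    @property
    def n_pos(self) -> int:
        return sum(1 for _, s in self.provenance if s == 1)

    @property
    def n_neg(self) -> int:
        return sum(1 for _, s in self.provenance if s == -1)

    @property
    def polarity(self) -> int:
        if self.forced_conflicted:
            return CONFLICTED
        np_, nn = self.n_pos, self.n_neg
        if np_ > nn:
            return 1
        if nn > np_:
            return -1
        return CONFLICTED

    @property
    def is_conflicted(self) -> bool:
        return self.polarity == CONFLICTED

    def assert_sign(self, origin: str, sign: int) -> None:
        """Record one more ``(origin, sign)`` assertion."""
        if sign not in (1, -1):
            raise ValueError(f"sign must be +1 or -1, got {sign!r}")
        self.provenance.append((origin, sign))


class CausalMap:
    """A signed directed causal map with optional focal problem node.

    At most one edge exists per ordered ``(src, dst)`` pair; repeated
    assertions accumulate in that edge's provenance.  Every edge endpoint
    is a concept of the map.
    """

    def __init__(self, map_id: str = "map", focal: Optional[str] = None):
        self.map_id = map_id
        self._concepts: dict[str, Concept] = {}
        self._edges: dict[tuple[str, str], CausalEdge] = {}
        self._focal: Optional[str] = None
        if focal is not None:
            self.set_focal(focal)

    # -- concepts ---------------------------------------------------------

    @property
    def concepts(self) -> dict[str, Concept]:
        return self._concepts

    @property
    def edges(self) -> dict[tuple[str, str], CausalEdge]:
        return self._edges

    @property
    def focal(self) -> Optional[str]:
        """Concept id of the focal problem, if set."""
        return self._focal

    def set_focal(self, label: str) -> Concept:
        c = self.add_concept(label)
        self._focal = c.id
        return c

    @property
    def n_nodes(self) -> int:
        return len(self._concepts)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def add_concept(
        self, label: str, *, protected: bool = False, aliases: Iterable[str] = ()
    ) -> Concept:
        """Return the concept with this (normalized) label, creating it if absent."""
        cid = normalize_label(label)
        if not cid:
            raise ValueError("concept label must be non-empty")
        c = self._concepts.get(cid)
        if c is None:
            c = Concept(id=cid, label=_WS.sub(" ", label.strip()), protected=protected)
            self._concepts[cid] = c
        if protected:
            c.protected = True
        for a in aliases:
            if a != c.label:
                c.aliases.add(a)
        return c

    def has_concept(self, label: str) -> bool:
        return normalize_label(label) in self._concepts

    def concept(self, label: str) -> Concept:
        return self._concepts[normalize_label(label)]

    # -- edges ------------------------------------------------------------

    def add_edge(
        self, src: str, dst: str, sign: int, origin: Optional[str] = None
    ) -> Optional[CausalEdge]:
        """Assert a signed causal link ``src -> dst``.

        Concepts are created if absent.  The edge's provenance is extended
        by ``(origin, sign)`` (``origin`` defaults to this map's id) and its
        polarity recomputed under the majority-vote conflict policy.

        A self-loop request (after label normalization) is rejected with a
        :class:`SelfLoopWarning` naming the concept, and ``None`` is
        returned.
        """
        s, d = self.add_concept(src), self.add_concept(dst)
        if s.id == d.id:
            warnings.warn(
                f"self-loop on concept {s.label!r} rejected", SelfLoopWarning,
                stacklevel=2,
            )
            return None
        key = (s.id, d.id)
        e = self._edges.get(key)
        if e is None:
            e = CausalEdge(src=s.id, dst=d.id)
            self._edges[key] = e
        e.assert_sign(self.map_id if origin is None else origin, sign)
        return e

    def get_edge(self, src: str, dst: str) -> Optional[CausalEdge]:
        return self._edges.get((normalize_label(src), normalize_label(dst)))

    def remove_concept(self, label: str) -> None:
        """Remove a concept and all incident edges."""
        cid = normalize_label(label)
        if cid not in self._concepts:
            raise KeyError(label)
        del self._concepts[cid]
        if self._focal == cid:
            self._focal = None
        for key in [k for k in self._edges if cid in k]:
            del self._edges[key]

    def in_degree(self, cid: str) -> int:
        return sum(1 for (_, d) in self._edges if d == cid)

    def out_degree(self, cid: str) -> int:
        return sum(1 for (s, _) in self._edges if s == cid)

    def degree(self, cid: str) -> int:
        return self.in_degree(cid) + self.out_degree(cid)

    # -- views ------------------------------------------------------------

    def to_networkx(self) -> nx.DiGraph:
        """Directed-graph view; nodes are concept ids, edges carry
        ``polarity``, ``n_pos``, ``n_neg`` and ``label`` attributes."""
        g = nx.DiGraph(map_id=self.map_id, focal=self._focal)
        for cid, c in self._concepts.items():
            g.add_node(cid, label=c.label, protected=c.protected)
        for (s, d), e in self._edges.items():
            g.add_edge(s, d, polarity=e.polarity, n_pos=e.n_pos, n_neg=e.n_neg)
        return g

    def copy(self, map_id: Optional[str] = None) -> "CausalMap":
        m = CausalMap(map_id=self.map_id if map_id is None else map_id)
        for c in self._concepts.values():
            m._concepts[c.id] = Concept(c.id, c.label, set(c.aliases), c.protected)
        for k, e in self._edges.items():
            m._edges[k] = CausalEdge(e.src, e.dst, list(e.provenance), e.forced_conflicted)
        m._focal = self._focal
        return m

    def signature(self, *, include_aliases: bool = True, include_focal: bool = True) -> tuple:
        """Order-independent structural identity: label sets, signed edges
        with provenance counts, and the focal id.  Two maps with equal
        signatures are the same map for every operation in this package.

        The keyword flags exist for round-trip comparisons against file
        formats that cannot carry aliases or the focal annotation (the
        plain edge-list dialect).
        """
        nodes = tuple(
            sorted(
                (c.id, c.label, tuple(sorted(c.aliases)) if include_aliases else ())
                for c in self._concepts.values()
            )
        )
        edges = tuple(
            sorted((s, d, e.polarity, e.n_pos, e.n_neg) for (s, d), e in self._edges.items())
        )
        return (nodes, edges, self._focal if include_focal else None)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CausalMap):
            return NotImplemented
        return self.signature() == other.signature()

    def __hash__(self):  # maps are mutable; identity hash
        return id(self)

    def __repr__(self) -> str:
        return (
            f"<CausalMap {self.map_id!r}: {self.n_nodes} concepts, "
            f"{self.n_edges} edges>"
        )

    def __iter__(self) -> Iterator[Concept]:
        return iter(self._concepts.values())


class Thesaurus:
    """Variant-to-canonical concept mapping with no redirect chains.

    Matching is case-insensitive and whitespace-normalized.  Looking up a
    canonical term, or any unknown string, returns the string itself, so
    ``resolve`` is always total and idempotent.
    """

    def __init__(self) -> None:
        self._entries: dict[str, str] = {}  # normalized variant -> canonical display
        self._canonical_norms: set[str] = set()

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str]], *, flatten: bool = False
    ) -> "Thesaurus":
        """Build from ``(variant, canonical)`` pairs.

        A redirect chain (``x -> y`` while ``y -> z``) is fatal unless
        ``flatten`` is set, in which case chains are flattened to their
        terminal canonical with a warning.  A variant mapped to two
        different canonicals is always fatal.
        """
        raw: dict[str, str] = {}
        display: dict[str, str] = {}
        for variant, canonical in pairs:
            v = normalize_label(variant)
            c = normalize_label(canonical)
            if not v or not c:
                raise ThesaurusError("empty variant or canonical string")
            if v == c:
                continue  # canonical fixed point, nothing to record
            if v in raw and raw[v] != c:
                raise ThesaurusError(
                    f"variant {variant!r} maps to both {display[raw[v]]!r} and {canonical!r}"
                )
            raw[v] = c
            display[c] = _WS.sub(" ", canonical.strip())

        # chain detection / flattening on normalized forms
        def terminal(c: str, seen: tuple[str, ...] = ()) -> str:
            if c in seen:
                raise ThesaurusError(f"cyclic thesaurus redirect through {c!r}")
            return terminal(raw[c], seen + (c,)) if c in raw else c

        th = cls()
        for v, c in raw.items():
            t = terminal(c)
            if t != c:
                if not flatten:
                    raise ThesaurusError(
                        f"redirect chain: {v!r} -> {display[c]!r} -> ... -> {display[t]!r} "
                        "(pass flatten=True to collapse)"
                    )
                warnings.warn(
                    f"thesaurus chain flattened: {v!r} now resolves to {display[t]!r}",
                    UserWarning, stacklevel=2,
                )
            th._entries[v] = display[t]
            th._canonical_norms.add(t)
        return th

    @property
    def entries(self) -> dict[str, str]:
        """Normalized variant -> canonical display string."""
        return dict(self._entries)

    def resolve(self, label: str) -> str:
        """Canonical form of ``label`` (the label itself if unknown)."""
        return self._entries.get(normalize_label(label), label)

    def variants_of(self, canonical: str) -> set[str]:
        c = normalize_label(canonical)
        return {v for v, canon in self._entries.items() if normalize_label(canon) == c}

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, label: str) -> bool:
        return normalize_label(label) in self._entries


@dataclass
class MapCensus:
    """Structural summary of a causal map.

    Node roles partition the concept set: *sources* only send causal
    influence (model parameters), *receivers* only receive it (model
    outputs), *transmitters* do both, and *isolated* concepts have no
    edges.  ``degree_concentration`` is ``max_degree / n_edges``, the
    fraction of all links concentrated on the single busiest concept — a
    simple centralization indicator.  ``diameter`` is ``None`` when the
    map has no edges (undefined).
    """

    n_nodes: int
    n_edges: int
    n_sources: int
    n_receivers: int
    n_transmitters: int
    n_isolated: int
    density: float
    avg_degree: float
    max_degree: int
    max_degree_concepts: list[str]
    diameter: Optional[int]
    has_cycles: bool
    degree_concentration: float

    def __post_init__(self) -> None:
        parts = self.n_sources + self.n_receivers + self.n_transmitters + self.n_isolated
        if parts != self.n_nodes:
            raise ValueError(
                f"node roles do not partition the map: "
                f"{parts} classified vs {self.n_nodes} nodes"
            )
        if not (0.0 <= self.density <= 1.0):
            raise ValueError(f"density out of range: {self.density}")

    def as_dict(self) -> dict:
        d = dict(self.__dict__)
        d["max_degree_concepts"] = list(self.max_degree_concepts)
        return d
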