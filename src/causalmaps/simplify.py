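"""Endpoint pruning and sign-preserving chain contraction.

A freshly aggregated map is typically large and unwieldy.  Two
simplifications bring it to a uniform level of granularity without
changing what the map says causally:

* **endpoint pruning** — sources (pure parameters) and receivers (pure
  outputs) judged out of scope by the experts are removed with their
  incident edges;
* **chain contraction** — a transmitter ``B`` sitting on exactly one path
  ``A -> B -> C`` may be skipped: ``B`` is removed and replaced by a
  direct edge ``A -> C`` whose sign is the product of the two edge signs,
  so the net direction of influence along the path is preserved.

Both operations are human-in-the-loop: the package proposes candidates
(:func:`propose_plan`), the experts approve subsets, and only approved
concepts are touched.  Protected concepts and the focal problem are never
candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .map_model import CausalEdge, CausalMap, normalize_label
from .metrics import NodeRole, classify_nodes

__all__ = [
    "SimplificationPlan",
    "PruneResult",
    "ContractionResult",
    "propose_plan",
    "prune_endpoints",
    "contract_chains",
]


@dataclass
class SimplificationPlan:
    """Candidates for review plus the approved subsets.

    ``sources`` and ``receivers`` list every endpoint concept for expert
    review; ``skippable`` lists transmitters with in-degree 1 and
    out-degree 1.  ``to_remove`` / ``to_contract`` hold the approved
    subsets and are validated against the candidate lists.
    """

    sources: list[str] = field(default_factory=list)
    receivers: list[str] = field(default_factory=list)
    skippable: list[str] = field(default_factory=list)
    to_remove: list[str] = field(default_factory=list)
    to_contract: list[str] = field(default_factory=list)

    @property
    def endpoints_for_review(self) -> list[str]:
        return self.sources + self.receivers

    def approve_removals(self, labels: Iterable[str]) -> None:
        pool = {normalize_label(x) for x in self.endpoints_for_review}
        for lbl in labels:
            if normalize_label(lbl) not in pool:
                raise ValueError(f"{lbl!r} is not an endpoint candidate")
            self.to_remove.append(lbl)

    def approve_contractions(self, labels: Iterable[str]) -> None:
        pool = {normalize_label(x) for x in self.skippable}
        for lbl in labels:
            if normalize_label(lbl) not in pool:
                raise ValueError(f"{lbl!r} is not a skippable-intermediate candidate")
            self.to_contract.append(lbl)


def propose_plan(cmap: CausalMap) -> SimplificationPlan:
    """List endpoint and skippable-intermediate candidates.

    Protected concepts and the focal problem never appear among the
    skippable candidates (and an attempt to remove them is rejected at
    execution time).
    """
    roles = classify_nodes(cmap)
    plan = SimplificationPlan()
    for cid in sorted(cmap.concepts):
        c = cmap.concepts[cid]
        if roles[cid] == NodeRole.SOURCE:
            plan.sources.append(c.label)
        elif roles[cid] == NodeRole.RECEIVER:
            plan.receivers.append(c.label)
        elif (
            roles[cid] == NodeRole.TRANSMITTER
            and cmap.in_degree(cid) == 1
            and cmap.out_degree(cid) == 1
            and not c.protected
            and cid != cmap.focal
        ):
            plan.skippable.append(c.label)
    return plan


@dataclass
class PruneResult:
    map: CausalMap
    removed: list[str]
    #: endpoints exposed by the removal (sources/receivers that were
    #: transmitters before); proposed for the next review round, never
    #: auto-removed.
    newly_exposed: list[str] = field(default_factory=list)


def prune_endpoints(
    cmap: CausalMap, to_remove: Sequence[str], *, iterative: bool = False
) -> PruneResult:
    """Remove approved source/receiver concepts and their incident edges.

    Every listed concept must currently be a source or a receiver and must
    not be protected or focal; violations raise with the concept named.
    With ``iterative`` set, endpoints newly exposed by the removal are
    reported for the next round of review.
    """
    roles = classify_nodes(cmap)
    out = cmap.copy()
    removed = []
    for lbl in to_remove:
        cid = normalize_label(lbl)
        if cid not in out.concepts:
            raise ValueError(f"cannot remove unknown concept {lbl!r}")
        c = out.concepts[cid]
        if c.protected or cid == cmap.focal:
            raise ValueError(f"cannot remove protected/focal concept {c.label!r}")
        if roles[cid] not in (NodeRole.SOURCE, NodeRole.RECEIVER, NodeRole.ISOLATED):
            raise ValueError(f"{c.label!r} is a transmitter, not an endpoint")
        out.remove_concept(cid)
        removed.append(c.label)
    result = PruneResult(map=out, removed=removed)
    if iterative:
        before = roles
        after = classify_nodes(out)
        endpoint = (NodeRole.SOURCE, NodeRole.RECEIVER)
        result.newly_exposed = sorted(
            out.concepts[cid].label
            for cid, r in after.items()
            if r in endpoint and before.get(cid) not in endpoint
        )
    return result


@dataclass
class ContractionResult:
    map: CausalMap
    contracted: list[str]
    #: ``(label, reason)`` for approved concepts that could not be
    #: contracted (degree precondition lost, conflicted incident edge,
    #: would create a self-loop, ...).
    skipped: list[tuple[str, str]] = field(default_factory=list)
    #: (src, dst) pairs where merging the contracted edge into an existing
    #: opposite-signed edge produced a conflicted edge.
    conflicts: list[tuple[str, str]] = field(default_factory=list)


def contract_chains(cmap: CausalMap, to_contract: Sequence[str]) -> ContractionResult:
    """Contract approved skippable intermediates, preserving path signs.

    For each contracted ``B`` with edges ``A -(s1)-> B -(s2)-> C``, ``B``
    is removed and ``A -(s1*s2)-> C`` added with the union of both edges'
    provenance.  If ``A -> C`` already exists with the same sign the
    provenance is merged; with the opposite sign the edge is marked
    conflicted and surfaced.  If ``A == C`` the contraction would create a
    self-loop, so ``B`` is retained and reported (this keeps elicited
    2-node feedback loops intact).  Chains of several approved concepts
    contract transitively, accumulating the full sign product.

    Approved concepts that no longer satisfy the in-degree-1 /
    out-degree-1 precondition when their turn comes (e.g. because an
    earlier contraction merged their edges) are reported and skipped, as
    are concepts with a sign-conflicted incident edge.
    """
    out = cmap.copy()
    result = ContractionResult(map=out, contracted=[])
    pending: dict[str, str] = {}
    for lbl in to_contract:
        cid = normalize_label(lbl)
        if cid not in out.concepts:
            raise ValueError(f"cannot contract unknown concept {lbl!r}")
        if out.concepts[cid].protected or cid == out.focal:
            raise ValueError(f"cannot contract protected/focal concept {lbl!r}")
        pending[cid] = out.concepts[cid].label

    progress = True
    while progress and pending:
        progress = False
        for cid in sorted(pending):
            ins = [(s, d) for (s, d) in out.edges if d == cid]
            outs = [(s, d) for (s, d) in out.edges if s == cid]
            if len(ins) != 1 or len(outs) != 1:
                continue  # may become contractible after another pass
            e_in, e_out = out.edges[ins[0]], out.edges[outs[0]]
            a, c = e_in.src, e_out.dst
            label = pending.pop(cid)
            if a == c:
                result.skipped.append((label, "contraction would create a self-loop"))
                progress = True
                break
            if e_in.is_conflicted or e_out.is_conflicted:
                result.skipped.append((label, "incident edge has conflicted sign"))
                progress = True
                break
            sign = e_in.polarity * e_out.polarity
            merged_prov = [(o, sign) for o, _ in e_in.provenance + e_out.provenance]
            out.remove_concept(cid)
            existing = out.edges.get((a, c))
            if existing is None:
                out.edges[(a, c)] = CausalEdge(a, c, merged_prov)
            else:
                if existing.polarity not in (sign, 0):
                    existing.forced_conflicted = True
                    result.conflicts.append((a, c))
                existing.provenance.extend(merged_prov)
            result.contracted.append(label)
            progress = True
            break

    for cid, label in pending.items():
        result.skipped.append(
            (label, f"degree precondition not met (in={out.in_degree(cid)}, out={out.out_degree(cid)})")
        )
    return result
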