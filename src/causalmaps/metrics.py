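"""Structural validation and census of a causal map.

An individual SME map is screened on four structural criteria before it
enters aggregation:

* **node roles** — sources (only outgoing influence, i.e. model
  parameters), receivers (only incoming, model outputs), transmitters
  (pass-through), isolated concepts;
* **diameter** — short causal chains suggest arguments were not well
  elaborated;
* **cycles** — feedback loops are expected in a well-facilitated map;
  their absence may reflect the known cognitive difficulty of articulating
  loops;
* **density** — elicited maps are expected to be very sparse, since
  participants are selective about the causal connections they perceive.

:func:`census` computes the full structural summary (node/edge counts,
role counts, density, degrees, diameter, cycle presence, degree
concentration) used to report a combined system map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from math import prod
from typing import Optional

import networkx as nx

from .map_model import CausalMap, MapCensus

__all__ = [
    "NodeRole",
    "QCThresholds",
    "QCFinding",
    "CycleCensus",
    "classify_nodes",
    "density",
    "degree_stats",
    "diameter",
    "cycle_census",
    "validate",
    "census",
]


class NodeRole(str, Enum):
    SOURCE = "source"          # out-degree >= 1, in-degree == 0
    RECEIVER = "receiver"      # in-degree >= 1, out-degree == 0
    TRANSMITTER = "transmitter"  # both
    ISOLATED = "isolated"      # degree 0


def classify_nodes(cmap: CausalMap) -> dict[str, NodeRole]:
    """Assign each concept exactly one structural role by in/out-degree."""
    indeg = {c: 0 for c in cmap.concepts}
    outdeg = {c: 0 for c in cmap.concepts}
    for s, d in cmap.edges:
        outdeg[s] += 1
        indeg[d] += 1
    roles = {}
    for c in cmap.concepts:
        if indeg[c] == 0 and outdeg[c] == 0:
            roles[c] = NodeRole.ISOLATED
        elif indeg[c] == 0:
            roles[c] = NodeRole.SOURCE
        elif outdeg[c] == 0:
            roles[c] = NodeRole.RECEIVER
        else:
            roles[c] = NodeRole.TRANSMITTER
    return roles


def density(cmap: CausalMap) -> float:
    """Directed density ``m / (n * (n - 1))`` (self-loops are excluded by
    construction).  Undefined for fewer than two concepts."""
    n = cmap.n_nodes
    if n < 2:
        raise ValueError(f"density undefined for {n} node(s)")
    return cmap.n_edges / (n * (n - 1))


def degree_stats(cmap: CausalMap) -> tuple[float, int, list[str]]:
    """``(avg_degree, max_degree, argmax labels)`` over total degree
    (in + out).  Average degree is ``2 m / n``; ties on the maximum return
    all argmax labels in lexicographic order."""
    n = cmap.n_nodes
    if n < 1:
        raise ValueError("degree stats undefined for an empty map")
    deg = {c: 0 for c in cmap.concepts}
    for s, d in cmap.edges:
        deg[s] += 1
        deg[d] += 1
    mx = max(deg.values())
    argmax = sorted(cmap.concepts[c].label for c, v in deg.items() if v == mx)
    return 2 * cmap.n_edges / n, mx, argmax


def diameter(cmap: CausalMap, mode: str = "directed") -> int:
    """Longest finite shortest-path length (in edges) over reachable pairs.

    ``directed`` (default) measures elaboration of causal chains; the
    ``undirected`` mode measures the same on the underlying undirected
    graph.  Unreachable pairs are ignored rather than treated as infinite.
    Undefined for a map with no edges.
    """
    if cmap.n_edges == 0:
        raise ValueError("diameter undefined for a map with no edges")
    g = cmap.to_networkx()
    if mode == "undirected":
        g = g.to_undirected()
    elif mode != "directed":
        raise ValueError(f"unknown diameter mode {mode!r}")
    best = 0
    for _, dists in nx.all_pairs_shortest_path_length(g):
        m = max(dists.values())
        if m > best:
            best = m
    return best


@dataclass
class CycleCensus:
    """Feedback-loop census.

    ``cycles`` lists vertex-simple directed cycles up to the requested
    length, each as ``(node tuple, sign)`` where the sign is the product
    of the edge polarities (``+1`` reinforcing, ``-1`` balancing, ``0`` if
    any edge on the loop is sign-conflicted).  ``truncated`` is set when
    enumeration hit the configured cap, in which case the list is partial
    but ``has_cycles`` (from the strongly-connected-component test) is
    still exact.
    """

    has_cycles: bool
    n_nontrivial_sccs: int
    cycles: list[tuple[tuple[str, ...], int]] = field(default_factory=list)
    truncated: bool = False


def cycle_census(cmap: CausalMap, max_len: int = 7, max_cycles: int = 10_000) -> CycleCensus:
    """Enumerate simple feedback loops and their signs.

    ``has_cycles`` comes from the exact SCC test (some strongly connected
    component has more than one node), independent of the enumeration cap.
    Enumeration is exhaustive up to ``max_len``; it stops with
    ``truncated=True`` after ``max_cycles`` cycles.
    """
    if max_len < 2:
        raise ValueError("max_len must be >= 2 (self-loops are excluded)")
    g = cmap.to_networkx()
    nontrivial = sum(1 for scc in nx.strongly_connected_components(g) if len(scc) > 1)
    cc = CycleCensus(has_cycles=nontrivial > 0, n_nontrivial_sccs=nontrivial)
    if not cc.has_cycles:
        return cc
    pol = {(s, d): e.polarity for (s, d), e in cmap.edges.items()}
    for cyc in nx.simple_cycles(g, length_bound=max_len):
        if len(cc.cycles) >= max_cycles:
            cc.truncated = True
            break
        sign = prod(pol[(cyc[i], cyc[(i + 1) % len(cyc)])] for i in range(len(cyc)))
        # canonical rotation so the census is order-independent
        k = min(range(len(cyc)), key=lambda i: cyc[i])
        cc.cycles.append((tuple(cyc[k:] + cyc[:k]), sign))
    cc.cycles.sort()
    return cc


@dataclass
class QCThresholds:
    """Advisory QC thresholds for individual-map screening.

    Defaults reflect what well-elaborated interview maps look like:
    individual maps in practice reach a diameter around 8, so a diameter
    below ``diameter_floor`` suggests under-elaborated chains; a map
    where more than half the concepts are sources reads as an early model
    with too many free parameters; elicited maps are expected to be very
    sparse.
    """

    diameter_floor: int = 5
    source_fraction_ceiling: float = 0.5
    density_ceiling: float = 0.05


@dataclass
class QCFinding:
    criterion: str  # node_types | diameter | cycles | density
    message: str

    def __str__(self) -> str:
        return f"[{self.criterion}] {self.message}"


def validate(cmap: CausalMap, thresholds: Optional[QCThresholds] = None) -> list[QCFinding]:
    """Screen a map against the structural QC criteria.

    All findings are advisory warnings, never errors: structure flags a
    map for review, the decision to revise rests with the facilitator.
    """
    th = thresholds or QCThresholds()
    findings: list[QCFinding] = []
    n = cmap.n_nodes
    if n == 0:
        return [QCFinding("node_types", "map is empty")]

    roles = classify_nodes(cmap)
    n_sources = sum(1 for r in roles.values() if r == NodeRole.SOURCE)
    frac = n_sources / n
    if frac > th.source_fraction_ceiling:
        findings.append(QCFinding(
            "node_types",
            f"{n_sources}/{n} concepts are sources ({frac:.0%}); an early model "
            "may have a lot of parameters — probe whether some are driven by "
            "other concepts",
        ))
    if cmap.n_edges > 0:
        diam = diameter(cmap)
        if diam < th.diameter_floor:
            findings.append(QCFinding(
                "diameter",
                f"diameter {diam} < {th.diameter_floor}; causal chains are short — "
                "arguments may not have been well elaborated",
            ))
        if not cycle_census(cmap, max_len=2).has_cycles:
            findings.append(QCFinding(
                "cycles",
                "no feedback loops; cognitive limitations may prevent "
                "stakeholders from identifying loops — probe for them",
            ))
    if n >= 2:
        dens = density(cmap)
        if dens > th.density_ceiling:
            findings.append(QCFinding(
                "density",
                f"density {dens:.3f} > {th.density_ceiling}; elicited maps are "
                "expected to be very sparse",
            ))
    return findings


def census(cmap: CausalMap) -> MapCensus:
    """Full structural census of a map (the combined-map summary table)."""
    n, m = cmap.n_nodes, cmap.n_edges
    roles = classify_nodes(cmap)
    counts = {role: 0 for role in NodeRole}
    for r in roles.values():
        counts[r] += 1
    if n >= 1 and m >= 1:
        avg, mx, argmax = degree_stats(cmap)
    else:
        avg, mx, argmax = 0.0, 0, []
    return MapCensus(
        n_nodes=n,
        n_edges=m,
        n_sources=counts[NodeRole.SOURCE],
        n_receivers=counts[NodeRole.RECEIVER],
        n_transmitters=counts[NodeRole.TRANSMITTER],
        n_isolated=counts[NodeRole.ISOLATED],
        density=density(cmap) if n >= 2 else 0.0,
        avg_degree=avg,
        max_degree=mx,
        max_degree_concepts=argmax,
        diameter=diameter(cmap) if m >= 1 else None,
        has_cycles=cycle_census(cmap, max_len=2).has_cycles,
        degree_concentration=(mx / m) if m else 0.0,
    )
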