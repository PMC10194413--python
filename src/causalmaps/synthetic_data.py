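"""Synthetic SME maps and panels.

Real individual maps come out of two-phase elicitation interviews: the
facilitator first asks systematically for direct causes and consequences
of the focal problem (producing a star around it), then probes for
mediators, more distal factors and interrelationships (extending chains
outward, cross-linking them, and occasionally closing feedback loops back
toward the focal region).  The generator emulates that shape rather than
drawing a uniform random graph, because the structural QC criteria
(diameter around 8, feedback loops present, low centralization with the
focal concept as the degree maximum) are properties of interview-shaped
maps, not of Erdős–Rényi graphs.

Construction invariants the rest of the package relies on:

* every non-back edge goes from a node at depth ``L`` to one at depth
  ``L + 1`` (negative depths are upstream of the focal problem), so with
  ``p_backedge = 0`` the map is acyclic and the directed diameter equals
  the upstream depth plus the downstream depth;
* back-edges run from a downstream concept to an immediate cause of the
  focal problem, so each one closes a directed feedback loop;
* the focal concept's star is sized to the map's max-degree target and
  every other concept is capped below it.

A *panel* shares one canonical concept pool and a deterministic per-pair
sign, so two experts asserting the same link always agree unless a sign
conflict is injected explicitly.  Lexical variants are injected per map
(an expert calls "family financial strain" what another calls "financial
strain (family)"), and the ground-truth thesaurus resolving them is
returned alongside, making panel aggregation exactly checkable.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import io_formats
from .map_model import CausalMap, Thesaurus, normalize_label
from .merge import aggregate

__all__ = [
    "GeneratorParams",
    "GroundTruth",
    "generate_sme_map",
    "generate_panel",
    "write_panel",
    "DEFAULT_FOCAL",
]

DEFAULT_FOCAL = "suicidal ideation"

_MODIFIERS = [
    "family", "community", "school", "parental", "childhood", "chronic",
    "economic", "social", "peer", "youth", "household", "neighborhood",
    "adolescent", "maternal", "caregiver", "early", "persistent", "local",
    "regional", "acute", "systemic", "interpersonal", "collective",
    "untreated", "longstanding",
]

_HEADS = [
    "stress", "trauma", "support", "isolation", "substance use",
    "violence exposure", "care access", "coping skills", "financial strain",
    "housing instability", "bullying", "connectedness", "stigma",
    "help-seeking", "sleep problems", "academic pressure", "neglect",
    "abuse", "discrimination", "food insecurity", "unemployment",
    "conflict", "supervision", "hopelessness", "self-esteem",
    "impulsivity", "safety", "belonging", "resilience", "screen time",
]


@dataclass
class GeneratorParams:
    """Conditions of a synthetic elicitation study.

    Defaults reproduce the study conditions the pipeline targets: a panel
    of 15 experts, 85 causal links per individual map, a per-map max
    degree around 15 concentrated on the focal problem, a per-map
    diameter around 8, and roughly 4 lexical variants per concept that
    collides across maps.
    """

    n_concept_pool: int = 400
    n_smes: int = 15
    edges_per_map: int = 85
    max_degree_target: int = 15
    target_diameter: int = 8
    p_negative: float = 0.25
    p_backedge: float = 0.15
    alias_rate: float = 0.3
    variants_per_aliased_term: float = 4.0
    #: probability that an assertion flips the panel-consensus sign,
    #: injecting an inter-expert sign conflict; off by default so the
    #: conflict policy can be tested in isolation.
    conflict_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("p_negative", "p_backedge", "alias_rate", "conflict_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_smes < 1:
            raise ValueError("n_smes must be >= 1")
        if self.target_diameter < 3:
            raise ValueError("target_diameter must be >= 3 (shorter maps leave "
                             "no room for mediator growth)")
        if self.max_degree_target < 4:
            raise ValueError("max_degree_target must be >= 4")
        if self.variants_per_aliased_term < 2:
            raise ValueError("variants_per_aliased_term must be >= 2")
        # the star, both forced deep chains and a little slack must fit
        floor = self.max_degree_target + 2 * self.target_diameter + 4
        if self.edges_per_map < floor:
            raise ValueError(
                f"edges_per_map={self.edges_per_map} infeasible: need >= {floor} "
                "for the focal star plus both deep chains"
            )
        if self.n_concept_pool < self.edges_per_map + 2:
            raise ValueError(
                "n_concept_pool must exceed edges_per_map + 1 so every new "
                "concept can be drawn without replacement"
            )
        if self.n_concept_pool > len(_MODIFIERS) * len(_HEADS):
            raise ValueError(
                f"n_concept_pool capped at {len(_MODIFIERS) * len(_HEADS)} distinct labels"
            )


@dataclass
class GroundTruth:
    """What the generator knows that the pipeline must recover."""

    pooled_map: CausalMap
    true_thesaurus: Thesaurus
    #: map_id -> set of (src id, dst id, polarity) canonical assertions
    per_map_membership: dict[str, set[tuple[str, str, int]]] = field(default_factory=dict)


def _concept_pool(params: GeneratorParams, rng: np.random.Generator) -> list[str]:
    combos = [f"{m} {h}" for m in _MODIFIERS for h in _HEADS]
    idx = rng.choice(len(combos), size=params.n_concept_pool, replace=False)
    return [combos[i] for i in sorted(idx)]


def _make_sign_fn(params: GeneratorParams):
    """Deterministic panel-level consensus sign for each ordered pair."""

    def sign(u: str, v: str) -> int:
        h = zlib.crc32(f"{params.seed}|{u}->{v}".encode()) % 10_000
        return -1 if h < params.p_negative * 10_000 else 1

    return sign


def _grow_map(
    params: GeneratorParams,
    focal: str,
    rng: np.random.Generator,
    pool: Sequence[str],
    sign_fn,
    core_causes: Sequence[str],
    core_consequences: Sequence[str],
    map_id: str,
) -> CausalMap:
    budget = params.edges_per_map
    d = int(np.clip(params.target_diameter + rng.choice([-1, 0, 0, 1]), 3, None))
    up, down = d - d // 2, d // 2
    k_star = int(np.clip(round(rng.normal(params.max_degree_target, 1.3)),
                         max(6, params.max_degree_target - 4),
                         params.max_degree_target + 4))
    k_star = min(k_star, budget - 2 * (d - 1) - 2)
    deg_cap = k_star - 2

    cmap = CausalMap(map_id=map_id)
    cmap.set_focal(focal)
    cmap.concept(focal).protected = True
    fid = cmap.focal
    level: dict[str, int] = {fid: 0}
    in_map = {fid}

    def draw_concept(prefer: Sequence[str] = ()) -> str:
        if prefer and rng.random() < 0.7:
            cands = [c for c in prefer if normalize_label(c) not in in_map]
            if cands:
                return cands[int(rng.integers(len(cands)))]
        while True:
            c = pool[int(rng.integers(len(pool)))]
            if normalize_label(c) not in in_map:
                return c

    def asserted_sign(u: str, v: str) -> int:
        s = sign_fn(u, v)
        if params.conflict_rate and rng.random() < params.conflict_rate:
            s = -s
        return s

    def link(src_label: str, dst_label: str) -> None:
        nonlocal budget
        cmap.add_edge(src_label, dst_label,
                      asserted_sign(normalize_label(src_label), normalize_label(dst_label)))
        budget -= 1

    def add_node(label: str, lvl: int, parent_label: str) -> str:
        nonlocal budget
        cid = normalize_label(label)
        in_map.add(cid)
        level[cid] = lvl
        if lvl < 0:
            link(label, parent_label)
        else:
            link(parent_label, label)
        # a new downstream concept may feed back toward the focal region
        if lvl > 0 and budget > 0 and params.p_backedge and rng.random() < params.p_backedge:
            targets = [t for t in in_map
                       if level[t] == -1 and cmap.degree(t) < deg_cap and t != cid
                       and (cid, t) not in cmap.edges]
            if targets:
                t = sorted(targets)[int(rng.integers(len(targets)))]
                link(cmap.concepts[cid].label, cmap.concepts[t].label)
        return cid

    # ---- phase 1: the focal star --------------------------------------
    n_causes = k_star // 2 + int(rng.integers(0, 2))
    n_causes = min(max(n_causes, 2), k_star - 2)
    causes = []
    for _ in range(n_causes):
        causes.append(add_node(draw_concept(core_causes), -1, focal))
    cons = []
    for _ in range(k_star - n_causes):
        cons.append(add_node(draw_concept(core_consequences), +1, focal))

    # ---- phase 2a: force one deep chain on each side ------------------
    tip = causes[int(rng.integers(len(causes)))]
    for lvl in range(-2, -up - 1, -1):
        tip = add_node(draw_concept(), lvl, cmap.concepts[tip].label)
    tip = cons[int(rng.integers(len(cons)))]
    for lvl in range(2, down + 1):
        tip = add_node(draw_concept(), lvl, cmap.concepts[tip].label)

    # ---- phase 2b: mediators, distal factors, interrelationships ------
    stall = 0
    while budget > 0:
        stall += 1
        if stall > 50 * params.edges_per_map:
            raise RuntimeError("generator stalled; parameters leave no legal move")
        act = rng.random()
        if act < 0.65:  # extend a chain with a new concept
            go_down = rng.random() < 0.6
            lo, hi = (1, down - 1) if go_down else (-up + 1, -1)
            cands = [c for c in in_map
                     if lo <= level[c] <= hi and cmap.degree(c) < deg_cap]
            if not cands:
                continue
            u = sorted(cands)[int(rng.integers(len(cands)))]
            lvl = level[u] + 1 if go_down else level[u] - 1
            add_node(draw_concept(), lvl, cmap.concepts[u].label)
        else:  # cross-link two existing concepts at adjacent depths
            by_level: dict[int, list[str]] = {}
            for c in in_map:
                if c != fid:
                    by_level.setdefault(level[c], []).append(c)
            pairs = [(l, l + 1) for l in by_level
                     if l + 1 in by_level and l + 1 != 0 and l != 0]
            if not pairs:
                continue
            la, lb = pairs[int(rng.integers(len(pairs)))]
            a = sorted(by_level[la])[int(rng.integers(len(by_level[la])))]
            b = sorted(by_level[lb])[int(rng.integers(len(by_level[lb])))]
            if a == b or (a, b) in cmap.edges:
                continue
            if cmap.degree(a) >= deg_cap or cmap.degree(b) >= deg_cap:
                continue
            link(cmap.concepts[a].label, cmap.concepts[b].label)
    return cmap


def generate_sme_map(
    params: Optional[GeneratorParams] = None,
    focal: str = DEFAULT_FOCAL,
    rng: Optional[np.random.Generator] = None,
) -> CausalMap:
    """Generate one synthetic individual SME map around ``focal``.

    Deterministic under ``params.seed`` (or an explicitly supplied
    ``rng``): the map is weakly connected, contains the focal concept,
    has exactly ``edges_per_map`` edges, and contains at least one
    directed feedback loop with overwhelming probability whenever
    ``p_backedge > 0`` (and never when it is 0).
    """
    params = params or GeneratorParams()
    params.validate()
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    pool = _concept_pool(params, np.random.default_rng(params.seed))
    sign_fn = _make_sign_fn(params)
    core = list(pool)
    return _grow_map(params, focal, rng, pool, sign_fn,
                     core_causes=core[:30], core_consequences=core[30:50],
                     map_id=f"sme-{params.seed}")


# ---------------------------------------------------------------------------
# lexical variants

_VARIANT_FORMS = [
    lambda s, w: f"level of {s}",
    lambda s, w: f"{w[-1]} ({' '.join(w[:-1])})" if len(w) > 1 else f"{s} (general)",
    lambda s, w: f"high {s}",
    lambda s, w: f"{s} issues",
    lambda s, w: "-".join(w) if len(w) > 1 else f"{s} status",
    lambda s, w: f"overall {s}",
    lambda s, w: f"{s} problems",
    lambda s, w: f"degree of {s}",
    lambda s, w: f"{s} (reported)",
    lambda s, w: f"extent of {s}",
]


class _VariantFactory:
    """Deterministic lexical variants of canonical labels.

    Variants are built by re-ordering, prefixing and parenthesization of
    the canonical label, so alias suggestion has realistic work to do.
    Each canonical term gets a small pool of variants (mean size
    ``variants_per_aliased_term``), and every generated string is kept
    globally unique so a variant can never collide with another concept.
    """

    def __init__(self, params: GeneratorParams, rng: np.random.Generator, reserved: set[str]):
        self._params = params
        self._rng = rng
        self._used = set(reserved)
        self._pools: dict[str, list[str]] = {}

    def pool_for(self, label: str) -> list[str]:
        cid = normalize_label(label)
        if cid not in self._pools:
            k = max(2, int(self._rng.poisson(self._params.variants_per_aliased_term)))
            words = label.split()
            variants = []
            j = 0
            while len(variants) < k and j < 4 * len(_VARIANT_FORMS):
                form = _VARIANT_FORMS[j % len(_VARIANT_FORMS)](label, words)
                if j >= len(_VARIANT_FORMS):
                    form = f"{form} ({j // len(_VARIANT_FORMS)})"
                j += 1
                if normalize_label(form) not in self._used:
                    self._used.add(normalize_label(form))
                    variants.append(form)
            self._pools[cid] = variants
        return self._pools[cid]

    def items(self):
        for cid, variants in self._pools.items():
            for v in variants:
                yield v, cid


def _alias_map(
    cmap: CausalMap, params: GeneratorParams, rng: np.random.Generator,
    factory: _VariantFactory,
) -> CausalMap:
    """Rewrite a canonical map with map-specific lexical variants."""
    rename: dict[str, str] = {}
    for cid in sorted(cmap.concepts):
        if cid == cmap.focal:
            continue  # the focal problem is fixed by the facilitator
        if rng.random() < params.alias_rate:
            pool = factory.pool_for(cmap.concepts[cid].label)
            if pool:
                rename[cid] = pool[int(rng.integers(len(pool)))]
    out = CausalMap(map_id=cmap.map_id)
    for cid in cmap.concepts:
        out.add_concept(rename.get(cid, cmap.concepts[cid].label))
    for (s, d), e in cmap.edges.items():
        for origin, sign in e.provenance:
            out.add_edge(rename.get(s, cmap.concepts[s].label),
                         rename.get(d, cmap.concepts[d].label), sign, origin=origin)
    if cmap.focal is not None:
        out.set_focal(cmap.concepts[cmap.focal].label)
        out.concept(cmap.concepts[cmap.focal].label).protected = True
    return out


def generate_panel(
    params: Optional[GeneratorParams] = None, focal: str = DEFAULT_FOCAL
) -> tuple[list[CausalMap], GroundTruth]:
    """Generate a panel of synthetic SME maps plus its ground truth.

    Returns ``n_smes`` maps (with lexical variants injected at
    ``alias_rate``) and a :class:`GroundTruth` carrying the canonical
    pooled map, the thesaurus resolving every injected variant, and each
    map's canonical edge membership.  Aggregating the panel with the true
    thesaurus reconstructs the pooled map exactly when no sign conflicts
    are injected.
    """
    params = params or GeneratorParams()
    params.validate()
    master = np.random.default_rng(params.seed)
    pool = _concept_pool(params, np.random.default_rng(params.seed))
    sign_fn = _make_sign_fn(params)
    core_causes, core_consequences = pool[:30], pool[30:50]

    canonical_maps = []
    map_rngs = master.spawn(params.n_smes + 1)
    for i in range(params.n_smes):
        canonical_maps.append(
            _grow_map(params, focal, map_rngs[i], pool, sign_fn,
                      core_causes, core_consequences, map_id=f"sme{i + 1:02d}")
        )

    pooled, _ = aggregate(canonical_maps)
    truth = GroundTruth(pooled_map=pooled, true_thesaurus=Thesaurus())
    for m in canonical_maps:
        truth.per_map_membership[m.map_id] = {
            (s, d, e.polarity) for (s, d), e in m.edges.items()
        }

    reserved = {normalize_label(p) for p in pool} | {normalize_label(focal)}
    factory = _VariantFactory(params, map_rngs[-1], reserved)
    panel = [_alias_map(m, params, map_rngs[-1], factory) for m in canonical_maps]

    pairs = [(v, pooled.concepts[cid].label if cid in pooled.concepts else cid)
             for v, cid in factory.items()]
    truth.true_thesaurus = Thesaurus.from_pairs(pairs)
    return panel, truth


def write_panel(
    directory: Path | str, panel: Sequence[CausalMap], truth: GroundTruth
) -> None:
    """Write one edge-list CSV per synthetic SME plus the ground-truth
    thesaurus and pooled map."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for m in panel:
        io_formats.write_map(m, directory / f"{m.map_id}.csv", "edgelist-csv")
    io_formats.write_thesaurus(truth.true_thesaurus, directory / "truth_thesaurus.csv")
    io_formats.write_map(truth.pooled_map, directory / "truth_pooled.csv", "edgelist-csv")
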