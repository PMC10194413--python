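# Methods

## The object of study

An individual causal map is a signed digraph elicited in a facilitated
interview around one focal problem. The package treats such maps, and
their aggregate, as first-class objects: concepts are identified by a
normalized label (trimmed, internal whitespace collapsed, case-folded;
display casing preserved), edges carry a polarity in {+1, −1} and a
provenance multiset of (map-id, sign) assertions, and at most one edge
exists per ordered pair. Self-loops are rejected at ingest: the feedback
of interest is multi-node loops, and a one-node loop has no
interpretation in this formalism. Concepts carry no weights — the
elicitation records only the direction of influence, so numeric weights
in input files are reduced to their sign (zero means "no edge").

## Conflict policy

Nothing in the elicitation protocol forces two experts to agree on a
sign. When a pair (src, dst) accumulates mixed assertions, the edge takes
the majority sign; an exact tie makes it *conflicted* (polarity 0).
Conflicted edges stay in the map (the disagreement is data) but are
excluded from sign-dependent operations — chain contraction skips them —
until a curator resolves them. When a contraction merges a new edge into
an existing edge of the opposite sign, the result is likewise forced to
the conflicted state and surfaced, rather than letting provenance counts
silently pick a winner; this flag survives serialization in all three
formats.

## Structural QC and census

Node typology, density m/(n(n−1)), average total degree 2m/n, maximum
total degree and degree concentration (max degree / m, a simple
centralization indicator) are computed directly. Two conventions are
deliberately explicit:

- **Diameter** defaults to the directed definition — the longest finite
  shortest-path length over ordered reachable pairs — because the
  quantity is meant to measure how elaborated *causal chains* are, and
  chains are directed. An undirected mode is provided because published
  map summaries do not always state their convention; reported checks
  against an external map accept either mode.
- **Average degree** is kept at full precision and *displayed* at 3
  decimal places alongside the exact value, so display rounding can never
  masquerade as a different number.

Feedback-loop presence uses the exact strongly-connected-component test
and is never capped; the signed simple-cycle *enumeration* (sign =
product of edge polarities; + reinforcing, − balancing) is exhaustive up
to a configurable length (default 7) and count cap (default 10,000),
because simple-cycle counts grow exponentially while the QC question —
"are there loops, and of which kind are the short ones?" — does not need
the full list.

QC findings are advisory and threshold-based: diameter below 5 (elicited
maps from engaged experts reach about 8), source fraction above 0.5 (an
early model with too many free parameters), density above 0.05 (elicited
maps are very sparse). All thresholds are configurable; the defaults
encode qualitative expectations, not sharp facts.

## Canonicalization and aggregation

The thesaurus is a chain-free variant → canonical mapping; lookups are
total (unknown and canonical strings return themselves), matching is
case- and whitespace-insensitive, and redirect chains are fatal unless
explicitly flattened. Canonicalization is idempotent; merged concepts
keep every absorbed surface form as an alias, and edges whose endpoints
collapse together are dropped and recorded rather than silently becoming
self-loops. Aggregation unions canonical concepts and edges, merges
provenance multisets, and is invariant under panel permutation (verified
property). Alias *suggestion* ranks cross-map label pairs by the better
of a plain and a token-order-insensitive string ratio (stdlib sequence
matching); it is advisory only, since concept equivalence is a semantic
judgment that belongs to the experts.

## Simplification

Simplification is plan → approve → execute, mirroring the
expert-in-the-loop consultation of a real study: the package lists all
sources and receivers for review and all transmitters with in-degree 1
and out-degree 1 as skippable, and touches only approved concepts (an
`--auto` mode contracts all skippables for batch experiments). Endpoint
pruning refuses transmitters, protected concepts and the focal problem by
name. Contraction replaces A →(s₁) B →(s₂) C with A →(s₁·s₂) C, merging
provenance with the assertion signs rewritten to the path product;
approved chains contract transitively with the full product. Contractions
that would create a self-loop (A = C) are refused so elicited 2-node
loops survive. Two invariants are enforced by test: contraction never
changes the degree of any non-neighbor of a contracted concept, and never
creates reachability that did not exist.

## The synthetic generator

The generator emulates the two-phase interview: phase 1 builds a star of
direct causes and consequences around the focal problem; phase 2 deepens
chains outward (mediators and distal factors), cross-links adjacent
depths, and lets each new downstream concept close a feedback loop toward
the focal region with probability `p_backedge`. Construction invariants:
every non-back edge goes from depth L to L+1, so `p_backedge = 0` yields
a DAG and the directed diameter equals the chosen upstream plus
downstream depth; back-edges run to depth −1, so each closes a cycle
without lengthening any shortest forward path; the focal star is sized by
the map's max-degree draw and every other concept is capped below it.

Defaults encode the study conditions the pipeline targets: 15 experts,
exactly 85 edges per map, max-degree target 15 (drawn per map with s.d.
1.3), diameter target 8 (±1 jitter), `p_negative = 0.25` (roughly a
quarter of elicited links are protective/decreasing — a choice, as real
per-map sign ratios are not published), `p_backedge = 0.15`, concept pool
of 400 canonical terms (so a 15-map panel pools to a combined map in the
~360-concept range), `alias_rate = 0.3` and about 4 lexical variants per
aliased term. Panel-level signs are a deterministic function of the
ordered pair, so two experts asserting the same link always agree unless
`conflict_rate` injects disagreement explicitly. Lexical variants are
deterministic transforms (re-ordering, prefixing, parenthesization,
hyphenation) kept globally unique, and the generating thesaurus is
returned as ground truth, which makes panel aggregation exactly
checkable (node and signed-edge precision and recall of 1.0 at defaults).

What the generator does **not** emulate: real transcripts and their
coding ambiguity, heterogeneous expert expertise, semantic (rather than
lexical) synonymy, weighted or uncertain assertions, and interview-length
effects. Passing tests therefore show the pipeline's correctness on
interview-*shaped* graphs, not the fidelity of any substantive claim
about suicide or ACEs.

## Problem sizes and determinism

Oracle-equivalence checks run on 500 random digraphs of up to 8 nodes,
where exhaustive Floyd–Warshall, DFS cycle enumeration and simple-path
enumeration are feasible as independent second routes; contraction checks
use 200 such maps; generator calibration uses 100 seeded replicates.
Every stochastic component is driven by an explicit integer seed
(NumPy `default_rng`, spawned per map), and equal seeds give
byte-identical panels and pipeline artifacts; the run log records the
tool version and a configuration hash, never timestamps.

## Known limitations

- The pipeline identifies concepts lexically (after normalization and the
  thesaurus); it will not unify true synonyms absent from the thesaurus.
- The census of an external combined map depends on the unstated diameter
  convention of its source; both modes are reported for that reason.
- Cycle enumeration beyond the cap is truncated (flagged); only loop
  *existence* is always exact.
- The endpoint-pruning stage models expert consultation as an explicit
  approved list; it offers no heuristic for which endpoints matter.
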