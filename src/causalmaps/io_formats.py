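"""Readers and writers for the file formats the pipeline touches.

Supported inputs:

* signed edge lists (CSV: ``source, target, polarity[, n_pos, n_neg]``),
  with a configurable polarity vocabulary;
* MentalModeler-style signed adjacency matrices (first row and column are
  concept labels, cell ``(i, j)`` is the signed weight of ``i -> j``);
* thesaurus CSVs (``variant, canonical``).

Supported outputs: the canonical edge-list dialect, GraphML and JSON.
Output ordering is deterministic (normalized-label lexicographic), so two
writes of the same map are byte-identical.

Numeric edge weights are reduced to their sign: the elicitation protocol
records only polarity, not strength.  A weight of exactly zero means "no
edge" and the row/cell is skipped with a warning.

The plain edge-list dialect cannot represent isolated concepts, alias
sets or the focal annotation; JSON and GraphML carry the full model.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import networkx as nx

from .map_model import CausalEdge, CausalMap, SelfLoopWarning, Thesaurus

__all__ = [
    "EdgeListDialect",
    "DEFAULT_DIALECT",
    "EdgeListFormatError",
    "read_edgelist",
    "read_adjacency_matrix",
    "read_thesaurus",
    "write_thesaurus",
    "write_map",
    "read_map",
    "load_osf_release",
]

PathLike = Union[str, Path]


class EdgeListFormatError(ValueError):
    """Malformed edge-list / adjacency input (carries file context)."""


@dataclass
class EdgeListDialect:
    """How to interpret a signed edge-list file.

    ``polarity_vocabulary`` maps accepted tokens to a sign; tokens not in
    the table fall back to numeric parsing, where the cell's sign is used
    and zero means "no edge".
    """

    delimiter: str = ","
    header: bool = True
    polarity_vocabulary: dict[str, int] = field(
        default_factory=lambda: {
            "+": 1, "-": -1,
            "+1": 1, "-1": -1, "1": 1,
            "increase": 1, "decrease": -1,
            "increases": 1, "decreases": -1,
            "positive": 1, "negative": -1,
        }
    )

    def sign_of(self, token: str) -> Optional[int]:
        """Sign for a polarity token; 0 for "no edge"; None if unknown."""
        t = token.strip().lower()
        if t in self.polarity_vocabulary:
            return self.polarity_vocabulary[t]
        try:
            x = float(t)
        except ValueError:
            return None
        return 0 if x == 0 else (1 if x > 0 else -1)


DEFAULT_DIALECT = EdgeListDialect()


def read_edgelist(
    path: PathLike,
    dialect: EdgeListDialect = DEFAULT_DIALECT,
    *,
    map_id: Optional[str] = None,
) -> CausalMap:
    """Read a signed edge list into a :class:`CausalMap`.

    Rows need at least three columns (source, target, polarity).  If the
    canonical provenance columns ``n_pos, n_neg`` are present, provenance
    counts are reconstructed.  Self-loop rows and zero-weight rows are
    skipped with a warning naming the line; an unknown polarity token is a
    row-level :class:`EdgeListFormatError` with the line number.
    """
    path = Path(path)
    cmap = CausalMap(map_id=map_id or path.stem)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter=dialect.delimiter)
        rows = list(reader)
    start = 0
    has_counts = False
    if dialect.header and rows:
        head = [h.strip().lower() for h in rows[0]]
        has_counts = "n_pos" in head and "n_neg" in head
        start = 1
    body = [(i + 1, r) for i, r in enumerate(rows) if i >= start and any(c.strip() for c in r)]
    if not body:
        warnings.warn(f"{path.name}: no edge rows, returning empty map", UserWarning, stacklevel=2)
        return cmap
    for lineno, row in body:
        if len(row) < 3:
            raise EdgeListFormatError(
                f"{path.name}:{lineno}: expected >=3 columns (source, target, polarity), got {len(row)}"
            )
        src, dst, tok = row[0], row[1], row[2]
        sign = dialect.sign_of(tok)
        if sign is None:
            raise EdgeListFormatError(
                f"{path.name}:{lineno}: unknown polarity token {tok.strip()!r}"
            )
        if sign == 0:
            warnings.warn(
                f"{path.name}:{lineno}: zero weight means no edge, row skipped",
                UserWarning, stacklevel=2,
            )
            continue
        if has_counts and len(row) >= 5:
            s, d = cmap.add_concept(src), cmap.add_concept(dst)
            if s.id == d.id:
                warnings.warn(
                    f"{path.name}:{lineno}: self-loop on {s.label!r} skipped",
                    SelfLoopWarning, stacklevel=2,
                )
                continue
            n_pos, n_neg = int(row[3]), int(row[4])
            prov = [(cmap.map_id, 1)] * n_pos + [(cmap.map_id, -1)] * n_neg
            forced = tok.strip() == "0" and n_pos != n_neg
            cmap.edges[(s.id, d.id)] = CausalEdge(s.id, d.id, prov, forced)
        else:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                cmap.add_edge(src, dst, sign)
            for w in caught:
                warnings.warn(f"{path.name}:{lineno}: {w.message}", w.category, stacklevel=2)
    return cmap


def read_adjacency_matrix(path: PathLike, *, map_id: Optional[str] = None) -> CausalMap:
    """Read a MentalModeler-style signed adjacency CSV.

    The first row and first column are concept labels; cell ``(i, j)`` is
    the signed weight of the edge ``i -> j`` (reduced to its sign).  A
    non-square matrix is fatal; nonzero diagonal cells are skipped with a
    warning.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        rows = [r for r in csv.reader(fh) if any(c.strip() for c in r)]
    if not rows:
        raise EdgeListFormatError(f"{path.name}: empty adjacency file")
    col_labels = [c.strip() for c in rows[0][1:]]
    n = len(col_labels)
    if len(rows) - 1 != n:
        raise EdgeListFormatError(
            f"{path.name}: non-square matrix ({len(rows) - 1} rows vs {n} columns)"
        )
    cmap = CausalMap(map_id=map_id or path.stem)
    row_labels = []
    for r in rows[1:]:
        if len(r) - 1 != n:
            raise EdgeListFormatError(
                f"{path.name}: row {r[0]!r} has {len(r) - 1} cells, expected {n}"
            )
        row_labels.append(r[0].strip())
    if [l.lower() for l in row_labels] != [l.lower() for l in col_labels]:
        raise EdgeListFormatError(f"{path.name}: row and column labels differ")
    for label in row_labels:
        cmap.add_concept(label)
    for i, r in enumerate(rows[1:]):
        for j, cell in enumerate(r[1:]):
            cell = cell.strip()
            if not cell:
                continue
            try:
                w = float(cell)
            except ValueError:
                raise EdgeListFormatError(
                    f"{path.name}: non-numeric cell {cell!r} at ({row_labels[i]!r}, {col_labels[j]!r})"
                ) from None
            if w == 0:
                continue
            if i == j:
                warnings.warn(
                    f"{path.name}: diagonal cell for {row_labels[i]!r} skipped",
                    SelfLoopWarning, stacklevel=2,
                )
                continue
            cmap.add_edge(row_labels[i], col_labels[j], 1 if w > 0 else -1)
    return cmap


def read_thesaurus(path: PathLike, *, flatten: bool = False) -> Thesaurus:
    """Read a two-column ``variant, canonical`` CSV into a :class:`Thesaurus`.

    Redirect chains are fatal unless ``flatten`` is set (then collapsed to
    the terminal canonical with a warning); a variant mapped to two
    different canonicals is always fatal.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with path.open(newline="") as fh:
        for i, row in enumerate(csv.reader(fh)):
            if not row or not any(c.strip() for c in row):
                continue
            if i == 0 and [c.strip().lower() for c in row[:2]] == ["variant", "canonical"]:
                continue
            if len(row) < 2:
                raise EdgeListFormatError(f"{path.name}:{i + 1}: expected 2 columns")
            pairs.append((row[0], row[1]))
    return Thesaurus.from_pairs(pairs, flatten=flatten)


def write_thesaurus(th: Thesaurus, path: PathLike) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["variant", "canonical"])
        for v, c in sorted(th.entries.items()):
            w.writerow([v, c])


# ---------------------------------------------------------------------------
# map writers / readers

_FORMATS = ("edgelist-csv", "graphml", "json")


def write_map(cmap: CausalMap, path: PathLike, fmt: str = "edgelist-csv") -> None:
    """Write a map to ``path`` in one of ``edgelist-csv``, ``graphml``, ``json``.

    Output is deterministic: concepts and edges are emitted in
    normalized-label lexicographic order.
    """
    path = Path(path)
    if fmt == "edgelist-csv":
        _write_edgelist(cmap, path)
    elif fmt == "graphml":
        _write_graphml(cmap, path)
    elif fmt == "json":
        _write_json(cmap, path)
    else:
        raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")


def read_map(path: PathLike, fmt: Optional[str] = None, *, map_id: Optional[str] = None) -> CausalMap:
    """Read a map written by :func:`write_map` (format inferred from the
    suffix when ``fmt`` is omitted)."""
    path = Path(path)
    if fmt is None:
        fmt = {".csv": "edgelist-csv", ".graphml": "graphml", ".json": "json"}.get(path.suffix)
        if fmt is None:
            raise ValueError(f"cannot infer format from suffix {path.suffix!r}")
    if fmt == "edgelist-csv":
        return read_edgelist(path, map_id=map_id)
    if fmt == "graphml":
        return _read_graphml(path, map_id=map_id)
    if fmt == "json":
        return _read_json(path, map_id=map_id)
    raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")


def _sorted_edges(cmap: CausalMap):
    return sorted(cmap.edges.items(), key=lambda kv: kv[0])


def _write_edgelist(cmap: CausalMap, path: Path) -> None:
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["source", "target", "polarity", "n_pos", "n_neg"])
        for (s, d), e in _sorted_edges(cmap):
            w.writerow(
                [cmap.concepts[s].label, cmap.concepts[d].label,
                 f"{e.polarity:+d}" if e.polarity else "0", e.n_pos, e.n_neg]
            )


def _write_graphml(cmap: CausalMap, path: Path) -> None:
    g = nx.DiGraph()
    g.graph["map_id"] = cmap.map_id
    if cmap.focal is not None:
        g.graph["focal"] = cmap.focal
    for cid in sorted(cmap.concepts):
        c = cmap.concepts[cid]
        g.add_node(cid, label=c.label, protected=c.protected,
                   aliases=json.dumps(sorted(c.aliases)))
    for (s, d), e in _sorted_edges(cmap):
        g.add_edge(s, d, polarity=e.polarity, n_pos=e.n_pos, n_neg=e.n_neg,
                   conflicted=e.forced_conflicted,
                   provenance=json.dumps(sorted(e.provenance)))
    nx.write_graphml(g, path, named_key_ids=True)


def _read_graphml(path: Path, *, map_id: Optional[str] = None) -> CausalMap:
    g = nx.read_graphml(path)
    cmap = CausalMap(map_id=map_id or g.graph.get("map_id", path.stem))
    for cid, data in g.nodes(data=True):
        cmap.add_concept(
            data.get("label", cid),
            protected=bool(data.get("protected", False)),
            aliases=json.loads(data.get("aliases", "[]")),
        )
    for s, d, data in g.edges(data=True):
        if "provenance" in data:
            prov = [(o, int(sg)) for o, sg in json.loads(data["provenance"])]
        else:
            prov = [(cmap.map_id, int(data.get("polarity", 1)) or 1)]
        cmap.edges[(s, d)] = CausalEdge(s, d, prov, bool(data.get("conflicted", False)))
    focal = g.graph.get("focal")
    if focal is not None and focal in cmap.concepts:
        cmap.set_focal(focal)
    return cmap


def _write_json(cmap: CausalMap, path: Path) -> None:
    doc = {
        "map_id": cmap.map_id,
        "focal": cmap.focal,
        "concepts": [
            {
                "id": cid,
                "label": cmap.concepts[cid].label,
                "aliases": sorted(cmap.concepts[cid].aliases),
                "protected": cmap.concepts[cid].protected,
            }
            for cid in sorted(cmap.concepts)
        ],
        "edges": [
            {
                "src": s, "dst": d,
                "polarity": e.polarity, "n_pos": e.n_pos, "n_neg": e.n_neg,
                "conflicted": e.forced_conflicted,
                "provenance": sorted(e.provenance),
            }
            for (s, d), e in _sorted_edges(cmap)
        ],
    }
    path.write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def _read_json(path: Path, *, map_id: Optional[str] = None) -> CausalMap:
    doc = json.loads(path.read_text())
    cmap = CausalMap(map_id=map_id or doc.get("map_id", path.stem))
    for c in doc["concepts"]:
        cmap.add_concept(c["label"], protected=c.get("protected", False),
                         aliases=c.get("aliases", ()))
    for e in doc["edges"]:
        prov = [(o, int(s)) for o, s in e.get("provenance", [])]
        cmap.edges[(e["src"], e["dst"])] = CausalEdge(
            e["src"], e["dst"], prov, bool(e.get("conflicted", False))
        )
    if doc.get("focal"):
        cmap.set_focal(doc["focal"])
    return cmap


def load_osf_release(directory: PathLike) -> tuple[CausalMap, Thesaurus]:
    """Load the openly released combined map and thesaurus from a local
    directory (``combined_map.csv`` + ``thesaurus.csv``).

    The study's combined map and thesaurus are published on an open
    repository; this helper reads a locally downloaded copy (the package
    never fetches over the network).  The map file may be either a signed
    edge list or a MentalModeler-style adjacency matrix.
    """
    directory = Path(directory)
    map_path = directory / "combined_map.csv"
    th_path = directory / "thesaurus.csv"
    if not map_path.exists() or not th_path.exists():
        raise FileNotFoundError(
            f"released files not found under {directory}/ "
            "(expected combined_map.csv and thesaurus.csv; download them "
            "from the study's open repository first)"
        )
    try:
        cmap = read_edgelist(map_path, map_id="combined")
    except EdgeListFormatError:
        cmap = read_adjacency_matrix(map_path, map_id="combined")
    return cmap, read_thesaurus(th_path, flatten=True)
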