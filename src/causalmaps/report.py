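"""Human-readable reporting: census tables, QC and merge reports."""

from __future__ import annotations

import csv
import io
import json
from typing import Sequence

from .map_model import MapCensus
from .merge import MergeReport
from .metrics import QCFinding

__all__ = ["census_rows", "census_table", "census_csv", "census_json",
           "qc_text", "merge_report_json"]


def census_rows(c: MapCensus) -> list[tuple[str, str]]:
    """Census as (row label, displayed value) pairs.

    Density and average degree are displayed at 3 decimal places, with
    the full-precision average alongside so no information is lost to
    display rounding.
    """
    rows = [
        ("Number of nodes", str(c.n_nodes)),
        ("Number of source nodes", str(c.n_sources)),
        ("Number of receiver nodes", str(c.n_receivers)),
        ("Number of transmitter nodes", str(c.n_transmitters)),
        ("Number of isolated nodes", str(c.n_isolated)),
        ("Number of edges", str(c.n_edges)),
        ("Density", f"{c.density:.3f}"),
        ("Average degree", f"{c.avg_degree:.3f} (exact {c.avg_degree!r})"),
        ("Maximum degree", f"{c.max_degree} ({', '.join(c.max_degree_concepts)})"
                           if c.max_degree_concepts else str(c.max_degree)),
        ("Diameter", str(c.diameter) if c.diameter is not None else "undefined (no edges)"),
        ("Contains feedback loops", "yes" if c.has_cycles else "no"),
        ("Degree concentration", f"{c.degree_concentration:.3f}"),
    ]
    return rows


def census_table(c: MapCensus, title: str = "Characteristics of the map") -> str:
    rows = census_rows(c)
    width = max(len(k) for k, _ in rows)
    lines = [title, "-" * len(title)]
    lines += [f"{k:<{width}}  {v}" for k, v in rows]
    return "\n".join(lines)


def census_csv(c: MapCensus) -> str:
    buf = io.StringIO()
    w = csv.writer(buf)
    w.writerow(["Structural characteristic", "Value"])
    for k, v in census_rows(c):
        w.writerow([k, v])
    return buf.getvalue()


def census_json(c: MapCensus) -> str:
    return json.dumps(c.as_dict(), indent=1, sort_keys=True) + "\n"


def qc_text(map_id: str, findings: Sequence[QCFinding]) -> str:
    if not findings:
        return f"{map_id}: all structural checks passed\n"
    lines = [f"{map_id}: {len(findings)} finding(s)"]
    lines += [f"  {f}" for f in findings]
    return "\n".join(lines) + "\n"


def merge_report_json(r: MergeReport) -> str:
    doc = {
        "n_maps": r.n_maps,
        "n_terms_resolved": r.n_terms_resolved,
        "resolved_terms": r.resolved_terms,
        "variants_per_term": r.variants_per_term,
        "mean_variants_per_term": r.mean_variants_per_term,
        "n_sign_conflicts": r.n_sign_conflicts,
        "collapsed_self_loops": [
            {"edge": list(pair), "canonical": canon}
            for pair, canon in r.collapsed_self_loops
        ],
    }
    return json.dumps(doc, indent=1, sort_keys=True) + "\n"
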