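"""End-to-end pipeline: validate each map, merge, plan simplification,
census the result, and write an artifact directory.

Re-running with the same configuration and inputs produces identical
artifacts (the run log records the tool version and a config hash, no
timestamps), so pipelines are diffable across runs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

from . import __version__, io_formats, metrics, report
from .config import PipelineConfig
from .map_model import CausalMap, Thesaurus
from .merge import aggregate
from .simplify import propose_plan

__all__ = ["run_pipeline"]


def run_pipeline(
    config: PipelineConfig,
    inputs: Sequence[CausalMap],
    out_dir: Path | str,
    thesaurus: Optional[Thesaurus] = None,
    *,
    census_only: bool = False,
) -> Path:
    """Run validate -> merge -> simplification plan -> census.

    With ``census_only`` (or a single input and no thesaurus) the merge
    and planning stages are skipped and only QC + census artifacts are
    written.  Returns the artifact directory.
    """
    if not inputs:
        raise ValueError("pipeline needs at least one input map")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"causalmaps {__version__}", f"config {config.digest()}"]
    th = metrics.QCThresholds(
        diameter_floor=config.diameter_floor,
        source_fraction_ceiling=config.source_fraction_ceiling,
        density_ceiling=config.density_ceiling,
    )

    stage = "validate"
    try:
        for m in inputs:
            findings = metrics.validate(m, th)
            (out / f"qc_{m.map_id}.txt").write_text(report.qc_text(m.map_id, findings))
            log.append(f"validate {m.map_id}: {len(findings)} finding(s)")

        if census_only or (len(inputs) == 1 and thesaurus is None):
            final = inputs[0]
        else:
            stage = "merge"
            final, mreport = aggregate(inputs, thesaurus)
            ext = {"edgelist-csv": "csv", "graphml": "graphml", "json": "json"}[config.output_format]
            io_formats.write_map(final, out / f"combined.{ext}", config.output_format)
            (out / "merge_report.json").write_text(report.merge_report_json(mreport))
            log.append(
                f"merge: {mreport.n_maps} maps -> {final.n_nodes} concepts, "
                f"{final.n_edges} edges, {mreport.n_sign_conflicts} sign conflict(s)"
            )

            stage = "simplify"
            plan = propose_plan(final)
            (out / "plan_endpoints.txt").write_text(
                "".join(f"{x}\n" for x in plan.endpoints_for_review))
            (out / "plan_skippable.txt").write_text(
                "".join(f"{x}\n" for x in plan.skippable))
            log.append(
                f"simplify: {len(plan.sources)} sources + {len(plan.receivers)} "
                f"receivers for review, {len(plan.skippable)} skippable"
            )

        stage = "census"
        c = metrics.census(final)
        (out / "census.csv").write_text(report.census_csv(c))
        (out / "census.json").write_text(report.census_json(c))
        (out / "census.txt").write_text(report.census_table(c) + "\n")
        log.append(f"census: {c.n_nodes} nodes, {c.n_edges} edges")
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    (out / "run.log").write_text("".join(f"{line}\n" for line in log))
    return out
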