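"""The whole pipeline on files, exactly as the CLI runs it.

Writes a synthetic panel to disk, then runs validate -> merge ->
simplification plan -> census, producing the artifact directory a real
study run would archive (per-map QC reports, the combined map with
provenance, plan files, the census table, a run log).
"""

import tempfile
from pathlib import Path

from causalmaps import PipelineConfig, run_pipeline
from causalmaps.io_formats import read_edgelist, read_thesaurus
from causalmaps.synthetic_data import GeneratorParams, generate_panel, write_panel

with tempfile.TemporaryDirectory() as tmp:
    panel_dir = Path(tmp) / "panel"
    panel, truth = generate_panel(GeneratorParams(seed=1))
    write_panel(panel_dir, panel, truth)
    print("inputs:", len(list(panel_dir.glob("sme*.csv"))), "edge-list files "
          "+ truth_thesaurus.csv (as the CLI's `simulate` would write)")

    maps = [read_edgelist(p) for p in sorted(panel_dir.glob("sme*.csv"))]
    th = read_thesaurus(panel_dir / "truth_thesaurus.csv")
    out = run_pipeline(PipelineConfig(), maps, Path(tmp) / "run", th)

    print("artifacts:", ", ".join(sorted(p.name for p in out.iterdir())))
    print()
    print((out / "census.txt").read_text())
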