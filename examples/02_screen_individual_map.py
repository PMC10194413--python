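"""Structural QC screening of an individual expert map.

After an interview is transcribed into a map, its structure is screened:
too many sources suggests an under-elaborated early model, a small
diameter suggests short causal chains, and the absence of feedback loops
suggests the facilitator should probe for them (people find loops hard
to articulate).  A synthetic interview-shaped map passes all checks; a
bare star around the focal problem does not.
"""

from causalmaps import CausalMap, validate
from causalmaps.report import qc_text
from causalmaps.synthetic_data import GeneratorParams, generate_sme_map

good = generate_sme_map(GeneratorParams(seed=11))
print(qc_text(good.map_id, validate(good)))

star = CausalMap("early-draft", focal="suicidal ideation")
for cause in ("ACEs", "bullying", "isolation", "hopelessness"):
    star.add_edge(cause, "suicidal ideation", 1)
print(qc_text(star.map_id, validate(star)))
print("Each finding names the criterion that fired; findings are advisory — "
      "they flag a map for another pass with the expert, nothing more.")
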