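"""Build a small signed causal map by hand and print its structural census.

A causal map is a directed graph: an edge A -(+)-> B says that an increase
in A increases B; A -(-)-> B says it decreases B.  The census reports the
node typology (sources = parameters, receivers = outputs, transmitters =
pass-throughs), density, degrees, diameter and feedback-loop presence.
"""

from causalmaps import CausalMap, census
from causalmaps.report import census_table

m = CausalMap("example", focal="suicidal ideation")
m.add_edge("ACEs", "internalized trauma", 1)
m.add_edge("internalized trauma", "suicidal ideation", 1)
m.add_edge("connectedness", "suicidal ideation", -1)
m.add_edge("suicidal ideation", "social withdrawal", 1)
m.add_edge("social withdrawal", "connectedness", -1)  # closes a balancing loop

print(census_table(census(m), "Characteristics of the example map"))

from causalmaps import cycle_census

print()
for nodes, sign in cycle_census(m).cycles:
    kind = "reinforcing" if sign > 0 else "balancing"
    print(f"feedback loop {' -> '.join(nodes)} ({kind}, sign {sign:+d})")
print("A loop's sign is the product of its edge signs: here "
      "(-1)(+1)(-1) = +1, a reinforcing loop — withdrawal erodes "
      "connectedness, weakening its protective effect and feeding ideation "
      "further. A balancing loop (sign -1) would counteract change instead.")
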