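"""Endpoint pruning and sign-preserving chain contraction.

A raw aggregate map is large and uneven in granularity.  The package
proposes (i) source/receiver concepts for possible removal and (ii)
pass-through concepts with in-degree 1 and out-degree 1 that can be
skipped; approved contractions replace A -> B -> C by a direct A -> C
edge whose sign is the product of the two signs, so the net direction of
influence is preserved.
"""

from causalmaps import CausalMap, contract_chains, propose_plan, prune_endpoints

m = CausalMap("demo", focal="suicidal ideation")
m.add_edge("economic policy", "family financial stress", 1)
m.add_edge("family financial stress", "parental conflict", 1)
m.add_edge("parental conflict", "ACEs", 1)
m.add_edge("ACEs", "suicidal ideation", 1)
m.add_edge("connectedness", "suicidal ideation", -1)
m.add_edge("treatment access", "connectedness", 1)
m.add_edge("suicidal ideation", "community exposure to suicide", 1)

plan = propose_plan(m)
print("sources for review:   ", plan.sources)
print("receivers for review: ", plan.receivers)
print("skippable mediators:  ", plan.skippable)

pruned = prune_endpoints(m, ["economic policy"], iterative=True)
print(f"\nafter pruning 'economic policy': {pruned.map.n_nodes} concepts; "
      f"newly exposed endpoints: {pruned.newly_exposed}")

res = contract_chains(pruned.map, ["family financial stress", "parental conflict"])
print(f"after contracting the financial-stress chain: {res.map.n_nodes} concepts")
e = res.map.get_edge("ACEs", "suicidal ideation")
chain_edge = [f"{s}->{d}({res.map.edges[(s,d)].polarity:+d})" for s, d in res.map.edges]
print("remaining edges:", ", ".join(sorted(chain_edge)))
print("The contracted path carried signs (+)(+) so the direct edge is still "
      "positive; a (+)(-) chain would have contracted to a negative edge.")
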