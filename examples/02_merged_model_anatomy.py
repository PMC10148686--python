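"""Look inside the merged HMM: skip edges, weights, glocal constants.

Builds a tiny backbone in which one two-sequence subset is entirely
gapped at an interior column, so its profile HMM has no match state
there and contributes a column-skipping transition to the merged
topology.  Then parameterises the merged model for one query and shows
how the adjusted-bitscore weights split between the two subset HMMs.
"""

from ehmmalign import (Alignment, NullModel, Sequence, add_glocal,
                       bit_score, build_merged_topology, build_profile_hmm,
                       compute_adjusted_weights, induce_subalignment,
                       parameterize)

backbone = Alignment({
    "a": "ACGTA",
    "b": "ACGTA",
    "c": "AC-TA",
    "d": "AC-TA",
})
h_full = build_profile_hmm(induce_subalignment(backbone, ["a", "b"]),
                           subset_id="ab")
h_gap = build_profile_hmm(induce_subalignment(backbone, ["c", "d"]),
                          subset_id="cd")
print("subset ab match columns:", h_full.column_map)
print("subset cd match columns:", h_gap.column_map,
      "(column 2 is all-gap in cd)")

topology = build_merged_topology([h_full, h_gap], backbone.length)
print("merged match states   :", topology.S)
skip = (("M", 1), ("M", 3))
print("skip edge M1->M3      :", skip in topology.edges,
      "| supporters:", [i for i, _ in topology.edge_support[skip]])

query = Sequence("q", "ACTA")   # looks like the gapped subset
scores = [bit_score(h, query, NullModel()) for h in (h_full, h_gap)]
weights = compute_adjusted_weights(scores, [2, 2])
print(f"bit scores            : ab={scores[0]:.2f}  cd={scores[1]:.2f}")
print(f"adjusted weights      : ab={weights.weights[0]:.3f}  "
      f"cd={weights.weights[1]:.3f}")

merged = parameterize(topology, [h_full, h_gap], weights)
glocal = add_glocal(merged, renormalize=False)
entries = sorted(p for (u, v), p in glocal.transitions.items()
                 if u == ("S",) and v[0] == "M")
print(f"entry edges pre-norm  : {len(entries)} x {entries[0]:.4f} "
      f"(total {sum(entries):.2f})")
print()
print("The query matching the gapped subset pulls the weight toward cd,")
print("so the merged model's skip edge becomes cheap for this query and")
print("expensive for queries resembling the full-length subset.")
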