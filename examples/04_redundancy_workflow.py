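"""Two-stage redundancy removal: sequence clustering + interface rescue.

Clusters sequence families at 0.95 identity, labels complexes by their chain
clusters, and shows how the interface-similarity stage reinstates a complex
that shares sequences but binds a different epitope.
"""

import ablandscape as ab

# -- stage 1: greedy sequence clustering at 0.95 identity -------------------
near = ab.make_sequence_family(3, identity=0.97, length=120, seed=0)
far = ab.make_sequence_family(1, identity=1.0, length=120, seed=99)
sequences = {f"h{i}": s for i, s in enumerate(near + far)}
clusters = ab.greedy_cluster(sequences, threshold=0.95)
print("heavy-chain clusters:", clusters.cluster_of)

label = ab.label_complex(15, 21, [23, 1])
print(f"complex label for clusters H=15, L=21, antigens {{1, 23}}: {label}")

# -- stage 2: interface similarity rescues distinct binding sites -----------
site_a = frozenset(("paratope", p, "", "Y") for p in range(105, 115))
site_b = frozenset(("paratope", p, "", "Y") for p in range(27, 37))
sim = ab.interface_similarity(site_a, site_b, "complex1", "complex2")
print(
    f"shared-interface fraction: {sim.overall:.2f} "
    f"-> {'redundant' if sim.is_redundant else 'distinct binding sites, both kept'}"
)

# -- full accounting on the dataset-scale fixture ---------------------------
entries, interfaces = ab.make_dedup_manifest()
result = ab.deduplicate(entries, interfaces)
print(
    f"\n{len(entries)} labelled complexes -> {result.stage1_representatives} "
    f"stage-1 representatives + {result.reinstated} reinstated "
    f"= {result.final_total} nonredundant"
)
print(
    "\nSequence clustering alone would discard antibodies that bind the\n"
    "same antigen on different epitopes; the interface stage keeps them."
)
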