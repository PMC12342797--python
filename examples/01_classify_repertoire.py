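"""Classify a handful of proteins into immune receptor classes.

Each protein is summarised by its ordered domain calls; the classifier
applies the most-specific-first rule ladder (NLR rules before PRR rules,
NBS always routes to the NLR branch).
"""

from irgloss import DomainArchitecture, classify_protein, classify_proteome

proteins = [
    ("g1", ["CC", "NBS", "LRR"]),          # canonical CNL resistance gene
    ("g2", ["TIR", "CC", "NBS", "LRR"]),   # TIR and CC both upstream of NBS
    ("g3", ["TIR", "LRR"]),                # TIR plus another domain, no NBS
    ("g4", ["LYSM", "TM", "KINASE"]),      # chitin-receptor-like kinase
    ("g5", ["LRR", "TM"]),                 # receptor-like protein
    ("g6", ["KINASE"]),                    # ordinary kinase: not an IRG
]

archs = [DomainArchitecture(pid, doms) for pid, doms in proteins]
for arch in archs:
    print(f"{arch.protein_id}: {','.join(arch.domains):<18} -> {classify_protein(arch)}")

counts = classify_proteome(archs, "demo_species")
nonzero = {c.value: n for c, n in counts.counts.items() if n}
print(f"\nrepertoire counts (IRGs only, NONE excluded): {nonzero}")
print(f"total IRGs: {counts.total} of {len(archs)} proteins")
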