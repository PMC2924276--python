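"""Orthogroup assembly from reciprocal best hits with monophyly checks.

Builds a small cross-species similarity matrix, extracts reciprocal
best hits, merges them into orthologous groups, validates each group
against a gene tree, and applies the family nomenclature.
"""

import pandas as pd

from famevol.orthology import (
    assemble_orthogroups,
    name_orthogroups,
    reciprocal_best_hits,
)
from famevol.trees import SpeciesTree

# similarity scores (e.g. BLAST bit scores) between two species' genes
scores = pd.DataFrame(
    [[310, 55, 40], [60, 280, 35], [45, 50, 90]],
    index=["DmelIR25a", "DmelIR8a", "DmelIR75a"],
    columns=["DsecIR25a", "DsecIR8a", "DsecIR75a"],
)
pairs = reciprocal_best_hits(scores)
print("reciprocal best hits:", pairs)

gene_tree = SpeciesTree.from_newick(
    "(((DmelIR25a:1,DsecIR25a:1):2,(DmelIR8a:1,DsecIR8a:1):2):1,"
    "(DmelIR75a:2,DsecIR75a:2):2);",
    require_binary=False,
)
groups = assemble_orthogroups(
    pairs, genes=list(scores.index) + list(scores.columns), gene_tree=gene_tree
)
names = name_orthogroups(groups, reference_species="Dmel")
for g in groups:
    print(f"{names[g.name]:>8}: {g.members}  monophyletic={g.monophyletic}")
print()
print("each group is a connected component of the RBH graph; the flag")
print("reports whether the smallest clade containing the group on the")
print("gene tree excludes all other genes.")
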