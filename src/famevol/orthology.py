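"""Orthologous group assembly from reciprocal best hits.

Genes of two species are candidate orthologues when each is the other's
strict unique best-scoring hit (reciprocal best hits, RBH).  Pairs
across several species are merged into orthogroups as connected
components of the RBH graph; when a gene tree is supplied, each group
is checked for monophyly (the smallest clade containing the group must
contain no outside gene), and non-monophyletic groups are flagged
rather than silently split.  A renaming utility applies the field's
nomenclature: orthologues share the reference-species gene name,
in-paralogues get ``.1``/``.2`` suffixes, and groups without a
reference member are numbered from 101 upward.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import pandas as pd

from famevol.trees import SpeciesTree

__all__ = [
    "OrthoGroup",
    "reciprocal_best_hits",
    "assemble_orthogroups",
    "name_orthogroups",
]


def reciprocal_best_hits(scores: pd.DataFrame) -> List[Tuple[str, str]]:
    """Reciprocal best hits of a similarity matrix (rows = species A genes,
    columns = species B genes, higher = better).

    A pair (a, b) is emitted iff b is the strict unique maximum of a's
    row and a the strict unique maximum of b's column; ties disqualify.
    """
    if scores.empty:
        raise ValueError("empty score matrix")
    pairs: List[Tuple[str, str]] = []
    vals = scores.to_numpy(dtype=float)
    for i, a in enumerate(scores.index):
        row = vals[i]
        best = row.max()
        if (row == best).sum() != 1:
            continue
        j = int(row.argmax())
        col = vals[:, j]
        if (col == col.max()).sum() != 1 or col.argmax() != i:
            continue
        pairs.append((str(a), str(scores.columns[j])))
    return pairs


@dataclass
class OrthoGroup:
    """A putative orthologous group."""

    name: str
    members: List[str]
    monophyletic: Optional[bool] = None  # None when no gene tree was supplied


def assemble_orthogroups(
    rbh_pairs: Sequence[Tuple[str, str]],
    genes: Optional[Sequence[str]] = None,
    gene_tree: Optional[SpeciesTree] = None,
) -> List[OrthoGroup]:
    """Connected components of the RBH graph, with optional monophyly check.

    ``genes`` lists all genes under consideration; genes in no pair
    become singleton groups.  With a gene tree, a group is monophyletic
    iff the leaf set of the MRCA of its members equals the group.
    """
    graph = nx.Graph()
    if genes:
        graph.add_nodes_from(genes)
    graph.add_edges_from(rbh_pairs)
    components = [sorted(c) for c in nx.connected_components(graph)]
    components.sort()
    groups = []
    for i, members in enumerate(components):
        mono: Optional[bool] = None
        if gene_tree is not None:
            mono = _is_monophyletic(gene_tree, members)
        groups.append(OrthoGroup(name=f"OG{i:03d}", members=members, monophyletic=mono))
    return groups


def _is_monophyletic(tree: SpeciesTree, members: Sequence[str]) -> bool:
    tips = set(tree.tip_names)
    missing = set(members) - tips
    if missing:
        raise ValueError(f"genes missing from the gene tree: {sorted(missing)}")
    if len(members) == 1:
        return True
    taxa = [
        leaf.taxon
        for leaf in tree.tree.leaf_node_iter()
        if leaf.taxon.label in set(members)
    ]
    mrca = tree.tree.mrca(taxa=taxa)
    clade = {leaf.taxon.label for leaf in mrca.leaf_iter()}
    return clade == set(members)


def name_orthogroups(
    groups: Sequence[OrthoGroup],
    reference_species: str = "Dmel",
    novel_start: int = 101,
    family_prefix: str = "IR",
) -> Dict[str, str]:
    """Assign nomenclature names to orthogroups.

    Gene ids are expected as ``<SpeciesCode><GeneName>`` (e.g.
    ``DmelIR25a``).  A group containing reference-species members takes
    the reference gene name (``.1``/``.2`` suffixes mark reference
    in-paralogues within one group); groups without a reference member
    are numbered ``<prefix>101`` upward in input order.
    """
    names: Dict[str, str] = {}
    counter = novel_start
    for group in groups:
        ref = sorted(
            m[len(reference_species):]
            for m in group.members
            if m.startswith(reference_species)
        )
        if ref:
            if len(ref) == 1:
                names[group.name] = ref[0]
            else:
                names[group.name] = "/".join(
                    f"{ref[0]}.{i + 1}" for i in range(len(ref))
                )
        else:
            names[group.name] = f"{family_prefix}{counter}"
            counter += 1
    return names
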