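"""Physico-chemical conservation profiling of protein alignments.

Each alignment column is scored by the number of physico-chemical
properties (out of a fixed set of ten) whose presence/absence indicator
is uniform across all non-gap residues of the column — the
property-conservation index familiar from alignment viewers.  A fully
conserved column scores 10; a column mixing, say, a charged and an
aliphatic residue agrees on fewer properties.  Per-column scores are
averaged over consecutive 50-column blocks to profile which regions of
a receptor family (e.g. the C-terminal ion-channel module versus the
divergent N-terminus) are under the strongest constraint.
"""

from __future__ import annotations

from typing import Dict, FrozenSet, List, Sequence

import numpy as np

__all__ = [
    "PROPERTY_TABLE",
    "column_conservation",
    "block_profile",
    "conservation_profile",
]

# Ten-property residue classification (Taylor-style Venn sets as used in
# alignment-annotation tools).  Version 1; changing this table changes
# every score, so treat it as a frozen fixture.
PROPERTY_TABLE: Dict[str, FrozenSet[str]] = {
    "hydrophobic": frozenset("ILVCAGMFYWHKT"),
    "polar": frozenset("YWHKREQDNSTC"),
    "small": frozenset("VCAGDNSTP"),
    "tiny": frozenset("AGCS"),
    "aliphatic": frozenset("ILV"),
    "aromatic": frozenset("FYWH"),
    "positive": frozenset("HKR"),
    "negative": frozenset("DE"),
    "charged": frozenset("HKRDE"),
    "proline": frozenset("P"),
}

_VALID = frozenset("ACDEFGHIKLMNPQRSTVWY")
_GAPS = frozenset("-.")


def column_conservation(column: Sequence[str]) -> int:
    """Number of properties uniformly present or uniformly absent.

    Gap characters are excluded from the uniformity test; an all-gap
    column scores 0.  Non-amino-acid characters are an error.
    """
    residues = [c.upper() for c in column if c not in _GAPS]
    if not residues:
        return 0
    bad = set(residues) - _VALID
    if bad:
        raise ValueError(f"non-amino-acid character(s) in column: {sorted(bad)}")
    score = 0
    for members in PROPERTY_TABLE.values():
        flags = {r in members for r in residues}
        if len(flags) == 1:
            score += 1
    return score


def block_profile(scores: Sequence[float], block_size: int = 50) -> List[float]:
    """Means over consecutive non-overlapping blocks of columns.

    The final partial block is averaged over its own length.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    if len(scores) == 0:
        raise ValueError("empty score list")
    out = []
    for i in range(0, len(scores), block_size):
        chunk = scores[i : i + block_size]
        out.append(float(np.mean(chunk)))
    return out


def conservation_profile(
    msa: Dict[str, str], block_size: int = 50
) -> Dict[str, List[float]]:
    """Per-column scores and block means for a protein alignment."""
    rows = list(msa.values())
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError("alignment rows have unequal lengths")
    width = widths.pop()
    scores = [
        column_conservation([row[i] for row in rows]) for i in range(width)
    ]
    return {
        "per_column": [float(s) for s in scores],
        "block_means": block_profile(scores, block_size),
    }
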