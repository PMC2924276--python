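"""Intron position/phase comparative analysis.

An intron is described by k, the number of CDS nucleotides preceding it:
its phase is k mod 3 (0 = between codons, 1/2 = after the first/second
codon position) and its residue is the codon it interrupts (the residue
before the junction for phase 0).  Sites are projected from gene
coordinates onto a protein multiple alignment so that "same position"
becomes a single column-equality test across genes; conservation is then
classified as full (column + phase), position-only, or sliding (columns
within a small window, the signature of intron sliding by a few
nucleotides).

Presence/absence of introns at the union of observed sites forms a
binary character matrix, from which an unrooted tree is built by Fitch
parsimony (exhaustive topology search up to 8 taxa, NNI hill-climbing
beyond).  Integer intron counts are reconstructed on a fixed tree by
linear-cost Sankoff parsimony, and the 5' positional bias of intron
placement (the retroposition signature) is tested with an exact binomial.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import binomtest

from famevol.io_formats import GeneStructure

__all__ = [
    "IntronSite",
    "AlignedIntron",
    "IntronCharacterMatrix",
    "derive_intron_sites",
    "map_introns_to_alignment",
    "alignment_column_to_residue",
    "classify_intron_correspondence",
    "build_intron_character_matrix",
    "parsimony_intron_tree",
    "fitch_score",
    "ancestral_intron_counts",
    "intron_position_bias",
]


@dataclass(frozen=True)
class IntronSite:
    """One intron of one gene, in coding coordinates."""

    gene_id: str
    k: int  # CDS nucleotides preceding the intron
    phase: int  # k mod 3
    residue: int  # 1-based protein residue holding the junction
    rel_pos: float  # k / CDS length, in (0, 1)


def derive_intron_sites(structure: GeneStructure) -> List[IntronSite]:
    """Intron (k, phase, residue, relative position) records of a gene.

    One site per exon-exon junction, computed on the coding strand in
    coding order; single-exon genes yield an empty list.  Phase-0
    introns are assigned to the residue before the junction (r = k/3),
    phase-1/2 to the interrupted codon's residue (r = ceil(k/3)).
    """
    lengths = [b - a + 1 for a, b in structure.coding_exons]
    cds_len = sum(lengths)
    sites: List[IntronSite] = []
    k = 0
    for length in lengths[:-1]:
        k += length
        phase = k % 3
        residue = k // 3 if phase == 0 else math.ceil(k / 3)
        sites.append(
            IntronSite(
                gene_id=structure.gene_id,
                k=k,
                phase=phase,
                residue=residue,
                rel_pos=k / cds_len,
            )
        )
    return sites


@dataclass(frozen=True)
class AlignedIntron:
    """An intron site projected onto a protein alignment column (1-based)."""

    gene_id: str
    column: int
    phase: int
    site: IntronSite


def _residue_to_column(row: str, residue: int) -> int:
    seen = 0
    for col, ch in enumerate(row, start=1):
        if ch not in "-.":
            seen += 1
            if seen == residue:
                return col
    raise ValueError(
        f"residue {residue} exceeds ungapped row length {seen}"
    )


def alignment_column_to_residue(row: str, column: int) -> int:
    """Inverse of the residue->column projection (1-based both ways)."""
    if not (1 <= column <= len(row)):
        raise ValueError(f"column {column} outside alignment of width {len(row)}")
    if row[column - 1] in "-.":
        raise ValueError(f"column {column} is a gap in this row")
    return sum(1 for ch in row[:column] if ch not in "-.")


def map_introns_to_alignment(
    sites_by_gene: Dict[str, Sequence[IntronSite]],
    msa: Dict[str, str],
) -> Dict[str, List[AlignedIntron]]:
    """Project each gene's intron residues onto its alignment row."""
    out: Dict[str, List[AlignedIntron]] = {}
    for gene, sites in sites_by_gene.items():
        if gene not in msa:
            raise KeyError(f"gene {gene!r} missing from the alignment")
        row = msa[gene]
        out[gene] = [
            AlignedIntron(
                gene_id=gene,
                column=_residue_to_column(row, s.residue),
                phase=s.phase,
                site=s,
            )
            for s in sites
        ]
    return out


def classify_intron_correspondence(
    map_a: Sequence[AlignedIntron],
    map_b: Sequence[AlignedIntron],
    slide_window: int = 2,
) -> Dict[str, List[Tuple[AlignedIntron, AlignedIntron]]]:
    """Match introns of two genes on a shared alignment.

    Categories: ``full`` (same column and phase), ``position_only``
    (same column, different phase), ``sliding`` (columns differing by at
    most ``slide_window`` residues, any phase).  Matching is greedy by
    smallest column distance, ties to the lower column; each site is
    used at most once.
    """
    candidates = []
    for ia, a in enumerate(map_a):
        for ib, b in enumerate(map_b):
            d = abs(a.column - b.column)
            if d <= slide_window:
                candidates.append((d, min(a.column, b.column), ia, ib))
    candidates.sort()
    used_a: set = set()
    used_b: set = set()
    result: Dict[str, List[Tuple[AlignedIntron, AlignedIntron]]] = {
        "full": [],
        "position_only": [],
        "sliding": [],
    }
    for d, _c, ia, ib in candidates:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        a, b = map_a[ia], map_b[ib]
        if d == 0 and a.phase == b.phase:
            result["full"].append((a, b))
        elif d == 0:
            result["position_only"].append((a, b))
        else:
            result["sliding"].append((a, b))
    return result


@dataclass
class IntronCharacterMatrix:
    """Binary presence/absence of introns at each potential site."""

    taxa: List[str]
    characters: List[Tuple[int, int]]  # representative (column, phase) per class
    matrix: np.ndarray  # taxa x characters, dtype uint8

    def row(self, taxon: str) -> np.ndarray:
        return self.matrix[self.taxa.index(taxon)]


def build_intron_character_matrix(
    maps: Dict[str, Sequence[AlignedIntron]],
    slide_window: int = 2,
) -> IntronCharacterMatrix:
    """Character matrix over the union of observed intronic sites.

    Observed (column, phase) classes whose columns lie within
    ``slide_window`` of each other are merged (single-linkage), treating
    slid introns as the same potential site; each merged class becomes
    one binary character labelled by its smallest (column, phase) member.
    """
    if len(maps) < 2:
        raise ValueError("need at least two genes")
    keys = sorted({(m.column, m.phase) for ms in maps.values() for m in ms})
    # single-linkage merge of keys whose columns are within the window
    parent = list(range(len(keys)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(keys)), 2):
        if abs(keys[i][0] - keys[j][0]) <= slide_window:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)

    class_of = {keys[i]: find(i) for i in range(len(keys))}
    reps = sorted({find(i) for i in range(len(keys))})
    rep_index = {r: ix for ix, r in enumerate(reps)}
    characters = [keys[r] for r in reps]
    taxa = sorted(maps)
    matrix = np.zeros((len(taxa), len(characters)), dtype=np.uint8)
    for ti, taxon in enumerate(taxa):
        for m in maps[taxon]:
            matrix[ti, rep_index[class_of[(m.column, m.phase)]]] = 1
    return IntronCharacterMatrix(taxa=taxa, characters=characters, matrix=matrix)


def write_character_matrix(
    matrix: IntronCharacterMatrix, path: str, fmt: str = "phylip"
) -> None:
    """Write the binary matrix as relaxed PHYLIP or NEXUS."""
    n, m = matrix.matrix.shape
    if fmt == "phylip":
        with open(path, "w") as fh:
            fh.write(f"{n} {m}\n")
            for i, taxon in enumerate(matrix.taxa):
                row = "".join(str(int(v)) for v in matrix.matrix[i])
                fh.write(f"{taxon}  {row}\n")
    elif fmt == "nexus":
        with open(path, "w") as fh:
            fh.write("#NEXUS\nBEGIN DATA;\n")
            fh.write(f"  DIMENSIONS NTAX={n} NCHAR={m};\n")
            fh.write('  FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;\n')
            fh.write("  MATRIX\n")
            for i, taxon in enumerate(matrix.taxa):
                row = "".join(str(int(v)) for v in matrix.matrix[i])
                fh.write(f"    {taxon}  {row}\n")
            fh.write("  ;\nEND;\n")
    else:
        raise ValueError("fmt must be 'phylip' or 'nexus'")


# ---------------------------------------------------------------------------
# Fitch parsimony over binary characters


def _unrooted_topologies(n: int):
    """Yield all unrooted topologies on taxa 0..n-1 as rooted-triple nests.

    Each topology is represented as a nested tuple rooted on the edge to
    taxon 0: (0, subtree) where subtrees are ints or pairs.
    """

    def insert_all(subtree, leaf):
        # yield all trees obtained by inserting leaf on any edge of subtree
        yield (subtree, leaf)
        if isinstance(subtree, tuple):
            left, right = subtree
            for t in insert_all(left, leaf):
                yield (t, right)
            for t in insert_all(right, leaf):
                yield (left, t)

    def build(k, subtree):
        if k == n:
            yield subtree
        else:
            for t in insert_all(subtree, k):
                yield from build(k + 1, t)

    if n < 3:
        raise ValueError("need at least 3 taxa")
    yield from build(3, (1, 2))


def _fitch_rooted(subtree, matrix: np.ndarray) -> Tuple[np.ndarray, int]:
    """Fitch up-pass; returns (state-set array per character, added score)."""
    if isinstance(subtree, int):
        # state sets as bitmasks: state 0 -> 1, state 1 -> 2
        return matrix[subtree] + 1, 0
    left_set, left_score = _fitch_rooted(subtree[0], matrix)
    right_set, right_score = _fitch_rooted(subtree[1], matrix)
    inter = left_set & right_set
    union = left_set | right_set
    empty = inter == 0
    result = np.where(empty, union, inter)
    return result, left_score + right_score + int(empty.sum())


def fitch_score(topology, matrix: np.ndarray) -> int:
    """Parsimony length of one unrooted topology (nested-tuple form)."""
    root_set, score = _fitch_rooted(topology, matrix)
    tip0 = matrix[0] + 1
    score += int((root_set & tip0 == 0).sum())
    return score


def _nested_to_newick(subtree, taxa: List[str], lengths: Dict) -> str:
    if isinstance(subtree, int):
        return taxa[subtree]
    return f"({_nested_to_newick(subtree[0], taxa, lengths)},{_nested_to_newick(subtree[1], taxa, lengths)})"


def _all_nni(topology):
    """Yield NNI neighbours of a nested-tuple topology."""

    def rearrangements(tree):
        if not isinstance(tree, tuple):
            return
        a, b = tree
        if isinstance(a, tuple):
            # swap children of a with b
            yield ((a[0], b), a[1])
            yield ((a[1], b), a[0])
        if isinstance(b, tuple):
            yield (b[0], (a, b[1]))
            yield (b[1], (a, b[0]))
        for t in rearrangements(a):
            yield (t, b)
        for t in rearrangements(b):
            yield (a, t)

    yield from rearrangements(topology)


@dataclass
class ParsimonyTree:
    """Result of a parsimony search over intron characters."""

    newick: str
    score: int
    branch_changes: Dict[str, int]  # branch label -> state changes
    topology: object
    taxa: List[str]


def _assign_states(subtree, matrix, parent_state, changes, taxa):
    """Deterministic MPR down-pass; tie in a state set resolves to the
    parent's state when possible, else to absence (state 0)."""
    sets, _ = _fitch_rooted(subtree, matrix)
    if isinstance(subtree, int):
        state = matrix[subtree].astype(np.uint8)
        label = taxa[subtree]
    else:
        pbit = (parent_state + 1).astype(np.uint8)
        keep = (sets & pbit) != 0
        state = np.where(keep, parent_state, (sets == 2).astype(np.uint8)).astype(
            np.uint8
        )
        label = None
    n_changes = int((state != parent_state).sum())
    if label is None:
        label = f"clade({_nested_to_newick(subtree, taxa, {})})"
    changes[label] = n_changes
    if isinstance(subtree, tuple):
        _assign_states(subtree[0], matrix, state, changes, taxa)
        _assign_states(subtree[1], matrix, state, changes, taxa)
    return state


def parsimony_intron_tree(
    matrix: IntronCharacterMatrix,
    exhaustive_max_taxa: int = 8,
) -> ParsimonyTree:
    """Unrooted Fitch-parsimony tree over the binary intron characters.

    Exhaustive search over all unrooted topologies up to
    ``exhaustive_max_taxa`` taxa (10395 at 8); beyond that, deterministic
    NNI hill-climbing from a sequential-addition starting tree.  Branch
    lengths are the state changes assigned by one deterministic
    most-parsimonious reconstruction (the scale of an intron phylogram:
    non-conserved intron positions per branch).
    """
    n = len(matrix.taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    M = matrix.matrix
    if n <= exhaustive_max_taxa:
        best, best_score = None, None
        for topo in _unrooted_topologies(n):
            s = fitch_score(topo, M)
            if best_score is None or s < best_score:
                best, best_score = topo, s
    else:
        # deterministic stepwise addition then NNI hill-climb
        topo = (1, 2)
        for leaf in range(3, n):
            options = []

            def insert_all(subtree, lf):
                yield (subtree, lf)
                if isinstance(subtree, tuple):
                    a, b = subtree
                    for t in insert_all(a, lf):
                        yield (t, b)
                    for t in insert_all(b, lf):
                        yield (a, t)

            for cand in insert_all(topo, leaf):
                options.append((fitch_score(cand, M), cand))
            topo = min(options, key=lambda x: x[0])[1]
        best, best_score = topo, fitch_score(topo, M)
        improved = True
        while improved:
            improved = False
            for cand in _all_nni(best):
                s = fitch_score(cand, M)
                if s < best_score:
                    best, best_score = cand, s
                    improved = True
                    break

    # branch changes from one deterministic MPR, rooted at taxon 0's edge
    root_sets, _ = _fitch_rooted(best, M)
    tip0 = M[0] + 1
    inter = root_sets & tip0
    root_state = np.where(inter != 0, M[0], (root_sets == 2)).astype(np.uint8)
    changes: Dict[str, int] = {}
    changes[matrix.taxa[0]] = int(
        (root_state != M[0]).sum()
    )  # edge between taxon 0 and the rest
    _assign_states(best, M, root_state, changes, matrix.taxa)
    newick = f"({matrix.taxa[0]},{_nested_to_newick(best, matrix.taxa, {})});"
    return ParsimonyTree(
        newick=newick,
        score=best_score,
        branch_changes=changes,
        topology=best,
        taxa=matrix.taxa,
    )


# ---------------------------------------------------------------------------
# Sankoff linear-cost ancestral counts


def ancestral_intron_counts(
    tree,
    tip_counts: Dict[str, int],
    max_state: Optional[int] = None,
) -> Tuple[Dict[str, Tuple[int, int]], int]:
    """Linear-cost (|i-j|) Sankoff parsimony for integer intron counts.

    ``tree`` is a :class:`~famevol.trees.SpeciesTree` (or any object with
    the same traversal API) whose tips are keyed in ``tip_counts``.
    Returns per-node intervals [lo, hi] of states attaining the global
    minimum, plus the total cost.  The per-node optimum set is an
    interval because every cost profile is convex.
    """
    if any(v < 0 for v in tip_counts.values()):
        raise ValueError("negative intron count")
    if max_state is None:
        max_state = max(tip_counts.values(), default=0) + 1
    states = np.arange(max_state + 1)
    cost_mat = np.abs(states[:, None] - states[None, :])

    up: Dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf():
            vec = np.full(max_state + 1, np.inf)
            vec[tip_counts[node.taxon.label]] = 0
            up[id(node)] = vec
        else:
            vec = np.zeros(max_state + 1)
            for child in node.child_nodes():
                vec = vec + (cost_mat + up[id(child)][None, :]).min(axis=1)
            up[id(node)] = vec

    total = float(up[id(tree.root)].min())

    # outside pass: down[v][s] = best cost of everything outside subtree(v)
    down: Dict[int, np.ndarray] = {id(tree.root): np.zeros(max_state + 1)}
    for node in tree.preorder():
        for child in node.child_nodes():
            sib_sum = np.zeros(max_state + 1)
            for sib in node.child_nodes():
                if sib is not child:
                    sib_sum = sib_sum + (cost_mat + up[id(sib)][None, :]).min(axis=1)
            combined = down[id(node)] + sib_sum
            down[id(child)] = (cost_mat + combined[None, :]).min(axis=1)

    intervals: Dict[str, Tuple[int, int]] = {}
    for node in tree.preorder():
        total_v = up[id(node)] + down[id(node)]
        opt = np.where(np.isclose(total_v, total_v.min()))[0]
        intervals[node.label] = (int(opt.min()), int(opt.max()))
    return intervals, int(round(total))


# ---------------------------------------------------------------------------
# 5' positional bias


def intron_position_bias(rel_positions: Sequence[float]) -> Tuple[float, float]:
    """Fraction of introns in the 5' half and exact binomial p vs 0.5.

    A strong 5' bias is the hallmark of repertoire expansion by
    retroposition: recombination of partially reverse-transcribed cDNAs
    (which initiate at the 3' end) with parental genes preferentially
    removes 3' introns.
    """
    n = len(rel_positions)
    if n == 0:
        raise ValueError("no intron positions given")
    k = sum(1 for r in rel_positions if r <= 0.5)
    res = binomtest(k, n, 0.5, alternative="two-sided")
    return k / n, float(res.pvalue)
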