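"""Intron derivation, alignment mapping, parsimony and positional bias."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famevol.io_formats import GeneStructure
from famevol.introns import (
    AlignedIntron,
    IntronCharacterMatrix,
    IntronSite,
    alignment_column_to_residue,
    ancestral_intron_counts,
    build_intron_character_matrix,
    classify_intron_correspondence,
    derive_intron_sites,
    fitch_score,
    intron_position_bias,
    map_introns_to_alignment,
    parsimony_intron_tree,
)
from famevol.trees import SpeciesTree


class TestDeriveSites:
    def test_two_exon_arithmetic(self):
        s = GeneStructure("g", "sp", "+", [(1, 100), (201, 400)])
        (site,) = derive_intron_sites(s)
        assert (site.k, site.phase, site.residue) == (100, 1, 34)
        assert site.rel_pos == pytest.approx(1 / 3)

    def test_single_exon_gene_has_no_introns(self):
        s = GeneStructure("g", "sp", "+", [(1, 300)])
        assert derive_intron_sites(s) == []

    def test_minus_strand_mirror(self):
        # minus-strand gene whose coding-order exon lengths are 100 then 200
        plus = GeneStructure("g+", "sp", "+", [(1, 100), (201, 400)])
        minus = GeneStructure("g-", "sp", "-", [(1, 200), (301, 400)])
        sp = derive_intron_sites(plus)[0]
        sm = derive_intron_sites(minus)[0]
        assert (sm.k, sm.phase, sm.residue, sm.rel_pos) == (
            sp.k,
            sp.phase,
            sp.residue,
            sp.rel_pos,
        )

    def test_phase0_assigned_to_preceding_residue(self):
        s = GeneStructure("g", "sp", "+", [(1, 99), (201, 401)])
        (site,) = derive_intron_sites(s)
        assert (site.k, site.phase, site.residue) == (99, 0, 33)


def _site(gene, residue, phase=0):
    return IntronSite(gene, 3 * residue, phase, residue, 0.5)


class TestAlignmentMapping:
    def test_gapless_row(self):
        maps = map_introns_to_alignment({"g": [_site("g", 2)]}, {"g": "MKR"})
        assert maps["g"][0].column == 2

    def test_leading_gap_shifts_column(self):
        maps = map_introns_to_alignment({"g": [_site("g", 2)]}, {"g": "-MKR"})
        assert maps["g"][0].column == 3

    def test_residue_beyond_row_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            map_introns_to_alignment({"g": [_site("g", 9)]}, {"g": "MK-R"})

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(1, 20), st.lists(st.integers(0, 20), max_size=10), st.integers(0, 10**6))
    def test_roundtrip_through_random_gaps(self, length, gap_cols, seed):
        rng = np.random.default_rng(seed)
        residues = "ACDEFGHIKLMNPQRSTVWY"
        ungapped = "".join(rng.choice(list(residues), size=length))
        row = list(ungapped)
        for g in sorted(set(gap_cols), reverse=True):
            row.insert(min(g, len(row)), "-")
        row = "".join(row)
        r = int(rng.integers(1, length + 1))
        maps = map_introns_to_alignment({"g": [_site("g", r)]}, {"g": row})
        col = maps["g"][0].column
        assert alignment_column_to_residue(row, col) == r


class TestCorrespondence:
    def test_full_match(self):
        a = [AlignedIntron("a", 10, 0, _site("a", 10))]
        b = [AlignedIntron("b", 10, 0, _site("b", 10))]
        res = classify_intron_correspondence(a, b)
        assert len(res["full"]) == 1 and not res["position_only"] and not res["sliding"]

    def test_position_only(self):
        a = [AlignedIntron("a", 10, 0, _site("a", 10))]
        b = [AlignedIntron("b", 10, 2, _site("b", 10, 2))]
        res = classify_intron_correspondence(a, b)
        assert len(res["position_only"]) == 1

    def test_sliding_within_window(self):
        a = [AlignedIntron("a", 10, 0, _site("a", 10))]
        b = [AlignedIntron("b", 12, 0, _site("b", 12))]
        res = classify_intron_correspondence(a, b, slide_window=2)
        assert len(res["sliding"]) == 1
        assert not classify_intron_correspondence(a, b, slide_window=1)["sliding"]

    def test_each_site_matched_at_most_once(self):
        a = [
            AlignedIntron("a", 10, 0, _site("a", 10)),
            AlignedIntron("a", 11, 0, _site("a", 11)),
        ]
        b = [AlignedIntron("b", 10, 0, _site("b", 10))]
        res = classify_intron_correspondence(a, b)
        matched = sum(len(v) for v in res.values())
        assert matched == 1
        assert res["full"][0][0].column == 10  # exact match preferred


class TestCharacterMatrix:
    def test_shape_and_orthogonality(self):
        maps = {
            "g1": [AlignedIntron("g1", 10, 0, _site("g1", 10))],
            "g2": [AlignedIntron("g2", 50, 1, _site("g2", 50, 1))],
            "g3": [
                AlignedIntron("g3", 10, 0, _site("g3", 10)),
                AlignedIntron("g3", 90, 2, _site("g3", 90, 2)),
            ],
        }
        m = build_intron_character_matrix(maps, slide_window=2)
        assert m.matrix.shape == (3, 3)
        assert not (m.matrix.sum(axis=0) == 0).any()  # no all-zero characters
        assert (m.row("g1") & m.row("g2")).sum() == 0  # disjoint sets orthogonal

    def test_identical_maps_give_identical_rows(self):
        maps = {
            "g1": [AlignedIntron("g1", 10, 0, _site("g1", 10))],
            "g2": [AlignedIntron("g2", 10, 0, _site("g2", 10))],
        }
        m = build_intron_character_matrix(maps)
        assert (m.row("g1") == m.row("g2")).all()

    def test_sliding_sites_merged_into_one_character(self):
        maps = {
            "g1": [AlignedIntron("g1", 10, 0, _site("g1", 10))],
            "g2": [AlignedIntron("g2", 12, 0, _site("g2", 12))],
        }
        m = build_intron_character_matrix(maps, slide_window=2)
        assert len(m.characters) == 1
        assert m.matrix.sum() == 2


def _oracle_min_score(matrix):
    """Independent exhaustive Fitch oracle: own topology enumeration and
    own set-based Fitch recursion."""
    n = matrix.shape[0]

    def topologies(labels):
        if len(labels) == 3:
            yield (labels[0], (labels[1], labels[2]))
            return
        head, rest = labels[-1], labels[:-1]
        for t in topologies(rest):
            for t2 in _insertions(t, head):
                yield t2

    def _insertions(tree, leaf):
        if isinstance(tree, int):
            yield (tree, leaf)
        else:
            a, b = tree
            yield (tree, leaf)
            for ta in _insertions(a, leaf):
                yield (ta, b)
            for tb in _insertions(b, leaf):
                yield (a, tb)

    def fitch(tree, char):
        if isinstance(tree, int):
            return {char[tree]}, 0
        (sa, ca), (sb, cb) = fitch(tree[0], char), fitch(tree[1], char)
        inter = sa & sb
        if inter:
            return inter, ca + cb
        return sa | sb, ca + cb + 1

    best = None
    for topo in topologies(list(range(n))):
        score = 0
        for j in range(matrix.shape[1]):
            _s, c = fitch(topo, matrix[:, j])
            score += c
        if best is None or score < best:
            best = score
    return best


class TestParsimony:
    def test_quartet_with_two_split_characters(self):
        m = IntronCharacterMatrix(
            taxa=["A", "B", "C", "D"],
            characters=[(10, 0), (20, 1)],
            matrix=np.array([[1, 1], [1, 1], [0, 0], [0, 0]], dtype=np.uint8),
        )
        r = parsimony_intron_tree(m)
        assert r.score == 2
        # the unrooted topology must carry the AB|CD split
        assert ("(A,(B,(C,D)));" == r.newick) or ("((A,B)" in r.newick)
        assert sum(r.branch_changes.values()) == r.score

    def test_identical_rows_score_zero(self):
        m = IntronCharacterMatrix(
            taxa=["A", "B", "C", "D"],
            characters=[(10, 0)],
            matrix=np.ones((4, 1), dtype=np.uint8),
        )
        r = parsimony_intron_tree(m)
        assert r.score == 0
        assert all(v == 0 for v in r.branch_changes.values())

    def test_too_few_taxa_rejected(self):
        m = IntronCharacterMatrix(
            taxa=["A", "B"], characters=[(1, 0)], matrix=np.eye(2, 1, dtype=np.uint8)
        )
        with pytest.raises(ValueError):
            parsimony_intron_tree(m)

    @pytest.mark.parametrize("n_taxa,seed", [(5, 0), (5, 1), (6, 2), (6, 3)])
    def test_matches_exhaustive_oracle(self, n_taxa, seed):
        rng = np.random.default_rng(seed)
        M = rng.integers(0, 2, size=(n_taxa, 8)).astype(np.uint8)
        M = M[:, M.sum(axis=0) > 0]
        m = IntronCharacterMatrix(
            taxa=[f"t{i}" for i in range(n_taxa)],
            characters=[(i, 0) for i in range(M.shape[1])],
            matrix=M,
        )
        assert parsimony_intron_tree(m).score == _oracle_min_score(M)

    def test_nni_search_beyond_exhaustive_cutoff(self):
        # 9 taxa with a clean nested signal: hill-climbing must find the
        # zero-homoplasy score
        n = 9
        M = np.tril(np.ones((n, n - 2), dtype=np.uint8), k=-1)[:, : n - 3]
        M = M[:, M.sum(axis=0) > 0]
        m = IntronCharacterMatrix(
            taxa=[f"t{i}" for i in range(n)],
            characters=[(i, 0) for i in range(M.shape[1])],
            matrix=M,
        )
        r = parsimony_intron_tree(m, exhaustive_max_taxa=8)
        assert r.score == M.shape[1]  # one change per nested character


class TestSankoffCounts:
    def test_cherry_median_interval(self):
        t = SpeciesTree.from_newick("(a:1,b:1);")
        iv, cost = ancestral_intron_counts(t, {"a": 14, "b": 15})
        assert iv["N0"] == (14, 15)
        assert cost == 1

    def test_two_cherry_example(self):
        t = SpeciesTree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        iv, cost = ancestral_intron_counts(t, {"a": 14, "b": 15, "c": 3, "d": 2})
        assert iv["N0"] == (3, 14)
        assert cost == 13

    def test_equal_tips_cost_zero(self, demo_tree):
        iv, cost = ancestral_intron_counts(
            demo_tree, {s: 7 for s in demo_tree.tip_names}
        )
        assert cost == 0
        assert all(v == (7, 7) for v in iv.values())

    def test_matches_exhaustive_dp_over_states(self):
        t = SpeciesTree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        tips = {"a": 14, "b": 15, "c": 3, "d": 2}
        best = None
        for root, x, y in itertools.product(range(21), repeat=3):
            c = (
                abs(14 - x) + abs(15 - x) + abs(x - root)
                + abs(3 - y) + abs(2 - y) + abs(y - root)
            )
            best = c if best is None else min(best, c)
        _iv, cost = ancestral_intron_counts(t, tips, max_state=20)
        assert cost == best


class TestCharacterMatrixWriter:
    def _matrix(self):
        return IntronCharacterMatrix(
            taxa=["gA", "gB", "gC"],
            characters=[(10, 0), (20, 1)],
            matrix=np.array([[1, 0], [1, 1], [0, 1]], dtype=np.uint8),
        )

    def test_phylip_output(self, tmp_path):
        from famevol.introns import write_character_matrix

        p = tmp_path / "m.phy"
        write_character_matrix(self._matrix(), str(p), fmt="phylip")
        lines = p.read_text().splitlines()
        assert lines[0].split() == ["3", "2"]
        assert lines[1].split() == ["gA", "10"]

    def test_nexus_output(self, tmp_path):
        from famevol.introns import write_character_matrix

        p = tmp_path / "m.nex"
        write_character_matrix(self._matrix(), str(p), fmt="nexus")
        text = p.read_text()
        assert text.startswith("#NEXUS")
        assert "NTAX=3 NCHAR=2" in text
        assert "gB  11" in text


class TestPositionBias:
    def test_fraction(self):
        frac, _p = intron_position_bias([0.1, 0.2, 0.6])
        assert frac == pytest.approx(2 / 3)

    def test_all_first_half_closed_form(self):
        frac, p = intron_position_bias([0.1] * 10)
        assert frac == 1.0
        assert p == pytest.approx(min(1.0, 2 * 0.5**10))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            intron_position_bias([])
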