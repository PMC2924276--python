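"""Codon alignments, NG86 counting, ML codon models, LRT, group tests."""

import itertools
import math

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import mannwhitneyu

from famevol import synthetic
from famevol.codon import CODON_INDEX, build_rate_matrix
from famevol.selection import (
    CodonAlignment,
    build_codon_alignment,
    compare_omega_groups,
    date_duplication,
    fit_m0,
    likelihood_ratio_test,
    mean_group_identity,
    ng86_pairwise,
    pairwise_identity,
)
from famevol.trees import SpeciesTree


class TestBuildCodonAlignment:
    MSA = {"g1": "MK-RW", "g2": "MKQRW"}
    CDS = {"g1": "ATGAAACGTTGG", "g2": "ATGAAACAACGATGG"}

    def test_gap_columns_removed(self):
        aln = build_codon_alignment(self.MSA, self.CDS)
        assert aln.n_codons == 4
        assert aln.rows["g1"] == "ATGAAACGTTGG"
        assert aln.rows["g2"] == "ATGAAACGATGG"
        assert aln.column_map == [1, 2, 4, 5]

    def test_retained_codons_unchanged_by_gap_removal(self):
        aln = build_codon_alignment(self.MSA, self.CDS)
        for gid in aln.ids:
            ungapped_cols = [
                c for c in range(len(self.MSA[gid])) if self.MSA[gid][c] not in "-."
            ]
            cds = self.CDS[gid]
            for j, col in enumerate(aln.column_map):
                k = ungapped_cols.index(col - 1)
                assert aln.codon(gid, j) == cds[3 * k : 3 * k + 3]

    def test_silent_difference_keeps_identical_proteins(self):
        msa = {"a": "MK", "b": "MK"}
        cds = {"a": "ATGAAA", "b": "ATGAAG"}
        aln = build_codon_alignment(msa, cds)
        assert aln.rows["a"] != aln.rows["b"]

    def test_terminal_stop_tolerated(self):
        aln = build_codon_alignment({"a": "MK"}, {"a": "ATGAAATAA"})
        assert aln.rows["a"] == "ATGAAA"

    def test_translation_mismatch_names_gene_and_position(self):
        with pytest.raises(ValueError, match="residue 2"):
            build_codon_alignment({"a": "MW"}, {"a": "ATGAAA"})

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            build_codon_alignment({"a": "MKR"}, {"a": "ATGAAA"})


class TestNG86:
    def test_identical_rows(self):
        r = ng86_pairwise("CCT" * 9, "CCT" * 9)
        assert r.Sd == 0 and r.Nd == 0
        assert r.dS == 0 and r.dN == 0
        assert r.omega is None

    def test_proline_worked_example(self):
        # 9 codons, one synonymous third-position change
        r = ng86_pairwise("CCT" * 9, "CCT" * 8 + "CCC")
        assert r.S == pytest.approx(9.0)
        assert r.N == pytest.approx(18.0)
        assert (r.Sd, r.Nd) == (1.0, 0.0)
        assert r.dS == pytest.approx(0.1203, abs=1e-4)
        assert r.dN == 0.0
        assert r.omega == 0.0

    def test_sites_sum_to_three_per_codon(self):
        for codon in ["ATG", "TGG", "GGG", "TTA", "CGA"]:
            r = ng86_pairwise(codon, codon)
            assert r.S + r.N == pytest.approx(3.0)

    def test_low_divergence_recovery(self, rng):
        # pairwise NG86 omega within 25% of truth at low divergence,
        # averaged over seeded replicates
        tree = SpeciesTree.from_newick("(A:0.025,B:0.025);")
        ests = []
        for seed in range(12):
            seqs, _ = synthetic.simulate_codon_alignment(
                tree, 3000, omega=0.2, kappa=2.0, seed=seed
            )
            r = ng86_pairwise(seqs["A"], seqs["B"])
            if r.omega is not None:
                ests.append(r.omega)
        assert abs(np.mean(ests) - 0.2) / 0.2 < 0.25

    def test_saturation_flagged_when_ps_reaches_three_quarters(self):
        # every third position differs synonymously -> pS = 1, the
        # Jukes-Cantor correction is undefined and must be flagged
        r = ng86_pairwise("CTT" * 4, "CTC" + "CTA" + "CTG" + "CTC")
        assert r.saturated and r.dS is None
        r2 = ng86_pairwise("CCT" * 9, "CCT" * 8 + "CCC")
        assert not r2.saturated


class TestM0:
    def test_identical_sequences_collapse_branch_lengths(self):
        tree = SpeciesTree.from_newick("(A:0.1,B:0.1);")
        aln = CodonAlignment(
            ids=["A", "B"],
            rows={"A": "ATGAAACGT" * 10, "B": "ATGAAACGT" * 10},
            column_map=list(range(1, 31)),
        )
        fit = fit_m0(aln, tree, frequencies="uniform")
        assert sum(fit.branch_lengths.values()) < 1e-4
        assert fit.boundary  # omega unidentifiable, pinned at a bound

    def test_two_sequence_lnl_matches_expm_oracle(self):
        tree = SpeciesTree.from_newick("(A:0.1,B:0.15);")
        seqs, _ = synthetic.simulate_codon_alignment(tree, 200, 0.3, 2.0, seed=5)
        aln = CodonAlignment(
            ids=list(seqs), rows=seqs, column_map=list(range(1, 201))
        )
        fit = fit_m0(aln, tree, frequencies="uniform")
        Q = build_rate_matrix(fit.kappa, fit.omega)
        P = expm(Q * sum(fit.branch_lengths.values()))
        a = [CODON_INDEX[seqs["A"][i : i + 3]] for i in range(0, 600, 3)]
        b = [CODON_INDEX[seqs["B"][i : i + 3]] for i in range(0, 600, 3)]
        oracle = sum(math.log(P[i, j] / 61.0) for i, j in zip(a, b))
        assert fit.lnL == pytest.approx(oracle, abs=1e-6)

    def test_ng86_and_m0_agree_at_low_divergence(self, five_taxon_tree):
        seqs, _ = synthetic.simulate_codon_alignment(
            five_taxon_tree, 1000, omega=0.25, kappa=2.0, seed=3
        )
        aln = CodonAlignment(
            ids=list(seqs), rows=seqs, column_map=list(range(1, 1001))
        )
        fit = fit_m0(aln, five_taxon_tree, frequencies="uniform")
        pair_omegas = [
            r.omega
            for a, b in itertools.combinations(list(seqs), 2)
            if (r := ng86_pairwise(seqs[a], seqs[b])).omega is not None
        ]
        assert abs(np.mean(pair_omegas) - fit.omega) / fit.omega < 0.2


class TestBranchModel:
    def _classes(self, tree):
        return {
            n.label: (1 if n.label in ("C", "D", "N2") else 0)
            for n in tree.branches()
        }

    def test_null_data_gives_similar_class_estimates(self, ladder_tree):
        # single replicates are noisy; the seeded-panel means of the two
        # class estimates must agree when the data carry one true omega
        from famevol.selection import fit_branch_model

        est0, est1 = [], []
        for seed in (21, 24, 25):
            seqs, _ = synthetic.simulate_codon_alignment(
                ladder_tree, 800, omega=0.25, kappa=2.0, seed=seed
            )
            aln = CodonAlignment(
                ids=list(seqs), rows=seqs, column_map=list(range(1, 801))
            )
            fit = fit_branch_model(
                aln, ladder_tree, self._classes(ladder_tree), frequencies="uniform"
            )
            est0.append(fit.omegas[0])
            est1.append(fit.omegas[1])
        w0, w1 = np.mean(est0), np.mean(est1)
        assert abs(w0 - w1) / max(w0, w1) < 0.2

    def test_two_ratio_recovery_over_seeded_panel(self, ladder_tree):
        # single-replicate class estimates are noisy (each class sees only
        # part of the tree length), so assert on the panel mean
        from famevol.selection import fit_branch_model

        classes = self._classes(ladder_tree)
        branch_omega = {
            lab: (0.4 if classes[lab] == 1 else 0.1) for lab in classes
        }
        est0, est1 = [], []
        for seed in (22, 30, 31):
            seqs, _ = synthetic.simulate_codon_alignment(
                ladder_tree, 1000, omega=0.1, kappa=2.0, seed=seed,
                branch_omega=branch_omega,
            )
            aln = CodonAlignment(
                ids=list(seqs), rows=seqs, column_map=list(range(1, 1001))
            )
            fit = fit_branch_model(aln, ladder_tree, classes, frequencies="uniform")
            est0.append(fit.omegas[0])
            est1.append(fit.omegas[1])
        assert abs(np.mean(est0) - 0.1) / 0.1 < 0.25
        assert abs(np.mean(est1) - 0.4) / 0.4 < 0.25
        assert all(a < b for a, b in zip(est0, est1))  # classes separate

    def test_missing_branch_label_rejected(self, ladder_tree):
        from famevol.selection import fit_branch_model

        seqs, _ = synthetic.simulate_codon_alignment(
            ladder_tree, 60, omega=0.2, kappa=2.0, seed=23
        )
        aln = CodonAlignment(ids=list(seqs), rows=seqs, column_map=list(range(1, 61)))
        with pytest.raises(ValueError, match="without a class"):
            fit_branch_model(aln, ladder_tree, {"A": 0, "B": 1}, frequencies="uniform")


class TestLRT:
    def test_zero_statistic(self):
        assert likelihood_ratio_test(-100.0, -100.0, 1) == 1.0

    @pytest.mark.parametrize("stat,df", [(3.841, 1), (5.991, 2)])
    def test_chi_square_quantiles(self, stat, df):
        assert likelihood_ratio_test(-100.0, -100.0 + stat / 2, df) == pytest.approx(
            0.05, abs=5e-4
        )

    def test_negative_statistic_rejected(self):
        with pytest.raises(ValueError, match="below null"):
            likelihood_ratio_test(-100.0, -100.5, 1)


class TestGroupComparison:
    def test_identical_groups(self):
        med_a, med_b, p = compare_omega_groups([1, 2, 3], [1, 2, 3])
        assert med_a == med_b == 2
        assert p == 1.0

    def test_fully_separated_quartets_exact(self):
        _a, _b, p = compare_omega_groups([1, 2, 3, 4], [5, 6, 7, 8])
        assert p == pytest.approx(2 / 70)

    def test_symmetry(self):
        a, b = [0.1, 0.3, 0.2, 0.5], [0.4, 0.6, 0.7]
        assert compare_omega_groups(a, b)[2] == pytest.approx(
            compare_omega_groups(b, a)[2]
        )

    def test_exact_route_matches_scipy_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            a = list(rng.permutation(20)[:5] + rng.random(5))
            b = list(rng.permutation(20)[:7] + 30 * rng.random(7))
            _ma, _mb, p = compare_omega_groups(a, b)
            u = mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert p == pytest.approx(u.pvalue, abs=1e-9)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_omega_groups([1, 2], [3, 4, 5])


class TestDuplicationDating:
    def test_symmetric_midpoint(self):
        assert date_duplication(0.1, 0.1, 0.1, 35) == (17.5, 17.5)

    def test_duplication_at_present(self):
        assert date_duplication(0.2, 0.0, 0.0, 35) == (0.0, 0.0)

    def test_asymmetric_arithmetic(self):
        a1, a2 = date_duplication(0.2, 0.02, 0.03, 35)
        assert a1 == pytest.approx(35 * 0.02 / 0.22)
        assert a2 == pytest.approx(35 * 0.03 / 0.23)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            date_duplication(0.0, 0.0, 0.1, 35)


class TestIdentity:
    def test_pairwise_ignores_gap_columns(self):
        assert pairwise_identity("MK-RW", "MKQRW") == 1.0
        assert pairwise_identity("MKARW", "MKQRW") == pytest.approx(4 / 5)

    def test_group_summary(self):
        groups = [
            {"a": "MKRW", "b": "MKRW"},  # 100%
            {"a": "MKRW", "b": "MARW"},  # 75%
        ]
        mean, sem, per = mean_group_identity(groups)
        assert per == [100.0, 75.0]
        assert mean == pytest.approx(87.5)
        assert sem == pytest.approx(12.5)
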