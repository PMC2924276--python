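"""Codon-level selection analysis: dN/dS by counting and by ML.

Protein-guided codon alignments (gap columns removed) feed two routes to
omega = dN/dS: the Nei-Gojobori (1986) counting method with Jukes-Cantor
correction, and maximum-likelihood fits of the one-ratio (M0) and
two-ratio branch codon models by felsenstein pruning over the 61 sense
codons.  Nested fits are compared with a chi-square likelihood ratio
test, group omega distributions with Wilcoxon rank-sum, and gene
duplications are dated from synonymous divergence (dS) against a
calibrated species split.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from famevol.codon import (
    CODON_INDEX,
    CODONS,
    STOP_CODONS,
    CodonRateMatrix,
    f3x4_frequencies,
    translate_codon,
)
from famevol.io_formats import SequenceRecord
from famevol.trees import SpeciesTree

__all__ = [
    "CodonAlignment",
    "PairwiseDnDs",
    "CodonModelFit",
    "build_codon_alignment",
    "ng86_pairwise",
    "fit_m0",
    "fit_branch_model",
    "likelihood_ratio_test",
    "compare_omega_groups",
    "date_duplication",
    "pairwise_identity",
    "mean_group_identity",
]


# ---------------------------------------------------------------------------
# codon alignment construction


@dataclass
class CodonAlignment:
    """Gap-column-free codon matrix with a map back to MSA columns."""

    ids: List[str]
    rows: Dict[str, str]  # id -> nucleotide string, length = 3 * n_codons
    column_map: List[int]  # retained codon column -> original MSA column (1-based)

    @property
    def n_codons(self) -> int:
        return len(self.column_map)

    def codon(self, gene: str, column: int) -> str:
        """Codon of ``gene`` at retained column ``column`` (0-based)."""
        return self.rows[gene][3 * column : 3 * column + 3]

    def encoded(self) -> np.ndarray:
        """(n_seqs, n_codons) array of sense-codon indices, in ``ids`` order."""
        out = np.empty((len(self.ids), self.n_codons), dtype=np.int64)
        for i, gid in enumerate(self.ids):
            row = self.rows[gid]
            for j in range(self.n_codons):
                out[i, j] = CODON_INDEX[row[3 * j : 3 * j + 3]]
        return out


def build_codon_alignment(
    protein_msa: Union[Dict[str, str], Sequence[SequenceRecord]],
    cds_records: Union[Dict[str, str], Sequence[SequenceRecord]],
) -> CodonAlignment:
    """Thread coding sequences under a protein alignment.

    Every CDS must translate to its (gap-stripped) alignment row; a
    terminal stop codon on the CDS is tolerated and dropped.  Columns
    containing a gap in any sequence are removed, and an internal stop
    or 'X' marker inside the retained region is an error (pseudogenes
    and incomplete genes are excluded from selection analyses upstream).
    """
    if not isinstance(protein_msa, dict):
        protein_msa = {r.id: r.seq for r in protein_msa}
    if not isinstance(cds_records, dict):
        cds_records = {r.id: r.seq for r in cds_records}
    ids = list(protein_msa)
    widths = {len(v) for v in protein_msa.values()}
    if len(widths) != 1:
        raise ValueError("protein alignment rows have unequal lengths")
    width = widths.pop()

    threaded: Dict[str, List[Optional[str]]] = {}
    for gid in ids:
        row = protein_msa[gid]
        if gid not in cds_records:
            raise KeyError(f"no CDS for {gid!r}")
        cds = cds_records[gid].upper().replace("U", "T")
        ungapped = row.replace("-", "").replace(".", "")
        if len(cds) == 3 * (len(ungapped) + 1) and cds[-3:] in STOP_CODONS:
            cds = cds[:-3]
        if len(cds) != 3 * len(ungapped):
            raise ValueError(
                f"{gid}: CDS length {len(cds)} does not match protein length "
                f"{len(ungapped)}"
            )
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        for pos, (codon, aa) in enumerate(zip(codons, ungapped), start=1):
            if aa in "Xx":
                continue  # marker columns are dropped later or error below
            trans = translate_codon(codon)
            if trans == "*" or trans != aa.upper():
                raise ValueError(
                    f"{gid}: codon {codon} at residue {pos} does not translate "
                    f"to aligned residue {aa!r}"
                )
        cells: List[Optional[str]] = []
        k = 0
        for ch in row:
            if ch in "-.":
                cells.append(None)
            else:
                cells.append(codons[k])
                k += 1
        threaded[gid] = cells

    keep: List[int] = []
    for col in range(width):
        cell_ok = True
        for gid in ids:
            cell = threaded[gid][col]
            aa = protein_msa[gid][col]
            if cell is None:
                cell_ok = False
                break
            if aa == "X" or translate_codon(cell) == "*":
                raise ValueError(
                    f"{gid}: internal stop at alignment column {col + 1} "
                    "inside the retained region"
                )
            if aa == "x":
                cell_ok = False  # unknown residue: treat like a gap column
                break
        if cell_ok:
            keep.append(col)

    rows = {
        gid: "".join(threaded[gid][col] for col in keep) for gid in ids
    }
    return CodonAlignment(ids=ids, rows=rows, column_map=[c + 1 for c in keep])


# ---------------------------------------------------------------------------
# NG86 counting


@dataclass
class PairwiseDnDs:
    """Nei-Gojobori site/difference counts and corrected rates."""

    S: float
    N: float
    Sd: float
    Nd: float
    dS: Optional[float]
    dN: Optional[float]
    omega: Optional[float]
    saturated: bool = False  # p >= 3/4, Jukes-Cantor correction undefined


def _codon_site_counts(codon: str) -> Tuple[float, float]:
    syn = 0.0
    for pos in range(3):
        n_syn = 0
        n_valid = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            n_valid += 1
            if translate_codon(alt) == translate_codon(codon):
                n_syn += 1
        if n_valid:
            syn += n_syn / n_valid
    return syn, 3.0 - syn


def _codon_diff_counts(a: str, b: str) -> Tuple[float, float]:
    positions = [i for i in range(3) if a[i] != b[i]]
    if not positions:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(positions):
        cur = a
        sd = nd = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                through_stop = True
                break
            if translate_codon(cur) == translate_codon(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if not through_stop:
            paths.append((sd, nd))
    if not paths:  # all paths pass through a stop; fall back to including them
        for order in itertools.permutations(positions):
            cur = a
            sd = nd = 0
            for pos in order:
                nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
                if translate_codon(cur) == translate_codon(nxt):
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            paths.append((sd, nd))
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def _jc_correct(p: float) -> Optional[float]:
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_pairwise(row_a: str, row_b: str) -> PairwiseDnDs:
    """Nei-Gojobori (1986) dN/dS between two gap-free codon rows.

    Sites are averaged over the two sequences, multiple-hit codons are
    averaged over equally weighted substitution paths (paths through
    stop codons excluded), and proportions are Jukes-Cantor corrected.
    """
    if len(row_a) != len(row_b) or len(row_a) % 3:
        raise ValueError("rows must be equal length and a multiple of 3")
    n_codons = len(row_a) // 3
    S = N = Sd = Nd = 0.0
    for k in range(n_codons):
        ca, cb = row_a[3 * k : 3 * k + 3], row_b[3 * k : 3 * k + 3]
        for c in (ca, cb):
            if c in STOP_CODONS or c not in CODON_INDEX:
                raise ValueError(f"invalid or stop codon {c!r}")
        sa, na = _codon_site_counts(ca)
        sb, nb = _codon_site_counts(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = _codon_diff_counts(ca, cb)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = _jc_correct(pS)
    dN = _jc_correct(pN)
    saturated = dS is None or dN is None
    omega: Optional[float] = None
    if dS is not None and dN is not None and dS > 0:
        omega = dN / dS
    return PairwiseDnDs(S=S, N=N, Sd=Sd, Nd=Nd, dS=dS, dN=dN, omega=omega, saturated=saturated)


# ---------------------------------------------------------------------------
# ML codon model fitting


@dataclass
class CodonModelFit:
    """Result of an ML codon model fit."""

    model: str  # "M0" or "branch"
    kappa: float
    omegas: Tuple[float, ...]  # one per ratio class
    branch_lengths: Dict[str, float]
    lnL: float
    converged: bool
    n_restarts: int
    frequencies: str = "uniform"
    boundary: bool = False  # omega/kappa pinned at a search bound

    @property
    def omega(self) -> float:
        return self.omegas[0]


class _CodonPruner:
    """Pattern-compressed pruning likelihood for GY-style codon models."""

    def __init__(
        self,
        alignment: CodonAlignment,
        tree: SpeciesTree,
        branch_class: Dict[str, int],
        n_classes: int,
        frequencies: str = "uniform",
    ):
        if set(tree.tip_names) != set(alignment.ids):
            raise ValueError("tree tips and alignment ids differ")
        self.tree = tree
        self.branch_class = branch_class
        self.n_classes = n_classes
        data = alignment.encoded()
        self.taxon_row = {gid: i for i, gid in enumerate(alignment.ids)}
        patterns, counts = np.unique(data, axis=1, return_counts=True)
        self.patterns = patterns
        self.counts = counts.astype(float)
        if frequencies == "uniform":
            self.pi = np.full(len(CODONS), 1.0 / len(CODONS))
        elif frequencies == "f3x4":
            self.pi = f3x4_frequencies(list(alignment.rows.values()))
        else:
            raise ValueError("frequencies must be 'uniform' or 'f3x4'")
        self.frequencies = frequencies
        self._cache: Dict[Tuple[float, float], CodonRateMatrix] = {}

    def _model(self, kappa: float, omega: float) -> CodonRateMatrix:
        key = (kappa, omega)
        if key not in self._cache:
            if len(self._cache) > 64:
                self._cache.clear()
            self._cache[key] = CodonRateMatrix(kappa, omega, self.pi)
        return self._cache[key]

    def loglik(
        self, kappa: float, omegas: Sequence[float], blens: Dict[str, float]
    ) -> float:
        models = [self._model(kappa, w) for w in omegas]
        npat = self.patterns.shape[1]
        logscale = 0.0
        partial: Dict[int, np.ndarray] = {}
        for node in self.tree.postorder():
            if node.is_leaf():
                continue
            vec = np.ones((len(CODONS), npat))
            for child in node.child_nodes():
                P = models[self.branch_class[child.label]].transition_matrix(
                    blens[child.label]
                )
                if child.is_leaf():
                    states = self.patterns[self.taxon_row[child.taxon.label]]
                    vec = vec * P[:, states]
                else:
                    vec = vec * (P @ partial[id(child)])
            mx = vec.max(axis=0)
            if np.any(mx <= 0):
                return -np.inf
            vec = vec / mx
            logscale = logscale + self.counts @ np.log(mx)
            partial[id(node)] = vec
        site_lik = self.pi @ partial[id(self.tree.root)]
        if np.any(site_lik <= 0):
            return -np.inf
        return float(self.counts @ np.log(site_lik) + logscale)


_LOG_BOUNDS_RATE = (math.log(1e-4), math.log(99.0))
_LOG_BOUNDS_BLEN = (math.log(1e-7), math.log(30.0))
_STARTS = [(2.0, 0.4), (1.0, 0.1), (4.0, 1.0)]


def _fit_codon_model(
    pruner: _CodonPruner,
    n_classes: int,
    model_name: str,
    starts: Optional[List[Tuple[float, ...]]] = None,
    init_blen: float = 0.1,
) -> CodonModelFit:
    branch_labels = [n.label for n in pruner.tree.branches()]
    nb = len(branch_labels)

    def unpack(x: np.ndarray):
        kappa = math.exp(x[0])
        omegas = [math.exp(v) for v in x[1 : 1 + n_classes]]
        blens = {
            lab: math.exp(v)
            for lab, v in zip(branch_labels, x[1 + n_classes :])
        }
        return kappa, omegas, blens

    def neg(x: np.ndarray) -> float:
        kappa, omegas, blens = unpack(x)
        ll = pruner.loglik(kappa, omegas, blens)
        return -ll if np.isfinite(ll) else 1e12

    bounds = (
        [_LOG_BOUNDS_RATE] * (1 + n_classes) + [_LOG_BOUNDS_BLEN] * nb
    )
    if starts is None:
        starts = [
            (k0,) + (w0,) * n_classes + (init_blen,) * nb for k0, w0 in _STARTS
        ]
    best = None
    n_used = 0
    for start in starts:
        n_used += 1
        x0 = np.log(np.asarray(start, dtype=float))
        res = minimize(
            neg,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-10, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun:
            best = res
        if best.fun < 1e11 and n_used >= 2 and abs(res.fun - best.fun) < 1e-4:
            break  # two agreeing restarts; skip the third
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e11:
        raise RuntimeError(
            f"{model_name} fit failed to converge after {n_used} restarts"
        )
    kappa, omegas, blens = unpack(best.x)
    lo, hi = math.exp(_LOG_BOUNDS_RATE[0]), math.exp(_LOG_BOUNDS_RATE[1])
    boundary = any(
        not (lo * 1.01 < v < hi * 0.99) for v in [kappa, *omegas]
    )
    if sum(blens.values()) < 1e-6:
        boundary = True  # no substitutions: omega and kappa unidentifiable
    return CodonModelFit(
        model=model_name,
        kappa=kappa,
        omegas=tuple(omegas),
        branch_lengths=blens,
        lnL=float(-best.fun),
        converged=bool(best.success or best.fun < 1e11),
        n_restarts=n_used,
        frequencies=pruner.frequencies,
        boundary=boundary,
    )


def fit_m0(
    alignment: CodonAlignment,
    tree: SpeciesTree,
    frequencies: str = "f3x4",
    starts: Optional[List[Tuple[float, ...]]] = None,
) -> CodonModelFit:
    """One-ratio (M0) ML fit: single omega and kappa, free branch lengths.

    Multiple restarts from distinct starting points guard against local
    optima; the best log-likelihood is kept.  With a rooted input tree
    and a reversible model, only the sum of the two root-adjacent branch
    lengths is identifiable; their split is arbitrary.
    """
    branch_class = {n.label: 0 for n in tree.branches()}
    pruner = _CodonPruner(alignment, tree, branch_class, 1, frequencies)
    return _fit_codon_model(pruner, 1, "M0", starts=starts)


def fit_branch_model(
    alignment: CodonAlignment,
    tree: SpeciesTree,
    branch_classes: Dict[str, int],
    frequencies: str = "f3x4",
    starts: Optional[List[Tuple[float, ...]]] = None,
) -> CodonModelFit:
    """Two-ratio branch model: one omega per branch class.

    ``branch_classes`` maps every branch (child-node label) to class 0
    or 1; ``omegas[c]`` in the result is the estimate for class c.  The
    caller may discard one class's ratio, e.g. when an outgroup lineage
    is included only to polarise the ingroup estimate.
    """
    labels = {n.label for n in tree.branches()}
    missing = labels - set(branch_classes)
    if missing:
        raise ValueError(f"branches without a class label: {sorted(missing)}")
    classes = {branch_classes[lab] for lab in labels}
    if classes != {0, 1}:
        raise ValueError("branch_classes must use both labels 0 and 1")
    pruner = _CodonPruner(alignment, tree, branch_classes, 2, frequencies)
    return _fit_codon_model(pruner, 2, "branch", starts=starts)


def likelihood_ratio_test(
    lnl_null: float, lnl_alt: float, df: int, tolerance: float = 1e-6
) -> float:
    """Upper-tail chi-square p-value for nested model comparison."""
    if df < 1:
        raise ValueError("df must be >= 1")
    stat = 2.0 * (lnl_alt - lnl_null)
    if stat < -tolerance:
        raise ValueError(
            f"alternative log-likelihood below null by {-stat / 2:.6g}; "
            "refit before testing"
        )
    return float(chi2.sf(max(stat, 0.0), df))


# ---------------------------------------------------------------------------
# group comparison and dating


def _exact_ranksum_p(a: Sequence[float], b: Sequence[float]) -> float:
    values = sorted(list(a) + list(b))
    # assign ranks 1..n (no ties by precondition)
    rank_of = {v: i + 1 for i, v in enumerate(values)}
    na = len(a)
    w_obs = sum(rank_of[v] for v in a)
    n = na + len(b)
    sums = [sum(c) for c in itertools.combinations(range(1, n + 1), na)]
    total = len(sums)
    p_low = sum(1 for s in sums if s <= w_obs) / total
    p_high = sum(1 for s in sums if s >= w_obs) / total
    return min(1.0, 2.0 * min(p_low, p_high))


def _approx_ranksum_p(a: Sequence[float], b: Sequence[float]) -> float:
    values = list(a) + list(b)
    n = len(values)
    order = sorted(range(n), key=lambda i: values[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[order[j + 1]] == values[order[i]]:
            j += 1
        mean_rank = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = mean_rank
        i = j + 1
    na, nb = len(a), len(b)
    w = sum(ranks[:na])
    mean_w = na * (n + 1) / 2.0
    # tie-corrected variance
    tie_term = 0.0
    from collections import Counter

    for count in Counter(values).values():
        tie_term += count**3 - count
    var_w = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_w <= 0:
        return 1.0
    z = (w - mean_w) / math.sqrt(var_w)
    from scipy.stats import norm

    return float(2.0 * norm.sf(abs(z)))


def compare_omega_groups(
    omegas_a: Sequence[float], omegas_b: Sequence[float]
) -> Tuple[float, float, float]:
    """Medians and two-sided Wilcoxon rank-sum p between two omega sets.

    The exact rank-sum distribution is enumerated when the smaller group
    has at most 8 values and there are no ties; otherwise the normal
    approximation with tie correction is used.
    """
    if len(omegas_a) < 3 or len(omegas_b) < 3:
        raise ValueError("each group needs at least 3 values")
    med_a = float(np.median(omegas_a))
    med_b = float(np.median(omegas_b))
    pooled = list(omegas_a) + list(omegas_b)
    no_ties = len(set(pooled)) == len(pooled)
    if min(len(omegas_a), len(omegas_b)) <= 8 and no_ties:
        if len(omegas_a) <= len(omegas_b):
            p = _exact_ranksum_p(omegas_a, omegas_b)
        else:
            p = _exact_ranksum_p(omegas_b, omegas_a)
    else:
        p = _approx_ranksum_p(omegas_a, omegas_b)
    return med_a, med_b, p


def date_duplication(
    dS_before: float, dS_after_1: float, dS_after_2: float, T_div: float
) -> Tuple[float, float]:
    """Date a duplication from dS on the pre- and post-duplication branches.

    With dS accumulating clock-like, the fraction of the path from the
    calibrated species split that lies after the duplication estimates
    the duplication age:  age_k = T_div * dS_after_k / (dS_before +
    dS_after_k), one estimate per post-duplication branch.
    """
    if min(dS_before, dS_after_1, dS_after_2) < 0:
        raise ValueError("dS values must be non-negative")
    ages = []
    for after in (dS_after_1, dS_after_2):
        denom = dS_before + after
        if denom == 0:
            raise ValueError("dS_before + dS_after is zero; cannot date")
        ages.append(T_div * after / denom)
    return ages[0], ages[1]


# ---------------------------------------------------------------------------
# sequence identity summaries


def pairwise_identity(row_a: str, row_b: str) -> float:
    """Fraction of identical residues over columns where both rows are ungapped."""
    if len(row_a) != len(row_b):
        raise ValueError("rows must be aligned (equal length)")
    same = tot = 0
    for x, y in zip(row_a, row_b):
        if x in "-." or y in "-.":
            continue
        tot += 1
        if x.upper() == y.upper():
            same += 1
    return same / tot if tot else 0.0


def mean_group_identity(
    group_msas: Sequence[Dict[str, str]],
) -> Tuple[float, float, List[float]]:
    """Mean within-orthogroup pairwise identity, with s.e.m. across groups.

    Each element of ``group_msas`` is one orthogroup's protein alignment
    (id -> aligned row).  Within a group, identity is averaged over all
    sequence pairs; the return value is (mean %, s.e.m. %, per-group %).
    """
    per_group: List[float] = []
    for msa in group_msas:
        rows = list(msa.values())
        if len(rows) < 2:
            continue
        idents = [
            pairwise_identity(a, b) for a, b in itertools.combinations(rows, 2)
        ]
        per_group.append(100.0 * float(np.mean(idents)))
    if not per_group:
        raise ValueError("no group with >= 2 sequences")
    mean = float(np.mean(per_group))
    sem = float(np.std(per_group, ddof=1) / math.sqrt(len(per_group))) if len(per_group) > 1 else 0.0
    return mean, sem, per_group
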