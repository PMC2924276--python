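"""Gene family birth-death reconciliation on a dated species tree.

The model is the linear birth-death process with equal per-gene gain and
loss rates (lambda = mu), the single-parameter model used by CAFE-style
analyses of gene family counts.  Writing alpha = lambda*t / (1 + lambda*t),
the probability that a single gene leaves c descendants after time t is

    P(1 -> 0) = alpha,          P(1 -> c) = (1 - alpha)^2 alpha^(c-1)  (c >= 1)

and for s independent ancestor genes

    P(s -> c) = sum_j  C(s, j) C(s + c - j - 1, s - 1)
                      alpha^(s + c - 2j) (1 - 2 alpha)^j ,

the classical Tucker/Bailey solution.  The family likelihood is computed
by pruning over integer ancestral counts; a single lambda is fitted by
bounded scalar maximisation of the summed log-likelihood.

Ancestral counts are reconstructed by a max-product (joint MAP) dynamic
programme, per-branch gains and losses are read off the reconstruction,
and rates are summarised per branch and tree-wide:

    r_i = events_i / C_parent(i) / t_i
    D   = sum_i L_i / sum_i (C_i * t_i),    B likewise with gains,

where C_i is the reconstructed count at the parent node of branch i.
Pseudogenes observed at tips are treated as losses already realised on
the terminal branch: they are excluded from the "present" count used in
the likelihood and added to that branch's loss tally as pseudogenisation
events.  Incomplete gene annotations count as present.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import comb

from famevol.trees import SpeciesTree

__all__ = [
    "FamilyCountTable",
    "EventReconstruction",
    "RateSummary",
    "bd_transition_prob",
    "bd_transition_matrix",
    "fit_birth_death_rate",
    "reconstruct_ancestral_counts",
    "count_branch_events",
    "summarize_rates",
]


# ---------------------------------------------------------------------------
# count table


@dataclass
class FamilyCountTable:
    """Per-family, per-species gene counts.

    ``counts[family][species] = (functional, pseudogene, incomplete)``.
    The count used as "present" in likelihood and reconstruction is
    functional + incomplete.
    """

    counts: Dict[str, Dict[str, Tuple[int, int, int]]]

    def __post_init__(self) -> None:
        for fam, per_sp in self.counts.items():
            for sp, (f, p, i) in per_sp.items():
                if min(f, p, i) < 0:
                    raise ValueError(f"negative count for {fam}/{sp}")

    @property
    def families(self) -> List[str]:
        return list(self.counts)

    @property
    def species(self) -> List[str]:
        sp = set()
        for per_sp in self.counts.values():
            sp.update(per_sp)
        return sorted(sp)

    def present(self, family: str, species: str) -> int:
        f, _p, i = self.counts[family].get(species, (0, 0, 0))
        return f + i

    def pseudogenes(self, family: str, species: str) -> int:
        return self.counts[family].get(species, (0, 0, 0))[1]

    def max_present(self) -> int:
        return max(
            (self.present(f, s) for f in self.families for s in self.counts[f]),
            default=0,
        )

    @classmethod
    def from_tsv(cls, path: str) -> "FamilyCountTable":
        df = pd.read_csv(path, sep="\t")
        required = {"family", "species", "functional"}
        if not required <= set(df.columns):
            raise ValueError(f"count table needs columns {sorted(required)}")
        counts: Dict[str, Dict[str, Tuple[int, int, int]]] = {}
        for _, row in df.iterrows():
            fam = str(row["family"])
            counts.setdefault(fam, {})[str(row["species"])] = (
                int(row["functional"]),
                int(row.get("pseudogene", 0) or 0),
                int(row.get("incomplete", 0) or 0),
            )
        return cls(counts)

    def to_tsv(self, path: str) -> None:
        rows = []
        for fam, per_sp in self.counts.items():
            for sp, (f, p, i) in per_sp.items():
                rows.append((fam, sp, f, p, i))
        pd.DataFrame(
            rows, columns=["family", "species", "functional", "pseudogene", "incomplete"]
        ).to_csv(path, sep="\t", index=False)

    def validate_against_tree(self, tree: SpeciesTree) -> None:
        tips = set(tree.tip_names)
        for fam, per_sp in self.counts.items():
            unknown = set(per_sp) - tips
            if unknown:
                raise ValueError(
                    f"family {fam!r} names species absent from the tree: {sorted(unknown)}"
                )


# ---------------------------------------------------------------------------
# transition kernel


def bd_transition_prob(s: int, c: int, t: float, lam: float) -> float:
    """P(c descendant genes after time t | s ancestor genes), lambda = mu."""
    if s < 0 or c < 0 or t < 0 or lam < 0:
        raise ValueError("s, c, t and lam must all be non-negative")
    if s == 0:
        return 1.0 if c == 0 else 0.0
    lt = lam * t
    if lt == 0:
        return 1.0 if c == s else 0.0
    alpha = lt / (1.0 + lt)
    total = 0.0
    for j in range(min(s, c) + 1):
        total += (
            comb(s, j, exact=True)
            * comb(s + c - j - 1, s - 1, exact=True)
            * alpha ** (s + c - 2 * j)
            * (1.0 - 2.0 * alpha) ** j
        )
    return float(max(total, 0.0))


def bd_transition_matrix(n_max: int, t: float, lam: float) -> np.ndarray:
    """Dense (n_max+1) x (n_max+1) matrix of ``bd_transition_prob`` values.

    Row s, column c.  Vectorised over the closed-form sum; rows sum to one
    up to truncation of counts above ``n_max``.
    """
    n = n_max + 1
    lt = lam * t
    if lt == 0:
        return np.eye(n)
    alpha = lt / (1.0 + lt)
    S = np.arange(n)[:, None].astype(float)
    C = np.arange(n)[None, :].astype(float)
    M = np.zeros((n, n))
    for j in range(n):
        mask = (j <= np.minimum(S, C)) & (S >= 1)
        term = np.where(
            mask,
            comb(S, j) * comb(S + C - j - 1, np.maximum(S - 1, 0))
            * alpha ** (S + C - 2 * j) * (1.0 - 2.0 * alpha) ** j,
            0.0,
        )
        M += term
    M[0, :] = 0.0
    M[0, 0] = 1.0
    return np.maximum(M, 0.0)


# ---------------------------------------------------------------------------
# likelihood + fit


def _family_loglik(
    tree: SpeciesTree,
    observed: Dict[str, int],
    lam: float,
    c_max: int,
    mats: Dict[str, np.ndarray],
) -> float:
    """Log-likelihood of one family's tip counts, root prior uniform on 1..c_max."""
    partial: Dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf():
            vec = np.zeros(c_max + 1)
            obs = observed.get(node.taxon.label, 0)
            if obs > c_max:
                raise ValueError(f"tip count {obs} exceeds bound {c_max}")
            vec[obs] = 1.0
            partial[id(node)] = vec
        else:
            vec = np.ones(c_max + 1)
            for child in node.child_nodes():
                vec = vec * (mats[child.label] @ partial[id(child)])
            partial[id(node)] = vec
    root_vec = partial[id(tree.root)]
    lik = root_vec[1:].mean()  # uniform prior over 1..c_max (presence at root)
    if lik <= 0:
        return -math.inf
    return math.log(lik)


def _branch_matrices(tree: SpeciesTree, lam: float, c_max: int) -> Dict[str, np.ndarray]:
    by_length: Dict[float, np.ndarray] = {}
    mats = {}
    for node in tree.branches():
        t = float(node.edge.length or 0.0)
        if t not in by_length:
            by_length[t] = bd_transition_matrix(c_max, t, lam)
        mats[node.label] = by_length[t]
    return mats


def total_loglik(
    table: FamilyCountTable,
    tree: SpeciesTree,
    lam: float,
    c_max: Optional[int] = None,
) -> float:
    """Summed log-likelihood over families at rate ``lam``."""
    if c_max is None:
        c_max = 2 * table.max_present() + 5
    mats = _branch_matrices(tree, lam, c_max)
    total = 0.0
    for fam in table.families:
        observed = {sp: table.present(fam, sp) for sp in table.counts[fam]}
        total += _family_loglik(tree, observed, lam, c_max, mats)
    return total


def fit_birth_death_rate(
    table: FamilyCountTable,
    tree: SpeciesTree,
    lam_bounds: Tuple[float, float] = (1e-7, 1.0),
    c_max: Optional[int] = None,
) -> Tuple[float, float]:
    """ML estimate of the single birth-death rate lambda (= mu).

    Returns ``(lam_hat, loglik)``.  The likelihood is maximised over
    log-lambda with a bounded scalar optimiser; deterministic.
    """
    table.validate_against_tree(tree)
    if not table.families:
        raise ValueError("empty count table")
    if table.max_present() == 0:
        raise ValueError("all families are empty at every tip")
    if c_max is None:
        c_max = 2 * table.max_present() + 5

    lo, hi = math.log(lam_bounds[0]), math.log(lam_bounds[1])

    def neg(loglam: float) -> float:
        return -total_loglik(table, tree, math.exp(loglam), c_max)

    res = minimize_scalar(
        neg, bounds=(lo, hi), method="bounded", options={"xatol": 1e-8}
    )
    lam_hat = float(math.exp(res.x))
    return lam_hat, float(-res.fun)


# ---------------------------------------------------------------------------
# ancestral reconstruction and events


@dataclass
class EventReconstruction:
    """Joint MAP ancestral counts and per-branch event tallies."""

    tree: SpeciesTree
    lam: float
    # node label -> {family -> count}; tips carry the observed present count
    node_counts: Dict[str, Dict[str, int]] = field(default_factory=dict)
    # branch (child-node label) -> {family -> signed count change}
    branch_deltas: Dict[str, Dict[str, int]] = field(default_factory=dict)
    pseudogenes: Dict[str, Dict[str, int]] = field(default_factory=dict)

    def count_at(self, node_label: str, family: str) -> int:
        return self.node_counts[node_label][family]

    def total_count_at(self, node_label: str) -> int:
        return sum(self.node_counts[node_label].values())


def reconstruct_ancestral_counts(
    table: FamilyCountTable,
    tree: SpeciesTree,
    lam: float,
    c_max: Optional[int] = None,
) -> EventReconstruction:
    """Joint max-probability integer counts at every internal node.

    Max-product dynamic programming over counts 0..c_max with the root
    restricted to >= 1 (presence conditioning); ties broken toward the
    smaller count.  A family absent from every tip short-circuits to
    all-zero ancestors (conditioning removed for that degenerate case).
    """
    table.validate_against_tree(tree)
    if c_max is None:
        c_max = 2 * table.max_present() + 5
    mats = _branch_matrices(tree, lam, c_max)
    with np.errstate(divide="ignore"):
        logmats = {k: np.log(v) for k, v in mats.items()}

    rec = EventReconstruction(tree=tree, lam=lam)
    rec.node_counts = {n.label: {} for n in tree.preorder()}
    rec.branch_deltas = {n.label: {} for n in tree.branches()}
    rec.pseudogenes = {n.label: {} for n in tree.branches()}

    for fam in table.families:
        observed = {sp: table.present(fam, sp) for sp in table.counts[fam]}
        if all(v == 0 for v in observed.values()):
            for n in tree.preorder():
                rec.node_counts[n.label][fam] = 0
            for n in tree.branches():
                rec.branch_deltas[n.label][fam] = 0
        else:
            _reconstruct_family(tree, observed, logmats, c_max, fam, rec)
        for n in tree.branches():
            if n.is_leaf():
                rec.pseudogenes[n.label][fam] = table.pseudogenes(fam, n.taxon.label)
            parent = n.parent_node
            rec.branch_deltas[n.label][fam] = (
                rec.node_counts[n.label][fam] - rec.node_counts[parent.label][fam]
            )
    return rec


def _reconstruct_family(
    tree: SpeciesTree,
    observed: Dict[str, int],
    logmats: Dict[str, np.ndarray],
    c_max: int,
    fam: str,
    rec: EventReconstruction,
) -> None:
    score: Dict[int, np.ndarray] = {}
    backptr: Dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf():
            obs = observed.get(node.taxon.label, 0)
            if obs > c_max:
                raise ValueError(
                    f"tip count {obs} exceeds the count bound {c_max}; "
                    "raise c_max"
                )
            vec = np.full(c_max + 1, -np.inf)
            vec[obs] = 0.0
            score[id(node)] = vec
        else:
            vec = np.zeros(c_max + 1)
            for child in node.child_nodes():
                # cand[s, c] = log P(s->c) + score_child(c)
                cand = logmats[child.label] + score[id(child)][None, :]
                best = np.argmax(cand, axis=1)  # first max = smallest count
                backptr[id(child)] = best
                vec = vec + cand[np.arange(c_max + 1), best]
            score[id(node)] = vec

    root_scores = score[id(tree.root)].copy()
    root_scores[0] = -np.inf  # presence at the root
    root_state = int(np.argmax(root_scores))

    assign: Dict[int, int] = {id(tree.root): root_state}
    for node in tree.preorder():
        if node is tree.root:
            continue
        parent_state = assign[id(node.parent_node)]
        assign[id(node)] = int(backptr[id(node)][parent_state])
    for node in tree.preorder():
        rec.node_counts[node.label][fam] = assign[id(node)]


@dataclass
class BranchEvents:
    """Per-branch gain/loss tallies summed over families."""

    gains: Dict[str, int]
    losses: Dict[str, int]  # includes pseudogenisation losses
    pseudogenisations: Dict[str, int]

    @property
    def total_gains(self) -> int:
        return sum(self.gains.values())

    @property
    def total_losses(self) -> int:
        return sum(self.losses.values())

    @property
    def total_pseudogenisations(self) -> int:
        return sum(self.pseudogenisations.values())


def count_branch_events(rec: EventReconstruction) -> BranchEvents:
    """Tally gains and losses per branch from a reconstruction.

    Each unit of count change is one event (a +2 branch is two gain
    events).  Pseudogene counts observed at tips are added to the
    terminal branch's losses and tallied separately as pseudogenisations.
    """
    gains: Dict[str, int] = {}
    losses: Dict[str, int] = {}
    pseudo: Dict[str, int] = {}
    for node in rec.tree.branches():
        lab = node.label
        g = sum(max(d, 0) for d in rec.branch_deltas[lab].values())
        l = sum(max(-d, 0) for d in rec.branch_deltas[lab].values())
        p = sum(rec.pseudogenes[lab].values())
        gains[lab] = g
        losses[lab] = l + p
        pseudo[lab] = p
    return BranchEvents(gains=gains, losses=losses, pseudogenisations=pseudo)


@dataclass
class RateSummary:
    """Per-branch and tree-averaged birth (B) and death (D) rates, /gene/My."""

    per_branch_birth: Dict[str, float]
    per_branch_death: Dict[str, float]
    B: float
    D: float
    n_branches: int
    total_gains: int
    total_losses: int
    total_pseudogenisations: int


def summarize_rates(
    events: BranchEvents,
    rec: EventReconstruction,
    tree: SpeciesTree,
) -> RateSummary:
    """Per-branch rates and tree-averaged B and D.

    Per branch i: rate = events_i / C_parent(i) / t_i.  Tree averages
    divide the event totals by sum_i C_parent(i) * t_i over all branches.
    """
    pb_birth: Dict[str, float] = {}
    pb_death: Dict[str, float] = {}
    denom = 0.0
    for node in tree.branches():
        lab = node.label
        t = float(node.edge.length or 0.0)
        c_parent = rec.total_count_at(node.parent_node.label)
        if t == 0 and (events.gains[lab] or events.losses[lab]):
            raise ValueError(f"events on zero-length branch {lab!r}")
        if t > 0 and c_parent > 0:
            pb_birth[lab] = events.gains[lab] / c_parent / t
            pb_death[lab] = events.losses[lab] / c_parent / t
        else:
            pb_birth[lab] = 0.0
            pb_death[lab] = 0.0
        denom += c_parent * t
    tg, tl = events.total_gains, events.total_losses
    B = tg / denom if denom > 0 else 0.0
    D = tl / denom if denom > 0 else 0.0
    return RateSummary(
        per_branch_birth=pb_birth,
        per_branch_death=pb_death,
        B=B,
        D=D,
        n_branches=tree.n_branches,
        total_gains=tg,
        total_losses=tl,
        total_pseudogenisations=events.total_pseudogenisations,
    )
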