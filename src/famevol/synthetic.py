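"""Synthetic data with ground truth for every analysis in the package.

Three generators emulate the statistical structure the estimators
assume:

* gene family counts evolving along a dated species tree under a linear
  birth-death process (lambda = mu by default, matching the fitted
  model), simulated exactly with per-event exponential waiting times,
  with optional retention of terminal-branch losses as observable
  pseudogenes;
* intron presence/absence/sliding histories of an ancestral set of
  (residue, phase) sites;
* gap-free codon alignments under the one-ratio (omega, kappa) codon
  model with uniform codon frequencies.

Each generator returns a full per-branch event log; replaying the log
from the root state reproduces every tip state exactly, which the test
suite uses as an internal-consistency oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from famevol.codon import CODONS, CodonRateMatrix
from famevol.family_dynamics import FamilyCountTable
from famevol.trees import SpeciesTree

__all__ = [
    "FamilySimTruth",
    "IntronSimTruth",
    "CodonSimTruth",
    "demo_tree",
    "DEMO_TREE_NEWICK",
    "simulate_family_evolution",
    "simulate_intron_history",
    "simulate_codon_alignment",
]


# A 12-taxon drosophilid-like dated tree (branch lengths in My; root at
# 40 My, the estimated age of the last common ancestor of the sequenced
# drosophilids).  Divergence times follow published mutation-clock
# estimates for the group.
DEMO_TREE_NEWICK = (
    "((((((Dmel:5.4,(Dsim:2.3,Dsec:2.3):3.1):5.0,(Dyak:6.1,Dere:6.1):4.3):15.6,"
    "Dana:26.0):5.0,(Dpse:1.4,Dper:1.4):29.6):4.0,Dwil:35.0):5.0,"
    "((Dmoj:26.7,Dvir:26.7):5.3,Dgri:32.0):8.0);"
)


def demo_tree() -> SpeciesTree:
    """The 12-taxon dated demonstration tree."""
    return SpeciesTree.from_newick(DEMO_TREE_NEWICK)


# ---------------------------------------------------------------------------
# family counts


@dataclass
class FamilySimTruth:
    """Ground truth for one simulated family."""

    family: str
    lam: float
    mu: float
    root_count: int
    # branch (child-node label) -> (gains, losses, pseudogenes_retained)
    events: Dict[str, Tuple[int, int, int]] = field(default_factory=dict)
    tip_counts: Dict[str, int] = field(default_factory=dict)

    def replay(self, tree: SpeciesTree) -> Dict[str, int]:
        """Recompute tip counts from the root count and the event log."""
        counts = {tree.root.label: self.root_count}
        for node in tree.preorder():
            if node is tree.root:
                continue
            g, l, _p = self.events[node.label]
            counts[node.label] = counts[node.parent_node.label] + g - l
        return {t: counts[t] for t in tree.tip_names}


def _evolve_branch(
    n: int, t: float, lam: float, mu: float, rng: np.random.Generator
) -> Tuple[int, int, int]:
    """Exact linear birth-death along one branch; returns (n_end, gains, losses)."""
    gains = losses = 0
    elapsed = 0.0
    while n > 0:
        rate = n * (lam + mu)
        if rate == 0:
            break
        elapsed += rng.exponential(1.0 / rate)
        if elapsed >= t:
            break
        if rng.random() < lam / (lam + mu):
            n += 1
            gains += 1
        else:
            n -= 1
            losses += 1
    return n, gains, losses


def simulate_family_evolution(
    tree: SpeciesTree,
    lam: float,
    mu: float,
    root_count: int = 1,
    pseudo_fraction: float = 0.0,
    n_families: int = 100,
    seed: int = 0,
) -> Tuple[FamilyCountTable, List[FamilySimTruth]]:
    """Simulate gene family counts under the birth-death model.

    Each loss on a terminal branch leaves an observable pseudogene with
    probability ``pseudo_fraction`` (drosophilids purge pseudogenes
    quickly, so only recent, terminal-branch losses remain visible).
    """
    if lam < 0 or mu < 0:
        raise ValueError("rates must be non-negative")
    if root_count < 1:
        raise ValueError("root_count must be >= 1")
    rng = np.random.default_rng([seed, 101])
    counts: Dict[str, Dict[str, Tuple[int, int, int]]] = {}
    truths: List[FamilySimTruth] = []
    for k in range(n_families):
        fam = f"fam{k:04d}"
        truth = FamilySimTruth(family=fam, lam=lam, mu=mu, root_count=root_count)
        state = {tree.root.label: root_count}
        for node in tree.preorder():
            if node is tree.root:
                continue
            t = float(node.edge.length or 0.0)
            n0 = state[node.parent_node.label]
            n1, g, l = _evolve_branch(n0, t, lam, mu, rng)
            pseudo = 0
            if node.is_leaf() and pseudo_fraction > 0 and l > 0:
                pseudo = int(rng.binomial(l, pseudo_fraction))
            truth.events[node.label] = (g, l, pseudo)
            state[node.label] = n1
        truth.tip_counts = {t: state[t] for t in tree.tip_names}
        counts[fam] = {
            tip: (state[tip], truth.events[tip][2], 0) for tip in tree.tip_names
        }
        truths.append(truth)
    return FamilyCountTable(counts), truths


# ---------------------------------------------------------------------------
# intron histories


@dataclass
class IntronSimTruth:
    """Event log of a simulated intron history."""

    loss_rate: float
    gain_rate: float
    slide_prob: float
    slide_window: int
    ancestral_sites: List[Tuple[str, int, int]]  # (site_id, residue, phase)
    # (branch, event, site_id, old_residue, new_residue)
    events: List[Tuple[str, str, str, Optional[int], Optional[int]]] = field(
        default_factory=list
    )


def simulate_intron_history(
    tree: SpeciesTree,
    ancestral_sites: Sequence[Tuple[int, int]],
    loss_rate: float = 0.0,
    gain_rate: float = 0.0,
    slide_prob: float = 0.0,
    slide_window: int = 2,
    protein_length: int = 500,
    seed: int = 0,
) -> Tuple[Dict[str, List[Tuple[str, int, int]]], IntronSimTruth]:
    """Evolve intron (residue, phase) sites along the tree.

    Per branch of length t: each site is lost with probability
    1 - exp(-loss_rate * t); a surviving site slides with probability
    ``slide_prob``, moving by at most ``slide_window`` residues while
    keeping its identity in the log; Poisson(gain_rate * t) new sites
    appear at uniform residues and phases.

    Returns per-tip site lists keyed by tip name, each entry
    ``(site_id, residue, phase)``, plus the truth log.
    """
    if loss_rate < 0 or gain_rate < 0:
        raise ValueError("rates must be non-negative")
    if slide_window < 1:
        raise ValueError("slide_window must be >= 1")
    for r, p in ancestral_sites:
        if p not in (0, 1, 2):
            raise ValueError(f"intron phase {p} outside {{0,1,2}}")
        if not (1 <= r <= protein_length):
            raise ValueError(f"ancestral residue {r} outside protein")
    rng = np.random.default_rng([seed, 202])
    anc = [
        (f"anc{i:02d}", int(r), int(p)) for i, (r, p) in enumerate(ancestral_sites)
    ]
    truth = IntronSimTruth(
        loss_rate=loss_rate,
        gain_rate=gain_rate,
        slide_prob=slide_prob,
        slide_window=slide_window,
        ancestral_sites=list(anc),
    )
    node_sites: Dict[str, List[Tuple[str, int, int]]] = {tree.root.label: list(anc)}
    gained = 0
    for node in tree.preorder():
        if node is tree.root:
            continue
        t = float(node.edge.length or 0.0)
        lab = node.label
        sites: List[Tuple[str, int, int]] = []
        p_loss = 1.0 - np.exp(-loss_rate * t)
        for sid, r, p in node_sites[node.parent_node.label]:
            if rng.random() < p_loss:
                truth.events.append((lab, "loss", sid, r, None))
                continue
            if slide_prob > 0 and rng.random() < slide_prob:
                shifts = [
                    d
                    for d in range(-slide_window, slide_window + 1)
                    if d != 0 and 1 <= r + d <= protein_length
                ]
                new_r = r + int(rng.choice(shifts))
                truth.events.append((lab, "slide", sid, r, new_r))
                r = new_r
            sites.append((sid, r, p))
        n_gain = int(rng.poisson(gain_rate * t)) if gain_rate > 0 else 0
        for _ in range(n_gain):
            sid = f"gain{gained:03d}"
            gained += 1
            r = int(rng.integers(1, protein_length + 1))
            p = int(rng.integers(0, 3))
            truth.events.append((lab, "gain", sid, None, r))
            sites.append((sid, r, p))
        node_sites[lab] = sites
    return {t: node_sites[t] for t in tree.tip_names}, truth


# ---------------------------------------------------------------------------
# codon alignments


@dataclass
class CodonSimTruth:
    omega: float
    kappa: float
    branch_lengths: Dict[str, float]
    seed: int


def simulate_codon_alignment(
    tree: SpeciesTree,
    n_codons: int,
    omega: float,
    kappa: float,
    seed: int = 0,
    branch_omega: Optional[Dict[str, float]] = None,
) -> Tuple[Dict[str, str], CodonSimTruth]:
    """Simulate a gap-free codon alignment under the one-ratio model.

    Branch lengths are read as expected substitutions per codon; codon
    frequencies are uniform over the 61 sense codons, so no stop codon
    can ever be produced.  ``branch_omega`` optionally overrides omega
    on named branches (child-node labels), e.g. to generate two-ratio
    data for branch-model tests.  Returns ``{tip_name:
    nucleotide_string}`` and the truth record.
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    rng = np.random.default_rng([seed, 303])
    models: Dict[float, CodonRateMatrix] = {}

    def model_for(w: float) -> CodonRateMatrix:
        if w not in models:
            models[w] = CodonRateMatrix(kappa=kappa, omega=w)
        return models[w]

    n_states = len(CODONS)
    states: Dict[str, np.ndarray] = {
        tree.root.label: rng.integers(0, n_states, size=n_codons)
    }
    for node in tree.preorder():
        if node is tree.root:
            continue
        t = float(node.edge.length or 0.0)
        parent = states[node.parent_node.label]
        if t == 0:
            states[node.label] = parent.copy()
            continue
        w = omega
        if branch_omega is not None:
            w = branch_omega.get(node.label, omega)
        P = model_for(w).transition_matrix(t)
        cum = np.cumsum(P, axis=1)
        u = rng.random(n_codons)
        child = np.empty(n_codons, dtype=np.int64)
        for s in range(n_states):
            mask = parent == s
            if mask.any():
                child[mask] = np.searchsorted(cum[s], u[mask])
        states[node.label] = np.minimum(child, n_states - 1)
    seqs = {
        tip: "".join(CODONS[s] for s in states[tip]) for tip in tree.tip_names
    }
    truth = CodonSimTruth(
        omega=omega,
        kappa=kappa,
        branch_lengths={
            n.label: float(n.edge.length or 0.0) for n in tree.branches()
        },
        seed=seed,
    )
    return seqs, truth
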