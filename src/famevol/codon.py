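"""Codon substitution machinery shared by the simulator and the fitters.

The model is the one-ratio (M0) Goldman-Yang-style codon model over the
61 sense codons of the universal genetic code: substitutions occur one
nucleotide at a time, transitions are weighted by kappa, nonsynonymous
changes by omega, and the target codon by its stationary frequency:

    q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous]

for codons i, j differing at exactly one position, 0 otherwise.  The
generator is scaled so that branch lengths are expected substitutions
per codon.  The chain is time-reversible, so transition matrices are
computed through a symmetric eigendecomposition (cheap to re-evaluate at
many branch lengths).
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "CODONS",
    "CODON_INDEX",
    "CODON_AA",
    "GENETIC_CODE",
    "STOP_CODONS",
    "translate_codon",
    "build_rate_matrix",
    "CodonRateMatrix",
    "f3x4_frequencies",
]

_BASES = "TCAG"
GENETIC_CODE: Dict[str, str] = {}
_AAS = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
_i = 0
for _b1 in _BASES:
    for _b2 in _BASES:
        for _b3 in _BASES:
            GENETIC_CODE[_b1 + _b2 + _b3] = _AAS[_i]
            _i += 1

STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")
CODONS: List[str] = [c for c in GENETIC_CODE if GENETIC_CODE[c] != "*"]
CODON_INDEX: Dict[str, int] = {c: i for i, c in enumerate(CODONS)}
CODON_AA: List[str] = [GENETIC_CODE[c] for c in CODONS]

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def translate_codon(codon: str) -> str:
    codon = codon.upper().replace("U", "T")
    if codon not in GENETIC_CODE:
        raise ValueError(f"not a codon: {codon!r}")
    return GENETIC_CODE[codon]


def _neighbour_tables() -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boolean 61x61 tables: single-nt neighbour, transition, synonymous."""
    n = len(CODONS)
    nb = np.zeros((n, n), dtype=bool)
    ts = np.zeros((n, n), dtype=bool)
    syn = np.zeros((n, n), dtype=bool)
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) == 1:
                nb[i, j] = True
                ts[i, j] = diffs[0] in _TRANSITIONS
                syn[i, j] = CODON_AA[i] == CODON_AA[j]
    return nb, ts, syn


_NB, _TS, _SYN = _neighbour_tables()


def build_rate_matrix(
    kappa: float, omega: float, pi: Optional[np.ndarray] = None
) -> np.ndarray:
    """Scaled 61x61 generator; rows sum to zero, mean rate one per codon."""
    if kappa <= 0 or omega < 0:
        raise ValueError("kappa must be > 0 and omega >= 0")
    n = len(CODONS)
    if pi is None:
        pi = np.full(n, 1.0 / n)
    pi = np.asarray(pi, dtype=float)
    Q = np.where(_NB, 1.0, 0.0)
    Q = Q * np.where(_TS, kappa, 1.0)
    Q = Q * np.where(_SYN, 1.0, omega)
    Q = Q * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -float(pi @ np.diag(Q))
    if scale > 0:
        Q /= scale
    return Q


class CodonRateMatrix:
    """Eigendecomposed reversible codon generator.

    ``transition_matrix(t)`` returns P(t) = exp(Qt) via the symmetric
    decomposition B = D^{1/2} Q D^{-1/2} (D = diag(pi)), which is exact
    for the reversible GY-style chain and much cheaper than a fresh
    matrix exponential per branch length.
    """

    def __init__(self, kappa: float, omega: float, pi: Optional[np.ndarray] = None):
        n = len(CODONS)
        if pi is None:
            pi = np.full(n, 1.0 / n)
        self.pi = np.asarray(pi, dtype=float)
        self.kappa = float(kappa)
        self.omega = float(omega)
        self.Q = build_rate_matrix(kappa, omega, self.pi)
        sq = np.sqrt(self.pi)
        B = (self.Q * sq[:, None]) / sq[None, :]
        B = 0.5 * (B + B.T)  # enforce symmetry against round-off
        w, U = np.linalg.eigh(B)
        self._w = w
        self._left = U / sq[None, :].T  # D^{-1/2} U
        self._right = U.T * sq[None, :]  # U' D^{1/2}

    def transition_matrix(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("negative branch length")
        P = (self._left * np.exp(self._w * t)[None, :]) @ self._right
        np.maximum(P, 0.0, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


def f3x4_frequencies(codon_rows: Sequence[str], pseudocount: float = 0.5) -> np.ndarray:
    """F3x4 codon frequencies from position-specific nucleotide counts.

    A small pseudocount keeps every sense codon at positive frequency so
    the reversible decomposition stays well-conditioned.
    """
    counts = np.full((3, 4), pseudocount)
    base_idx = {b: i for i, b in enumerate("TCAG")}
    for row in codon_rows:
        for k in range(0, len(row) - 2, 3):
            for pos in range(3):
                b = row[k + pos].upper()
                if b in base_idx:
                    counts[pos, base_idx[b]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            freqs[0, base_idx[c[0]]] * freqs[1, base_idx[c[1]]] * freqs[2, base_idx[c[2]]]
            for c in CODONS
        ]
    )
    return pi / pi.sum()
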