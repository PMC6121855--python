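"""Empirical amino-acid substitution model.

A single fixed reversible 20-state model is used everywhere sequences are
simulated or likelihoods are computed. It is derived from the BLOSUM62
matrix shipped with Biopython: BLOSUM62 entries are half-bit log-odds
``B_ij = 2 log2(q_ij / (p_i p_j))``, so target substitution frequencies are
recovered as ``q_ij ∝ p_i p_j 2^(B_ij / 2)`` using the published BLOSUM62
background frequencies. The exchangeability ``s_ij = q_ij / (p_i p_j)``
together with the equilibrium frequencies (marginals of ``q``) defines a
GTR-style rate matrix ``Q``, normalized to one expected substitution per
unit branch length. Site rates are equal; there are no indels.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

from .core import AMINO_ACIDS

N_STATES = 20
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# Background amino-acid frequencies used in the construction of BLOSUM62
# (Henikoff & Henikoff alignment database), keyed by residue.
_BLOSUM62_BACKGROUND = {
    "A": 0.074, "C": 0.025, "D": 0.054, "E": 0.054, "F": 0.047,
    "G": 0.074, "H": 0.026, "I": 0.068, "K": 0.058, "L": 0.099,
    "M": 0.025, "N": 0.045, "P": 0.039, "Q": 0.034, "R": 0.052,
    "S": 0.057, "T": 0.051, "V": 0.073, "W": 0.013, "Y": 0.032,
}


def _build_model() -> tuple[np.ndarray, np.ndarray]:
    """Return (Q, pi): the normalized rate matrix and equilibrium freqs."""
    blosum = substitution_matrices.load("BLOSUM62")
    p = np.array([_BLOSUM62_BACKGROUND[aa] for aa in AMINO_ACIDS])
    p = p / p.sum()
    B = np.empty((N_STATES, N_STATES))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            B[i, j] = blosum[a][b]
    # target frequencies q_ij ∝ p_i p_j 2^(B_ij/2); symmetric by construction
    q = np.outer(p, p) * np.exp2(B / 2.0)
    q = q / q.sum()
    pi = q.sum(axis=1)
    s = q / np.outer(pi, pi)  # exchangeabilities, symmetric
    Q = s * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    # normalize: expected rate -sum_i pi_i Q_ii = 1
    rate = -np.dot(pi, np.diag(Q))
    Q /= rate
    return Q, pi


_Q, _PI = _build_model()


def rate_matrix() -> np.ndarray:
    return _Q.copy()


def stationary_frequencies() -> np.ndarray:
    return _PI.copy()


@lru_cache(maxsize=None)
def _eigensystem() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Symmetric eigendecomposition of the reversible Q for stable expm."""
    pi_sqrt = np.sqrt(_PI)
    # S = D^{1/2} Q D^{-1/2} is symmetric for a reversible Q
    S = (_Q * pi_sqrt[:, None]) / pi_sqrt[None, :]
    S = (S + S.T) / 2.0
    w, U = np.linalg.eigh(S)
    right = U / pi_sqrt[:, None]       # D^{-1/2} U
    left = U.T * pi_sqrt[None, :]      # U^T D^{1/2}
    return w, right, left


def transition_matrix(t: float) -> np.ndarray:
    """P(t) = exp(Q t); rows sum to 1."""
    if t < 0:
        raise ValueError("branch length must be nonnegative")
    w, right, left = _eigensystem()
    P = (right * np.exp(w * t)[None, :]) @ left
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P


def encode(seq: str) -> np.ndarray:
    """Sequence to state indices; gaps/unknowns map to -1 (missing data)."""
    return np.array([AA_INDEX.get(c, -1) for c in seq], dtype=np.int64)


def decode(states: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[s] for s in states)
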