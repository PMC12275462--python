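"""Reversible nucleotide substitution models (GTR/REV family).

The neutral model is a time-reversible 4x4 rate matrix Q, its stationary
base frequencies pi, and a tree with neutral branch lengths.  Q is
unit-normalized (-sum_i pi_i q_ii = 1) so that branch-length scaling
factors are interpretable relative to the neutral substitution rate.

Transition probabilities exp(Q t) are computed from the symmetric
eigendecomposition of D^{1/2} Q D^{-1/2} with D = diag(pi), which is
exact for reversible Q; the decomposition is cached per model so one
factorization serves every branch and scale.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tree import PhyloTree

__all__ = ["NeutralModel", "build_rev", "ALPHABET"]

ALPHABET = "ACGT"
# order of the six exchangeability parameters: AC, AG, AT, CG, CT, GT
_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]


@dataclass
class NeutralModel:
    """Reversible rate matrix + frequencies + neutral tree."""

    Q: np.ndarray
    pi: np.ndarray
    tree: PhyloTree | None = None
    _eig: tuple[np.ndarray, np.ndarray, np.ndarray] = field(
        init=False, repr=False, default=None  # type: ignore[assignment]
    )

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=np.float64)
        self.pi = np.asarray(self.pi, dtype=np.float64)
        if self.Q.shape != (4, 4) or self.pi.shape != (4,):
            raise ValueError("Q must be 4x4 and pi length 4")
        if np.any(self.pi <= 0):
            raise ValueError("frequencies must be positive")
        if abs(self.pi.sum() - 1.0) > 1e-8:
            raise ValueError("frequencies must sum to 1")
        off = self.Q[~np.eye(4, dtype=bool)]
        if np.any(off < -1e-12):
            raise ValueError("off-diagonal rates must be non-negative")
        if np.max(np.abs(self.Q.sum(axis=1))) > 1e-8:
            raise ValueError("rate matrix rows must sum to 0")
        db = self.pi[:, None] * self.Q - (self.pi[:, None] * self.Q).T
        if np.max(np.abs(db)) > 1e-4:
            raise ValueError("rate matrix violates detailed balance")
        self._eig = self._decompose()

    def _decompose(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        sq = np.sqrt(self.pi)
        S = (sq[:, None] * self.Q) / sq[None, :]
        S = 0.5 * (S + S.T)  # symmetrize away roundoff
        w, V = np.linalg.eigh(S)
        left = V / sq[:, None]       # D^{-1/2} V
        right = V.T * sq[None, :]    # V^T D^{1/2}
        return w, left, right

    @property
    def rate(self) -> float:
        """Expected substitutions per site per unit time."""
        return float(-(self.pi * np.diag(self.Q)).sum())

    def transition_matrix(self, t: float, scale: float = 1.0) -> np.ndarray:
        """P = exp(Q * t * scale); rows sum to 1."""
        if t < 0 or scale < 0:
            raise ValueError("t and scale must be non-negative")
        return self.transition_matrices(np.array([t * scale]))[0]

    def transition_matrices(self, ts: np.ndarray) -> np.ndarray:
        """exp(Q t) for a vector of effective branch lengths, shape (k,4,4)."""
        w, left, right = self._eig
        ew = np.exp(np.outer(np.asarray(ts, dtype=np.float64), w))  # (k,4)
        P = np.einsum("ij,kj,jl->kil", left, ew, right)
        np.clip(P, 0.0, 1.0, out=P)
        P /= P.sum(axis=2, keepdims=True)
        return P


def build_rev(exchangeabilities, pi) -> NeutralModel:
    """Build a unit-normalized reversible rate matrix.

    ``exchangeabilities`` are the six symmetric rate multipliers in the
    order AC, AG, AT, CG, CT, GT; ``pi`` the stationary frequencies.
    """
    ex = np.asarray(exchangeabilities, dtype=np.float64)
    pi = np.asarray(pi, dtype=np.float64)
    if ex.shape != (6,):
        raise ValueError("expected 6 exchangeabilities")
    if np.any(ex < 0) or not np.any(ex > 0):
        raise ValueError("exchangeabilities must be non-negative, not all zero")
    if np.any(pi <= 0):
        raise ValueError("frequencies must be positive")
    if abs(pi.sum() - 1.0) > 1e-8:
        raise ValueError("frequencies must sum to 1")
    Q = np.zeros((4, 4))
    for r, (i, j) in zip(ex, _PAIRS):
        Q[i, j] = r * pi[j]
        Q[j, i] = r * pi[i]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(pi * np.diag(Q)).sum()
    return NeutralModel(Q / mu, pi)
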