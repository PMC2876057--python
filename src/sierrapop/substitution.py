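"""Nucleotide substitution models (HKY85, TN93) as rate matrices.

State order is A, C, G, T.  Rate matrices are scaled so the expected number
of substitutions per site per unit time equals one, so branch lengths are in
substitutions/site.  Transition probabilities are computed through a
symmetric eigendecomposition (both models are time-reversible), which is
numerically stable and lets a whole vector of branch lengths be evaluated in
one shot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: default base frequencies, typical of an AT-rich teleost control region
DEFAULT_FREQS = np.array([0.32, 0.21, 0.14, 0.33])


def hky_rate_matrix(kappa: float, freqs: np.ndarray | None = None) -> np.ndarray:
    """HKY85 rate matrix (transitions weighted ``kappa``), mean rate 1."""
    return tn93_rate_matrix(kappa, kappa, freqs)


def tn93_rate_matrix(kappa_R: float, kappa_Y: float,
                     freqs: np.ndarray | None = None) -> np.ndarray:
    """Tamura–Nei rate matrix with separate purine/pyrimidine transition rates."""
    pi = DEFAULT_FREQS if freqs is None else np.asarray(freqs, dtype=float)
    if pi.shape != (4,) or abs(pi.sum() - 1) > 1e-8 or np.any(pi <= 0):
        raise ValueError("freqs must be 4 positive values summing to 1")
    Q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            if {i, j} == {0, 2}:        # A<->G purine transition
                Q[i, j] = kappa_R * pi[j]
            elif {i, j} == {1, 3}:      # C<->T pyrimidine transition
                Q[i, j] = kappa_Y * pi[j]
            else:
                Q[i, j] = pi[j]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -np.sum(pi * np.diag(Q))       # expected rate under stationarity
    return Q / mu


@dataclass
class SubstitutionModel:
    """A reversible model with precomputed spectral decomposition."""

    Q: np.ndarray
    freqs: np.ndarray

    def __post_init__(self) -> None:
        pi = self.freqs
        rt = np.sqrt(pi)
        S = (rt[:, None] * self.Q) / rt[None, :]   # symmetric similarity
        w, U = np.linalg.eigh((S + S.T) / 2.0)
        self._w = w
        self._left = U.T * rt[None, :]             # U^T D^{1/2}
        self._right = U / rt[:, None]              # D^{-1/2} U
        # P(t) = right @ diag(exp(w t)) @ left

    @classmethod
    def hky(cls, kappa: float, freqs: np.ndarray | None = None) -> "SubstitutionModel":
        pi = DEFAULT_FREQS if freqs is None else np.asarray(freqs, dtype=float)
        return cls(hky_rate_matrix(kappa, pi), pi)

    @classmethod
    def tn93(cls, kappa_R: float, kappa_Y: float,
             freqs: np.ndarray | None = None) -> "SubstitutionModel":
        pi = DEFAULT_FREQS if freqs is None else np.asarray(freqs, dtype=float)
        return cls(tn93_rate_matrix(kappa_R, kappa_Y, pi), pi)

    def transition_probabilities(self, t: np.ndarray | float) -> np.ndarray:
        """P(t) for scalar or vector ``t``; shape (..., 4, 4)."""
        t = np.asarray(t, dtype=float)
        expwt = np.exp(np.multiply.outer(t, self._w))          # (..., 4)
        P = np.einsum("ik,...k,kj->...ij", self._right, expwt, self._left)
        return np.clip(P, 0.0, None)
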