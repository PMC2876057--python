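"""Pairwise Tamura–Nei distances and molecular-diversity statistics.

Distances follow the Tamura–Nei (1993) estimator with optional gamma
rate-heterogeneity correction (the field's standard for control-region
data, here defaulting to shape 0.4).  Diversity statistics are the classic
Nei (1987) estimators: unbiased haplotype diversity h with its sampling SD,
mean pairwise raw differences k, and per-site nucleotide diversity π with
its (stochastic + sampling) SD.  π and k deliberately use *raw* differences
with pairwise deletion, so π·L = k holds on gap-free data; the TN93+Γ model
is reserved for the Φ-statistics and trees.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .sequences import Alignment, collapse_haplotypes

__all__ = [
    "DistanceMatrix", "DiversitySummary", "tn93_distance_matrix",
    "raw_difference_matrix", "p_distance_matrix", "diversity_summary",
    "diversity_table",
]


class SaturationError(ValueError):
    """A sequence pair is too diverged for the distance formula."""


class OverlapError(ValueError):
    """A sequence pair shares no unambiguous sites."""


class SampleSizeError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray
    model: str

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        assert d.shape == (len(self.labels), len(self.labels))
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0.0)
        self.d = d

    def submatrix(self, labels: Iterable[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(labels=list(labels),
                              d=self.d[np.ix_(idx, idx)], model=self.model)

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for lab, row in zip(self.labels, self.d):
                fh.write(lab[:10].ljust(12)
                         + " ".join(f"{x:.6f}" for x in row) + "\n")


@dataclass
class DiversitySummary:
    population: str
    n: int
    nh: int
    h: float
    h_sd: float
    pi: float
    pi_sd: float
    k: float
    S: int


# ---------------------------------------------------------------------------
# Pairwise counts
# ---------------------------------------------------------------------------

def _pair_counts(mat: np.ndarray):
    """Vectorised pairwise difference / overlap counts over an int8 matrix."""
    n = mat.shape[0]
    valid = mat >= 0
    diff = np.zeros((n, n))
    overlap = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid[i + 1:]
        overlap[i, i + 1:] = both.sum(axis=1)
        diff[i, i + 1:] = ((mat[i] != mat[i + 1:]) & both).sum(axis=1)
    diff += diff.T
    overlap += overlap.T
    np.fill_diagonal(overlap, mat.shape[1])
    return diff, overlap


def raw_difference_matrix(aln: Alignment) -> DistanceMatrix:
    diff, _ = _pair_counts(aln.matrix())
    return DistanceMatrix(labels=aln.ids, d=diff, model="raw_differences")


def p_distance_matrix(aln: Alignment) -> DistanceMatrix:
    diff, overlap = _pair_counts(aln.matrix())
    if np.any(overlap == 0):
        raise OverlapError("a sequence pair has zero unambiguous overlap")
    d = np.where(overlap > 0, diff / np.maximum(overlap, 1), 0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=aln.ids, d=d, model="p_distance")


# ---------------------------------------------------------------------------
# Tamura–Nei (1993)
# ---------------------------------------------------------------------------

def _tn93_pair(x: np.ndarray, y: np.ndarray, alpha: float | None,
               freqs: np.ndarray | None) -> float:
    both = (x >= 0) & (y >= 0)
    L = int(both.sum())
    if L == 0:
        raise OverlapError("zero pairwise overlap")
    xs, ys = x[both], y[both]
    if freqs is None:
        counts = np.bincount(xs, minlength=4) + np.bincount(ys, minlength=4)
        pi = counts / counts.sum()
    else:
        pi = freqs
    pi = np.maximum(pi, 1e-12)
    gA, gC, gG, gT = pi
    gR, gY = gA + gG, gC + gT
    neq = xs != ys
    sets = xs[neq] + ys[neq] * 4
    P1 = np.isin(sets, [0 + 2 * 4, 2 + 0 * 4]).sum() / L      # A<->G
    P2 = np.isin(sets, [1 + 3 * 4, 3 + 1 * 4]).sum() / L      # C<->T
    Q = neq.sum() / L - P1 - P2                               # transversions

    k1 = 2.0 * gA * gG / gR
    k2 = 2.0 * gT * gC / gY
    k3 = 2.0 * (gR * gY - gA * gG * gY / gR - gT * gC * gR / gY)
    w1 = 1.0 - P1 / k1 - Q / (2.0 * gR)
    w2 = 1.0 - P2 / k2 - Q / (2.0 * gY)
    w3 = 1.0 - Q / (2.0 * gR * gY)
    if min(w1, w2, w3) <= 0:
        raise SaturationError("saturated pair (log argument non-positive)")
    if alpha is None:
        return float(-k1 * np.log(w1) - k2 * np.log(w2) - k3 * np.log(w3))
    a = alpha
    return float(k1 * a * (w1 ** (-1.0 / a) - 1.0)
                 + k2 * a * (w2 ** (-1.0 / a) - 1.0)
                 + k3 * a * (w3 ** (-1.0 / a) - 1.0))


def tn93_distance_matrix(aln: Alignment, gamma_alpha: float | None = 0.4,
                         *, pooled_freqs: bool = False) -> DistanceMatrix:
    """TN93 (optionally gamma-corrected) distances among all sequences.

    Base frequencies are estimated from each pair (the classic pairwise
    estimator); set ``pooled_freqs=True`` to use whole-alignment frequencies.
    Raises :class:`SaturationError` naming the pair when the correction is
    undefined.
    """
    if len(aln) < 2:
        raise SampleSizeError("need at least two sequences")
    mat = aln.matrix()
    n = len(aln)
    freqs = None
    if pooled_freqs:
        counts = np.bincount(mat[mat >= 0], minlength=4)
        freqs = counts / counts.sum()
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d[i, j] = d[j, i] = _tn93_pair(mat[i], mat[j], gamma_alpha, freqs)
            except SaturationError as err:
                raise SaturationError(
                    f"pair ({aln.ids[i]}, {aln.ids[j]}): {err}") from None
    model = "TN93" if gamma_alpha is None else f"TN93_gamma({gamma_alpha})"
    return DistanceMatrix(labels=aln.ids, d=d, model=model)


# ---------------------------------------------------------------------------
# Diversity statistics
# ---------------------------------------------------------------------------

def diversity_summary(aln: Alignment, population: str | None = None
                      ) -> DiversitySummary:
    """Nei (1987) diversity estimators for one population sample."""
    sub = aln if population is None else aln.subset([population])
    n = len(sub)
    if n < 2:
        raise SampleSizeError(f"population {population!r}: need n >= 2, got {n}")

    spec = collapse_haplotypes(sub)
    p = np.array(spec.counts) / n
    sum2, sum3 = float(np.sum(p ** 2)), float(np.sum(p ** 3))
    h = haplotype_diversity_from_counts(spec.counts)
    # Nei (1987) eq. 8.12 sampling variance of h
    var_h = (2.0 / (n * (n - 1.0))
             * (2.0 * (n - 2.0) * (sum3 - sum2 ** 2) + sum2 - sum2 ** 2))
    h_sd = float(np.sqrt(max(var_h, 0.0)))

    mat = sub.matrix()
    diff, overlap = _pair_counts(mat)
    iu = np.triu_indices(n, 1)
    if np.any(overlap[iu] == 0):
        raise OverlapError("a pair has zero unambiguous overlap")
    k = float(diff[iu].mean())
    pi = float((diff[iu] / overlap[iu]).mean())
    # Nei (1987) eq. 10.7 total variance of pi (sampling + stochastic)
    var_pi = ((n + 1.0) / (3.0 * (n - 1.0)) * pi / aln.length
              + 2.0 * (n ** 2 + n + 3.0) / (9.0 * n * (n - 1.0)) * pi ** 2)
    pi_sd = float(np.sqrt(max(var_pi, 0.0)))

    col_valid = mat >= 0
    S = 0
    for j in range(sub.length):
        col = mat[col_valid[:, j], j]
        if np.unique(col).size >= 2:
            S += 1
    return DiversitySummary(population=population or "all", n=n, nh=spec.nh,
                            h=h, h_sd=h_sd, pi=pi, pi_sd=pi_sd, k=k, S=S)


def haplotype_diversity_from_counts(counts: Iterable[int]) -> float:
    """Unbiased h = n/(n−1)·(1 − Σ p_i²) straight from a haplotype spectrum."""
    c = np.asarray(list(counts), dtype=float)
    n = c.sum()
    if n < 2:
        raise SampleSizeError("need n >= 2")
    # (n² − Σc²)/(n(n−1)): algebraically identical, exact for all-unique
    return float((n * n - np.sum(c ** 2)) / (n * (n - 1.0)))


def diversity_table(aln: Alignment) -> pd.DataFrame:
    """Per-population diversity block in the classic per-population layout."""
    rows = []
    for pop in aln.populations:
        s = diversity_summary(aln, pop)
        rows.append({"population": pop, "n": s.n, "nh": s.nh,
                     "h": round(s.h, 3), "h_sd": round(s.h_sd, 4),
                     "pi": round(s.pi, 5), "pi_sd": round(s.pi_sd, 5),
                     "k": round(s.k, 3), "S": s.S})
    return pd.DataFrame(rows)
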