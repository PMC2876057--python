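"""Historical demography: mismatch distributions, expansion fits, Fu's Fs,
and molecular-clock unit conversions.

The sudden (demographic) expansion model is the Rogers–Harpending model: a
population at mutation-scaled size θ0 grows instantaneously to θ1 at
mutational time τ = 2uT before the present.  The expected distribution of
pairwise differences is

    F_j(τ, θ0, θ1) = F̂_j(θ1)
        + exp(−τ(θ1+1)/θ1) · Σ_{i≤j} (τ^i / i!) · [F̂_{j−i}(θ0) − F̂_{j−i}(θ1)]

with F̂_j(θ) = θ^j/(θ+1)^{j+1} the equilibrium geometric.  The spatial
(range) expansion model is the continent-island analogue: a deme of size θ
exchanging migrants at scaled rate M with an effectively infinite pool of
demes, all descended from a single deme of the same size at time τ; its
expected mismatch follows in closed form from the coalescence-time density
(incomplete-gamma terms, see :func:`expected_mismatch_spatial`).

Both models are fitted by least squares on mismatch *frequencies*; the SSD
goodness-of-fit p-value and the 95% CI of τ come from a parametric
bootstrap (coalescent simulation under the fitted model, refitting each
replicate).  Fu's Fs uses the Ewens sampling distribution of the number of
haplotypes, computed exactly from unsigned Stirling numbers of the first
kind.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammainc, gammaincc, gammaln

from .sequences import Alignment, collapse_haplotypes
from .diversity import _pair_counts

__all__ = [
    "RateModel", "MismatchHistogram", "DemographicFit", "SpatialFit",
    "FuResult", "mismatch_histogram", "expected_mismatch_sudden",
    "expected_mismatch_spatial", "fit_demographic_expansion",
    "fit_spatial_expansion", "histogram_from_diff_matrix",
    "fu_fs", "fu_fs_from_summary", "ewens_k_pmf",
    "tau_to_time", "theta_to_N", "census_from_catch",
]

PARAM_CAP = 99_999.0


class SizeError(ValueError):
    pass


class RateError(ValueError):
    pass


@dataclass(frozen=True)
class RateModel:
    """Molecular-clock rate model.

    Defaults follow the control-region calibration used for the mackerel
    analysis: 3.6% per site per Myr (3.6e-8 /site/year), 648 sites, and a
    2-year generation time.  ``u`` is the per-sequence per-generation rate,
    u = L · rate · generation_years; with θ = 2Nu and τ = 2uT these defaults
    convert τ = 13.4 to 287.2 ky and θ = 255.3 to N ≈ 2.7 × 10⁶.
    """

    rate_per_site_per_year: float = 3.6e-8
    L: int = 648
    generation_years: float = 2.0

    def __post_init__(self) -> None:
        if (self.rate_per_site_per_year <= 0 or self.L <= 0
                or self.generation_years <= 0):
            raise RateError("all rate-model fields must be positive")

    @property
    def u(self) -> float:
        """Mutation rate per sequence per generation."""
        return self.L * self.rate_per_site_per_year * self.generation_years


def tau_to_time(tau: float, rm: RateModel = RateModel()
                ) -> tuple[float, float, float]:
    """Convert mutational expansion time τ (= 2uT) to (generations, years, ky)."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    generations = tau / (2.0 * rm.u)
    years = generations * rm.generation_years
    return generations, years, years / 1000.0


def theta_to_N(theta: float, rm: RateModel = RateModel()) -> float:
    """Effective female count N = θ/(2u)."""
    if theta < 0:
        raise ValueError("theta must be >= 0")
    return theta / (2.0 * rm.u)


def census_from_catch(catch_tonnes: float, mean_weight_g: float) -> float:
    """Harvested individuals = catch (g) / mean individual weight (g)."""
    if catch_tonnes <= 0 or mean_weight_g <= 0:
        raise ValueError("inputs must be positive")
    return catch_tonnes * 1.0e6 / mean_weight_g


# ---------------------------------------------------------------------------
# Mismatch histogram
# ---------------------------------------------------------------------------

@dataclass
class MismatchHistogram:
    counts: np.ndarray          # pairs per integer difference class 0..max
    n: int                      # sample size
    n_pairs: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        assert abs(self.counts.sum() - self.n_pairs) < 1e-9

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.n_pairs

    @property
    def mean(self) -> float:
        return float(np.arange(len(self.counts)) @ self.frequencies)


def mismatch_histogram(aln: Alignment, population: str | None = None
                       ) -> MismatchHistogram:
    """Histogram of raw pairwise differences (pairwise deletion)."""
    sub = aln if population is None else aln.subset([population])
    n = len(sub)
    if n < 3:
        raise SizeError(f"need n >= 3, got {n}")
    diff, _ = _pair_counts(sub.matrix())
    iu = np.triu_indices(n, 1)
    d = np.rint(diff[iu]).astype(int)
    counts = np.bincount(d)
    return MismatchHistogram(counts=counts, n=n, n_pairs=len(d))


def histogram_from_diff_matrix(diff: np.ndarray) -> MismatchHistogram:
    n = diff.shape[0]
    iu = np.triu_indices(n, 1)
    d = np.rint(diff[iu]).astype(int)
    return MismatchHistogram(counts=np.bincount(d), n=n, n_pairs=len(d))


# ---------------------------------------------------------------------------
# Expected mismatch curves
# ---------------------------------------------------------------------------

def _geometric(j: np.ndarray, theta: float) -> np.ndarray:
    """Equilibrium mismatch F̂_j(θ) = θ^j/(θ+1)^{j+1}, stable for large θ."""
    j = np.asarray(j, dtype=float)
    if theta <= 0:
        return np.where(j == 0, 1.0, 0.0)
    return np.exp(j * math.log(theta) - (j + 1.0) * math.log(theta + 1.0))


def expected_mismatch_sudden(n_classes: int, tau: float, theta0: float,
                             theta1: float) -> np.ndarray:
    """Rogers–Harpending expected mismatch frequencies for classes 0..n_classes-1."""
    j = np.arange(n_classes)
    g1 = _geometric(j, theta1)
    g0 = _geometric(j, theta0)
    if tau <= 0:
        return g0
    logpois = j * math.log(tau) - gammaln(j + 1.0)
    pois = np.exp(logpois)
    conv = np.convolve(pois, g0 - g1)[:n_classes]
    decay = math.exp(-tau * (theta1 + 1.0) / theta1) if theta1 > 0 else 0.0
    return g1 + decay * conv


def expected_mismatch_spatial(n_classes: int, tau: float, theta: float,
                              M: float) -> np.ndarray:
    """Continent-island (range-expansion) expected mismatch frequencies.

    Two lineages sampled in one deme either coalesce locally (rate 1/θ per
    mutational time unit) or are separated by migration (rate M/θ for the
    pair) and then only coalesce in the single ancestral deme beyond τ:

        F_j = (1/θ) c1^{-(j+1)} P(j+1, c1 τ)
            + S · (1/θ) e^{τ/θ} c2^{-(j+1)} Q(j+1, c2 τ)

    with c1 = 1 + (1+M)/θ, c2 = 1 + 1/θ, P/Q the regularised incomplete
    gamma functions, and S the probability of reaching τ uncoalesced:
    S = e^{−(1+M)τ/θ} + M/(1+M) · (1 − e^{−(1+M)τ/θ}).
    """
    j = np.arange(n_classes, dtype=float)
    if theta <= 0:
        # instantaneous local coalescence: everything collapses to class 0
        # unless separated; degenerate limit handled by a tiny theta
        theta = 1e-9
    c1 = 1.0 + (1.0 + M) / theta
    c2 = 1.0 + 1.0 / theta
    esc = math.exp(-(1.0 + M) * tau / theta)
    S = esc + (M / (1.0 + M)) * (1.0 - esc) if M > 0 else esc
    term1 = (1.0 / theta) * np.exp(-(j + 1.0) * math.log(c1)) \
        * gammainc(j + 1.0, c1 * tau)
    with np.errstate(divide="ignore"):
        log_q = np.log(gammaincc(j + 1.0, c2 * tau))
    log2 = (tau / theta) - (j + 1.0) * np.log(c2) + log_q
    term2 = (S / theta) * np.exp(log2)
    return term1 + term2


# ---------------------------------------------------------------------------
# Least-squares fitting
# ---------------------------------------------------------------------------

@dataclass
class DemographicFit:
    tau: float
    theta0: float
    theta1: float
    ssd: float
    p_ssd: float | None = None
    tau_ci95: tuple[float, float] | None = None
    time_ci95_ky: tuple[float, float] | None = None
    boundary_flags: list[str] = field(default_factory=list)
    model: str = "sudden_expansion"


@dataclass
class SpatialFit:
    tau: float
    theta: float
    M: float
    m: float
    ssd: float
    p_ssd: float | None = None
    tau_ci95: tuple[float, float] | None = None
    time_ci95_ky: tuple[float, float] | None = None
    boundary_flags: list[str] = field(default_factory=list)
    model: str = "spatial_expansion"


def _ssd(obs: np.ndarray, expected: np.ndarray) -> float:
    return float(np.sum((obs - expected) ** 2))


def _sudden_tau_grid(n_classes: int, taus: np.ndarray, theta0: float,
                     theta1: float) -> np.ndarray:
    """Expected sudden-expansion curves for a whole vector of τ, shape (T, C)."""
    j = np.arange(n_classes)
    g1 = _geometric(j, theta1)
    g0 = _geometric(j, theta0)
    taus = np.asarray(taus, dtype=float)
    safe = np.maximum(taus[:, None], 1e-300)
    logpois = j[None, :] * np.log(safe) - gammaln(j + 1.0)[None, :]
    pois = np.exp(logpois)
    pois[taus == 0] = 0.0
    pois[taus == 0, 0] = 1.0
    G = np.zeros((n_classes, n_classes))
    diff = g0 - g1
    for off in range(n_classes):                 # lower-triangular Toeplitz
        G[off:, off] = diff[:n_classes - off][: n_classes - off]
    conv = pois @ G.T
    decay = np.exp(-taus * (theta1 + 1.0) / theta1) if theta1 > 0 else np.zeros_like(taus)
    return g1[None, :] + decay[:, None] * conv


def _fit_sudden_core(obs: np.ndarray) -> tuple[float, float, float, float]:
    n_classes = len(obs)
    mean = float(np.arange(n_classes) @ obs)
    taus = np.linspace(0.0, max(2.0 * mean, 4.0), 31)
    theta0s = np.concatenate([[0.0], np.geomspace(0.05, max(mean, 1.0), 8)])
    theta1s = np.geomspace(max(mean, 1.0), PARAM_CAP, 8)
    best = (np.inf, 0.0, 0.0, theta1s[0])
    for t1 in theta1s:
        for t0 in theta0s:
            curves = _sudden_tau_grid(n_classes, taus, t0, t1)
            ssds = np.sum((curves - obs[None, :]) ** 2, axis=1)
            i = int(np.argmin(ssds))
            if ssds[i] < best[0]:
                best = (float(ssds[i]), float(taus[i]), t0, t1)

    def objective(x):
        tv, t0, t1 = x
        if tv < 0 or t0 < 0 or t1 <= 0 or t1 > PARAM_CAP or t0 > t1:
            return 1e6
        return _ssd(obs, expected_mismatch_sudden(n_classes, tv, t0, t1))

    res = minimize(objective, x0=[best[1], best[2], best[3]],
                   method="Nelder-Mead",
                   options={"xatol": 1e-3, "fatol": 1e-12, "maxiter": 300})
    if res.fun <= best[0]:
        tau, t0, t1 = (max(res.x[0], 0.0), max(res.x[1], 0.0),
                       min(max(res.x[2], 1e-6), PARAM_CAP))
        return float(res.fun), float(tau), float(t0), float(t1)
    return best


def _spatial_tau_grid(n_classes: int, taus: np.ndarray, theta: float,
                      M: float) -> np.ndarray:
    """Expected spatial-expansion curves for a vector of τ, shape (T, C)."""
    j = np.arange(n_classes, dtype=float)
    taus = np.asarray(taus, dtype=float)
    theta = max(theta, 1e-9)
    c1 = 1.0 + (1.0 + M) / theta
    c2 = 1.0 + 1.0 / theta
    esc = np.exp(-(1.0 + M) * taus / theta)
    S = esc + (M / (1.0 + M)) * (1.0 - esc) if M > 0 else esc
    jp1 = j + 1.0
    term1 = (1.0 / theta) * np.exp(-jp1 * math.log(c1))[None, :] \
        * gammainc(jp1[None, :], c1 * taus[:, None])
    with np.errstate(divide="ignore"):
        log_q = np.log(gammaincc(jp1[None, :], c2 * taus[:, None]))
    log2 = (taus[:, None] / theta) - jp1[None, :] * math.log(c2) + log_q
    term2 = (S[:, None] / theta) * np.exp(log2)
    return term1 + term2


def _fit_spatial_core(obs: np.ndarray) -> tuple[float, float, float, float]:
    n_classes = len(obs)
    mean = float(np.arange(n_classes) @ obs)
    taus = np.linspace(0.0, max(2.0 * mean, 4.0), 31)
    thetas = np.concatenate([[1e-3], np.geomspace(0.05, max(2.0 * mean, 1.0), 8)])
    Ms = np.geomspace(0.1, PARAM_CAP, 10)
    best = (np.inf, 0.0, thetas[1], Ms[0])
    for M in Ms:
        for th in thetas:
            curves = _spatial_tau_grid(n_classes, taus, th, M)
            ssds = np.sum((curves - obs[None, :]) ** 2, axis=1)
            i = int(np.argmin(ssds))
            if ssds[i] < best[0]:
                best = (float(ssds[i]), float(taus[i]), th, M)

    def objective(x):
        tv, th, M = x
        if tv < 0 or th <= 0 or M < 0 or M > PARAM_CAP:
            return 1e6
        return _ssd(obs, expected_mismatch_spatial(n_classes, tv, th, M))

    res = minimize(objective, x0=[best[1], best[2], best[3]],
                   method="Nelder-Mead",
                   options={"xatol": 1e-3, "fatol": 1e-12, "maxiter": 300})
    if res.fun <= best[0]:
        return (float(res.fun), float(max(res.x[0], 0.0)),
                float(max(res.x[1], 1e-9)), float(np.clip(res.x[2], 0.0, PARAM_CAP)))
    return best


def fit_demographic_expansion(hist: MismatchHistogram, n_boot: int = 1000,
                              seed: int = 0,
                              rm: RateModel = RateModel()) -> DemographicFit:
    """Least-squares Rogers–Harpending fit with parametric-bootstrap SSD test.

    The bootstrap simulates coalescent samples (infinite sites) under the
    fitted expansion, refits each, and reports p = P(SSD* ≥ SSD_obs) plus
    the 2.5–97.5 percentile interval of the refitted τ (also in ky).
    Parameters pinned at the 99 999 cap are flagged, not errors.
    """
    obs = hist.frequencies
    ssd, tau, t0, t1 = _fit_sudden_core(obs)
    flags = []
    if t1 >= PARAM_CAP * (1 - 1e-6):
        flags.append("theta1_at_cap")
    if tau <= 1e-9:
        flags.append("tau_at_zero")
    fit = DemographicFit(tau=tau, theta0=t0, theta1=t1, ssd=ssd,
                         boundary_flags=flags)
    if n_boot > 0:
        from .simulate import Scenario, simulate_pairwise_differences
        rng = np.random.default_rng(seed)
        ssds, taus = [], []
        for _ in range(n_boot):
            sc = Scenario(kind="sudden_expansion", n=hist.n,
                          tau=max(tau, 1e-6), theta0=t0,
                          theta1=max(t1, 1e-3), seed=0)
            diff = simulate_pairwise_differences(sc, rng)
            h_b = histogram_from_diff_matrix(diff)
            s_b, tau_b, *_ = _fit_sudden_core(h_b.frequencies)
            ssds.append(s_b)
            taus.append(tau_b)
        fit.p_ssd = float(np.mean(np.asarray(ssds) >= ssd))
        lo, hi = np.percentile(taus, [2.5, 97.5])
        fit.tau_ci95 = (float(lo), float(hi))
        fit.time_ci95_ky = (tau_to_time(lo, rm)[2], tau_to_time(hi, rm)[2])
    return fit


def fit_spatial_expansion(hist: MismatchHistogram, n_boot: int = 1000,
                          seed: int = 0,
                          rm: RateModel = RateModel()) -> SpatialFit:
    """Least-squares continent-island (range expansion) fit; see
    :func:`fit_demographic_expansion` for the bootstrap conventions."""
    obs = hist.frequencies
    ssd, tau, theta, M = _fit_spatial_core(obs)
    flags = []
    if M >= PARAM_CAP * (1 - 1e-6):
        flags.append("M_at_cap")
    if tau <= 1e-9:
        flags.append("tau_at_zero")
    m = M * rm.u / theta if theta > 0 else math.inf
    fit = SpatialFit(tau=tau, theta=theta, M=M, m=m, ssd=ssd,
                     boundary_flags=flags)
    if n_boot > 0:
        from .simulate import Scenario, simulate_pairwise_differences
        rng = np.random.default_rng(seed)
        ssds, taus = [], []
        for _ in range(n_boot):
            # bootstrap from the continent-island model itself (exact and
            # cheap even at the M cap)
            sc = Scenario(kind="continent_island", n=hist.n,
                          tau=max(tau, 1e-6), theta=max(theta, 1e-3),
                          M=max(M, 1e-3), seed=0)
            diff = simulate_pairwise_differences(sc, rng)
            h_b = histogram_from_diff_matrix(diff)
            s_b, tau_b, *_ = _fit_spatial_core(h_b.frequencies)
            ssds.append(s_b)
            taus.append(tau_b)
        fit.p_ssd = float(np.mean(np.asarray(ssds) >= ssd))
        lo, hi = np.percentile(taus, [2.5, 97.5])
        fit.tau_ci95 = (float(lo), float(hi))
        fit.time_ci95_ky = (tau_to_time(lo, rm)[2], tau_to_time(hi, rm)[2])
    return fit


# ---------------------------------------------------------------------------
# Fu's Fs
# ---------------------------------------------------------------------------

@dataclass
class FuResult:
    fs: float
    p: float | None
    k_hat: float
    nh_obs: int
    s_prime: float
    flagged: str | None = None


@lru_cache(maxsize=64)
def _stirling_row(n: int) -> tuple[int, ...]:
    """Unsigned Stirling numbers of the first kind |s(n, k)| for k = 0..n."""
    row = [0, 1]
    for m in range(2, n + 1):
        new = [0] * (m + 1)
        for k in range(1, m + 1):
            new[k] = row[k - 1] + (m - 1) * (row[k] if k < len(row) else 0)
        row = new
    if n == 1:
        row = [0, 1]
    return tuple(row)


def ewens_k_pmf(n: int, theta: float) -> np.ndarray:
    """P(K = k | θ, n) for k = 0..n under the Ewens sampling distribution,
    computed exactly in log space from Stirling numbers."""
    if n < 1:
        raise SizeError("n must be >= 1")
    if theta <= 0:
        out = np.zeros(n + 1)
        out[1] = 1.0
        return out
    row = _stirling_row(n)
    log_rising = sum(math.log(theta + i) for i in range(n))
    logs = np.full(n + 1, -np.inf)
    for k in range(1, n + 1):
        if row[k] > 0:
            logs[k] = math.log(row[k]) + k * math.log(theta) - log_rising
    return np.exp(logs)


def fu_fs_from_summary(n: int, nh_obs: int, k_hat: float) -> FuResult:
    """Fu's Fs from (n, observed haplotype count, mean pairwise differences).

    S′ = P(K ≥ nh_obs | θ̂ = k̂, n); Fs = ln(S′/(1−S′)).  Degenerate spectra
    (S′ numerically 0 or 1, e.g. a monomorphic sample) are flagged and give
    ±inf.
    """
    pmf = ewens_k_pmf(n, k_hat)
    s_prime = float(pmf[nh_obs:].sum())
    if s_prime >= 1.0 - 1e-15:
        return FuResult(fs=math.inf, p=None, k_hat=k_hat, nh_obs=nh_obs,
                        s_prime=1.0, flagged="s_prime_one")
    if s_prime <= 1e-300:
        return FuResult(fs=-math.inf, p=None, k_hat=k_hat, nh_obs=nh_obs,
                        s_prime=0.0, flagged="s_prime_zero")
    fs = math.log(s_prime / (1.0 - s_prime))
    return FuResult(fs=fs, p=None, k_hat=k_hat, nh_obs=nh_obs,
                    s_prime=s_prime)


def fu_fs(aln: Alignment, population: str | None = None, n_sim: int = 1000,
          seed: int = 0) -> FuResult:
    """Fu's Fs for one population with a simulation p-value.

    p is the fraction of n_sim neutral constant-size coalescent samples
    (θ = k̂, infinite sites) whose Fs is ≤ the observed Fs.
    """
    sub = aln if population is None else aln.subset([population])
    n = len(sub)
    if n < 4:
        raise SizeError(f"need n >= 4, got {n}")
    spec = collapse_haplotypes(sub)
    diff, _ = _pair_counts(sub.matrix())
    iu = np.triu_indices(n, 1)
    k_hat = float(diff[iu].mean())
    res = fu_fs_from_summary(n, spec.nh, k_hat)
    if n_sim > 0 and math.isfinite(res.fs):
        from .simulate import Scenario, simulate_pairwise_differences
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_sim):
            d = simulate_pairwise_differences(
                Scenario(kind="constant", theta=max(k_hat, 1e-6), n=n, seed=0), rng)
            k_s = float(d[iu].mean())
            nh_s = _nh_from_diff(d)
            r = fu_fs_from_summary(n, nh_s, k_s)
            if r.fs <= res.fs:
                count += 1
        res.p = count / n_sim
    return res


def _nh_from_diff(diff: np.ndarray) -> int:
    """Number of distinct haplotypes from a zero/nonzero difference matrix."""
    n = diff.shape[0]
    same = diff == 0
    seen = np.zeros(n, dtype=bool)
    nh = 0
    for i in range(n):
        if not seen[i]:
            nh += 1
            seen |= same[i]
    return nh
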