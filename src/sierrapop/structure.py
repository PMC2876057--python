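"""Population structure: Φ-statistics, AMOVA, pooling, trees, isolation by distance.

Φ_ST is the molecular analogue of F_ST obtained from an analysis of
molecular variance (AMOVA) on squared inter-haplotype distances; p-values
come from permutation nulls with the +1 correction so p is never exactly
zero.  The module also provides the hierarchical (group / population /
individual) AMOVA, the temporal-replicate pooling rule, Slatkin's
linearisation Φ/(1−Φ) with a UPGMA population tree, a Mantel test of
isolation by distance on migrant estimates M = (1−Φ)/(2Φ), and Bonferroni
correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage

from .diversity import DistanceMatrix

__all__ = [
    "PhiResult", "AmovaResult", "IbdResult", "pairwise_phi_st",
    "pairwise_phi_matrix", "hierarchical_amova", "pool_temporal_samples",
    "slatkin_linearize", "slatkin_upgma", "mantel_ibd", "bonferroni",
    "significance_stars",
]

DEFAULT_PERMUTATIONS = 20100


class SizeError(ValueError):
    pass


class HierarchyError(ValueError):
    pass


class ParameterError(ValueError):
    pass


class InfiniteDistanceError(ValueError):
    pass


@dataclass
class PhiResult:
    pair: tuple[str, str]
    phi_st: float
    p: float
    n_perm: int


@dataclass
class AmovaResult:
    phi_ct: float
    phi_sc: float
    phi_st: float
    var_among_groups: float
    var_among_pops: float
    var_within: float
    p_ct: float
    p_sc: float
    p_st: float
    n_perm: int

    @property
    def total_variance(self) -> float:
        return self.var_among_groups + self.var_among_pops + self.var_within


@dataclass
class IbdResult:
    r: float
    r2: float
    p: float
    n_perm: int
    migrants: pd.DataFrame = field(repr=False)
    excluded_pairs: list[tuple[str, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Two-level AMOVA / pairwise Phi_ST
# ---------------------------------------------------------------------------

def _phi_from_groups(dsq: np.ndarray, groups: np.ndarray) -> float:
    """Φ_ST from squared distances and an integer group labelling."""
    N = len(groups)
    labels = np.unique(groups)
    ss_total = dsq.sum() / (2.0 * N)
    ss_within = 0.0
    sizes = []
    for g in labels:
        idx = np.nonzero(groups == g)[0]
        sizes.append(len(idx))
        ss_within += dsq[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    sizes = np.array(sizes, dtype=float)
    G = len(labels)
    df_a, df_w = G - 1, N - G
    if df_w <= 0:
        return 0.0
    ms_within = ss_within / df_w
    ms_among = (ss_total - ss_within) / df_a
    n_prime = (N - np.sum(sizes ** 2) / N) / df_a
    sigma_a = (ms_among - ms_within) / n_prime
    total = sigma_a + ms_within
    return float(sigma_a / total) if total > 0 else 0.0


def pairwise_phi_st(dm: DistanceMatrix, pops: dict[str, list[str]],
                    pair: tuple[str, str],
                    n_perm: int = DEFAULT_PERMUTATIONS,
                    seed: int = 0) -> PhiResult:
    """Φ_ST between two populations with a permutation p-value.

    ``pops`` maps population label -> sequence ids present in ``dm``.
    Individuals are permuted between the two populations; the p-value uses
    the +1 correction: p = (1 + #{Φ* ≥ Φ}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    a, b = pair
    ids_a, ids_b = pops[a], pops[b]
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise SizeError(f"both populations need >= 2 sequences ({a}: {len(ids_a)}, "
                        f"{b}: {len(ids_b)})")
    order = {lab: i for i, lab in enumerate(dm.labels)}
    idx = np.array([order[i] for i in sorted(ids_a)] + [order[i] for i in sorted(ids_b)])
    dsq = dm.d[np.ix_(idx, idx)] ** 2
    groups = np.array([0] * len(ids_a) + [1] * len(ids_b))
    obs = _phi_from_groups(dsq, groups)

    rng = np.random.default_rng(seed)
    phis = _phi_two_group_perms(dsq, len(ids_a), n_perm, rng)
    count = int(np.sum(phis >= obs - 1e-12))
    p = (1.0 + count) / (n_perm + 1.0)
    return PhiResult(pair=(a, b), phi_st=obs, p=p, n_perm=n_perm)


def _phi_two_group_perms(dsq: np.ndarray, n_a: int, n_perm: int,
                         rng: np.random.Generator,
                         chunk: int = 4096) -> np.ndarray:
    """Vectorised two-group Φ_ST over permuted individual labels."""
    N = dsq.shape[0]
    n_b = N - n_a
    total = dsq.sum()
    t = dsq.sum(axis=1)
    ss_total = total / (2.0 * N)
    n_prime = N - (n_a ** 2 + n_b ** 2) / N
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        B = min(chunk, n_perm - done)
        order = np.argsort(rng.random((B, N)), axis=1)
        V = np.zeros((B, N))
        np.put_along_axis(V, order[:, :n_a], 1.0, axis=1)
        W = V @ dsq
        A = (W * V).sum(axis=1)                  # Σ v_i v_j d_ij
        Bq = total - 2.0 * (V @ t) + A           # Σ (1-v)(1-v) d_ij
        ss_within = A / (2.0 * n_a) + Bq / (2.0 * n_b)
        ms_w = ss_within / (N - 2.0)
        ms_a = ss_total - ss_within              # df_a = 1
        sigma_a = (ms_a - ms_w) / n_prime
        denom = sigma_a + ms_w
        out[done:done + B] = np.where(denom > 0, sigma_a / denom, 0.0)
        done += B
    return out


def pairwise_phi_matrix(dm: DistanceMatrix, pops: dict[str, list[str]],
                        n_perm: int = DEFAULT_PERMUTATIONS,
                        seed: int = 0) -> pd.DataFrame:
    """All pairwise Φ_ST values and p-values as a tidy table."""
    names = list(pops)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            res = pairwise_phi_st(dm, pops, (names[i], names[j]),
                                  n_perm=n_perm, seed=seed + 7919 * (i * len(names) + j))
            rows.append({"pop_a": names[i], "pop_b": names[j],
                         "phi_st": res.phi_st, "p": res.p, "n_perm": res.n_perm})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hierarchical AMOVA
# ---------------------------------------------------------------------------

def _amova_components(dsq: np.ndarray, pop_of: np.ndarray, group_of_pop: np.ndarray
                      ) -> tuple[float, float, float]:
    """Three-level variance components (σ_a among groups, σ_b among pops
    within groups, σ_c within pops) from squared distances."""
    N = len(pop_of)
    pops = np.unique(pop_of)
    groups = np.unique(group_of_pop)
    P, G = len(pops), len(groups)

    ss_total = dsq.sum() / (2.0 * N)
    ss_wp = 0.0
    n_p = {}
    for p in pops:
        idx = np.nonzero(pop_of == p)[0]
        n_p[p] = len(idx)
        ss_wp += dsq[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    ss_wg = 0.0
    n_g = {}
    for g in groups:
        gpops = pops[group_of_pop == g]
        idx = np.nonzero(np.isin(pop_of, gpops))[0]
        n_g[g] = len(idx)
        ss_wg += dsq[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    ss_ag = ss_total - ss_wg
    ss_ap = ss_wg - ss_wp

    df_ag, df_ap, df_wp = G - 1, P - G, N - P
    sigma_c = ss_wp / df_wp if df_wp > 0 else 0.0
    sum_npsq_by_group = {g: sum(n_p[p] ** 2 for p in pops[group_of_pop == g])
                         for g in groups}
    if df_ap > 0:
        n1 = (N - sum(sum_npsq_by_group[g] / n_g[g] for g in groups)) / df_ap
        sigma_b = (ss_ap / df_ap - sigma_c) / n1 if n1 > 0 else 0.0
    else:
        sigma_b = 0.0
    if df_ag > 0:
        n2 = (sum(sum_npsq_by_group[g] / n_g[g] for g in groups)
              - sum(n_p[p] ** 2 for p in pops) / N) / df_ag
        n3 = (N - sum(v ** 2 for v in n_g.values()) / N) / df_ag
        sigma_a = (ss_ag / df_ag - sigma_c - n2 * sigma_b) / n3 if n3 > 0 else 0.0
    else:
        sigma_a = 0.0
    return float(sigma_a), float(sigma_b), float(sigma_c)


def amova_ss_decomposition(dsq: np.ndarray, pop_of: np.ndarray,
                           group_of_pop: np.ndarray) -> tuple[float, float, float, float]:
    """(SS among groups, SS among pops within groups, SS within pops, SS total)."""
    N = len(pop_of)
    pops = np.unique(pop_of)
    ss_total = dsq.sum() / (2.0 * N)
    ss_wp = sum(dsq[np.ix_(np.nonzero(pop_of == p)[0], np.nonzero(pop_of == p)[0])].sum()
                / (2.0 * np.sum(pop_of == p)) for p in pops)
    ss_wg = 0.0
    for g in np.unique(group_of_pop):
        gpops = pops[group_of_pop == g]
        idx = np.nonzero(np.isin(pop_of, gpops))[0]
        ss_wg += dsq[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return ss_total - ss_wg, ss_wg - ss_wp, ss_wp, ss_total


def hierarchical_amova(dm: DistanceMatrix, pops: dict[str, list[str]],
                       groups: dict[str, str],
                       n_perm: int = DEFAULT_PERMUTATIONS,
                       seed: int = 0) -> AmovaResult:
    """Three-level AMOVA (groups of populations / populations / individuals).

    Permutation nulls follow the standard scheme: Φ_CT permutes whole
    populations among groups, Φ_SC permutes individuals among populations
    within their group, Φ_ST permutes individuals among all populations.
    """
    group_names = sorted(set(groups.values()))
    if len(group_names) < 2:
        raise HierarchyError("need >= 2 groups; use pairwise_phi_st for two "
                             "populations in one group")
    pop_names = list(pops)
    order = {lab: i for i, lab in enumerate(dm.labels)}
    idx, pop_of = [], []
    for pi, pname in enumerate(pop_names):
        for rid in sorted(pops[pname]):
            idx.append(order[rid])
            pop_of.append(pi)
    idx = np.array(idx)
    pop_of = np.array(pop_of)
    dsq = dm.d[np.ix_(idx, idx)] ** 2
    group_of_pop = np.array([group_names.index(groups[p]) for p in pop_names])

    sa, sb, sc = _amova_components(dsq, pop_of, group_of_pop)
    total = sa + sb + sc
    phi_ct = sa / total if total > 0 else 0.0
    phi_sc = sb / (sb + sc) if (sb + sc) > 0 else 0.0
    phi_st = (sa + sb) / total if total > 0 else 0.0

    rng = np.random.default_rng(seed)
    c_ct = c_sc = c_st = 0
    P = len(pop_names)
    for _ in range(n_perm):
        # phi_ct: permute populations among groups
        perm_g = group_of_pop.copy()
        rng.shuffle(perm_g)
        a, b, c = _amova_components(dsq, pop_of, perm_g)
        if (a / (a + b + c) if (a + b + c) > 0 else 0.0) >= phi_ct - 1e-12:
            c_ct += 1
        # phi_sc: permute individuals among pops within groups
        perm_pop = pop_of.copy()
        for g in range(len(group_names)):
            gpops = np.nonzero(group_of_pop == g)[0]
            mask = np.isin(pop_of, gpops)
            vals = perm_pop[mask]
            rng.shuffle(vals)
            perm_pop[mask] = vals
        a, b, c = _amova_components(dsq, perm_pop, group_of_pop)
        if (b / (b + c) if (b + c) > 0 else 0.0) >= phi_sc - 1e-12:
            c_sc += 1
        # phi_st: permute individuals among all pops
        perm_all = pop_of.copy()
        rng.shuffle(perm_all)
        a, b, c = _amova_components(dsq, perm_all, group_of_pop)
        if ((a + b) / (a + b + c) if (a + b + c) > 0 else 0.0) >= phi_st - 1e-12:
            c_st += 1
    np1 = n_perm + 1.0
    return AmovaResult(phi_ct=phi_ct, phi_sc=phi_sc, phi_st=phi_st,
                       var_among_groups=sa, var_among_pops=sb, var_within=sc,
                       p_ct=(1 + c_ct) / np1, p_sc=(1 + c_sc) / np1,
                       p_st=(1 + c_st) / np1, n_perm=n_perm)


# ---------------------------------------------------------------------------
# Temporal pooling
# ---------------------------------------------------------------------------

@dataclass
class PoolingPlan:
    pooled: list[str]
    separate: list[str]
    flagged: list[str]
    tests: pd.DataFrame


def pool_temporal_samples(dm: DistanceMatrix, pops: dict[str, list[str]],
                          replicates: list[str], alpha: float = 0.05,
                          n_perm: int = 999, seed: int = 0) -> PoolingPlan:
    """Decide which temporal replicates of one locality can be pooled.

    All pairwise Φ_ST tests are run among the replicates; replicates that
    are non-significant against every other replicate are merged.  Each
    excluded replicate is then re-tested against the pooled remainder and
    flagged if it still differs (the odd-year pattern).
    """
    if len(replicates) < 2:
        return PoolingPlan(pooled=list(replicates), separate=[], flagged=[],
                           tests=pd.DataFrame())
    tests = pairwise_phi_matrix(dm, {r: pops[r] for r in replicates},
                                n_perm=n_perm, seed=seed)
    # connected components of the non-significance graph: replicates that do
    # not differ (directly or through intermediates) pool together
    comp = {r: {r} for r in replicates}
    for _, row in tests.iterrows():
        if row.p >= alpha:
            merged = comp[row.pop_a] | comp[row.pop_b]
            for r in merged:
                comp[r] = merged
    components = {frozenset(c) for c in comp.values()}
    pooled_set = max(components,
                     key=lambda c: (len(c), sum(len(pops[r]) for r in c)))
    pooled = [r for r in replicates if r in pooled_set]
    separate = [r for r in replicates if r not in pooled_set]
    flagged = []
    retests = []
    if pooled and separate:
        merged_ids = [rid for r in pooled for rid in pops[r]]
        for r in separate:
            res = pairwise_phi_st(dm, {"pooled": merged_ids, r: pops[r]},
                                  ("pooled", r), n_perm=n_perm, seed=seed + 13)
            retests.append({"pop_a": "pooled", "pop_b": r,
                            "phi_st": res.phi_st, "p": res.p, "n_perm": n_perm})
            if res.p < alpha:
                flagged.append(r)
    if retests:
        tests = pd.concat([tests, pd.DataFrame(retests)], ignore_index=True)
    return PoolingPlan(pooled=pooled, separate=separate, flagged=flagged,
                       tests=tests)


# ---------------------------------------------------------------------------
# Slatkin linearisation + UPGMA
# ---------------------------------------------------------------------------

def slatkin_linearize(phi: pd.DataFrame | np.ndarray,
                      labels: list[str] | None = None) -> tuple[list[str], np.ndarray]:
    """D = Φ/(1−Φ) per pair; negative Φ clamped to 0 with a warning."""
    if isinstance(phi, pd.DataFrame):
        labels = sorted(set(phi.pop_a) | set(phi.pop_b))
        mat = np.zeros((len(labels), len(labels)))
        for _, row in phi.iterrows():
            i, j = labels.index(row.pop_a), labels.index(row.pop_b)
            mat[i, j] = mat[j, i] = row.phi_st
    else:
        mat = np.asarray(phi, dtype=float)
        if labels is None:
            labels = [f"P{i+1}" for i in range(mat.shape[0])]
    if not np.allclose(mat, mat.T):
        raise ValueError("Phi matrix must be symmetric")
    if np.any(mat >= 1.0 - 1e-12):
        bad = np.argwhere(mat >= 1.0 - 1e-12)
        i, j = bad[0]
        raise InfiniteDistanceError(
            f"Phi_ST = 1 between {labels[i]} and {labels[j]}: infinite "
            "linearised distance")
    if np.any(mat < 0):
        warnings.warn("negative Phi_ST clamped to 0 in Slatkin linearisation")
        mat = np.clip(mat, 0.0, None)
    D = mat / (1.0 - mat)
    np.fill_diagonal(D, 0.0)
    return list(labels), D


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    newick = {i: labels[i] for i in range(n)}
    for k, (a, b, h, _cnt) in enumerate(Z):
        a, b = int(a), int(b)
        node = n + k
        ha, hb = h / 2.0 - heights[a], h / 2.0 - heights[b]
        newick[node] = f"({newick[a]}:{max(ha, 0.0):.6g},{newick[b]}:{max(hb, 0.0):.6g})"
        heights[node] = h / 2.0
    return newick[n + len(Z) - 1] + ";"


def slatkin_upgma(phi: pd.DataFrame | np.ndarray,
                  labels: list[str] | None = None) -> tuple[np.ndarray, str]:
    """Linearised-distance matrix and an ultrametric UPGMA tree (Newick)."""
    labels, D = slatkin_linearize(phi, labels)
    iu = np.triu_indices(len(labels), 1)
    Z = linkage(D[iu], method="average")
    return D, _linkage_to_newick(Z, labels)


# ---------------------------------------------------------------------------
# Isolation by distance (Mantel)
# ---------------------------------------------------------------------------

def migrants_from_phi(phi: float) -> float:
    """Slatkin's M = (1−Φ)/(2Φ), the scaled migrant estimate for haploids."""
    if phi <= 0:
        return np.nan
    return (1.0 - phi) / (2.0 * phi)


def mantel_ibd(phi: pd.DataFrame | np.ndarray, geo: np.ndarray,
               labels: list[str] | None = None,
               n_perm: int = DEFAULT_PERMUTATIONS, seed: int = 0,
               exclude: str | None = None) -> IbdResult:
    """Mantel test of migrant estimates against geographic distance.

    Pairs with Φ_ST ≤ 0 have undefined M; they are flagged and excluded
    from the correlation (with a warning).  The null permutes population
    rows/columns of the geographic matrix jointly; p is two-sided on |r|
    with the +1 correction.
    """
    if isinstance(phi, pd.DataFrame):
        labels_all = sorted(set(phi.pop_a) | set(phi.pop_b))
        pm = np.zeros((len(labels_all), len(labels_all)))
        for _, row in phi.iterrows():
            i, j = labels_all.index(row.pop_a), labels_all.index(row.pop_b)
            pm[i, j] = pm[j, i] = row.phi_st
    else:
        pm = np.asarray(phi, dtype=float)
        labels_all = labels or [f"P{i+1}" for i in range(pm.shape[0])]
    geo = np.asarray(geo, dtype=float)
    keep = [i for i, lab in enumerate(labels_all) if lab != exclude]
    labels_used = [labels_all[i] for i in keep]
    pm = pm[np.ix_(keep, keep)]
    geo = geo[np.ix_(keep, keep)]
    k = len(labels_used)
    if k < 4:
        warnings.warn("fewer than 4 populations: Mantel permutation null is "
                      "degenerate")
    M = np.full_like(pm, np.nan)
    pos = pm > 0
    M[pos] = (1.0 - pm[pos]) / (2.0 * pm[pos])
    iu = np.triu_indices(k, 1)
    valid = pos[iu]
    excluded = [(labels_used[i], labels_used[j])
                for i, j in zip(*iu) if pm[i, j] <= 0]
    if excluded:
        warnings.warn(f"{len(excluded)} pair(s) with Phi_ST <= 0 excluded from IBD")
    x = M[iu][valid]
    y = geo[iu][valid]
    if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
        return IbdResult(r=np.nan, r2=np.nan, p=np.nan, n_perm=0,
                         migrants=pd.DataFrame(M, index=labels_used,
                                               columns=labels_used),
                         excluded_pairs=excluded)
    r_obs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(k)
        gp = geo[np.ix_(perm, perm)][iu][valid]
        if np.std(gp) == 0:
            continue
        if abs(np.corrcoef(x, gp)[0, 1]) >= abs(r_obs) - 1e-12:
            count += 1
    p = (1.0 + count) / (n_perm + 1.0)
    return IbdResult(r=r_obs, r2=r_obs ** 2, p=p, n_perm=n_perm,
                     migrants=pd.DataFrame(M, index=labels_used,
                                           columns=labels_used),
                     excluded_pairs=excluded)


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bonferroni(pvals: list[float], alpha: float = 0.05) -> dict:
    """Bonferroni-adjusted significance calls: significant iff p < α/m."""
    if not pvals:
        raise ParameterError("empty p-value list")
    threshold = alpha / len(pvals)
    return {"threshold": threshold,
            "significant": [p < threshold for p in pvals]}


def significance_stars(p: float, single: float = 0.05, double: float = 0.001) -> str:
    """Star convention for report tables (* p<0.05, ** p<0.001)."""
    if p < double:
        return "**"
    if p < single:
        return "*"
    return ""
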