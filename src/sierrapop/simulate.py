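"""Coalescent synthetic-data generator.

Draws genealogies under the demographic scenarios the analysis targets —
constant size, sudden (demographic) expansion, finite-island spatial
expansion, and a two-deme isolation-with-migration split — then evolves
finite-sites sequences along the genealogy under an HKY/TN93 model with
gamma rate heterogeneity, optionally adding adjacent-site "doublet"
hotspot substitutions.  Output is an :class:`~sierrapop.sequences.Alignment`
plus a truth record, so every downstream stage can be tested without any
external data.

Scaling conventions
-------------------
Time is measured in units of *N* generations (haploid/maternal coalescent:
a pair of lineages in a deme of relative size *s* coalesces at rate 1/*s*).
With θ = 2Nu (u = per-sequence per-generation mutation rate), mutations
accumulate at rate θ/2 per lineage per time unit, so a pair separated for
time *t* carries on average *t*·θ expected differences; E[k] = θ for a
constant-size population.  The expansion time parameter τ (mutational
units, τ = 2uT) maps to t = τ/θ₁ in these units; the split time of the
isolation-with-migration model is T = t/N directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .sequences import Alignment, Record
from .substitution import DEFAULT_FREQS, SubstitutionModel

__all__ = [
    "Scenario", "TruthRecord", "Genealogy", "simulate_genealogy",
    "simulate_sample", "make_study_like_dataset",
]


class ScenarioError(ValueError):
    """Invalid scenario parameter combination."""


@dataclass
class Scenario:
    """Generating conditions for one synthetic sample.

    kind:
        ``constant`` (θ), ``sudden_expansion`` (τ, θ0, θ1),
        ``spatial_expansion_approx`` (τ, θ, M; finite-island approximation
        with ``n_demes`` islands) or ``isolation_with_migration``
        (θ, M, T; two demes sampled).
    n:
        sample size per deme (scalar, or one per sampled deme for IM).
    """

    kind: str
    n: int | Sequence[int] = 20
    L: int = 648
    theta: float | None = None
    theta0: float | None = None
    theta1: float | None = None
    tau: float | None = None
    M: float | None = None
    T: float | None = None
    n_demes: int = 20                    # islands for the spatial model
    mutation_model: str = "TN93"         # TN93 | HKY
    kappa: float = 8.0                   # transition/transversion rate weight
    kappa_Y: float | None = None         # TN93 pyrimidine rate (defaults to kappa)
    gamma_alpha: float | None = 0.4      # site-rate heterogeneity; None = uniform
    freqs: np.ndarray = field(default_factory=lambda: DEFAULT_FREQS.copy())
    doublet_hotspots: list[tuple[int, int]] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        need = {
            "constant": ("theta",),
            "sudden_expansion": ("tau", "theta0", "theta1"),
            "spatial_expansion_approx": ("tau", "theta", "M"),
            "continent_island": ("tau", "theta", "M"),
            "isolation_with_migration": ("theta", "M", "T"),
        }
        if self.kind not in need:
            raise ScenarioError(f"unknown scenario kind {self.kind!r}")
        for name in need[self.kind]:
            val = getattr(self, name)
            if val is None or val < 0:
                raise ScenarioError(f"{self.kind} requires {name} >= 0")
        if self.kind == "sudden_expansion" and self.theta1 <= 0:
            raise ScenarioError("theta1 must be positive")
        if self.kind in ("constant", "spatial_expansion_approx",
                         "continent_island") and self.theta <= 0:
            raise ScenarioError("theta must be positive")
        if self.L <= 0 or np.any(np.asarray(self.n) < 1):
            raise ScenarioError("L and n must be positive")


@dataclass
class Genealogy:
    """Binary genealogy over ``n_tips`` tips; nodes ``0..n_tips-1`` are tips."""

    n_tips: int
    parent: np.ndarray       # (2n-1,) parent index, -1 for root
    time: np.ndarray         # (2n-1,) node times (coalescent units)
    tip_deme: np.ndarray     # (n,) sampled deme per tip

    @property
    def root(self) -> int:
        return int(np.nonzero(self.parent == -1)[0][0])

    @property
    def tmrca(self) -> float:
        return float(self.time[self.root])

    @property
    def tree_length(self) -> float:
        has_parent = self.parent >= 0
        return float(np.sum(self.time[self.parent[has_parent]]
                            - self.time[has_parent]))

    def children(self) -> list[list[int]]:
        kids: list[list[int]] = [[] for _ in range(len(self.parent))]
        for i, p in enumerate(self.parent):
            if p >= 0:
                kids[p].append(i)
        return kids


@dataclass
class TruthRecord:
    scenario: dict
    tmrca: float
    tree_length: float
    demes: list[int]
    doublets_applied: list[tuple[int, int]]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "scenario": self.scenario,
                "tmrca": self.tmrca,
                "tree_length": self.tree_length,
                "demes": self.demes,
                "doublets_applied": [list(d) for d in self.doublets_applied],
            }, fh, indent=1)


# ---------------------------------------------------------------------------
# Structured coalescent engine
# ---------------------------------------------------------------------------

@dataclass
class Epoch:
    """Piecewise-constant demography: deme sizes and per-lineage migration
    rates holding from ``start`` backwards in time until the next epoch.
    ``relocate`` moves every lineage of a source deme into a destination
    deme at the epoch boundary (deme merger / founder event)."""

    start: float
    sizes: np.ndarray                      # relative deme sizes
    mig: np.ndarray                        # (D, D) per-lineage rates, diag 0
    relocate: dict[int, int] = field(default_factory=dict)


def _coalesce(rng: np.random.Generator, tip_demes: np.ndarray,
              epochs: list[Epoch]) -> Genealogy:
    n = len(tip_demes)
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes)
    lineages = list(range(n))
    demes = {i: int(tip_demes[i]) for i in range(n)}

    t = 0.0
    ei = 0
    nxt = epochs[1].start if len(epochs) > 1 else np.inf
    next_node = n
    while len(lineages) > 1:
        ep = epochs[ei]
        D = len(ep.sizes)
        k = np.zeros(D, dtype=np.int64)
        for lin in lineages:
            k[demes[lin]] += 1
        coal = k * (k - 1) / 2.0 / ep.sizes
        mig = k[:, None] * ep.mig
        R = coal.sum() + mig.sum()
        if R <= 0:
            if not np.isfinite(nxt):
                raise ScenarioError("coalescent process stalled (zero total rate)")
            dt = np.inf
        else:
            dt = rng.exponential(1.0 / R)
        if t + dt >= nxt:
            t = nxt
            ei += 1
            ep = epochs[ei]
            for lin in lineages:
                d = demes[lin]
                if d in ep.relocate:
                    demes[lin] = ep.relocate[d]
            nxt = epochs[ei + 1].start if ei + 1 < len(epochs) else np.inf
            continue
        t += dt
        u = rng.uniform(0, R)
        if u < coal.sum():
            d = int(np.searchsorted(np.cumsum(coal), u, side="right"))
            pool = [lin for lin in lineages if demes[lin] == d]
            i, j = rng.choice(len(pool), size=2, replace=False)
            a, b = pool[i], pool[j]
            node = next_node
            next_node += 1
            parent[a] = parent[b] = node
            time[node] = t
            lineages.remove(a)
            lineages.remove(b)
            lineages.append(node)
            demes[node] = d
        else:
            u -= coal.sum()
            flat = np.cumsum(mig.ravel())
            idx = int(np.searchsorted(flat, u, side="right"))
            d_from, d_to = divmod(idx, D)
            pool = [lin for lin in lineages if demes[lin] == d_from]
            demes[pool[int(rng.integers(len(pool)))]] = d_to
    return Genealogy(n_tips=n, parent=parent, time=time, tip_deme=tip_demes)


def _epochs_for(sc: Scenario) -> tuple[np.ndarray, list[Epoch], float]:
    """Tip demes, epoch schedule and mutation scale θ_mut for a scenario."""
    zero = np.zeros((1, 1))
    if sc.kind == "constant":
        n = int(np.atleast_1d(sc.n)[0])
        tips = np.zeros(n, dtype=np.int64)
        return tips, [Epoch(0.0, np.array([1.0]), zero)], sc.theta
    if sc.kind == "sudden_expansion":
        n = int(np.atleast_1d(sc.n)[0])
        tips = np.zeros(n, dtype=np.int64)
        t_exp = sc.tau / sc.theta1
        ancestral = max(sc.theta0 / sc.theta1, 1e-9)
        eps = [Epoch(0.0, np.array([1.0]), zero),
               Epoch(t_exp, np.array([ancestral]), zero)]
        return tips, eps, sc.theta1
    if sc.kind == "spatial_expansion_approx":
        n = int(np.atleast_1d(sc.n)[0])
        D = sc.n_demes
        tips = np.zeros(n, dtype=np.int64)      # all sampled in deme 0
        mig = np.full((D, D), (sc.M / 2.0) / (D - 1))
        np.fill_diagonal(mig, 0.0)
        t_exp = sc.tau / sc.theta
        eps = [Epoch(0.0, np.ones(D), mig),
               Epoch(t_exp, np.ones(D), np.zeros((D, D)),
                     relocate={d: 0 for d in range(1, D)})]
        return tips, eps, sc.theta
    if sc.kind == "isolation_with_migration":
        ns = np.atleast_1d(sc.n)
        n1, n2 = (int(ns[0]), int(ns[0])) if ns.size == 1 else (int(ns[0]), int(ns[1]))
        tips = np.array([0] * n1 + [1] * n2, dtype=np.int64)
        mig = np.array([[0.0, sc.M / 2.0], [sc.M / 2.0, 0.0]])
        eps = [Epoch(0.0, np.ones(2), mig),
               Epoch(sc.T, np.ones(2), np.zeros((2, 2)), relocate={1: 0})]
        return tips, eps, sc.theta
    raise ScenarioError(sc.kind)


def _coalesce_continent_island(rng: np.random.Generator, n: int, tau: float,
                               theta: float, M: float) -> Genealogy:
    """Exact continent-island genealogy: n lineages in a focal deme of size 1
    coalesce at pair rate 1 or emigrate (rate M/2 per lineage) into an
    effectively infinite pool where they are inert; at t = τ/θ everything
    collapses into a single ancestral deme of size 1.  Event count is O(n),
    so arbitrarily large M is cheap."""
    t_exp = tau / theta
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes)
    inside = list(range(n))
    outside: list[int] = []
    t = 0.0
    nxt = n
    while len(inside) + len(outside) > 1 and t < t_exp:
        k = len(inside)
        rate = k * (k - 1) / 2.0 + k * M / 2.0
        if rate <= 0:
            break
        dt = rng.exponential(1.0 / rate)
        if t + dt >= t_exp:
            break
        t += dt
        if rng.random() < (k * (k - 1) / 2.0) / rate:
            i, j = rng.choice(k, size=2, replace=False)
            a, b = inside[i], inside[j]
            parent[a] = parent[b] = nxt
            time[nxt] = t
            inside.remove(a)
            inside.remove(b)
            inside.append(nxt)
            nxt += 1
        else:
            outside.append(inside.pop(int(rng.integers(k))))
    # ancestral phase: single deme, standard coalescent
    t = max(t, t_exp)
    lineages = inside + outside
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = lineages[i], lineages[j]
        parent[a] = parent[b] = nxt
        time[nxt] = t
        lineages.remove(a)
        lineages.remove(b)
        lineages.append(nxt)
        nxt += 1
    return Genealogy(n_tips=n, parent=parent, time=time,
                     tip_deme=np.zeros(n, dtype=np.int64))


def simulate_genealogy(sc: Scenario, rng: np.random.Generator | None = None
                       ) -> tuple[Genealogy, float]:
    """Draw a genealogy under the scenario; returns it with θ_mut (the θ that
    sets the per-lineage mutation rate θ_mut/2 in tree time units)."""
    sc.validate()
    rng = np.random.default_rng(sc.seed) if rng is None else rng
    if sc.kind == "continent_island":
        n = int(np.atleast_1d(sc.n)[0])
        return (_coalesce_continent_island(rng, n, sc.tau, sc.theta, sc.M),
                sc.theta)
    tips, epochs, theta_mut = _epochs_for(sc)
    return _coalesce(rng, tips, epochs), theta_mut


def simulate_pairwise_differences(sc: Scenario,
                                  rng: np.random.Generator | None = None
                                  ) -> np.ndarray:
    """Pairwise difference matrix under the infinite-sites approximation.

    Draws the genealogy for the scenario, drops Poisson(θ/2 · branch length)
    mutations on each branch, and counts mutations on the path between each
    tip pair.  Much faster than full sequence evolution; used for mismatch
    parametric bootstraps and neutrality-test null simulations.
    """
    rng = np.random.default_rng(sc.seed) if rng is None else rng
    gen, theta_mut = simulate_genealogy(sc, rng)
    n = gen.n_tips
    n_nodes = len(gen.parent)
    has_parent = gen.parent >= 0
    blen = np.where(has_parent,
                    gen.time[np.where(has_parent, gen.parent, 0)] - gen.time,
                    0.0)
    muts = rng.poisson(blen * theta_mut / 2.0)
    # descendant-tip masks built bottom-up in time order
    masks = np.zeros((n_nodes, n), dtype=bool)
    masks[np.arange(n), np.arange(n)] = True
    for v in np.argsort(gen.time, kind="stable"):
        p = gen.parent[v]
        if p >= 0:
            masks[p] |= masks[v]
    diff = np.zeros((n, n))
    for v in np.nonzero(muts * has_parent)[0]:
        mask = masks[v]
        diff += muts[v] * (mask[:, None] ^ mask[None, :])
    return diff


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------

def _site_rates(rng: np.random.Generator, L: int, alpha: float | None) -> np.ndarray:
    if alpha is None:
        return np.ones(L)
    return rng.gamma(shape=alpha, scale=1.0 / alpha, size=L)


def evolve_sequences(gen: Genealogy, theta_mut: float, L: int,
                     model: SubstitutionModel, gamma_alpha: float | None,
                     rng: np.random.Generator) -> np.ndarray:
    """Finite-sites evolution along a genealogy; returns (n_tips, L) int codes.

    Branch lengths in substitutions/site are Δt · (θ/2) / L, so the expected
    raw difference count between two tips separated by total time 2t is θ·t
    (before multiple-hit saturation)."""
    rates = _site_rates(rng, L, gamma_alpha)
    n_nodes = len(gen.parent)
    seqs = np.empty((n_nodes, L), dtype=np.int8)
    root = gen.root
    seqs[root] = rng.choice(4, size=L, p=model.freqs)
    kids = gen.children()
    order = [root]
    stack = [root]
    while stack:
        node = stack.pop()
        for c in kids[node]:
            order.append(c)
            stack.append(c)
    for node in order[1:]:
        p = gen.parent[node]
        b = (gen.time[p] - gen.time[node]) * theta_mut / 2.0 / L
        P = model.transition_probabilities(b * rates)           # (L, 4, 4)
        probs = P[np.arange(L), seqs[p]]                        # (L, 4)
        cdf = np.cumsum(probs, axis=1)
        u = rng.random(L) * cdf[:, -1]
        seqs[node] = (u[:, None] > cdf[:, :-1]).sum(axis=1)
    return seqs[:gen.n_tips]


def _apply_doublets(mat: np.ndarray, gen: Genealogy,
                    hotspots: list[tuple[int, int]],
                    rng: np.random.Generator) -> list[tuple[int, int]]:
    """Inject one joint substitution per hotspot pair on a random internal
    branch (transversion swap A<->T, C<->G at both sites), so the two
    minority states co-occur in the same descendant sequences."""
    swap = np.array([3, 2, 1, 0], dtype=np.int8)    # A<->T, C<->G
    kids = gen.children()
    applied = []
    internal = [v for v in range(gen.n_tips, len(gen.parent))
                if gen.parent[v] >= 0]
    if not internal:
        return applied
    lengths = np.array([gen.time[gen.parent[v]] - gen.time[v] for v in internal])
    if lengths.sum() <= 0:
        return applied
    for (i, j) in hotspots:
        if not (1 <= i < j <= mat.shape[1]) or j != i + 1:
            raise ScenarioError(f"hotspot ({i}, {j}) is not an adjacent in-range pair")
        v = internal[int(rng.choice(len(internal), p=lengths / lengths.sum()))]
        desc = []
        stack = [v]
        while stack:
            u = stack.pop()
            if u < gen.n_tips:
                desc.append(u)
            stack.extend(kids[u])
        if 0 < len(desc) < mat.shape[0]:
            for col in (i - 1, j - 1):
                # homogenise the column then swap the carriers: clean doublet
                major = np.bincount(mat[:, col], minlength=4).argmax()
                mat[:, col] = major
                mat[desc, col] = swap[major]
            applied.append((i, j))
    return applied


def _make_model(sc: Scenario) -> SubstitutionModel:
    if sc.mutation_model.upper() == "HKY":
        return SubstitutionModel.hky(sc.kappa, sc.freqs)
    if sc.mutation_model.upper() == "TN93":
        kY = sc.kappa if sc.kappa_Y is None else sc.kappa_Y
        return SubstitutionModel.tn93(sc.kappa, kY, sc.freqs)
    raise ScenarioError(f"unknown mutation model {sc.mutation_model!r}")


DEME_NAMES_DEFAULT = ("P1", "P2", "P3", "P4", "P5", "P6", "P7", "P8")


def simulate_sample(sc: Scenario,
                    deme_names: Sequence[str] = DEME_NAMES_DEFAULT,
                    years: Sequence[int] | None = None,
                    rng: np.random.Generator | None = None
                    ) -> tuple[Alignment, TruthRecord]:
    """Simulate one dataset under a scenario: genealogy, sequences, labels."""
    rng = np.random.default_rng(sc.seed) if rng is None else rng
    gen, theta_mut = simulate_genealogy(sc, rng)
    model = _make_model(sc)
    mat = evolve_sequences(gen, theta_mut, sc.L, model, sc.gamma_alpha, rng)
    applied = _apply_doublets(mat, gen, sc.doublet_hotspots, rng)

    bases = np.array(list("ACGT"))
    records = []
    for i in range(gen.n_tips):
        d = int(gen.tip_deme[i])
        year = 2000 if years is None else int(years[d])
        records.append(Record(id=f"{deme_names[d]}_{i:03d}",
                              population=deme_names[d], year=year,
                              seq="".join(bases[mat[i]])))
    aln = Alignment(records=records)
    truth = TruthRecord(
        scenario={k: (v.tolist() if isinstance(v, np.ndarray) else v)
                  for k, v in vars(sc).items()},
        tmrca=gen.tmrca, tree_length=gen.tree_length,
        demes=[int(d) for d in gen.tip_deme], doublets_applied=applied,
    )
    return aln, truth


# ---------------------------------------------------------------------------
# Study-like multi-population dataset
# ---------------------------------------------------------------------------

STUDY_POPS = ("SIN", "SIN04", "MICH", "OAX", "CH", "PE")
STUDY_N = (43, 26, 31, 50, 47, 49)
STUDY_YEARS = (2003, 2004, 2002, 2004, 2003, 2005)
#: five hotspot pairs at the positions reported for the real control region
STUDY_HOTSPOTS = [(141, 142), (218, 219), (247, 248), (318, 319), (476, 477)]


def make_study_like_dataset(seed: int = 0, outdir: str | Path | None = None
                            ) -> tuple[Alignment, TruthRecord]:
    """Six pseudo-populations echoing a multi-year eastern-Pacific sampling design.

    Five demes (SIN, MICH, OAX, CH, PE) exchange migrants in an island model
    (M = 8) on top of a shared sudden expansion (τ = 12.5, present per-deme
    θ = 250, ancestral θ = 1), which yields h ≈ 0.99–1.0 and π ≈ 0.015–0.023
    over 648 sites.  A sixth sample, SIN04, is a temporal replicate at the
    SIN locality forced through a severe recent bottleneck (sweepstakes
    founder pool at t = 0.02, rejoining SIN at t = 0.024), emulating the
    low-diversity "chaotic genetic patchiness" replicate: its sequences stay
    almost all distinct (private recent mutations) but its π falls well
    under half the median of the other samples, and it separates from SIN
    in temporal pooling tests.
    """
    rng = np.random.default_rng(seed)
    D = 6
    theta, tau = 250.0, 12.5
    ones = np.ones(D)
    main = [0, 2, 3, 4, 5]
    M_island = 8.0
    mig = np.zeros((D, D))
    for a in main:
        for b in main:
            if a != b:
                mig[a, b] = (M_island / 2.0) / (len(main) - 1)
    bottleneck = ones.copy()
    bottleneck[1] = 5e-4            # sweepstakes founder pool for SIN04
    ancestral = np.full(D, 1.0 / theta)
    epochs = [
        Epoch(0.0, ones, mig),
        Epoch(0.02, bottleneck, mig),                           # SIN04 crash
        Epoch(0.024, ones, mig, relocate={1: 0}),               # founder joins SIN
        Epoch(tau / theta, ancestral, np.zeros((D, D)),
              relocate={d: 0 for d in range(1, D)}),            # expansion
    ]
    tips = np.concatenate([np.full(n, d, dtype=np.int64)
                           for d, n in enumerate(STUDY_N)])
    gen = _coalesce(rng, tips, epochs)
    model = SubstitutionModel.tn93(8.0, 8.0, DEFAULT_FREQS)
    mat = evolve_sequences(gen, theta, 648, model, 0.4, rng)
    applied = _apply_doublets(mat, gen, STUDY_HOTSPOTS, rng)

    bases = np.array(list("ACGT"))
    records = []
    counters = {p: 0 for p in STUDY_POPS}
    for i in range(gen.n_tips):
        d = int(gen.tip_deme[i])
        pop = STUDY_POPS[d]
        counters[pop] += 1
        records.append(Record(id=f"{pop}_{counters[pop]:03d}", population=pop,
                              year=STUDY_YEARS[d],
                              seq="".join(bases[mat[i]])))
    aln = Alignment(records=records)
    truth = TruthRecord(
        scenario={"kind": "study_like", "theta": theta, "tau": tau,
                  "M_island": M_island, "founder_size": 0.03,
                  "founder_merge_time": 0.04, "seed": seed,
                  "populations": list(STUDY_POPS), "n": list(STUDY_N)},
        tmrca=gen.tmrca, tree_length=gen.tree_length,
        demes=[int(d) for d in gen.tip_deme], doublets_applied=applied,
    )
    if outdir is not None:
        from .sequences import write_alignment
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_alignment(aln, outdir / "alignment.fasta", outdir / "labels.tsv")
        truth.to_json(outdir / "truth.json")
    return aln, truth
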