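# sierrapop

Phylogeography and historical demography of mtDNA control-region data,
built around the classic single-locus marine-fish workflow: a set of
population samples of aligned D-loop sequences is summarised (haplotype and
nucleotide diversity), tested for structure (Φ-statistics/AMOVA with
permutation nulls, Slatkin-linearised population trees, Mantel isolation by
distance), screened for historical expansions (mismatch distributions under
sudden-demographic and spatial/range expansion models, Fu's *F*s), placed
on a clock (τ and θ conversions to years and female effective sizes), and
compared pairwise under a two-population isolation-with-migration
coalescent sampled by MCMC.  A coalescent simulator generates study-like
synthetic datasets — including sweepstakes "chaotic genetic patchiness"
temporal replicates — so every stage is testable without external data.

The package is aimed at population geneticists working with single-locus
(mtDNA) data on weakly structured, high-diversity marine species, and at
anyone who wants a scriptable, tested replacement for the
Arlequin/MDIV/MEGA toolchain of that literature.

## The statistics at its core

* **Diversity** — unbiased haplotype diversity `h = (n² − Σcᵢ²)/(n(n−1))`
  over haplotype copy numbers `cᵢ`; nucleotide diversity `π = k/L` from
  mean raw pairwise differences `k` (pairwise deletion), with Nei (1987)
  sampling variances.
* **Distances** — Tamura–Nei (TN93) with optional gamma rate-heterogeneity
  correction (default shape α = 0.4), pairwise base-frequency estimation,
  explicit saturation errors.
* **Structure** — Φ_ST from AMOVA on squared inter-haplotype distances;
  three-level AMOVA (Φ_CT, Φ_SC, Φ_ST) with the standard permutation
  schemes (default 20 100 permutations, +1-corrected p); Slatkin
  linearisation D = Φ/(1−Φ) with UPGMA; Mantel test on migrant estimates
  M = (1−Φ)/(2Φ) against nautical-mile distances; Bonferroni correction.
* **Demography** — Rogers–Harpending sudden-expansion mismatch curves
  F_j(τ, θ₀, θ₁) and a closed-form continent-island spatial-expansion
  analogue F_j(τ, θ, M); least-squares fits with parametric-bootstrap SSD
  tests and 95% CIs; Fu's `Fs = ln(S′/(1−S′))` with
  S′ = P(K ≥ k_obs | θ̂ = k̂) computed exactly from unsigned Stirling
  numbers.
* **Clock** — τ = 2uT and θ = 2Nu with u = L · rate · generation-years
  (defaults 3.6%/Myr·site, L = 648, 2-yr generations).
* **Isolation with migration** — Metropolis–Hastings over
  (θ, M, T, genealogy) with explicit migration paths, HKY pruning
  likelihood, structured-coalescent prior, Gibbs updates for M, and
  endpoint-conditioned migration-path bridges; marginal posterior grids
  with highest-posterior point estimates and TMRCA summaries.

## Worked example

```python
from sierrapop.simulate import make_study_like_dataset
from sierrapop.diversity import diversity_table, tn93_distance_matrix
from sierrapop.structure import pool_temporal_samples

aln, truth = make_study_like_dataset(seed=20100)
print(diversity_table(aln))
```

```
population  n  nh     h   h_sd      pi   pi_sd      k   S
       SIN 43  40 0.997 0.0059 0.02012 0.01026 13.040 123
     SIN04 26  23 0.988 0.0156 0.00788 0.00440  5.108  50
      MICH 31  29 0.996 0.0095 0.01833 0.00948 11.875  98
       OAX 50  45 0.996 0.0049 0.02181 0.01104 14.133 143
        CH 47  42 0.995 0.0054 0.02173 0.01101 14.082 145
        PE 49  47 0.998 0.0046 0.02111 0.01070 13.678 135
```

Every sample shows the near-maximal haplotype diversity (h ≈ 0.99–1.0) and
π ≈ 2% typical of expanded mtDNA control-region populations — except the
SIN04 temporal replicate, whose π (0.0079, 37% of the median) betrays its
sweepstakes-founder origin.  The pooling test then keeps it separate:

```python
dm = tn93_distance_matrix(aln, 0.4)
pops = {p: [r.id for r in aln.records if r.population == p]
        for p in aln.populations}
plan = pool_temporal_samples(dm, pops, ["SIN", "SIN04"], n_perm=2009, seed=1)
# plan.pooled == ['SIN'], plan.flagged == ['SIN04']
```

The numbered drivers under `analysis/` run the whole study on this dataset
(`01_simulate_dataset.py` → `06_im_mcmc.py`), writing tables to `results/`:
the mismatch fits put the expansion at τ ≈ 10–15 (≈ 215–320 ky; the odd
replicate at ≈ 112 ky), Fu's *F*s is strongly negative everywhere, the
hierarchical AMOVA finds no among-region variance (Φ_CT < 0) while
populations within regions differ (Φ_SC > 0, p < 0.001), and the Mantel
test finds no isolation by distance.  A `sierrapop` CLI exposes each stage
(`sierrapop simulate`, `phist`, `amova`, `mismatch`, `fs`, `convert`,
`tree`, `imcoal`, `pipeline`).

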