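# Methods

This note documents the models implemented in `sierrapop`, the choices made
where the design was genuinely open, and what the synthetic-data generator
does and does not emulate.

## Scope and data model

The unit of analysis is a multiple-sequence alignment of equal-length
mtDNA control-region sequences (default L = 648) carrying a population
label and collection year per record (sidecar TSV, keeping the FASTA
standard-clean).  Positions are 1-based.  Ambiguity handling: `N` and `-`
are excluded pairwise ("pairwise deletion") in all distance and mismatch
computations; for haplotype identity an `N` matches any base by default,
so sequencing ambiguity does not inflate the haplotype count (exact-match
mode is available).  Haplotype grouping is canonicalised (unambiguous
sequences define classes in lexicographic order) so it is invariant to
record order.

The site classifier reports variable, singleton and parsimony-informative
sites and transition/transversion types independently; published tallies
of this kind are not always mutually consistent (sites vs. mutations vs.
multi-state columns), so no identity among them is enforced beyond
singletons + parsimony-informative = variable.

## Distances and diversity

Pairwise distances use the Tamura–Nei (1993) estimator, optionally with
the gamma rate-heterogeneity correction (each −c·ln(w) term becomes
c·α·(w^(−1/α) − 1)); the default shape α = 0.4 reflects the strong site-rate
skew of control-region data.  Base frequencies are estimated per pair (the
classic pairwise estimator); whole-alignment frequencies are an option.
Saturated pairs (non-positive logarithm argument) raise an error naming
the pair rather than returning NaN.

Diversity statistics deliberately split models: π and k use *raw*
differences so the identity π·L = k holds (observed data of this kind obey
it, e.g. 12.695/648 = 0.01959), whereas Φ-statistics and trees use
TN93+Γ(0.4).  h uses the unbiased estimator written as
(n² − Σcᵢ²)/(n(n−1)), which is exact (h = 1.0 precisely) for all-singleton
samples; variances are the Nei (1987) eq. 8.12 / 10.7 forms.

## AMOVA and permutation tests

Φ_ST derives from the sums-of-squares decomposition of squared
inter-individual distances (SS within group g is Σ_{i<j∈g} d²ᵢⱼ/n_g).  The
three-level design estimates σ²_a (among groups), σ²_b (among populations
within groups) and σ²_c (within populations) with the standard unbalanced-
design coefficients.  Permutation nulls: individuals between two
populations for pairwise Φ_ST; whole populations among groups for Φ_CT;
individuals among populations within groups for Φ_SC; individuals among
all populations for Φ_ST.  p-values carry the +1 correction,
p = (1 + #{Φ* ≥ Φ})/(n_perm + 1), so p is never 0; the default
permutation count is 20 100.  The two-group permutation path is vectorised
(batch quadratic forms), which is what makes 500-replicate calibration
studies cheap.

Temporal pooling: the rule "pool replicates that are pairwise
non-significant" is implemented as connected components of the
non-significance graph (largest component pools; ties broken by sample
size), because an odd replicate that differs from *every* other would
otherwise leave no poolable set.  Excluded replicates are re-tested
against the pooled remainder and flagged if still different.

Slatkin linearisation D = Φ/(1−Φ) clamps negative Φ to 0 (with a warning)
and refuses Φ = 1; the population tree is average-linkage UPGMA on D.
Isolation by distance correlates M = (1−Φ)/(2Φ) with geographic distance
(nautical miles, user-supplied); pairs with Φ ≤ 0 have undefined M and are
excluded with a warning; the Mantel null permutes population rows/columns
of the geographic matrix jointly, two-sided on |r|.  (The haploid migrant
formula is the standard Slatkin form; source texts sometimes print it with
the parentheses lost.)

## Mismatch distributions and expansion fits

Sudden (demographic) expansion follows Rogers–Harpending: with
F̂_j(θ) = θ^j/(θ+1)^{j+1},

    F_j(τ, θ0, θ1) = F̂_j(θ1) + e^{−τ(θ1+1)/θ1} Σ_{i≤j} (τ^i/i!) [F̂_{j−i}(θ0) − F̂_{j−i}(θ1)]

The spatial (range) expansion model is the continent-island analogue: two
lineages sampled in a deme of scaled size θ either coalesce locally (rate
1/θ per mutational time unit) or are separated by migration (pair rate
M/θ) into an effectively infinite pool, coalescing only in the single
ancestral deme beyond τ.  Integrating the coalescence-time density gives
the closed form implemented in `expected_mismatch_spatial` (regularised
incomplete-gamma terms); at large M it converges to the pure-growth
demographic curve, which is tested.

Fitting is least squares on mismatch *frequencies* (SSD on frequencies,
the convention of the standard software in this literature): a vectorised
grid over (τ, θ0/θ, θ1/M) followed by Nelder–Mead refinement, with θ1 and
M capped at 99 999 — boundary hits are flagged, not errors, mirroring how
such tables report them.  The SSD p-value and the 95% CI of τ come from a
parametric bootstrap: coalescent samples are simulated under the fitted
model (infinite sites; the continent-island bootstrap uses an exact
continent-island genealogy sampler so large M costs nothing), refitted,
and p = P(SSD* ≥ SSD_obs); the CI is the 2.5–97.5 percentile of refitted
τ, also converted to ky.  Default 1000 bootstrap replicates (drivers and
tests use 200).  On equilibrium (no-expansion) data τ̂ is unstable and the
residual SSD large — a property the tests assert rather than hide.

## Fu's Fs

θ̂ = k̂ (mean pairwise differences); S′ = P(K ≥ nh_obs | θ̂, n) under the
Ewens sampling distribution, computed from unsigned Stirling numbers of
the first kind held as exact integers (log-space assembly), so the n ≤ 60
range of typical samples is exact to float precision; Fs = ln(S′/(1−S′)).
Degenerate spectra (monomorphic samples) are flagged ±∞.  The p-value
simulates n_sim neutral constant-size coalescent samples at θ = θ̂
(infinite sites) and reports the fraction with Fs ≤ Fs_obs.

## Clock conversions

RateModel holds the per-site per-year rate (default 3.6e−8, i.e.
3.6%/Myr), L (648) and generation time (2 yr); u = L·rate·generation is
the per-sequence per-generation rate.  Conversions implement τ = 2uT
(time T = τ/(2u) generations) and N = θ/(2u).  Note an erratum-style
caveat: the relation is sometimes printed as "T = 2μ/τ", which is
dimensionally inconsistent; the τ = 2uT form is the one that reproduces
the published conversions (13.4 → 287.2 ky, 255.3 → 2.7 × 10⁶ females)
and is used throughout.  The census utility divides catch mass by mean
individual mass (10 000 t at 450 g → 22.2 × 10⁶ fish).

## Trees

NJ agglomeration and UPGMA are delegated to dendropy's
`PhylogeneticDistanceMatrix`; negative NJ branches are zeroed with their
deficit transferred to the parent edge (Kuhner–Felsenstein style) and
counted.  Bootstrap resamples alignment columns, rebuilds TN93+Γ NJ trees,
and scores each original internal bipartition; replicates whose resampled
distances saturate are skipped and the divisor reduced.  Outgroup rooting
bisects the outgroup's edge.  Clock linearisation sets each node's age to
its mean root-to-tip path (clipped monotone) and converts with a
*between-lineage* divergence rate (default 2.1%/Myr ⇒ 1.05%/Myr per
lineage; the metadata records both to prevent factor-of-two drift).

## Isolation with migration

The MDIV-style model: two demes of equal female effective size N split
T·N generations ago from an ancestral deme of the same size, exchanging
migrants at scaled rate M = 2Nm; θ = 2Nu sets the mutation rate (θ/2 per
sequence per time unit of N generations); HKY finite-sites likelihood with
κ estimated from the pooled transition/transversion ratio by default and
empirical base frequencies.  Priors are uniform: θ on (0, 2×Watterson]
(user-tunable), M and T on (0, 10].

The sampler is Metropolis–Hastings over (θ, M, T, G) where the genealogy G
carries explicit migration events per branch.  Moves: sliding windows for
θ, T and node times; a whole-tree scale move (Jacobian-corrected) that
decorrelates tree size from T and θ; fixed-times nearest-neighbour
interchanges for topology; full migration-path redraws per branch from an
endpoint-conditioned Poisson bridge (parity-conditioned count drawn
exactly by inverse CDF); a node-deme flip move that resamples the three
adjacent paths so lineage deme histories mix; and a Gibbs update for M
from its truncated-Gamma conditional, which removes the M-path feedback
loop that otherwise mixes slowly.  Validity (no cross-deme coalescence
below T, no events above T) is enforced through the structured-coalescent
log-density, which returns −∞ for inconsistent states.  With the
likelihood held constant the sampler reproduces its uniform priors — the
key correctness diagnostic, asserted in the tests.

Chains are initialised from a UPGMA genealogy with T just below the
shallowest deme-mixed node and no migration events.  The two population
labels are sorted internally, so label order cannot change the chain
(symmetry is tested as exact equality).  Point estimates are the
highest-posterior grid bins (50 bins per parameter); TMRCA is the
posterior mean root age, converted to years via N_e = θ̂/(2u).  Divergence
time is weakly identified in this model class — posteriors for T are
reported with credible intervals rather than asserted to converge.
Historical settings (5 M cycles, 500 k burn-in) are available through
`IMConfig`; desk-scale analyses and tests use 100 k cycles with n ≤ 15 per
deme, which the recovery studies show is enough to localise M and cover T
at the 80% level.

## Synthetic-data generator

Time is scaled in units of N generations (haploid/maternal coalescent);
mutations accrue at θ/2 per lineage per unit, so E[k] = θ at equilibrium —
verified against coalescent theory and cross-checked against msprime.
Scenarios: constant size; sudden expansion (τ, θ0, θ1; epoch-scaled
Kingman); finite-island spatial expansion (the fitter's continuum model
approximated by 20 islands with a merge at τ/θ); an exact continent-island
sampler (used for spatial parametric bootstraps); and the two-deme IM
model.  Sequences evolve under TN93/HKY (default κ-weight 8, AT-rich
control-region base frequencies) with per-site gamma rates (α = 0.4) via
exact per-branch transition matrices; optional adjacent-site "doublet"
hotspots inject a joint transversion swap on one internal branch per
hotspot, reproducing the co-occurring minority-state pattern used to test
doublet detection.

`make_study_like_dataset` emulates the published sampling design: six
samples (n = 43, 26, 31, 50, 47, 49), five demes in an island model
(M = 8) over a shared sudden expansion (present per-deme θ = 250,
ancestral θ = 1, τ = 12.5 — chosen so h ≈ 0.99–1.0, π ≈ 0.015–0.023 and
mean pairwise differences ≈ 13 over 648 sites, the observed condition
ranges), plus a SIN04 temporal replicate forced through a severe
sweepstakes bottleneck (relative size 5 × 10⁻⁴ between t = 0.020 and
0.024, then merged into SIN).  That construction yields a replicate whose
sequences are almost all distinct (h ≈ 0.99) yet whose π sits well under
half the median of the other samples, and which the pooling test isolates
— the "chaotic genetic patchiness" pattern.  What the generator does *not*
emulate: recombination and selection (absent from the model), sequencing
error beyond the optional N-ambiguity handling, uneven temporal cohorts
within a sample, and real geography (migration is island-symmetric, so
passing tests say nothing about clinal IBD in real data — the IBD test on
this fixture is expected null).

## Numerical and reporting conventions

Permutation and bootstrap p-values are +1-corrected; all stochastic
routines take explicit seeds and are reproducible bit-for-bit; expected
mismatch curves are validated to sum to 1 within 1e−6 at truncation;
report tables carry the config hash and seed; star conventions follow the
field's tables (* p < 0.05, ** p < 0.001).  Problem sizes in the drivers
and tests (200-replicate bootstraps, 100 k-cycle chains, ≤ 60-taxon
bootstrap trees) are the package's desk-scale defaults; all are plain
parameters.

## Known limitations

Single-locus inference inherits the usual caveat that mtDNA is one
realisation of the coalescent; nothing here corrects for that.  The
spatial-expansion fit treats the continent-island model as literal; the
finite-island generator only approximates it (emigrants can re-meet), so
spatial parameter recovery is assessed against the exact continent-island
sampler.  The IM sampler's NNI-plus-scale topology moves are adequate for
desk-scale sample sizes but would mix slowly for hundreds of sequences;
the likelihood is recomputed in full rather than incrementally.  AMOVA
variance components can be negative (small or antistructured data); they
are reported as computed.
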