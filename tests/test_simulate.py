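"""Coalescent generator: expectations, determinism, study-like dataset."""

import numpy as np
import pytest

from sierrapop.diversity import raw_difference_matrix
from sierrapop.sequences import classify_sites
from sierrapop.simulate import (
    Scenario, ScenarioError, make_study_like_dataset, simulate_genealogy,
    simulate_pairwise_differences, simulate_sample,
)


class TestCoalescentExpectations:
    def test_mean_pairwise_differences_equals_theta(self):
        """E[k] = θ under the constant-size model (small multiple-hit bias
        tolerated at θ/L ≈ 0.008)."""
        rng = np.random.default_rng(1)
        iu = np.triu_indices(20, 1)
        ks = []
        for _ in range(250):
            sc = Scenario(kind="constant", theta=5, n=20, seed=0)
            aln, _ = simulate_sample(sc, rng=rng)
            ks.append(raw_difference_matrix(aln).d[iu].mean())
        se = np.std(ks) / np.sqrt(len(ks))
        assert np.mean(ks) == pytest.approx(5.0, abs=max(4 * se, 0.25))

    def test_mean_matches_msprime_oracle(self):
        """Infinite-sites pairwise differences agree with an independent
        coalescent simulator under identical scaling."""
        import msprime
        rng = np.random.default_rng(2)
        theta, n, reps = 6.0, 15, 300
        iu = np.triu_indices(n, 1)
        ours = []
        for _ in range(reps):
            d = simulate_pairwise_differences(
                Scenario(kind="constant", theta=theta, n=n, seed=0), rng)
            ours.append(d[iu].mean())
        theirs = []
        # msprime: haploid Ne=1, per-generation... use mutation rate theta/2
        # on an Ne=1 haploid coalescent (time in units of Ne gens)
        reps_ts = msprime.sim_ancestry(
            samples=n, ploidy=1, population_size=1.0, num_replicates=reps,
            random_seed=7)
        for ts in reps_ts:
            mts = msprime.sim_mutations(ts, rate=theta / 2.0, random_seed=5,
                                        discrete_genome=False)
            k = mts.diversity(span_normalise=False, mode="site")
            theirs.append(k)
        se = np.sqrt(np.var(ours) / reps + np.var(theirs) / reps)
        assert np.mean(ours) == pytest.approx(np.mean(theirs),
                                              abs=max(4 * se, 0.3))

    def test_tmrca_moments_match_theory(self):
        rng = np.random.default_rng(3)
        n = 10
        tm = []
        for _ in range(800):
            gen, _ = simulate_genealogy(
                Scenario(kind="constant", theta=1, n=n, seed=0), rng)
            tm.append(gen.tmrca)
        expect = 2.0 * (1.0 - 1.0 / n)
        se = np.std(tm) / np.sqrt(len(tm))
        assert np.mean(tm) == pytest.approx(expect, abs=4 * se)

    def test_expansion_mismatch_crest_near_tau(self):
        rng = np.random.default_rng(4)
        crests = []
        for _ in range(40):
            d = simulate_pairwise_differences(
                Scenario(kind="sudden_expansion", tau=10, theta0=1,
                         theta1=500, n=40, seed=0), rng)
            iu = np.triu_indices(40, 1)
            counts = np.bincount(d[iu].astype(int))
            crests.append(np.argmax(counts))
        assert np.mean(crests) == pytest.approx(10, abs=1.5)

    def test_transition_transversion_reflects_kappa(self):
        """Higher κ yields proportionally more transitions."""
        counts = {}
        for kappa in (1.0, 16.0):
            aln, _ = simulate_sample(Scenario(
                kind="constant", theta=12, n=20, seed=6, mutation_model="HKY",
                kappa=kappa, gamma_alpha=None))
            cls = classify_sites(aln)
            types = list(cls.substitution_types.values())
            ti = sum(t == "transition" for t in types)
            tv = sum(t == "transversion" for t in types)
            counts[kappa] = ti / max(tv, 1)
        assert counts[16.0] > 3 * counts[1.0]


class TestDeterminismAndValidation:
    def test_same_seed_byte_identical(self):
        sc = dict(kind="sudden_expansion", tau=8, theta0=1, theta1=100, n=12,
                  seed=42, doublet_hotspots=[(5, 6)])
        a1, t1 = simulate_sample(Scenario(**sc))
        a2, t2 = simulate_sample(Scenario(**sc))
        assert [r.seq for r in a1.records] == [r.seq for r in a2.records]
        assert t1.tmrca == t2.tmrca

    def test_invalid_scenarios_rejected(self):
        with pytest.raises(ScenarioError):
            Scenario(kind="warp", theta=1).validate()
        with pytest.raises(ScenarioError):
            Scenario(kind="constant", theta=-1).validate()
        with pytest.raises(ScenarioError):
            Scenario(kind="isolation_with_migration", theta=1, M=1,
                     T=None).validate()

    def test_im_sampled_demes_labelled(self):
        sc = Scenario(kind="isolation_with_migration", theta=4, M=1, T=1,
                      n=(5, 7), seed=1)
        aln, truth = simulate_sample(sc)
        assert [r.population for r in aln.records].count("P1") == 5
        assert truth.demes == [0] * 5 + [1] * 7


class TestStudyLikeDataset:
    def test_construction_shape(self, study_dataset):
        aln, truth = study_dataset
        pops = {p: sum(r.population == p for r in aln.records)
                for p in aln.populations}
        assert pops == {"SIN": 43, "SIN04": 26, "MICH": 31, "OAX": 50,
                        "CH": 47, "PE": 49}
        assert aln.length == 648
        assert len(truth.doublets_applied) == 5

    def test_odd_replicate_low_diversity_across_seeds(self):
        from sierrapop.diversity import diversity_summary
        hits = 0
        seeds = range(6)
        for seed in seeds:
            aln, _ = make_study_like_dataset(seed)
            pis = {p: diversity_summary(aln, p).pi for p in aln.populations}
            others = [v for k, v in pis.items() if k != "SIN04"]
            if pis["SIN04"] < 0.5 * np.median(others):
                hits += 1
        assert hits >= len(list(seeds)) - 1

    def test_pooling_flags_odd_replicate_end_to_end(self):
        """The pipeline's pooling rule isolates the odd temporal replicate."""
        from sierrapop.diversity import tn93_distance_matrix
        from sierrapop.structure import pool_temporal_samples
        hits = 0
        seeds = range(5)
        for seed in seeds:
            aln, _ = make_study_like_dataset(seed)
            sub = aln.subset(["SIN", "SIN04"])
            dm = tn93_distance_matrix(sub, 0.4)
            pops = {p: [r.id for r in sub.records if r.population == p]
                    for p in sub.populations}
            plan = pool_temporal_samples(dm, pops, ["SIN", "SIN04"],
                                         n_perm=199, seed=seed)
            if plan.flagged == ["SIN04"]:
                hits += 1
        assert hits >= 4
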