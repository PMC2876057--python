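"""Phi-statistics, AMOVA, pooling, Slatkin/UPGMA, Mantel, Bonferroni."""

import numpy as np
import pytest

from sierrapop.diversity import DistanceMatrix, raw_difference_matrix
from sierrapop.simulate import Scenario, simulate_sample
from sierrapop.structure import (
    HierarchyError, InfiniteDistanceError, SizeError, amova_ss_decomposition,
    bonferroni, hierarchical_amova, mantel_ibd, pairwise_phi_st,
    pool_temporal_samples, significance_stars, slatkin_linearize, slatkin_upgma,
)


def _pops_from(aln):
    return {p: [r.id for r in aln.records if r.population == p]
            for p in aln.populations}


def _split_pops(aln, n_a):
    ids = aln.ids
    return {"A": ids[:n_a], "B": ids[n_a:]}


class TestPairwisePhi:
    def test_identical_populations_phi_near_zero(self):
        aln, _ = simulate_sample(Scenario(kind="constant", theta=6, n=24, seed=1))
        dm = raw_difference_matrix(aln)
        res = pairwise_phi_st(dm, _split_pops(aln, 12), ("A", "B"),
                              n_perm=199, seed=0)
        assert abs(res.phi_st) < 0.12 and res.p > 0.05

    def test_fixed_difference_phi_one(self):
        d = np.zeros((6, 6))
        d[:3, 3:] = d[3:, :3] = 4.0
        dm = DistanceMatrix(labels=[f"s{i}" for i in range(6)], d=d,
                            model="raw_differences")
        res = pairwise_phi_st(dm, {"A": ["s0", "s1", "s2"],
                                   "B": ["s3", "s4", "s5"]},
                              ("A", "B"), n_perm=99, seed=0)
        assert res.phi_st == pytest.approx(1.0)

    def test_island_model_expectation(self):
        """Mean Φ̂_ST tracks 1/(1+2Nm) for a haploid two-deme island model."""
        M = 4.0              # 2Nm
        expect = 1.0 / (1.0 + 2.0 * M)   # two-deme scaled island expectation
        phis = []
        for seed in range(60):
            sc = Scenario(kind="isolation_with_migration", theta=10, M=M,
                          T=50.0, n=(12, 12), seed=seed, gamma_alpha=None)
            aln, _ = simulate_sample(sc)
            dm = raw_difference_matrix(aln)
            res = pairwise_phi_st(dm, _pops_from(aln), ("P1", "P2"),
                                  n_perm=1, seed=0)
            phis.append(res.phi_st)
        # generous band: finite-deme/finite-sample bias plus MC error
        assert np.mean(phis) == pytest.approx(expect, abs=0.06)

    def test_reproducible_and_order_invariant(self):
        aln, _ = simulate_sample(Scenario(kind="constant", theta=5, n=16, seed=7))
        dm = raw_difference_matrix(aln)
        pops = _split_pops(aln, 8)
        r1 = pairwise_phi_st(dm, pops, ("A", "B"), n_perm=299, seed=11)
        r2 = pairwise_phi_st(dm, pops, ("A", "B"), n_perm=299, seed=11)
        pops_shuffled = {k: list(reversed(v)) for k, v in pops.items()}
        r3 = pairwise_phi_st(dm, pops_shuffled, ("A", "B"), n_perm=299, seed=11)
        assert r1.p == r2.p == r3.p and r1.phi_st == r3.phi_st

    def test_small_population_rejected(self):
        aln, _ = simulate_sample(Scenario(kind="constant", theta=5, n=5, seed=0))
        dm = raw_difference_matrix(aln)
        with pytest.raises(SizeError):
            pairwise_phi_st(dm, {"A": aln.ids[:1], "B": aln.ids[1:]},
                            ("A", "B"), n_perm=9, seed=0)


class TestAmova:
    def test_components_conserve_total_ss(self, rng):
        for _ in range(20):
            n_pops = rng.integers(3, 6)
            sizes = rng.integers(3, 8, size=n_pops)
            N = sizes.sum()
            d = rng.random((N, N)) * 5
            d = d + d.T
            np.fill_diagonal(d, 0)
            pop_of = np.repeat(np.arange(n_pops), sizes)
            group_of = rng.integers(0, 2, size=n_pops)
            if len(set(group_of)) < 2:
                group_of[0] = 1 - group_of[0]
            ag, ap, wp, tot = amova_ss_decomposition(d ** 2, pop_of, group_of)
            assert ag + ap + wp == pytest.approx(tot, abs=1e-9)

    def test_two_identical_pops_per_group(self):
        aln, _ = simulate_sample(Scenario(kind="constant", theta=6, n=32, seed=5))
        dm = raw_difference_matrix(aln)
        ids = aln.ids
        pops = {f"P{i}": ids[8 * i:8 * (i + 1)] for i in range(4)}
        groups = {"P0": "g1", "P1": "g1", "P2": "g2", "P3": "g2"}
        res = hierarchical_amova(dm, pops, groups, n_perm=99, seed=0)
        assert abs(res.phi_ct) < 0.15 and abs(res.phi_sc) < 0.15
        total = (res.var_among_groups + res.var_among_pops + res.var_within)
        assert res.total_variance == pytest.approx(total)

    def test_between_group_divergence_only(self):
        """Two anciently diverged demes, each split into two recent samples."""
        sc = Scenario(kind="isolation_with_migration", theta=8, M=0.0, T=4.0,
                      n=(16, 16), seed=3, gamma_alpha=None)
        aln, _ = simulate_sample(sc)
        dm = raw_difference_matrix(aln)
        ids = aln.ids
        pops = {"A1": ids[:8], "A2": ids[8:16], "B1": ids[16:24],
                "B2": ids[24:]}
        groups = {"A1": "north", "A2": "north", "B1": "south", "B2": "south"}
        res = hierarchical_amova(dm, pops, groups, n_perm=99, seed=0)
        assert res.phi_ct > 0.2 and abs(res.phi_sc) < 0.1

    def test_one_pop_per_group_matches_pairwise(self):
        aln, _ = simulate_sample(Scenario(
            kind="isolation_with_migration", theta=8, M=1.0, T=0.5,
            n=(10, 10), seed=2, gamma_alpha=None))
        dm = raw_difference_matrix(aln)
        pops = _pops_from(aln)
        res_h = hierarchical_amova(dm, pops, {"P1": "g1", "P2": "g2"},
                                   n_perm=9, seed=0)
        res_p = pairwise_phi_st(dm, pops, ("P1", "P2"), n_perm=9, seed=0)
        assert res_h.phi_st == pytest.approx(res_p.phi_st, abs=1e-9)

    def test_single_group_rejected(self):
        aln, _ = simulate_sample(Scenario(kind="constant", theta=4, n=8, seed=1))
        dm = raw_difference_matrix(aln)
        with pytest.raises(HierarchyError):
            hierarchical_amova(dm, _split_pops(aln, 4),
                               {"A": "g", "B": "g"}, n_perm=9, seed=0)


class TestPooling:
    def test_null_replicates_pooled(self):
        aln, _ = simulate_sample(Scenario(kind="constant", theta=8, n=30, seed=4))
        dm = raw_difference_matrix(aln)
        ids = aln.ids
        pops = {"Y03": ids[:15], "Y08": ids[15:]}
        plan = pool_temporal_samples(dm, pops, ["Y03", "Y08"], n_perm=199,
                                     seed=0)
        assert set(plan.pooled) == {"Y03", "Y08"} and not plan.flagged

    def test_divergent_replicate_kept_and_flagged(self, study_dataset):
        from sierrapop.diversity import tn93_distance_matrix
        aln, _ = study_dataset
        sub = aln.subset(["SIN", "SIN04"])
        dm = tn93_distance_matrix(sub, 0.4)
        pops = {p: [r.id for r in sub.records if r.population == p]
                for p in sub.populations}
        # two replicates from SIN plus the odd year
        half = len(pops["SIN"]) // 2
        pops3 = {"SIN03": pops["SIN"][:half], "SIN08": pops["SIN"][half:],
                 "SIN04": pops["SIN04"]}
        plan = pool_temporal_samples(dm, pops3, ["SIN03", "SIN08", "SIN04"],
                                     n_perm=199, seed=1)
        assert set(plan.pooled) == {"SIN03", "SIN08"}
        assert plan.flagged == ["SIN04"]

    def test_single_replicate_unchanged(self):
        plan = pool_temporal_samples(None, {"X": []}, ["X"])
        assert plan.pooled == ["X"] and not plan.separate


class TestSlatkinUpgma:
    def test_linearization_closed_form(self):
        labels, D = slatkin_linearize(np.array([[0, 0.5], [0.5, 0]]))
        assert D[0, 1] == pytest.approx(1.0)

    def test_zero_phi_star_tree(self):
        D, newick = slatkin_upgma(np.zeros((4, 4)))
        assert np.all(D == 0)
        assert newick.count(":0") >= 3

    def test_negative_phi_clamped(self):
        with pytest.warns(UserWarning):
            _, D = slatkin_linearize(np.array([[0, -0.02], [-0.02, 0]]))
        assert D[0, 1] == 0.0

    def test_phi_one_infinite(self):
        with pytest.raises(InfiniteDistanceError):
            slatkin_linearize(np.array([[0, 1.0], [1.0, 0]]))

    def test_two_clade_structure_recovered(self):
        phi = np.full((4, 4), 0.2)
        phi[0, 1] = phi[1, 0] = phi[2, 3] = phi[3, 2] = 0.01
        np.fill_diagonal(phi, 0)
        _, newick = slatkin_upgma(phi, labels=["a", "b", "c", "d"])
        import dendropy
        t = dendropy.Tree.get(data=newick, schema="newick")
        clades = {frozenset(lf.taxon.label for lf in nd.leaf_iter())
                  for nd in t.preorder_node_iter() if not nd.is_leaf()}
        assert frozenset({"a", "b"}) in clades
        assert frozenset({"c", "d"}) in clades


class TestMantel:
    def test_perfect_linear_relation(self):
        geo = np.array([[0, 1, 2, 3], [1, 0, 1, 2], [2, 1, 0, 1],
                        [3, 2, 1, 0]], dtype=float)
        # M exactly linear (decreasing) in distance
        M = 10 - 2 * geo
        phi = 1.0 / (2 * M + 1)          # invert M=(1-phi)/(2phi)
        np.fill_diagonal(phi, 0)
        res = mantel_ibd(phi, geo, n_perm=999, seed=0)
        assert res.r2 == pytest.approx(1.0, abs=1e-9)
        assert res.p < 0.2               # only 24 distinct permutations

    def test_nonpositive_phi_excluded(self):
        phi = np.array([[0, 0.1, -0.05, 0.2],
                        [0.1, 0, 0.1, 0.1],
                        [-0.05, 0.1, 0, 0.1],
                        [0.2, 0.1, 0.1, 0]])
        geo = np.abs(np.subtract.outer(np.arange(4.0), np.arange(4.0)))
        with pytest.warns(UserWarning):
            res = mantel_ibd(phi, geo, n_perm=99, seed=0)
        assert len(res.excluded_pairs) == 1

    def test_three_populations_warn(self):
        phi = np.full((3, 3), 0.1)
        np.fill_diagonal(phi, 0)
        geo = np.abs(np.subtract.outer(np.arange(3.0), np.arange(3.0)))
        with pytest.warns(UserWarning, match="fewer than 4"):
            mantel_ibd(phi, geo, n_perm=99, seed=0)

    def test_exclude_population(self):
        phi = np.full((5, 5), 0.1)
        np.fill_diagonal(phi, 0)
        geo = np.abs(np.subtract.outer(np.arange(5.0), np.arange(5.0)))
        res = mantel_ibd(phi, geo, labels=list("abcde"), n_perm=99, seed=0,
                         exclude="e")
        assert "e" not in res.migrants.index


class TestBonferroni:
    def test_fifteen_tests_threshold(self):
        out = bonferroni([0.001] * 15, alpha=0.05)
        assert out["threshold"] == pytest.approx(0.05 / 15)

    def test_single_test(self):
        assert bonferroni([0.04], alpha=0.05)["significant"] == [True]

    def test_just_above_threshold_not_significant(self):
        out = bonferroni([0.0034] + [0.5] * 14, alpha=0.05)
        assert not out["significant"][0]

    def test_stars(self):
        assert significance_stars(0.0005) == "**"
        assert significance_stars(0.01) == "*"
        assert significance_stars(0.2) == ""
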