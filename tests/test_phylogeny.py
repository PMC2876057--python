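"""NJ trees, bootstrap supports, outgroup rooting, clock linearisation."""

import numpy as np
import pytest

from conftest import make_alignment
from sierrapop.diversity import DistanceMatrix
from sierrapop.phylogeny import (
    RootingError, TreeSizeError, bootstrap_support, linearize_tree, nj_tree,
    upgma_tree,
)
from sierrapop.sequences import Alignment, Record
from sierrapop.simulate import Scenario, simulate_sample


def _tip_distances(tree):
    pdm = tree.phylogenetic_distance_matrix()
    tn = tree.taxon_namespace
    labs = sorted(t.label for t in tn)
    out = {}
    for i, a in enumerate(labs):
        for b in labs[i + 1:]:
            out[(a, b)] = pdm.distance(tn.get_taxon(a), tn.get_taxon(b))
    return out


def _random_additive_matrix(rng, n=6):
    """Random rooted topology with positive branch lengths -> additive matrix."""
    import dendropy
    taxa = [f"t{i}" for i in range(n)]
    nodes = [(lab,) for lab in taxa]
    newick = {(lab,): lab for lab in taxa}
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        la, lb = rng.uniform(0.5, 3.0, size=2)
        merged = tuple(sorted(a + b))
        newick[merged] = f"({newick[a]}:{la:.4f},{newick[b]}:{lb:.4f})"
        nodes = [x for x in nodes if x not in (a, b)] + [merged]
    tree = dendropy.Tree.get(data=newick[nodes[0]] + ";", schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    tn = tree.taxon_namespace
    d = np.zeros((n, n))
    for i, a in enumerate(taxa):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.distance(tn.get_taxon(a),
                                             tn.get_taxon(taxa[j]))
    return taxa, d, tree


def _unrooted_bipartitions(tree, all_taxa):
    ref = sorted(all_taxa)[0]
    out = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = frozenset(all_taxa) - side
        if 1 < len(side) < len(all_taxa) - 1:
            out.add(side)
    return out


class TestNJ:
    def test_three_taxa_exact_branch_lengths(self):
        d = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], float)
        st = nj_tree(DistanceMatrix(labels=["a", "b", "c"], d=d, model="x"))
        dist = _tip_distances(st.tree)
        assert dist[("a", "b")] == pytest.approx(2.0)
        assert dist[("a", "c")] == pytest.approx(3.0)
        assert dist[("b", "c")] == pytest.approx(3.0)

    def test_four_taxon_additive_exact_recovery(self):
        labs = ["a", "b", "c", "d"]
        d = np.array([[0, 2, 5, 5], [2, 0, 5, 5],
                      [5, 5, 0, 2], [5, 5, 2, 0]], float)
        st = nj_tree(DistanceMatrix(labels=labs, d=d, model="x"))
        dist = _tip_distances(st.tree)
        for (i, a) in enumerate(labs):
            for j in range(i + 1, 4):
                assert dist[(a, labs[j])] == pytest.approx(d[i, j])

    def test_additive_topology_recovery_50_random_fixtures(self, rng):
        for _ in range(50):
            taxa, d, true_tree = _random_additive_matrix(rng)
            st = nj_tree(DistanceMatrix(labels=taxa, d=d, model="x"))
            assert _unrooted_bipartitions(st.tree, taxa) == \
                _unrooted_bipartitions(true_tree, taxa)

    def test_ultrametric_input_matches_upgma_topology(self, rng):
        # build an ultrametric matrix via a random UPGMA-like hierarchy
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform
        x = rng.random((7, 3))
        Z = linkage(x, method="average")
        from scipy.cluster.hierarchy import cophenet
        d = squareform(cophenet(Z))
        labs = [f"t{i}" for i in range(7)]
        dmat = DistanceMatrix(labels=labs, d=d, model="x")
        nj = nj_tree(dmat)
        up = upgma_tree(dmat)
        assert _unrooted_bipartitions(nj.tree, labs) == \
            _unrooted_bipartitions(up.tree, labs)

    def test_too_few_taxa(self):
        with pytest.raises(TreeSizeError):
            nj_tree(DistanceMatrix(labels=["a", "b"],
                                   d=np.array([[0, 1], [1, 0.0]]), model="x"))


class TestBootstrap:
    @pytest.fixture(scope="class")
    def split_alignment(self):
        sc = Scenario(kind="isolation_with_migration", theta=20, M=0.0, T=3.0,
                      n=(6, 6), seed=7, gamma_alpha=None)
        aln, _ = simulate_sample(sc)
        rng = np.random.default_rng(0)
        og = list(aln.records[0].seq)
        idx = rng.choice(len(og), size=160, replace=False)
        for i in idx:
            og[i] = "ACGT"[("ACGT".index(og[i]) + 2) % 4]
        return Alignment(records=aln.records
                         + [Record("OUT", "outgroup", 1999, "".join(og))])

    def test_deep_split_high_support(self, split_alignment):
        st = bootstrap_support(split_alignment, B=100, seed=1, outgroup="OUT")
        ingroup = [r.id for r in split_alignment.records
                   if r.population == "P2"]
        all_taxa = frozenset(r.id for r in split_alignment.records)
        ref = split_alignment.ids[0]
        side = frozenset(ingroup)
        canon = side if ref not in side else all_taxa - side
        assert st.supports[canon] >= 90
        assert st.rooted

    def test_single_replicate_supports_binary(self, split_alignment):
        st = bootstrap_support(split_alignment, B=1, seed=2, outgroup="OUT")
        assert set(st.supports.values()) <= {0.0, 100.0}

    def test_shuffled_columns_low_support(self, split_alignment):
        rng = np.random.default_rng(3)
        recs = []
        mat = np.array([list(r.seq) for r in split_alignment.records])
        for j in range(mat.shape[1]):
            rng.shuffle(mat[:, j])
        for r, row in zip(split_alignment.records, mat):
            recs.append(Record(r.id, r.population, r.year, "".join(row)))
        st = bootstrap_support(Alignment(records=recs), B=60, seed=4)
        assert np.mean(list(st.supports.values())) < 60

    def test_missing_outgroup_rejected(self, split_alignment):
        with pytest.raises(RootingError):
            bootstrap_support(split_alignment, B=1, seed=0, outgroup="NOPE")


class TestLinearize:
    def test_pairwise_divergence_definition(self):
        # two tips at distance 0.021 -> 1.0 Myr at 2.1 %/Myr
        import dendropy
        tree = dendropy.Tree.get(data="(a:0.0105,b:0.0105);", schema="newick")
        from sierrapop.phylogeny import SupportTree
        st = SupportTree(tree=tree, rooted=True)
        lin = linearize_tree(st, 0.021)
        assert max(lin.node_ages_years.values()) == pytest.approx(1.0e6)

    def test_zero_length_tree_all_zero_ages(self):
        import dendropy
        tree = dendropy.Tree.get(data="(a:0.0,(b:0.0,c:0.0):0.0);",
                                 schema="newick")
        from sierrapop.phylogeny import SupportTree
        lin = linearize_tree(SupportTree(tree=tree, rooted=True), 0.021)
        assert max(lin.node_ages_years.values()) == 0.0

    def test_unrooted_rejected(self):
        d = np.array([[0, 1, 2], [1, 0, 2], [2, 2, 0.0]])
        st = nj_tree(DistanceMatrix(labels=["a", "b", "c"], d=d, model="x"))
        with pytest.raises(RootingError):
            linearize_tree(st)

    def test_clock_data_age_recovery(self):
        """Simulated clock-like divergence linearises near the true age."""
        sc = Scenario(kind="isolation_with_migration", theta=2, M=0.0, T=8.0,
                      n=(5, 5), seed=21, gamma_alpha=None, mutation_model="HKY")
        aln, truth = simulate_sample(sc)
        st = bootstrap_support(aln, B=10, seed=0, outgroup=aln.ids[0])
        lin = linearize_tree(st, 0.021)
        # true root age in years given the simulation's mutation scaling:
        # tmrca (units of N gens) -> substitutions/site = tmrca * theta/2 / L
        depth_subs = truth.tmrca * 2.0 / 2.0 / 648
        expected_years = depth_subs / 0.0105 * 1e6
        got = max(lin.node_ages_years.values())
        assert got == pytest.approx(expected_years, rel=0.45)
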