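"""Distance-based haplotype trees: neighbour joining, bootstrap support,
outgroup rooting and clock linearisation.

Trees are built from TN93(+Γ) distances with the Saitou–Nei neighbour-joining
agglomeration (via dendropy) and supported by non-parametric bootstrap over
alignment columns.  Rooted trees can be linearised under a strict clock,
converting node depths to ages with a between-lineage divergence rate
(default 2.1%/Myr, i.e. a per-lineage rate of 1.05%/Myr — divergence rates
count changes on both lineages, so the per-lineage rate is half; the output
metadata records this to avoid factor-of-two drift).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .diversity import DistanceMatrix, SaturationError, tn93_distance_matrix
from .sequences import Alignment, Record

__all__ = ["SupportTree", "nj_tree", "bootstrap_support", "linearize_tree",
           "upgma_tree"]

DEFAULT_DIVERGENCE_RATE_PER_MYR = 0.021   # between-lineage, subs/site/Myr


class TreeSizeError(ValueError):
    pass


class RootingError(ValueError):
    pass


@dataclass
class SupportTree:
    """A dendropy tree plus support values and optional node ages."""

    tree: dendropy.Tree
    rooted: bool
    supports: dict[frozenset, float] = field(default_factory=dict)
    node_ages_years: dict[int, float] = field(default_factory=dict)
    negative_branches_fixed: int = 0
    metadata: dict = field(default_factory=dict)

    def newick(self) -> str:
        return self.tree.as_string(schema="newick",
                                   suppress_rooting=True).strip()


def _pdm_from_distance_matrix(dm: DistanceMatrix) -> dendropy.PhylogeneticDistanceMatrix:
    buf = io.StringIO()
    buf.write("," + ",".join(dm.labels) + "\n")
    for lab, row in zip(dm.labels, dm.d):
        buf.write(lab + "," + ",".join(f"{x:.12g}" for x in row) + "\n")
    buf.seek(0)
    return dendropy.PhylogeneticDistanceMatrix.from_csv(buf, delimiter=",")


def _fix_negative_branches(tree: dendropy.Tree) -> int:
    """Kuhner–Felsenstein adjustment: zero a negative branch and transfer its
    deficit to the parent edge so path lengths through it are preserved."""
    fixed = 0
    for node in tree.postorder_node_iter():
        e = node.edge
        if e.length is not None and e.length < 0:
            parent = node.parent_node
            if parent is not None and parent.edge.length is not None:
                parent.edge.length += e.length
            e.length = 0.0
            fixed += 1
    # a transfer can push the parent negative; clamp whatever remains
    for e in tree.preorder_edge_iter():
        if e.length is not None and e.length < 0:
            e.length = 0.0
            fixed += 1
    return fixed


def nj_tree(dm: DistanceMatrix) -> SupportTree:
    """Unrooted Saitou–Nei neighbour-joining tree from a distance matrix."""
    if len(dm.labels) < 3:
        raise TreeSizeError("neighbour joining needs >= 3 taxa")
    tree = _pdm_from_distance_matrix(dm).nj_tree()
    fixed = _fix_negative_branches(tree)
    if fixed:
        warnings.warn(f"{fixed} negative NJ branch(es) adjusted to zero")
    return SupportTree(tree=tree, rooted=False, negative_branches_fixed=fixed,
                       metadata={"method": "nj", "distance_model": dm.model})


def upgma_tree(dm: DistanceMatrix) -> SupportTree:
    """Ultrametric UPGMA (average-linkage) tree from a distance matrix."""
    if len(dm.labels) < 2:
        raise TreeSizeError("UPGMA needs >= 2 taxa")
    tree = _pdm_from_distance_matrix(dm).upgma_tree()
    return SupportTree(tree=tree, rooted=True,
                       metadata={"method": "upgma", "distance_model": dm.model})


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def _bipartitions(tree: dendropy.Tree, all_taxa: frozenset,
                  reference: str) -> set[frozenset]:
    """Non-trivial bipartitions as canonical leaf-label frozensets (the side
    not containing the reference taxon)."""
    out = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if reference in side:
            side = all_taxa - side
        if 1 < len(side) < len(all_taxa) - 1 or (len(side) > 1 and side != all_taxa):
            out.add(side)
    return out


def bootstrap_support(aln: Alignment, B: int = 1000, seed: int = 0,
                      outgroup: str | None = None,
                      gamma_alpha: float | None = 0.4) -> SupportTree:
    """NJ tree with column-resampling bootstrap supports, outgroup-rooted.

    Supports are the percentage of replicates containing each internal
    bipartition of the full-data tree (multiples of 100/B).  Replicates in
    which a resampled pair saturates the distance correction are skipped
    (with a warning) and the divisor reduced accordingly.
    """
    if outgroup is not None and outgroup not in aln.ids:
        raise RootingError(f"outgroup {outgroup!r} not in alignment")
    dm = tn93_distance_matrix(aln, gamma_alpha)
    base = nj_tree(dm)
    all_taxa = frozenset(dm.labels)
    ref = dm.labels[0]
    observed = _bipartitions(base.tree, all_taxa, ref)
    counts = {bp: 0 for bp in observed}

    rng = np.random.default_rng(seed)
    mat = aln.matrix()
    effective = 0
    for _ in range(B):
        cols = rng.integers(0, aln.length, size=aln.length)
        sub = mat[:, cols]
        bases = np.array(list("ACGTN"))
        # rebuild an Alignment around the resampled matrix (N for ambiguity)
        seqs = ["".join(np.where(row >= 0, bases[np.clip(row, 0, 3)], "N"))
                for row in sub]
        rep_aln = Alignment(records=[
            Record(r.id, r.population, r.year, s)
            for r, s in zip(aln.records, seqs)])
        try:
            rep_dm = tn93_distance_matrix(rep_aln, gamma_alpha)
        except SaturationError:
            continue
        rep_tree = _pdm_from_distance_matrix(rep_dm).nj_tree()
        _fix_negative_branches(rep_tree)
        rep_bps = _bipartitions(rep_tree, all_taxa, ref)
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
        effective += 1
    if effective < B:
        warnings.warn(f"{B - effective} bootstrap replicate(s) skipped "
                      "due to distance saturation")
    supports = {bp: 100.0 * c / effective if effective else 0.0
                for bp, c in counts.items()}

    tree = base.tree
    if outgroup is not None:
        node = tree.find_node_with_taxon_label(outgroup)
        if node is None:
            raise RootingError(f"outgroup {outgroup!r} not found in tree")
        half = (node.edge.length or 0.0) / 2.0
        tree.reroot_at_edge(node.edge, length1=half, length2=half,
                            update_bipartitions=False)
        rooted = True
    else:
        rooted = False
    # attach supports as internal-node labels
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        canon = side if ref not in side else all_taxa - side
        if canon in supports:
            node.label = f"{supports[canon]:.0f}"
    return SupportTree(tree=tree, rooted=rooted, supports=supports,
                       negative_branches_fixed=base.negative_branches_fixed,
                       metadata={"method": "nj+bootstrap", "B": B,
                                 "effective_B": effective,
                                 "outgroup": outgroup,
                                 "distance_model": dm.model})


# ---------------------------------------------------------------------------
# Clock linearisation
# ---------------------------------------------------------------------------

def linearize_tree(st: SupportTree,
                   divergence_rate_per_myr: float = DEFAULT_DIVERGENCE_RATE_PER_MYR
                   ) -> SupportTree:
    """Impose a strict clock and convert node depths to ages in years.

    Each node's age (subs/site) is the average path length to its descendant
    tips, clipped so parents are never younger than children; ages convert
    to years via the *between-lineage* divergence rate: a pair at TN93
    distance 0.021 diverged 1 Myr ago at 2.1%/Myr.
    """
    if not st.rooted:
        raise RootingError("linearisation needs a rooted tree")
    if divergence_rate_per_myr <= 0:
        raise ValueError("divergence rate must be positive")
    tree = st.tree
    per_lineage = divergence_rate_per_myr / 2.0
    depth: dict[int, tuple[float, int]] = {}
    ages: dict[int, float] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            depth[id(node)] = (0.0, 1)
            ages[id(node)] = 0.0
        else:
            tot, cnt = 0.0, 0
            for ch in node.child_nodes():
                s, c = depth[id(ch)]
                tot += s + (ch.edge.length or 0.0) * c
                cnt += c
            depth[id(node)] = (tot, cnt)
            mean_depth = tot / cnt
            age = mean_depth / per_lineage * 1.0e6
            kid_max = max(ages[id(ch)] for ch in node.child_nodes())
            ages[id(node)] = max(age, kid_max)
    node_ages = {}
    for node in tree.preorder_node_iter():
        node_ages[id(node)] = ages[id(node)]
        # rewrite branch lengths in years for an ultrametric output tree
        if node.parent_node is not None:
            node.edge.length = ages[id(node.parent_node)] - ages[id(node)]
    out = SupportTree(tree=tree, rooted=True, supports=st.supports,
                      node_ages_years=node_ages,
                      negative_branches_fixed=st.negative_branches_fixed,
                      metadata={**st.metadata,
                                "divergence_rate_per_myr": divergence_rate_per_myr,
                                "per_lineage_rate_per_myr": per_lineage,
                                "branch_length_unit": "years"})
    return out
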