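"""Population structure: pooling test, pairwise Phi_ST, AMOVA, Slatkin
UPGMA and isolation by distance.

Temporal replicates at the Sinaloa locality are tested first; the odd year
is expected to stay separate.  Pairwise Phi_ST values (TN93+Γ(0.4)
distances, permutation nulls, Bonferroni-corrected) feed the Slatkin
linearisation/UPGMA tree and the Mantel IBD test on migrant estimates.
"""

from pathlib import Path

import pandas as pd

from sierrapop.diversity import tn93_distance_matrix
from sierrapop.sequences import read_alignment
from sierrapop.structure import (
    bonferroni, hierarchical_amova, mantel_ibd, pairwise_phi_matrix,
    pool_temporal_samples, significance_stars, slatkin_upgma,
)

BASE = Path(__file__).resolve().parents[1] / "results"
SEED = 20100
N_PERM = 2009            # keeps the driver quick; the library default is 20100
GROUPS = {"SIN": "north", "SIN04": "north", "MICH": "north",
          "OAX": "central", "CH": "central", "PE": "south"}


def main() -> None:
    aln = read_alignment(BASE / "data" / "alignment.fasta",
                         BASE / "data" / "labels.tsv")
    dm = tn93_distance_matrix(aln, 0.4)
    pops = {p: [r.id for r in aln.records if r.population == p]
            for p in aln.populations}

    plan = pool_temporal_samples(dm, pops, ["SIN", "SIN04"], n_perm=N_PERM,
                                 seed=SEED)
    print(f"temporal pooling at Sinaloa: pooled={plan.pooled} "
          f"flagged={plan.flagged}")

    phi = pairwise_phi_matrix(dm, pops, n_perm=N_PERM, seed=SEED)
    thr = bonferroni(phi.p.tolist())["threshold"]
    phi["stars"] = phi.p.map(significance_stars)
    phi["bonferroni_significant"] = phi.p < thr
    phi.to_csv(BASE / "phi_st.tsv", sep="\t", index=False)
    print(f"\npairwise Phi_ST (Bonferroni threshold {thr:.4f}):")
    print(phi.to_string(index=False))

    res = hierarchical_amova(dm, pops, GROUPS, n_perm=999, seed=SEED)
    print(f"\nAMOVA north/central/south: Phi_CT={res.phi_ct:.3f} "
          f"(p={res.p_ct:.3f}), Phi_SC={res.phi_sc:.3f} (p={res.p_sc:.3f}), "
          f"Phi_ST={res.phi_st:.3f} (p={res.p_st:.3f})")

    _, newick = slatkin_upgma(phi)
    (BASE / "upgma_slatkin.nwk").write_text(newick + "\n")
    print(f"\nSlatkin/UPGMA population tree: {newick}")

    geo = pd.read_csv(BASE / "data" / "geo_nm.tsv", sep="\t", index_col=0)
    labels = sorted(set(phi.pop_a) | set(phi.pop_b))
    ibd = mantel_ibd(phi, geo.loc[labels, labels].to_numpy(float),
                     n_perm=N_PERM, seed=SEED, exclude="SIN04")
    print(f"\nIBD (SIN04 excluded): r^2 = {ibd.r2:.2f}, p = {ibd.p:.2f} "
          f"({len(ibd.excluded_pairs)} negative-Phi pairs dropped)")


if __name__ == "__main__":
    main()
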