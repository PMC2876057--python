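"""Molecular diversity per sample: n, haplotypes, h, pi, k, variable sites.

Reads the simulated dataset from step 01 and writes the Table-1-style
genetic-variability block.  The expected pattern: every sample near-maximal
haplotype diversity (h ~ 0.99-1.0), pi ~ 2%, except the founder-limited
SIN04 replicate at well under half the median pi.
"""

from pathlib import Path

from sierrapop.diversity import diversity_table
from sierrapop.sequences import read_alignment

BASE = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    aln = read_alignment(BASE / "data" / "alignment.fasta",
                         BASE / "data" / "labels.tsv")
    df = diversity_table(aln)
    df.to_csv(BASE / "diversity.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    odd = df.loc[df.population == "SIN04", "pi"].iloc[0]
    med = df.loc[df.population != "SIN04", "pi"].median()
    print(f"\nSIN04 pi = {odd:.4f} vs median {med:.4f} "
          f"({odd / med:.0%}): the chaotic-patchiness replicate")


if __name__ == "__main__":
    main()
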