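#!/usr/bin/env python
"""Per-gene shuffle test: how many genes change GC skew from 5' to 3'?

Applies the permutation test (100-bp end windows, 1,000 mononucleotide
shuffles, one-sided top-5% threshold) to the skewed synthetic species and
to the null set.  The skewed species should flag a large fraction of genes
(its 5' and 3' ends are built with opposite skews); the null set calibrates
the test's false-positive rate at ~5%.
"""

from pathlib import Path

from skewscape.io import extract_genes, read_annotations, read_fasta, read_orf_fasta
from skewscape.significance import significant_fraction

SEED = 20260928
ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "analysis_data"
OUT = ROOT / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    seqs = read_fasta(DATA / "species.fasta")
    genes = extract_genes(seqs, read_annotations(DATA / "species.gff3"), flank=0)
    frac, table = significant_fraction(genes, end_bp=100, n_shuffles=1000,
                                       alpha=0.05, seed=SEED + 10)
    table.to_csv(DATA / "shuffle_skewed.tsv", sep="\t", index=False)
    print(f"skewed species: {100 * frac:.1f}% of {len(genes)} genes show a "
          "significant 5'->3' GC-skew increase")

    null = read_orf_fasta(DATA / "null_orfs.fasta")
    frac0, table0 = significant_fraction(null, end_bp=100, n_shuffles=1000,
                                         alpha=0.05, seed=SEED + 11)
    table0.to_csv(DATA / "shuffle_null.tsv", sep="\t", index=False)
    print(f"null set: {100 * frac0:.1f}% flagged (type-I calibration; "
          "nominal 5%)")

    with open(OUT / "shuffle_summary.tsv", "w") as fh:
        fh.write("gene_set\tn_genes\tfraction_significant\n")
        fh.write(f"skewed\t{len(genes)}\t{frac:.4f}\n")
        fh.write(f"null\t{len(null)}\t{frac0:.4f}\n")


if __name__ == "__main__":
    main()
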