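#!/usr/bin/env python
"""Generate the synthetic study inputs: a skewed 'species' and a null set.

Writes a genome FASTA + GFF3 (plus truth JSON) for 2,000 codon-structured
ORFs of 1,500 bp whose coding-strand GC skew follows the three-regime
profile (5' C-biased ramp, mildly G-biased centre, 3' G-biased ramp), a
matched position-homogeneous null gene set, and expression/methylation
covariate tables.  Everything downstream (02-06) reads these files.

Outputs land in scratch/analysis_data/ (bulky sequence files) and are
reproducible from the fixed seed.
"""

from pathlib import Path

from skewscape.io import write_fasta
from skewscape.synthetic import (SyntheticSpec, emit_genome, generate_expression,
                                 generate_genes, generate_methylation,
                                 generate_null_genes, write_truth)

SEED = 20260928
DATA = Path(__file__).resolve().parents[1] / "scratch" / "analysis_data"


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)

    spec = SyntheticSpec(seed=SEED, orf_mode=True)  # defaults: 2000 x 1500 bp
    genes, truth = generate_genes(spec)
    emit_genome(genes, DATA / "species.fasta", DATA / "species.gff3",
                intergenic_len=200, seed=SEED + 1)
    write_truth(truth, DATA / "species.truth.json")
    print(f"skewed species: {len(genes)} ORFs "
          f"(a={spec.a}, b={spec.b:.0f}, c={spec.c}, d={spec.d:.0f}, e={spec.e})")

    null = generate_null_genes(2000, length=600, gc_content=0.40, seed=SEED + 2)
    write_fasta({g.gene_id: g.cds for g in null}, DATA / "null_orfs.fasta")
    print(f"null set: {len(null)} position-homogeneous genes of 600 bp")

    expr = generate_expression(genes, rho5=-0.10, rho3=0.07, seed=SEED + 3)
    with open(DATA / "expression.tsv", "w") as fh:
        for k, v in expr.items():
            fh.write(f"{k}\t{v:.6g}\n")
    meth = generate_methylation(genes, n_methylated=150, seed=SEED + 4)
    with open(DATA / "methylation.tsv", "w") as fh:
        for k, v in meth.items():
            fh.write(f"{k}\t{v:.6g}\n")
    print("covariates: expression for all genes (weak end-skew coupling), "
          "methylation levels for a random subset of 150")


if __name__ == "__main__":
    main()
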