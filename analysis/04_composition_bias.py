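#!/usr/bin/env python
"""Terminal composition biases: nucleotides, amino acids, codon positions.

On the skewed synthetic species, compares base and residue usage between
the first 21 and last 20 codons, reports per-residue chi-square tests and
codon GC-skew colouring, and profiles the skew separately at the three
codon positions and at fourfold-degenerate third positions (split by
expression decile).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from skewscape.composition import (codon_position_skew,
                                   fourfold_degenerate_skew, terminal_aa_bias,
                                   terminal_nucleotide_ratios)
from skewscape.io import (extract_genes, read_annotations, read_fasta,
                          read_two_column_tsv)

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "analysis_data"
OUT = ROOT / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    seqs = read_fasta(DATA / "species.fasta")
    genes = extract_genes(seqs, read_annotations(DATA / "species.gff3"), flank=0)

    nt = terminal_nucleotide_ratios(genes)
    nt.to_frame().to_csv(OUT / "nucleotide_ratios.tsv", sep="\t")
    print("5'/3' nucleotide frequency ratios:",
          ", ".join(f"{b}={nt[b]:.2f}" for b in "ACGT"))
    print("  (C > 1: C-enrichment at 5' ends; G < 1: G-enrichment at 3' ends)")

    aa = terminal_aa_bias(genes, drop_initial_met=True)
    aa.to_csv(OUT / "aa_bias.tsv", sep="\t", index=False)
    sig = aa[aa["chi2_p"] < 0.001]
    print(f"{len(sig)}/{len(aa)} residues biased at P < 0.001; "
          "top 5'-enriched:",
          ", ".join(aa.head(3)["residue"]),
          "| top 3'-enriched:", ", ".join(aa.tail(3)["residue"]))

    pos = pd.DataFrame(
        {f"position_{k}": codon_position_skew(genes, k, n_bins=40) for k in (1, 2, 3)}
    )
    pos.to_csv(OUT / "codon_position_skew.tsv", sep="\t", index_label="bin")
    print("codon-position skew (bin 1 -> bin 40 change):",
          ", ".join(f"p{k}: {pos[f'position_{k}'].iloc[0]:+.2f}->"
                    f"{pos[f'position_{k}'].iloc[-1]:+.2f}" for k in (1, 2, 3)))

    expr = read_two_column_tsv(DATA / "expression.tsv")
    ff = fourfold_degenerate_skew(genes, expression=expr, quantile=0.10, n_bins=40)
    pd.DataFrame(ff).to_csv(OUT / "fourfold_skew.tsv", sep="\t", index_label="bin")
    print(f"fourfold-degenerate third-base skew, gene-body mean: "
          f"all={np.nanmean(ff['all']):+.3f}, "
          f"low-expression decile={np.nanmean(ff['low']):+.3f}, "
          f"high={np.nanmean(ff['high']):+.3f}")


if __name__ == "__main__":
    main()
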