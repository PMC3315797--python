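"""Terminal nucleotide/amino-acid biases and codon-resolved skews.

The 5' window is the first 21 codons of a strict ORF (including the
initiator Met) and the 3' window the last 20 codons before the stop; the
stop codon itself is never counted.  Per-residue enrichment between the
windows is tested with a plain 2x2 chi-square (this residue vs all others,
5' vs 3' window, no continuity correction), and each residue carries the
mean GC skew of its synonymous codons for interpretation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable as _BioCodonTable
from Bio.Seq import Seq
from scipy import stats

from ._nucl import encode
from .io import OrientedGene
from .skew import BinnedMetagene, Pair, binned_metagene, seq_skew, skew

logger = logging.getLogger(__name__)

NUCLEOTIDES = "ACGT"

#: NCBI translation table ids: 1 = standard nuclear; 12 = alternative yeast
#: nuclear (CUG-clade, CUG -> Ser), relevant for Candida albicans.
STANDARD_TABLE = 1
CUG_CLADE_TABLE = 12


@dataclass
class AminoAcidBias:
    residue: str
    count5: int
    count3: int
    ratio5to3: float
    codon_skew: float
    chi2_p: float


def codon_table(table_id: int = STANDARD_TABLE) -> dict[str, str]:
    """Codon -> residue map (DNA alphabet) for an NCBI table id; stops as '*'."""
    tbl = _BioCodonTable.unambiguous_dna_by_id[table_id]
    out = dict(tbl.forward_table)
    for stop in tbl.stop_codons:
        out[stop] = "*"
    if len(out) != 64:
        raise ValueError(f"table {table_id} does not cover all 64 codons")
    return out


def codon_gc_skew(
    residue: str,
    table_id: int = STANDARD_TABLE,
    weights: Literal["uniform", "usage"] = "uniform",
    usage: Mapping[str, float] | None = None,
) -> float:
    """Mean GC skew of the codons encoding ``residue``.

    Codons with no G or C (skew undefined) are excluded from the mean; with
    ``weights='usage'`` the mean is weighted by the supplied codon usage.
    """
    tbl = codon_table(table_id)
    codons = [c for c, aa in tbl.items() if aa == residue]
    if not codons:
        raise ValueError(f"residue {residue!r} not encoded by table {table_id}")
    skews = np.array([seq_skew(c) for c in codons])
    ok = ~np.isnan(skews)
    if not ok.any():
        return np.nan
    if weights == "usage":
        if usage is None:
            raise ValueError("usage weights requested but no usage supplied")
        w = np.array([usage.get(c, 0.0) for c in codons])
        w = np.where(ok, w, 0.0)
        if w.sum() == 0:
            return np.nan
        return float(np.dot(np.where(ok, skews, 0.0), w) / w.sum())
    return float(skews[ok].mean())


def _eligible(genes: Sequence[OrientedGene], n5: int, n3: int) -> list[OrientedGene]:
    """Strict ORFs long enough for disjoint windows plus the stop codon."""
    need = 3 * (n5 + n3 + 1)
    kept = [g for g in genes if g.is_strict_orf() and len(g.cds) >= need]
    if len(kept) < len(genes):
        logger.info("%d gene(s) excluded (not strict ORF or shorter than %d bp)",
                    len(genes) - len(kept), need)
    return kept


def _windows(gene: OrientedGene, n5: int, n3: int) -> tuple[str, str]:
    """(5' window, 3' window) nucleotide strings; stop codon excluded."""
    cds = gene.cds
    return cds[: 3 * n5], cds[len(cds) - 3 * (n3 + 1) : len(cds) - 3]


def terminal_nucleotide_ratios(
    genes: Sequence[OrientedGene],
    n5_codons: int = 21,
    n3_codons: int = 20,
) -> pd.Series:
    """5'/3' frequency ratio of each nucleotide over pooled terminal windows."""
    kept = _eligible(genes, n5_codons, n3_codons)
    if not kept:
        raise ValueError("no eligible genes")
    c5 = np.zeros(4, dtype=np.int64)
    c3 = np.zeros(4, dtype=np.int64)
    for g in kept:
        w5, w3 = _windows(g, n5_codons, n3_codons)
        c5 += np.bincount(encode(w5)[encode(w5) >= 0], minlength=4)[:4]
        c3 += np.bincount(encode(w3)[encode(w3) >= 0], minlength=4)[:4]
    f5 = c5 / c5.sum()
    f3 = c3 / c3.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(f3 > 0, f5 / np.where(f3 > 0, f3, 1), np.nan)
    return pd.Series(ratio, index=list(NUCLEOTIDES), name="ratio_5_to_3")


def terminal_aa_bias(
    genes: Sequence[OrientedGene],
    n5_codons: int = 21,
    n3_codons: int = 20,
    drop_initial_met: bool = False,
    table_id: int = STANDARD_TABLE,
) -> pd.DataFrame:
    """Per-residue 5'-vs-3' usage bias over the terminal windows.

    Returns one row per residue (ranked by ratio5to3, descending) with
    counts, the 5'/3' frequency ratio, the mean GC skew of the residue's
    codons, and the 2x2 chi-square p-value.  ``drop_initial_met`` excludes
    the first residue of every gene (always Met in strict ORFs) from the 5'
    counts, since it is positionally forced rather than compositionally
    biased.
    """
    kept = _eligible(genes, n5_codons, n3_codons)
    if not kept:
        raise ValueError("no eligible genes")
    counts5: dict[str, int] = {}
    counts3: dict[str, int] = {}
    for g in kept:
        w5, w3 = _windows(g, n5_codons, n3_codons)
        aa5 = str(Seq(w5).translate(table=table_id))
        aa3 = str(Seq(w3).translate(table=table_id))
        if drop_initial_met:
            aa5 = aa5[1:]
        for r in aa5:
            counts5[r] = counts5.get(r, 0) + 1
        for r in aa3:
            counts3[r] = counts3.get(r, 0) + 1
    residues = sorted(set(counts5) | set(counts3))
    total5 = sum(counts5.values())
    total3 = sum(counts3.values())
    rows = []
    for r in residues:
        k5 = counts5.get(r, 0)
        k3 = counts3.get(r, 0)
        if k5 + k3 == 0 or total5 == 0 or total3 == 0:
            ratio = np.nan
        elif k3 == 0:
            ratio = np.nan
        else:
            ratio = (k5 / total5) / (k3 / total3)
        table = np.array([[k5, total5 - k5], [k3, total3 - k3]])
        if k5 + k3 == 0:
            p = 1.0
        else:
            expected = stats.contingency.expected_freq(table)
            if (expected < 5).any():
                warnings.warn(
                    f"residue {r}: expected count < 5 in chi-square table",
                    stacklevel=2,
                )
            _, p, _, _ = stats.chi2_contingency(table, correction=False)
        rows.append(AminoAcidBias(r, k5, k3, ratio, codon_gc_skew(r, table_id), float(p)))
    df = pd.DataFrame([vars(b) for b in rows])
    return df.sort_values("ratio5to3", ascending=False, na_position="last").reset_index(drop=True)


def codon_position_skew(
    genes: Sequence[OrientedGene],
    position: int,
    n_bins: int = 40,
    pair: Pair = "GC",
) -> np.ndarray:
    """Binned metagene skew restricted to one codon position (1, 2 or 3)."""
    kept = [g for g in genes if g.is_strict_orf()]
    if not kept:
        raise ValueError("no strict-ORF genes")
    mg = binned_metagene(kept, n_bins=n_bins, flank_bp=0, codon_position=position)
    return mg.body_skew(pair)


def fourfold_degenerate_prefixes(table_id: int = STANDARD_TABLE) -> frozenset[str]:
    """Dinucleotide prefixes whose four codons all encode the same residue."""
    tbl = codon_table(table_id)
    out = set()
    for p in (a + b for a in NUCLEOTIDES for b in NUCLEOTIDES):
        aas = {tbl[p + x] for x in NUCLEOTIDES}
        if len(aas) == 1 and "*" not in aas:
            out.add(p)
    return frozenset(out)


def fourfold_degenerate_skew(
    genes: Sequence[OrientedGene],
    expression: Mapping[str, float] | None = None,
    quantile: float = 0.10,
    n_bins: int = 40,
    pair: Pair = "GC",
    table_id: int = STANDARD_TABLE,
) -> dict[str, np.ndarray]:
    """Binned skew at third bases of fourfold-degenerate codons.

    Returns a dict with key 'all' and, when an expression table is given,
    'low'/'high' for the bottom/top expression quantile gene sets.
    """
    kept = [g for g in genes if g.is_strict_orf()]
    if not kept:
        raise ValueError("no strict-ORF genes")
    prefixes = fourfold_degenerate_prefixes(table_id)

    def _pooled(gene_set: Sequence[OrientedGene]) -> np.ndarray:
        body = np.zeros((n_bins, 4), dtype=np.int64)
        for g in gene_set:
            codes = encode(g.cds)
            L = len(codes)
            mask = np.zeros(L, dtype=bool)
            for i in range(0, L - 2, 3):
                if g.cds[i : i + 2] in prefixes:
                    mask[i + 2] = True
            bins = (np.arange(L) * n_bins) // L
            valid = mask & (codes >= 0)
            np.add.at(body, (bins[valid], codes[valid].astype(np.intp)), 1)
        return skew(body, pair)

    out = {"all": _pooled(kept)}
    if expression is not None:
        matched = [g for g in kept if g.gene_id in expression]
        matched.sort(key=lambda g: expression[g.gene_id])
        k = int(len(matched) * quantile)
        if k < 10:
            warnings.warn(f"only {k} genes per expression decile", stacklevel=2)
        if 2 * k > len(matched):
            raise ValueError("quantile too large: deciles would overlap")
        out["low"] = _pooled(matched[:k])
        out["high"] = _pooled(matched[-k:])
    return out


def count_fourfold_sites(gene: OrientedGene, table_id: int = STANDARD_TABLE) -> int:
    """Number of fourfold-degenerate third positions in one strict ORF."""
    prefixes = fourfold_degenerate_prefixes(table_id)
    return sum(
        1
        for i in range(0, len(gene.cds) - 2, 3)
        if gene.cds[i : i + 2] in prefixes
    )
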