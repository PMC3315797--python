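"""Synthetic gene sets and genomes with known, configurable skew structure.

Composition is generated directly (no substitution-process simulation): the
target coding-strand GC skew at each position follows a three-regime
profile — a linear 5' ramp, a flat centre and a linear 3' ramp — plus a
constant AT skew.  A target skew s at GC content g maps to base
probabilities P(G) = g(1+s)/2, P(C) = g(1-s)/2, and analogously A/T from
the AT skew.  Flanks get their own constant skews (promoter and 3' UTR).

Every generator takes a seed and is reproducible bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._nucl import decode, revcomp
from .io import STOP_CODONS, GeneRecord, OrientedGene, write_fasta

_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]


def three_line_skew(x: np.ndarray, length: int, a: float, b: float, c: float,
                    d: float, e: float) -> np.ndarray:
    """Target GC skew at 0-based position ``x`` of a gene of ``length`` bp.

    s(x) = c + a*max(0, 1 - x/b) + e*max(0, 1 - u/d) with u = bp from the
    last base (u = length-1-x).  At the first base s = c + a; the 5' ramp
    ends b bp in; the 3' ramp starts d bp before the end where s = c + e.
    b = 0 or d = 0 disables the corresponding ramp.
    """
    x = np.asarray(x, dtype=float)
    s = np.full_like(x, float(c))
    if b > 0:
        s = s + a * np.maximum(0.0, 1.0 - x / b)
    if d > 0:
        u = (length - 1) - x
        s = s + e * np.maximum(0.0, 1.0 - u / d)
    return s


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic gene-set generator.

    Defaults describe a strongly skewed gene set: GC content 0.40, a
    negative 5' ramp (a=-0.3 over b=300 bp), a mildly positive centre
    (c=0.1), a positive 3' ramp (e=0.2 starting d=200 bp before the stop),
    a small constant positive AT skew, a C-biased promoter and a G-biased
    3' UTR, with per-position Gaussian jitter of the target skew.
    """

    n_genes: int = 2000
    length: int | tuple[int, int] = 1500
    gc_content: float = 0.40
    at_skew: float = 0.05
    a: float = -0.3
    b: float = 300.0
    c: float = 0.1
    d: float = 200.0
    e: float = 0.2
    promoter_skew: float = -0.4
    utr_skew: float = 0.2
    flank_bp: int = 200
    noise_sd: float = 0.02
    orf_mode: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")
        peak = abs(self.c) + abs(self.a) + abs(self.e)
        if peak > 1 or abs(self.at_skew) > 1:
            raise ValueError("implied skews exceed [-1, 1]; infeasible base probabilities")


def _draw_bases(rng: np.random.Generator, gc_skew: np.ndarray, gc_content: float,
                at_skew: float) -> np.ndarray:
    """Sample one base per position from the skew-implied probabilities."""
    s = np.clip(np.asarray(gc_skew, dtype=float), -1.0, 1.0)
    g = gc_content
    n = len(s)
    probs = np.empty((n, 4))
    probs[:, 0] = (1 - g) * (1 + at_skew) / 2  # A
    probs[:, 1] = g * (1 - s) / 2  # C
    probs[:, 2] = g * (1 + s) / 2  # G
    probs[:, 3] = (1 - g) * (1 - at_skew) / 2  # T
    cum = np.cumsum(probs, axis=-1)
    u = rng.random(n)
    return np.minimum((u[:, None] > cum).sum(axis=-1), 3).astype(np.int8)


def _gene_length(rng: np.random.Generator, length, orf_mode: bool) -> int:
    if isinstance(length, (tuple, list)):
        lo, hi = length
        L = int(rng.integers(lo, hi + 1))
    else:
        L = int(length)
    if orf_mode:
        L -= L % 3
        L = max(L, 9)
    return L


def _enforce_orf(rng: np.random.Generator, codes: np.ndarray,
                 probs_skew: np.ndarray, gc: float, at: float) -> np.ndarray:
    """Force ATG start and a stop end; resample in-frame internal stops."""
    stop_code = {"TAA": (3, 0, 0), "TAG": (3, 0, 2), "TGA": (3, 2, 0)}
    codes = codes.copy()
    codes[0:3] = (0, 3, 2)  # ATG
    codes[-3:] = stop_code[str(rng.choice(["TAA", "TAG", "TGA"]))]
    stops = {(3, 0, 0), (3, 0, 2), (3, 2, 0)}
    for i in range(3, len(codes) - 3, 3):
        tries = 0
        while tuple(codes[i : i + 3]) in stops:
            codes[i : i + 3] = _draw_bases(rng, probs_skew[i : i + 3], gc, at)
            tries += 1
            if tries > 200:  # pragma: no cover - astronomically unlikely
                codes[i : i + 3] = (0, 0, 0)
    return codes


def generate_genes(spec: SyntheticSpec) -> tuple[list[OrientedGene], dict]:
    """Generate genes following the spec's three-regime skew profile.

    Returns the gene list and a truth record holding the parameters; the
    target profile at any position is recomputable via
    :func:`three_line_skew` with the recorded a..e.
    """
    rng = np.random.default_rng(spec.seed)
    genes: list[OrientedGene] = []
    for i in range(spec.n_genes):
        L = _gene_length(rng, spec.length, spec.orf_mode)
        target = three_line_skew(np.arange(L), L, spec.a, spec.b, spec.c, spec.d, spec.e)
        if spec.noise_sd > 0:
            target = target + rng.normal(0.0, spec.noise_sd, size=L)
        target = np.clip(target, -1.0, 1.0)
        codes = _draw_bases(rng, target, spec.gc_content, spec.at_skew)
        if spec.orf_mode:
            codes = _enforce_orf(rng, codes, target, spec.gc_content, spec.at_skew)
        up = dn = ""
        if spec.flank_bp > 0:
            up_codes = _draw_bases(
                rng, np.full(spec.flank_bp, spec.promoter_skew), spec.gc_content, spec.at_skew
            )
            dn_codes = _draw_bases(
                rng, np.full(spec.flank_bp, spec.utr_skew), spec.gc_content, spec.at_skew
            )
            up, dn = decode(up_codes), decode(dn_codes)
        genes.append(OrientedGene(gene_id=f"synth{i:05d}", cds=decode(codes),
                                  upstream=up, downstream=dn))
    truth = asdict(spec)
    truth["gene_ids"] = [g.gene_id for g in genes]
    return genes, truth


def generate_null_genes(
    n: int,
    length: int = 600,
    gc_content: float = 0.40,
    seed: int | None = None,
    flank_bp: int = 0,
) -> list[OrientedGene]:
    """Position-homogeneous i.i.d. genes: P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2."""
    rng = np.random.default_rng(seed)
    genes = []
    for i in range(n):
        codes = _draw_bases(rng, np.zeros(length), gc_content, 0.0)
        up = dn = ""
        if flank_bp:
            up = decode(_draw_bases(rng, np.zeros(flank_bp), gc_content, 0.0))
            dn = decode(_draw_bases(rng, np.zeros(flank_bp), gc_content, 0.0))
        genes.append(OrientedGene(gene_id=f"null{i:05d}", cds=decode(codes),
                                  upstream=up, downstream=dn))
    return genes


def generate_codon_genes(
    n_genes: int,
    n_codons: int,
    codon_probs: Mapping[str, float] | None = None,
    window_overrides: Sequence[tuple[slice, Mapping[str, float]]] = (),
    seed: int | None = None,
) -> list[OrientedGene]:
    """Codon-structured ORFs with controllable per-window codon usage.

    Each gene is ATG + (n_codons - 2) sense codons + TAA.  ``codon_probs``
    weights the 61 sense codons (uniform by default); ``window_overrides``
    replaces the weights on a slice of codon indices (0 = the ATG), e.g.
    ``(slice(-21, -1), {...})`` for the 20 codons before the stop.
    """
    if n_codons < 3:
        raise ValueError("n_codons must be >= 3 (start + one sense + stop)")
    rng = np.random.default_rng(seed)

    def _p(weights: Mapping[str, float] | None) -> np.ndarray:
        w = np.ones(len(_SENSE_CODONS))
        if weights:
            for cod, wt in weights.items():
                if cod in STOP_CODONS:
                    raise ValueError(f"cannot weight stop codon {cod}")
                w[_SENSE_CODONS.index(cod)] = wt
        return w / w.sum()

    base_p = _p(codon_probs)
    probs_per_codon = np.tile(base_p, (n_codons, 1))
    idx = np.arange(n_codons)
    for sl, weights in window_overrides:
        probs_per_codon[idx[sl]] = _p(weights)

    # sample column-wise: one vectorised draw per codon position
    picks = np.empty((n_genes, n_codons - 2), dtype=np.int64)
    for j in range(1, n_codons - 1):
        picks[:, j - 1] = rng.choice(len(_SENSE_CODONS), size=n_genes, p=probs_per_codon[j])
    sense = np.array(_SENSE_CODONS)
    genes = []
    for i in range(n_genes):
        cds = "ATG" + "".join(sense[picks[i]]) + "TAA"
        genes.append(OrientedGene(gene_id=f"cod{i:05d}", cds=cds))
    return genes


def generate_expression(
    genes: Sequence[OrientedGene],
    rho5: float = 0.0,
    rho3: float = 0.0,
    end_bp: int = 75,
    seed: int | None = None,
) -> dict[str, float]:
    """Per-gene expression levels with target correlation to end-window skews.

    Latent log-levels are rho5*z5 + rho3*z3 + independent noise, where z5/z3
    are standardised end-window GC skews; returned levels are exponentiated
    (heavy-tailed, like RNA-seq abundance estimates).
    """
    from .skew import seq_skew

    rng = np.random.default_rng(seed)
    s5 = np.array([seq_skew(g.cds[:end_bp]) for g in genes])
    s3 = np.array([seq_skew(g.cds[-end_bp:]) for g in genes])

    def _z(v: np.ndarray) -> np.ndarray:
        v = np.where(np.isnan(v), np.nanmean(v), v)
        sd = v.std()
        return (v - v.mean()) / (sd if sd > 0 else 1.0)

    resid = max(0.0, 1.0 - rho5 ** 2 - rho3 ** 2) ** 0.5
    latent = rho5 * _z(s5) + rho3 * _z(s3) + resid * rng.standard_normal(len(genes))
    levels = np.exp(latent)
    return {g.gene_id: float(v) for g, v in zip(genes, levels)}


def generate_methylation(
    genes: Sequence[OrientedGene],
    n_methylated: int = 150,
    seed: int | None = None,
) -> dict[str, float]:
    """A random methylated subset with lognormal levels (null association)."""
    rng = np.random.default_rng(seed)
    ids = [g.gene_id for g in genes]
    chosen = rng.choice(len(ids), size=min(n_methylated, len(ids)), replace=False)
    return {ids[i]: float(v) for i, v in zip(chosen, rng.lognormal(0.0, 1.0, len(chosen)))}


def emit_genome(
    genes: Sequence[OrientedGene],
    fasta_path: str | Path,
    gff_path: str | Path,
    intergenic_len: int = 500,
    gc_content: float = 0.40,
    seed: int | None = None,
    contig_id: str = "contig1",
) -> list[GeneRecord]:
    """Place genes on a contig with random strands and write FASTA + GFF3.

    Each gene's own flanks are embedded in the contig immediately around its
    CDS (spacers of ``intergenic_len`` random bases separate the flank
    blocks), so re-extraction through :func:`skewscape.io.extract_genes`
    with the same flank length reproduces the input genes exactly.
    """
    rng = np.random.default_rng(seed)
    pieces: list[str] = []
    records: list[GeneRecord] = []
    pos = 0

    def _spacer() -> str:
        if intergenic_len <= 0:
            return ""
        return decode(_draw_bases(rng, np.zeros(intergenic_len), gc_content, 0.0))

    sp = _spacer()
    pieces.append(sp)
    pos += len(sp)
    for gene in genes:
        strand = "+" if rng.random() < 0.5 else "-"
        block_fwd = gene.upstream + gene.cds + gene.downstream
        if strand == "+":
            block = block_fwd
            cds_start = pos + len(gene.upstream)
        else:
            block = revcomp(block_fwd)
            cds_start = pos + len(gene.downstream)
        cds_end = cds_start + len(gene.cds)
        pieces.append(block)
        pos += len(block)
        records.append(GeneRecord(gene_id=gene.gene_id, chrom=contig_id,
                                  start=cds_start, end=cds_end, strand=strand))
        sp = _spacer()
        pieces.append(sp)
        pos += len(sp)

    contig = "".join(pieces)
    write_fasta({contig_id: contig}, fasta_path)
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {contig_id} 1 {len(contig)}\n")
        for r in records:
            gid = r.gene_id
            fh.write(
                f"{contig_id}\tskewscape\tgene\t{r.start + 1}\t{r.end}\t.\t{r.strand}\t.\tID={gid}\n"
            )
            fh.write(
                f"{contig_id}\tskewscape\tCDS\t{r.start + 1}\t{r.end}\t.\t{r.strand}\t0\t"
                f"ID={gid}.cds;Parent={gid}\n"
            )
    return records


def write_truth(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1)
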