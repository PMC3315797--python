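"""Genome input: FASTA sequences, GFF3/GTF annotations, coding-strand extraction.

All internal coordinates are 0-based half-open; conversion from GFF's
1-based inclusive convention happens once, inside :func:`read_annotations`.
Minus-strand genes are reverse-complemented at extraction so that ``cds``,
``upstream`` and ``downstream`` are all in coding-strand orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
from Bio import SeqIO

from ._nucl import IUPAC_NUCLEOTIDES, revcomp

logger = logging.getLogger(__name__)

STOP_CODONS = ("TAA", "TAG", "TGA")


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input; message names the offending line."""


@dataclass
class SequenceSet:
    """Named nucleotide sequences, stored upper-case.

    Invariants: ids unique (enforced by the dict), lengths > 0, characters
    restricted to IUPAC nucleotide codes.
    """

    records: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, key: str) -> str:
        return self.records[key]

    def __contains__(self, key: str) -> bool:
        return key in self.records

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def items(self):
        return self.records.items()


@dataclass
class GeneRecord:
    """One gene's genomic location: 0-based half-open coordinates.

    ``intervals`` holds the CDS parts, sorted ascending and non-overlapping;
    ``start``/``end`` span the union.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.intervals:
            self.intervals = [(self.start, self.end)]
        self.intervals = sorted(self.intervals)
        for (s0, e0), (s1, _e1) in zip(self.intervals, self.intervals[1:]):
            if s1 < e0:
                raise ValueError(f"overlapping intervals in gene {self.gene_id}")
        if self.start > self.end:
            raise ValueError(f"start > end in gene {self.gene_id}")


@dataclass
class OrientedGene:
    """A gene's coding-strand sequence plus flanks.

    ``upstream`` is 5' of the start codon and ``downstream`` 3' of the stop,
    both in coding-strand orientation.  ``truncated_5``/``truncated_3`` flag
    flanks shortened by a contig edge.
    """

    gene_id: str
    cds: str
    upstream: str = ""
    downstream: str = ""
    truncated_5: bool = False
    truncated_3: bool = False

    def __len__(self) -> int:
        return len(self.cds)

    def is_strict_orf(self) -> bool:
        """ATG start, stop-codon end, length >= 6 and divisible by 3."""
        c = self.cds
        return (
            len(c) >= 6
            and len(c) % 3 == 0
            and c.startswith("ATG")
            and c[-3:] in STOP_CODONS
        )


def read_fasta(path: str | Path) -> SequenceSet:
    """Read a (possibly line-wrapped) multi-FASTA file into a SequenceSet.

    Lower-case is normalised to upper-case; whitespace within sequences is
    collapsed.  Duplicate ids, empty files, text before the first header and
    non-IUPAC characters raise :class:`FastaFormatError` naming the line.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaFormatError(
                    f"{path}: line {lineno}: expected a '>' header before sequence data"
                )
            break
        else:
            raise FastaFormatError(f"{path}: empty file")

    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FastaFormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seq = str(rec.seq).upper().replace(" ", "")
        if not seq:
            raise FastaFormatError(f"{path}: record {rec.id!r} has empty sequence")
        bad = set(seq) - IUPAC_NUCLEOTIDES
        if bad:
            raise FastaFormatError(
                f"{path}: record {rec.id!r} contains non-IUPAC characters {sorted(bad)}"
            )
        records[rec.id] = seq
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return SequenceSet(records)


def write_fasta(seqs: Mapping[str, str] | SequenceSet, path: str | Path, width: int = 60) -> None:
    items = seqs.items() if hasattr(seqs, "items") else seqs
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_annotations(path: str | Path, feature_type: str = "CDS") -> list[GeneRecord]:
    """Parse gene models from GFF3 or GTF.

    Rows of ``feature_type`` are grouped by Parent (GFF3) or gene_id (GTF),
    falling back to the feature's own ID.  Coordinates are converted to
    0-based half-open.  Records whose intervals fall outside a declared
    ``##sequence-region`` are dropped with a warning.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    region_bounds: dict[str, tuple[int, int]] = {}
    for directive in db.directives:
        parts = directive.split()
        if parts and parts[0] == "sequence-region" and len(parts) >= 4:
            region_bounds[parts[1]] = (int(parts[2]), int(parts[3]))

    grouped: dict[str, list] = {}
    order: list[str] = []
    for feat in db.features_of_type(feature_type):
        attrs = feat.attributes
        if "Parent" in attrs:
            gid = attrs["Parent"][0]
        elif "gene_id" in attrs:
            gid = attrs["gene_id"][0]
        elif "ID" in attrs:
            gid = attrs["ID"][0]
        else:
            gid = feat.id
        if gid not in grouped:
            grouped[gid] = []
            order.append(gid)
        grouped[gid].append(feat)

    out: list[GeneRecord] = []
    for gid in order:
        feats = grouped[gid]
        chrom = feats[0].seqid
        strand = feats[0].strand if feats[0].strand in "+-" else "+"
        intervals = sorted((f.start - 1, f.end) for f in feats)  # GFF 1-based inclusive -> 0-based half-open
        if chrom in region_bounds:
            lo, hi = region_bounds[chrom]
            if intervals[0][0] < lo - 1 or intervals[-1][1] > hi:
                logger.warning(
                    "gene %s: interval outside declared sequence-region of %s; dropped",
                    gid, chrom,
                )
                continue
        out.append(
            GeneRecord(
                gene_id=gid,
                chrom=chrom,
                start=intervals[0][0],
                end=intervals[-1][1],
                strand=strand,
                intervals=intervals,
            )
        )
    return out


def extract_genes(
    seqs: SequenceSet,
    genes: Iterable[GeneRecord],
    flank: int = 0,
    strict_orf: bool = True,
) -> list[OrientedGene]:
    """Resolve each gene to a coding-strand :class:`OrientedGene` with flanks.

    Multi-part CDSs are concatenated in transcription order; minus-strand
    genes are reverse-complemented.  With ``strict_orf``, genes failing the
    ATG/stop/length-divisible-by-3 checks are excluded (counted in a log
    message).  Genes on unknown chromosomes or with out-of-bounds intervals
    are dropped with a warning.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    out: list[OrientedGene] = []
    n_not_orf = 0
    for g in genes:
        if g.chrom not in seqs:
            logger.warning("gene %s: unknown chromosome %r; dropped", g.gene_id, g.chrom)
            continue
        chrom_seq = seqs[g.chrom]
        if g.start < 0 or g.end > len(chrom_seq):
            logger.warning("gene %s: interval outside chromosome bounds; dropped", g.gene_id)
            continue
        cds_fwd = "".join(chrom_seq[s:e] for s, e in g.intervals)
        left_start = max(0, g.start - flank)
        left = chrom_seq[left_start : g.start]
        right = chrom_seq[g.end : g.end + flank]
        if g.strand == "+":
            cds, upstream, downstream = cds_fwd, left, right
        else:
            cds = revcomp(cds_fwd)
            upstream, downstream = revcomp(right), revcomp(left)
        gene = OrientedGene(
            gene_id=g.gene_id,
            cds=cds,
            upstream=upstream,
            downstream=downstream,
            truncated_5=len(upstream) < flank,
            truncated_3=len(downstream) < flank,
        )
        if strict_orf and not gene.is_strict_orf():
            n_not_orf += 1
            continue
        out.append(gene)
    if n_not_orf:
        logger.info("extract_genes: %d gene(s) excluded by strict ORF checks", n_not_orf)
    return out


def read_orf_fasta(path: str | Path, strict_orf: bool = False) -> list[OrientedGene]:
    """Read a pre-extracted ORF multi-FASTA (one coding-strand ORF per record)."""
    seqs = read_fasta(path)
    genes = [OrientedGene(gene_id=k, cds=v) for k, v in seqs.items()]
    if strict_orf:
        kept = [g for g in genes if g.is_strict_orf()]
        if len(kept) < len(genes):
            logger.info(
                "read_orf_fasta: %d record(s) excluded by strict ORF checks",
                len(genes) - len(kept),
            )
        return kept
    return genes


def read_two_column_tsv(path: str | Path) -> dict[str, float]:
    """Read a two-column gene->value table (expression or methylation levels)."""
    out: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected two tab-separated columns")
            out[parts[0]] = float(parts[1])
    return out
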