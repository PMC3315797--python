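"""Skew statistics and the three profile representations.

GC skew is (G - C)/(G + C) and AT skew is (A - T)/(A + T), a symmetric
metric in [-1, 1] computed on the coding strand.  Positions are aggregated
by *pooling counts* (skew of summed counts) rather than averaging per-gene
skews, so a position covered by many genes behaves like one long sequence;
a mean-of-genes mode is kept as an option for sensitivity analysis.
Undefined skews (zero denominator) propagate as NaN and are never coerced
to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from ._nucl import A, C, G, T, base_counts, encode
from .io import OrientedGene

Pair = Literal["GC", "AT"]


@dataclass(frozen=True)
class CompositionCounts:
    """Counts of the four unambiguous bases (N and ambiguity codes excluded)."""

    nA: int = 0
    nC: int = 0
    nG: int = 0
    nT: int = 0

    def __post_init__(self) -> None:
        if min(self.nA, self.nC, self.nG, self.nT) < 0:
            raise ValueError("composition counts must be non-negative")

    @classmethod
    def from_seq(cls, seq: str) -> "CompositionCounts":
        a, c, g, t = base_counts(encode(seq))
        return cls(int(a), int(c), int(g), int(t))

    def __add__(self, other: "CompositionCounts") -> "CompositionCounts":
        return CompositionCounts(
            self.nA + other.nA, self.nC + other.nC, self.nG + other.nG, self.nT + other.nT
        )

    def as_array(self) -> np.ndarray:
        return np.array([self.nA, self.nC, self.nG, self.nT], dtype=np.int64)


def skew(counts, pair: Pair = "GC") -> float | np.ndarray:
    """Signed composition skew in [-1, 1]; NaN where the denominator is zero.

    ``counts`` may be a :class:`CompositionCounts` or an array whose last
    axis has length 4 (A, C, G, T); the array form is vectorised.
    """
    if isinstance(counts, CompositionCounts):
        arr = counts.as_array()
    else:
        arr = np.asarray(counts)
        if arr.shape[-1] != 4:
            raise ValueError("counts array must have last axis of length 4 (A,C,G,T)")
        if np.any(arr < 0):
            raise ValueError("composition counts must be non-negative")
    if pair == "GC":
        num = arr[..., G] - arr[..., C]
        den = arr[..., G] + arr[..., C]
    elif pair == "AT":
        num = arr[..., A] - arr[..., T]
        den = arr[..., A] + arr[..., T]
    else:
        raise ValueError(f"pair must be 'GC' or 'AT', got {pair!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def seq_skew(seq: str, pair: Pair = "GC") -> float:
    """Skew of a plain nucleotide string."""
    return skew(CompositionCounts.from_seq(seq), pair)


@dataclass
class SkewProfile:
    """Per-offset skew of genes superposed at a common anchor.

    For ``anchor='start'`` offset 0 is the first base of the start codon and
    negative offsets lie in the upstream flank.  For ``anchor='stop'`` offset
    0 is the first base of the stop codon, so the stop codon occupies offsets
    0..2 and the downstream flank begins at offset 3.
    """

    anchor: Literal["start", "stop"]
    pair: Pair
    offsets: np.ndarray
    values: np.ndarray
    n: np.ndarray
    counts: np.ndarray = field(repr=False, default=None)

    def value_at(self, offset: int) -> float:
        idx = int(np.searchsorted(self.offsets, offset))
        if idx >= len(self.offsets) or self.offsets[idx] != offset:
            raise KeyError(f"offset {offset} not in profile")
        return float(self.values[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "skew": self.values, "n": self.n})


@dataclass
class BinnedMetagene:
    """Gene bodies divided into ``n_bins`` bins plus position-wise flanks.

    Base i (0-based) of a gene of length L maps to bin floor(i*n_bins/L),
    so every base lands in exactly one bin regardless of gene length.
    Counts are pooled over genes; per-cell composition is retained so either
    skew pair can be recomputed.
    """

    n_bins: int
    flank_bp: int
    body_counts: np.ndarray  # (n_bins, 4)
    upstream_counts: np.ndarray  # (flank_bp, 4), row 0 = farthest upstream
    downstream_counts: np.ndarray  # (flank_bp, 4)
    n_genes: int = 0

    def body_skew(self, pair: Pair = "GC") -> np.ndarray:
        return skew(self.body_counts, pair)

    def upstream_skew(self, pair: Pair = "GC") -> np.ndarray:
        return skew(self.upstream_counts, pair)

    def downstream_skew(self, pair: Pair = "GC") -> np.ndarray:
        return skew(self.downstream_counts, pair)

    def flank_binned_skew(self, pair: Pair = "GC", bin_bp: int = 20) -> tuple[np.ndarray, np.ndarray]:
        """Flank skews pooled into bins of ``bin_bp`` for display."""
        def _bin(counts: np.ndarray) -> np.ndarray:
            k = len(counts) // bin_bp
            pooled = counts[: k * bin_bp].reshape(k, bin_bp, 4).sum(axis=1)
            return skew(pooled, pair)

        return _bin(self.upstream_counts), _bin(self.downstream_counts)

    def to_frame(self, pair: Pair = "GC") -> pd.DataFrame:
        rows = []
        for i in range(self.flank_bp):
            rows.append(("upstream", i - self.flank_bp, skew(self.upstream_counts[i], pair),
                         int(self.upstream_counts[i].sum())))
        body = self.body_skew(pair)
        for b in range(self.n_bins):
            rows.append(("body", b, float(body[b]), int(self.body_counts[b].sum())))
        for i in range(self.flank_bp):
            rows.append(("downstream", i, skew(self.downstream_counts[i], pair),
                         int(self.downstream_counts[i].sum())))
        return pd.DataFrame(rows, columns=["region", "position", "skew", "n_bases"])


@dataclass
class SkewTrack:
    """Sliding-window skew along one sequence."""

    seq_id: str
    window: int
    step: int
    centers: np.ndarray
    values: np.ndarray
    pair: Pair = "GC"

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            half = self.window // 2
            for c, v in zip(self.centers, self.values):
                if np.isnan(v):
                    continue
                fh.write(f"{self.seq_id}\t{c - half}\t{c - half + self.window}\t{v:.6g}\n")


def _moving_average(values: np.ndarray, width: int) -> np.ndarray:
    """Centred NaN-aware moving average of odd width."""
    if width <= 1:
        return values
    if width % 2 == 0:
        width += 1
    half = width // 2
    v = np.concatenate([np.full(half, np.nan), values, np.full(half, np.nan)])
    ok = ~np.isnan(v)
    num = np.convolve(np.where(ok, v, 0.0), np.ones(width), mode="valid")
    den = np.convolve(ok.astype(float), np.ones(width), mode="valid")
    with np.errstate(invalid="ignore"):
        return np.where(den > 0, num / np.where(den > 0, den, 1), np.nan)


def superposed_profile(
    genes: Sequence[OrientedGene],
    anchor: Literal["start", "stop"] = "start",
    upstream_bp: int = 200,
    downstream_bp: int = 1000,
    pair: Pair = "GC",
    codon_average: bool = False,
    smooth_bp: int = 0,
    aggregate: Literal["pool", "mean"] = "pool",
) -> SkewProfile:
    """Superpose genes at the start or stop codon and compute per-offset skew.

    For ``anchor='start'``: offsets < 0 are read from the upstream flank,
    offsets >= 0 from the CDS (genes contribute only to offsets they cover;
    the 3' flank is never mixed into body offsets).  For ``anchor='stop'``:
    offsets <= 2 are read from the CDS counted back from the stop codon
    (offset 0 = first stop base) and offsets >= 3 from the downstream flank.

    With ``codon_average``, coding-region values are averaged over each codon
    triplet ("averaged over the three bases"); with ``smooth_bp > 0`` a
    centred moving average of that width is applied last.
    """
    if not genes:
        raise ValueError("need at least one gene")
    offsets = np.arange(-upstream_bp, downstream_bp + 1)
    n_off = len(offsets)
    pooled = np.zeros((n_off, 4), dtype=np.int64)
    n_genes_at = np.zeros(n_off, dtype=np.int64)
    per_gene_sum = np.zeros(n_off) if aggregate == "mean" else None
    per_gene_n = np.zeros(n_off, dtype=np.int64) if aggregate == "mean" else None

    for gene in genes:
        cds = encode(gene.cds)
        L = len(cds)
        if anchor == "start":
            flank = encode(gene.upstream) if gene.upstream else np.empty(0, np.int8)
            n_up = min(upstream_bp, len(flank))
            # upstream: offset -1 is the last flank base
            if n_up:
                rows = np.arange(upstream_bp - n_up, upstream_bp)
                codes = flank[len(flank) - n_up :]
                _accumulate(pooled, n_genes_at, rows, codes, per_gene_sum, per_gene_n, pair)
            n_dn = min(downstream_bp + 1, L)
            rows = np.arange(upstream_bp, upstream_bp + n_dn)
            _accumulate(pooled, n_genes_at, rows, cds[:n_dn], per_gene_sum, per_gene_n, pair)
        elif anchor == "stop":
            # offset 0 = cds position L-3
            flank = encode(gene.downstream) if gene.downstream else np.empty(0, np.int8)
            lo = max(-upstream_bp, -(L - 3))
            rows = np.arange(lo + upstream_bp, upstream_bp + 3)
            codes = cds[L - 3 + lo : L]
            _accumulate(pooled, n_genes_at, rows, codes, per_gene_sum, per_gene_n, pair)
            n_dn = min(downstream_bp - 2, len(flank))
            if n_dn > 0:
                rows = np.arange(upstream_bp + 3, upstream_bp + 3 + n_dn)
                _accumulate(pooled, n_genes_at, rows, flank[:n_dn], per_gene_sum, per_gene_n, pair)
        else:
            raise ValueError(f"anchor must be 'start' or 'stop', got {anchor!r}")

    if aggregate == "pool":
        values = skew(pooled, pair)
    else:
        with np.errstate(invalid="ignore"):
            values = np.where(per_gene_n > 0, per_gene_sum / np.maximum(per_gene_n, 1), np.nan)

    if codon_average:
        values = _codon_average(values, offsets, anchor)
    if smooth_bp > 0:
        values = _moving_average(values, smooth_bp)
    return SkewProfile(anchor=anchor, pair=pair, offsets=offsets, values=values,
                       n=n_genes_at, counts=pooled)


def _accumulate(pooled, n_genes_at, rows, codes, per_gene_sum, per_gene_n, pair):
    valid = codes >= 0
    np.add.at(pooled, (rows[valid], codes[valid].astype(np.intp)), 1)
    n_genes_at[rows] += 1
    if per_gene_sum is not None:
        one_hot = np.zeros((len(rows), 4), dtype=np.int64)
        one_hot[np.arange(len(rows))[valid], codes[valid].astype(np.intp)] = 1
        vals = skew(one_hot, pair)
        ok = ~np.isnan(vals)
        per_gene_sum[rows[ok]] += vals[ok]
        per_gene_n[rows[ok]] += 1


def _codon_average(values: np.ndarray, offsets: np.ndarray, anchor: str) -> np.ndarray:
    """Replace each coding-region value with the mean over its codon triplet.

    Coding offsets are >= 0 for the start anchor and <= 2 for the stop anchor
    (strict ORFs keep the reading frame aligned at both ends).
    """
    out = values.copy()
    coding = offsets >= 0 if anchor == "start" else offsets <= 2
    cod_off = offsets[coding]
    cod_val = values[coding]
    codon_idx = np.floor_divide(cod_off, 3)
    df = pd.DataFrame({"codon": codon_idx, "v": cod_val})
    means = df.groupby("codon")["v"].transform("mean").to_numpy()
    out[coding] = means
    return out


def _gene_bin_counts(codes: np.ndarray, n_bins: int, mask: np.ndarray | None = None) -> np.ndarray:
    """Pooled (n_bins, 4) counts for one encoded gene body."""
    L = len(codes)
    bins = (np.arange(L) * n_bins) // L
    valid = codes >= 0
    if mask is not None:
        valid = valid & mask
    out = np.zeros((n_bins, 4), dtype=np.int64)
    np.add.at(out, (bins[valid], codes[valid].astype(np.intp)), 1)
    return out


def binned_metagene(
    genes: Sequence[OrientedGene],
    n_bins: int = 40,
    flank_bp: int = 200,
    codon_position: int | None = None,
) -> BinnedMetagene:
    """Pool gene bodies into ``n_bins`` bins plus position-wise flanks.

    ``codon_position`` (1, 2 or 3) optionally restricts body counting to
    bases at that position within each codon (frame taken from the ATG).
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    body = np.zeros((n_bins, 4), dtype=np.int64)
    up = np.zeros((flank_bp, 4), dtype=np.int64)
    dn = np.zeros((flank_bp, 4), dtype=np.int64)
    for gene in genes:
        codes = encode(gene.cds)
        mask = None
        if codon_position is not None:
            if codon_position not in (1, 2, 3):
                raise ValueError("codon_position must be 1, 2 or 3")
            mask = (np.arange(len(codes)) % 3) == (codon_position - 1)
        body += _gene_bin_counts(codes, n_bins, mask)
        if flank_bp and gene.upstream:
            f = encode(gene.upstream)[-flank_bp:]
            rows = np.arange(flank_bp - len(f), flank_bp)
            v = f >= 0
            np.add.at(up, (rows[v], f[v].astype(np.intp)), 1)
        if flank_bp and gene.downstream:
            f = encode(gene.downstream)[:flank_bp]
            rows = np.arange(len(f))
            v = f >= 0
            np.add.at(dn, (rows[v], f[v].astype(np.intp)), 1)
    return BinnedMetagene(
        n_bins=n_bins, flank_bp=flank_bp, body_counts=body,
        upstream_counts=up, downstream_counts=dn, n_genes=len(genes),
    )


def sliding_track(
    seq: str,
    seq_id: str = "seq",
    window: int = 2000,
    step: int | None = None,
    pair: Pair = "GC",
) -> SkewTrack:
    """Skew in sliding windows along a sequence; step defaults to window/10."""
    if window <= 0:
        raise ValueError("window must be > 0")
    if window > len(seq):
        raise ValueError("window exceeds sequence length")
    if step is None:
        step = max(1, window // 10)
    codes = encode(seq)
    one_hot = np.zeros((len(codes), 4), dtype=np.int64)
    valid = codes >= 0
    one_hot[np.arange(len(codes))[valid], codes[valid].astype(np.intp)] = 1
    csum = np.vstack([np.zeros((1, 4), dtype=np.int64), np.cumsum(one_hot, axis=0)])
    starts = np.arange(0, len(codes) - window + 1, step)
    counts = csum[starts + window] - csum[starts]
    values = skew(counts, pair)
    return SkewTrack(seq_id=seq_id, window=window, step=step,
                     centers=starts + window // 2, values=np.atleast_1d(values), pair=pair)
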