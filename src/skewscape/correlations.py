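"""Correlation analyses: local AT-skew/GC-content vs GC-skew, cross-species
skew scatter, expression vs end-window skews, and methylation association.

End windows are taken from the CDS ends (default 75 bp) with an option to
use the flanks instead.  Expression levels are rank-transformed by default
before the Pearson correlation, since abundance estimates are heavy-tailed;
a raw-value switch is provided.  The methylation test is a one-sided Welch
(unequal-variance) two-sample t-test of methylated vs remaining genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._nucl import encode
from .io import OrientedGene
from .skew import Pair, _gene_bin_counts, seq_skew, skew


def summarize_genes(
    genes: Sequence[OrientedGene],
    end_bp: int = 75,
    window_source: Literal["cds", "flank"] = "cds",
) -> pd.DataFrame:
    """Per-gene skew/content summary (one row per gene, indexed by id)."""
    rows = []
    for g in genes:
        codes = encode(g.cds)
        counts = np.bincount(codes[codes >= 0], minlength=4)[:4]
        total = counts.sum()
        if window_source == "cds":
            w5, w3 = g.cds[:end_bp], g.cds[-end_bp:]
        else:
            w5, w3 = g.upstream[-end_bp:], g.downstream[:end_bp]
        rows.append(
            {
                "gene_id": g.gene_id,
                "length": len(g.cds),
                "gc_skew_total": skew(counts, "GC"),
                "at_skew_total": skew(counts, "AT"),
                "gc_content": (counts[1] + counts[2]) / total if total else np.nan,
                "gc_skew_5end": seq_skew(w5) if w5 else np.nan,
                "gc_skew_3end": seq_skew(w3) if w3 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def local_skew_correlation(
    genes: Sequence[OrientedGene],
    n_bins: int = 40,
) -> pd.DataFrame:
    """Per-bin Pearson r across genes of GC skew vs AT skew and vs GC content.

    Each gene's body is divided into ``n_bins`` bins; within every bin, the
    per-gene GC skew is correlated across genes against the per-gene AT skew
    and GC content of the same bin.  Genes with undefined values are
    excluded pairwise; a bin left with fewer than 3 pairs (or a constant
    vector) yields NaN.
    """
    if len(genes) < 3:
        raise ValueError("need at least 3 genes")
    gc = np.full((len(genes), n_bins), np.nan)
    at = np.full((len(genes), n_bins), np.nan)
    content = np.full((len(genes), n_bins), np.nan)
    for i, g in enumerate(genes):
        counts = _gene_bin_counts(encode(g.cds), n_bins)
        gc[i] = skew(counts, "GC")
        at[i] = skew(counts, "AT")
        tot = counts.sum(axis=1)
        with np.errstate(invalid="ignore"):
            content[i] = np.where(tot > 0, (counts[:, 1] + counts[:, 2]) / np.maximum(tot, 1), np.nan)

    def _r(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
        ok = ~(np.isnan(x) | np.isnan(y))
        n = int(ok.sum())
        if n < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            return np.nan, n
        return float(stats.pearsonr(x[ok], y[ok])[0]), n

    rows = []
    for b in range(n_bins):
        r_at, n_at = _r(gc[:, b], at[:, b])
        r_content, n_content = _r(gc[:, b], content[:, b])
        rows.append({"bin": b, "r_gc_vs_at": r_at, "r_gc_vs_content": r_content,
                     "n": min(n_at, n_content)})
    return pd.DataFrame(rows)


@dataclass
class ScatterResult:
    r: float
    slope: float
    intercept: float
    p: float
    table: pd.DataFrame


def species_scatter(table: pd.DataFrame, x: str = "gc_skew", y: str = "at_skew") -> ScatterResult:
    """Pearson r and least-squares slope of per-species overall skews."""
    if len(table) < 3:
        raise ValueError("need at least 3 species rows")
    xv = table[x].to_numpy(dtype=float)
    yv = table[y].to_numpy(dtype=float)
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise ValueError("constant column: correlation undefined")
    res = stats.linregress(xv, yv)
    out = table.copy()
    out["residual"] = yv - (res.slope * xv + res.intercept)
    return ScatterResult(r=float(res.rvalue), slope=float(res.slope),
                         intercept=float(res.intercept), p=float(res.pvalue), table=out)


@dataclass
class ExpressionCorrelation:
    r5: float
    r3: float
    p5: float
    p3: float
    n: int


def expression_correlation(
    genes: Sequence[OrientedGene],
    expression: Mapping[str, float],
    end_bp: int = 75,
    n_perm: int = 1000,
    rank_transform: bool = True,
    log_transform: bool = False,
    seed: int | None = None,
    window_source: Literal["cds", "flank"] = "cds",
) -> ExpressionCorrelation:
    """Pearson r of expression vs 5'- and 3'-end-window GC skews.

    p-values come from gene-label permutation (two-sided on |r|).
    ``rank_transform`` (default) ranks expression before correlating;
    ``log_transform`` takes log1p instead (mutually exclusive semantics:
    ranking wins if both are set).
    """
    summ = summarize_genes(genes, end_bp=end_bp, window_source=window_source)
    matched = summ.index.intersection(expression.keys())
    if len(matched) == 0:
        raise ValueError("no overlap between gene ids and expression table")
    if len(matched) < 10:
        raise ValueError(f"only {len(matched)} matched genes; need >= 10")
    expr = np.array([expression[g] for g in matched], dtype=float)
    if rank_transform:
        expr = stats.rankdata(expr)
    elif log_transform:
        expr = np.log1p(expr)
    s5 = summ.loc[matched, "gc_skew_5end"].to_numpy()
    s3 = summ.loc[matched, "gc_skew_3end"].to_numpy()
    rng = np.random.default_rng(seed)

    def _corr_p(skews: np.ndarray) -> tuple[float, float]:
        ok = ~np.isnan(skews)
        x, y = expr[ok], skews[ok]
        r = float(stats.pearsonr(x, y)[0])
        hits = 0
        for _ in range(n_perm):
            rp = stats.pearsonr(rng.permutation(x), y)[0]
            if abs(rp) >= abs(r):
                hits += 1
        return r, (1 + hits) / (1 + n_perm)

    r5, p5 = _corr_p(s5)
    r3, p3 = _corr_p(s3)
    return ExpressionCorrelation(r5=r5, r3=r3, p5=p5, p3=p3, n=int(len(matched)))


@dataclass
class MethylationAssociation:
    t5: float
    p5: float
    t3: float
    p3: float
    r_level_5: float
    r_level_3: float
    n_methylated: int


def methylation_association(
    genes: Sequence[OrientedGene],
    levels: Mapping[str, float],
    end_bp: int = 75,
) -> MethylationAssociation:
    """Is the mean end-window GC skew of methylated genes greater than the rest?

    One-sided Welch t-test on each end window, plus the Pearson r of
    methylation level vs end skews within the methylated set.  ``levels``
    keys define the methylated set, which must be a strict subset of the
    gene ids with at least 3 members.
    """
    summ = summarize_genes(genes, end_bp=end_bp)
    meth_ids = summ.index.intersection(levels.keys())
    if len(meth_ids) < 3:
        raise ValueError("methylated overlap < 3 genes")
    if len(meth_ids) == len(summ):
        raise ValueError("methylated set must be a strict subset of genes")
    rest = summ.index.difference(meth_ids)

    def _welch(col: str) -> tuple[float, float]:
        a = summ.loc[meth_ids, col].dropna()
        b = summ.loc[rest, col].dropna()
        t, p = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
        return float(t), float(p)

    t5, p5 = _welch("gc_skew_5end")
    t3, p3 = _welch("gc_skew_3end")
    lv = np.array([levels[g] for g in meth_ids], dtype=float)

    def _r(col: str) -> float:
        s = summ.loc[meth_ids, col].to_numpy()
        ok = ~np.isnan(s)
        if ok.sum() < 3 or np.std(s[ok]) == 0 or np.std(lv[ok]) == 0:
            return np.nan
        return float(stats.pearsonr(lv[ok], s[ok])[0])

    return MethylationAssociation(t5=t5, p5=p5, t3=t3, p3=p3,
                                  r_level_5=_r("gc_skew_5end"), r_level_3=_r("gc_skew_3end"),
                                  n_methylated=int(len(meth_ids)))
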