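"""Three-line piecewise model of GC skew along genes.

The pooled skew of a gene set is summarised over three 750-bp regions — one
aligned to the start codon, one to the centre of genes, one to the stop —
and modelled as a linear 5' ramp, a flat centre, and a linear 3' ramp:

    5' region (x bp from ATG):   s(x) = c + a * max(0, (b - x) / b)
    centre region:               s = c
    3' region (u bp before the last base): s(u) = c + e * max(0, (d - u) / d)

with a the skew difference at the ATG relative to the centre, b the 5'
ramp length, c the central skew, d the 3' ramp start (bp before the stop)
and e the skew difference at the stop.  c is the mean of the centre
series; (a, b) and (d, e) are fit by exhaustive enumeration over a grid,
minimising squared error.  Given c the 5' and 3' terms are separable, and
for each ramp length the quadratic in the amplitude is evaluated over the
whole amplitude grid at once; a naive re-enumeration gives identical
results and is retained as a cross-check in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Literal, Sequence

import numpy as np

from ._nucl import encode
from .io import OrientedGene
from .skew import Pair, skew


@dataclass
class Regions:
    """Pooled-count skew series of the three aligned 750-bp regions."""

    region_len: int
    skew5: np.ndarray  # index = bp from the ATG
    skew_centre: np.ndarray
    skew3: np.ndarray  # index j; bp before the last base = region_len - 1 - j
    n_genes: int = 0


@dataclass
class ThreeLineFit:
    a: float
    b: float
    c: float
    d: float
    e: float
    sse: float
    region_len: int = 750

    def __post_init__(self) -> None:
        if not (0 <= self.b <= self.region_len and 0 <= self.d <= self.region_len):
            raise ValueError("ramp extents b, d must lie in [0, region_len]")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


def build_regions(
    genes: Sequence[OrientedGene],
    region_len: int = 750,
    pair: Pair = "GC",
    strict: bool = False,
) -> Regions:
    """Pool per-position counts for the 5'-, centre- and 3'-aligned regions.

    Genes shorter than ``region_len`` contribute partially: the 5' region
    takes their first min(L, region_len) bases, the 3' region their last,
    and the centre region receives the whole gene centred within the
    region.  With ``strict`` such genes are excluded instead.
    """
    counts5 = np.zeros((region_len, 4), dtype=np.int64)
    countsC = np.zeros((region_len, 4), dtype=np.int64)
    counts3 = np.zeros((region_len, 4), dtype=np.int64)
    n_used = 0
    for gene in genes:
        codes = encode(gene.cds)
        L = len(codes)
        if strict and L < region_len:
            continue
        n_used += 1
        k = min(L, region_len)
        head = codes[:k]
        v = head >= 0
        np.add.at(counts5, (np.arange(k)[v], head[v].astype(np.intp)), 1)
        tail = codes[L - k :]
        v = tail >= 0
        np.add.at(counts3, (np.arange(region_len - k, region_len)[v], tail[v].astype(np.intp)), 1)
        if L >= region_len:
            c0 = (L - region_len) // 2
            mid = codes[c0 : c0 + region_len]
            rows = np.arange(region_len)
        else:
            mid = codes
            rows = np.arange((region_len - L) // 2, (region_len - L) // 2 + L)
        v = mid >= 0
        np.add.at(countsC, (rows[v], mid[v].astype(np.intp)), 1)
    if n_used == 0:
        raise ValueError("no eligible genes for region building")
    return Regions(
        region_len=region_len,
        skew5=skew(counts5, pair),
        skew_centre=skew(countsC, pair),
        skew3=skew(counts3, pair),
        n_genes=n_used,
    )


def _ramp5(b: float, region_len: int) -> np.ndarray:
    x = np.arange(region_len, dtype=float)
    if b <= 0:
        return np.zeros(region_len)
    return np.maximum(0.0, (b - x) / b)


def _ramp3(d: float, region_len: int) -> np.ndarray:
    u = region_len - 1 - np.arange(region_len, dtype=float)
    if d <= 0:
        return np.zeros(region_len)
    return np.maximum(0.0, (d - u) / d)


def _fit_ramp(y: np.ndarray, c: float, amp_grid: np.ndarray, len_grid: np.ndarray,
              ramp_fn, region_len: int) -> tuple[float, float, float]:
    """Best (amplitude, ramp length, sse) over the grid; ties -> smallest length.

    For each candidate length the sse over the whole amplitude grid is the
    quadratic sse(amp) = C0 - 2*amp*S1 + amp^2*S2 with S1 = sum r*(y-c),
    S2 = sum r^2 over defined positions — identical to evaluating every
    (amp, length) pair explicitly.
    """
    ok = ~np.isnan(y)
    resid = np.where(ok, y - c, 0.0)
    c0 = float(np.sum(resid[ok] ** 2))
    best = (0.0, float(len_grid[0]), np.inf)
    for length in len_grid:
        r = ramp_fn(float(length), region_len)
        r = np.where(ok, r, 0.0)
        s1 = float(np.dot(r, resid))
        s2 = float(np.dot(r, r))
        if s2 == 0.0:
            sse = c0
            amp = 0.0
        else:
            sses = c0 - 2.0 * amp_grid * s1 + amp_grid ** 2 * s2
            i = int(np.argmin(sses))
            sse, amp = float(sses[i]), float(amp_grid[i])
        if sse < best[2] - 1e-12:
            best = (amp, float(length), sse)
    return best


def fit_three_line(
    regions: Regions,
    a_step: float = 0.01,
    e_step: float = 0.01,
    b_step: float = 10.0,
    d_step: float = 10.0,
) -> ThreeLineFit:
    """Exhaustive-grid least-squares fit of the three-line model.

    c is the mean of the centre series; a, e range over [-1, 1] and b, d
    over [0, region_len] at the given steps.  Ties are broken toward the
    smallest b, then the smallest d.
    """
    if min(a_step, e_step, b_step, d_step) <= 0:
        raise ValueError("grid steps must be positive")
    R = regions.region_len
    c = float(np.nanmean(regions.skew_centre))
    a_grid = np.round(np.arange(-1.0, 1.0 + a_step / 2, a_step), 10)
    e_grid = np.round(np.arange(-1.0, 1.0 + e_step / 2, e_step), 10)
    b_grid = np.arange(0.0, R + b_step / 2, b_step)
    d_grid = np.arange(0.0, R + d_step / 2, d_step)

    a, b, sse5 = _fit_ramp(regions.skew5, c, a_grid, b_grid, _ramp5, R)
    e, d, sse3 = _fit_ramp(regions.skew3, c, e_grid, d_grid, _ramp3, R)
    okC = ~np.isnan(regions.skew_centre)
    sseC = float(np.sum((regions.skew_centre[okC] - c) ** 2))
    return ThreeLineFit(a=a, b=b, c=c, d=d, e=e, sse=sse5 + sseC + sse3, region_len=R)


def predict_three_line(
    fit: ThreeLineFit,
    region: Literal["5prime", "centre", "3prime"],
    positions: Sequence[float] | np.ndarray,
) -> np.ndarray:
    """Evaluate the fitted model.

    ``positions`` are bp from the ATG for the 5' region, bp before the last
    base for the 3' region (0 = the stop's final base), and arbitrary
    within-region indices for the centre.  Positions outside
    [0, region_len) raise.
    """
    pos = np.asarray(positions, dtype=float)
    if np.any(pos < 0) or np.any(pos >= fit.region_len):
        raise ValueError("positions must lie within [0, region_len)")
    if region == "centre":
        return np.full_like(pos, fit.c)
    if region == "5prime":
        if fit.b <= 0:
            return np.full_like(pos, fit.c)
        return fit.c + fit.a * np.maximum(0.0, (fit.b - pos) / fit.b)
    if region == "3prime":
        if fit.d <= 0:
            return np.full_like(pos, fit.c)
        return fit.c + fit.e * np.maximum(0.0, (fit.d - pos) / fit.d)
    raise ValueError(f"unknown region {region!r}")
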