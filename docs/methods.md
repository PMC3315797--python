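# Methods

## The quantity under study

GC skew, (G − C)/(G + C), and AT skew, (A − T)/(A + T), measure departures
from intra-strand parity (Chargaff's second rule) on the coding strand of a
gene. In many unicellular fungi the coding strand is C-biased near the
translation start, roughly constant through the gene body, and G-biased
near the stop, so the skew profile along a gene looks like a down-ramp, a
plateau, and an up-ramp. skewscape computes this profile three ways,
tests it per gene, models it, and traces its consequences for terminal
amino-acid usage and its association with expression and methylation
covariates.

Both skews are undefined when the denominator is zero. Undefined values
propagate as NaN everywhere — they are excluded from means and model
residuals, never coerced to 0.

## Aggregation: pooled counts, not mean of skews

All profiles aggregate genes by summing base counts per position/bin and
taking the skew of the sums ("total skew for each position"). This weights
every base equally, keeps the statistic defined wherever any gene
contributes a G or C, and makes pooling associative: the skew of a
concatenation equals the skew of summed counts. A mean-of-per-gene-skews
mode (`aggregate="mean"` in `superposed_profile`) exists for sensitivity
analysis; it weights genes equally instead and differs whenever coverage or
composition varies across genes.

## Profiles

- **Superposed profile** (`superposed_profile`): genes aligned at the start
  or stop codon; per-offset pooled skew. Offset 0 is the first base of the
  anchor codon. Body offsets never mix with the opposite flank: a start-
  anchored profile reads only the upstream flank (negative offsets) and the
  CDS, each gene contributing to the offsets it covers. Optional
  codon-averaging replaces each coding value with the mean of its codon
  triplet; optional smoothing applies a centred NaN-aware moving average
  (default width when requested: 9 bp — a deliberately mild choice, since
  the appropriate amount of smoothing is a display decision).
- **Binned metagene** (`binned_metagene`): base i of a gene of length L
  maps to bin floor(i·n_bins/L), so every base lands in exactly one of the
  40 default bins regardless of gene length; 200-bp flanks are pooled
  position-wise. Per-cell counts are retained so GC and AT skew (or GC
  content) can be recomputed from the same object.
- **Sliding track** (`sliding_track`): windowed skew along a chromosome
  (default window 2 kb, step window/10), exported as bedGraph.

## Per-gene permutation test

`shuffle_test` compares the GC skew of the last 100 bp of the CDS with the
first 100 bp (Δ = skew₃′ − skew₅′) against a null built by uniformly
permuting the gene's own bases 1,000 times — a mononucleotide shuffle,
preserving overall composition, the minimal null consistent with shuffling
whole genes. The empirical p-value uses the add-one pseudocount,
p = (1 + #{Δ_null ≥ Δ_obs})/(1 + n_shuffles), so p is never 0 and ties
count against significance (slightly conservative). Significance is
one-sided toward increasing skew 5′→3′ — the direction of the phenomenon —
at the top-5% threshold; a two-sided switch exists. The 100-bp windows
include the start and stop codons; excluding them is a documented option
but not the default. Genes shorter than 200 bp, or with an undefined
window skew, are ineligible and reported separately.

Calibration: on 2,000 position-homogeneous genes (600 bp, GC 0.40) the
test flags ≈5% of genes (the acceptance suite checks the 99% binomial band
[3.9%, 6.3%]).

## Three-line model

Pooled skew is summarised over three 750-bp regions: start-aligned,
centre-aligned (the middle 750 bp of each gene; shorter genes contribute
centred partial coverage), and stop-aligned. The model has five
parameters: a (skew at the ATG minus central skew), b (5′ ramp length,
bp), c (central skew), d (3′ ramp start, bp before the stop), e (skew at
the stop minus central skew):

    5′ region:  s(x) = c + a·max(0, (b − x)/b)      x bp from the ATG
    centre:     s    = c
    3′ region:  s(u) = c + e·max(0, (d − u)/d)      u bp before the last base

c is the mean of the centre series. (a, b) and (d, e) are fit by
exhaustive enumeration — a, e over [−1, 1] step 0.01; b, d over
[0, 750] step 10 bp — minimising squared error on the per-position pooled
series. Because the 5′ and 3′ terms are separable given c, each ramp
length's error over the whole amplitude grid reduces to a quadratic
evaluated in closed form; this factorisation returns exactly the same
minimiser as the naive double loop (the test suite keeps the naive
enumeration as an oracle and checks exact agreement). Ties break toward
the smallest b, then the smallest d; a zero-length ramp fixes its
amplitude to 0. Setting b = 0 or d = 0 disables a ramp, so the flat model
is nested and the fitted SSE can never exceed it.

## Terminal composition biases

Windows are the first 21 codons (including the initiator Met) and the last
20 codons before the stop; the stop codon is never counted. Genes must be
strict ORFs at least 3·(21+20+1) bp long so the windows and stop are
disjoint. Per-nucleotide output is the ratio of pooled 5′-window frequency
to 3′-window frequency. Per-residue output adds a 2×2 chi-square test
(this residue vs all others × 5′ vs 3′ window) without continuity
correction — a warning, not an exact test, is issued when an expected count
falls below 5 — and the mean GC skew of the residue's synonymous codons
(uniform weights by default; codons with no G or C are excluded from the
mean; usage-weighted mode available). `drop_initial_met` removes the first
residue of every gene from the 5′ counts, since position 1 is forced to
Met rather than compositionally chosen. The per-residue 2×2 form was
chosen over a global residues×window table because it yields one p-value
per residue. Codon tables are taken from NCBI ids (standard = 1); the
CUG-clade alternative nuclear code (id 12, CUG→Ser, relevant to
*Candida albicans*) is selectable. Fourfold-degenerate codon families are
derived programmatically from the active table, not hard-coded, so they
follow the table choice.

## Correlations

- Per-bin Pearson r across genes of GC skew vs AT skew and vs GC content
  (40 bins; pairwise NaN exclusion; r undefined below 3 pairs or for
  constant vectors).
- Cross-species scatter: Pearson r and least-squares slope over a table of
  per-species overall skews.
- Expression: Pearson r between expression and 75-bp end-window GC skews,
  with a permutation p-value (1,000 label permutations, two-sided).
  End windows are taken from the CDS ends; a flag switches to flank
  windows for users whose annotation includes UTRs. Expression is
  rank-transformed by default (abundance estimates are heavy-tailed);
  log1p and raw modes exist.
- Methylation: one-sided Welch t-test (methylated mean end skew greater
  than the rest) on each end window, plus Pearson r of methylation level
  vs end skews within the methylated subset. Welch was preferred over the
  pooled-variance t-test because group sizes and variances are unequal by
  construction.

## Synthetic data

The generator produces the study conditions directly rather than
simulating an evolutionary process. Defaults: 2,000 genes of 1,500 bp, GC
content 0.40, constant AT skew +0.05, three-line GC-skew parameters
a = −0.3, b = 300, c = 0.1, d = 200, e = 0.2, promoter skew −0.4, 3′-UTR
skew +0.2 over 200-bp flanks, and per-position Gaussian jitter of the
target skew with sd 0.02. These values describe a strongly skewed
fungal-like gene set: a C-biased promoter that is the most negative region,
a 5′ ramp a few hundred bp long, a mildly G-biased body, and a G-biased 3′
end extending into the UTR, with AT skew flat and positive. A target skew
s at GC content g maps to per-position base probabilities
P(G) = g(1+s)/2, P(C) = g(1−s)/2, and analogously A/T from the AT skew.

`orf_mode` forces an ATG start, a sampled stop, and rejection-resamples
in-frame internal stops. This conditioning slightly perturbs realised
composition relative to the target (stop codons are G-containing in two of
three cases, so forbidding them shifts body skew by a few hundredths);
exact parameter-recovery benchmarks therefore use free-nucleotide mode,
while ORF-dependent analyses (translation windows, codon positions) use
`orf_mode`. `generate_codon_genes` offers direct control of codon usage
per window for composition-bias ground truth, and expression/methylation
covariates can be co-generated with specified coupling to end-window
skews.

What the generator does not emulate: codon-usage structure of real
genomes (free mode), introns and UTR annotation ambiguity, chromosomal
context (replication-origin skew gradients), and correlated evolution
between neighbouring genes. Passing tests demonstrate the pipeline's
correctness and calibration on known ground truth, not biological claims
about any real genome.

`emit_genome` places genes (with their own flanks embedded) on a contig
with random strands and intergenic spacers, writing FASTA + GFF3; the
round-trip through extraction is byte-exact, which is the integration test
for the coordinate and strand conventions (0-based half-open internally,
converted once at the GFF boundary).

## Problem sizes and numerical choices

Profile and fit computations are exact integer-count operations plus one
division, so tolerances appear only in stochastic checks, which use
binomial/normal sampling bounds at the generated sample sizes (e.g. 3–4
standard deviations of the pooled-count skew per bin). Analysis drivers
and acceptance checks use 2,000 genes per set — large enough that pooled
per-position skew standard errors are ≈0.035 at 750-bp regions and the
shuffle-test calibration band is tight, while a full run stays in the
tens of seconds. The multi-species scatter uses 64 sets of 40 genes.
Ramp-length grids step 10 bp; amplitude grids step 0.01 — the recovery
tolerance (±0.03 on amplitudes, ±2 grid steps on ramp lengths) reflects
those steps plus sampling noise.

## Known limitations

- The permutation test's mononucleotide shuffle ignores codon structure;
  dinucleotide- or codon-preserving shuffles are deliberately not offered
  as defaults.
- Per-gene three-line fits are not provided: the model is defined on pooled
  series of sufficiently large gene sets, and 750 noisy per-gene positions
  do not constrain five parameters usefully.
- No confidence intervals on fitted parameters (a bootstrap over genes
  would be the natural extension).
- GFF attribute handling is limited to ID/Parent/gene_id; trans-splicing
  and fuzzy coordinates are out of scope.
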