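import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from skewscape._nucl import encode, revcomp
from skewscape.io import OrientedGene
from skewscape.skew import (CompositionCounts, binned_metagene, seq_skew, skew,
                            sliding_track, superposed_profile)

dna = st.text(alphabet="ACGT", min_size=1, max_size=300)


class TestSkewStatistic:
    @pytest.mark.parametrize(
        "counts,pair,expected",
        [
            (CompositionCounts(nG=4, nC=0), "GC", 1.0),
            (CompositionCounts(nG=1, nC=1), "GC", 0.0),
            (CompositionCounts(nG=3, nC=1), "GC", 0.5),
            (CompositionCounts(nA=3, nT=1), "AT", 0.5),
        ],
    )
    def test_examples(self, counts, pair, expected):
        assert skew(counts, pair) == pytest.approx(expected)

    def test_zero_denominator_is_nan(self):
        assert np.isnan(skew(CompositionCounts(nA=5, nT=5), "GC"))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            CompositionCounts(nG=-1)
        with pytest.raises(ValueError):
            skew(np.array([0, 0, -1, 0]))

    @settings(max_examples=100, deadline=None)
    @given(dna, st.sampled_from(["GC", "AT"]))
    def test_revcomp_antisymmetry(self, seq, pair):
        a = seq_skew(seq, pair)
        b = seq_skew(revcomp(seq), pair)
        if np.isnan(a):
            assert np.isnan(b)
        else:
            assert b == pytest.approx(-a)
            assert -1.0 <= a <= 1.0

    @settings(max_examples=50, deadline=None)
    @given(dna, dna, st.sampled_from(["GC", "AT"]))
    def test_pooling_associativity(self, s1, s2, pair):
        """Skew of a concatenation equals skew of summed counts."""
        pooled = CompositionCounts.from_seq(s1) + CompositionCounts.from_seq(s2)
        a, b = seq_skew(s1 + s2, pair), skew(pooled, pair)
        assert (np.isnan(a) and np.isnan(b)) or a == pytest.approx(b)


class TestSuperposedProfile:
    def test_atg_third_base_skew_is_one(self, small_orf_genes):
        prof = superposed_profile(small_orf_genes, anchor="start",
                                  upstream_bp=50, downstream_bp=100)
        assert prof.value_at(2) == 1.0

    def test_stop_codon_g_positions(self):
        tag = [OrientedGene(f"g{i}", "ATG" + "AAA" * 10 + "TAG") for i in range(5)]
        prof = superposed_profile(tag, anchor="stop", upstream_bp=10, downstream_bp=10)
        assert prof.value_at(2) == 1.0  # the G of TAG
        tga = [OrientedGene(f"g{i}", "ATG" + "AAA" * 10 + "TGA") for i in range(5)]
        prof = superposed_profile(tga, anchor="stop", upstream_bp=10, downstream_bp=10)
        assert prof.value_at(1) == 1.0  # the G of TGA

    def test_homogeneous_g_run(self):
        genes = [OrientedGene("g", "ATGGGGTAA")] * 3
        prof = superposed_profile(genes, anchor="start", upstream_bp=0, downstream_bp=8)
        for off in (3, 4, 5):
            assert prof.value_at(off) == 1.0

    def test_random_uniform_genes_near_zero(self, rng):
        from conftest import random_gene

        genes = [random_gene(rng, length=200, gene_id=f"g{i}") for i in range(1000)]
        prof = superposed_profile(genes, anchor="start", upstream_bp=0, downstream_bp=150)
        assert np.nanmean(np.abs(prof.values)) < 0.05

    def test_codon_average_pools_triplets(self):
        genes = [OrientedGene("g", "GGCCCG")]
        prof = superposed_profile(genes, anchor="start", upstream_bp=0,
                                  downstream_bp=5, codon_average=True)
        # per-base values [1,1,-1,-1,-1,1] -> triplet means [1/3, -1/3]
        assert np.allclose(prof.values, [1 / 3] * 3 + [-1 / 3] * 3)

    def test_upstream_offsets_read_flank(self):
        genes = [OrientedGene("g", "ATGAAATAA", upstream="GG", downstream="CC")]
        prof = superposed_profile(genes, anchor="start", upstream_bp=2, downstream_bp=2)
        assert prof.value_at(-1) == 1.0 and prof.value_at(-2) == 1.0
        prof = superposed_profile(genes, anchor="stop", upstream_bp=2, downstream_bp=4)
        assert prof.value_at(3) == -1.0  # first downstream base (C)

    def test_short_genes_contribute_partially(self):
        genes = [OrientedGene("long", "ATG" + "G" * 30),
                 OrientedGene("short", "ATGCC")]
        prof = superposed_profile(genes, anchor="start", upstream_bp=0, downstream_bp=20)
        assert prof.n[prof.offsets == 4][0] == 2
        assert prof.n[prof.offsets == 10][0] == 1

    def test_mean_of_genes_mode_differs_from_pooling(self):
        genes = [OrientedGene("a", "G"), OrientedGene("b", "C"), OrientedGene("c", "C")]
        pool = superposed_profile(genes, anchor="start", upstream_bp=0, downstream_bp=0)
        mean = superposed_profile(genes, anchor="start", upstream_bp=0, downstream_bp=0,
                                  aggregate="mean")
        assert pool.values[0] == pytest.approx(-1 / 3)
        assert mean.values[0] == pytest.approx(-1 / 3)  # equal here: per-base skews
        # with unequal coverage they diverge; pooled equals count-sum skew
        genes = [OrientedGene("a", "GC"), OrientedGene("b", "G")]
        pool = superposed_profile(genes, anchor="start", upstream_bp=0, downstream_bp=1)
        assert pool.values[1] == pytest.approx(-1.0)


class TestBinnedMetagene:
    def test_hand_enumerated_bins(self):
        mg = binned_metagene([OrientedGene("g", "ATGGGGCCCTAA")], n_bins=4, flank_bp=0)
        vals = mg.body_skew("GC")
        assert vals[0] == 1.0 and vals[1] == 1.0 and vals[2] == -1.0
        assert np.isnan(vals[3])  # TAA has no G or C: undefined, not coerced
        mg = binned_metagene([OrientedGene("g", "ATGGGGCCCTAG")], n_bins=4, flank_bp=0)
        assert mg.body_skew("GC")[3] == 1.0

    def test_matches_brute_force_oracle(self, rng):
        from conftest import random_gene

        genes = [random_gene(rng, length=int(rng.integers(40, 120)), gene_id=f"g{i}")
                 for i in range(100)]
        n_bins = 7
        # oracle: assign every base of every gene to its bin and tally
        tally = np.zeros((n_bins, 4), dtype=int)
        for g in genes:
            L = len(g.cds)
            for i, base in enumerate(g.cds):
                tally[(i * n_bins) // L, "ACGT".index(base)] += 1
        mg = binned_metagene(genes, n_bins=n_bins, flank_bp=0)
        assert np.array_equal(mg.body_counts, tally)

    def test_mirror_antisymmetry(self, rng):
        from conftest import random_gene

        genes = [random_gene(rng, length=80, gene_id=f"g{i}") for i in range(20)]
        flipped = [OrientedGene(g.gene_id, revcomp(g.cds)) for g in genes]
        fwd = binned_metagene(genes, n_bins=8, flank_bp=0).body_skew("GC")
        rev = binned_metagene(flipped, n_bins=8, flank_bp=0).body_skew("GC")
        assert np.allclose(fwd, -rev[::-1], equal_nan=True)

    def test_flat_generator_recovery(self):
        from skewscape.synthetic import SyntheticSpec, generate_genes

        spec = SyntheticSpec(n_genes=800, length=600, a=0, b=0, c=0.2, d=0, e=0,
                             noise_sd=0, seed=3, flank_bp=0)
        genes, _ = generate_genes(spec)
        mg = binned_metagene(genes, n_bins=40, flank_bp=0)
        vals = mg.body_skew("GC")
        n_gc = mg.body_counts[:, 1] + mg.body_counts[:, 2]
        sd = np.sqrt((1 - 0.2 ** 2) / n_gc)
        assert np.all(np.abs(vals - 0.2) < 3.5 * sd)

    def test_each_base_in_exactly_one_bin(self, small_orf_genes):
        mg = binned_metagene(small_orf_genes, n_bins=40, flank_bp=0)
        total = sum(len(g.cds) for g in small_orf_genes)
        assert mg.body_counts.sum() == total

    def test_invalid_bin_count(self):
        with pytest.raises(ValueError):
            binned_metagene([OrientedGene("g", "ATG")], n_bins=0)


class TestSlidingTrack:
    def test_two_block_sequence(self):
        track = sliding_track("G" * 2000 + "C" * 2000, window=2000, step=2000)
        assert np.allclose(track.values, [1.0, -1.0])

    def test_revcomp_reversal_negates(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=500))
        a = sliding_track(seq, window=100, step=100).values
        b = sliding_track(revcomp(seq), window=100, step=100).values
        assert np.allclose(a, -b[::-1], equal_nan=True)

    def test_homogeneous_sequence_bounded_fluctuation(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=20000))
        track = sliding_track(seq, window=2000)
        sd = np.sqrt(1 / (0.5 * 2000))  # binomial sd at ~half GC bases per window
        assert np.all(np.abs(track.values) < 3.5 * sd)

    def test_window_contract(self):
        with pytest.raises(ValueError):
            sliding_track("ACGT", window=0)
        with pytest.raises(ValueError):
            sliding_track("ACGT", window=10)

    def test_all_values_in_bounds(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=5000))
        track = sliding_track(seq, window=250)
        assert np.all((track.values >= -1) & (track.values <= 1))
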