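import numpy as np
import pytest

from skewscape.composition import (CUG_CLADE_TABLE, codon_gc_skew,
                                   codon_position_skew, codon_table,
                                   count_fourfold_sites,
                                   fourfold_degenerate_prefixes,
                                   fourfold_degenerate_skew,
                                   terminal_aa_bias,
                                   terminal_nucleotide_ratios)
from skewscape.io import OrientedGene
from skewscape.synthetic import generate_codon_genes

# Fourfold-degenerate codon families of the standard nuclear code: the
# dinucleotide prefixes of Leu4(CTN), Val(GTN), Ser4(TCN), Pro(CCN),
# Thr(ACN), Ala(GCN), Arg4(CGN) and Gly(GGN).
FOURFOLD_PREFIXES = {"CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG"}


def _orf(codons, gid="g"):
    return OrientedGene(gid, "ATG" + "".join(codons) + "TAA")


class TestCodonGcSkew:
    @pytest.mark.parametrize("residue,expected", [("W", 1.0), ("K", 1.0), ("F", -1.0)])
    def test_enumerated_values(self, residue, expected):
        assert codon_gc_skew(residue) == pytest.approx(expected)

    def test_matches_brute_force_for_all_residues(self):
        tbl = codon_table()
        for residue in set(tbl.values()) - {"*"}:
            vals = []
            for codon, aa in tbl.items():
                if aa != residue:
                    continue
                g, c = codon.count("G"), codon.count("C")
                if g + c:
                    vals.append((g - c) / (g + c))
            assert codon_gc_skew(residue) == pytest.approx(np.mean(vals))

    def test_usage_weighting(self):
        # Gly: GGC (skew 1/3) vs GGG (skew 1): usage all on GGG -> 1.0
        assert codon_gc_skew("G", weights="usage", usage={"GGG": 1.0}) == pytest.approx(1.0)

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError):
            codon_gc_skew("B")

    def test_cug_clade_table_moves_cug_to_ser(self):
        tbl = codon_table(CUG_CLADE_TABLE)
        assert tbl["CTG"] == "S"
        assert codon_table(1)["CTG"] == "L"


class TestTerminalNucleotideRatios:
    def test_identical_window_composition_gives_unit_ratios(self):
        # every codon is ATG (internal Mets), so both windows have the same
        # base frequencies: A, T, G ratios are exactly 1; C is absent from
        # the 3' window, hence undefined
        genes = [OrientedGene(f"g{i}", "ATG" * 41 + "TAA") for i in range(5)]
        ratios = terminal_nucleotide_ratios(genes)
        assert ratios["A"] == ratios["T"] == ratios["G"] == 1.0
        assert np.isnan(ratios["C"])

    def test_c_enriched_5prime_recovered(self):
        # C-rich proline codons up-weighted in the 5' window only
        boost = {c: 10.0 for c in ("CCA", "CCT", "CCG", "CCC")}
        genes = generate_codon_genes(
            600, 60,
            window_overrides=[(slice(1, 21), boost)],
            seed=4,
        )
        ratios = terminal_nucleotide_ratios(genes)
        assert ratios["C"] > 1.3
        assert 0.6 < ratios["A"] < 1.1
        assert ratios["C"] > ratios["G"]

    def test_short_genes_excluded(self):
        short = _orf(["AAA"] * 10, "short")
        ok = _orf(["AAA"] * 45, "ok")
        ratios = terminal_nucleotide_ratios([short, ok])
        assert ratios["A"] > 0  # computed from the eligible gene only
        with pytest.raises(ValueError):
            terminal_nucleotide_ratios([short])


class TestTerminalAaBias:
    def test_equal_windows_give_p_one(self):
        # same 20 codons in the 5' (after Met) and 3' windows
        block = ["GCT", "TGC"] * 10
        genes = [_orf(block + ["AAA"] * 10 + block, f"g{i}") for i in range(4)]
        df = terminal_aa_bias(genes, drop_initial_met=True)
        assert np.allclose(df["chi2_p"], 1.0)
        assert np.allclose(df["ratio5to3"].dropna(), 1.0)

    def test_trp_doubled_at_3prime(self):
        genes = generate_codon_genes(
            500, 130,
            window_overrides=[(slice(-21, -1), {"TGG": 2.0})],
            seed=5,
        )
        df = terminal_aa_bias(genes).set_index("residue")
        assert 0.35 < df.loc["W", "ratio5to3"] < 0.65
        assert df.loc["W", "codon_skew"] == 1.0

    def test_drop_initial_met_accounting(self):
        genes = generate_codon_genes(50, 60, seed=6)
        df = terminal_aa_bias(genes, drop_initial_met=True)
        assert df["count5"].sum() == 20 * len(genes)
        df = terminal_aa_bias(genes, drop_initial_met=False)
        assert df["count5"].sum() == 21 * len(genes)
        assert df["count3"].sum() == 20 * len(genes)

    def test_null_chi2_p_not_inflated(self):
        """With i.i.d. codon usage across positions the per-residue
        chi-square p-values should not pile up near 0."""
        genes = generate_codon_genes(400, 60, seed=7)
        df = terminal_aa_bias(genes, drop_initial_met=True)
        p = df["chi2_p"].to_numpy()
        assert (p < 0.05).mean() < 0.25
        assert 0.25 < np.mean(p) < 0.75


class TestCodonPositionSkew:
    def test_repeated_gca_codon(self):
        genes = [OrientedGene("g", "ATG" + "GCA" * 40 + "TAA")]
        p1 = codon_position_skew(genes, 1, n_bins=1)
        p2 = codon_position_skew(genes, 2, n_bins=1)
        p3 = codon_position_skew(genes, 3, n_bins=1)
        # ATG/TAA contribute too: position1 {A,G,T}, position2 {T,C,A}, position3 {G,A,A}
        assert p1[0] == 1.0  # G's from GCA + ATG's G at pos 3? no: pos1 of GCA = G
        assert p2[0] == -1.0
        assert p3[0] == 1.0  # only G (from ATG pos3) among G/C at third positions

    def test_positions_partition_total_counts(self, small_orf_genes):
        from skewscape.skew import binned_metagene

        total = binned_metagene(small_orf_genes, n_bins=5, flank_bp=0).body_counts
        parts = sum(
            binned_metagene(small_orf_genes, n_bins=5, flank_bp=0,
                            codon_position=k).body_counts
            for k in (1, 2, 3)
        )
        assert np.array_equal(total, parts)

    def test_ramp_visible_at_all_positions(self):
        from skewscape.synthetic import SyntheticSpec, generate_genes

        spec = SyntheticSpec(n_genes=600, length=900, seed=8, orf_mode=True,
                             noise_sd=0, flank_bp=0)
        genes, _ = generate_genes(spec)
        for k in (1, 2, 3):
            vals = codon_position_skew(genes, k, n_bins=10)
            assert vals[0] < vals[5] - 0.05 or vals[0] < vals[-1]


class TestFourfoldDegenerate:
    def test_prefix_set_matches_published_families(self):
        assert set(fourfold_degenerate_prefixes()) == FOURFOLD_PREFIXES

    def test_all_g_third_bases(self):
        genes = [OrientedGene("g", "ATG" + "GGG" * 30 + "TAA")]
        out = fourfold_degenerate_skew(genes, n_bins=1)
        assert out["all"][0] == 1.0

    def test_site_count_matches_brute_force(self, small_orf_genes):
        for g in small_orf_genes[:20]:
            expected = sum(
                1 for i in range(0, len(g.cds) - 2, 3)
                if g.cds[i:i + 2] in FOURFOLD_PREFIXES
            )
            assert count_fourfold_sites(g) == expected

    def test_expression_deciles_disjoint(self, small_orf_genes):
        expr = {g.gene_id: float(i) for i, g in enumerate(small_orf_genes)}
        out = fourfold_degenerate_skew(small_orf_genes, expression=expr, quantile=0.1)
        assert {"all", "low", "high"} <= set(out)

    def test_overlapping_quantiles_rejected(self, small_orf_genes):
        expr = {g.gene_id: float(i) for i, g in enumerate(small_orf_genes)}
        with pytest.raises(ValueError):
            fourfold_degenerate_skew(small_orf_genes, expression=expr, quantile=0.6)
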