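"""End-to-end per-species analysis runs and multi-species aggregation."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .composition import terminal_aa_bias, terminal_nucleotide_ratios
from .correlations import (expression_correlation, methylation_association,
                           species_scatter, summarize_genes)
from .io import (OrientedGene, extract_genes, read_annotations, read_fasta,
                 read_orf_fasta, read_two_column_tsv)
from .significance import significant_fraction
from .skew import binned_metagene, superposed_profile
from .threeline import build_regions, fit_three_line

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one per-species run; unknown keys are rejected."""

    species: str = "species"
    fasta: str | None = None
    gff: str | None = None
    orf_fasta: str | None = None
    expression: str | None = None
    methylation: str | None = None
    out_dir: str = "skewscape_out"
    flank_bp: int = 200
    n_bins: int = 40
    shuffle_end_bp: int = 100
    n_shuffles: int = 1000
    alpha: float = 0.05
    region_len: int = 750
    corr_end_bp: int = 75
    max_shuffle_genes: int | None = None
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _load_genes(config: RunConfig) -> list[OrientedGene]:
    if config.orf_fasta:
        return read_orf_fasta(config.orf_fasta, strict_orf=False)
    if not config.fasta or not config.gff:
        raise FileNotFoundError("config must set either orf_fasta or fasta+gff")
    for p in (config.fasta, config.gff):
        if not Path(p).exists():
            raise FileNotFoundError(f"input file not found: {p}")
    seqs = read_fasta(config.fasta)
    records = read_annotations(config.gff)
    return extract_genes(seqs, records, flank=config.flank_bp, strict_orf=True)


def run_species_report(config: RunConfig) -> dict:
    """Run every analysis stage on one species and write a report bundle.

    Writes metagene/profile TSVs, the three-line fit JSON, nucleotide and
    amino-acid bias tables, the shuffle-test table, and a summary JSON with
    provenance (parameters and package version).  Deterministic given the
    config's seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genes = _load_genes(config)
    if not genes:
        raise ValueError("no genes loaded")
    summary: dict = {
        "species": config.species,
        "n_genes": len(genes),
        "config": asdict(config),
        "version": __version__,
    }

    for pair in ("GC", "AT"):
        mg = binned_metagene(genes, n_bins=config.n_bins, flank_bp=config.flank_bp)
        mg.to_frame(pair).to_csv(out / f"metagene_{pair.lower()}.tsv", sep="\t", index=False)
    for anchor in ("start", "stop"):
        prof = superposed_profile(genes, anchor=anchor, upstream_bp=config.flank_bp,
                                  downstream_bp=config.flank_bp)
        prof.to_frame().to_csv(out / f"profile_{anchor}.tsv", sep="\t", index=False)

    regions = build_regions(genes, region_len=config.region_len)
    fit = fit_three_line(regions)
    (out / "threeline_fit.json").write_text(fit.to_json())
    summary["threeline"] = json.loads(fit.to_json())

    shuffle_genes = genes
    if config.max_shuffle_genes is not None:
        shuffle_genes = genes[: config.max_shuffle_genes]
    frac, table = significant_fraction(
        shuffle_genes, end_bp=config.shuffle_end_bp, n_shuffles=config.n_shuffles,
        alpha=config.alpha, seed=config.seed,
    )
    table.to_csv(out / "shuffle_test.tsv", sep="\t", index=False)
    summary["significant_fraction"] = frac

    orfs = [g for g in genes if g.is_strict_orf()]
    if orfs:
        try:
            terminal_nucleotide_ratios(orfs).to_frame().to_csv(
                out / "nucleotide_ratios.tsv", sep="\t"
            )
            bias = terminal_aa_bias(orfs)
            bias.to_csv(out / "aa_bias.tsv", sep="\t", index=False)
            summary["n_biased_residues_p001"] = int((bias["chi2_p"] < 0.001).sum())
        except ValueError as err:
            logger.warning("composition-bias stage skipped: %s", err)

    summ = summarize_genes(genes, end_bp=config.corr_end_bp)
    summ.to_csv(out / "gene_summaries.tsv", sep="\t")
    summary["overall_gc_skew"] = float(np.nanmean(summ["gc_skew_total"]))
    summary["overall_at_skew"] = float(np.nanmean(summ["at_skew_total"]))

    if config.expression:
        expr = read_two_column_tsv(config.expression)
        ec = expression_correlation(genes, expr, end_bp=config.corr_end_bp,
                                    seed=config.seed)
        summary["expression_correlation"] = asdict(ec)
    if config.methylation:
        levels = read_two_column_tsv(config.methylation)
        ma = methylation_association(genes, levels, end_bp=config.corr_end_bp)
        summary["methylation_association"] = asdict(ma)

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary


def run_multi_species(configs: Sequence[RunConfig]) -> pd.DataFrame:
    """Run each species and merge overall skews into one table.

    The returned frame has one row per species (overall GC skew, AT skew,
    gene count) and feeds :func:`skewscape.correlations.species_scatter`.
    """
    if not configs:
        raise ValueError("need at least one species config")
    names = [c.species for c in configs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate species ids")
    rows = []
    for config in configs:
        s = run_species_report(config)
        rows.append({"species": s["species"], "gc_skew": s["overall_gc_skew"],
                     "at_skew": s["overall_at_skew"], "n_genes": s["n_genes"]})
    return pd.DataFrame(rows).set_index("species")
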