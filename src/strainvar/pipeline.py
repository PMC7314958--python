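"""End-to-end orchestration: parse inputs, classify, summarize, optional
homology, and write a combined report.

The report records every denominator and threshold used, so a run is fully
reproducible from ``report.json`` plus the input files.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any

import pandas as pd

from . import __version__
from .consequence import SPLICE_WINDOW, classify_all
from .homology import (
    DEFAULT_EVALUE_THRESHOLD,
    nucleotide_scheme,
    presence_absence,
    protein_scheme,
    reciprocal_best_hits,
)
from .io import (
    read_family_table,
    read_fasta,
    read_gff3,
    read_group_table,
    read_vcf,
)
from .summarize import (
    DEFAULT_AAC_BINS,
    affection_classes,
    bin_by_aac,
    enrichment_test,
    family_rollup,
    genome_identity,
    overview,
    per_gene_summary,
    variant_density,
)

logger = logging.getLogger("strainvar")

__all__ = ["RunConfig", "run_pipeline", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    genome: str
    gff: str
    vcf: str
    outdir: str
    families: str | None = None
    groups: str | None = None
    second_cds: str | None = None       # derived strain's CDS set (FASTA)
    second_genome: str | None = None    # derived strain's assembly (FASTA)
    cds_gene_total: int | None = None   # defaults to the parsed gene count
    family_gene_total: int | None = None  # defaults to the annotated gene count
    evalue_threshold: float = DEFAULT_EVALUE_THRESHOLD
    splice_window: int = SPLICE_WINDOW
    aac_selection_threshold: int = 50   # gene selection for enrichment
    affection_cuts: tuple[float, float] = (5.0, 10.0)
    homology_mode: str = "nucleotide"
    quiet: bool = False

    def validate(self) -> None:
        for name in ("genome", "gff", "vcf"):
            path = getattr(self, name)
            if not path or not os.path.exists(path):
                raise ConfigError(f"{name} file missing: {path!r}")
        for name in ("families", "groups", "second_cds", "second_genome"):
            path = getattr(self, name)
            if path is not None and not os.path.exists(path):
                raise ConfigError(f"{name} file missing: {path!r}")
        if self.splice_window < 0:
            raise ConfigError("splice window must be >= 0")
        if self.evalue_threshold <= 0:
            raise ConfigError("e-value threshold must be positive")


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run classify -> summarize -> (optional) orthologs/presence.

    Writes all stage outputs plus ``report.json`` and ``warnings.tsv`` into
    ``config.outdir`` and returns the report dictionary.
    """
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    all_warnings: list[str] = []

    genome = read_fasta(config.genome)
    models = read_gff3(config.gff, genome)
    variants = read_vcf(config.vcf, genome)
    gene_universe = {m.gene_id for m in models}
    logger.info("parsed %d contigs (%d bp), %d gene models, %d variants",
                len(genome.contigs), genome.total_size, len(models), len(variants))

    cds_gene_total = config.cds_gene_total or len(models)
    logger.info("CDS gene denominator: %d", cds_gene_total)

    consequences = classify_all(variants, models, genome, config.splice_window)
    consequences.to_csv(os.path.join(config.outdir, "consequences.tsv"), sep="\t", index=False)

    from .consequence import build_spliced_cds, translate

    protein_lengths = {}
    for m in models:
        seq, _ = build_spliced_cds(m, genome)
        prot = translate(seq[: len(seq) - len(seq) % 3])
        protein_lengths[m.gene_id] = len(prot.rstrip("*"))

    summaries, warn = per_gene_summary(consequences, protein_lengths)
    all_warnings.extend(warn)
    pd.DataFrame(
        [
            {
                "gene_id": s.gene_id, "protein_length": s.protein_length,
                "n_AAC": s.n_AAC, "n_synonymous": s.n_synonymous,
                "n_insertion": s.n_insertion, "n_deletion": s.n_deletion,
                "n_frameshift": s.n_frameshift, "n_VCSS": s.n_VCSS,
                "n_total": s.n_total, "degree_of_affection": s.degree_of_affection,
            }
            for s in summaries
        ]
    ).to_csv(os.path.join(config.outdir, "gene_summaries.tsv"), sep="\t", index=False)

    bins = bin_by_aac(summaries, DEFAULT_AAC_BINS)
    bins.to_csv(os.path.join(config.outdir, "gene_bins.tsv"), sep="\t", index=False)

    selection = [s for s in summaries if s.n_AAC >= config.aac_selection_threshold]
    low, mid, high = affection_classes(selection, config.affection_cuts)

    families = None
    family_gene_total = config.family_gene_total
    if config.families:
        families, warn = read_family_table(config.families, gene_universe)
        all_warnings.extend(warn)
        family_gene_total = family_gene_total or len(families.annotated_genes)
        logger.info("family gene denominator: %d", family_gene_total)
        fams, classes, warn = family_rollup(summaries, families)
        all_warnings.extend(warn)
        pd.DataFrame(
            [
                {
                    "family": f.family, "n_genes": f.n_genes,
                    "genes_with_variants": f.genes_with_variants,
                    "total_variants": f.total_variants,
                    "variants_per_gene": f.variants_per_gene,
                    "genes_with_AAC": f.genes_with_AAC,
                    "genes_with_insertion": f.genes_with_insertion,
                    "genes_with_deletion": f.genes_with_deletion,
                    "genes_with_frameshift": f.genes_with_frameshift,
                    "genes_with_VCSS": f.genes_with_VCSS,
                }
                for f in fams
            ]
        ).to_csv(os.path.join(config.outdir, "families_summary.tsv"), sep="\t", index=False)
        classes.to_csv(os.path.join(config.outdir, "family_classes.tsv"), sep="\t", index=False)

    table = overview(consequences, cds_gene_total, families, family_gene_total)
    table.to_csv(os.path.join(config.outdir, "overview.tsv"), sep="\t", index=False)

    enrichment_rows = []
    if config.groups:
        groups, warn = read_group_table(config.groups, gene_universe, cds_gene_total)
        all_warnings.extend(warn)
        selected_ids = [s.gene_id for s in selection]
        for label, members in sorted(groups.groups.items()):
            p, x, n, K = enrichment_test(selected_ids, members, cds_gene_total)
            enrichment_rows.append(
                {"group": label, "group_size": K, "selection_size": n,
                 "overlap": x, "p_value": p}
            )
        pd.DataFrame(
            enrichment_rows,
            columns=["group", "group_size", "selection_size", "overlap", "p_value"],
        ).to_csv(os.path.join(config.outdir, "enrichment.tsv"), sep="\t", index=False)

    homology_report: dict[str, Any] = {}
    if config.second_cds:
        scheme = (
            protein_scheme() if config.homology_mode == "protein" else nucleotide_scheme()
        )
        query_cds = {}
        for m in models:
            seq, _ = build_spliced_cds(m, genome)
            query_cds[m.gene_id] = seq
        target_cds = read_fasta(config.second_cds).contigs
        pairs = reciprocal_best_hits(query_cds, target_cds, scheme, config.evalue_threshold)
        pd.DataFrame([{"a": p.a_id, "b": p.b_id, "score": p.score} for p in pairs]).to_csv(
            os.path.join(config.outdir, "ortholog_pairs.tsv"), sep="\t", index=False
        )
        homology_report["ortholog_pairs"] = len(pairs)
        if config.second_genome:
            target_genome = read_fasta(config.second_genome).contigs
            calls = presence_absence(
                query_cds, target_cds, target_genome, nucleotide_scheme(),
                config.evalue_threshold,
            )
            pd.DataFrame(
                [{"gene_id": c.gene_id, "status": c.status} for c in calls]
            ).to_csv(os.path.join(config.outdir, "presence.tsv"), sep="\t", index=False)
            homology_report["presence"] = {
                status: sum(1 for c in calls if c.status == status)
                for status in ("present_in_cds", "present_in_genome_only", "absent")
            }

    primary = consequences[consequences["primary"]]
    n_variants = int(primary["variant_idx"].nunique())
    n_snps = int(sum(r["n_all"] for _, r in table.iterrows() if r["category"] == "SNPs"))
    n_indels = int(sum(r["n_all"] for _, r in table.iterrows() if r["category"] == "indels"))
    region_counts = primary["region"].value_counts().to_dict()

    report = {
        "tool": "strainvar",
        "version": __version__,
        "parameters": {
            "cds_gene_total": cds_gene_total,
            "family_gene_total": family_gene_total,
            "evalue_threshold": config.evalue_threshold,
            "splice_window": config.splice_window,
            "aac_selection_threshold": config.aac_selection_threshold,
            "affection_cuts": list(config.affection_cuts),
        },
        "totals": {
            "variants": n_variants,
            "snps": n_snps,
            "indels": n_indels,
            "regions": {k: int(v) for k, v in sorted(region_counts.items())},
            "genes_with_aac": sum(1 for s in summaries if s.n_AAC > 0),
            "genome_identity_pct": genome_identity(n_snps, genome.total_size),
            "bp_per_variant": variant_density(n_variants, genome.total_size),
        },
        "affection_classes": {"le_5": low, "5_to_10": mid, "gt_10": high},
        "enrichment": enrichment_rows,
        "homology": homology_report,
    }
    with open(os.path.join(config.outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(os.path.join(config.outdir, "warnings.tsv"), "w") as fh:
        fh.write("warning\n")
        for w in all_warnings:
            fh.write(w + "\n")
    logger.info("report written to %s", os.path.join(config.outdir, "report.json"))
    return report
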