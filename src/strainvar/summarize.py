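"""Per-gene and per-family aggregation, headline summary statistics, and
hypergeometric overrepresentation tests.

Percentages are rounded half-up (2 decimals; genome identity 1 decimal) so
summary tables reproduce printed values bit-exactly from their
numerator/denominator pairs.  Denominators are always explicit inputs — the
reference annotation's gene total for CDS percentages, the family list's
total for family percentages — never inferred from the tables themselves.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .io import FamilyAnnotation

__all__ = [
    "GeneVariantSummary",
    "FamilySummary",
    "round_half_up",
    "per_gene_summary",
    "bin_by_aac",
    "affection_classes",
    "family_rollup",
    "overview",
    "genome_identity",
    "variant_density",
    "enrichment_test",
    "hypergeom_tail",
    "CAZY_CLASS_PREFIXES",
    "DEFAULT_AAC_BINS",
]

CAZY_CLASS_PREFIXES = ("GH", "GT", "PL", "CE", "AA", "CBM", "EXP")

# Fig-7-style binning of genes by AAC count, plus open tails at >=50 / >=100
DEFAULT_AAC_BINS: tuple[tuple[int, int | None], ...] = (
    (1, 10), (11, 49), (50, 99), (100, None),
)

AAC_EFFECTS = ("AAC", "stop_gained", "stop_lost")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (0.005 -> 0.01), as printed tables use."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def pct(numerator: int, denominator: int, ndigits: int = 2) -> float | None:
    """100*numerator/denominator rounded half-up; None for a zero denominator."""
    if denominator == 0:
        return None
    return round_half_up(100.0 * numerator / denominator, ndigits)


@dataclass
class GeneVariantSummary:
    gene_id: str
    protein_length: int | None
    n_AAC: int
    n_synonymous: int
    n_insertion: int
    n_deletion: int
    n_frameshift: int
    n_VCSS: int
    n_total: int  # all gene-linked consequence records

    @property
    def degree_of_affection(self) -> float | None:
        """AAC count as a percentage of protein length."""
        if not self.protein_length:
            return None
        return 100.0 * self.n_AAC / self.protein_length


@dataclass
class FamilySummary:
    family: str
    n_genes: int
    genes_with_variants: int
    total_variants: int
    genes_with_AAC: int
    genes_with_insertion: int
    genes_with_deletion: int
    genes_with_frameshift: int
    genes_with_VCSS: int

    @property
    def variants_per_gene(self) -> float:
        return self.total_variants / self.n_genes if self.n_genes else 0.0


# ---------------------------------------------------------------------------
# Per-gene aggregation
# ---------------------------------------------------------------------------


def per_gene_summary(
    consequences: pd.DataFrame, protein_lengths: Mapping[str, int] | None = None
) -> tuple[list[GeneVariantSummary], list[str]]:
    """Aggregate the consequence table per gene.

    Every gene with at least one gene-linked record appears, including genes
    whose only variants are intronic/UTR (zero effect counts), so region
    tallies conserve totals.  Stop gained/lost are folded into the AAC count
    (the generic amino-acid-change category) but stay distinguishable in the
    consequence table itself.  Returns (summaries, warnings).
    """
    protein_lengths = protein_lengths or {}
    warnings: list[str] = []
    out: list[GeneVariantSummary] = []
    linked = consequences[consequences["gene_id"].notna()]
    for gene_id, grp in linked.groupby("gene_id", sort=True):
        eff = grp["effect"]
        in_cds = grp["region"] == "CDS"
        plen = protein_lengths.get(gene_id)
        if plen is None and protein_lengths:
            warnings.append(f"no protein length for {gene_id}; degree of affection omitted")
        out.append(
            GeneVariantSummary(
                gene_id=gene_id,
                protein_length=plen,
                n_AAC=int(eff.isin(AAC_EFFECTS).sum()),
                n_synonymous=int((eff == "synonymous").sum()),
                n_insertion=int((in_cds & (grp["vclass"] == "insertion")).sum()),
                n_deletion=int((in_cds & (grp["vclass"] == "deletion")).sum()),
                n_frameshift=int((eff == "frameshift").sum()),
                n_VCSS=int((eff == "VCSS").sum()),
                n_total=len(grp),
            )
        )
    return out, warnings


def bin_by_aac(
    summaries: Sequence[GeneVariantSummary],
    bins: Sequence[tuple[int, int | None]] = DEFAULT_AAC_BINS,
    tails: Sequence[int] = (50, 100),
) -> pd.DataFrame:
    """Histogram of genes by AAC count, with open-ended tail rows.

    Percentages are relative to the number of genes with at least one AAC.
    """
    with_aac = [s for s in summaries if s.n_AAC >= 1]
    denom = len(with_aac)
    rows = []
    for lo, hi in bins:
        label = f"{lo}-{hi}" if hi is not None else f">={lo}"
        n = sum(1 for s in with_aac if s.n_AAC >= lo and (hi is None or s.n_AAC <= hi))
        rows.append({"bin": label, "kind": "bin", "n_genes": n, "pct": pct(n, denom)})
    for t in tails:
        n = sum(1 for s in with_aac if s.n_AAC >= t)
        rows.append({"bin": f">={t}", "kind": "tail", "n_genes": n, "pct": pct(n, denom)})
    return pd.DataFrame(rows)


def affection_classes(
    summaries: Sequence[GeneVariantSummary], cuts: tuple[float, float] = (5.0, 10.0)
) -> tuple[int, int, int]:
    """Partition a selection into <=lo%, (lo,hi]%, >hi% degree-of-affection
    classes.  Boundary values fall in the lower class.  Genes without a
    degree of affection are excluded."""
    lo, hi = cuts
    n_low = n_mid = n_high = 0
    for s in summaries:
        d = s.degree_of_affection
        if d is None:
            continue
        if d <= lo:
            n_low += 1
        elif d <= hi:
            n_mid += 1
        else:
            n_high += 1
    return n_low, n_mid, n_high


# ---------------------------------------------------------------------------
# Family-level aggregation
# ---------------------------------------------------------------------------


def cazy_class(family: str) -> str:
    for prefix in sorted(CAZY_CLASS_PREFIXES, key=len, reverse=True):
        if family.upper().startswith(prefix):
            return prefix
    return "other"


def family_rollup(
    summaries: Sequence[GeneVariantSummary], annotation: FamilyAnnotation
) -> tuple[list[FamilySummary], pd.DataFrame, list[str]]:
    """Per-family variant burden, size-normalized, plus top-level class tallies.

    A gene carrying two family labels contributes to both rollups.  Returns
    (family summaries, class-level DataFrame, warnings).
    """
    by_gene = {s.gene_id: s for s in summaries}
    warnings: list[str] = []
    fams: list[FamilySummary] = []
    for family, members in sorted(annotation.families.items()):
        cls = cazy_class(family)
        if cls == "other":
            warnings.append(f"unknown family prefix for {family!r}; grouped under 'other'")
        stats = [by_gene.get(g) for g in members]
        fams.append(
            FamilySummary(
                family=family,
                n_genes=len(members),
                genes_with_variants=sum(1 for s in stats if s and s.n_total > 0),
                total_variants=sum(s.n_total for s in stats if s),
                genes_with_AAC=sum(1 for s in stats if s and s.n_AAC > 0),
                genes_with_insertion=sum(1 for s in stats if s and s.n_insertion > 0),
                genes_with_deletion=sum(1 for s in stats if s and s.n_deletion > 0),
                genes_with_frameshift=sum(1 for s in stats if s and s.n_frameshift > 0),
                genes_with_VCSS=sum(1 for s in stats if s and s.n_VCSS > 0),
            )
        )
    rows = []
    for f in fams:
        rows.append(
            {
                "class": cazy_class(f.family),
                "family": f.family,
                "n_genes": f.n_genes,
                "genes_with_variants": f.genes_with_variants,
                "total_variants": f.total_variants,
                "variants_per_gene": f.variants_per_gene,
                "genes_with_AAC": f.genes_with_AAC,
            }
        )
    per_family = pd.DataFrame(rows)
    if per_family.empty:
        classes = pd.DataFrame(
            columns=["class", "n_genes", "genes_with_variants", "total_variants",
                     "genes_with_AAC"]
        )
    else:
        classes = (
            per_family.groupby("class")[
                ["n_genes", "genes_with_variants", "total_variants", "genes_with_AAC"]
            ]
            .sum()
            .reset_index()
        )
    return fams, classes, warnings


# ---------------------------------------------------------------------------
# Overview table (variant totals and shares)
# ---------------------------------------------------------------------------


def overview(
    consequences: pd.DataFrame,
    cds_gene_total: int,
    annotation: FamilyAnnotation | None = None,
    family_gene_total: int | None = None,
) -> pd.DataFrame:
    """Genome-wide and family-restricted variant overview.

    Rows: total variants, SNPs, indels (MNVs decomposed into per-base SNPs
    for the SNP/indel split), then the coding-effect categories with affected
    gene counts.  Gene percentages use the explicit ``cds_gene_total`` and
    ``family_gene_total`` denominators; variant percentages use the matching
    category total in the all-variants column.
    """
    primary = consequences[consequences["primary"]]
    fam_genes = annotation.annotated_genes if annotation else set()
    in_fam = consequences["gene_id"].isin(fam_genes)

    def _counts(df: pd.DataFrame) -> tuple[int, int, int]:
        per_variant = df.drop_duplicates("variant_idx")
        snps = sum(
            len(r) if len(r) == len(a) else 0
            for r, a in zip(per_variant["ref"], per_variant["alt"])
        )
        indels = int((per_variant["ref"].str.len() != per_variant["alt"].str.len()).sum())
        return snps + indels, snps, indels

    total_all, snp_all, indel_all = _counts(primary)
    # family restriction: variants with any consequence record in a family gene
    fam_idx = set(consequences.loc[in_fam, "variant_idx"])
    total_fam, snp_fam, indel_fam = _counts(
        primary[primary["variant_idx"].isin(fam_idx)]
    )

    rows = [
        {"category": "total_variants", "n_all": total_all, "pct_all": pct(total_all, total_all),
         "n_family": total_fam, "pct_family": pct(total_fam, total_all)},
        {"category": "SNPs", "n_all": snp_all, "pct_all": pct(snp_all, total_all),
         "n_family": snp_fam, "pct_family": pct(snp_fam, snp_all)},
        {"category": "indels", "n_all": indel_all, "pct_all": pct(indel_all, total_all),
         "n_family": indel_fam, "pct_family": pct(indel_fam, indel_all)},
    ]

    linked = consequences[consequences["gene_id"].notna()]
    cats = {
        "AACs_in_CDS": linked["effect"].isin(AAC_EFFECTS),
        "deletions_in_CDS": (linked["region"] == "CDS") & (linked["vclass"] == "deletion"),
        "insertions_in_CDS": (linked["region"] == "CDS") & (linked["vclass"] == "insertion"),
        "frameshifts": linked["effect"] == "frameshift",
        "VCSSs": linked["effect"] == "VCSS",
    }
    for name, mask in cats.items():
        sub = linked[mask]
        fam_sub = sub[sub["gene_id"].isin(fam_genes)]
        n_genes = sub["gene_id"].nunique()
        n_fam_genes = fam_sub["gene_id"].nunique()
        rows.append(
            {
                "category": name,
                "n_all": len(sub),
                "pct_all": pct(n_genes, cds_gene_total),
                "n_family": len(fam_sub),
                "pct_family": pct(n_fam_genes, family_gene_total or 0),
                "n_genes_all": n_genes,
                "n_genes_family": n_fam_genes,
            }
        )
    return pd.DataFrame(rows)


def genome_identity(snp_count: int, genome_size_bp: int) -> float:
    """Percent identity implied by a SNP count: 100*(1 - snps/size), 1 decimal."""
    if genome_size_bp <= 0:
        raise ValueError("genome size must be positive")
    if snp_count > genome_size_bp:
        raise ValueError("SNP count exceeds genome size")
    return round_half_up(100.0 * (1.0 - snp_count / genome_size_bp), 1)


def variant_density(total_variants: int, genome_size_bp: int) -> float | None:
    """Basepairs per variant (one difference per N bp), 1 decimal."""
    if total_variants == 0:
        return None
    return round_half_up(genome_size_bp / total_variants, 1)


# ---------------------------------------------------------------------------
# Overrepresentation
# ---------------------------------------------------------------------------


def hypergeom_tail(N: int, K: int, n: int, x: int) -> float:
    """Upper-tail P(X >= x) for a hypergeometric draw: population N with K
    marked, sample of n, at least x marked observed."""
    if x > min(n, K) or K > N or n > N or min(N, K, n, x) < 0:
        raise ValueError(f"inconsistent counts N={N} K={K} n={n} x={x}")
    return float(hypergeom.sf(x - 1, N, K, n))


def enrichment_test(
    selected_genes: Iterable[str], group_genes: Iterable[str], population_size: int
) -> tuple[float, int, int, int]:
    """One-sided overrepresentation of a functional group in a selection.

    Returns (p, x, n, K): the hypergeometric upper-tail probability of seeing
    at least x = |selection ∩ group| group members in a selection of n genes,
    given K group members among ``population_size`` genes.  No
    multiple-testing correction (apply one downstream if testing many groups).
    """
    sel = set(selected_genes)
    grp = set(group_genes)
    x, n, K = len(sel & grp), len(sel), len(grp)
    return hypergeom_tail(population_size, K, n, x), x, n, K
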