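import pandas as pd
import pytest

import strainvar as sv
from strainvar.summarize import (
    GeneVariantSummary,
    affection_classes,
    bin_by_aac,
    pct,
    round_half_up,
)

from oracles import hypergeom_oracle


def gs(gene_id, n_aac, plen=200, **kw):
    defaults = dict(n_synonymous=0, n_insertion=0, n_deletion=0,
                    n_frameshift=0, n_VCSS=0, n_total=n_aac)
    defaults.update(kw)
    return GeneVariantSummary(gene_id=gene_id, protein_length=plen, n_AAC=n_aac,
                              **defaults)


class TestRounding:
    @pytest.mark.parametrize(
        "num,den,expected",
        [
            (660_566, 686_403, 96.24),   # SNP share of all variants
            (25_837, 686_403, 3.76),     # indel share
            (16_299, 686_403, 2.37),     # family-gene share of all variants
            (10_027, 12_541, 79.95),     # genes with AACs / CDS gene total
            (17, 317, 5.36),             # family genes with deletions
            (30, 317, 9.46),             # family genes with insertions
            (33, 317, 10.41),            # family genes with VCSSs
            (293, 317, 92.43),           # family genes with AACs
        ],
    )
    def test_printed_percentages_recompute(self, num, den, expected):
        assert pct(num, den) == expected

    def test_half_up_not_bankers(self):
        assert round_half_up(0.125, 2) == 0.13
        assert round_half_up(2.5, 0) == 3.0

    def test_zero_denominator_undefined(self):
        assert pct(5, 0) is None


class TestPerGeneSummary:
    TABLE = pd.DataFrame(
        [
            # gene g1: 2 AACs + 1 frameshift
            dict(variant_idx=0, contig="c", pos=10, ref="A", alt="T", vclass="SNP",
                 gene_id="g1", region="CDS", effect="AAC", primary=True),
            dict(variant_idx=1, contig="c", pos=30, ref="A", alt="T", vclass="SNP",
                 gene_id="g1", region="CDS", effect="AAC", primary=True),
            dict(variant_idx=2, contig="c", pos=50, ref="AT", alt="A",
                 vclass="deletion", gene_id="g1", region="CDS",
                 effect="frameshift", primary=True),
            # gene g2: only an intronic variant
            dict(variant_idx=3, contig="c", pos=99, ref="G", alt="C", vclass="SNP",
                 gene_id="g2", region="intron", effect="none", primary=True),
            # intergenic
            dict(variant_idx=4, contig="c", pos=500, ref="G", alt="C", vclass="SNP",
                 gene_id=None, region="intergenic", effect="none", primary=True),
        ]
    )

    def test_counts_partitioned_by_effect(self):
        summaries, _ = sv.per_gene_summary(self.TABLE, {"g1": 200, "g2": 100})
        by_id = {s.gene_id: s for s in summaries}
        assert by_id["g1"].n_AAC == 2
        assert by_id["g1"].n_frameshift == 1
        assert by_id["g1"].n_deletion == 1

    def test_intronic_only_gene_included_with_zero_counts(self):
        summaries, _ = sv.per_gene_summary(self.TABLE)
        by_id = {s.gene_id: s for s in summaries}
        assert by_id["g2"].n_AAC == 0 and by_id["g2"].n_total == 1

    def test_degree_of_affection(self):
        s = gs("g", 20, plen=200)
        assert s.degree_of_affection == 10.0

    def test_missing_protein_length_warns(self):
        summaries, warnings = sv.per_gene_summary(self.TABLE, {"g1": 200})
        assert any("g2" in w for w in warnings)
        by_id = {s.gene_id: s for s in summaries}
        assert by_id["g2"].degree_of_affection is None


class TestBinning:
    def test_fig_style_bins(self):
        summaries = [gs(f"g{i}", n) for i, n in enumerate([3, 7, 55, 120])]
        table = bin_by_aac(summaries, bins=((1, 10), (11, 49), (50, 99), (100, None)))
        bins = table[table["kind"] == "bin"]["n_genes"].tolist()
        assert bins == [2, 0, 1, 1]

    def test_empty_input_all_zero(self):
        table = bin_by_aac([])
        assert (table["n_genes"] == 0).all()

    def test_tails_agree_with_direct_filter(self):
        counts = [1, 5, 49, 50, 51, 99, 100, 150, 7, 60]
        summaries = [gs(f"g{i}", n) for i, n in enumerate(counts)]
        table = bin_by_aac(summaries)
        tails = dict(zip(table[table["kind"] == "tail"]["bin"],
                         table[table["kind"] == "tail"]["n_genes"]))
        assert tails[">=50"] == sum(1 for n in counts if n >= 50)
        assert tails[">=100"] == sum(1 for n in counts if n >= 100)

    def test_bin_counts_sum_to_selection(self):
        counts = [1, 2, 11, 49, 50, 120, 130]
        summaries = [gs(f"g{i}", n) for i, n in enumerate(counts)]
        table = bin_by_aac(summaries)
        assert table[table["kind"] == "bin"]["n_genes"].sum() == len(counts)


class TestAffectionClasses:
    def test_one_per_class(self):
        sums = [gs("a", 8, 200), gs("b", 14, 200), gs("c", 24, 200)]
        # degrees 4.0, 7.0, 12.0
        assert affection_classes(sums) == (1, 1, 1)

    def test_boundaries_belong_to_lower_class(self):
        sums = [gs("a", 10, 200), gs("b", 20, 200)]  # degrees 5.0 and 10.0
        assert affection_classes(sums) == (1, 1, 0)

    def test_partition_is_exhaustive(self):
        sums = [gs(f"g{i}", i, 100) for i in range(1, 30)]
        assert sum(affection_classes(sums)) == len(sums)


class TestFamilyRollup:
    def test_normalized_rate_and_gene_counts(self):
        ann = sv.FamilyAnnotation()
        ann.add("g1", "GH5_5")
        ann.add("g2", "GH5_5")
        sums = [gs("g1", 6, n_total=6), gs("g2", 0, n_total=0)]
        fams, classes, _ = sv.family_rollup(sums, ann)
        (f,) = fams
        assert f.variants_per_gene == 3.0 and f.genes_with_variants == 1

    def test_multi_label_gene_counts_in_both(self):
        ann = sv.FamilyAnnotation()
        ann.add("g1", "GH5_5")
        ann.add("g1", "CBM13")
        fams, _, _ = sv.family_rollup([gs("g1", 2, n_total=2)], ann)
        assert all(f.genes_with_variants == 1 for f in fams)

    def test_class_tally_sums_subfamilies(self):
        ann = sv.FamilyAnnotation()
        for g, fam in [("g1", "GH5_5"), ("g2", "GH16"), ("g3", "AA3_2")]:
            ann.add(g, fam)
        sums = [gs("g1", 1, n_total=1), gs("g2", 2, n_total=2), gs("g3", 3, n_total=3)]
        _, classes, _ = sv.family_rollup(sums, ann)
        gh = classes[classes["class"] == "GH"].iloc[0]
        assert gh["n_genes"] == 2 and gh["total_variants"] == 3

    def test_unknown_prefix_grouped_other_with_warning(self):
        ann = sv.FamilyAnnotation()
        ann.add("g1", "XYZ9")
        _, classes, warnings = sv.family_rollup([gs("g1", 1)], ann)
        assert "other" in set(classes["class"])
        assert warnings


class TestHeadlineStats:
    def test_identity_from_printed_pair(self):
        assert sv.genome_identity(660_566, 42_500_000) == 98.4

    def test_identity_no_snps(self):
        assert sv.genome_identity(0, 1_000) == 100.0

    def test_identity_matches_column_comparison(self):
        a = "ACGTACGTACGTACGTACGT"
        b = "ACGTACGAACGTACCTACGT"  # 2 mismatching columns
        mismatches = sum(1 for x, y in zip(a, b) if x != y)
        assert sv.genome_identity(mismatches, len(a)) == round_half_up(
            100 * (1 - mismatches / len(a)), 1
        )

    def test_identity_contract_error(self):
        with pytest.raises(ValueError):
            sv.genome_identity(10, 5)

    def test_density_examples(self):
        assert sv.variant_density(1_000, 60_000) == 60.0
        assert sv.variant_density(686_403, 42_500_000) == 61.9
        assert sv.variant_density(0, 100) is None

    def test_density_linear_in_size(self):
        assert sv.variant_density(100, 30_000) == sv.variant_density(100, 60_000) / 2


class TestEnrichment:
    def test_small_case_matches_enumeration(self):
        # N=20, K=5, n=4, x>=3: 155 favourable draws of C(20,4)=4845
        p = sv.hypergeom_tail(20, 5, 4, 3)
        assert p == pytest.approx(155 / 4845, abs=1e-12)
        assert p == pytest.approx(hypergeom_oracle(20, 5, 4, 3), abs=1e-12)

    @pytest.mark.parametrize("N,K,n,x", [(10, 3, 4, 1), (12, 6, 5, 3),
                                         (15, 4, 6, 2), (25, 8, 5, 4)])
    def test_tail_equals_enumeration(self, N, K, n, x):
        assert sv.hypergeom_tail(N, K, n, x) == pytest.approx(
            hypergeom_oracle(N, K, n, x), abs=1e-12
        )

    def test_zero_overlap_certain(self):
        assert sv.hypergeom_tail(20, 5, 4, 0) == 1.0

    def test_full_draw_certain(self):
        assert sv.hypergeom_tail(12, 5, 12, 5) == pytest.approx(1.0)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            sv.hypergeom_tail(20, 5, 4, 5)

    def test_gene_set_interface(self):
        p, x, n, K = sv.enrichment_test(
            ["g1", "g2", "g3", "g4"], ["g1", "g2", "g9", "g10", "g11"], 20
        )
        assert (x, n, K) == (2, 4, 5)
        assert p == pytest.approx(hypergeom_oracle(20, 5, 4, 2), abs=1e-12)


class TestOverview:
    def test_totals_and_conservation(self, small_parsed, small_bundle):
        genome, models, variants = small_parsed
        table = sv.classify_all(variants, models, genome)
        ov = sv.overview(table, cds_gene_total=len(models),
                         annotation=small_bundle.families,
                         family_gene_total=len(small_bundle.families.annotated_genes))
        row = {r["category"]: r for _, r in ov.iterrows()}
        assert row["SNPs"]["n_all"] + row["indels"]["n_all"] == row["total_variants"]["n_all"]
        assert row["total_variants"]["n_all"] == len(variants)
        assert row["total_variants"]["pct_all"] == 100.0
        # family variants are a subset
        assert row["total_variants"]["n_family"] <= row["total_variants"]["n_all"]

    def test_percentages_recompute_from_cells(self, small_parsed, small_bundle):
        genome, models, variants = small_parsed
        table = sv.classify_all(variants, models, genome)
        fam_total = len(small_bundle.families.annotated_genes)
        ov = sv.overview(table, len(models), small_bundle.families, fam_total)
        for _, r in ov.iterrows():
            if "n_genes_all" in r and pd.notna(r.get("n_genes_all")):
                assert r["pct_all"] == pct(int(r["n_genes_all"]), len(models))
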