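import pytest

import strainvar as sv
from strainvar.consequence import classify_all, translate
from strainvar.io import reverse_complement


def make_gene(gene_id="gA", contig="c1", strand="+", exons=None, cds=None, phases=None):
    cds = cds or [(11, 19)]
    order = cds if strand == "+" else list(reversed(cds))
    if phases is None:
        run, by_iv = 0, {}
        for s, e in order:
            by_iv[(s, e)] = (3 - run % 3) % 3
            run += e - s + 1
        phases = [by_iv[iv] for iv in cds]
    return sv.GeneModel(
        gene_id=gene_id, contig=contig, strand=strand,
        exons=exons or list(cds), cds=cds, phases=phases,
    )


class TestSplicedCds:
    def test_plus_strand_simple(self):
        genome = sv.Genome({"c1": "ATGGCATAA" + "G" * 20})
        gene = make_gene(cds=[(1, 9)])
        seq, posmap = sv.build_spliced_cds(gene, genome)
        assert seq == "ATGGCATAA"
        assert posmap[1] == 0 and posmap[9] == 8

    def test_minus_strand_reverse_complement(self):
        # genomic "TTAT GCCAT": minus-strand CDS over last 6 bases reads ATGGCA
        genome = sv.Genome({"c1": "TTTTGCCAT"})
        gene = make_gene(strand="-", cds=[(4, 9)])
        seq, posmap = sv.build_spliced_cds(gene, genome)
        assert seq == "ATGGCA"
        assert posmap[9] == 0 and posmap[4] == 5

    def test_two_exon_map_is_bijection(self):
        genome = sv.Genome({"c1": "ATG" + "GTTTTTTTAG" + "GCATAA" + "C" * 10})
        gene = make_gene(exons=[(1, 3), (14, 19)], cds=[(1, 3), (14, 19)])
        seq, posmap = sv.build_spliced_cds(gene, genome)
        assert seq == "ATGGCATAA"
        assert sorted(posmap.values()) == list(range(9))
        inverse = {v: k for k, v in posmap.items()}
        assert all(posmap[inverse[i]] == i for i in range(9))

    def test_cds_outside_contig_is_data_error(self):
        genome = sv.Genome({"c1": "ATGGCA"})
        gene = make_gene(cds=[(1, 9)])
        with pytest.raises(sv.DataError):
            sv.build_spliced_cds(gene, genome)


class TestTranslate:
    @pytest.mark.parametrize(
        "cds,protein",
        [("ATGGCTTAA", "MA*"), ("", ""), ("ATGTGA", "M*"), ("GCTGAT", "AD")],
    )
    def test_standard_code(self, cds, protein):
        assert translate(cds) == protein

    def test_partial_codon_rejected(self):
        with pytest.raises(ValueError):
            translate("ATGGC")


# a two-exon plus-strand gene with UTRs for region assignment:
# exon1 = 5..10 (UTR) + 11..19 (CDS part 1), intron 20..29 (GTxxxxxxAG),
# exon2 = 30..32 (CDS part 2) + 33..38 (UTR)
REGION_GENOME = sv.Genome(
    {"c1": "CCCC" + "AACCTT" + "ATGGCTGCT" + "GTTTTTTTAG" + "TAA" + "CCAACC" + "G" * 10}
)
REGION_GENE = make_gene(
    exons=[(5, 19), (30, 38)], cds=[(11, 19), (30, 32)]
)


class TestAssignRegion:
    @pytest.mark.parametrize(
        "pos,expected",
        [
            (2, ("intergenic", None)),
            (7, ("five_prime_UTR", "gA")),
            (12, ("CDS", "gA")),
            (20, ("splice_site", "gA")),  # the G of the GT donor
            (21, ("splice_site", "gA")),  # the T of the GT donor
            (24, ("intron", "gA")),
            (28, ("splice_site", "gA")),  # the A of the AG acceptor
            (31, ("CDS", "gA")),
            (35, ("three_prime_UTR", "gA")),
        ],
    )
    def test_region_and_precedence(self, pos, expected):
        ref = REGION_GENOME.contigs["c1"][pos - 1]
        alt = "A" if ref != "A" else "C"
        v = sv.VariantRecord("c1", pos, ref, alt)
        assert sv.assign_region(v, [REGION_GENE]) == [expected]

    def test_minus_strand_utr_orientation(self):
        gene = make_gene(
            strand="-", exons=[(5, 19), (30, 38)], cds=[(11, 19), (30, 32)]
        )
        v = sv.VariantRecord("c1", 7, REGION_GENOME.contigs["c1"][6], "A")
        ((region, _),) = sv.assign_region(v, [gene])
        assert region == "three_prime_UTR"


class TestClassify:
    def _one(self, v, gene=REGION_GENE, genome=REGION_GENOME):
        ((region, gid),) = sv.assign_region(v, [gene])
        (c,) = sv.classify(v, gene, genome, region)
        return c

    def test_synonymous_codon(self):
        # codon 2 GCT -> GCA, both Ala
        c = self._one(sv.VariantRecord("c1", 16, "T", "A"))
        assert (c.effect, c.aa_ref, c.aa_pos, c.aa_alt) == ("synonymous", "A", 2, "A")

    def test_amino_acid_change(self):
        # codon 3 GCT -> GAT: Ala -> Asp
        c = self._one(sv.VariantRecord("c1", 18, "C", "A"))
        assert (c.effect, c.aa_ref, c.aa_pos, c.aa_alt) == ("AAC", "A", 3, "D")

    def test_stop_lost(self):
        # codon 4 TAA (stop, spliced over the intron) -> CAA
        c = self._one(sv.VariantRecord("c1", 30, "T", "C"))
        assert c.effect == "stop_lost"

    def test_one_base_deletion_is_frameshift(self):
        c = self._one(sv.VariantRecord("c1", 12, "TG", "T"))
        assert c.effect == "frameshift"

    def test_three_base_insertion_is_inframe(self):
        c = self._one(sv.VariantRecord("c1", 12, "T", "TGCA"))
        assert c.effect == "inframe_insertion"

    def test_snp_in_donor_dinucleotide_is_vcss(self):
        c = self._one(sv.VariantRecord("c1", 21, "T", "C"))
        assert c.effect == "VCSS" and c.region == "splice_site"

    def test_strand_symmetry(self):
        """A mirrored minus-strand construction yields identical effects."""
        seq = REGION_GENOME.contigs["c1"]
        L = len(seq)
        mirror = sv.Genome({"c1": reverse_complement(seq)})
        flip = lambda iv: (L - iv[1] + 1, L - iv[0] + 1)  # noqa: E731
        gene_m = make_gene(
            strand="-",
            exons=sorted(flip(iv) for iv in REGION_GENE.exons),
            cds=sorted(flip(iv) for iv in REGION_GENE.cds),
        )
        for pos in (12, 16, 18, 21, 30):
            ref = seq[pos - 1]
            alt = "A" if ref != "A" else "G"
            c_plus = self._one(sv.VariantRecord("c1", pos, ref, alt))
            v_m = sv.VariantRecord(
                "c1", L - pos + 1, reverse_complement(ref), reverse_complement(alt)
            )
            ((region, _),) = sv.assign_region(v_m, [gene_m])
            (c_minus,) = sv.classify(v_m, gene_m, mirror, region)
            assert (c_minus.effect, c_minus.aa_pos) == (c_plus.effect, c_plus.aa_pos)


class TestClassifyAll:
    def test_empty_input(self):
        table = classify_all([], [REGION_GENE], REGION_GENOME)
        assert len(table) == 0

    def test_primary_rows_partition_variants(self, small_parsed):
        genome, models, variants = small_parsed
        table = classify_all(variants, models, genome)
        primary = table[table["primary"]]
        assert len(primary) == len(variants)
        assert set(primary["region"]).issubset(
            {"CDS", "intron", "five_prime_UTR", "three_prime_UTR", "splice_site",
             "intergenic"}
        )

    def test_class_effect_consistency(self, small_parsed):
        """SNPs never shift the frame; indels never substitute amino acids."""
        genome, models, variants = small_parsed
        table = classify_all(variants, models, genome)
        snps = table[table["vclass"] == "SNP"]
        indels = table[table["vclass"].isin(["insertion", "deletion"])]
        assert not snps["effect"].isin(["frameshift", "inframe_insertion",
                                        "inframe_deletion"]).any()
        assert not indels["effect"].isin(["AAC", "synonymous", "stop_gained",
                                          "stop_lost"]).any()

    def test_truth_label_recovery(self, small_parsed, small_mutated):
        """The engine recovers every simulator truth label exactly."""
        genome, models, variants = small_parsed
        _, truth, _ = small_mutated
        table = classify_all(variants, models, genome)
        primary = table[table["primary"]]
        assert len(primary) == len(truth.variants)
        for row in primary.itertuples():
            v = sv.VariantRecord(row.contig, int(row.pos), row.ref, row.alt)
            gid, region, effect = truth.labels[v]
            observed_gene = row.gene_id if isinstance(row.gene_id, str) else None
            assert (observed_gene, row.region, row.effect) == (gid, region, effect), v


class TestBruteForceOracle:
    """On short genes, classify must agree with full mutant-protein diffing."""

    def test_snp_effects_match_protein_diff(self, small_bundle):
        genome, models = small_bundle.genome, small_bundle.models
        checked = 0
        for gene in models[:6]:
            cds, posmap = sv.build_spliced_cds(gene, genome)
            ref_prot = translate(cds)
            inverse = {off: p for p, off in posmap.items()}
            for off in range(0, len(cds), max(1, len(cds) // 30)):
                pos = inverse[off]
                ref_base = genome.contigs[gene.contig][pos - 1]
                for alt_base in "ACGT":
                    if alt_base == ref_base:
                        continue
                    v = sv.VariantRecord(gene.contig, pos, ref_base, alt_base)
                    (c,) = sv.classify(v, gene, genome, "CDS")
                    # oracle: rebuild the mutant CDS, translate, diff proteins
                    alt_tx = alt_base if gene.strand == "+" else reverse_complement(alt_base)
                    mutant = cds[:off] + alt_tx + cds[off + 1 :]
                    mut_prot = translate(mutant)
                    diffs = [i for i, (a, b) in enumerate(zip(ref_prot, mut_prot)) if a != b]
                    if not diffs:
                        assert c.effect == "synonymous"
                    else:
                        (i,) = diffs
                        assert c.aa_pos == i + 1
                        if mut_prot[i] == "*":
                            assert c.effect == "stop_gained"
                        elif ref_prot[i] == "*":
                            assert c.effect == "stop_lost"
                        else:
                            assert c.effect == "AAC"
                    checked += 1
        assert checked > 100
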