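"""Synthetic two-strain benchmark: a toy reference genome with
intron-containing gene models, plus a mutated derived strain carrying
truth-labeled SNPs, short indels, explicit splice-site variants, and
whole-gene deletions.

The generator emulates the statistical structure of a close strain-to-strain
comparison: roughly one variant per 60 bp, a 96:4 SNP:indel split, a skewed
gene-family table, and a handful of genes entirely missing from the derived
strain.  Every injected variant carries a truth consequence label computed
from the generator's own construction records (which gene region it landed
in, which codon it changed) — independently of the consequence engine, whose
recovery of these labels is the pipeline's principal oracle.

Truth labels are attached to *left-normalized* variant records, and an indel
is only injected where its normalized reference interval lies in a single
region of a single gene (or intergenic space), so region semantics are
unambiguous.  Injected sites are kept >= ``min_variant_spacing`` bp apart;
the per-site rate is compensated for the resulting dead zone so realized
density matches the configured rates.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .io import (
    FamilyAnnotation,
    FunctionalGroups,
    GeneModel,
    Genome,
    VariantRecord,
    normalize_variant,
    reverse_complement,
    write_fasta,
    write_gff3,
    write_two_column_tsv,
    write_vcf,
)
from .consequence import translate

__all__ = ["SimConfig", "TruthSet", "ReferenceBundle", "generate_reference", "mutate",
           "write_reference_bundle", "write_derived"]

_STOPS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"
_NONSTOP_CODONS = tuple(
    a + b + c
    for a in _BASES for b in _BASES for c in _BASES
    if a + b + c not in _STOPS
)


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the synthetic comparison.

    Default rates give ~1 variant / 60 bp at a 96:4 SNP:indel split; the
    family table covers a minority of genes with skewed family sizes
    (largest family 8 members); splice-site SNPs are injected explicitly
    because random placement rarely hits the 4-bp GT/AG window at toy scale.
    """

    seed: int = 1
    n_contigs: int = 1
    contig_length: int = 100_000
    n_genes: int = 50
    introns_per_gene: tuple[int, int] = (1, 3)
    exon_length: tuple[int, int] = (90, 240)
    intron_length: tuple[int, int] = (20, 60)
    utr_length: tuple[int, int] = (6, 30)
    family_spec: tuple[tuple[str, int], ...] = (
        ("AA3_2", 8), ("GH5_5", 2), ("GH16", 3), ("GT2", 2), ("CBM13", 2),
    )
    group_spec: tuple[tuple[str, int], ...] = (("F-box", 6), ("kinase", 10))
    snp_rate: float = 0.96 / 60
    indel_rate: float = 0.04 / 60
    indel_length: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    n_splice_snps: int = 8
    min_variant_spacing: int = 10
    deleted_gene_ids: tuple[str, ...] = ()
    unannotated_gene_ids: tuple[str, ...] = ()

    def validate(self) -> None:
        if not (0 <= self.snp_rate <= 1 and 0 <= self.indel_rate <= 1):
            raise ValueError("rates must be in [0, 1]")
        total = self.snp_rate + self.indel_rate
        if total * (self.min_variant_spacing - 1) >= 1:
            raise ValueError("variant rate too high for the minimum spacing")
        if self.intron_length[0] < 8:
            raise ValueError("introns must be at least 8 bp (GT..AG plus interior)")
        if self.n_genes < 1 or self.n_contigs < 1:
            raise ValueError("need at least one gene and one contig")


@dataclass
class _GeneRecord:
    """Construction-time bookkeeping for one simulated gene."""

    model: GeneModel
    cds_seq: str                      # spliced CDS, transcript orientation
    posmap: dict[int, int]            # genomic pos -> 0-based coding offset
    region_of: dict[int, str]         # genomic pos -> region label
    flank_start: int                  # excision bounds for whole-gene deletion
    flank_end: int


@dataclass
class ReferenceBundle:
    genome: Genome
    models: list[GeneModel]
    families: FamilyAnnotation
    groups: FunctionalGroups
    cds: dict[str, str]
    proteins: dict[str, str]
    config: SimConfig
    records: dict[str, _GeneRecord] = field(repr=False, default_factory=dict)


@dataclass
class TruthSet:
    variants: list[VariantRecord]
    labels: dict[VariantRecord, tuple[str | None, str, str]]  # (gene, region, effect)
    deleted_genes: list[str]


# ---------------------------------------------------------------------------
# Reference generation
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_BASES), size=n)) if n else ""


def _build_gene(rng: np.random.Generator, cfg: SimConfig):
    """One gene in transcript orientation.

    Returns (sequence, exon/cds/phase intervals in 1-based gene offsets,
    CDS offset lists, region labels per offset).
    """
    n_introns = int(rng.integers(cfg.introns_per_gene[0], cfg.introns_per_gene[1] + 1))
    chunks = [int(rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1))
              for _ in range(n_introns + 1)]
    excess = sum(chunks) % 3
    chunks[-1] -= excess
    n_codons = sum(chunks) // 3
    coding = "ATG" + "".join(
        rng.choice(_NONSTOP_CODONS) for _ in range(n_codons - 2)
    ) + str(rng.choice(_STOPS))
    introns = []
    for _ in range(n_introns):
        ilen = int(rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1))
        introns.append("GT" + _random_seq(rng, ilen - 4) + "AG")
    u5 = int(rng.integers(cfg.utr_length[0], cfg.utr_length[1] + 1))
    u3 = int(rng.integers(cfg.utr_length[0], cfg.utr_length[1] + 1))
    utr5, utr3 = _random_seq(rng, u5), _random_seq(rng, u3)

    seq_parts = [utr5]
    exons: list[tuple[int, int]] = []   # transcript-orientation gene offsets
    cds: list[tuple[int, int]] = []
    regions: dict[int, str] = {}
    cds_offsets: list[int] = []         # gene offset of each coding base, in order
    cursor = 0
    for t in range(1, u5 + 1):
        regions[t] = "five_prime_UTR"
    cursor = u5
    exon_start = 1
    coding_used = 0
    for i, clen in enumerate(chunks):
        chunk = coding[coding_used : coding_used + clen]
        seq_parts.append(chunk)
        cds.append((cursor + 1, cursor + clen))
        for t in range(cursor + 1, cursor + clen + 1):
            regions[t] = "CDS"
            cds_offsets.append(t)
        cursor += clen
        coding_used += clen
        if i < n_introns:
            exons.append((exon_start, cursor))
            iseq = introns[i]
            seq_parts.append(iseq)
            ilen = len(iseq)
            for k, t in enumerate(range(cursor + 1, cursor + ilen + 1)):
                regions[t] = (
                    "splice_site" if k < 2 or k >= ilen - 2 else "intron"
                )
            cursor += ilen
            exon_start = cursor + 1
    seq_parts.append(utr3)
    for t in range(cursor + 1, cursor + u3 + 1):
        regions[t] = "three_prime_UTR"
    exons.append((exon_start, cursor + u3))
    exons[0] = (1, exons[0][1])
    cursor += u3
    seq = "".join(seq_parts)
    assert len(seq) == cursor
    return seq, exons, cds, cds_offsets, regions


def generate_reference(config: SimConfig) -> ReferenceBundle:
    """Deterministically build the reference strain for a config.

    All models are complete (ATG start, stop codon, CDS length a multiple of
    3), introns are flanked by GT..AG, and intergenic spacers are >= 20 bp.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    contig_names = [f"contig{i + 1}" for i in range(config.n_contigs)]
    contig_seqs = {c: list(_random_seq(rng, config.contig_length)) for c in contig_names}

    models: list[GeneModel] = []
    records: dict[str, _GeneRecord] = {}
    contig_idx, cursor = 0, 20  # leave a 20 bp margin at contig start
    for gi in range(config.n_genes):
        gene_id = f"g{gi + 1:03d}"
        seq, exons_t, cds_t, cds_offsets, regions_t = _build_gene(rng, config)
        strand = "+" if rng.random() < 0.5 else "-"
        glen = len(seq)
        spacer = int(rng.integers(20, 121))
        while True:
            start = cursor + spacer
            if start + glen - 1 <= config.contig_length - 20:
                break
            contig_idx += 1
            cursor = 20
            if contig_idx >= config.n_contigs:
                raise ValueError(
                    f"cannot place {config.n_genes} genes in "
                    f"{config.n_contigs} x {config.contig_length} bp"
                )
        contig = contig_names[contig_idx]
        if strand == "-":
            gseq = reverse_complement(seq)
            flip = lambda iv: (glen - iv[1] + 1, glen - iv[0] + 1)  # noqa: E731
            exons_g = sorted(flip(iv) for iv in exons_t)
            cds_g = sorted(flip(iv) for iv in cds_t)
            to_genomic = lambda t: start - 1 + (glen - t + 1)  # noqa: E731
        else:
            gseq = seq
            exons_g = [(a, b) for a, b in exons_t]
            cds_g = [(a, b) for a, b in cds_t]
            to_genomic = lambda t: start - 1 + t  # noqa: E731
        exons_abs = [(s + start - 1, e + start - 1) for s, e in exons_g]
        cds_abs = [(s + start - 1, e + start - 1) for s, e in cds_g]
        # phases in translation order, then stored per ascending interval
        order = cds_abs if strand == "+" else list(reversed(cds_abs))
        run, phase_by_iv = 0, {}
        for s, e in order:
            phase_by_iv[(s, e)] = (3 - run % 3) % 3
            run += e - s + 1
        model = GeneModel(
            gene_id=gene_id, contig=contig, strand=strand,
            exons=exons_abs, cds=cds_abs,
            phases=[phase_by_iv[iv] for iv in cds_abs],
            protein_id=f"{gene_id}.t1",
        )
        contig_seqs[contig][start - 1 : start - 1 + glen] = list(gseq)
        posmap = {to_genomic(t): i for i, t in enumerate(cds_offsets)}
        region_of = {to_genomic(t): r for t, r in regions_t.items()}
        records[gene_id] = _GeneRecord(
            model=model,
            cds_seq=coding_seq_of(seq, cds_t),
            posmap=posmap,
            region_of=region_of,
            flank_start=max(1, start - 10),
            flank_end=min(config.contig_length, start + glen - 1 + 10),
        )
        models.append(model)
        cursor = start + glen - 1

    genome = Genome({c: "".join(s) for c, s in contig_seqs.items()})
    for m in models:
        m.validate(genome)

    gene_ids = [m.gene_id for m in models]
    families = FamilyAnnotation()
    free = list(gene_ids)
    for label, count in config.family_spec:
        if count > len(free):
            raise ValueError(f"family {label!r} needs {count} genes; only {len(free)} left")
        chosen = rng.choice(free, size=count, replace=False)
        for g in chosen:
            families.add(str(g), label)
        free = [g for g in free if g not in set(map(str, chosen))]
    groups = FunctionalGroups(genome_gene_total=len(gene_ids))
    for label, count in config.group_spec:
        chosen = rng.choice(gene_ids, size=min(count, len(gene_ids)), replace=False)
        for g in chosen:
            groups.add(str(g), label)

    cds = {g: r.cds_seq for g, r in records.items()}
    proteins = {g: translate(s) for g, s in cds.items()}
    return ReferenceBundle(genome, models, families, groups, cds, proteins, config, records)


def coding_seq_of(gene_seq: str, cds_intervals: list[tuple[int, int]]) -> str:
    return "".join(gene_seq[s - 1 : e] for s, e in cds_intervals)


# ---------------------------------------------------------------------------
# Mutation
# ---------------------------------------------------------------------------


def _truth_for_snp(
    rec: _GeneRecord, pos: int, ref: str, alt: str
) -> tuple[str, str]:
    region = rec.region_of[pos]
    if region == "splice_site":
        return "splice_site", "VCSS"
    if region != "CDS":
        return region, "none"
    off = rec.posmap[pos]
    if rec.model.strand == "-":
        ref, alt = reverse_complement(ref), reverse_complement(alt)
    ci = off // 3
    ref_codon = rec.cds_seq[ci * 3 : ci * 3 + 3]
    assert ref_codon[off % 3] == ref
    alt_codon = ref_codon[: off % 3] + alt + ref_codon[off % 3 + 1 :]
    ref_aa, alt_aa = translate(ref_codon), translate(alt_codon)
    if ref_aa == alt_aa:
        return "CDS", "synonymous"
    if alt_aa == "*":
        return "CDS", "stop_gained"
    if ref_aa == "*":
        return "CDS", "stop_lost"
    return "CDS", "AAC"


def mutate(reference: ReferenceBundle, config: SimConfig | None = None):
    """Inject variants and whole-gene deletions into the reference.

    Returns ``(derived_genome, truth, derived_cds)`` where ``derived_cds``
    maps each surviving, annotated gene to its mutated spliced CDS (the
    derived strain's predicted CDS set for homology steps).
    """
    cfg = config or reference.config
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    genome = reference.genome
    spacing = cfg.min_variant_spacing

    # per-contig lookup: genomic pos -> owning gene record (or None)
    owner: dict[str, dict[int, str]] = {c: {} for c in genome.contigs}
    for gid, rec in reference.records.items():
        for p in rec.region_of:
            owner[rec.model.contig][p] = gid

    deleted = list(cfg.deleted_gene_ids)
    unknown = set(deleted) - set(reference.records)
    if unknown:
        raise ValueError(f"unknown deleted_gene_ids {sorted(unknown)}")
    excised: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.contigs}
    for gid in deleted:
        rec = reference.records[gid]
        excised[rec.model.contig].append((rec.flank_start, rec.flank_end))
    for contig, ivals in excised.items():  # merge touching flanks of neighbors
        merged: list[tuple[int, int]] = []
        for s, e in sorted(ivals):
            if merged and s <= merged[-1][1] + 1:
                merged[-1] = (merged[-1][0], max(e, merged[-1][1]))
            else:
                merged.append((s, e))
        excised[contig] = merged

    def in_excised(contig: str, s: int, e: int) -> bool:
        return any(not (e < a or s > b) for a, b in excised[contig])

    def region_at(contig: str, pos: int) -> tuple[str | None, str]:
        gid = owner[contig].get(pos)
        if gid is None:
            return None, "intergenic"
        return gid, reference.records[gid].region_of[pos]

    def uniform_region(contig: str, s: int, e: int) -> tuple[str | None, str] | None:
        tags = {region_at(contig, p) for p in range(s, e + 1)}
        return tags.pop() if len(tags) == 1 else None

    # dead-zone compensation so realized density matches the configured rates
    total_rate = cfg.snp_rate + cfg.indel_rate
    eff = total_rate / (1.0 - total_rate * (spacing - 1)) if total_rate else 0.0
    p_snp = eff * (cfg.snp_rate / total_rate) if total_rate else 0.0
    p_indel = eff - p_snp

    variants: list[VariantRecord] = []
    labels: dict[VariantRecord, tuple[str | None, str, str]] = {}
    occupied: dict[str, set[int]] = {c: set() for c in genome.contigs}

    def too_close(contig: str, s: int, e: int) -> bool:
        occ = occupied[contig]
        return any(p in occ for p in range(s - spacing + 1, e + spacing))

    def register(v: VariantRecord, gene: str | None, region: str, effect: str) -> None:
        variants.append(v)
        labels[v] = (gene, region, effect)
        s, e = v.ref_interval
        occupied[v.contig].update(range(s, e + 1))

    max_indel = max(cfg.indel_length) if cfg.indel_length else 1
    for contig, seq in genome.contigs.items():
        L = len(seq)
        pos = 2
        while pos <= L - max_indel - 2:
            u = rng.random()
            if u >= eff:
                pos += 1
                continue
            if u < p_snp:
                if in_excised(contig, pos, pos) or too_close(contig, pos, pos):
                    pos += 1
                    continue
                ref = seq[pos - 1]
                alt = str(rng.choice([b for b in _BASES if b != ref]))
                v = VariantRecord(contig, pos, ref, alt)
                gid, region = region_at(contig, pos)
                if gid is None:
                    register(v, None, "intergenic", "none")
                else:
                    region, effect = _truth_for_snp(reference.records[gid], pos, ref, alt)
                    register(v, gid, region, effect)
                pos += spacing
                continue
            # indel anchored at pos
            length = int(rng.choice(cfg.indel_length))
            is_ins = rng.random() < 0.5
            if is_ins:
                ref = seq[pos - 1]
                alt = ref + _random_seq(rng, length)
                raw = VariantRecord(contig, pos, ref, alt)
            else:
                if pos + length > L:
                    pos += 1
                    continue
                ref = seq[pos - 1 : pos + length]
                raw = VariantRecord(contig, pos, ref, ref[0])
            v = normalize_variant(raw, genome)
            s, e = v.ref_interval
            if in_excised(contig, s, e) or too_close(contig, s, e):
                pos += 1
                continue
            tag = uniform_region(contig, s, e)
            if tag is None:
                pos += 1  # straddles a region boundary: do not inject
                continue
            gid, region = tag
            if region == "splice_site":
                effect = "VCSS"
            elif region == "CDS":
                if length % 3 != 0:
                    effect = "frameshift"
                else:
                    effect = "inframe_insertion" if is_ins else "inframe_deletion"
            else:
                effect = "none"
            register(v, gid, region, effect)
            pos += spacing

    # explicit splice-site SNPs (random placement rarely hits the 4 bp window)
    splice_sites = [
        (rec.model.contig, p)
        for gid, rec in reference.records.items()
        if gid not in deleted
        for p, r in sorted(rec.region_of.items())
        if r == "splice_site"
    ]
    if cfg.n_splice_snps and splice_sites:
        order = rng.permutation(len(splice_sites))
        placed = 0
        for i in order:
            if placed >= cfg.n_splice_snps:
                break
            contig, p = splice_sites[i]
            if in_excised(contig, p, p) or too_close(contig, p, p):
                continue
            ref = genome.contigs[contig][p - 1]
            alt = str(rng.choice([b for b in _BASES if b != ref]))
            gid, _ = region_at(contig, p)
            register(VariantRecord(contig, p, ref, alt), gid, "splice_site", "VCSS")
            placed += 1

    # build the derived genome: apply edits right-to-left, then excisions
    derived_contigs: dict[str, str] = {}
    for contig, seq in genome.contigs.items():
        events: list[tuple[int, int, str]] = []  # (start, end, replacement)
        for v in variants:
            if v.contig == contig:
                s, e = v.ref_interval
                events.append((s, e, v.alt))
        for s, e in excised[contig]:
            events.append((s, e, ""))
        chars = list(seq)
        for s, e, repl in sorted(events, key=lambda t: -t[0]):
            chars[s - 1 : e] = list(repl)
        derived_contigs[contig] = "".join(chars)
    derived_genome = Genome(derived_contigs)

    # derived CDS set: apply each gene's coding edits to its spliced CDS
    derived_cds: dict[str, str] = {}
    skip = set(deleted) | set(cfg.unannotated_gene_ids)
    gene_edits: dict[str, list[tuple[int, VariantRecord]]] = {}
    for v in variants:
        gid, region, _ = labels[v]
        if gid and region == "CDS" and gid not in skip:
            gene_edits.setdefault(gid, []).append((v.ref_interval[0], v))
    for gid, rec in reference.records.items():
        if gid in skip:
            continue
        cds = list(rec.cds_seq)
        edits = []
        for _, v in gene_edits.get(gid, ()):
            s, e = v.ref_interval
            if v.vclass == "SNP":
                off = rec.posmap[s]
                alt = v.alt if rec.model.strand == "+" else reverse_complement(v.alt)
                edits.append((off, off, alt))
            elif v.vclass == "deletion":
                offs = sorted(rec.posmap[p] for p in range(s + 1, e + 1))
                edits.append((offs[0], offs[-1], ""))
            else:  # insertion
                ins = v.alt[1:]
                if s not in rec.posmap:
                    continue
                off = rec.posmap[s]
                if rec.model.strand == "+":
                    edits.append((off + 1, off, ins))  # insert after off
                else:
                    edits.append((off, off - 1, reverse_complement(ins)))
        for a, b, repl in sorted(edits, key=lambda t: -t[0]):
            cds[a : b + 1] = list(repl)
        derived_cds[gid] = "".join(cds)

    truth = TruthSet(variants=variants, labels=labels, deleted_genes=deleted)
    return derived_genome, truth, derived_cds


# ---------------------------------------------------------------------------
# Output writing
# ---------------------------------------------------------------------------


def write_reference_bundle(bundle: ReferenceBundle, outdir: str | os.PathLike) -> None:
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    write_fasta(bundle.genome.contigs, os.path.join(outdir, "reference.fasta"))
    write_gff3(bundle.models, os.path.join(outdir, "genes.gff3"))
    write_fasta(bundle.cds, os.path.join(outdir, "reference_cds.fasta"))
    write_fasta(bundle.proteins, os.path.join(outdir, "reference_proteins.fasta"))
    fam_rows = [
        (g, lab)
        for g, labs in sorted(bundle.families.gene_to_families.items())
        for lab in sorted(labs)
    ]
    write_two_column_tsv(fam_rows, os.path.join(outdir, "families.tsv"), ("gene_id", "family"))
    grp_rows = [
        (g, lab) for lab, genes in sorted(bundle.groups.groups.items()) for g in sorted(genes)
    ]
    write_two_column_tsv(grp_rows, os.path.join(outdir, "groups.tsv"), ("gene_id", "group"))


def write_derived(
    derived_genome: Genome,
    truth: TruthSet,
    derived_cds: Mapping[str, str],
    reference: ReferenceBundle,
    outdir: str | os.PathLike,
) -> None:
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    write_fasta(derived_genome.contigs, os.path.join(outdir, "derived.fasta"))
    write_fasta(dict(derived_cds), os.path.join(outdir, "derived_cds.fasta"))
    write_vcf(truth.variants, reference.genome, os.path.join(outdir, "truth.vcf"))
    with open(os.path.join(outdir, "truth_labels.tsv"), "w") as fh:
        fh.write("contig\tpos\tref\talt\tgene_id\tregion\teffect\n")
        for v in sorted(truth.variants, key=lambda x: (x.contig, x.pos)):
            gid, region, effect = truth.labels[v]
            fh.write(f"{v.contig}\t{v.pos}\t{v.ref}\t{v.alt}\t{gid or '.'}\t{region}\t{effect}\n")
    with open(os.path.join(outdir, "deleted_genes.txt"), "w") as fh:
        for gid in truth.deleted_genes:
            fh.write(gid + "\n")


def simulate_to_dir(config: SimConfig, outdir: str | os.PathLike) -> None:
    """Full simulation: reference + derived strain written to ``outdir``."""
    bundle = generate_reference(config)
    derived_genome, truth, derived_cds = mutate(bundle, config)
    write_reference_bundle(bundle, outdir)
    write_derived(derived_genome, truth, derived_cds, bundle, outdir)
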