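"""Core data model and readers/writers for the standard formats.

All coordinates are 1-based and inclusive, matching both GFF3 and VCF, so no
off-by-one translation happens at parse time.  Gene models hold one transcript
per gene (the longest spliced CDS wins; ties break on the lexicographically
smallest mRNA id).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gffutils
import pysam
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "FormatError",
    "DataError",
    "Genome",
    "GeneModel",
    "VariantRecord",
    "FamilyAnnotation",
    "FunctionalGroups",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_vcf",
    "write_vcf",
    "normalize_variant",
    "read_family_table",
    "read_group_table",
]

VALID_BASES = frozenset("ACGTN")


class FormatError(ValueError):
    """A file violates the expected format."""


class DataError(ValueError):
    """Inputs are well-formed but mutually inconsistent."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Genome:
    """A set of contigs: id -> uppercase nucleotide sequence (A/C/G/T/N)."""

    contigs: dict[str, str]

    @property
    def total_size(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def slice(self, contig: str, start: int, end: int) -> str:
        """1-based inclusive slice."""
        seq = self.contigs[contig]
        if start < 1 or end > len(seq):
            raise DataError(f"slice {contig}:{start}-{end} outside contig bounds (1..{len(seq)})")
        return seq[start - 1 : end]


@dataclass
class GeneModel:
    """One transcript per gene.

    ``exons`` and ``cds`` are lists of 1-based closed intervals stored in
    ascending genomic order regardless of strand; ``phases`` aligns with
    ``cds``.  Splicing in transcript orientation is the consequence engine's
    job (:func:`strainvar.consequence.build_spliced_cds`).
    """

    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    phases: list[int]
    protein_id: str | None = None
    complete: bool = True

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def cds_span(self) -> tuple[int, int]:
        return self.cds[0][0], self.cds[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons, ascending genomic order."""
        out = []
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            out.append((e1 + 1, s2 - 1))
        return out

    def spliced_cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def validate(self, genome: Genome | None = None) -> None:
        if self.strand not in "+-":
            raise FormatError(f"{self.gene_id}: strand must be + or -")
        for name, ivals in (("exon", self.exons), ("CDS", self.cds)):
            if not ivals:
                raise FormatError(f"{self.gene_id}: no {name} intervals")
            for s, e in ivals:
                if s > e:
                    raise FormatError(f"{self.gene_id}: inverted {name} interval {s}..{e}")
            for (_, e1), (s2, _) in zip(ivals, ivals[1:]):
                if s2 <= e1:
                    raise FormatError(f"{self.gene_id}: {name} intervals overlap or are unsorted")
        # every CDS interval must sit inside some exon
        for cs, ce in self.cds:
            if not any(es <= cs and ce <= ee for es, ee in self.exons):
                raise FormatError(f"{self.gene_id}: CDS {cs}..{ce} outside exons")
        if genome is not None:
            clen = len(genome.contigs[self.contig])
            if self.exons[0][0] < 1 or self.exons[-1][1] > clen:
                raise FormatError(f"{self.gene_id}: intervals outside contig bounds")
        if self.complete and self.spliced_cds_length() % 3 != 0:
            raise FormatError(
                f"{self.gene_id}: complete model with CDS length "
                f"{self.spliced_cds_length()} not a multiple of 3"
            )
        # phase must be consistent with the running CDS length in translation order
        order = self.cds if self.strand == "+" else list(reversed(self.cds))
        phases = self.phases if self.strand == "+" else list(reversed(self.phases))
        run = 0
        for (s, e), phase in zip(order, phases):
            expected = (3 - run % 3) % 3
            if phase != expected:
                raise FormatError(
                    f"{self.gene_id}: CDS phase {phase} at {s}..{e}, expected {expected}"
                )
            run += e - s + 1


@dataclass(frozen=True)
class VariantRecord:
    """A normalized VCF-style record (1-based position of the first ref base)."""

    contig: str
    pos: int
    ref: str
    alt: str

    @property
    def vclass(self) -> str:
        if len(self.ref) == len(self.alt):
            return "SNP" if len(self.ref) == 1 else "MNV"
        return "insertion" if len(self.alt) > len(self.ref) else "deletion"

    @property
    def ref_interval(self) -> tuple[int, int]:
        return self.pos, self.pos + len(self.ref) - 1

    def snp_equivalents(self) -> int:
        """Per-base SNP count: MNVs decompose into one SNP per substituted base."""
        return len(self.ref) if self.vclass in ("SNP", "MNV") else 0


@dataclass
class FamilyAnnotation:
    """gene id -> family labels, and family -> member gene list.

    A gene may carry several labels (a protein with two CAZy modules).
    """

    gene_to_families: dict[str, set[str]] = field(default_factory=dict)

    @property
    def families(self) -> dict[str, list[str]]:
        fam: dict[str, list[str]] = {}
        for g, labels in self.gene_to_families.items():
            for lab in labels:
                fam.setdefault(lab, []).append(g)
        return {k: sorted(v) for k, v in fam.items()}

    @property
    def annotated_genes(self) -> set[str]:
        return set(self.gene_to_families)

    def add(self, gene_id: str, label: str) -> None:
        self.gene_to_families.setdefault(gene_id, set()).add(label)


@dataclass
class FunctionalGroups:
    """Functional group label ('F-box', 'kinase', ...) -> gene-id set."""

    groups: dict[str, set[str]] = field(default_factory=dict)
    genome_gene_total: int | None = None

    def add(self, gene_id: str, label: str) -> None:
        self.groups.setdefault(label, set()).add(gene_id)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | os.PathLike) -> Genome:
    """Read a multi-record FASTA into a :class:`Genome`.

    Sequences are uppercased; only A/C/G/T/N are accepted; duplicate record
    ids are rejected.
    """
    contigs: dict[str, str] = {}
    n = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n += 1
        if rec.id in contigs:
            raise FormatError(f"duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - VALID_BASES
        if bad:
            raise FormatError(f"record {rec.id!r}: invalid characters {sorted(bad)}")
        if not seq:
            raise FormatError(f"record {rec.id!r}: empty sequence")
        contigs[rec.id] = seq
    if n == 0:
        raise FormatError(f"{path}: empty or not FASTA")
    return Genome(contigs)


def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def read_gff3(path: str | os.PathLike, genome: Genome | None = None) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS features into :class:`GeneModel` objects.

    One model per gene: among a gene's mRNAs the longest spliced CDS is kept
    (tie -> lexicographically smallest mRNA id).  Minus-strand intervals are
    stored in ascending genomic order.
    """
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        candidates = []
        for mrna in db.children(gene, featuretype="mRNA"):
            exons = sorted((f.start, f.end) for f in db.children(mrna, featuretype="exon"))
            cds_feats = sorted(
                ((f.start, f.end, f.frame) for f in db.children(mrna, featuretype="CDS"))
            )
            if not cds_feats:
                continue
            cds = [(s, e) for s, e, _ in cds_feats]
            phases = []
            for s, e, frame in cds_feats:
                if frame not in ("0", "1", "2"):
                    raise FormatError(f"{mrna.id}: CDS {s}..{e} missing phase")
                phases.append(int(frame))
            if not exons:
                exons = list(cds)
            spliced = sum(e - s + 1 for s, e in cds)
            candidates.append((spliced, mrna.id, exons, cds, phases))
        if not candidates:
            continue
        candidates.sort(key=lambda c: (-c[0], c[1]))
        _, mrna_id, exons, cds, phases = candidates[0]
        model = GeneModel(
            gene_id=gene.id,
            contig=gene.seqid,
            strand=gene.strand,
            exons=exons,
            cds=cds,
            phases=phases,
            protein_id=mrna_id,
        )
        model.validate(genome)
        models.append(model)
    return models


def write_gff3(models: Iterable[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            gs, ge = m.span
            fh.write(
                f"{m.contig}\tstrainvar\tgene\t{gs}\t{ge}\t.\t{m.strand}\t.\tID={m.gene_id}\n"
            )
            mrna_id = m.protein_id or f"{m.gene_id}.t1"
            fh.write(
                f"{m.contig}\tstrainvar\tmRNA\t{gs}\t{ge}\t.\t{m.strand}\t.\t"
                f"ID={mrna_id};Parent={m.gene_id}\n"
            )
            for s, e in m.exons:
                fh.write(
                    f"{m.contig}\tstrainvar\texon\t{s}\t{e}\t.\t{m.strand}\t.\tParent={mrna_id}\n"
                )
            for (s, e), phase in zip(m.cds, m.phases):
                fh.write(
                    f"{m.contig}\tstrainvar\tCDS\t{s}\t{e}\t.\t{m.strand}\t{phase}\t"
                    f"Parent={mrna_id}\n"
                )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def normalize_variant(v: VariantRecord, genome: Genome) -> VariantRecord:
    """Left-normalize: minimal allele representation at the smallest position.

    Standard algorithm: trim a shared trailing base (extending left through
    the reference when an allele would empty), then trim shared leading bases.
    Idempotent by construction.
    """
    pos, ref, alt = v.pos, v.ref, v.alt
    seq = genome.contigs[v.contig]
    while True:
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                if pos == 1:
                    raise DataError(f"cannot left-extend variant at {v.contig}:1")
                pos -= 1
                base = seq[pos - 1]
                ref, alt = base + ref, base + alt
        elif len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
            ref, alt = ref[1:], alt[1:]
            pos += 1
        else:
            break
    return VariantRecord(v.contig, pos, ref, alt)


def read_vcf(path: str | os.PathLike, genome: Genome) -> list[VariantRecord]:
    """Read a VCF into normalized :class:`VariantRecord` objects.

    Multiallelic records are split into one record per alt allele; every
    record is left-normalized and its ref allele verified against the genome.
    """
    out: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                if set(alt.upper()) - set("ACGT"):
                    raise FormatError(
                        f"{rec.chrom}:{rec.pos}: unsupported alt allele {alt!r}"
                    )
                v = VariantRecord(rec.chrom, rec.pos, rec.ref.upper(), alt.upper())
                if v.contig not in genome.contigs:
                    raise DataError(f"variant contig {v.contig!r} not in genome")
                s, e = v.ref_interval
                observed = genome.slice(v.contig, s, e)
                if observed != v.ref:
                    raise DataError(
                        f"{v.contig}:{v.pos}: REF {v.ref!r} does not match genome {observed!r}"
                    )
                if "N" in v.ref or "N" in v.alt:
                    raise DataError(f"{v.contig}:{v.pos}: variant touches N bases")
                out.append(normalize_variant(v, genome))
    return out


def write_vcf(
    variants: Sequence[VariantRecord], genome: Genome, path: str | os.PathLike
) -> None:
    header = pysam.VariantHeader()
    for name, seq in genome.contigs.items():
        header.contigs.add(name, length=len(seq))
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for v in sorted(variants, key=lambda x: (x.contig, x.pos, x.ref, x.alt)):
            rec = vcf.new_record(
                contig=v.contig, start=v.pos - 1, stop=v.pos - 1 + len(v.ref),
                alleles=(v.ref, v.alt),
            )
            vcf.write(rec)


# ---------------------------------------------------------------------------
# Family / group tables
# ---------------------------------------------------------------------------

_HEADER_FIRST_FIELDS = {"gene", "gene_id", "geneid", "id"}


def _read_two_column_tsv(path: str | os.PathLike) -> list[tuple[str, str]]:
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{i + 1}: expected two tab-separated columns")
            if i == 0 and parts[0].strip().lower() in _HEADER_FIRST_FIELDS:
                continue  # optional header
            rows.append((parts[0].strip(), parts[1].strip()))
    return rows


def read_family_table(
    path: str | os.PathLike, gene_universe: set[str] | None = None
) -> tuple[FamilyAnnotation, list[str]]:
    """Read gene->family TSV.  Returns (annotation, warnings).

    Duplicate (gene, label) rows collapse; genes absent from ``gene_universe``
    are reported as warnings, not errors.
    """
    ann = FamilyAnnotation()
    warnings: list[str] = []
    for gene, label in _read_two_column_tsv(path):
        if gene_universe is not None and gene not in gene_universe:
            warnings.append(f"family table: unknown gene id {gene!r}")
            continue
        ann.add(gene, label)
    return ann, warnings


def read_group_table(
    path: str | os.PathLike,
    gene_universe: set[str] | None = None,
    genome_gene_total: int | None = None,
) -> tuple[FunctionalGroups, list[str]]:
    """Read gene->functional-group TSV (same shape as the family table)."""
    groups = FunctionalGroups(genome_gene_total=genome_gene_total)
    warnings: list[str] = []
    for gene, label in _read_two_column_tsv(path):
        if gene_universe is not None and gene not in gene_universe:
            warnings.append(f"group table: unknown gene id {gene!r}")
            continue
        groups.add(gene, label)
    return groups, warnings


def write_two_column_tsv(
    rows: Iterable[tuple[str, str]], path: str | os.PathLike, header: tuple[str, str]
) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for a, b in rows:
            fh.write(f"{a}\t{b}\n")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
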