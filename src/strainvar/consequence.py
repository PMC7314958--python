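"""Variant consequence classification against gene models.

Every variant is assigned a genomic region (CDS, intron, UTRs, splice site,
intergenic) and, inside coding sequence, a coding effect: synonymous,
amino-acid change (AAC), stop gained/lost, in-frame indel, frameshift, or a
variant in a consensus splice site (VCSS, the GT donor / AG acceptor
dinucleotides).  A variant overlapping several genes yields one record per
gene; a single *primary* record per variant (most severe effect) supports
genome-level tallies that conserve the total variant count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from Bio.Seq import Seq

from .io import DataError, GeneModel, Genome, VariantRecord, reverse_complement

__all__ = [
    "Consequence",
    "build_spliced_cds",
    "translate",
    "assign_region",
    "classify",
    "classify_all",
    "SEVERITY_ORDER",
    "SPLICE_WINDOW",
]

# intron offsets (from each end) forming the consensus window: GT..AG
SPLICE_WINDOW = 2

REGIONS = ("CDS", "intron", "five_prime_UTR", "three_prime_UTR", "splice_site", "intergenic")

# severity for choosing the per-variant primary record (most severe first)
SEVERITY_ORDER = (
    "frameshift",
    "stop_gained",
    "stop_lost",
    "VCSS",
    "AAC",
    "inframe_insertion",
    "inframe_deletion",
    "synonymous",
    "complex",
    "none",
)
_SEVERITY_RANK = {e: i for i, e in enumerate(SEVERITY_ORDER)}
_REGION_RANK = {r: i for i, r in enumerate(
    ("splice_site", "CDS", "five_prime_UTR", "three_prime_UTR", "intron", "intergenic")
)}


@dataclass(frozen=True)
class Consequence:
    variant: VariantRecord
    gene_id: str | None
    region: str
    effect: str
    aa_ref: str | None = None
    aa_pos: int | None = None
    aa_alt: str | None = None


def translate(cds: str) -> str:
    """Standard genetic code (table 1); internal stops reported as ``*``."""
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not a multiple of 3")
    return str(Seq(cds).translate())


def build_spliced_cds(gene: GeneModel, genome: Genome) -> tuple[str, dict[int, int]]:
    """Assemble the coding sequence in translation order.

    Returns ``(sequence, posmap)`` where ``posmap`` maps each genomic CDS
    position to its 0-based offset in the returned sequence (a bijection over
    CDS bases).  Minus-strand genes are reverse-complemented.  The sequence
    starts at the phase-adjusted first codon base.
    """
    contig = genome.contigs.get(gene.contig)
    if contig is None:
        raise DataError(f"{gene.gene_id}: contig {gene.contig!r} not in genome")
    if gene.cds[-1][1] > len(contig):
        raise DataError(f"{gene.gene_id}: CDS outside contig bounds")
    parts: list[str] = []
    positions: list[int] = []
    order = gene.cds if gene.strand == "+" else list(reversed(gene.cds))
    phases = gene.phases if gene.strand == "+" else list(reversed(gene.phases))
    for s, e in order:
        chunk = contig[s - 1 : e]
        pos_range = range(s, e + 1)
        if gene.strand == "-":
            chunk = reverse_complement(chunk)
            pos_range = range(e, s - 1, -1)
        parts.append(chunk)
        positions.extend(pos_range)
    seq = "".join(parts)
    skip = phases[0] if phases else 0
    seq = seq[skip:]
    posmap = {p: i for i, p in enumerate(positions[skip:])}
    return seq, posmap


# ---------------------------------------------------------------------------
# Region assignment
# ---------------------------------------------------------------------------


def _splice_positions(gene: GeneModel, window: int = SPLICE_WINDOW) -> set[int]:
    sites: set[int] = set()
    for s, e in gene.introns:
        length = e - s + 1
        w = min(window, length)
        sites.update(range(s, s + w))
        sites.update(range(e - w + 1, e + 1))
    return sites


def _region_in_gene(
    v: VariantRecord, gene: GeneModel, window: int = SPLICE_WINDOW
) -> str | None:
    """Region of the variant's ref interval within one gene, or None."""
    s, e = v.ref_interval
    gs, ge = gene.span
    if e < gs or s > ge:
        return None
    pts = set(range(s, e + 1))
    if pts & _splice_positions(gene, window):
        return "splice_site"
    in_cds = any(not (e < cs or s > ce) for cs, ce in gene.cds)
    in_exon = any(not (e < es or s > ee) for es, ee in gene.exons)
    if in_cds:
        return "CDS"
    if in_exon:
        cs, ce = gene.cds_span
        if e < cs:
            upstream = True
        elif s > ce:
            upstream = False
        else:  # exonic, flanks CDS on both sides without overlap: treat as 5'
            upstream = True
        if gene.strand == "+":
            return "five_prime_UTR" if upstream else "three_prime_UTR"
        return "three_prime_UTR" if upstream else "five_prime_UTR"
    return "intron"


def assign_region(
    v: VariantRecord, genes: Sequence[GeneModel], window: int = SPLICE_WINDOW
) -> list[tuple[str, str | None]]:
    """All (region, gene_id) assignments for a variant.

    Splice site takes precedence over intron, CDS over UTR (handled inside
    :func:`_region_in_gene`).  A variant overlapping no gene is intergenic.
    """
    hits = []
    for g in genes:
        if g.contig != v.contig:
            continue
        region = _region_in_gene(v, g, window)
        if region is not None:
            hits.append((region, g.gene_id))
    return hits or [("intergenic", None)]


# ---------------------------------------------------------------------------
# Coding-effect classification
# ---------------------------------------------------------------------------


def _spans_cds_and_intron(v: VariantRecord, gene: GeneModel) -> bool:
    s, e = v.ref_interval
    pts = range(s, e + 1)
    in_cds = any(any(cs <= p <= ce for cs, ce in gene.cds) for p in pts)
    outside = any(not any(cs <= p <= ce for cs, ce in gene.cds) for p in pts)
    return in_cds and outside


def classify(
    v: VariantRecord,
    gene: GeneModel,
    genome: Genome,
    region: str,
    window: int = SPLICE_WINDOW,
) -> list[Consequence]:
    """Coding consequence(s) of a variant already assigned CDS or splice_site.

    SNP: compare ref/alt codon translations.  Indel: frameshift iff the net
    length change is not a multiple of 3.  MNVs are evaluated codon-wise over
    the substituted block, one AAC per changed amino acid.
    """
    if region == "splice_site":
        return [Consequence(v, gene.gene_id, "splice_site", "VCSS")]
    if region != "CDS":
        return [Consequence(v, gene.gene_id, region, "none")]

    cds_seq, posmap = build_spliced_cds(gene, genome)

    if v.vclass in ("SNP", "MNV"):
        if _spans_cds_and_intron(v, gene):
            return [Consequence(v, gene.gene_id, "CDS", "complex")]
        edited = list(cds_seq)
        changed_offsets = []
        for i, p in enumerate(range(v.pos, v.pos + len(v.ref))):
            if p not in posmap:
                continue
            off = posmap[p]
            ref_base, alt_base = v.ref[i], v.alt[i]
            if gene.strand == "-":
                ref_base = reverse_complement(ref_base)
                alt_base = reverse_complement(alt_base)
            if edited[off] != ref_base:
                raise DataError(
                    f"{v.contig}:{v.pos}: ref base disagrees with spliced CDS of {gene.gene_id}"
                )
            edited[off] = alt_base
            changed_offsets.append(off)
        if not changed_offsets:
            return [Consequence(v, gene.gene_id, "CDS", "complex")]
        n_codons = len(cds_seq) // 3
        out: list[Consequence] = []
        for ci in sorted({off // 3 for off in changed_offsets}):
            if ci >= n_codons:  # trailing partial codon on an incomplete model
                continue
            ref_codon = cds_seq[ci * 3 : ci * 3 + 3]
            alt_codon = "".join(edited[ci * 3 : ci * 3 + 3])
            ref_aa = translate(ref_codon)
            alt_aa = translate(alt_codon)
            if ref_aa == alt_aa:
                eff = "synonymous"
            elif alt_aa == "*":
                eff = "stop_gained"
            elif ref_aa == "*":
                eff = "stop_lost"
            else:
                eff = "AAC"
            out.append(Consequence(v, gene.gene_id, "CDS", eff, ref_aa, ci + 1, alt_aa))
        if not out:
            return [Consequence(v, gene.gene_id, "CDS", "complex")]
        # a pure SNP yields exactly one record; MNVs may yield several
        return out

    # indel
    if _spans_cds_and_intron(v, gene):
        return [Consequence(v, gene.gene_id, "CDS", "complex")]
    delta = abs(len(v.alt) - len(v.ref))
    if delta % 3 != 0:
        eff = "frameshift"
    elif v.vclass == "insertion":
        eff = "inframe_insertion"
    else:
        eff = "inframe_deletion"
    return [Consequence(v, gene.gene_id, "CDS", eff)]


def classify_all(
    variants: Iterable[VariantRecord],
    models: Sequence[GeneModel],
    genome: Genome,
    window: int = SPLICE_WINDOW,
) -> pd.DataFrame:
    """Classify every variant; returns the full consequence table.

    One or more rows per variant; the ``primary`` column marks exactly one
    row per variant, chosen by effect severity (frameshift > stop_gained >
    VCSS > AAC > in-frame > synonymous > non-coding regions), so primary
    rows partition the variant set.
    """
    by_contig: dict[str, list[GeneModel]] = {}
    for m in models:
        by_contig.setdefault(m.contig, []).append(m)
    model_by_id = {m.gene_id: m for m in models}

    rows: list[dict] = []
    for vi, v in enumerate(variants):
        assignments = assign_region(v, by_contig.get(v.contig, ()), window)
        records: list[Consequence] = []
        for region, gene_id in assignments:
            if gene_id is None:
                records.append(Consequence(v, None, "intergenic", "none"))
            elif region in ("CDS", "splice_site"):
                records.extend(classify(v, model_by_id[gene_id], genome, region, window))
            else:
                records.append(Consequence(v, gene_id, region, "none"))
        best = min(
            range(len(records)),
            key=lambda i: (
                _SEVERITY_RANK[records[i].effect],
                _REGION_RANK[records[i].region],
                records[i].gene_id or "",
            ),
        )
        for i, c in enumerate(records):
            rows.append(
                {
                    "variant_idx": vi,
                    "contig": c.variant.contig,
                    "pos": c.variant.pos,
                    "ref": c.variant.ref,
                    "alt": c.variant.alt,
                    "vclass": c.variant.vclass,
                    "gene_id": c.gene_id,
                    "region": c.region,
                    "effect": c.effect,
                    "aa_ref": c.aa_ref,
                    "aa_pos": c.aa_pos,
                    "aa_alt": c.aa_alt,
                    "primary": i == best,
                }
            )
    columns = [
        "variant_idx", "contig", "pos", "ref", "alt", "vclass", "gene_id",
        "region", "effect", "aa_ref", "aa_pos", "aa_alt", "primary",
    ]
    return pd.DataFrame(rows, columns=columns)
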