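# Methods

## Scope and data model

`strainvar` analyzes a haploid strain-vs-strain comparison downstream of
read mapping, variant calling and gene prediction.  Its inputs are a
reference genome (FASTA), one gene model per gene (GFF3 `gene`/`mRNA`/
`exon`/`CDS` with `ID`/`Parent` and the phase column), a variant set
relative to the reference (VCF 4.x), optional gene→family and
gene→functional-group tables (two-column TSV), and, for the homology
stages, the second strain's predicted CDS set and assembly (FASTA).

All coordinates are 1-based inclusive — the native convention of both GFF3
and VCF — so no translation happens at parse time.  If a gene carries
several mRNAs, the transcript with the longest spliced CDS is kept (ties:
lexicographically smallest mRNA id); the analysis treats genes and models
1:1.  Variants are left-normalized on read (minimal allele representation
at the smallest position, the `vt normalize` algorithm), multiallelic
records are split per alt, and every REF allele is verified against the
genome; a mismatch or an allele touching an `N` base is a hard data error
rather than a silent misclassification.

Variant classes: SNP (|ref| = |alt| = 1), insertion (|alt| > |ref|),
deletion (|ref| > |alt|), MNV (|ref| = |alt| > 1).  For SNP/indel tallies an
MNV counts as one SNP per substituted base; for consequence calling it is
evaluated whole, codon-wise, with one AAC per changed amino acid.

## Consequence classification

Region assignment per overlapping gene, with precedence
`splice_site > CDS > UTR > intron`:

* **splice_site** — the variant's reference interval intersects an
  intron's consensus dinucleotides, i.e. intron positions {1, 2, L−1, L}
  (GT donor / AG acceptor).  The window half-width (default 2) is a
  parameter; the canonical dinucleotides are the minimal defensible
  definition of a "consensus splice site" and any variant there is labeled
  VCSS (variant in consensus splice site) regardless of class.
* **CDS** — effect from the spliced CDS: SNPs compare ref/alt codon
  translations (equal → synonymous; alt codon is a stop → stop_gained;
  a lost reference stop → stop_lost; otherwise AAC with (ref-AA, protein
  position, alt-AA)).  Indels are frameshift iff the net length change is
  not a multiple of 3, else inframe_insertion/inframe_deletion.
* **UTR** — exonic but outside the CDS span, 5' or 3' by strand.
* **intron** interior, and **intergenic** otherwise.

The spliced CDS is assembled in translation order (minus-strand genes
reverse-complemented) together with a bijective genomic-position ↔
CDS-offset map; the sequence starts at the phase-adjusted first codon base.
Translation uses the standard genetic code; internal stops are permitted
and reported.

A variant overlapping several genes yields one record per gene.  For
genome-level tallies, exactly one *primary* record per variant is chosen by
effect severity — frameshift > stop_gained > stop_lost > VCSS > AAC >
in-frame > synonymous > non-coding regions — so primary region counts sum
exactly to the variant total.  A substitution or indel straddling an
exon/intron boundary without touching the consensus dinucleotides is
flagged `complex` and contributes to region totals only; stop_gained and
stop_lost are folded into the generic AAC count in the summary tables but
remain distinguishable in the full consequence table.

## Summaries

Per gene: counts of AACs, synonymous changes, CDS insertions/deletions,
frameshifts and VCSSs, plus *degree of affection* = 100 · AACs / protein
length (%).  Genes whose only variants are intronic or UTR still appear
with zero effect counts, preserving totals.  Genes are binned by AAC count
(default bins 1–10, 11–49, 50–99, ≥100, with ≥50/≥100 tail rows) and, for a
selection such as "≥ 50 AACs", partitioned into degree-of-affection classes
≤5%, (5,10]%, >10% (boundaries in the lower class; both cuts configurable).

Per family: gene count, genes with ≥1 variant per effect type, total
variants, and the size-normalized rate total_variants / n_genes.  A gene
with two family labels contributes to both families.  Top-level class
tallies (GH, GT, PL, CE, AA, CBM, EXP) come from family-label prefixes;
unknown prefixes group under `other` with a warning.

Percentages are rounded half-up (2 decimals; genome identity 1 decimal),
matching how published tables print, and denominators are always explicit
inputs (the reference annotation's gene total; the family list's total) —
never inferred — because mixed or undocumented denominators are a real
failure mode of published tables.  Genome identity is
100 · (1 − SNPs/genome size); variant density is genome size / variants
(bp per variant).

Overrepresentation uses the one-sided hypergeometric upper tail
P(X ≥ x) with population N (explicit parameter), K group members, selection
of n, overlap x, via `scipy.stats.hypergeom`; no multiple-testing correction
by default since typically only a handful of groups are tested (apply
Benjamini–Hochberg downstream when screening many).

## Homology

Alignment is exact Smith–Waterman with affine gaps (a gap of length k costs
`open + k·extend`), computed by Biopython's `PairwiseAligner`; no heuristic
seeding, since inputs are desk-scale and exactness permits brute-force
verification.  Identity is percent identical columns over the optimal
traceback (gap columns in the denominator).  Defaults: protein BLOSUM62
with gaps 11/1 (λ = 0.267, K = 0.041); nucleotide +1/−2 with gaps 5/2
(λ = 1.28, K = 0.46).  The Karlin–Altschul parameters are fixed per scheme
rather than estimated: e-values `E = K·m·n·exp(−λS)` here rank hits
deterministically, they are not publication statistics.  Best hits require
E ≤ 1e−5 (configurable) and rank by higher score, then lower e-value, then
higher identity, then target id.

Orthologs are reciprocal best hits: (a, b) is a pair iff b is a's best hit
and a is b's.  Presence/absence is two-stage: stage 1 searches each query
against the target's annotated CDS set; misses are re-searched against the
full assembly in nucleotide mode on **both strands** (a minus-strand gene is
invisible to a single-strand scan); `absent` requires failure of both
stages, `present_in_genome_only` marks genes present in sequence but
missing from the annotation.

## Synthetic benchmark

The generator builds, from one seeded `numpy` generator (no global state):

* `n_contigs` × `contig_length` of uniform random sequence (default
  1 × 100 kb);
* 50 genes (default) placed with ≥ 20 bp spacers, random strand, 1–3
  introns of 20–60 bp starting GT and ending AG, coding exon chunks of
  90–240 bp adjusted to a multiple of 3, ATG start, single stop, 6–30 bp
  UTRs — every model is complete and validates against the GFF3 contracts;
* a skewed family table (default five families covering 17/50 genes,
  largest 8 members) and functional-group table — a scaled-down rendering
  of a genome where a ~300-gene CAZyme complement sits inside ~12,500
  genes, chosen so family statistics are testable at toy scale;
* a derived strain with SNPs and 1–6 bp indels at a total ~1/60 bp
  (96:4 SNP:indel), explicit splice-site SNPs (default 8; random placement
  rarely hits the 4-bp window at toy scale), and whole-gene deletions
  excised with 10 bp flanks.

Injected sites are kept ≥ 10 bp apart so consequences are independent; the
per-site Bernoulli rate is compensated for the resulting dead zone
(`r' = p/(1 − p·(spacing−1))`) so the realized density matches the
configured rates.  An indel is only injected where its *normalized*
reference interval lies within a single region of a single gene, making its
truth label unambiguous.  Truth labels are computed from the generator's own
construction records (region maps and codon offsets), not by the
consequence engine — engine recovery of every label is the pipeline's
principal oracle, and it is exact (100%) at the default scale.

What the simulator does **not** emulate: realistic nucleotide composition,
repeats and low-complexity sequence, heterozygosity/diploidy, clustered or
region-biased variant density, multi-isoform genes, overlapping genes,
sequencing error.  Passing tests therefore demonstrate correctness of the
classification, aggregation and homology logic under clean assumptions —
not robustness to noisy gene models or variant calls from real pipelines.

## Numerical and design choices

* Rounding: decimal half-up (not banker's) for all printed percentages.
* Severity ordering (above) resolves multi-gene and multi-effect overlaps
  deterministically; alignment tie-breaks fall back to lexicographic ids.
* Degenerate inputs: zero mutation rates are valid (identity mutation, empty
  truth set); an empty family table is valid; a zero denominator yields an
  undefined (None) percentage rather than an exception.
* Acceptance-scale choices: the benchmark runs at 1 contig × 100 kb with 50
  genes (~1,650 variants); homology metrics use 15-gene subsets and a
  14–16-gene simulation — small enough for exact Smith–Waterman everywhere.
* The `simulate`/`classify`/`orthologs`/`presence`/`summarize`/`run` CLI is
  a thin layer over the library; `run` writes `report.json` capturing every
  denominator and threshold used, and `warnings.tsv` collecting non-fatal
  issues (unknown gene ids, unknown family prefixes).

## Known limitations

* Consequence calling assumes variants are sparse: two variants inside one
  codon are classified independently, not jointly.
* Indels spanning exon/intron boundaries are flagged `complex` rather than
  given a coding effect; re-splicing prediction is out of scope.
* E-values use fixed Karlin–Altschul parameters and ungapped nucleotide
  constants; they order hits correctly but are not calibrated significance
  estimates.
* The full dynamic-programming search is quadratic per pair; it is meant
  for hundreds, not tens of thousands, of sequences.  Genome-scale ortholog
  screens should use a seeded aligner upstream and this package's RBH logic
  on the resulting scores.
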