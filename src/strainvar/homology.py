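"""Local alignment, best hits, reciprocal-best-hit orthology, presence/absence.

Alignment is exact Smith–Waterman with affine gaps (no heuristic seeding;
inputs are desk-scale).  E-values follow the Karlin–Altschul form
``E = K * m * n * exp(-lambda * S)`` with fixed per-scheme parameters — they
rank hits; they are not publication statistics.  Presence/absence mirrors a
two-stage homology screen: query against the target's annotated CDS set,
then re-search the misses against the full genome assembly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "ScoringScheme",
    "HomologyHit",
    "OrthologPair",
    "PresenceCall",
    "protein_scheme",
    "nucleotide_scheme",
    "align_local",
    "evalue",
    "best_hits",
    "reciprocal_best_hits",
    "presence_absence",
    "DEFAULT_EVALUE_THRESHOLD",
]

DEFAULT_EVALUE_THRESHOLD = 1e-5


@dataclass
class ScoringScheme:
    """Alignment scoring: mode, substitution scores, affine gap penalties.

    A gap of length k costs ``gap_open + k * gap_extend``.  ``karlin_lambda``
    and ``karlin_K`` scale scores to e-values.
    """

    mode: str  # "protein" | "nucleotide"
    match: int = 1
    mismatch: int = -2
    gap_open: float = 5.0
    gap_extend: float = 2.0
    karlin_lambda: float = 1.28
    karlin_K: float = 0.46
    matrix_name: str = "BLOSUM62"
    _matrix: object = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.mode not in ("protein", "nucleotide"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "protein":
            self._matrix = substitution_matrices.load(self.matrix_name)

    @property
    def alphabet(self) -> set[str]:
        if self.mode == "protein":
            return set(str(self._matrix.alphabet))
        return set("ACGTN")

    def make_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        if self.mode == "protein":
            aligner.substitution_matrix = self._matrix
        else:
            aligner.match_score = self.match
            aligner.mismatch_score = self.mismatch
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        return aligner


def protein_scheme(gap_open: float = 11, gap_extend: float = 1) -> ScoringScheme:
    """BLOSUM62 with affine gaps; Karlin parameters for gapped BLOSUM62."""
    return ScoringScheme(
        mode="protein", gap_open=gap_open, gap_extend=gap_extend,
        karlin_lambda=0.267, karlin_K=0.041,
    )


def nucleotide_scheme(
    match: int = 1, mismatch: int = -2, gap_open: float = 5, gap_extend: float = 2
) -> ScoringScheme:
    """+1/-2 nucleotide scoring; ungapped Karlin parameters for that matrix."""
    return ScoringScheme(
        mode="nucleotide", match=match, mismatch=mismatch,
        gap_open=gap_open, gap_extend=gap_extend,
        karlin_lambda=1.28, karlin_K=0.46,
    )


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    target_id: str
    score: float
    evalue: float
    identity: float  # % identical columns over aligned columns
    aligned_length: int


@dataclass(frozen=True)
class OrthologPair:
    a_id: str
    b_id: str
    score: float


@dataclass(frozen=True)
class PresenceCall:
    gene_id: str
    status: str  # present_in_cds | present_in_genome_only | absent
    cds_hit: HomologyHit | None
    genome_hit: HomologyHit | None


def _check_alphabet(seq: str, scheme: ScoringScheme, name: str) -> None:
    if not seq:
        raise ValueError(f"{name}: empty sequence")
    bad = set(seq) - scheme.alphabet
    if bad:
        raise ValueError(f"{name}: characters {sorted(bad)} outside {scheme.mode} alphabet")


def align_local(a: str, b: str, scheme: ScoringScheme) -> tuple[float, float, int]:
    """Optimal local alignment of ``a`` vs ``b``.

    Returns ``(score, identity_percent, aligned_length)``; a non-positive
    optimal score means no local alignment exists and returns ``(0, 0.0, 0)``.
    Identity is computed over the optimal traceback (gap columns included in
    the denominator).
    """
    _check_alphabet(a, scheme, "query")
    _check_alphabet(b, scheme, "target")
    aligner = scheme.make_aligner()
    score = aligner.score(a, b)
    if score <= 0:
        return 0.0, 0.0, 0
    aln = next(iter(aligner.align(a, b)))
    counts = aln.counts()
    aligned_len = counts.gaps + counts.identities + counts.mismatches
    identity = 100.0 * counts.identities / aligned_len if aligned_len else 0.0
    return float(score), identity, aligned_len


def evalue(score: float, query_len: int, db_len: int, scheme: ScoringScheme) -> float:
    """Karlin–Altschul expectation ``E = K * m * n * exp(-lambda * S)``."""
    if query_len <= 0 or db_len <= 0:
        raise ValueError("lengths must be positive")
    return scheme.karlin_K * query_len * db_len * math.exp(-scheme.karlin_lambda * score)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def best_hits(
    queries: Mapping[str, str],
    targets: Mapping[str, str],
    scheme: ScoringScheme,
    e_threshold: float = DEFAULT_EVALUE_THRESHOLD,
    both_strands: bool = False,
) -> dict[str, HomologyHit | None]:
    """Best target hit per query, or None when no hit passes the threshold.

    Ranking: higher score, then lower e-value, then higher identity, then
    lexicographically smallest target id.  ``both_strands`` (nucleotide mode
    only) also aligns against the reverse complement of each target and
    keeps the better strand — needed when searching a genome assembly whose
    genes lie on either strand.
    """
    if both_strands and scheme.mode != "nucleotide":
        raise ValueError("both_strands applies to nucleotide mode only")
    db_len = sum(len(t) for t in targets.values())
    out: dict[str, HomologyHit | None] = {}
    for qid, qseq in queries.items():
        hits: list[HomologyHit] = []
        for tid, tseq in targets.items():
            score, identity, alen = align_local(qseq, tseq, scheme)
            if both_strands:
                rscore, rident, ralen = align_local(qseq, _revcomp(tseq), scheme)
                if rscore > score:
                    score, identity, alen = rscore, rident, ralen
            if score <= 0:
                continue
            e = evalue(score, len(qseq), db_len, scheme)
            if e <= e_threshold:
                hits.append(HomologyHit(qid, tid, score, e, identity, alen))
        hits.sort(key=lambda h: (-h.score, h.evalue, -h.identity, h.target_id))
        out[qid] = hits[0] if hits else None
    return out


def reciprocal_best_hits(
    set_a: Mapping[str, str],
    set_b: Mapping[str, str],
    scheme: ScoringScheme,
    e_threshold: float = DEFAULT_EVALUE_THRESHOLD,
) -> list[OrthologPair]:
    """Ortholog pairs: (a, b) such that each is the other's best hit."""
    a_best = best_hits(set_a, set_b, scheme, e_threshold)
    b_best = best_hits(set_b, set_a, scheme, e_threshold)
    pairs = []
    for aid, hit in a_best.items():
        if hit is None:
            continue
        back = b_best.get(hit.target_id)
        if back is not None and back.target_id == aid:
            pairs.append(OrthologPair(aid, hit.target_id, hit.score))
    return sorted(pairs, key=lambda p: (p.a_id, p.b_id))


def presence_absence(
    query_cds: Mapping[str, str],
    target_cds: Mapping[str, str],
    target_genome: Mapping[str, str],
    scheme: ScoringScheme | None = None,
    e_threshold: float = DEFAULT_EVALUE_THRESHOLD,
) -> list[PresenceCall]:
    """Two-stage presence/absence calling for a gene list.

    Stage 1 searches each query against the target's CDS set; queries without
    a significant hit are re-searched against the full genome assembly
    (nucleotide mode).  A gene is absent only when both stages fail.
    """
    scheme = scheme or nucleotide_scheme()
    genome_scheme = scheme if scheme.mode == "nucleotide" else nucleotide_scheme()
    stage1 = best_hits(query_cds, target_cds, scheme, e_threshold)
    misses = {q: s for q, s in query_cds.items() if stage1[q] is None}
    stage2 = (
        best_hits(misses, target_genome, genome_scheme, e_threshold, both_strands=True)
        if misses
        else {}
    )
    calls = []
    for gid in query_cds:
        hit1 = stage1[gid]
        if hit1 is not None:
            calls.append(PresenceCall(gid, "present_in_cds", hit1, None))
            continue
        hit2 = stage2.get(gid)
        if hit2 is not None:
            calls.append(PresenceCall(gid, "present_in_genome_only", None, hit2))
        else:
            calls.append(PresenceCall(gid, "absent", None, None))
    return calls
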