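"""Cross-haplotype protein alignment.

Pairs are pre-screened with a shared k-mer filter (all true homolog pairs at
desk scale share many 5-mers) and then aligned with exact local dynamic
programming (BLOSUM62, affine gaps) via Bio.Align.PairwiseAligner. Identity
is matches over aligned columns; coverage is the aligned span over the
sequence length, kept per side because split/merge detection needs the
asymmetry. The 80/80 retention rule uses the larger of the two coverages so
that a fragment perfectly contained in its counterpart still passes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .models import GeneModel, GenomeSequence, representative_transcript
from .sequence import extract_cds_and_translate

log = logging.getLogger("hapgene")

__all__ = [
    "ProteinAlignmentHit",
    "align_pair",
    "align_proteins",
    "proteins_for",
    "IDENTITY_MIN",
    "COVERAGE_MIN",
]

IDENTITY_MIN = 80.0  # percent
COVERAGE_MIN = 80.0  # percent


@dataclass(frozen=True)
class ProteinAlignmentHit:
    query_id: str
    subject_id: str
    identity_pct: float
    query_coverage_pct: float
    subject_coverage_pct: float
    score: float
    q_start: int = 0   # aligned span on query (aa, 0-based half-open)
    q_end: int = 0
    s_start: int = 0
    s_end: int = 0

    @property
    def coverage_pct(self) -> float:
        """Screening coverage: the better-covered side."""
        return max(self.query_coverage_pct, self.subject_coverage_pct)

    def passes_filter(
        self, min_identity: float = IDENTITY_MIN, min_coverage: float = COVERAGE_MIN
    ) -> bool:
        return self.identity_pct >= min_identity and self.coverage_pct >= min_coverage


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = _make_aligner()


def _sanitize(pep: str) -> str:
    # PairwiseAligner rejects letters outside the matrix alphabet
    allowed = set("ARNDCQEGHILKMFPSTWYVBZX*")
    return "".join(c if c in allowed else "X" for c in pep.upper()).replace("*", "X")


def align_pair(
    query_id: str, query: str, subject_id: str, subject: str
) -> ProteinAlignmentHit | None:
    """Best local alignment of two peptides, or None if either is empty."""
    if not query or not subject:
        return None
    alns = _ALIGNER.align(_sanitize(query), _sanitize(subject))
    if len(alns) == 0 or alns.score <= 0:
        return None
    aln = alns[0]
    q_ranges, s_ranges = aln.aligned
    if len(q_ranges) == 0:
        return None
    q_start, q_end = int(q_ranges[0][0]), int(q_ranges[-1][1])
    s_start, s_end = int(s_ranges[0][0]), int(s_ranges[-1][1])
    matches = 0
    aligned_cols = 0
    for (qs, qe), (ss, se) in zip(q_ranges, s_ranges):
        aligned_cols += qe - qs
        for i in range(qe - qs):
            if query[qs + i].upper() == subject[ss + i].upper():
                matches += 1
    # interior gaps count as aligned columns
    for (prev_q, prev_s), (next_q, next_s) in zip(
        ((r[1], s[1]) for r, s in zip(q_ranges, s_ranges)),
        ((r[0], s[0]) for r, s in zip(q_ranges[1:], s_ranges[1:])),
    ):
        aligned_cols += (next_q - prev_q) + (next_s - prev_s)
    identity = 100.0 * matches / aligned_cols if aligned_cols else 0.0
    return ProteinAlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        identity_pct=float(identity),
        query_coverage_pct=100.0 * (q_end - q_start) / len(query),
        subject_coverage_pct=100.0 * (s_end - s_start) / len(subject),
        score=float(alns.score),
        q_start=q_start, q_end=q_end, s_start=s_start, s_end=s_end,
    )


def _kmer_index(peptides: dict[str, str], k: int) -> dict[str, set[str]]:
    index: dict[str, set[str]] = {}
    for pid, pep in peptides.items():
        for i in range(len(pep) - k + 1):
            index.setdefault(pep[i : i + k], set()).add(pid)
    return index


def candidate_pairs(
    queries: dict[str, str], subjects: dict[str, str],
    k: int = 5, min_shared: int = 3,
) -> list[tuple[str, str]]:
    """Pairs sharing at least ``min_shared`` k-mers (order-stable)."""
    index = _kmer_index(subjects, k)
    pairs: list[tuple[str, str]] = []
    for qid in sorted(queries):
        pep = queries[qid]
        counts: dict[str, int] = {}
        seen = set()
        for i in range(len(pep) - k + 1):
            kmer = pep[i : i + k]
            if kmer in seen:
                continue
            seen.add(kmer)
            for sid in index.get(kmer, ()):
                counts[sid] = counts.get(sid, 0) + 1
        for sid in sorted(s for s, c in counts.items() if c >= min_shared):
            pairs.append((qid, sid))
    return pairs


def align_proteins(
    queries: dict[str, str],
    subjects: dict[str, str],
    min_identity: float = IDENTITY_MIN,
    min_coverage: float = COVERAGE_MIN,
    apply_filter: bool = True,
    k: int = 5,
    min_shared: int = 3,
) -> list[ProteinAlignmentHit]:
    """All-vs-all protein hits between two haplotype proteomes.

    With ``apply_filter`` (the default) hits below the identity/coverage
    thresholds are excluded; split/merge detection re-runs without the filter
    so that low-coverage fragment hits survive.
    """
    empties = [pid for d in (queries, subjects) for pid, p in d.items() if not p]
    if empties:
        log.warning("align_proteins: skipping %d empty peptide(s)", len(empties))
    queries = {p: s for p, s in queries.items() if s}
    subjects = {p: s for p, s in subjects.items() if s}
    hits: list[ProteinAlignmentHit] = []
    for qid, sid in candidate_pairs(queries, subjects, k=k, min_shared=min_shared):
        hit = align_pair(qid, queries[qid], sid, subjects[sid])
        if hit is None:
            continue
        if apply_filter and not hit.passes_filter(min_identity, min_coverage):
            continue
        hits.append(hit)
    return hits


def proteins_for(
    models: list[GeneModel], genome: GenomeSequence
) -> dict[str, str]:
    """Representative-transcript peptides per gene (stop-free)."""
    peptides: dict[str, str] = {}
    for g in models:
        tx = representative_transcript(g)
        if not tx.cds_segments:
            continue
        _, pep, _ = extract_cds_and_translate(tx, genome, g.seq_name, g.strand)
        peptides[g.gene_id] = pep.split("*")[0] if "*" in pep else pep
    return peptides
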