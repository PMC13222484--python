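"""Bi-allelic pair identification, allelic expression classification, tissue
specificity, and lincRNA positional/TE rules.

Allelic expression states follow the nearest-ideal-vector rule: the per-pair
TPM profile is normalised to proportions and assigned to Balanced (0.5, 0.5),
H1_dominant (1, 0) or H2_dominant (0, 1) by minimal Euclidean distance, with
NE (not expressed) decided first by a summed-TPM floor. The implied decision
boundary is a 0.75 proportion for dominance — the midpoint between the
Balanced and dominant vectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .align import ProteinAlignmentHit
from .liftover import SyntenyIndex
from .models import GeneModel, Interval, SyntenyBlock, TEAnnotation

__all__ = [
    "IdealVectors",
    "AllelicPair",
    "identify_bialleles",
    "classify_allelic_state",
    "tau",
    "tissue_specific_call",
    "classify_lnc_position",
    "te_association",
]


@dataclass(frozen=True)
class IdealVectors:
    balanced: tuple[float, float] = (0.5, 0.5)
    h1_dominant: tuple[float, float] = (1.0, 0.0)
    h2_dominant: tuple[float, float] = (0.0, 1.0)
    expression_floor: float = 0.5  # summed TPM below which a pair is NE


@dataclass
class AllelicPair:
    gene_h1: str
    gene_h2: str
    anchor_type: str = "syntenic_anchor"   # or homology_only
    sequence_identical: bool = False
    expressed_any_tissue: bool = True
    states: dict[str, str] = field(default_factory=dict)  # tissue -> state


def classify_allelic_state(
    tpm_h1: float, tpm_h2: float, vectors: IdealVectors | None = None
) -> str:
    """Nearest ideal vector on expression proportions; ties go to Balanced."""
    vectors = vectors or IdealVectors()
    if tpm_h1 < 0 or tpm_h2 < 0:
        raise ValueError("negative TPM")
    total = tpm_h1 + tpm_h2
    if total < vectors.expression_floor:
        return "NE"
    p = (tpm_h1 / total, tpm_h2 / total)
    options = [
        ("Balanced", vectors.balanced),
        ("H1_dominant", vectors.h1_dominant),
        ("H2_dominant", vectors.h2_dominant),
    ]
    dists = [
        (math.dist(p, vec), i, name) for i, (name, vec) in enumerate(options)
    ]
    # Balanced is listed first, so exact ties resolve toward it
    return min(dists)[2]


def tau(profile) -> float:
    """Tissue-specificity index: tau = sum(1 - x_i / x_max) / (n - 1).

    0 for uniform expression, 1 for single-tissue expression. Undefined for
    an all-zero profile (NaN).
    """
    x = np.asarray(profile, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("profile must be a 1-D vector of >=2 tissues")
    if (x < 0).any():
        raise ValueError("negative expression")
    m = x.max()
    if m == 0:
        return float("nan")
    return float(np.sum(1 - x / m) / (x.size - 1))


def tissue_specific_call(
    profile, tissues: list[str] | None = None,
    ratio: float = 3.0, ratio_to: str = "second",
) -> tuple[bool, str | None]:
    """Tissue-specific when the highest TPM exceeds ``ratio`` times the
    second-highest (``ratio_to='second'``, default) or the lowest
    (``ratio_to='lowest'``). A strictly positive top over a zero reference is
    specific; an all-zero profile is not.
    """
    x = np.asarray(profile, dtype=float)
    if x.size < 2:
        raise ValueError("need >=2 tissues")
    order = np.argsort(x)[::-1]
    top = x[order[0]]
    if top == 0:
        return False, None
    ref = x[order[1]] if ratio_to == "second" else x.min()
    dominant = tissues[order[0]] if tissues else str(order[0])
    if ref == 0:
        return True, dominant
    specific = bool(top / ref > ratio)
    return specific, (dominant if specific else None)


# ------------------------------------------------------------------ pairing


def identify_bialleles(
    models_h1: list[GeneModel],
    models_h2: list[GeneModel],
    clusters: list[set[str]],
    blocks: list[SyntenyBlock],
    hits: list[ProteinAlignmentHit] | None = None,
) -> tuple[list[AllelicPair], list[str], list[str]]:
    """Pair genes across haplotypes by shared homology cluster plus lifted
    positional overlap.

    A hap1/hap2 gene pair is bi-allelic when both genes belong to the same
    cluster and the hap1 gene's span, lifted through the synteny blocks,
    overlaps the hap2 gene's span. Among multiple candidates, the pair with
    the greatest lifted overlap wins (ties: highest alignment score, then
    lexicographic id). Returns (pairs, mono-allelic hap1 ids, mono-allelic
    hap2 ids).
    """
    by_id_h1 = {m.gene_id: m for m in models_h1}
    by_id_h2 = {m.gene_id: m for m in models_h2}
    index = SyntenyIndex(blocks, "h1to2")
    score_of: dict[tuple[str, str], float] = {}
    for h in hits or []:
        key = (h.query_id, h.subject_id)
        score_of[key] = max(score_of.get(key, 0.0), h.score)

    candidate_edges: list[tuple[int, float, str, str, str]] = []
    for cluster in clusters:
        h1_members = sorted(g for g in cluster if g in by_id_h1)
        h2_members = sorted(g for g in cluster if g in by_id_h2)
        for g1 in h1_members:
            m1 = by_id_h1[g1]
            lifted = index.lift_interval(m1.seq_name, m1.span)
            for g2 in h2_members:
                m2 = by_id_h2[g2]
                overlap = sum(
                    iv.overlap(m2.span)
                    for seq, iv, _o in lifted.mapped_intervals
                    if seq == m2.seq_name
                )
                if overlap > 0:
                    candidate_edges.append(
                        (overlap, score_of.get((g1, g2), 0.0), g1, g2, "syntenic_anchor")
                    )
                elif score_of.get((g1, g2), 0.0) > 0:
                    candidate_edges.append(
                        (0, score_of[(g1, g2)], g1, g2, "homology_only")
                    )

    # greedy one-to-one matching, best (overlap, score) first
    candidate_edges.sort(key=lambda e: (-e[0], -e[1], e[2], e[3]))
    used_h1: set[str] = set()
    used_h2: set[str] = set()
    pairs: list[AllelicPair] = []
    for overlap, _score, g1, g2, anchor in candidate_edges:
        if g1 in used_h1 or g2 in used_h2:
            continue
        used_h1.add(g1)
        used_h2.add(g2)
        pairs.append(AllelicPair(gene_h1=g1, gene_h2=g2, anchor_type=anchor))
    mono_h1 = sorted(set(by_id_h1) - used_h1)
    mono_h2 = sorted(set(by_id_h2) - used_h2)
    pairs.sort(key=lambda p: p.gene_h1)
    return pairs, mono_h1, mono_h2


# ------------------------------------------------------------------ lincRNA


def classify_lnc_position(
    transcript_span: Interval,
    seq_name: str,
    coding_models: list[GeneModel],
    min_length: int = 200,
) -> str:
    """'intergenic' (lincRNA), 'overlapping', or 'rejected' (<200 bp).

    Any single bp of overlap with a protein-coding gene span (strand-agnostic)
    disqualifies a transcript from lincRNA status.
    """
    if len(transcript_span) < min_length:
        return "rejected"
    for m in coding_models:
        if m.seq_name == seq_name and transcript_span.overlap(m.span) > 0:
            return "overlapping"
    return "intergenic"


def te_association(
    transcript_span: Interval, seq_name: str, te: TEAnnotation,
    min_fraction: float = 0.5,
) -> tuple[float, bool, str | None]:
    """TE-covered fraction of the transcript span; associated when strictly
    greater than ``min_fraction``. Returns (fraction, associated, dominant
    TE class by covered bp)."""
    covered_by_class: dict[str, int] = {}
    covered = 0
    last_end = transcript_span.start
    for iv, cls in te.on(seq_name):
        s = max(iv.start, last_end)
        e = min(iv.end, transcript_span.end)
        if e > s:
            covered += e - s
            covered_by_class[cls] = covered_by_class.get(cls, 0) + (e - s)
            last_end = e
    frac = covered / len(transcript_span) if len(transcript_span) else 0.0
    associated = frac > min_fraction
    dominant = (
        max(sorted(covered_by_class), key=covered_by_class.__getitem__)
        if covered_by_class else None
    )
    return frac, associated, dominant if associated else dominant
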