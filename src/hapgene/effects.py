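"""Functional-consequence prediction for inter-haplotype variants.

A variant's effect on a gene model is determined by rebuilding the mutated
coding sequence in transcript space and comparing translations, with
splice-site calls when a variant touches the first or last two intron bases.
Each (variant, transcript) pair receives exactly one effect class, chosen by
severity; the class fixes the impact level:

HIGH      start_lost, stop_gained, stop_lost, frameshift,
          splice_donor_lost, splice_acceptor_lost
MODERATE  inframe_indel, missense
LOW       synonymous
MODIFIER  noncoding_region
"""

from __future__ import annotations

from dataclasses import dataclass

from intervaltree import IntervalTree

from .models import GeneModel, GenomeSequence, TranscriptModel, Variant, representative_transcript
from .sequence import STOP_CODONS, reverse_complement, translate

__all__ = ["EffectCall", "classify_variant_effect", "call_high_effect_genes",
           "IMPACT_OF", "SEVERITY_ORDER"]

IMPACT_OF = {
    "start_lost": "HIGH",
    "stop_gained": "HIGH",
    "stop_lost": "HIGH",
    "frameshift": "HIGH",
    "splice_donor_lost": "HIGH",
    "splice_acceptor_lost": "HIGH",
    "inframe_indel": "MODERATE",
    "missense": "MODERATE",
    "synonymous": "LOW",
    "noncoding_region": "MODIFIER",
}

# most to least severe; splice classes share one rank
SEVERITY_ORDER = [
    "start_lost",
    "stop_gained",
    "splice_donor_lost",
    "splice_acceptor_lost",
    "frameshift",
    "stop_lost",
    "inframe_indel",
    "missense",
    "synonymous",
    "noncoding_region",
]
_RANK = {c: i for i, c in enumerate(SEVERITY_ORDER)}


@dataclass(frozen=True)
class EffectCall:
    gene_id: str
    transcript_id: str
    variant: Variant
    effect_class: str

    @property
    def impact(self) -> str:
        return IMPACT_OF[self.effect_class]


def classify_variant_effect(
    gene: GeneModel,
    variant: Variant,
    genome: GenomeSequence,
    transcript: TranscriptModel | None = None,
) -> EffectCall:
    """Predict the consequence of ``variant`` on a transcript of ``gene``
    (the representative transcript unless one is given)."""
    tx = transcript if transcript is not None else representative_transcript(gene)
    cls = _effect_class(tx, gene.strand, variant, genome[gene.seq_name]) \
        if variant.seq_name == gene.seq_name else "noncoding_region"
    return EffectCall(gene.gene_id, tx.transcript_id, variant, cls)


def _effect_class(
    tx: TranscriptModel, strand: str, variant: Variant, chrom: str
) -> str:
    span = tx.span
    v_iv = variant.ref_interval
    if v_iv.end <= span.start or v_iv.start >= span.end:
        return "noncoding_region"

    candidates: list[str] = []

    # --- splice windows: first/last two intron bases in transcription order
    for intron in tx.introns():
        left = (intron.start, intron.start + 2)
        right = (intron.end - 2, intron.end)
        if strand == "+":
            donor, acceptor = left, right
        else:
            donor, acceptor = right, left
        if _touches(variant, donor):
            candidates.append("splice_donor_lost")
        if _touches(variant, acceptor):
            candidates.append("splice_acceptor_lost")

    # --- coding consequences via CDS rebuild
    if tx.cds_segments:
        old_cds, new_cds = _mutate_cds(tx, strand, variant, chrom)
        if new_cds != old_cds:
            candidates.extend(_coding_candidates(old_cds, new_cds))

    if not candidates:
        return "noncoding_region"
    return min(candidates, key=_RANK.__getitem__)


def _touches(variant: Variant, window: tuple[int, int]) -> bool:
    """Does the variant alter the bases of the 2-bp window?

    SNPs/deletions: reference-footprint overlap with the window (for anchored
    deletions only the truly deleted bases count). Insertions: an insertion
    point strictly inside the window splits it.
    """
    ws, we = window
    if variant.var_class == "SNP":
        return ws <= variant.pos < we
    if variant.var_class == "DEL":
        ds = variant.pos + len(variant.alt_allele)
        de = variant.pos + len(variant.ref_allele)
        return ds < we and ws < de
    ip = variant.pos + 1  # insertion lands between ip-1 and ip
    return ws < ip < we


def _mutate_cds(
    tx: TranscriptModel, strand: str, variant: Variant, chrom: str
) -> tuple[str, str]:
    """Return (reference CDS, variant-applied CDS), both in transcription
    order. Variant portions outside the CDS are ignored (they are handled by
    the splice-window check)."""
    positions = [p for seg in tx.cds_segments for p in range(seg.start, seg.end)]
    bases = [chrom[p] for p in positions]
    old = "".join(bases)

    keep = [True] * len(positions)
    subst: dict[int, str] = {}
    insert_after_genomic: tuple[int, str] | None = None

    if variant.var_class == "SNP":
        subst[variant.pos] = variant.alt_allele
    elif variant.var_class == "DEL":
        ds = variant.pos + len(variant.alt_allele)
        de = variant.pos + len(variant.ref_allele)
        for i, p in enumerate(positions):
            if ds <= p < de:
                keep[i] = False
    else:  # INS between pos and pos+1
        insert_after_genomic = (variant.pos, variant.alt_allele[1:])

    out: list[str] = []
    pos_out: list[int] = []
    for i, p in enumerate(positions):
        if not keep[i]:
            continue
        out.append(subst.get(p, bases[i]))
        pos_out.append(p)

    if insert_after_genomic is not None:
        ip, payload = insert_after_genomic
        in_cds = any(seg.start <= ip and ip + 1 < seg.end for seg in tx.cds_segments)
        if in_cds:
            idx = next(i for i, p in enumerate(pos_out) if p > ip)
            out[idx:idx] = list(payload)
            pos_out[idx:idx] = [-1] * len(payload)

    new = "".join(out)
    if strand == "-":
        old = reverse_complement(old)
        new = reverse_complement(new)
    return old, new


def _premature_stop(cds: str) -> bool:
    n = len(cds) // 3
    for i in range(n - 1):
        if cds[3 * i : 3 * i + 3] in STOP_CODONS:
            return True
    return False


def _coding_candidates(old: str, new: str) -> list[str]:
    cands: list[str] = []
    if new[:3] != "ATG" and old[:3] == "ATG":
        cands.append("start_lost")
    delta = len(new) - len(old)
    if delta % 3 != 0:
        cands.append("frameshift")
        return cands
    if _premature_stop(new) and not _premature_stop(old):
        cands.append("stop_gained")
    old_term = len(old) >= 3 and old[-3:] in STOP_CODONS
    new_term = len(new) >= 3 and new[-3:] in STOP_CODONS
    if old_term and not new_term and not _premature_stop(new):
        cands.append("stop_lost")
    if delta != 0:
        cands.append("inframe_indel")
    elif translate(old) != translate(new):
        cands.append("missense")
    else:
        cands.append("synonymous")
    return cands


def call_high_effect_genes(
    models: list[GeneModel], variants: list[Variant], genome: GenomeSequence
) -> set[str]:
    """Gene ids whose representative transcript carries at least one
    HIGH-impact effect call.

    Only small variants (<50 bp) are annotated; structural events are the
    province of the SV-evidence path.
    """
    trees: dict[str, IntervalTree] = {}
    for v in variants:
        if v.size >= 50:
            continue
        iv = v.ref_interval
        trees.setdefault(v.seq_name, IntervalTree()).addi(
            iv.start, max(iv.end, iv.start + 1), v
        )
    high: set[str] = set()
    for gene in models:
        tree = trees.get(gene.seq_name)
        if tree is None:
            continue
        tx = representative_transcript(gene)
        sp = tx.span
        for hit in sorted(tree.overlap(sp.start, sp.end)):
            call = classify_variant_effect(gene, hit.data, genome, tx)
            if call.impact == "HIGH":
                high.add(gene.gene_id)
                break
    return high
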