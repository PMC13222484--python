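"""Haplotype-aware annotation refinement.

The engine compares the two haplotypes' preliminary annotations and corrects
the asymmetries that single-haplotype annotation produces:

1. cross-haplotype protein alignment and single-linkage clustering;
2. validation of candidate haplotype-specific genes against allelic evidence
   (HIGH-impact variants, structural variants, unaligned regions) — genes with
   none of these are candidate *unannotated* genes, i.e. annotation errors;
3. rescue of unannotated genes by projecting the counterpart model through
   synteny, gated on intact splice sites, an intact ORF, and (when available)
   splice-junction hints;
4. detection and repair of split/merged gene models;
5. removal of TE-dominated genes (>30% overlap) and of putative false
   positives (short mono-exonic models with no domain, no expression and no
   cross-haplotype homology).

Every gene added or removed is recorded in an audit log so that
``genes_in + added - removed == genes_out`` reconciles exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .align import (
    COVERAGE_MIN,
    IDENTITY_MIN,
    ProteinAlignmentHit,
    align_proteins,
    proteins_for,
)
from .effects import call_high_effect_genes, classify_variant_effect
from .liftover import (
    SV_MIN_LEN,
    ProjectionResult,
    SVEvidence,
    SyntenyIndex,
    project_gene_model,
    sv_evidence_for_gene,
)
from .models import (
    ExpressionTable,
    GeneModel,
    GenomeSequence,
    Interval,
    SyntenyBlock,
    TEAnnotation,
    Variant,
    representative_transcript,
)

__all__ = [
    "RefinementConfig",
    "RefinementInputs",
    "HapSpecificReport",
    "SplitMergeCall",
    "RefinementResult",
    "cluster_cross_haplotype",
    "validate_hapspecific",
    "rescue_missing_genes",
    "detect_split_merge",
    "repair_split_merge",
    "filter_te_genes",
    "filter_false_positives",
    "run_refinement",
]


@dataclass
class RefinementConfig:
    min_identity: float = IDENTITY_MIN
    min_coverage: float = COVERAGE_MIN
    adjacency_bp: int = 10_000
    min_projection_fraction: float = 0.5
    te_max_overlap: float = 0.30
    fp_max_len: int = 300
    fragment_overlap_max: float = 0.20
    fragment_coverage_min: float = 50.0  # % of the fragment-side protein


@dataclass
class RefinementInputs:
    hap1: GenomeSequence
    hap2: GenomeSequence
    genes_h1: list[GeneModel]
    genes_h2: list[GeneModel]
    variants: list[Variant]            # hap1 coordinates (ref = hap1)
    blocks: list[SyntenyBlock]
    te_h1: TEAnnotation | None = None
    te_h2: TEAnnotation | None = None
    junctions_h2: set[tuple[str, int, int]] | None = None
    junctions_h1: set[tuple[str, int, int]] | None = None
    expr_h1: ExpressionTable | None = None
    expr_h2: ExpressionTable | None = None
    domains: set[str] | None = None


@dataclass
class HapSpecificReport:
    candidate_specific: dict[str, set[str]]
    high_confidence_specific: dict[str, set[str]]
    candidate_unannotated: dict[str, set[str]]
    evidence: dict[str, str] = field(default_factory=dict)

    def n_unannotated(self) -> int:
        return sum(len(v) for v in self.candidate_unannotated.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for hap in sorted(self.candidate_specific):
            for gid in sorted(self.candidate_specific[hap]):
                if gid in self.high_confidence_specific[hap]:
                    label = "high_confidence_specific"
                else:
                    label = "candidate_unannotated"
                rows.append(
                    {"gene_id": gid, "haplotype": hap, "label": label,
                     "evidence": self.evidence.get(gid, "")}
                )
        return pd.DataFrame(rows, columns=["gene_id", "haplotype", "label", "evidence"])


@dataclass
class SplitMergeCall:
    pattern: str                 # split_in_target | merged_in_target
    source_genes: list[str]
    target_genes: list[str]
    adjacency_gap_bp: int
    supported_by_junctions: bool = False
    target_hap: str = "hap2"


@dataclass
class RefinementResult:
    refined_h1: list[GeneModel]
    refined_h2: list[GeneModel]
    report_before: HapSpecificReport
    report_after: HapSpecificReport
    split_merge_calls: list[SplitMergeCall]
    rescued: dict[str, list[str]]        # target hap -> rescued gene ids
    unrescued: dict[str, list[str]]
    repaired_calls: int
    audit: pd.DataFrame

    def audit_reconciles(self) -> bool:
        for hap, n_in, n_out in (
            ("hap1", self._n("hap1", "input"), len(self.refined_h1)),
            ("hap2", self._n("hap2", "input"), len(self.refined_h2)),
        ):
            added = self._n(hap, "added")
            removed = self._n(hap, "removed")
            if n_in + added - removed != n_out:
                return False
        return True

    def _n(self, hap: str, action: str) -> int:
        a = self.audit
        return int(((a["haplotype"] == hap) & (a["action"] == action)).sum())


# ------------------------------------------------------------------ clustering


def cluster_cross_haplotype(
    models_h1: list[GeneModel],
    models_h2: list[GeneModel],
    hits: list[ProteinAlignmentHit],
    min_identity: float = IDENTITY_MIN,
    min_coverage: float = COVERAGE_MIN,
) -> list[set[str]]:
    """Single-linkage clusters over the cross-haplotype hit graph.

    Hits below the identity/coverage retention thresholds are discarded
    before clustering; unlinked genes become singleton clusters.
    """
    g = nx.Graph()
    g.add_nodes_from(m.gene_id for m in models_h1)
    g.add_nodes_from(m.gene_id for m in models_h2)
    for h in hits:
        if h.passes_filter(min_identity, min_coverage):
            g.add_edge(h.query_id, h.subject_id)
    return sorted(
        (set(c) for c in nx.connected_components(g)),
        key=lambda c: min(c),
    )


def candidate_specific_sets(
    clusters: list[set[str]],
    models_h1: list[GeneModel],
    models_h2: list[GeneModel],
) -> dict[str, set[str]]:
    """Genes whose cluster contains members of only one haplotype."""
    hap_of = {m.gene_id: "hap1" for m in models_h1}
    hap_of.update({m.gene_id: "hap2" for m in models_h2})
    out: dict[str, set[str]] = {"hap1": set(), "hap2": set()}
    for cluster in clusters:
        haps = {hap_of[g] for g in cluster}
        if len(haps) == 1:
            out[haps.pop()].update(cluster)
    return out


# ------------------------------------------------------------------ validation


def validate_hapspecific(
    candidates: dict[str, set[str]],
    inputs: RefinementInputs,
    index_h1to2: SyntenyIndex,
    index_h2to1: SyntenyIndex,
    config: RefinementConfig | None = None,
) -> HapSpecificReport:
    """Label each candidate haplotype-specific gene by the first satisfied
    criterion: (i) HIGH-impact variant at its locus, (ii) disruptive SV over
    its coding region, (iii) residence in an unaligned region. Candidates
    with no evidence are candidate unannotated genes."""
    config = config or RefinementConfig()
    by_id = {m.gene_id: m for m in inputs.genes_h1 + inputs.genes_h2}
    high: dict[str, set[str]] = {}
    high["hap1"] = call_high_effect_genes(
        [by_id[g] for g in sorted(candidates["hap1"])], inputs.variants, inputs.hap1
    )
    high["hap2"] = _high_effect_hap2(
        [by_id[g] for g in sorted(candidates["hap2"])],
        inputs, index_h2to1, config,
    )
    report = HapSpecificReport(
        candidate_specific={h: set(candidates[h]) for h in ("hap1", "hap2")},
        high_confidence_specific={"hap1": set(), "hap2": set()},
        candidate_unannotated={"hap1": set(), "hap2": set()},
    )
    for hap, index in (("hap1", index_h1to2), ("hap2", index_h2to1)):
        for gid in sorted(candidates[hap]):
            gene = by_id[gid]
            if gid in high[hap]:
                report.high_confidence_specific[hap].add(gid)
                report.evidence[gid] = "high_effect_variant"
                continue
            ev = _sv_evidence(gene, hap, inputs, index)
            if ev.evidence_class == "unaligned_region":
                report.high_confidence_specific[hap].add(gid)
                report.evidence[gid] = "unaligned_region"
            elif ev.evidence_class != "none":
                report.high_confidence_specific[hap].add(gid)
                report.evidence[gid] = f"sv:{ev.evidence_class}"
            else:
                report.candidate_unannotated[hap].add(gid)
                report.evidence[gid] = "no_allelic_evidence"
    return report


def _sv_evidence(
    gene: GeneModel, hap: str, inputs: RefinementInputs, index: SyntenyIndex
) -> SVEvidence:
    if hap == "hap1":
        return sv_evidence_for_gene(gene, inputs.variants, inputs.blocks, index)
    return _sv_evidence_qry(gene, inputs.blocks, index)


def _sv_evidence_qry(
    gene: GeneModel, blocks: list[SyntenyBlock], index_h2to1: SyntenyIndex
) -> SVEvidence:
    """SV evidence for a hap2-annotated gene, read on the qry side: coding
    bases falling in qry-side gaps (hap2-only sequence) or inversions, and
    NOTAL residence."""
    tx = representative_transcript(gene)
    span = gene.span
    cds = [seg.interval for seg in tx.cds_segments] or list(tx.exons)
    cds_len = sum(len(c) for c in cds)
    unmapped = 0
    for c in cds:
        r = index_h2to1.lift_interval(gene.seq_name, c)
        unmapped += round((1 - r.fraction_mapped) * len(c))
    notal_bp = index_h2to1.notal_overlap(gene.seq_name, span)
    if len(span) and notal_bp / len(span) > 0.5:
        return SVEvidence(gene.gene_id, "unaligned_region", notal_bp / len(span))
    if cds_len and unmapped - notal_bp >= max(SV_MIN_LEN, 0.5 * cds_len):
        return SVEvidence(gene.gene_id, "coding_majority_deleted",
                          unmapped / cds_len)
    inv_bp = 0
    for b in blocks:
        if b.block_class != "INV" or b.qry_seq != gene.seq_name:
            continue
        for c in cds:
            inv_bp += c.overlap(b.qry_interval)
    if inv_bp >= 1:
        return SVEvidence(gene.gene_id, "coding_inverted",
                          inv_bp / cds_len if cds_len else 0.0)
    return SVEvidence(gene.gene_id, "none", 0.0)


def _high_effect_hap2(
    candidates: list[GeneModel],
    inputs: RefinementInputs,
    index_h2to1: SyntenyIndex,
    config: RefinementConfig,
) -> set[str]:
    """HIGH-impact calls for hap2-annotated candidates: the gene is projected
    onto hap1 and the (hap1-anchored) variants overlapping the projected model
    are classified against it. A HIGH call means the two alleles differ
    disruptively at the locus."""
    out: set[str] = set()
    small = [v for v in inputs.variants if v.size < SV_MIN_LEN]
    for gene in candidates:
        proj = project_gene_model(
            gene, index_h2to1, inputs.hap1,
            min_fraction=config.min_projection_fraction,
        )
        if proj.failed:
            continue
        ghost = GeneModel(gene.gene_id, proj.seq_name, proj.strand,
                          [proj.model], "projected")
        sp = ghost.span
        for v in small:
            if v.seq_name != proj.seq_name:
                continue
            iv = v.ref_interval
            if iv.end <= sp.start or iv.start >= sp.end:
                continue
            call = classify_variant_effect(ghost, v, inputs.hap1, proj.model)
            if call.impact == "HIGH":
                out.add(gene.gene_id)
                break
    return out


# ------------------------------------------------------------------ rescue


def _junctions_ok(
    proj: ProjectionResult, hints: set[tuple[str, int, int]] | None
) -> bool:
    if hints is None:
        return True
    return all(
        (proj.seq_name, i.start, i.end) in hints for i in proj.model.introns()
    )


def rescue_missing_genes(
    unannotated: list[GeneModel],
    index: SyntenyIndex,
    target_genome: GenomeSequence,
    existing_target: list[GeneModel],
    junction_hints: set[tuple[str, int, int]] | None = None,
    config: RefinementConfig | None = None,
) -> tuple[list[GeneModel], list[tuple[str, str]]]:
    """Project candidate unannotated genes onto the other haplotype.

    A projection is accepted only with intact GT..AG splice sites, an intact
    ORF, no overlap with an existing target model, and (when hints are given)
    every projected intron present among the hinted junctions. Rejected genes
    are returned with the reason — never silently dropped.
    """
    config = config or RefinementConfig()
    occupied: dict[str, list[Interval]] = {}
    for m in existing_target:
        occupied.setdefault(m.seq_name, []).append(m.span)
    rescued: list[GeneModel] = []
    unresolved: list[tuple[str, str]] = []
    for gene in sorted(unannotated, key=lambda g: g.gene_id):
        proj = project_gene_model(
            gene, index, target_genome,
            min_fraction=config.min_projection_fraction,
            transcript_id=gene.gene_id + ".rescued.t1",
        )
        if proj.failed:
            unresolved.append((gene.gene_id, proj.reason))
            continue
        span = proj.model.span
        if any(span.overlap(o) for o in occupied.get(proj.seq_name, [])):
            unresolved.append((gene.gene_id, "target_locus_occupied"))
            continue
        if not proj.splice_sites_intact:
            unresolved.append((gene.gene_id, "splice_sites_broken"))
            continue
        if not proj.orf_intact:
            unresolved.append((gene.gene_id, "orf_broken"))
            continue
        if not _junctions_ok(proj, junction_hints):
            unresolved.append((gene.gene_id, "junctions_unsupported"))
            continue
        model = GeneModel(
            gene.gene_id + ".rescued", proj.seq_name, proj.strand,
            [proj.model], source_haplotype=f"rescued_from:{gene.gene_id}",
        )
        rescued.append(model)
        occupied.setdefault(proj.seq_name, []).append(span)
    return rescued, unresolved


# ------------------------------------------------------------------ split/merge


def _one_side_intervals(hit: ProteinAlignmentHit, side: str) -> tuple[int, int]:
    return (hit.q_start, hit.q_end) if side == "q" else (hit.s_start, hit.s_end)


def _tile_ok(intervals: list[tuple[int, int]], max_overlap: float) -> bool:
    """Hit intervals on the single-protein side must tile near-disjointly."""
    for i, (s1, e1) in enumerate(intervals):
        for s2, e2 in intervals[i + 1 :]:
            ov = max(0, min(e1, e2) - max(s1, s2))
            shorter = max(1, min(e1 - s1, e2 - s2))
            if ov / shorter >= max_overlap:
                return False
    return True


def _adjacent_run(
    gene_ids: list[str],
    models: dict[str, GeneModel],
    order: dict[str, int],
    positional: list[GeneModel],
    adjacency_bp: int,
) -> int | None:
    """Gap if the genes are consecutive on one sequence within adjacency_bp
    with no intervening gene; None otherwise."""
    ms = sorted((models[g] for g in gene_ids), key=lambda m: m.span.start)
    if len({m.seq_name for m in ms}) != 1:
        return None
    max_gap = 0
    for a, b in zip(ms, ms[1:]):
        if order[b.gene_id] - order[a.gene_id] != 1:
            return None  # another annotated gene lies between
        gap = b.span.start - a.span.end
        if gap > adjacency_bp:
            return None
        max_gap = max(max_gap, gap)
    return max_gap


def detect_split_merge(
    models_src: list[GeneModel],
    models_tgt: list[GeneModel],
    hits: list[ProteinAlignmentHit],
    adjacency_bp: int = 10_000,
    junction_hints: set[tuple[str, int, int]] | None = None,
    min_identity: float = IDENTITY_MIN,
    fragment_overlap_max: float = 0.20,
    fragment_coverage_min: float = 50.0,
    target_hap: str = "hap2",
) -> list[SplitMergeCall]:
    """Detect split (one source protein over >=2 adjacent target genes) and
    merged (>=2 adjacent source genes over one target protein) structures.

    ``hits`` must be unfiltered by the 80/80 coverage rule: split halves have
    low coverage on the single-protein side by nature. Identity still gates
    individual hits, and the fragment-side protein must itself be mostly
    (>= ``fragment_coverage_min`` %) aligned, which excludes short spurious
    local matches to unrelated genes.
    """
    src = {m.gene_id: m for m in models_src}
    tgt = {m.gene_id: m for m in models_tgt}
    by_query: dict[str, list[ProteinAlignmentHit]] = {}
    by_subject: dict[str, list[ProteinAlignmentHit]] = {}
    for h in hits:
        if h.identity_pct < min_identity:
            continue
        if h.query_id not in src or h.subject_id not in tgt:
            continue
        if h.subject_coverage_pct >= fragment_coverage_min:
            by_query.setdefault(h.query_id, []).append(h)
        if h.query_coverage_pct >= fragment_coverage_min:
            by_subject.setdefault(h.subject_id, []).append(h)

    def _order_index(models: list[GeneModel]) -> tuple[dict[str, int], list[GeneModel]]:
        positional = sorted(models, key=lambda m: (m.seq_name, m.span.start))
        return {m.gene_id: i for i, m in enumerate(positional)}, positional

    src_order, src_pos = _order_index(models_src)
    tgt_order, tgt_pos = _order_index(models_tgt)

    calls: list[SplitMergeCall] = []

    # split_in_target: one source gene, >=2 adjacent target fragments
    for qid in sorted(by_query):
        hs = sorted(by_query[qid], key=lambda h: h.subject_id)
        if len({h.subject_id for h in hs}) < 2:
            continue
        best_per_subject = {}
        for h in hs:
            cur = best_per_subject.get(h.subject_id)
            if cur is None or h.score > cur.score:
                best_per_subject[h.subject_id] = h
        group = sorted(best_per_subject.values(), key=lambda h: h.subject_id)
        gap = _adjacent_run([h.subject_id for h in group], tgt, tgt_order,
                            tgt_pos, adjacency_bp)
        if gap is None:
            continue
        if not _tile_ok([_one_side_intervals(h, "q") for h in group],
                        fragment_overlap_max):
            continue
        frag_ids = [h.subject_id for h in group]
        calls.append(
            SplitMergeCall(
                pattern="split_in_target",
                source_genes=[qid],
                target_genes=sorted(frag_ids, key=lambda g: tgt[g].span.start),
                adjacency_gap_bp=gap,
                supported_by_junctions=_gap_junction_support(
                    [tgt[g] for g in frag_ids], junction_hints),
                target_hap=target_hap,
            )
        )

    # merged_in_target: >=2 adjacent source genes, one target gene
    for sid in sorted(by_subject):
        hs = by_subject[sid]
        if len({h.query_id for h in hs}) < 2:
            continue
        best_per_query = {}
        for h in hs:
            cur = best_per_query.get(h.query_id)
            if cur is None or h.score > cur.score:
                best_per_query[h.query_id] = h
        group = sorted(best_per_query.values(), key=lambda h: h.query_id)
        gap = _adjacent_run([h.query_id for h in group], src, src_order,
                            src_pos, adjacency_bp)
        if gap is None:
            continue
        if not _tile_ok([_one_side_intervals(h, "s") for h in group],
                        fragment_overlap_max):
            continue
        calls.append(
            SplitMergeCall(
                pattern="merged_in_target",
                source_genes=sorted((h.query_id for h in group),
                                    key=lambda g: src[g].span.start),
                target_genes=[sid],
                adjacency_gap_bp=gap,
                supported_by_junctions=False,
                target_hap=target_hap,
            )
        )
    calls.sort(key=lambda c: (c.pattern, c.source_genes, c.target_genes))
    return calls


def _gap_junction_support(
    fragments: list[GeneModel], hints: set[tuple[str, int, int]] | None
) -> bool:
    """True if a hinted intron spans every inter-fragment gap."""
    if hints is None or len(fragments) < 2:
        return False
    frs = sorted(fragments, key=lambda m: m.span.start)
    for a, b in zip(frs, frs[1:]):
        gs, ge = a.span.end, b.span.start
        if not any(
            seq == a.seq_name and s <= gs and e >= ge for seq, s, e in hints
        ):
            return False
    return True


def repair_split_merge(
    calls: list[SplitMergeCall],
    models_src: list[GeneModel],
    models_tgt: list[GeneModel],
    index: SyntenyIndex,
    target_genome: GenomeSequence,
    junction_hints: set[tuple[str, int, int]] | None = None,
    config: RefinementConfig | None = None,
) -> tuple[list[GeneModel], set[str], list[SplitMergeCall], list[SplitMergeCall]]:
    """Project source models over the erroneous target structures.

    Returns (new target models, retired target gene ids, repaired calls,
    unrepaired calls). Repairs are gated exactly like rescue: intact splice
    sites, intact ORF, hinted junctions. Unrepairable calls keep the original
    models and remain flagged.
    """
    config = config or RefinementConfig()
    src = {m.gene_id: m for m in models_src}
    added: list[GeneModel] = []
    retired: set[str] = set()
    repaired: list[SplitMergeCall] = []
    unrepaired: list[SplitMergeCall] = []
    for call in calls:
        projections: list[tuple[str, ProjectionResult]] = []
        ok = True
        for gid in call.source_genes:
            proj = project_gene_model(
                src[gid], index, target_genome,
                min_fraction=config.min_projection_fraction,
                transcript_id=gid + ".repaired.t1",
            )
            if proj.failed or not proj.splice_sites_intact or not proj.orf_intact \
                    or not _junctions_ok(proj, junction_hints):
                ok = False
                break
            projections.append((gid, proj))
        if not ok:
            unrepaired.append(call)
            continue
        for gid, proj in projections:
            added.append(
                GeneModel(gid + ".repaired", proj.seq_name, proj.strand,
                          [proj.model],
                          source_haplotype=f"repaired_from:{gid}")
            )
        retired.update(call.target_genes)
        repaired.append(call)
    return added, retired, repaired, unrepaired


# ------------------------------------------------------------------ filters


def filter_te_genes(
    models: list[GeneModel], te: TEAnnotation, max_overlap: float = 0.30
) -> tuple[list[GeneModel], list[GeneModel]]:
    """Remove genes whose span is TE-covered for strictly more than
    ``max_overlap`` of its length."""
    kept, removed = [], []
    for m in models:
        span = m.span
        covered = 0
        last_end = span.start
        for iv, _cls in te.on(m.seq_name):
            s = max(iv.start, last_end)
            e = min(iv.end, span.end)
            if e > s:
                covered += e - s
                last_end = e
        frac = covered / len(span) if len(span) else 0.0
        (removed if frac > max_overlap else kept).append(m)
    return kept, removed


def filter_false_positives(
    models: list[GeneModel],
    domains: set[str] | None,
    expression: ExpressionTable | None,
    homology_hits: list[ProteinAlignmentHit] | None,
    config: RefinementConfig | None = None,
) -> tuple[list[GeneModel], list[GeneModel]]:
    """Exclude genes meeting ALL four false-positive criteria: mono-exonic and
    shorter than 300 bp; no identifiable protein domain; zero expression in
    every sample; no cross-haplotype homolog at the 80/80 thresholds. A
    missing evidence table leaves its criterion unmet (gene kept)."""
    config = config or RefinementConfig()
    with_homolog: set[str] = set()
    if homology_hits is not None:
        for h in homology_hits:
            if h.passes_filter(config.min_identity, config.min_coverage):
                with_homolog.add(h.query_id)
                with_homolog.add(h.subject_id)
    kept, removed = [], []
    for m in models:
        tx = representative_transcript(m)
        c1 = tx.is_mono_exonic and tx.length < config.fp_max_len
        c2 = domains is not None and m.gene_id not in domains
        c3 = (
            expression is not None
            and m.gene_id in expression
            and float(expression.row(m.gene_id).sum()) == 0.0
        )
        c4 = homology_hits is not None and m.gene_id not in with_homolog
        (removed if (c1 and c2 and c3 and c4) else kept).append(m)
    return kept, removed


# ------------------------------------------------------------------ driver


def run_refinement(
    inputs: RefinementInputs, config: RefinementConfig | None = None
) -> RefinementResult:
    """Full refinement: align -> cluster -> validate -> rescue -> split/merge
    repair -> TE filter -> false-positive filter, with a reconciling audit."""
    config = config or RefinementConfig()
    audit: list[dict] = []

    def note(stage, hap, gene_id, action, detail=""):
        audit.append({"stage": stage, "haplotype": hap, "gene_id": gene_id,
                      "action": action, "detail": detail})

    for m in inputs.genes_h1:
        note("input", "hap1", m.gene_id, "input")
    for m in inputs.genes_h2:
        note("input", "hap2", m.gene_id, "input")

    index_h1to2 = SyntenyIndex(inputs.blocks, "h1to2")
    index_h2to1 = SyntenyIndex(inputs.blocks, "h2to1")

    # stage 1-2: align and cluster
    pep1 = proteins_for(inputs.genes_h1, inputs.hap1)
    pep2 = proteins_for(inputs.genes_h2, inputs.hap2)
    hits = align_proteins(pep1, pep2, apply_filter=False)
    clusters = cluster_cross_haplotype(
        inputs.genes_h1, inputs.genes_h2, hits,
        config.min_identity, config.min_coverage,
    )
    candidates = candidate_specific_sets(clusters, inputs.genes_h1, inputs.genes_h2)

    # stage 3: validate
    report_before = validate_hapspecific(
        candidates, inputs, index_h1to2, index_h2to1, config
    )

    # stage 4: rescue (candidate unannotated genes, both directions)
    genes_h1 = list(inputs.genes_h1)
    genes_h2 = list(inputs.genes_h2)
    by_id = {m.gene_id: m for m in genes_h1 + genes_h2}
    rescued: dict[str, list[str]] = {"hap1": [], "hap2": []}
    unrescued: dict[str, list[str]] = {"hap1": [], "hap2": []}
    for src_hap, tgt_hap, index, genome, existing, hints in (
        ("hap1", "hap2", index_h1to2, inputs.hap2, genes_h2, inputs.junctions_h2),
        ("hap2", "hap1", index_h2to1, inputs.hap1, genes_h1, inputs.junctions_h1),
    ):
        cands = [by_id[g] for g in sorted(report_before.candidate_unannotated[src_hap])]
        new_models, unresolved = rescue_missing_genes(
            cands, index, genome, existing, hints, config
        )
        for m in new_models:
            note("rescue", tgt_hap, m.gene_id, "added", m.source_haplotype)
            rescued[tgt_hap].append(m.gene_id)
        for gid, reason in unresolved:
            note("rescue", src_hap, gid, "unresolved", reason)
            unrescued[tgt_hap].append(gid)
        if tgt_hap == "hap2":
            genes_h2 = genes_h2 + new_models
        else:
            genes_h1 = genes_h1 + new_models

    # stage 5: split/merge detection and repair (both target directions)
    inverted = [
        ProteinAlignmentHit(
            query_id=h.subject_id, subject_id=h.query_id,
            identity_pct=h.identity_pct,
            query_coverage_pct=h.subject_coverage_pct,
            subject_coverage_pct=h.query_coverage_pct,
            score=h.score,
            q_start=h.s_start, q_end=h.s_end,
            s_start=h.q_start, s_end=h.q_end,
        )
        for h in hits
    ]
    all_calls: list[SplitMergeCall] = []
    repaired_n = 0
    touched: set[str] = set()  # genes already involved in a completed repair
    for src_models, tgt_models, dir_hits, index, genome, hints, tgt_hap in (
        (inputs.genes_h1, inputs.genes_h2, hits, index_h1to2, inputs.hap2,
         inputs.junctions_h2, "hap2"),
        (inputs.genes_h2, inputs.genes_h1, inverted, index_h2to1, inputs.hap1,
         inputs.junctions_h1, "hap1"),
    ):
        calls = detect_split_merge(
            src_models, tgt_models, dir_hits, config.adjacency_bp,
            hints, config.min_identity, config.fragment_overlap_max,
            config.fragment_coverage_min, target_hap=tgt_hap,
        )
        # a repair completed in the other direction makes its mirror call stale
        calls = [
            c for c in calls
            if not touched.intersection(c.source_genes + c.target_genes)
        ]
        all_calls.extend(calls)
        added, retired, repaired, unrepaired = repair_split_merge(
            calls, src_models, tgt_models, index, genome, hints, config
        )
        for c in repaired:
            touched.update(c.source_genes)
            touched.update(c.target_genes)
        repaired_n += len(repaired)
        cur = genes_h2 if tgt_hap == "hap2" else genes_h1
        cur = [m for m in cur if m.gene_id not in retired]
        for gid in sorted(retired):
            note("split_merge", tgt_hap, gid, "removed", "replaced_by_projection")
        for m in added:
            note("split_merge", tgt_hap, m.gene_id, "added", m.source_haplotype)
        cur = cur + added
        for call in unrepaired:
            note("split_merge", tgt_hap, "+".join(call.target_genes),
                 "flagged", f"unrepaired_{call.pattern}")
        if tgt_hap == "hap2":
            genes_h2 = cur
        else:
            genes_h1 = cur

    # stage 6: TE filter
    for hap, te in (("hap1", inputs.te_h1), ("hap2", inputs.te_h2)):
        if te is None:
            continue
        cur = genes_h1 if hap == "hap1" else genes_h2
        kept, removed = filter_te_genes(cur, te, config.te_max_overlap)
        for m in removed:
            note("te_filter", hap, m.gene_id, "removed", "te_overlap>0.30")
        if hap == "hap1":
            genes_h1 = kept
        else:
            genes_h2 = kept

    # stage 7: false-positive filter (uses the original unfiltered hit set)
    for hap, expr in (("hap1", inputs.expr_h1), ("hap2", inputs.expr_h2)):
        cur = genes_h1 if hap == "hap1" else genes_h2
        kept, removed = filter_false_positives(
            cur, inputs.domains, expr, hits, config
        )
        for m in removed:
            note("fp_filter", hap, m.gene_id, "removed", "all_four_criteria")
        if hap == "hap1":
            genes_h1 = kept
        else:
            genes_h2 = kept

    genes_h1.sort(key=lambda g: (g.seq_name, g.span.start, g.gene_id))
    genes_h2.sort(key=lambda g: (g.seq_name, g.span.start, g.gene_id))

    # post-refinement specificity report
    pep1b = proteins_for(genes_h1, inputs.hap1)
    pep2b = proteins_for(genes_h2, inputs.hap2)
    hits_after = align_proteins(pep1b, pep2b, apply_filter=False)
    clusters_after = cluster_cross_haplotype(
        genes_h1, genes_h2, hits_after, config.min_identity, config.min_coverage
    )
    inputs_after = RefinementInputs(
        hap1=inputs.hap1, hap2=inputs.hap2,
        genes_h1=genes_h1, genes_h2=genes_h2,
        variants=inputs.variants, blocks=inputs.blocks,
    )
    report_after = validate_hapspecific(
        candidate_specific_sets(clusters_after, genes_h1, genes_h2),
        inputs_after, index_h1to2, index_h2to1, config,
    )

    return RefinementResult(
        refined_h1=genes_h1,
        refined_h2=genes_h2,
        report_before=report_before,
        report_after=report_after,
        split_merge_calls=all_calls,
        rescued=rescued,
        unrescued=unrescued,
        repaired_calls=repaired_n,
        audit=pd.DataFrame(
            audit, columns=["stage", "haplotype", "gene_id", "action", "detail"]
        ),
    )
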