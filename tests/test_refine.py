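"""Refinement engine: rescue, split/merge repair, filters, and the audit."""

import pytest

from conftest import small_config
from hapgene.align import align_proteins, proteins_for
from hapgene.liftover import SyntenyIndex
from hapgene.models import (
    CdsSegment,
    ExpressionTable,
    GeneModel,
    Interval,
    TEAnnotation,
    TranscriptModel,
)
from hapgene.refine import (
    RefinementInputs,
    detect_split_merge,
    filter_false_positives,
    filter_te_genes,
    rescue_missing_genes,
    run_refinement,
)
from hapgene.sequence import extract_cds_and_translate
from hapgene.simulate import (
    simulate_expression,
    simulate_haplotype_pair,
)


def _inputs_for(sim):
    cfg = sim.config
    e1, e2 = simulate_expression(sim.truth, list(cfg.tissues), cfg)
    return RefinementInputs(
        hap1=sim.hap1, hap2=sim.hap2, genes_h1=sim.genes_h1,
        genes_h2=sim.genes_h2, variants=sim.variants, blocks=sim.blocks,
        te_h1=sim.te, junctions_h2=sim.junctions, expr_h1=e1, expr_h2=e2,
        domains=sim.domains,
    )


class TestBatteryRecovery:
    def test_dropped_genes_rescued_with_peptide_identity(
            self, battery, battery_refined):
        t = battery.truth
        dropped = set(t.with_status("dropped_hap2"))
        rescued_ids = {g for g in battery_refined.rescued["hap2"]}
        recovered = {g[: -len(".rescued")] for g in rescued_ids}
        assert len(recovered & dropped) / len(dropped) >= 0.9
        by_id1 = {g.gene_id: g for g in battery.genes_h1}
        by_id2 = {g.gene_id: g for g in battery_refined.refined_h2}
        for rid in sorted(rescued_ids):
            src = by_id1[rid[: -len(".rescued")]]
            new = by_id2[rid]
            _, p1, _ = extract_cds_and_translate(
                src.transcripts[0], battery.hap1, src.seq_name, src.strand)
            _, p2, _ = extract_cds_and_translate(
                new.transcripts[0], battery.hap2, new.seq_name, new.strand)
            assert p1 == p2

    def test_split_and_merge_events_repaired(self, battery, battery_refined):
        t = battery.truth
        n_events = len(t.with_status("split_hap2")) \
            + len(t.with_status("merged_hap2")) // 2
        assert battery_refined.repaired_calls / n_events >= 0.8

    def test_spurious_removed_without_false_removals(
            self, battery, battery_refined):
        t = battery.truth
        spurious = set(t.genes.index[t.genes["status"] == "spurious"])
        audit = battery_refined.audit
        removed = set(audit[audit["action"] == "removed"]["gene_id"])
        assert len(spurious & removed) / len(spurious) >= 0.9
        # removals beyond spurious are only retired split/merge structures
        sm_targets = {
            g for c in battery_refined.split_merge_calls for g in c.target_genes}
        assert removed - spurious - sm_targets == set()
        intact = set(t.with_status("intact"))
        assert removed & intact == set()

    def test_unannotated_reduced_at_least_threefold(self, battery_refined):
        before = battery_refined.report_before.n_unannotated()
        after = battery_refined.report_after.n_unannotated()
        assert before > 0
        assert after <= before / 3

    def test_validation_matches_truth_partition(self, battery, battery_refined):
        t = battery.truth
        report = battery_refined.report_before
        expected_high = set(
            t.with_status("high_effect_disabled", "hemizygous_deleted"))
        assert report.high_confidence_specific["hap1"] == expected_high
        spurious_h1 = {
            g for g in t.genes.index
            if t.genes.loc[g, "status"] == "spurious" and g.startswith("H1S")}
        expected_un = set(t.with_status("dropped_hap2")) | spurious_h1
        assert report.candidate_unannotated["hap1"] == expected_un

    def test_audit_reconciles_gene_counts(self, battery_refined):
        assert battery_refined.audit_reconciles()


class TestFixedPointAndDeterminism:
    def test_error_free_fixture_is_a_fixed_point(self):
        sim = simulate_haplotype_pair(small_config(
            seed=13, drop_fraction=0, split_fraction=0, merge_fraction=0,
            spurious_fraction=0, hemizygous_fraction=0, high_effect_fraction=0,
        ))
        out = run_refinement(_inputs_for(sim))
        assert [g.gene_id for g in out.refined_h1] == \
            [g.gene_id for g in sim.genes_h1]
        assert [g.gene_id for g in out.refined_h2] == \
            [g.gene_id for g in sim.genes_h2]
        assert out.report_before.n_unannotated() == 0

    def test_two_runs_are_byte_identical(self, tmp_path):
        from hapgene import io as hio

        sim = simulate_haplotype_pair(small_config(seed=17))
        outs = []
        for run in range(2):
            out = run_refinement(_inputs_for(sim))
            p1 = tmp_path / f"h1_{run}.gff3"
            p2 = tmp_path / f"h2_{run}.gff3"
            rep = tmp_path / f"rep_{run}.tsv"
            hio.write_gff3(out.refined_h1, p1)
            hio.write_gff3(out.refined_h2, p2)
            out.report_before.to_frame().to_csv(rep, sep="\t", index=False)
            outs.append((p1.read_bytes(), p2.read_bytes(), rep.read_bytes()))
        assert outs[0] == outs[1]


class TestRescueGates:
    def test_rescue_refused_when_projected_orf_is_broken(self, small_sim):
        t = small_sim.truth
        gid = t.with_status("dropped_hap2")[0]
        gene = next(g for g in small_sim.genes_h1 if g.gene_id == gid)
        index = SyntenyIndex(small_sim.blocks, "h1to2")
        # break the start codon at the projected hap2 locus
        from hapgene.liftover import project_gene_model
        proj = project_gene_model(gene, index, small_sim.hap2)
        tx = proj.model
        cds_start = tx.cds_segments[0].start if proj.strand == "+" \
            else tx.cds_segments[-1].end - 1
        chrom = small_sim.hap2[proj.seq_name]
        broken = chrom[:cds_start] + "C" + chrom[cds_start + 1:]
        from hapgene.models import GenomeSequence
        hap2_broken = GenomeSequence({**small_sim.hap2.records,
                                      proj.seq_name: broken})
        rescued, unresolved = rescue_missing_genes(
            [gene], index, hap2_broken, [], small_sim.junctions)
        assert rescued == []
        assert unresolved == [(gid, "orf_broken")]

    def test_rescue_refused_when_target_locus_occupied(self, small_sim):
        t = small_sim.truth
        gid = t.with_status("dropped_hap2")[0]
        gene = next(g for g in small_sim.genes_h1 if g.gene_id == gid)
        index = SyntenyIndex(small_sim.blocks, "h1to2")
        rescued, _ = rescue_missing_genes(
            [gene], index, small_sim.hap2, [], small_sim.junctions)
        assert len(rescued) == 1
        rescued2, unresolved2 = rescue_missing_genes(
            [gene], index, small_sim.hap2, rescued, small_sim.junctions)
        assert rescued2 == []
        assert unresolved2[0][1] == "target_locus_occupied"

    def test_rescued_models_carry_junction_support(self, small_sim):
        t = small_sim.truth
        index = SyntenyIndex(small_sim.blocks, "h1to2")
        genes = [g for g in small_sim.genes_h1
                 if g.gene_id in t.with_status("dropped_hap2")
                 and len(g.transcripts[0].exons) >= 2]
        rescued, _ = rescue_missing_genes(
            genes, index, small_sim.hap2, [], small_sim.junctions)
        assert rescued  # hinted junctions match, so multi-exon rescues succeed


class TestSplitMergeDetection:
    def test_planted_events_detected_on_fixture(self, small_sim):
        p1 = proteins_for(small_sim.genes_h1, small_sim.hap1)
        p2 = proteins_for(small_sim.genes_h2, small_sim.hap2)
        hits = align_proteins(p1, p2, apply_filter=False)
        calls = detect_split_merge(
            small_sim.genes_h1, small_sim.genes_h2, hits,
            junction_hints=small_sim.junctions)
        t = small_sim.truth
        split_sources = {c.source_genes[0] for c in calls
                         if c.pattern == "split_in_target"}
        assert set(t.with_status("split_hap2")) <= split_sources
        merge_sources = {g for c in calls if c.pattern == "merged_in_target"
                         for g in c.source_genes}
        assert set(t.with_status("merged_hap2")) <= merge_sources
        for c in calls:
            if c.pattern == "split_in_target" and \
                    c.source_genes[0] in set(t.with_status("split_hap2")):
                assert c.supported_by_junctions

    def test_one_to_one_orthologs_produce_no_calls(self):
        sim = simulate_haplotype_pair(small_config(
            seed=23, drop_fraction=0, split_fraction=0, merge_fraction=0,
            spurious_fraction=0, hemizygous_fraction=0, high_effect_fraction=0,
        ))
        p1 = proteins_for(sim.genes_h1, sim.hap1)
        p2 = proteins_for(sim.genes_h2, sim.hap2)
        hits = align_proteins(p1, p2, apply_filter=False)
        assert detect_split_merge(sim.genes_h1, sim.genes_h2, hits) == []


def _mono_gene(gid, start, length, chrom="c"):
    iv = Interval(start, start + length)
    return GeneModel(gid, chrom, "+", [TranscriptModel(
        f"{gid}.t", [iv], [CdsSegment(iv.start, iv.end - (length % 3))])])


class TestTeFilter:
    @pytest.mark.parametrize("frac,removed", [(0.30, False), (0.31, True)])
    def test_threshold_is_strictly_greater_than_30_percent(self, frac, removed):
        gene = _mono_gene("g", 0, 1000)
        te = TEAnnotation({"c": [(Interval(0, int(1000 * frac)), "LTR")]})
        kept, rem = filter_te_genes([gene], te)
        assert (len(rem) == 1) == removed

    def test_no_overlap_kept(self):
        gene = _mono_gene("g", 0, 1000)
        te = TEAnnotation({"c": [(Interval(5000, 6000), "LTR")]})
        kept, rem = filter_te_genes([gene], te)
        assert rem == []

    def test_overlapping_te_intervals_not_double_counted(self):
        gene = _mono_gene("g", 0, 1000)
        te = TEAnnotation({"c": [(Interval(0, 200), "LTR"),
                                 (Interval(100, 290), "TIR")]})
        kept, rem = filter_te_genes([gene], te)  # union = 290 < 301
        assert rem == []


class TestFalsePositiveFilter:
    def _expr(self, gid, values):
        return ExpressionTable([gid], ["t1", "t2"], [values])

    def test_all_four_criteria_removes(self):
        gene = _mono_gene("g", 0, 250)
        kept, rem = filter_false_positives(
            [gene], domains=set(), expression=self._expr("g", [0, 0]),
            homology_hits=[])
        assert [m.gene_id for m in rem] == ["g"]

    def test_length_300_keeps(self):
        gene = _mono_gene("g", 0, 350)
        kept, rem = filter_false_positives(
            [gene], set(), self._expr("g", [0, 0]), [])
        assert rem == []

    def test_any_expression_keeps(self):
        gene = _mono_gene("g", 0, 250)
        kept, rem = filter_false_positives(
            [gene], set(), self._expr("g", [2.0, 0]), [])
        assert rem == []

    def test_domain_keeps(self):
        gene = _mono_gene("g", 0, 250)
        kept, rem = filter_false_positives(
            [gene], {"g"}, self._expr("g", [0, 0]), [])
        assert rem == []

    def test_missing_tables_keep_everything(self):
        gene = _mono_gene("g", 0, 250)
        kept, rem = filter_false_positives([gene], None, None, None)
        assert rem == []

    def test_homolog_keeps(self):
        from hapgene.align import ProteinAlignmentHit

        gene = _mono_gene("g", 0, 250)
        hit = ProteinAlignmentHit("g", "other", 95.0, 100.0, 100.0, 50.0)
        kept, rem = filter_false_positives(
            [gene], set(), self._expr("g", [0, 0]), [hit])
        assert rem == []
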