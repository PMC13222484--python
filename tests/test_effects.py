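"""Variant-effect engine: spec-level examples, brute-force oracle
equivalence, and strand symmetry.

The oracle takes the opposite route from the engine: it rebuilds the entire
mutated chromosome, remaps the transcript's coordinates across the edit,
re-extracts and re-translates the transcript from the mutated genome, and
derives the consequence from the sequence-level differences.
"""

import numpy as np
import pytest

from hapgene.effects import (
    IMPACT_OF,
    call_high_effect_genes,
    classify_variant_effect,
)
from hapgene.models import (
    CdsSegment,
    GeneModel,
    GenomeSequence,
    Interval,
    TranscriptModel,
    Variant,
    representative_transcript,
)
from hapgene.sequence import (
    STOP_CODONS,
    extract_cds_and_translate,
    reverse_complement,
    splice_sites_intact,
)

# ------------------------------------------------------------------ oracle


def _map_coord(c: int, variant: Variant) -> int:
    ds = variant.pos + min(len(variant.ref_allele), len(variant.alt_allele))
    de = variant.pos + len(variant.ref_allele)
    delta = len(variant.alt_allele) - len(variant.ref_allele)
    if c <= ds:
        return c
    if c >= de:
        return c + delta
    return ds  # boundary inside a deletion clamps to its start


def _mutate_genome(chrom: str, variant: Variant) -> str:
    p = variant.pos
    assert chrom[p : p + len(variant.ref_allele)] == variant.ref_allele
    return chrom[:p] + variant.alt_allele + chrom[p + len(variant.ref_allele):]


def oracle_effect(gene: GeneModel, variant: Variant, genome: GenomeSequence) -> str:
    """Brute-force consequence call via full mutated-genome re-extraction."""
    tx = representative_transcript(gene)
    chrom = genome[gene.seq_name]
    span = tx.span
    v_iv = variant.ref_interval
    if v_iv.end <= span.start or v_iv.start >= span.end:
        return "noncoding_region"

    mutated = GenomeSequence({gene.seq_name: _mutate_genome(chrom, variant)})
    new_exons = [
        Interval(_map_coord(e.start, variant), _map_coord(e.end, variant))
        for e in tx.exons
    ]
    new_cds = [
        CdsSegment(_map_coord(c.start, variant), _map_coord(c.end, variant), c.phase)
        for c in tx.cds_segments
        if _map_coord(c.end, variant) - _map_coord(c.start, variant) > 0
    ]
    new_tx = TranscriptModel("o", [e for e in new_exons if len(e) > 0], new_cds)

    candidates = []
    # splice: compare each intron's donor/acceptor dinucleotides
    for old_i, new_i in zip(tx.introns(), new_tx.introns()):
        for side in ("donor", "acceptor"):
            if _site(chrom, old_i, gene.strand, side) != \
                    _site(mutated[gene.seq_name], new_i, gene.strand, side):
                candidates.append(f"splice_{side}_lost")

    old_cds, old_pep_raw, old_flags = extract_cds_and_translate(
        tx, genome, gene.seq_name, gene.strand)
    new_cds_seq, new_pep_raw, new_flags = extract_cds_and_translate(
        new_tx, mutated, gene.seq_name, gene.strand)

    if new_cds_seq != old_cds:
        if old_cds[:3] == "ATG" and new_cds_seq[:3] != "ATG":
            candidates.append("start_lost")
        delta = len(new_cds_seq) - len(old_cds)
        if delta % 3 != 0:
            candidates.append("frameshift")
        else:
            old_stop = _first_stop(old_cds)
            new_stop = _first_stop(new_cds_seq)
            old_premature = old_stop is not None and old_stop < len(old_cds) // 3 - 1
            new_premature = new_stop is not None and new_stop < len(new_cds_seq) // 3 - 1
            if new_premature and not old_premature:
                candidates.append("stop_gained")
            old_term = len(old_cds) >= 3 and old_cds[-3:] in STOP_CODONS
            new_term = len(new_cds_seq) >= 3 and new_cds_seq[-3:] in STOP_CODONS
            if old_term and not new_term and not new_premature:
                candidates.append("stop_lost")
            if delta != 0:
                candidates.append("inframe_indel")
            elif new_pep_raw != old_pep_raw:
                candidates.append("missense")
            else:
                candidates.append("synonymous")
    if not candidates:
        return "noncoding_region"
    order = ["start_lost", "stop_gained", "splice_donor_lost",
             "splice_acceptor_lost", "frameshift", "stop_lost",
             "inframe_indel", "missense", "synonymous"]
    return min(candidates, key=order.index)


def _site(chrom: str, intron: Interval, strand: str, side: str) -> str:
    left = chrom[intron.start : intron.start + 2]
    right = chrom[intron.end - 2 : intron.end]
    if strand == "+":
        return left if side == "donor" else right
    return reverse_complement(right) if side == "donor" else reverse_complement(left)


def _first_stop(cds: str):
    for i in range(len(cds) // 3):
        if cds[3 * i : 3 * i + 3] in STOP_CODONS:
            return i
    return None


# -------------------------------------------------------- random case source


def _random_variant(rng, gene: GeneModel, chrom: str) -> Variant:
    tx = representative_transcript(gene)
    kinds = ["snp_cds", "snp_cds", "snp_cds", "snp_intron", "snp_splice",
             "ins_cds", "del_cds", "ins3_cds", "del3_cds", "snp_start",
             "snp_stop", "snp_outside"]
    introns = tx.introns()
    while True:
        kind = kinds[rng.integers(0, len(kinds))]
        if kind in ("snp_intron", "snp_splice") and not introns:
            continue
        cds_pos = sorted(
            p for seg in tx.cds_segments for p in range(seg.start, seg.end))
        if kind == "snp_outside":
            p = tx.span.end + int(rng.integers(5, 50))
            if p >= len(chrom):
                continue
        elif kind == "snp_start":
            first = cds_pos[:3] if gene.strand == "+" else cds_pos[-3:]
            p = int(first[rng.integers(0, 3)])
        elif kind == "snp_stop":
            last = cds_pos[-3:] if gene.strand == "+" else cds_pos[:3]
            p = int(last[rng.integers(0, 3)])
        elif kind == "snp_intron":
            intron = introns[rng.integers(0, len(introns))]
            if len(intron) < 12:
                continue
            p = int(rng.integers(intron.start + 4, intron.end - 4))
        elif kind == "snp_splice":
            intron = introns[rng.integers(0, len(introns))]
            edge = [intron.start, intron.start + 1, intron.end - 2, intron.end - 1]
            p = int(edge[rng.integers(0, 4)])
        else:
            interior = cds_pos[6:-6]
            if len(interior) < 10:
                continue
            p = int(interior[rng.integers(0, len(interior))])
            seg = next(s for s in tx.cds_segments if s.start <= p < s.end)
            if kind in ("del_cds", "del3_cds"):
                n = 3 if kind == "del3_cds" else int(rng.integers(1, 3))
                if p + 1 + n > seg.end:  # keep the deletion inside one exon
                    continue
                return Variant(gene.seq_name, p, chrom[p : p + 1 + n], chrom[p])
            if kind in ("ins_cds", "ins3_cds"):
                n = 3 if kind == "ins3_cds" else int(rng.integers(1, 3))
                if p + 1 >= seg.end:
                    continue
                payload = "".join("ACGT"[i] for i in rng.integers(0, 4, n))
                return Variant(gene.seq_name, p, chrom[p], chrom[p] + payload)
        ref = chrom[p]
        alt = "ACGT"[rng.integers(0, 4)]
        if alt == ref:
            continue
        return Variant(gene.seq_name, p, ref, alt)


# ------------------------------------------------------------------ tests


def _gene(seq, exons, cds=None, strand="+"):
    cds = cds if cds is not None else [CdsSegment(e.start, e.end) for e in exons]
    return GeneModel("g", "c", strand, [TranscriptModel("t", exons, cds)]), \
        GenomeSequence({"c": seq})


class TestSpecExamples:
    def test_start_loss_snp(self):
        gene, g = _gene("ATGGCCTGA" + "A" * 20, [Interval(0, 9)])
        call = classify_variant_effect(gene, Variant("c", 0, "A", "C"), g)
        assert (call.effect_class, call.impact) == ("start_lost", "HIGH")

    def test_one_bp_insertion_is_frameshift(self):
        gene, g = _gene("ATGGCCAAATGA" + "A" * 20, [Interval(0, 12)])
        call = classify_variant_effect(gene, Variant("c", 4, "C", "CG"), g)
        assert (call.effect_class, call.impact) == ("frameshift", "HIGH")

    def test_donor_gt_to_ga_is_splice_loss(self):
        seq = "ATGGCC" + "GT" + "A" * 20 + "AG" + "AAATGA" + "C" * 10
        gene, g = _gene(seq, [Interval(0, 6), Interval(30, 36)])
        call = classify_variant_effect(gene, Variant("c", 7, "T", "A"), g)
        assert (call.effect_class, call.impact) == ("splice_donor_lost", "HIGH")

    def test_synonymous_snp_low(self):
        gene, g = _gene("ATGGCCTGA" + "A" * 20, [Interval(0, 9)])
        call = classify_variant_effect(gene, Variant("c", 5, "C", "A"), g)
        assert (call.effect_class, call.impact) == ("synonymous", "LOW")

    def test_inframe_deletion_moderate_not_high(self):
        gene, g = _gene("ATGGCCAAATGA" + "A" * 20, [Interval(0, 12)])
        call = classify_variant_effect(gene, Variant("c", 2, "GGCC", "G"), g)
        assert (call.effect_class, call.impact) == ("inframe_indel", "MODERATE")

    def test_outside_gene_is_modifier(self):
        gene, g = _gene("ATGGCCTGA" + "A" * 20, [Interval(0, 9)])
        call = classify_variant_effect(gene, Variant("c", 20, "A", "C"), g)
        assert (call.effect_class, call.impact) == ("noncoding_region", "MODIFIER")

    def test_impact_mapping_is_fixed(self):
        assert {c for c, i in IMPACT_OF.items() if i == "HIGH"} == {
            "start_lost", "stop_gained", "stop_lost", "frameshift",
            "splice_donor_lost", "splice_acceptor_lost"}


class TestOracleEquivalence:
    def test_engine_matches_brute_force_on_random_cases(self, small_sim, rng):
        genes = [g for g in small_sim.genes_h1 if not g.gene_id.startswith("H1S")]
        mismatches = []
        for _ in range(1000):
            gene = genes[rng.integers(0, len(genes))]
            chrom = small_sim.hap1[gene.seq_name]
            v = _random_variant(rng, gene, chrom)
            got = classify_variant_effect(gene, v, small_sim.hap1).effect_class
            want = oracle_effect(gene, v, small_sim.hap1)
            if got != want:
                mismatches.append((gene.gene_id, v, got, want))
        assert mismatches == []

    def test_variant_then_inverse_restores_peptide(self, small_sim, rng):
        genes = [g for g in small_sim.genes_h1 if not g.gene_id.startswith("H1S")]
        for _ in range(50):
            gene = genes[rng.integers(0, len(genes))]
            chrom = small_sim.hap1[gene.seq_name]
            v = _random_variant(rng, gene, chrom)
            mutated = _mutate_genome(chrom, v)
            inverse = Variant(v.seq_name, v.pos, v.alt_allele, v.ref_allele)
            restored = _mutate_genome(mutated, inverse)
            assert restored == chrom


def _flip_variant(v: Variant, chrom: str, rc_chrom: str, L: int) -> Variant:
    """The same genomic event expressed on the reverse-complemented sequence.

    Anchored VCF alleles are not symmetric under naive reverse complement:
    the anchor base sits on the other side of the event after flipping.
    """
    if v.var_class == "SNP":
        return Variant(v.seq_name, L - 1 - v.pos,
                       reverse_complement(v.ref_allele),
                       reverse_complement(v.alt_allele))
    if v.var_class == "INS":
        payload = v.alt_allele[1:]
        a = L - v.pos - 2  # anchor before the flipped insertion point
        return Variant(v.seq_name, a, rc_chrom[a],
                       rc_chrom[a] + reverse_complement(payload))
    r = len(v.ref_allele)
    a = L - v.pos - r - 1
    return Variant(v.seq_name, a, rc_chrom[a : a + r], rc_chrom[a])


class TestStrandSymmetry:
    def test_reverse_complementing_locus_preserves_class(self, small_sim, rng):
        genes = [g for g in small_sim.genes_h1 if not g.gene_id.startswith("H1S")]
        for _ in range(100):
            gene = genes[rng.integers(0, len(genes))]
            chrom = small_sim.hap1[gene.seq_name]
            v = _random_variant(rng, gene, chrom)
            fwd = classify_variant_effect(gene, v, small_sim.hap1).effect_class

            L = len(chrom)
            rc = GenomeSequence({gene.seq_name: reverse_complement(chrom)})
            tx = representative_transcript(gene)
            flip = lambda iv: (L - iv.end, L - iv.start)
            exons = [Interval(*flip(e)) for e in tx.exons]
            cds = [CdsSegment(*flip(c.interval), c.phase) for c in tx.cds_segments]
            gene_rc = GeneModel(
                gene.gene_id, gene.seq_name,
                "-" if gene.strand == "+" else "+",
                [TranscriptModel("t", exons, cds)])
            v_rc = _flip_variant(v, chrom, rc[gene.seq_name], L)
            rev = classify_variant_effect(gene_rc, v_rc, rc).effect_class
            assert rev == fwd, (gene.gene_id, v, fwd, rev)


class TestHighEffectGenes:
    def test_gene_with_only_synonymous_changes_excluded(self):
        gene, g = _gene("ATGGCCTGA" + "A" * 20, [Interval(0, 9)])
        assert call_high_effect_genes([gene], [Variant("c", 5, "C", "A")], g) == set()

    def test_planted_disabled_genes_exactly_recovered(self, small_sim):
        high = call_high_effect_genes(
            small_sim.genes_h1, small_sim.variants, small_sim.hap1)
        assert high == set(small_sim.truth.with_status("high_effect_disabled"))

    def test_empty_inputs_empty_set(self, small_sim):
        assert call_high_effect_genes([], [], small_sim.hap1) == set()
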