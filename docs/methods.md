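# Methods

## Problem setting

A phased diploid assembly carries two near-identical copies of every locus.
When each haplotype is annotated independently, the two annotations disagree
in ways the genomes do not: a gene called on one haplotype is missed on the
other, one true gene is split into fragments, two neighbouring genes are
fused, and low-evidence models (TE fragments, random ORFs) survive on one
side only. Naive cross-haplotype comparison then reports these artifacts as
"haplotype-specific" genes. The package separates genuine allelic absence
(hemizygous deletion, function-disrupting variants, unaligned sequence) from
annotation error, and corrects the errors using the other haplotype as a
template.

## Refinement procedure

The engine runs a fixed stage order on the two preliminary annotations:

1. **Protein alignment.** Representative peptides (longest transcript per
   gene, ties broken by transcript id) are aligned all-vs-all across
   haplotypes with exact local dynamic programming (BLOSUM62, gap open −11,
   extend −1). Candidate pairs are pre-screened by shared 5-mer counts
   (≥3 shared 5-mers), which at the scale this package targets retains every
   true homolog pair while skipping the quadratic bulk. Identity is matches
   over aligned columns; coverage is the aligned span over sequence length,
   kept per side.
2. **Clustering.** Hits at ≥80% identity and ≥80% coverage (the larger of
   the two sides, so a fragment fully contained in its counterpart passes)
   form a graph; connected components are gene clusters. Single-haplotype
   clusters are candidate haplotype-specific genes.
3. **Validation.** Each candidate is labelled by the first satisfied
   criterion: (i) a HIGH-impact variant on its representative transcript;
   (ii) a structural variant (≥50 bp) deleting the whole gene or ≥50% of its
   coding length, inserting ≥50 bp into coding sequence, or inverting coding
   bases; (iii) residence (majority of the gene span) in an unaligned region.
   Candidates with none of these are *candidate unannotated* genes —
   presumed annotation errors.
4. **Rescue.** Each candidate unannotated gene is projected through the
   synteny blocks onto the other haplotype. The projection is accepted only
   if every exon maps contiguously (≥50% of exonic length overall), all
   projected introns are canonical GT..AG, the projected CDS is a complete
   ORF (ATG start, terminal stop, no internal stop, length divisible by 3),
   the target locus carries no existing gene model, and — when splice
   junction hints are supplied — every projected intron matches a hinted
   junction. Rejected candidates are reported with the failing gate, never
   dropped silently.
5. **Split/merge repair.** A split is called when one source protein aligns
   (identity ≥80%) to two or more target genes that are consecutive on one
   sequence within 10 kb with no intervening gene, whose hit intervals tile
   near-disjoint (<20% mutual overlap) parts of the source, and which are
   themselves mostly (≥50%) covered by their hits — the last condition
   excludes short spurious local matches. A merge is the symmetric pattern.
   Repair replaces the erroneous structures with projections of the correct
   source models, gated exactly like rescue. Once a structure is repaired,
   its mirror-image call in the opposite direction is stale and skipped.
6. **TE filter.** Genes whose span is TE-covered for strictly more than 30%
   are removed (union of TE intervals; 30% exactly is kept).
7. **False-positive filter.** A gene is removed only if it meets all four
   criteria simultaneously: mono-exonic and shorter than 300 bp; no
   identifiable protein domain; zero expression in every sample; no
   cross-haplotype homolog at the 80/80 thresholds. A missing evidence table
   leaves its criterion unmet, so genes are kept by default.

Every gene added or removed is written to an audit log;
`genes_in + added − removed = genes_out` reconciles exactly per haplotype.

## Variant-effect model

Effects are computed on the representative transcript by rebuilding the
mutated CDS in transcript space and comparing translations. The class is the
most severe applicable one, in the order start_lost > stop_gained > splice
(donor/acceptor) > frameshift > stop_lost > inframe_indel > missense >
synonymous; splice calls fire when a variant alters the first or last two
intron bases in transcription order. Indels with a non-multiple-of-3 coding
length change are frameshifts regardless of downstream stops; in-frame
changes are examined for premature or lost stops. The mapping to impact
levels is fixed (start/stop/frameshift/splice → HIGH, inframe/missense →
MODERATE, synonymous → LOW, non-coding → MODIFIER). Gene-level HIGH calls
consider only small variants (<50 bp); structural events are the province of
the SV-evidence path, so a whole-gene deletion is reported as SV evidence
rather than as a cascade of coding effects. Variants are applied
independently; compound (phased multi-variant) effects are out of scope.

Leading CDS phase (GFF3 column 8) is honoured during translation, so
fragment models annotated mid-codon translate in frame — without this, split
fragments would produce out-of-frame peptides and split detection would be
blind to half of each event.

## Liftover model

Synteny blocks are treated as gap-free (length-matched) piecewise-linear
maps; inverted blocks reverse coordinates and flip strand. Where block
footprints overlap on the source side, collinear classes take precedence
(SYN > INV > TRANS > DUP), which makes duplications map through their
primary copy. Unaligned (NOTAL) blocks carry coordinates on exactly one side
and contribute nothing to mapping; the mapped fraction of an interval
decreases monotonically as NOTAL coverage grows.

For genes annotated on the second haplotype, SV evidence is read on the
query side: coding bases falling in query-side coverage gaps (sequence
present only in that haplotype) count as deleted-counterpart evidence, and
HIGH-variant evidence is obtained by projecting the gene onto haplotype 1
and classifying the variants that overlap the projection — a HIGH call
there means the two alleles differ disruptively at the locus.

## Allelic expression model

For each bi-allelic pair and tissue, the TPM pair is normalised to
proportions and assigned to the nearest ideal vector: Balanced (0.5, 0.5),
H1_dominant (1, 0), H2_dominant (0, 1), by Euclidean distance, with exact
ties resolved to Balanced. Pairs with summed TPM below 0.5 are NE (not
expressed) before any distance comparison. The implied decision boundary is
a 0.75 proportion for dominance — the midpoint between the Balanced and
dominant vectors; users who need a different boundary can supply their own
vectors. Bi-allelic pairs require shared cluster membership plus lifted
positional overlap; among multiple candidates the greatest overlap wins
(ties: alignment score, then id), and remaining genes are mono-allelic.

Tissue specificity uses the TAU index, τ = Σ(1 − x_i/x_max)/(n − 1), which
is 0 for uniform and 1 for single-tissue expression and is invariant to
uniform scaling. The tissue-specific flag uses the ratio of highest to
second-highest TPM, strictly greater than 3; a variant using the lowest
tissue as reference is available via `ratio_to="lowest"` because both
definitions circulate in the literature and they disagree on broad shallow
profiles.

lincRNA positional classification rejects transcripts under 200 bp and
requires zero overlap with any protein-coding gene span (strand-agnostic);
TE association requires strictly more than 50% of the span covered by TE
intervals, with the dominant class taken by covered bp.

## Synthetic fixtures

The generator builds haplotype 1 from scratch: intergenic background with
planted genes (1–6 fully coding exons, ATG start, GT..AG introns, terminal
stop, proteins of 80–400 aa), then derives haplotype 2 by applying an
explicit edit script — SNPs and 1–3 bp indels in intergenic space and
intron interiors (≥10 bp from splice sites), plus structural events
(DEL/INS/INV/DUP/TRANS, ≥50 bp) and unaligned segments placed between
genes. Because haplotype 2 is constructed from the script, the emitted VCF
plus the inversion blocks reconstruct it byte-exactly, and synteny emitted
at indel resolution (each block gap-free) makes liftover exact. Defaults
are 500 genes on 2 × 2.5 Mb chromosomes, SNPs at 5/kb and indels at 1/kb of
eligible sequence — heterozygosity of the magnitude seen in outbred woody
plant genomes — with 5% of genes dropped from the second haplotype's
annotation, 3% split, 2% merged, 2% hemizygous-deleted, 3% disabled by a
single planted HIGH variant (uniform over start-loss, stop-gain, frameshift,
splice-loss), and 5% spurious mono-exonic models per haplotype at disjoint
intergenic loci.

Merged-gene errors are planted as readthrough fusions: the transcription-
first gene's stop codon is excluded from the fused CDS, as a gene predictor
would do, so the fusion encodes one continuous ORF. Split fragments keep
their original CDS phases, so the downstream fragment is annotated
mid-codon. A domain list (all real genes, no spurious models) emulates a
protein-domain scan; expression tables realize planted per-tissue allelic
categories (dominant alleles drawn at an 0.925 share, dispersion 0.02 on the
share; NE genes at zero TPM) with one-third of expressed genes given a
divergent category in one tissue.

What the generator does not emulate — and what green tests therefore do not
certify on real data: sequencing and assembly error, TE sequence content
(intervals only), alternative isoforms (one transcript per gene), genes
inside inversions or unaligned regions (exercised by constructed unit
fixtures instead, since the truth-status vocabulary has no entry for them),
UTRs, overlapping genes, and realistic expression count noise. The TE track
is intergenic by construction so that the TE filter's behaviour on real
gene-TE overlap is tested by constructed cases, not the battery.

## Numerical and design choices

- Internal coordinates are 0-based half-open everywhere; GFF3/VCF/synteny
  files are 1-based inclusive at the boundary, BED is 0-based half-open.
- Sequences are uppercase-normalized on read; N is allowed and never matches.
- All randomness flows from a single seed through named per-stage
  substreams, so every output is byte-reproducible.
- Writers emit records in deterministic (sequence, start, id) order.
- The 80/80 coverage rule uses max(query, subject) for one-to-one screening;
  per-side coverages drive split/merge logic.
- "Adjacent" for split/merge means: same sequence, ≤10 kb gap, no
  intervening annotated gene.
- Thresholds are deliberately strict or exclusive exactly as documented:
  TE-gene removal at >30%, lincRNA TE association at >50%, tissue
  specificity at ratio >3, coding-majority deletion at ≥50%, hit retention
  at ≥80/≥80.
- Coding overlap for SV evidence uses the union of the representative
  transcript's CDS segments ("partial coding regions" reads as CDS, not
  gene span).
- A premature stop anywhere in the peptide is HIGH; there is no attenuation
  near the C-terminus.
- Problem sizes in tests: most properties run on a 60-gene, 2 × 400 kb
  fixture; recovery rates and determinism run on the 500-gene battery. The
  1000-case oracle comparison samples variants over all fixture genes.

## Known limitations

- Block-linear liftover assumes length-matched blocks; output from real
  whole-genome aligners with internal alignment gaps would need block
  splitting (as the fixture generator does) or base-level alignment.
- The k-mer prescreen can miss homolog pairs below ~60% identity; the 80%
  retention threshold makes this irrelevant for clustering, but exhaustive
  sub-threshold hit lists are not produced.
- Read-coverage evidence for split/merge decisions is not consumed;
  junction hints alone gate repairs when provided.
- Polyploid (>2 haplotype) generalization is out of scope; all pairings are
  hap1/hap2.
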