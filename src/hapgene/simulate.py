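"""Synthetic diploid fixtures with planted truth.

The generator builds a first haplotype with fully specified gene structures
(ATG start, GT..AG introns, stop codon), derives the second haplotype by
applying an explicit edit script (SNPs, small indels, structural events), and
emits annotations carrying planted errors (dropped, split, merged and spurious
models) together with a truth table. Because hap2 is constructed *from* the
edit script, the emitted VCF + rearrangement blocks reconstruct it exactly,
and every downstream stage can be scored against known truth.

Coordinate bookkeeping: small variants are placed only in intergenic space and
intron interiors, and structural events only between genes, so that genes with
truth status ``intact`` are copied to hap2 without any coding change. Synteny
is emitted at indel resolution (each collinear block is gap-free), which makes
piecewise-linear liftover exact.
"""

from __future__ import annotations

import dataclasses
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .models import (
    CdsSegment,
    ExpressionTable,
    GeneModel,
    GenomeSequence,
    Interval,
    InvariantError,
    SyntenyBlock,
    TEAnnotation,
    TranscriptModel,
    Variant,
)
from .sequence import STOP_CODONS, reverse_complement

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "SimulationResult",
    "simulate_haplotype_pair",
    "simulate_expression",
    "reconstruct_haplotype",
    "write_fixture_dir",
]

NT = np.array(list("ACGT"))

_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]

EXPRESSION_CATEGORIES = ("Balanced", "H1_dominant", "H2_dominant", "NE")

STATUSES = (
    "intact",
    "dropped_hap2",
    "split_hap2",
    "merged_hap2",
    "hemizygous_deleted",
    "high_effect_disabled",
    "spurious",
)

HIGH_VARIANT_KINDS = ("start_lost", "stop_gained", "frameshift", "splice_lost")

DEFAULT_TISSUES = ("pistil", "stamen", "stem", "leaf", "epicarp", "juice_sac", "seed")


@dataclass
class SimulationConfig:
    """All knobs of the simulator; the defaults are the standard fixture
    battery used throughout the test-suite and the acceptance analyses."""

    seed: int = 0
    n_chrom: int = 2
    chrom_len: int = 2_500_000
    n_genes: int = 500
    snp_rate: float = 0.005       # per eligible bp (intergenic + intron interior)
    indel_rate: float = 0.001     # per eligible bp, 1-3 bp events
    sv_events: list[tuple[str, int]] = field(
        default_factory=lambda: [
            ("DEL", 2000), ("DEL", 3000), ("DEL", 1500),
            ("INS", 1500), ("INS", 2500), ("INS", 1000),
            ("INV", 20_000), ("INV", 8000),
            ("DUP", 3000), ("DUP", 2000),
            ("TRANS", 4000), ("TRANS", 2500),
        ]
    )
    n_notal: int = 2              # unaligned segments per side (ref / qry)
    notal_len: int = 5000
    drop_fraction: float = 0.05
    split_fraction: float = 0.03
    merge_fraction: float = 0.02
    spurious_fraction: float = 0.05
    hemizygous_fraction: float = 0.02
    high_effect_fraction: float = 0.03
    te_density: float = 0.25
    # expression settings
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    dispersion: float = 0.02
    divergent_fraction: float = 0.33
    category_probs: tuple[float, float, float, float] = (0.62, 0.14, 0.14, 0.10)
    dominant_share: float = 0.925
    expression_floor: float = 0.5

    def __post_init__(self) -> None:
        for name in ("snp_rate", "indel_rate"):
            r = getattr(self, name)
            if not 0 <= r <= 1:
                raise InvariantError(f"{name} must be in [0, 1]")
        fracs = (
            self.drop_fraction + self.split_fraction + self.merge_fraction
            + self.hemizygous_fraction + self.high_effect_fraction
        )
        if fracs > 1:
            raise InvariantError("planted-error fractions sum > 1")
        for cls, length in self.sv_events:
            if cls not in ("DEL", "INS", "INV", "DUP", "TRANS"):
                raise InvariantError(f"unknown SV class {cls!r}")
            if length >= self.chrom_len:
                raise InvariantError(f"SV of {length} bp exceeds chromosome length")
        if abs(sum(self.category_probs) - 1) > 1e-9:
            raise InvariantError("category_probs must sum to 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sv_events" in raw:
            raw["sv_events"] = [tuple(e) for e in raw["sv_events"]]
        if "tissues" in raw:
            raw["tissues"] = tuple(raw["tissues"])
        if "category_probs" in raw:
            raw["category_probs"] = tuple(raw["category_probs"])
        return cls(**raw)


@dataclass
class TruthTable:
    """Planted truth: one status per simulated gene plus the planted allelic
    expression category for every tissue."""

    genes: pd.DataFrame       # index: gene_id (hap1 ids; spurious per hap)
    categories: pd.DataFrame  # index: gene_id, columns: tissues

    def status_of(self, gene_id: str) -> str:
        return str(self.genes.loc[gene_id, "status"])

    def with_status(self, *statuses: str) -> list[str]:
        mask = self.genes["status"].isin(statuses)
        return list(self.genes.index[mask])

    def category_of(self, gene_id: str, tissue: str) -> str:
        return str(self.categories.loc[gene_id, tissue])

    def to_tsv(self, path: str | Path) -> None:
        merged = self.genes.join(self.categories.add_prefix("cat_"), how="left")
        merged.index.name = "gene_id"
        merged.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TruthTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        cat_cols = [c for c in df.columns if c.startswith("cat_")]
        cats = df[cat_cols].rename(columns=lambda c: c[4:])
        return cls(genes=df.drop(columns=cat_cols), categories=cats)


@dataclass
class SimulationResult:
    config: SimulationConfig
    hap1: GenomeSequence
    hap2: GenomeSequence
    genes_h1: list[GeneModel]
    genes_h2: list[GeneModel]
    variants: list[Variant]
    blocks: list[SyntenyBlock]
    te: TEAnnotation
    truth: TruthTable
    junctions: set[tuple[str, int, int]]  # hap2 intron coordinates (0-based)
    domains: set[str] = field(default_factory=set)  # gene ids with protein domains


# ----------------------------------------------------------------- gene design


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(NT[rng.integers(0, 4, n)])


def _design_gene(rng: np.random.Generator) -> tuple[str, list[Interval], list[int]]:
    """Return (local sequence on '+', exon intervals, transcription-order
    phases). Exons are fully coding: ATG .. stop with GT..AG introns."""
    protein_len = int(rng.integers(80, 401))
    cds = "ATG" + "".join(rng.choice(_CODONS, protein_len)) + \
        ("TAA", "TAG", "TGA")[rng.integers(0, 3)]
    n_exons = int(rng.integers(1, 7))
    max_exons = max(1, len(cds) // 60)
    n_exons = min(n_exons, max_exons)
    cuts: list[int] = []
    if n_exons > 1:
        for _ in range(20):  # require >=30 bp between cuts
            cand = sorted(
                int(c) for c in
                rng.choice(np.arange(30, len(cds) - 30), n_exons - 1, replace=False)
            )
            if all(b - a >= 30 for a, b in zip(cand, cand[1:])):
                cuts = cand
                break
    pieces, prev = [], 0
    for c in list(cuts) + [len(cds)]:
        pieces.append(cds[prev:int(c)])
        prev = int(c)
    parts: list[str] = []
    exons: list[Interval] = []
    pos = 0
    for i, piece in enumerate(pieces):
        exons.append(Interval(pos, pos + len(piece)))
        parts.append(piece)
        pos += len(piece)
        if i < len(pieces) - 1:
            intron = "GT" + _random_seq(rng, int(rng.integers(56, 497))) + "AG"
            parts.append(intron)
            pos += len(intron)
    phases, cum = [], 0
    for piece in pieces:
        phases.append((3 - cum % 3) % 3)
        cum += len(piece)
    return "".join(parts), exons, phases


def _make_gene_model(
    gene_id: str, seq_name: str, strand: str, offset: int,
    local_len: int, exons: list[Interval], phases: list[int],
) -> GeneModel:
    if strand == "+":
        g_exons = [Interval(offset + e.start, offset + e.end) for e in exons]
        g_phases = phases
    else:
        g_exons = [
            Interval(offset + local_len - e.end, offset + local_len - e.start)
            for e in reversed(exons)
        ]
        g_phases = list(reversed(phases))
    cds = [CdsSegment(e.start, e.end, p) for e, p in zip(g_exons, g_phases)]
    tx = TranscriptModel(transcript_id=gene_id + ".t1", exons=g_exons, cds_segments=cds)
    return GeneModel(gene_id=gene_id, seq_name=seq_name, strand=strand,
                     transcripts=[tx], source_haplotype="hap1")


# ----------------------------------------------------------------- edit script


@dataclass(frozen=True, order=True)
class _Edit:
    start: int
    end: int        # == start for insertions
    kind: str       # 'del' | 'ins' | 'inv'
    payload: str = ""
    label: str = ""


def _apply_edit_script(
    seq: str, snps: list[tuple[int, str]], shifts: list[_Edit]
) -> tuple[str, list[tuple[int, int, int, str]], dict[str, tuple[int, int]]]:
    """Apply SNPs then coordinate-shifting edits.

    Returns (derived sequence, collinear map segments as
    (ref_start, ref_end, qry_start, orient), labelled qry intervals).
    """
    buf = bytearray(seq, "ascii")
    for pos, alt in snps:
        buf[pos] = ord(alt)
    snp_seq = buf.decode("ascii")

    shifts = sorted(shifts)
    prev_end = 0
    for e in shifts:
        if e.start < prev_end:
            raise InvariantError(f"overlapping edits at {e.start}")
        prev_end = max(prev_end, e.end)

    pieces: list[str] = []
    segments: list[tuple[int, int, int, str]] = []
    labels: dict[str, tuple[int, int]] = {}
    cur = q = 0
    for e in shifts:
        if e.start > cur:
            pieces.append(snp_seq[cur : e.start])
            segments.append((cur, e.start, q, "+"))
            q += e.start - cur
        if e.kind == "del":
            pass
        elif e.kind == "ins":
            pieces.append(e.payload)
            if e.label:
                labels[e.label] = (q, q + len(e.payload))
            q += len(e.payload)
        elif e.kind == "inv":
            pieces.append(reverse_complement(snp_seq[e.start : e.end]))
            segments.append((e.start, e.end, q, "-"))
            q += e.end - e.start
        else:  # pragma: no cover
            raise InvariantError(f"unknown edit kind {e.kind!r}")
        cur = e.end
    if cur < len(snp_seq):
        pieces.append(snp_seq[cur:])
        segments.append((cur, len(snp_seq), q, "+"))
    return "".join(pieces), segments, labels


class _CoordMap:
    """Exact hap1 -> hap2 coordinate map from collinear segments."""

    def __init__(self, segments: list[tuple[int, int, int, str]]):
        self.segments = sorted(segments)
        self._starts = [s[0] for s in self.segments]

    def map_point(self, pos: int) -> int | None:
        i = bisect_right(self._starts, pos) - 1
        if i < 0:
            return None
        s, e, q, orient = self.segments[i]
        if not s <= pos < e:
            return None
        return q + (pos - s) if orient == "+" else q + (e - 1 - pos)

    def map_interval(self, iv: Interval) -> Interval | None:
        """Exact mapping; requires both ends in the same forward segment."""
        a = self.map_point(iv.start)
        b = self.map_point(iv.end - 1)
        if a is None or b is None or b - a != len(iv) - 1:
            return None
        return Interval(a, b + 1)


# ----------------------------------------------------------------- simulator


class _Blocked:
    """Per-chromosome record of intervals no further edit may touch."""

    def __init__(self) -> None:
        self.intervals: list[tuple[int, int]] = []

    def add(self, start: int, end: int) -> None:
        self.intervals.append((start, end))

    def clashes(self, start: int, end: int, margin: int = 10) -> bool:
        return any(
            start < e + margin and s - margin < end for s, e in self.intervals
        )


def simulate_haplotype_pair(config: SimulationConfig) -> SimulationResult:
    """Generate a diploid fixture with planted truth (deterministic in seed)."""
    root = np.random.SeedSequence(config.seed)
    rngs = {
        name: np.random.default_rng(ss)
        for name, ss in zip(
            ("genes", "status", "variants", "sv", "te", "expr"), root.spawn(6)
        )
    }

    chrom_names = [f"chr{i + 1}" for i in range(config.n_chrom)]
    per_chrom = [
        config.n_genes // config.n_chrom
        + (1 if i < config.n_genes % config.n_chrom else 0)
        for i in range(config.n_chrom)
    ]

    hap1_seqs: dict[str, str] = {}
    genes_h1: list[GeneModel] = []
    gaps: dict[str, list[tuple[int, int]]] = {}
    rng = rngs["genes"]
    gene_no = 0
    for chrom, n in zip(chrom_names, per_chrom):
        pieces: list[str] = []
        chrom_gaps: list[tuple[int, int]] = []
        cursor = 0
        for _ in range(n):
            gap = int(rng.integers(2500, 6000))
            pieces.append(_random_seq(rng, gap))
            chrom_gaps.append((cursor, cursor + gap))
            cursor += gap
            gene_no += 1
            gid = f"H1G{gene_no:05d}"
            strand = "+" if rng.random() < 0.5 else "-"
            local, exons, phases = _design_gene(rng)
            pieces.append(local if strand == "+" else reverse_complement(local))
            genes_h1.append(
                _make_gene_model(gid, chrom, strand, cursor, len(local), exons, phases)
            )
            cursor += len(local)
        tail = max(3000, config.chrom_len - cursor)
        pieces.append(_random_seq(rng, tail))
        chrom_gaps.append((cursor, cursor + tail))
        hap1_seqs[chrom] = "".join(pieces)
        gaps[chrom] = chrom_gaps

    genes_by_id = {g.gene_id: g for g in genes_h1}

    # ---- truth statuses
    rng = rngs["status"]
    order = [g.gene_id for g in genes_h1]
    rng.shuffle(order)
    status: dict[str, str] = {gid: "intact" for gid in order}
    counterpart_of: dict[str, str] = {}

    n_merge_pairs = round(config.merge_fraction * config.n_genes / 2)
    merged_pairs: list[tuple[str, str]] = []
    by_pos = sorted(genes_h1, key=lambda g: (g.seq_name, g.span.start))
    for a, b in zip(by_pos, by_pos[1:]):
        if len(merged_pairs) >= n_merge_pairs:
            break
        if (
            a.seq_name == b.seq_name
            and a.strand == b.strand
            and status[a.gene_id] == "intact"
            and status[b.gene_id] == "intact"
        ):
            status[a.gene_id] = status[b.gene_id] = "merged_hap2"
            merged_pairs.append((a.gene_id, b.gene_id))

    def _take(n: int, want: str, pred=lambda g: True) -> list[str]:
        out = []
        for gid in order:
            if len(out) >= n:
                break
            if status[gid] == "intact" and pred(genes_by_id[gid]):
                status[gid] = want
                out.append(gid)
        return out

    split_ids = _take(
        round(config.split_fraction * config.n_genes), "split_hap2",
        lambda g: len(g.transcripts[0].exons) >= 2,
    )
    drop_ids = _take(round(config.drop_fraction * config.n_genes), "dropped_hap2")
    hemi_ids = _take(round(config.hemizygous_fraction * config.n_genes),
                     "hemizygous_deleted")
    high_ids = _take(round(config.high_effect_fraction * config.n_genes),
                     "high_effect_disabled")

    # ---- edit script
    # blocked records footprints of gene-directed and structural edits so the
    # background-variant sampler cannot collide with them; exon positions are
    # excluded from eligibility directly and need no blocking.
    blocked: dict[str, _Blocked] = {c: _Blocked() for c in chrom_names}

    snps: dict[str, list[tuple[int, str]]] = {c: [] for c in chrom_names}
    shifts: dict[str, list[_Edit]] = {c: [] for c in chrom_names}
    variants: list[Variant] = []
    high_kind: dict[str, str] = {}

    rng = rngs["sv"]

    def _register_variant(chrom: str, v: Variant) -> None:
        variants.append(v)
        if v.var_class == "SNP":
            snps[chrom].append((v.pos, v.alt_allele))
        elif v.var_class == "DEL":
            shifts[chrom].append(
                _Edit(v.pos + len(v.alt_allele), v.pos + len(v.ref_allele), "del")
            )
        else:
            shifts[chrom].append(
                _Edit(v.pos + 1, v.pos + 1, "ins", v.alt_allele[1:])
            )

    # hemizygous deletions: whole gene span + margin
    for gid in hemi_ids:
        g = genes_by_id[gid]
        s, e = g.span.start - 150, g.span.end + 150
        chrom_seq = hap1_seqs[g.seq_name]
        v = Variant(g.seq_name, s - 1, chrom_seq[s - 1 : e], chrom_seq[s - 1])
        _register_variant(g.seq_name, v)
        blocked[g.seq_name].add(s - 1, e)

    # one HIGH variant per disabled gene
    for gid in high_ids:
        g = genes_by_id[gid]
        kind = _plant_high_variant(rng, g, hap1_seqs[g.seq_name],
                                   lambda v, c=g.seq_name: _register_variant(c, v))
        high_kind[gid] = kind

    # intergenic structural events and unaligned (NOTAL) segments
    sv_records: list[tuple[str, str, int, int, str]] = []  # class, chrom, s, e, label
    # gaps between merged-pair genes stay empty so pair adjacency is preserved
    merge_gap_ends = {
        (genes_by_id[b].seq_name, genes_by_id[b].span.start)
        for _, b in merged_pairs
    }
    free_gaps = {
        c: [
            gv for gv in gaps[c]
            if gv[1] - gv[0] >= 1200 and (c, gv[1]) not in merge_gap_ends
        ]
        for c in chrom_names
    }
    notal_events = [("NOTAL_REF", config.notal_len)] * config.n_notal + [
        ("NOTAL_QRY", config.notal_len)
    ] * config.n_notal
    label_no = 0
    for cls, length in list(config.sv_events) + notal_events:
        placed = False
        chroms = list(chrom_names)
        rng.shuffle(chroms)
        need = 420 if cls in ("INS", "NOTAL_QRY") else length + 420
        for chrom in chroms:
            cands = [gv for gv in free_gaps[chrom] if gv[1] - gv[0] >= need]
            if not cands:
                continue
            gs, ge = cands[int(rng.integers(0, len(cands)))]
            free_gaps[chrom].remove((gs, ge))
            s = gs + 200
            label_no += 1
            label = f"L{label_no}"
            chrom_seq = hap1_seqs[chrom]
            if cls in ("DEL", "NOTAL_REF"):
                e = s + length
                v = Variant(chrom, s - 1, chrom_seq[s - 1 : e], chrom_seq[s - 1])
                _register_variant(chrom, v)
                sv_records.append((cls, chrom, s, e, label))
                blocked[chrom].add(s - 1, e)
            elif cls in ("INS", "NOTAL_QRY"):
                payload = _random_seq(rng, length)
                variants.append(Variant(chrom, s - 1, chrom_seq[s - 1],
                                        chrom_seq[s - 1] + payload))
                shifts[chrom].append(_Edit(s, s, "ins", payload, label))
                sv_records.append((cls, chrom, s, s, label))
                blocked[chrom].add(s - 1, s + 1)
            elif cls == "INV":
                e = s + length
                shifts[chrom].append(_Edit(s, e, "inv"))
                sv_records.append((cls, chrom, s, e, label))
                blocked[chrom].add(s, e)
            elif cls == "DUP":
                e = s + length
                payload = chrom_seq[s:e]
                variants.append(Variant(chrom, e - 1, chrom_seq[e - 1],
                                        chrom_seq[e - 1] + payload))
                shifts[chrom].append(_Edit(e, e, "ins", payload, label))
                sv_records.append((cls, chrom, s, e, label))
                blocked[chrom].add(s, e + 1)
            elif cls == "TRANS":
                e = s + length
                payload = chrom_seq[s:e]
                v = Variant(chrom, s - 1, chrom_seq[s - 1 : e], chrom_seq[s - 1])
                _register_variant(chrom, v)
                blocked[chrom].add(s - 1, e)
                # destination: another free gap
                dest = [gv for gv in free_gaps[chrom] if gv[1] - gv[0] >= 420]
                if not dest:
                    raise InvariantError("no free gap for TRANS destination")
                ds, de = dest[int(rng.integers(0, len(dest)))]
                free_gaps[chrom].remove((ds, de))
                dp = ds + 200
                variants.append(Variant(chrom, dp - 1, chrom_seq[dp - 1],
                                        chrom_seq[dp - 1] + payload))
                shifts[chrom].append(_Edit(dp, dp, "ins", payload, label))
                sv_records.append((cls, chrom, s, e, label))
                blocked[chrom].add(dp - 1, dp + 1)
            placed = True
            break
        if not placed:
            raise InvariantError(f"no intergenic gap can host a {cls} of {length} bp")

    # ---- allocate spurious-model loci now (hap1 coordinates) so that the
    # background sampler leaves them variant-free, like real exons
    rng_sp = rngs["status"]
    n_spur = round(config.spurious_fraction * config.n_genes)
    planned_spurious: list[tuple[str, str, int, int]] = []  # hap, chrom, s, len
    for hap in ("hap1", "hap2"):
        made = 0
        attempts = 0
        while made < n_spur and attempts < 20 * n_spur:
            attempts += 1
            chrom = chrom_names[int(rng_sp.integers(0, len(chrom_names)))]
            pool = free_gaps[chrom]
            if not pool:
                continue
            gs, ge = pool.pop(int(rng_sp.integers(0, len(pool))))
            if ge - gs < 1200:
                continue
            length = int(rng_sp.integers(150, 291))
            s = gs + 300
            planned_spurious.append((hap, chrom, s, length))
            blocked[chrom].add(s, s + length)
            made += 1
        if made < n_spur:
            raise InvariantError("could not place all spurious models")

    # background small variants: intergenic + intron interiors
    rng = rngs["variants"]
    for chrom in chrom_names:
        eligible: list[tuple[int, int]] = []
        for gs, ge in gaps[chrom]:
            if ge - gs > 100:
                eligible.append((gs + 50, ge - 50))
        for g in genes_h1:
            if g.seq_name != chrom or status[g.gene_id] == "hemizygous_deleted":
                continue
            for intron in g.transcripts[0].introns():
                if len(intron) > 24:
                    eligible.append((intron.start + 10, intron.end - 10))
        eligible.sort()
        total = sum(e - s for s, e in eligible)
        n_snp = rng.binomial(total, config.snp_rate)
        n_indel = rng.binomial(total, config.indel_rate)
        positions = _sample_positions(rng, eligible, n_snp + n_indel)
        kinds = np.array(["snp"] * n_snp + ["indel"] * n_indel)
        rng.shuffle(kinds)
        chrom_seq = hap1_seqs[chrom]
        last = -100
        for pos, kind in zip(positions, kinds):
            pos = int(pos)
            if pos - last < 10 or blocked[chrom].clashes(pos - 5, pos + 5):
                continue
            last = pos
            if kind == "snp":
                ref = chrom_seq[pos]
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                _register_variant(chrom, Variant(chrom, pos, ref, alt))
            else:
                n = int(rng.integers(1, 4))
                if rng.random() < 0.5:
                    _register_variant(chrom, Variant(
                        chrom, pos, chrom_seq[pos : pos + 1 + n], chrom_seq[pos]))
                else:
                    _register_variant(chrom, Variant(
                        chrom, pos, chrom_seq[pos],
                        chrom_seq[pos] + _random_seq(rng, n)))

    # ---- derive hap2 and coordinate maps
    hap2_seqs: dict[str, str] = {}
    maps: dict[str, _CoordMap] = {}
    blocks: list[SyntenyBlock] = []
    labels_all: dict[str, dict[str, tuple[int, int]]] = {}
    for chrom in chrom_names:
        seq2, segments, labels = _apply_edit_script(
            hap1_seqs[chrom], snps[chrom], shifts[chrom]
        )
        hap2_seqs[chrom] = seq2
        maps[chrom] = _CoordMap(segments)
        labels_all[chrom] = labels
        for s, e, q, orient in segments:
            blocks.append(
                SyntenyBlock(
                    ref_seq=chrom, ref_start=s, ref_end=e,
                    qry_seq=chrom, qry_start=q, qry_end=q + (e - s),
                    block_class="SYN" if orient == "+" else "INV",
                    orientation="same" if orient == "+" else "inverted",
                )
            )
    for cls, chrom, s, e, label in sv_records:
        q = labels_all[chrom].get(label)
        if cls in ("DUP", "TRANS"):
            blocks.append(SyntenyBlock(chrom, s, e, chrom, q[0], q[1], cls))
        elif cls == "NOTAL_REF":
            blocks.append(SyntenyBlock(chrom, s, e, "", -1, -1, "NOTAL"))
        elif cls == "NOTAL_QRY":
            blocks.append(SyntenyBlock("", -1, -1, chrom, q[0], q[1], "NOTAL"))

    hap1 = GenomeSequence(hap1_seqs, haplotype_label="hap1")
    hap2 = GenomeSequence(hap2_seqs, haplotype_label="hap2")

    # ---- hap2 annotation with planted errors
    genes_h2: list[GeneModel] = []
    junctions: set[tuple[str, int, int]] = set()

    def _map_transcript(g: GeneModel) -> TranscriptModel | None:
        tx = g.transcripts[0]
        exons, cds = [], []
        for e, c in zip(tx.exons, tx.cds_segments):
            m = maps[g.seq_name].map_interval(e)
            if m is None:
                return None
            exons.append(m)
            cds.append(CdsSegment(m.start, m.end, c.phase))
        return TranscriptModel(tx.transcript_id.replace("H1", "H2"),
                               exons, cds)

    for g in genes_h1:
        st = status[g.gene_id]
        if st in ("dropped_hap2", "hemizygous_deleted", "high_effect_disabled"):
            continue
        tx2 = _map_transcript(g)
        if tx2 is None:  # should not happen: genes avoid shifting edits
            raise InvariantError(f"gene {g.gene_id} failed exact mapping")
        h2_id = g.gene_id.replace("H1", "H2")
        for intron in tx2.introns():
            junctions.add((g.seq_name, intron.start, intron.end))
        if st == "split_hap2":
            k = len(tx2.exons) // 2
            for part, tag in ((slice(0, k), "a"), (slice(k, None), "b")):
                exs = tx2.exons[part]
                cds = [CdsSegment(e.start, e.end, c.phase)
                       for e, c in zip(exs, tx2.cds_segments[part])]
                frag_tx = TranscriptModel(f"{h2_id}{tag}.t1", list(exs), cds)
                genes_h2.append(GeneModel(f"{h2_id}{tag}", g.seq_name, g.strand,
                                          [frag_tx], "hap2"))
            counterpart_of[g.gene_id] = f"{h2_id}a,{h2_id}b"
        elif st == "merged_hap2":
            pass  # handled pairwise below
        else:
            genes_h2.append(GeneModel(h2_id, g.seq_name, g.strand, [tx2], "hap2"))
            counterpart_of[g.gene_id] = h2_id

    for a_id, b_id in merged_pairs:
        a, b = genes_by_id[a_id], genes_by_id[b_id]
        ta, tb = _map_transcript(a), _map_transcript(b)
        fused_id = a_id.replace("H1", "H2") + "m"
        exons = sorted(list(ta.exons) + list(tb.exons))
        cds_a = [CdsSegment(c.start, c.end, c.phase) for c in ta.cds_segments]
        cds_b = [CdsSegment(c.start, c.end, c.phase) for c in tb.cds_segments]
        # a readthrough fusion: drop the stop codon of the transcription-first
        # gene so the fused model encodes one continuous (erroneous) ORF
        if a.strand == "+":
            last = cds_a[-1]
            cds_a[-1] = CdsSegment(last.start, last.end - 3, last.phase)
        else:
            first = cds_b[0]
            cds_b[0] = CdsSegment(first.start + 3, first.end, first.phase)
        fused_tx = TranscriptModel(fused_id + ".t1", exons, sorted(cds_a + cds_b))
        genes_h2.append(GeneModel(fused_id, a.seq_name, a.strand, [fused_tx], "hap2"))
        counterpart_of[a_id] = fused_id
        counterpart_of[b_id] = fused_id

    # true hap2 junctions also exist for dropped genes (transcript evidence)
    for gid in drop_ids + high_ids:
        g = genes_by_id[gid]
        tx2 = _map_transcript(g)
        if tx2 is not None:
            for intron in tx2.introns():
                junctions.add((g.seq_name, intron.start, intron.end))

    # ---- materialize the spurious models planned earlier (disjoint
    # intergenic loci per haplotype, variant-free, TE-free)
    spurious_rows = []
    counters = {"hap1": 0, "hap2": 0}
    for hap, chrom, s, length in planned_spurious:
        if hap == "hap2":
            m = maps[chrom].map_interval(Interval(s, s + length))
            if m is None:  # cannot happen: locus was blocked before sampling
                raise InvariantError("spurious locus failed exact mapping")
            s, length = m.start, len(m)
        counters[hap] += 1
        sid = f"{'H1S' if hap == 'hap1' else 'H2S'}{counters[hap]:04d}"
        iv = Interval(s, s + length)
        tx = TranscriptModel(
            sid + ".t1", [iv], [CdsSegment(s, s + length - length % 3)]
        )
        model = GeneModel(sid, chrom, "+", [tx], hap)
        (genes_h1 if hap == "hap1" else genes_h2).append(model)
        spurious_rows.append((sid, hap, chrom, s, s + length))

    genes_h1.sort(key=lambda g: (g.seq_name, g.span.start, g.gene_id))
    genes_h2.sort(key=lambda g: (g.seq_name, g.span.start, g.gene_id))

    # ---- TE track: tiles the intergenic gaps left over after SV/spurious
    # placement (hap1 coordinates), up to the configured genome fraction
    rng = rngs["te"]
    te_intervals: dict[str, list[tuple[Interval, str]]] = {c: [] for c in chrom_names}
    te_classes = np.array(["LTR", "TIR", "Helitron", "other"])
    te_probs = np.array([0.5, 0.25, 0.15, 0.10])
    for chrom in chrom_names:
        target = config.te_density * len(hap1_seqs[chrom])
        covered = 0
        cands = sorted(free_gaps[chrom])
        rng.shuffle(cands)
        for gs, ge in cands:
            t = gs + 200
            while covered < target and t + 500 <= ge - 200:
                width = min(int(rng.integers(500, 4000)), ge - 200 - t)
                te_intervals[chrom].append(
                    (Interval(t, t + width), str(rng.choice(te_classes, p=te_probs)))
                )
                covered += width
                t += width + 150
            if covered >= target:
                break
    te = TEAnnotation(intervals=te_intervals)

    # ---- truth table
    rows = []
    for g in sorted(genes_by_id.values(), key=lambda g: g.gene_id):
        rows.append({
            "gene_id": g.gene_id, "haplotype": "hap1",
            "status": status[g.gene_id],
            "seq_name": g.seq_name, "start": g.span.start, "end": g.span.end,
            "counterpart_id": counterpart_of.get(g.gene_id, ""),
            "high_variant": high_kind.get(g.gene_id, ""),
        })
    for sid, hap, chrom, s, e in spurious_rows:
        rows.append({"gene_id": sid, "haplotype": hap, "status": "spurious",
                     "seq_name": chrom, "start": s, "end": e,
                     "counterpart_id": "", "high_variant": ""})
    genes_df = pd.DataFrame(rows).set_index("gene_id")

    cats = _plant_categories(rngs["expr"], genes_df, config)
    truth = TruthTable(genes=genes_df, categories=cats)

    variants.sort(key=lambda v: (v.seq_name, v.pos, v.ref_allele, v.alt_allele))
    blocks.sort(key=lambda b: (b.ref_seq, b.ref_start, b.qry_seq, b.qry_start))
    # emulated domain annotation: real gene products carry identifiable
    # domains, random spurious ORFs do not
    domains = {
        g.gene_id for g in genes_h1 + genes_h2
        if not g.gene_id.startswith(("H1S", "H2S"))
    }
    return SimulationResult(
        config=config, hap1=hap1, hap2=hap2,
        genes_h1=genes_h1, genes_h2=genes_h2,
        variants=variants, blocks=blocks, te=te, truth=truth,
        junctions=junctions, domains=domains,
    )


def _sample_positions(
    rng: np.random.Generator, eligible: list[tuple[int, int]], n: int
) -> np.ndarray:
    """Sample ~n distinct positions uniformly from the eligible intervals."""
    if not eligible or n == 0:
        return np.array([], dtype=int)
    lens = np.array([e - s for s, e in eligible])
    starts = np.array([s for s, _ in eligible])
    cum = np.concatenate([[0], np.cumsum(lens)])
    draws = rng.integers(0, cum[-1], n)
    idx = np.searchsorted(cum, draws, side="right") - 1
    pos = starts[idx] + (draws - cum[idx])
    return np.unique(pos)


def _plant_high_variant(
    rng: np.random.Generator, gene: GeneModel, chrom_seq: str, register
) -> str:
    """Plant exactly one function-disrupting variant in a gene; returns kind."""
    tx = gene.transcripts[0]
    kinds = list(HIGH_VARIANT_KINDS)
    if tx.is_mono_exonic:
        kinds.remove("splice_lost")
    kind = str(rng.choice(kinds))
    chrom = gene.seq_name
    cds_genomic = _cds_positions(tx, gene.strand)

    if kind == "start_lost":
        # mutate the genomic base of the start codon's first position (the 'A')
        p = cds_genomic[0]
        ref = chrom_seq[p]
        alt = "C" if ref != "C" else "G"
        register(Variant(chrom, p, ref, alt))
    elif kind == "stop_gained":
        n_codons = len(cds_genomic) // 3
        found = False
        idx = list(range(int(n_codons * 0.2), int(n_codons * 0.8)))
        rng.shuffle(idx)
        for ci in idx:
            pos3 = cds_genomic[3 * ci : 3 * ci + 3]
            codon = _tx_bases(chrom_seq, pos3, gene.strand)
            for off in range(3):
                for b in "ACGT":
                    cand = codon[:off] + b + codon[off + 1 :]
                    if cand in STOP_CODONS and cand != codon:
                        p = pos3[off]
                        ref = chrom_seq[p]
                        alt = b if gene.strand == "+" else reverse_complement(b)
                        register(Variant(chrom, p, ref, alt))
                        found = True
                        break
                if found:
                    break
            if found:
                break
        if not found:  # pragma: no cover - virtually impossible
            raise InvariantError("no stop-gain site found")
    elif kind == "frameshift":
        n = len(cds_genomic)
        p = int(cds_genomic[int(rng.integers(n // 4, 3 * n // 4))])
        register(Variant(chrom, p - 1, chrom_seq[p - 1 : p + 1], chrom_seq[p - 1]))
    else:  # splice_lost: kill a donor's second base (transcription order)
        introns = tx.introns()
        intron = introns[int(rng.integers(0, len(introns)))]
        if gene.strand == "+":
            p = intron.start + 1          # the 'T' of GT
        else:
            p = intron.end - 2            # complement of the 'T'
        ref = chrom_seq[p]
        alt = "C" if ref != "C" else "A"
        register(Variant(chrom, p, ref, alt))
    return kind


def _cds_positions(tx: TranscriptModel, strand: str) -> list[int]:
    """Genomic positions of CDS bases in transcription order."""
    pos = [p for seg in tx.cds_segments for p in range(seg.start, seg.end)]
    return pos if strand == "+" else pos[::-1]


def _tx_bases(chrom_seq: str, positions: list[int], strand: str) -> str:
    bases = "".join(chrom_seq[p] for p in positions)
    if strand == "-":
        bases = "".join(reverse_complement(b) for b in bases)
    return bases


# ----------------------------------------------------------------- expression


def _plant_categories(
    rng: np.random.Generator, genes_df: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    tissues = list(config.tissues)
    cats: dict[str, list[str]] = {}
    for gid, row in genes_df.iterrows():
        if row["status"] == "spurious":
            cats[gid] = ["NE"] * len(tissues)
            continue
        if row["status"] in ("hemizygous_deleted", "high_effect_disabled"):
            base = "H1_dominant"
        else:
            base = str(rng.choice(EXPRESSION_CATEGORIES, p=config.category_probs))
        per = [base] * len(tissues)
        if base != "NE" and rng.random() < config.divergent_fraction:
            t = int(rng.integers(0, len(tissues)))
            others = [c for c in ("Balanced", "H1_dominant", "H2_dominant")
                      if c != base]
            per[t] = str(rng.choice(others))
        cats[gid] = per
    return pd.DataFrame.from_dict(cats, orient="index", columns=tissues)


def simulate_expression(
    truth: TruthTable, tissues: list[str], config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionTable, ExpressionTable]:
    """Draw per-haplotype TPM tables realizing the planted categories.

    ``H1_dominant`` draws give the hap1 allele a share of at least ~0.85 of
    the pair total, ``Balanced`` a share near 0.5, and ``NE`` zero TPM, so at
    low dispersion the planted category is the nearest ideal vector.
    """
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed).spawn(7)[-1]
        )
    known = set(EXPRESSION_CATEGORIES)
    h1_ids, h2_ids = [], []
    h1_rows, h2_rows = [], []
    for gid, row in truth.genes.iterrows():
        cats = truth.categories.loc[gid, tissues]
        bad = set(cats) - known
        if bad:
            raise InvariantError(f"unknown expression category {sorted(bad)!r}")
        tot = max(2.0, float(rng.lognormal(3.0, 0.8)))
        vals1, vals2 = [], []
        for cat in cats:
            if cat == "NE":
                vals1.append(0.0)
                vals2.append(0.0)
                continue
            share = {"Balanced": 0.5, "H1_dominant": config.dominant_share,
                     "H2_dominant": 1 - config.dominant_share}[cat]
            share = float(np.clip(share + rng.normal(0, config.dispersion),
                                  0.01, 0.99))
            vals1.append(tot * share)
            vals2.append(tot * (1 - share))
        hap = row["haplotype"]
        counterpart = row["counterpart_id"]
        if hap == "hap1":
            h1_ids.append(gid)
            h1_rows.append(vals1)
            if counterpart and "," not in counterpart and not counterpart.endswith("m"):
                h2_ids.append(counterpart)
                h2_rows.append(vals2)
        else:  # hap2 spurious
            h2_ids.append(gid)
            h2_rows.append(vals2)
    expr1 = ExpressionTable(h1_ids, list(tissues), np.array(h1_rows))
    expr2 = ExpressionTable(h2_ids, list(tissues), np.array(h2_rows))
    return expr1, expr2


# ----------------------------------------------------------------- reconstruct


def reconstruct_haplotype(
    hap1: GenomeSequence, variants: list[Variant], blocks: list[SyntenyBlock]
) -> GenomeSequence:
    """Re-derive hap2 from the emitted edit script (VCF variants plus the
    inversion blocks, which the Variant vocabulary cannot express)."""
    out: dict[str, str] = {}
    for chrom, seq in hap1.records.items():
        snps: list[tuple[int, str]] = []
        shifts: list[_Edit] = []
        for v in variants:
            if v.seq_name != chrom:
                continue
            if v.var_class == "SNP":
                snps.append((v.pos, v.alt_allele))
            elif v.var_class == "DEL":
                shifts.append(_Edit(v.pos + len(v.alt_allele),
                                    v.pos + len(v.ref_allele), "del"))
            else:
                shifts.append(_Edit(v.pos + 1, v.pos + 1, "ins", v.alt_allele[1:]))
        for b in blocks:
            if b.block_class == "INV" and b.ref_seq == chrom:
                shifts.append(_Edit(b.ref_start, b.ref_end, "inv"))
        seq2, _, _ = _apply_edit_script(seq, snps, shifts)
        out[chrom] = seq2
    return GenomeSequence(out, haplotype_label="hap2(reconstructed)")


# ----------------------------------------------------------------- fixture dir


def write_fixture_dir(result: SimulationResult, out_dir: str | Path) -> None:
    """Write the full fixture as the pipeline's on-disk input formats."""
    from . import io as hio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hio.write_fasta(result.hap1, out / "hap1.fa")
    hio.write_fasta(result.hap2, out / "hap2.fa")
    hio.write_gff3(result.genes_h1, out / "hap1.gff3")
    hio.write_gff3(result.genes_h2, out / "hap2.gff3")
    hio.write_variants(result.variants, out / "variants.vcf")
    hio.write_synteny(result.blocks, out / "synteny.tsv")
    hio.write_te_bed(result.te, out / "te.bed")
    expr1, expr2 = simulate_expression(
        result.truth, list(result.config.tissues), result.config
    )
    hio.write_expression(expr1, out / "expr_hap1.tsv")
    hio.write_expression(expr2, out / "expr_hap2.tsv")
    result.truth.to_tsv(out / "truth.tsv")
    with open(out / "domains.tsv", "w") as fh:
        fh.write("gene_id\n")
        for gid in sorted(result.domains):
            fh.write(gid + "\n")
    with open(out / "junctions.tsv", "w") as fh:
        fh.write("seq_name\tstart\tend\n")
        for chrom, s, e in sorted(result.junctions):
            fh.write(f"{chrom}\t{s + 1}\t{e}\n")
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(result.config), fh)
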