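"""Readers and writers for the standard formats the pipeline touches.

External files use the conventions of the tools they emulate: GFF3, VCF and
synteny tables are 1-based inclusive, BED is 0-based half-open. Everything is
converted to internal 0-based half-open coordinates on read and back on write.
Writers emit records in a deterministic order (sequence, start, id) so that
identical inputs always produce byte-identical files.
"""

from __future__ import annotations

import logging
from pathlib import Path

import gffutils
import pandas as pd

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

log = logging.getLogger("hapgene")

__all__ = [
    "GffParseError",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_variants",
    "write_variants",
    "read_synteny",
    "write_synteny",
    "read_te_bed",
    "write_te_bed",
    "read_expression",
    "write_expression",
]


class GffParseError(ValueError):
    """Structured GFF3 parse failure, naming the offending feature/line."""


# ---------------------------------------------------------------- FASTA


def read_fasta(path: str | Path, haplotype_label: str = "") -> GenomeSequence:
    from Bio import SeqIO

    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise InvariantError(f"duplicate sequence name {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq)
    return GenomeSequence(records=records, haplotype_label=haplotype_label)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in genome.records:
            fh.write(f">{name}\n")
            seq = genome.records[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------- GFF3


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS features into :class:`GeneModel` objects.

    The result is independent of input line order; the feature hierarchy is
    reconstructed from ID/Parent attributes.
    """
    path = str(path)
    _prevalidate_gff(path)
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    known_ids = {f.id for f in db.all_features()}
    for feat in db.all_features():
        for parent in feat.attributes.get("Parent", []):
            if parent not in known_ids:
                raise GffParseError(
                    f"feature {feat.id or feat.featuretype!r} references "
                    f"unknown Parent {parent!r}"
                )

    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        transcripts = []
        for t in db.children(g, featuretype=("mRNA", "transcript"), order_by="start"):
            exons = [
                Interval(e.start - 1, e.end)
                for e in db.children(t, featuretype="exon", order_by="start")
            ]
            cds = [
                CdsSegment(c.start - 1, c.end, int(c.frame) if c.frame != "." else 0)
                for c in db.children(t, featuretype="CDS", order_by="start")
            ]
            if not exons:
                raise GffParseError(f"transcript {t.id!r} has no exons")
            try:
                transcripts.append(
                    TranscriptModel(transcript_id=t.id, exons=exons, cds_segments=cds)
                )
            except InvariantError as exc:
                raise GffParseError(str(exc)) from exc
        if not transcripts:
            raise GffParseError(f"gene {g.id!r} has no transcripts")
        genes.append(
            GeneModel(
                gene_id=g.id,
                seq_name=g.seqid,
                strand=g.strand,
                transcripts=sorted(transcripts, key=lambda t: t.transcript_id),
            )
        )
    genes.sort(key=lambda g: (g.seq_name, g.span.start, g.gene_id))
    return genes


def _prevalidate_gff(path: str) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise GffParseError(f"{path}:{lineno}: fewer than 9 columns")
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError:
                raise GffParseError(f"{path}:{lineno}: non-numeric coordinates")
            if end < start:
                raise GffParseError(f"{path}:{lineno}: end < start")


def write_gff3(models: list[GeneModel], path: str | Path, source: str = "hapgene") -> None:
    ids = [g.gene_id for g in models]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise InvariantError(f"duplicate gene ids: {sorted(dupes)}")
    lines = ["##gff-version 3"]
    for g in sorted(models, key=lambda m: (m.seq_name, m.span.start, m.gene_id)):
        gs = g.span
        lines.append(
            _gff_line(g.seq_name, source, "gene", gs, g.strand, ".", f"ID={g.gene_id}")
        )
        for t in g.transcripts:
            ts = t.span
            lines.append(
                _gff_line(
                    g.seq_name, source, "mRNA", ts, g.strand, ".",
                    f"ID={t.transcript_id};Parent={g.gene_id}",
                )
            )
            for i, ex in enumerate(t.exons, 1):
                lines.append(
                    _gff_line(
                        g.seq_name, source, "exon", ex, g.strand, ".",
                        f"ID={t.transcript_id}.exon{i};Parent={t.transcript_id}",
                    )
                )
            for i, c in enumerate(t.cds_segments, 1):
                lines.append(
                    _gff_line(
                        g.seq_name, source, "CDS", c.interval, g.strand, str(c.phase),
                        f"ID={t.transcript_id}.cds{i};Parent={t.transcript_id}",
                    )
                )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _gff_line(seq, source, ftype, iv, strand, phase, attrs) -> str:
    return "\t".join(
        [seq, source, ftype, str(iv.start + 1), str(iv.end), ".", strand, phase, attrs]
    )


# ---------------------------------------------------------------- VCF


def read_variants(path: str | Path) -> list[Variant]:
    """Read a minimal VCF (CHROM POS ID REF ALT). Multi-allelic records are
    split; symbolic/breakend alleles are skipped with a logged count."""
    variants: list[Variant] = []
    skipped = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, pos, _id, ref, alts = parts[0], int(parts[1]), parts[2], parts[3], parts[4]
            for alt in alts.split(","):
                if alt.startswith("<") or "[" in alt or "]" in alt or alt in (".", "*"):
                    skipped += 1
                    continue
                if len(ref) == len(alt) and len(ref) > 1:
                    skipped += 1  # MNP/complex substitution: unsupported
                    continue
                variants.append(
                    Variant(seq_name=chrom, pos=pos - 1, ref_allele=ref.upper(),
                            alt_allele=alt.upper())
                )
    if skipped:
        log.info("read_variants: skipped %d unsupported allele(s)", skipped)
    return variants


def write_variants(variants: list[Variant], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=hapgene\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: (v.seq_name, v.pos, v.ref_allele, v.alt_allele)):
            fh.write(
                f"{v.seq_name}\t{v.pos + 1}\t.\t{v.ref_allele}\t{v.alt_allele}"
                f"\t.\tPASS\t.\n"
            )


# ---------------------------------------------------------------- synteny


_SYNTENY_COLS = ["ref_seq", "ref_start", "ref_end", "qry_seq", "qry_start", "qry_end", "class"]


def read_synteny(path: str | Path) -> list[SyntenyBlock]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_SYNTENY_COLS) - set(df.columns)
    if missing:
        raise InvariantError(f"synteny table missing columns {sorted(missing)}")
    blocks: list[SyntenyBlock] = []
    for row in df.itertuples(index=False):
        cls = row[df.columns.get_loc("class")]
        rec = dict(zip(df.columns, row))
        ref_side = rec["ref_seq"] != "-"
        qry_side = rec["qry_seq"] != "-"
        blocks.append(
            SyntenyBlock(
                ref_seq=rec["ref_seq"] if ref_side else "",
                ref_start=int(rec["ref_start"]) - 1 if ref_side else -1,
                ref_end=int(rec["ref_end"]) if ref_side else -1,
                qry_seq=rec["qry_seq"] if qry_side else "",
                qry_start=int(rec["qry_start"]) - 1 if qry_side else -1,
                qry_end=int(rec["qry_end"]) if qry_side else -1,
                block_class=cls,
                orientation="inverted" if cls == "INV" else "same",
            )
        )
    return blocks


def write_synteny(blocks: list[SyntenyBlock], path: str | Path) -> None:
    rows = []
    for b in blocks:
        rows.append(
            {
                "ref_seq": b.ref_seq or "-",
                "ref_start": b.ref_start + 1 if b.ref_start >= 0 else "-",
                "ref_end": b.ref_end if b.ref_end >= 0 else "-",
                "qry_seq": b.qry_seq or "-",
                "qry_start": b.qry_start + 1 if b.qry_start >= 0 else "-",
                "qry_end": b.qry_end if b.qry_end >= 0 else "-",
                "class": b.block_class,
            }
        )
    df = pd.DataFrame(rows, columns=_SYNTENY_COLS)
    df = df.sort_values(
        ["ref_seq", "ref_start", "qry_seq", "qry_start"], kind="mergesort"
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- TE BED


def read_te_bed(path: str | Path) -> TEAnnotation:
    intervals: dict[str, list[tuple[Interval, str]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            cls = parts[3] if len(parts) > 3 else "other"
            intervals.setdefault(chrom, []).append((Interval(start, end), cls))
    return TEAnnotation(intervals=intervals)


def write_te_bed(te: TEAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(te.intervals):
            for iv, cls in sorted(te.intervals[chrom]):
                fh.write(f"{chrom}\t{iv.start}\t{iv.end}\t{cls}\n")


# ---------------------------------------------------------------- misc tables


def read_gene_list(path: str | Path) -> set[str]:
    """One gene id per line (optional ``gene_id`` header)."""
    out: set[str] = set()
    with open(path) as fh:
        for line in fh:
            tok = line.strip()
            if tok and tok != "gene_id":
                out.add(tok.split("\t")[0])
    return out


def read_junctions(path: str | Path) -> set[tuple[str, int, int]]:
    """Splice-junction hints: TSV of 1-based inclusive intron coordinates."""
    out: set[tuple[str, int, int]] = set()
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts[0] or parts[0] == "seq_name":
                continue
            out.add((parts[0], int(parts[1]) - 1, int(parts[2])))
    return out


# ---------------------------------------------------------------- expression


def read_expression(path: str | Path) -> ExpressionTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionTable(
        genes=list(df.index), tissues=list(df.columns), tpm=df.to_numpy(float)
    )


def write_expression(table: ExpressionTable, path: str | Path) -> None:
    df = pd.DataFrame(table.tpm, index=table.genes, columns=table.tissues)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.4f")
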