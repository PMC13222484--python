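"""Domain types shared across the pipeline.

All coordinates are stored 0-based half-open internally; the readers and
writers in :mod:`hapgene.io` convert from/to the 1-based inclusive convention
of GFF3/VCF/SyRI-style files at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "GenomeSequence",
    "Interval",
    "CdsSegment",
    "TranscriptModel",
    "GeneModel",
    "Variant",
    "SyntenyBlock",
    "ExpressionTable",
    "TEAnnotation",
    "InvariantError",
    "representative_transcript",
]

IUPAC_NT = set("ACGTNRYSWKMBDHV")

TE_CLASSES = ("LTR", "TIR", "Helitron", "other")

SYNTENY_CLASSES = ("SYN", "INV", "TRANS", "DUP", "NOTAL")


class InvariantError(ValueError):
    """A domain-type invariant was violated."""


@dataclass
class GenomeSequence:
    """A haplotype assembly: mapping of sequence name to nucleotide string.

    Sequences are uppercase-normalized on construction; ``N`` is allowed and
    treated as a mismatch everywhere downstream.
    """

    records: dict[str, str]
    haplotype_label: str = ""

    def __post_init__(self) -> None:
        norm: dict[str, str] = {}
        for name, seq in self.records.items():
            if len(seq) < 1:
                raise InvariantError(f"sequence {name!r} is empty")
            s = seq.upper()
            bad = set(s) - IUPAC_NT
            if bad:
                raise InvariantError(
                    f"sequence {name!r} contains non-IUPAC characters {sorted(bad)!r}"
                )
            norm[name] = s
        self.records = norm

    def __getitem__(self, name: str) -> str:
        return self.records[name]

    def __contains__(self, name: str) -> bool:
        return name in self.records

    def length(self, name: str) -> int:
        return len(self.records[name])


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open interval."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise InvariantError(f"bad interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "Interval") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "Interval") -> bool:
        return self.start <= other.start and other.end <= self.end


@dataclass(frozen=True, order=True)
class CdsSegment:
    start: int
    end: int
    phase: int = 0

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise InvariantError(f"bad CDS segment [{self.start}, {self.end})")
        if self.phase not in (0, 1, 2):
            raise InvariantError(f"bad phase {self.phase}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> Interval:
        return Interval(self.start, self.end)


@dataclass
class TranscriptModel:
    transcript_id: str
    exons: list[Interval]
    cds_segments: list[CdsSegment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds_segments = sorted(self.cds_segments)
        prev_end = -1
        for ex in self.exons:
            if ex.start < prev_end:
                raise InvariantError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )
            prev_end = ex.end
        for seg in self.cds_segments:
            if not any(
                ex.start <= seg.start and seg.end <= ex.end for ex in self.exons
            ):
                raise InvariantError(
                    f"transcript {self.transcript_id}: CDS segment "
                    f"[{seg.start}, {seg.end}) outside all exons"
                )
        if self.cds_segments and self.cds_length < 3:
            raise InvariantError(
                f"transcript {self.transcript_id}: coding length < 3"
            )

    @property
    def span(self) -> Interval:
        return Interval(self.exons[0].start, self.exons[-1].end)

    @property
    def is_mono_exonic(self) -> bool:
        return len(self.exons) == 1

    @property
    def cds_length(self) -> int:
        return sum(len(s) for s in self.cds_segments)

    @property
    def length(self) -> int:
        """Spliced transcript length (sum of exon lengths)."""
        return sum(len(e) for e in self.exons)

    def introns(self) -> list[Interval]:
        return [
            Interval(a.end, b.start)
            for a, b in zip(self.exons, self.exons[1:])
        ]


@dataclass
class GeneModel:
    gene_id: str
    seq_name: str
    strand: str
    transcripts: list[TranscriptModel]
    source_haplotype: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise InvariantError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if not self.transcripts:
            raise InvariantError(f"gene {self.gene_id}: no transcripts")

    @property
    def span(self) -> Interval:
        return Interval(
            min(t.span.start for t in self.transcripts),
            max(t.span.end for t in self.transcripts),
        )


def representative_transcript(gene: GeneModel) -> TranscriptModel:
    """Longest transcript (by spliced length); ties broken by transcript_id.

    The representative is used for all protein-level and gene-level decisions.
    """
    return max(gene.transcripts, key=lambda t: (t.length, _neg_id(t.transcript_id)))


class _neg_id(str):
    # orders lexicographically *smaller* ids as larger, so max() prefers them
    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


@dataclass(frozen=True)
class Variant:
    """SNP or indel between haplotypes; ``pos`` is 0-based on the reference
    haplotype, VCF-style anchored alleles for indels."""

    seq_name: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if not self.ref_allele or not self.alt_allele:
            raise InvariantError("empty allele")

    @property
    def var_class(self) -> str:
        r, a = len(self.ref_allele), len(self.alt_allele)
        if r == a == 1:
            return "SNP"
        if a > r:
            return "INS"
        if r > a:
            return "DEL"
        raise InvariantError(
            f"variant at {self.seq_name}:{self.pos} is neither SNP, INS nor DEL"
        )

    @property
    def ref_interval(self) -> Interval:
        return Interval(self.pos, self.pos + len(self.ref_allele))

    @property
    def size(self) -> int:
        """Length difference introduced (0 for SNP)."""
        return abs(len(self.alt_allele) - len(self.ref_allele))


@dataclass(frozen=True)
class SyntenyBlock:
    """Paired coordinate interval between haplotypes (0-based half-open
    internally). NOTAL blocks carry coordinates on exactly one side; the
    missing side has ``start == end == -1`` and an empty sequence name.
    """

    ref_seq: str
    ref_start: int
    ref_end: int
    qry_seq: str
    qry_start: int
    qry_end: int
    block_class: str
    orientation: str = "same"

    def __post_init__(self) -> None:
        if self.block_class not in SYNTENY_CLASSES:
            raise InvariantError(
                f"unknown block class {self.block_class!r}; "
                f"allowed: {', '.join(SYNTENY_CLASSES)}"
            )
        if self.orientation not in ("same", "inverted"):
            raise InvariantError(f"bad orientation {self.orientation!r}")
        if self.block_class == "INV" and self.orientation != "inverted":
            raise InvariantError("INV block must have orientation=inverted")
        has_ref = self.ref_start >= 0
        has_qry = self.qry_start >= 0
        if self.block_class == "NOTAL":
            if has_ref == has_qry:
                raise InvariantError(
                    "NOTAL block must have coordinates on exactly one side"
                )
        elif not (has_ref and has_qry):
            raise InvariantError(f"{self.block_class} block missing coordinates")
        for s, e, side in (
            (self.ref_start, self.ref_end, "ref"),
            (self.qry_start, self.qry_end, "qry"),
        ):
            if s >= 0 and e < s:
                raise InvariantError(f"{side} end < start")

    @property
    def ref_interval(self) -> Interval | None:
        if self.ref_start < 0:
            return None
        return Interval(self.ref_start, self.ref_end)

    @property
    def qry_interval(self) -> Interval | None:
        if self.qry_start < 0:
            return None
        return Interval(self.qry_start, self.qry_end)


@dataclass
class ExpressionTable:
    """Per-tissue TPM matrix (gene x tissue)."""

    genes: list[str]
    tissues: list[str]
    tpm: "object"  # numpy ndarray, shape (len(genes), len(tissues))

    def __post_init__(self) -> None:
        import numpy as np

        self.tpm = np.asarray(self.tpm, dtype=float)
        if len(set(self.genes)) != len(self.genes):
            raise InvariantError("duplicate gene ids")
        if len(set(self.tissues)) != len(self.tissues):
            raise InvariantError("duplicate tissue names")
        if self.tpm.shape != (len(self.genes), len(self.tissues)):
            raise InvariantError("TPM matrix shape mismatch")
        if (self.tpm < 0).any():
            raise InvariantError("negative TPM")
        self._index = {g: i for i, g in enumerate(self.genes)}

    def row(self, gene_id: str):
        return self.tpm[self._index[gene_id]]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index


@dataclass
class TEAnnotation:
    """TE intervals per sequence, each tagged with a class label."""

    intervals: dict[str, list[tuple[Interval, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, ivs in self.intervals.items():
            for iv, cls in ivs:
                if cls not in TE_CLASSES:
                    raise InvariantError(
                        f"unknown TE class {cls!r} on {name}; "
                        f"allowed: {', '.join(TE_CLASSES)}"
                    )
            ivs.sort(key=lambda t: t[0])

    def on(self, seq_name: str) -> list[tuple[Interval, str]]:
        return self.intervals.get(seq_name, [])
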