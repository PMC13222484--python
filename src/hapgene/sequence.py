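"""Nucleotide utilities: CDS extraction, translation and splice-site checks."""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .models import GeneModel, GenomeSequence, TranscriptModel

__all__ = [
    "reverse_complement",
    "TranslationFlags",
    "extract_cds_and_translate",
    "spliced_sequence",
    "splice_sites_intact",
]

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtn", "TGCANYRSWMKVHDBtgcan")

STOP_CODONS = {"TAA", "TAG", "TGA"}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    """Standard-code translation of complete codons (stops as ``*``)."""
    n = len(cds) - len(cds) % 3
    return str(Seq(cds[:n]).translate())


@dataclass(frozen=True)
class TranslationFlags:
    has_start: bool
    has_terminal_stop: bool
    internal_stop: bool
    length_multiple_of_3: bool

    @property
    def orf_intact(self) -> bool:
        return (
            self.has_start
            and self.has_terminal_stop
            and not self.internal_stop
            and self.length_multiple_of_3
        )


def spliced_sequence(
    model: TranscriptModel, genome: GenomeSequence, seq_name: str, strand: str
) -> str:
    """Exonic sequence in transcription order (reverse-complemented on '-')."""
    chrom = genome[seq_name]
    s = "".join(chrom[e.start : e.end] for e in model.exons)
    return reverse_complement(s) if strand == "-" else s


def extract_cds(
    model: TranscriptModel, genome: GenomeSequence, seq_name: str, strand: str
) -> str:
    """CDS in transcription order, honouring the leading segment's phase
    (bases to skip before the first complete codon, as in GFF3 column 8)."""
    chrom = genome[seq_name]
    s = "".join(chrom[c.start : c.end] for c in model.cds_segments)
    if strand == "-":
        s = reverse_complement(s)
        lead = model.cds_segments[-1].phase if model.cds_segments else 0
    else:
        lead = model.cds_segments[0].phase if model.cds_segments else 0
    return s[lead:]


def extract_cds_and_translate(
    model: TranscriptModel, genome: GenomeSequence, seq_name: str, strand: str
) -> tuple[str, str, TranslationFlags]:
    """Return (cds_sequence, peptide, flags) for a transcript.

    A CDS whose length is not a multiple of three is flagged and translated
    over its complete codons only.
    """
    if not model.cds_segments:
        raise ValueError(f"transcript {model.transcript_id} has no CDS")
    if seq_name not in genome:
        raise KeyError(f"sequence {seq_name!r} not in genome")
    cds = extract_cds(model, genome, seq_name, strand)
    peptide = translate(cds)
    if peptide.endswith("*"):
        peptide = peptide[:-1]  # terminal stop reported via flags, not sequence
    flags = classify_cds(cds)
    return cds, peptide, flags


def classify_cds(cds: str) -> TranslationFlags:
    peptide = translate(cds)
    has_start = cds[:3] == "ATG"
    mult3 = len(cds) % 3 == 0
    has_terminal_stop = mult3 and len(cds) >= 3 and cds[-3:] in STOP_CODONS
    body = peptide[:-1] if peptide.endswith("*") else peptide
    internal_stop = "*" in body
    return TranslationFlags(has_start, has_terminal_stop, internal_stop, mult3)


def splice_sites_intact(
    model: TranscriptModel, genome: GenomeSequence, seq_name: str, strand: str
) -> bool:
    """True iff every intron is canonical GT..AG in transcription order."""
    chrom = genome[seq_name]
    for intron in model.introns():
        if len(intron) < 4:
            return False
        left = chrom[intron.start : intron.start + 2]
        right = chrom[intron.end - 2 : intron.end]
        if strand == "+":
            donor, acceptor = left, right
        else:
            donor, acceptor = reverse_complement(right), reverse_complement(left)
        if donor != "GT" or acceptor != "AG":
            return False
    return True
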