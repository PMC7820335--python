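"""Coding-consequence annotation for candidate null mutations.

Given a coding sequence and a variant inside it, the variant is applied,
the mutant CDS is translated in frame from its start, and the consequence
is classified: a frameshift (indel length not divisible by 3) that exposes
a premature stop, an in-frame deletion/insertion, a premature stop without
frameshift, or none. Stop offsets are reported both from the CDS start and
from the transcription start (CDS offset + 5' UTR length), the style used
when relating a lesion to a transcript model.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

CONSEQUENCES = (
    "frameshift_premature_stop",
    "frameshift_no_stop",
    "inframe_deletion",
    "inframe_insertion",
    "premature_stop_no_frameshift",
    "none",
)


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class Variant:
    """A substitution or indel, 1-based within the CDS, VCF-style alleles."""

    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1 or not self.ref or not self.alt:
            raise AnnotationError("variant needs pos >= 1 and non-empty alleles")

    @property
    def net_length(self) -> int:
        return len(self.alt) - len(self.ref)

    @property
    def is_indel(self) -> bool:
        return len(self.alt) != len(self.ref)


@dataclass(frozen=True)
class MutationAnnotation:
    variant: Variant
    consequence: str
    stop_offset_cds: int | None  # bp from CDS start to the new stop's last base
    stop_offset_tx: int | None  # adds the 5' UTR length
    aa_lost: int = 0  # amino acids removed by an in-frame deletion
    premature: bool = False  # stop earlier than the unmutated terminator


def extract_cds(
    chrom_seq: str,
    cds_spans: list[tuple[int, int]],
    strand: str = "+",
    tx_start: int | None = None,
) -> tuple[str, int]:
    """Assemble a CDS from exon spans on a chromosome sequence.

    *cds_spans* are 0-based half-open intervals in chromosome coordinates;
    reverse-strand models are reverse-complemented after concatenation in
    genomic order. Returns (cds, utr5_len), where utr5_len is the distance
    from *tx_start* (transcription start, 0-based; strand-aware) to the CDS
    start, or 0 when no transcript start is given.
    """
    spans = sorted(cds_spans)
    for (a, b) in spans:
        if not (0 <= a < b <= len(chrom_seq)):
            raise AnnotationError(f"CDS span [{a}, {b}) outside the sequence")
    seq = "".join(chrom_seq[a:b] for a, b in spans)
    if strand == "-":
        seq = str(Seq(seq).reverse_complement())
        utr5 = 0 if tx_start is None else tx_start - (spans[-1][1] - 1)
    elif strand == "+":
        utr5 = 0 if tx_start is None else spans[0][0] - tx_start
    else:
        raise AnnotationError(f"strand must be '+' or '-', got {strand!r}")
    if utr5 < 0:
        raise AnnotationError("transcription start lies inside or after the CDS")
    return seq.upper(), utr5


def _first_stop_codon(cds: str) -> int | None:
    """0-based codon index of the first in-frame stop, scanning complete codons."""
    aa = str(Seq(cds[: len(cds) - len(cds) % 3]).translate())
    k = aa.find("*")
    return None if k == -1 else k


def annotate_variant(cds: str, utr5_len: int, variant: Variant) -> MutationAnnotation:
    """Classify a variant's coding consequence by translating the mutant CDS.

    *cds* must begin with ATG and have length divisible by 3; the variant's
    reference allele must match and lie entirely within the CDS.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise AnnotationError("CDS length not divisible by 3")
    if not cds.startswith("ATG"):
        raise AnnotationError("CDS does not begin with ATG")
    if utr5_len < 0:
        raise AnnotationError("utr5_len must be >= 0")
    p0 = variant.pos - 1
    if p0 + len(variant.ref) > len(cds):
        raise AnnotationError("variant extends outside the CDS")
    if cds[p0 : p0 + len(variant.ref)] != variant.ref.upper():
        raise AnnotationError(
            f"reference allele mismatch at CDS position {variant.pos}"
        )

    mutant = cds[:p0] + variant.alt.upper() + cds[p0 + len(variant.ref) :]
    stop_orig = _first_stop_codon(cds)
    stop_new = _first_stop_codon(mutant)
    net = variant.net_length
    frameshift = variant.is_indel and net % 3 != 0

    stop_offset_cds = None if stop_new is None else (stop_new + 1) * 3
    stop_offset_tx = None if stop_offset_cds is None else utr5_len + stop_offset_cds

    if frameshift:
        # any in-frame stop after a frameshift is novel relative to the
        # destroyed original frame
        premature = stop_new is not None
        consequence = (
            "frameshift_premature_stop" if premature else "frameshift_no_stop"
        )
        aa_lost = 0
    else:
        expected_stop = None if stop_orig is None else stop_orig + net // 3
        premature = (
            stop_new is not None
            and (expected_stop is None or stop_new < expected_stop)
        )
        if premature:
            consequence = "premature_stop_no_frameshift"
        elif variant.is_indel and net < 0:
            consequence = "inframe_deletion"
        elif variant.is_indel:
            consequence = "inframe_insertion"
        else:
            consequence = "none"
        aa_lost = (-net) // 3 if (variant.is_indel and net < 0) else 0

    return MutationAnnotation(
        variant=variant,
        consequence=consequence,
        stop_offset_cds=stop_offset_cds,
        stop_offset_tx=stop_offset_tx,
        aa_lost=aa_lost,
        premature=premature,
    )
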