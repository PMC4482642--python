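"""Per-genome content accounting: feature-class footprints and the derived
percent-reduction / footprint-fraction arithmetic.

Two accounting modes are provided.  ``summed`` adds per-transcript exon and
intron lengths, so bases shared by alternative transcripts are counted once
per transcript and class totals can exceed the genome size — the convention
behind published per-class totals for these genomes.  ``union`` de-duplicates
every class over the genome so totals are true footprints.  Intergenic DNA is
always the complement of the union of gene spans, and the unspliced
transcript footprint (exons + introns + UTRs) is always the union of
transcript spans.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, Mapping

from .intervals import Interval, IntervalSet
from .io import GenomeAnnotation

MODES = ("summed", "union")


@dataclass(frozen=True)
class ContentSummary:
    """Feature-class totals for one genome (all values in bp)."""

    exonic_bp: int
    intronic_bp: int
    intergenic_bp: int
    total_bp: int
    repeat_coding_bp: int
    repeat_noncoding_bp: int
    repeat_total_bp: int
    gene_count: int
    transcript_footprint_bp: int
    mode: str

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if name != "mode" and value < 0:
                raise ValueError(f"{name} negative: {value}")
        if self.repeat_coding_bp + self.repeat_noncoding_bp != self.repeat_total_bp:
            raise ValueError("repeat coding/noncoding split does not sum")


def summarize_content(annotation: GenomeAnnotation, mode: str = "summed",
                      repeat_split: str = "exon") -> ContentSummary:
    """Compute a :class:`ContentSummary` for one annotated genome.

    ``repeat_split`` decides what makes a repeat base "coding": overlap with
    the exonic union (``"exon"``) or with any gene span (``"gene"``).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if repeat_split not in ("exon", "gene"):
        raise ValueError("repeat_split must be 'exon' or 'gene'")

    total_bp = sum(annotation.seq_lengths.values())
    gene_union = IntervalSet(annotation.gene_spans())
    intergenic = total_bp - gene_union.total_length

    tx_spans = []
    exon_ivs = []
    for gene in annotation.genes.values():
        for tx in gene.transcripts:
            tx_spans.append(Interval(tx.seqid, tx.start, tx.end))
            exon_ivs.extend(tx.exons + tx.utr5 + tx.utr3)
    footprint_set = IntervalSet(tx_spans)
    exonic_union = IntervalSet(exon_ivs)

    if mode == "summed":
        exonic = sum(tx.exon_sum for g in annotation.genes.values()
                     for tx in g.transcripts)
        intronic = sum(iv.length for g in annotation.genes.values()
                       for tx in g.transcripts for iv in tx.introns())
    else:
        exonic = exonic_union.total_length
        # bases inside a transcript span but in no exon/UTR of any transcript
        intronic = (footprint_set.total_length
                    - exonic_union.intersect(footprint_set).total_length)

    coding_ref = exonic_union if repeat_split == "exon" else gene_union
    repeat_total = annotation.repeats.total_length
    repeat_coding = annotation.repeats.intersect(coding_ref).total_length

    return ContentSummary(
        exonic_bp=exonic,
        intronic_bp=intronic,
        intergenic_bp=intergenic,
        total_bp=total_bp,
        repeat_coding_bp=repeat_coding,
        repeat_noncoding_bp=repeat_total - repeat_coding,
        repeat_total_bp=repeat_total,
        gene_count=len(annotation.genes),
        transcript_footprint_bp=footprint_set.total_length,
        mode=mode,
    )


def percent_reduction(size_bp: float, reference_bp: float,
                      digits: int = 0) -> float:
    """Size reduction relative to a reference, as a percent.

    ``100 * (reference - size) / reference``, rounded half-up to ``digits``
    decimal places (whole percent by default, matching printed precision).
    """
    if reference_bp <= 0:
        raise ValueError("reference size must be positive")
    value = 100.0 * (reference_bp - size_bp) / reference_bp
    return round_half_up(value, digits)


def footprint_fractions(footprint_bp: float, assembled_bp: float,
                        estimated_bp: float,
                        other_footprints: Mapping[str, float] = (),
                        digits: int = 2) -> Dict[str, float]:
    """Genic-footprint fractions of the assembled and estimated genome size,
    plus percent difference against comparator species' footprints.

    Returns ``{"of_assembled": %, "of_estimated": %, "vs_<name>": %}``.
    """
    if footprint_bp <= 0 or assembled_bp <= 0 or estimated_bp <= 0:
        raise ValueError("all sizes must be positive")
    report = {
        "of_assembled": round_half_up(100.0 * footprint_bp / assembled_bp, digits),
        "of_estimated": round_half_up(100.0 * footprint_bp / estimated_bp, digits),
    }
    for name, other in dict(other_footprints).items():
        report[f"vs_{name}"] = round_half_up(
            100.0 * (footprint_bp - other) / other, digits)
    return report


def round_half_up(value: float, digits: int = 0) -> float:
    """Round half away from zero at ``digits`` decimals (printed-table style)."""
    quantum = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))
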