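"""Residual-polymorphism estimation by genomic feature class, and RAD-marker
segregation-distortion QC for genetic-map construction.

Each base of the genome is assigned exactly one class by precedence
``CDS_exon > UTR5 > UTR3 > intron > TSS > TE > intergenic`` (coding
annotation beats repeat annotation; the order is configurable).  Variant
sites from an all-sites VCF are tallied per class after two site filters:
per-base coverage above 600 (possible collapsed repeats) and base quality
below Q10 (Phred+33, 90% certainty) both remove a site from numerator *and*
denominator.  "Genic" for the headline residual-polymorphism figure means
CDS/UTR/intron combined — the well-assembled gene bodies.

Marker QC flags markers whose parental-allele frequency departs from 50:50
beyond 80:20, drops every marker on scaffolds with more than five flagged
markers (systematic distortion, e.g. reproductive incompatibility), drops
markers genotyped in fewer than 40 lines, and collapses duplicate-pattern
markers to one representative (recorded for later re-addition).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .io import GenomeAnnotation, logger

SITE_CLASSES = ("intergenic", "TE", "TSS", "intron", "UTR3", "UTR5", "CDS_exon")
GENIC_CLASSES = ("CDS_exon", "UTR5", "UTR3", "intron")
DEFAULT_TSS_WINDOW = 200
MAX_DEPTH = 600
MIN_QUALITY = 10.0


def classify_sites(annotation: GenomeAnnotation,
                   tss_window_bp: int = DEFAULT_TSS_WINDOW,
                   precedence: Sequence[str] = SITE_CLASSES,
                   ) -> Dict[str, np.ndarray]:
    """Per-base class map: seqid -> uint8 array of indices into SITE_CLASSES.

    Classes are painted lowest-precedence first so later (higher) classes
    overwrite earlier ones.  TSS is the ``tss_window_bp`` window immediately
    upstream of each transcript start, strand-aware and clipped to the
    scaffold.  The result is a partition: every base has exactly one class.
    """
    if sorted(precedence) != sorted(SITE_CLASSES):
        raise ValueError("precedence must be a permutation of SITE_CLASSES")
    logger.debug("site-class precedence (low to high): %s", list(precedence))
    maps = {seqid: np.zeros(length, dtype=np.uint8)
            for seqid, length in annotation.seq_lengths.items()}
    painters = {
        "intergenic": lambda: [],
        "TE": lambda: list(annotation.repeats),
        "TSS": lambda: _tss_windows(annotation, tss_window_bp),
        "intron": lambda: [iv for g in annotation.genes.values()
                           for tx in g.transcripts for iv in tx.introns()],
        "UTR3": lambda: [iv for g in annotation.genes.values()
                         for tx in g.transcripts for iv in tx.utr3],
        "UTR5": lambda: [iv for g in annotation.genes.values()
                         for tx in g.transcripts for iv in tx.utr5],
        "CDS_exon": lambda: [iv for g in annotation.genes.values()
                             for tx in g.transcripts for iv in tx.cds],
    }
    for cls in precedence:
        code = SITE_CLASSES.index(cls)
        for iv in painters[cls]():
            arr = maps.get(iv.seqid)
            if arr is not None:
                arr[iv.start:min(iv.end, arr.size)] = code
    return maps


def _tss_windows(annotation: GenomeAnnotation, window: int):
    from .intervals import Interval
    out = []
    for gene in annotation.genes.values():
        length = annotation.seq_lengths[gene.seqid]
        for tx in gene.transcripts:
            if tx.strand == "-":
                lo, hi = tx.end, min(length, tx.end + window)
            else:
                lo, hi = max(0, tx.start - window), tx.start
            if hi > lo:
                out.append(Interval(gene.seqid, lo, hi))
    return out


def class_totals(class_map: Mapping[str, np.ndarray]) -> Dict[str, int]:
    totals = {cls: 0 for cls in SITE_CLASSES}
    for arr in class_map.values():
        counts = np.bincount(arr, minlength=len(SITE_CLASSES))
        for i, cls in enumerate(SITE_CLASSES):
            totals[cls] += int(counts[i])
    return totals


# ---------------------------------------------------------------------------
# Polymorphism tally
# ---------------------------------------------------------------------------

@dataclass
class SiteClassTally:
    """Assayed and polymorphic site counts per feature class."""

    assayed: Dict[str, int] = field(default_factory=dict)
    polymorphic: Dict[str, int] = field(default_factory=dict)
    skipped_unmapped: int = 0
    excluded_by_filters: int = 0

    def fraction(self, cls: str) -> float:
        assayed = self.assayed.get(cls, 0)
        return self.polymorphic.get(cls, 0) / assayed if assayed else float("nan")

    def percent(self, cls: str) -> float:
        return 100.0 * self.fraction(cls)

    def genic_percent(self) -> float:
        """Residual polymorphism in well-assembled genic DNA, as percent."""
        assayed = sum(self.assayed.get(c, 0) for c in GENIC_CLASSES)
        poly = sum(self.polymorphic.get(c, 0) for c in GENIC_CLASSES)
        return 100.0 * poly / assayed if assayed else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "site_class": cls,
            "assayed_sites": self.assayed.get(cls, 0),
            "polymorphic_sites": self.polymorphic.get(cls, 0),
            "percent_polymorphic": self.percent(cls),
        } for cls in SITE_CLASSES])


def polymorphism_by_class(sites: pd.DataFrame,
                          class_map: Mapping[str, np.ndarray],
                          max_depth: float = MAX_DEPTH,
                          min_quality: float = MIN_QUALITY) -> SiteClassTally:
    """Tally polymorphic vs assayed sites per feature class.

    ``sites`` is the table from :func:`genarch.io.read_vcf_sites`.  Sites
    with depth above ``max_depth``, quality below ``min_quality``, or
    missing depth are excluded from numerator and denominator; sites on
    scaffolds absent from the class map are skipped and counted.
    """
    tally = SiteClassTally(
        assayed={cls: 0 for cls in SITE_CLASSES},
        polymorphic={cls: 0 for cls in SITE_CLASSES})
    for seqid, sub in sites.groupby("seqid", sort=False):
        arr = class_map.get(seqid)
        if arr is None:
            tally.skipped_unmapped += len(sub)
            logger.warning("scaffold %s absent from class map; %d site(s) "
                           "skipped", seqid, len(sub))
            continue
        depth = sub["depth"].to_numpy()
        qual = sub["base_quality"].to_numpy()
        ok = (~np.isnan(depth) & (depth <= max_depth)
              & ~np.isnan(qual) & (qual >= min_quality))
        tally.excluded_by_filters += int((~ok).sum())
        pos = sub["pos"].to_numpy()[ok]
        is_var = sub["is_variant"].to_numpy()[ok]
        codes = arr[pos]
        for code in range(len(SITE_CLASSES)):
            mask = codes == code
            cls = SITE_CLASSES[code]
            tally.assayed[cls] += int(mask.sum())
            tally.polymorphic[cls] += int(is_var[mask].sum())
    return tally


# ---------------------------------------------------------------------------
# RAD-marker QC
# ---------------------------------------------------------------------------

@dataclass
class MarkerQCReport:
    input_markers: int
    dropped_by_scaffold_distortion: int
    dropped_low_representation: int
    dropped_duplicate_only: int
    retained_markers: int
    flagged_scaffolds: Set[str] = field(default_factory=set)
    duplicates: Dict[str, List[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = (self.retained_markers + self.dropped_by_scaffold_distortion
                 + self.dropped_low_representation + self.dropped_duplicate_only)
        if total != self.input_markers:
            raise ValueError("marker counts do not partition the input")


def parental_allele_frequency(calls: Sequence[str],
                              include_het: bool = False) -> float:
    """Frequency of the A parental allele over informative calls.

    Heterozygous and missing calls are ignored by default (RILs are nearly
    homozygous); ``include_het=True`` counts H as half an A.  NaN when no
    informative calls remain.
    """
    a = sum(1 for c in calls if c == "A")
    b = sum(1 for c in calls if c == "B")
    h = sum(1 for c in calls if c == "H")
    if include_het:
        denom = a + b + h
        return (a + 0.5 * h) / denom if denom else float("nan")
    denom = a + b
    return a / denom if denom else float("nan")


def marker_qc(genotypes: pd.DataFrame, scaffold_map: Mapping[str, str],
              freq_hi: float = 0.80, freq_lo: float = 0.20,
              max_flagged_per_scaffold: int = 5, min_lines: int = 40,
              include_het: bool = False,
              ) -> Tuple[pd.DataFrame, MarkerQCReport]:
    """Segregation-distortion and representation QC on a genotype matrix.

    Order of operations: (1) flag markers with parental-allele frequency
    above ``freq_hi`` or below ``freq_lo`` and drop *all* markers on
    scaffolds with more than ``max_flagged_per_scaffold`` flagged markers;
    (2) drop markers genotyped (non-missing) in fewer than ``min_lines``
    lines, including markers with zero informative calls; (3) collapse
    duplicate-pattern markers to one representative, recording the
    duplicates for re-addition after map construction.  Idempotent.
    """
    markers = list(genotypes.index)
    flagged: List[str] = []
    for marker in markers:
        freq = parental_allele_frequency(genotypes.loc[marker],
                                         include_het=include_het)
        if not np.isnan(freq) and (freq > freq_hi or freq < freq_lo):
            flagged.append(marker)
    flags_per_scaffold: Dict[str, int] = {}
    for marker in flagged:
        scf = scaffold_map.get(marker)
        if scf is not None:
            flags_per_scaffold[scf] = flags_per_scaffold.get(scf, 0) + 1
    bad_scaffolds = {scf for scf, n in flags_per_scaffold.items()
                     if n > max_flagged_per_scaffold}
    after_distortion = [m for m in markers
                        if scaffold_map.get(m) not in bad_scaffolds]
    n_distortion = len(markers) - len(after_distortion)

    keep_rep: List[str] = []
    for marker in after_distortion:
        calls = genotypes.loc[marker]
        genotyped = int((calls != "-").sum())
        informative = int(calls.isin(["A", "B"]).sum())
        if genotyped >= min_lines and informative > 0:
            keep_rep.append(marker)
    n_lowrep = len(after_distortion) - len(keep_rep)

    seen_patterns: Dict[str, str] = {}
    duplicates: Dict[str, List[str]] = {}
    retained: List[str] = []
    for marker in keep_rep:
        pattern = "".join(genotypes.loc[marker])
        if pattern in seen_patterns:
            duplicates.setdefault(seen_patterns[pattern], []).append(marker)
        else:
            seen_patterns[pattern] = marker
            retained.append(marker)
    n_dup = len(keep_rep) - len(retained)

    report = MarkerQCReport(
        input_markers=len(markers),
        dropped_by_scaffold_distortion=n_distortion,
        dropped_low_representation=n_lowrep,
        dropped_duplicate_only=n_dup,
        retained_markers=len(retained),
        flagged_scaffolds=bad_scaffolds,
        duplicates=duplicates,
    )
    return genotypes.loc[retained], report
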