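"""Readers and writers for the formats the pipeline consumes.

GFF3 gene annotations, FASTA/FASTQ sequence, BED repeat tracks, VCF variant
sites, and the tabular ortholog / RIL-genotype files.  Every coordinate
leaving this module is 0-based half-open; GFF3 (1-based closed) and VCF
(1-based) are converted here and nowhere else.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, IO, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import Interval, IntervalSet

logger = logging.getLogger("genarch")

CHROM_CLASSES = ("autosome", "X", "unassigned")


class GffParseError(ValueError):
    """Malformed GFF3 syntax (names the offending line)."""


class AnnotationConsistencyError(ValueError):
    """Structurally valid GFF3 whose features contradict each other."""


# ---------------------------------------------------------------------------
# Annotation object model
# ---------------------------------------------------------------------------

@dataclass
class Transcript:
    id: str
    gene_id: str
    seqid: str
    strand: str
    start: int
    end: int
    exons: List[Interval] = field(default_factory=list)
    cds: List[Interval] = field(default_factory=list)
    utr5: List[Interval] = field(default_factory=list)
    utr3: List[Interval] = field(default_factory=list)

    @property
    def exon_sum(self) -> int:
        return sum(iv.length for iv in self.exons)

    @property
    def cds_sum(self) -> int:
        return sum(iv.length for iv in self.cds)

    def introns(self) -> List[Interval]:
        """Gaps between consecutive exons (positive gaps only)."""
        exons = sorted(self.exons, key=lambda iv: iv.start)
        out = []
        for a, b in zip(exons, exons[1:]):
            if b.start > a.end:
                out.append(Interval(self.seqid, a.end, b.start))
        return out


@dataclass
class Gene:
    id: str
    seqid: str
    strand: str
    start: int
    end: int
    transcripts: List[Transcript] = field(default_factory=list)

    @property
    def span(self) -> Interval:
        return Interval(self.seqid, self.start, self.end)

    def canonical_transcript(self) -> Transcript:
        """Longest summed-exon transcript; ties broken by lexicographic id."""
        return min(self.transcripts, key=lambda t: (-t.exon_sum, t.id))


@dataclass
class GenomeAnnotation:
    """Genes, transcripts, repeats and chromosome-class labels of one genome."""

    seq_lengths: Dict[str, int]
    genes: Dict[str, Gene] = field(default_factory=dict)
    repeats: IntervalSet = field(default_factory=IntervalSet)
    chrom_class: Dict[str, str] = field(default_factory=dict)

    @property
    def transcripts(self) -> Dict[str, Transcript]:
        return {t.id: t for g in self.genes.values() for t in g.transcripts}

    def gene_spans(self, seqid: str | None = None) -> List[Interval]:
        genes = self.genes.values()
        if seqid is not None:
            genes = [g for g in genes if g.seqid == seqid]
        return [g.span for g in genes]

    def class_of(self, seqid: str) -> str:
        return self.chrom_class.get(seqid, "unassigned")

    def validate(self) -> None:
        for gene in self.genes.values():
            length = self.seq_lengths.get(gene.seqid)
            if length is None:
                raise AnnotationConsistencyError(
                    f"gene {gene.id} on unknown sequence {gene.seqid}")
            if gene.start < 0 or gene.end > length:
                raise AnnotationConsistencyError(
                    f"gene {gene.id} span [{gene.start}, {gene.end}) outside "
                    f"[0, {length}) of {gene.seqid}")
            for tx in gene.transcripts:
                if tx.start < gene.start or tx.end > gene.end:
                    raise AnnotationConsistencyError(
                        f"transcript {tx.id} outside gene {gene.id} span")
                for iv in tx.exons + tx.cds + tx.utr5 + tx.utr3:
                    if iv.start < tx.start or iv.end > tx.end:
                        raise AnnotationConsistencyError(
                            f"feature [{iv.start}, {iv.end}) outside "
                            f"transcript {tx.id} span")
                exons = sorted(tx.exons, key=lambda iv: iv.start)
                for a, b in zip(exons, exons[1:]):
                    if b.start < a.end:
                        raise AnnotationConsistencyError(
                            f"overlapping exons in transcript {tx.id}")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_GENE_TYPES = {"gene"}
_TX_TYPES = {"mRNA", "transcript"}
_UTR5_TYPES = {"five_prime_UTR", "5'UTR"}
_UTR3_TYPES = {"three_prime_UTR", "3'UTR"}


def _parse_attributes(text: str) -> Dict[str, str]:
    out: Dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if part and "=" in part:
            key, value = part.split("=", 1)
            out[key] = value
    return out


def read_gff3(path: str | Path,
              seq_lengths: Optional[Mapping[str, int]] = None) -> GenomeAnnotation:
    """Parse a GFF3 file into a :class:`GenomeAnnotation`.

    Coordinates are converted from 1-based closed to 0-based half-open.
    Sequence lengths come from ``seq_lengths`` if given, otherwise from
    ``##sequence-region`` pragmas, otherwise from feature extents.
    Genes without any transcript are dropped (logged); features whose
    parents are unknown, or that fall outside their parent span, raise
    :class:`AnnotationConsistencyError`.
    """
    genes: Dict[str, Gene] = {}
    transcripts: Dict[str, Transcript] = {}
    pragma_lengths: Dict[str, int] = {}
    deferred: List[Tuple[int, str, str, int, int, Dict[str, str]]] = []

    with _maybe_gzip(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    pragma_lengths[parts[1]] = int(parts[3])
                continue
            if line.startswith("##FASTA"):
                break
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GffParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(cols)}")
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs_s = cols
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise GffParseError(
                    f"{path}: line {lineno}: non-integer coordinates") from exc
            start, end = start1 - 1, end1  # 1-based closed -> 0-based half-open
            if end <= start:
                raise GffParseError(
                    f"{path}: line {lineno}: empty feature [{start1}, {end1}]")
            attrs = _parse_attributes(attrs_s)

            if ftype in _GENE_TYPES:
                gid = attrs.get("ID")
                if gid is None:
                    raise GffParseError(f"{path}: line {lineno}: gene without ID")
                genes[gid] = Gene(id=gid, seqid=seqid, strand=strand,
                                  start=start, end=end)
            elif ftype in _TX_TYPES:
                tid = attrs.get("ID")
                parent = attrs.get("Parent")
                if tid is None or parent is None:
                    raise GffParseError(
                        f"{path}: line {lineno}: transcript without ID/Parent")
                if parent not in genes:
                    raise AnnotationConsistencyError(
                        f"{path}: line {lineno}: transcript {tid} references "
                        f"unknown gene {parent}")
                tx = Transcript(id=tid, gene_id=parent, seqid=seqid,
                                strand=strand, start=start, end=end)
                transcripts[tid] = tx
                genes[parent].transcripts.append(tx)
            elif ftype in ({"exon", "CDS"} | _UTR5_TYPES | _UTR3_TYPES):
                deferred.append((lineno, ftype, seqid, start, end, attrs))
            # other feature types ignored

    for lineno, ftype, seqid, start, end, attrs in deferred:
        parent = attrs.get("Parent")
        if parent is None or parent not in transcripts:
            raise AnnotationConsistencyError(
                f"{path}: line {lineno}: {ftype} references unknown "
                f"transcript {parent!r}")
        tx = transcripts[parent]
        iv = Interval(seqid, start, end)
        if ftype == "exon":
            tx.exons.append(iv)
        elif ftype == "CDS":
            tx.cds.append(iv)
        elif ftype in _UTR5_TYPES:
            tx.utr5.append(iv)
        else:
            tx.utr3.append(iv)

    orphans = [gid for gid, g in genes.items() if not g.transcripts]
    if orphans:
        logger.warning("%s: dropped %d gene(s) without transcripts", path, len(orphans))
        for gid in orphans:
            del genes[gid]

    if seq_lengths is not None:
        lengths = dict(seq_lengths)
    elif pragma_lengths:
        lengths = pragma_lengths
    else:
        lengths = {}
        for g in genes.values():
            lengths[g.seqid] = max(lengths.get(g.seqid, 0), g.end)

    ann = GenomeAnnotation(seq_lengths=lengths, genes=genes)
    ann.validate()
    return ann


def write_gff3(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write an annotation as GFF3 (the inverse of :func:`read_gff3`)."""
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for seqid in sorted(annotation.seq_lengths):
            out.write(f"##sequence-region {seqid} 1 "
                      f"{annotation.seq_lengths[seqid]}\n")

        def row(seqid: str, ftype: str, start: int, end: int,
                strand: str, attrs: str) -> str:
            return (f"{seqid}\tgenarch\t{ftype}\t{start + 1}\t{end}\t.\t"
                    f"{strand}\t.\t{attrs}\n")

        for gid in sorted(annotation.genes):
            g = annotation.genes[gid]
            out.write(row(g.seqid, "gene", g.start, g.end, g.strand, f"ID={g.id}"))
            for tx in sorted(g.transcripts, key=lambda t: t.id):
                out.write(row(tx.seqid, "mRNA", tx.start, tx.end, tx.strand,
                              f"ID={tx.id};Parent={g.id}"))
                for ftype, ivs in (("exon", tx.exons),
                                   ("five_prime_UTR", tx.utr5),
                                   ("CDS", tx.cds),
                                   ("three_prime_UTR", tx.utr3)):
                    for iv in sorted(ivs, key=lambda i: i.start):
                        out.write(row(iv.seqid, ftype, iv.start, iv.end,
                                      tx.strand, f"Parent={tx.id}"))


# ---------------------------------------------------------------------------
# BED repeats and chromosome-class tables
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> IntervalSet:
    """BED3+ intervals (already 0-based half-open)."""
    intervals = []
    with _maybe_gzip(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}: line {lineno}: BED needs >=3 columns")
            intervals.append(Interval(cols[0], int(cols[1]), int(cols[2])))
    return IntervalSet(intervals)


def write_bed(intervals: Iterable[Interval], path: str | Path,
              names: Optional[Sequence[str]] = None) -> None:
    with open(path, "w") as out:
        for i, iv in enumerate(intervals):
            name = f"\t{names[i]}" if names is not None else ""
            out.write(f"{iv.seqid}\t{iv.start}\t{iv.end}{name}\n")


def read_chrom_classes(path: str | Path) -> Dict[str, str]:
    """Two-column TSV ``seqid <tab> class`` with class in {autosome, X, unassigned}."""
    out: Dict[str, str] = {}
    df = pd.read_csv(path, sep="\t", header=None, names=["seqid", "chrom_class"],
                     comment="#", dtype=str)
    for seqid, cls in zip(df["seqid"], df["chrom_class"]):
        if cls not in CHROM_CLASSES:
            raise ValueError(f"{path}: unknown chromosome class {cls!r}")
        out[seqid] = cls
    return out


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> Dict[str, str]:
    with _maybe_gzip(path) as handle:
        return {rec.id: str(rec.seq).upper()
                for rec in SeqIO.parse(handle, "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    with open(path, "w") as out:
        SeqIO.write(records, out, "fasta")


def read_fastq(path: str | Path):
    """Yield Biopython SeqRecords from a (possibly gzipped) FASTQ file."""
    with _maybe_gzip(path) as handle:
        yield from SeqIO.parse(handle, "fastq")


def write_fastq(records, path: str | Path) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as out:
        SeqIO.write(records, out, "fastq")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf_sites(path: str | Path) -> pd.DataFrame:
    """Read per-site records from a VCF into a DataFrame (file order).

    Columns: ``seqid``, ``pos`` (0-based), ``depth`` (DP from INFO, falling
    back to the first sample's FORMAT DP; NaN when absent), ``base_quality``
    (QUAL; NaN when missing) and ``is_variant`` (non-empty ALT).  Records
    without DP are counted and logged; depth-filtered analyses exclude them
    via the NaN.
    """
    from cyvcf2 import VCF

    seqids: List[str] = []
    positions: List[int] = []
    depths: List[float] = []
    quals: List[float] = []
    variant: List[bool] = []
    n_missing_dp = 0
    vcf = VCF(str(path))
    for rec in vcf:
        depth = rec.INFO.get("DP")
        if depth is None:
            try:
                fmt = rec.format("DP")
                depth = None if fmt is None else float(fmt[0][0])
            except (KeyError, TypeError):
                depth = None
        if depth is None:
            n_missing_dp += 1
            depth = float("nan")
        seqids.append(rec.CHROM)
        positions.append(rec.start)
        depths.append(float(depth))
        quals.append(float("nan") if rec.QUAL is None else float(rec.QUAL))
        variant.append(bool(rec.ALT))
    vcf.close()
    if n_missing_dp:
        logger.warning("%s: %d record(s) lack DP and are excluded from "
                       "depth-filtered analyses", path, n_missing_dp)
    df = pd.DataFrame({
        "seqid": pd.Series(seqids, dtype="object"),
        "pos": pd.Series(positions, dtype="int64"),
        "depth": pd.Series(depths, dtype="float64"),
        "base_quality": pd.Series(quals, dtype="float64"),
        "is_variant": pd.Series(variant, dtype="bool"),
    })
    df.attrs["n_missing_dp"] = n_missing_dp
    return df


def write_vcf_sites(sites: pd.DataFrame, path: str | Path,
                    seq_lengths: Optional[Mapping[str, int]] = None) -> None:
    """Write a site table (as from :func:`read_vcf_sites`) as minimal VCF 4.2."""
    with open(path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write('##INFO=<ID=DP,Number=1,Type=Integer,'
                  'Description="Raw read depth">\n')
        if seq_lengths:
            for seqid in sorted(seq_lengths):
                out.write(f"##contig=<ID={seqid},length={seq_lengths[seqid]}>\n")
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        lines = []
        for row in sites.itertuples(index=False):
            alt = "A" if row.is_variant else "."
            dp = "." if pd.isna(row.depth) else f"DP={int(row.depth)}"
            qual = "." if pd.isna(row.base_quality) else f"{row.base_quality:g}"
            lines.append(f"{row.seqid}\t{row.pos + 1}\t.\tN\t{alt}\t{qual}\t.\t{dp}")
        out.write("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# Tabular ortholog / genotype files
# ---------------------------------------------------------------------------

ORTHOLOG_COLUMNS = ["gene_id", "species", "seqid", "start", "end"]


def read_ortholog_table(path: str | Path) -> pd.DataFrame:
    """TSV with header ``gene_id species seqid start end`` (0-based coords)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "species": str,
                                            "seqid": str})
    missing = set(ORTHOLOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: ortholog table missing columns {sorted(missing)}")
    return df[ORTHOLOG_COLUMNS + [c for c in df.columns
                                  if c not in ORTHOLOG_COLUMNS]]


def write_ortholog_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


GENOTYPE_CODES = {"A", "B", "H", "-"}


def read_genotype_matrix(path: str | Path) -> pd.DataFrame:
    """Markers x lines matrix of A/B/H/- calls; index = marker id."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    bad = set(df.values.ravel()) - GENOTYPE_CODES
    if bad:
        raise ValueError(f"{path}: unknown genotype codes {sorted(bad)}")
    return df


def write_genotype_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="marker")


def read_marker_scaffold_map(path: str | Path) -> Dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["marker", "seqid"], dtype=str, comment="#")
    return dict(zip(df["marker"], df["seqid"]))


# ---------------------------------------------------------------------------

def _maybe_gzip(path: str | Path) -> IO[str]:
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)
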