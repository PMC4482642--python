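"""Synthetic multi-species genomes with known ground truth.

The generator emulates the architecture contrasts the pipeline is built to
measure: an ancestral outcrosser-like gene set is simulated, and each derived
species (i) deletes a fixed fraction of genes together with their downstream
intergenic DNA, (ii) rescales intron lengths per chromosome class, and
(iii) translocates genes between chromosomes at a stated rate.  Orthology is
recorded for surviving genes.  Downstream stages can therefore be checked
against exact bookkeeping (gene counts, footprints) or distributional truth
(heterozygosity rates, translocation rates, allele frequencies).

Length distributions are log-normal: intron, intergenic and repeat lengths
in real nematode genomes are heavy-tailed and right-skewed, and a log-normal
keeps the per-class medians interpretable (``median = exp(mu)``).  Sequence
content is i.i.d. with configurable GC, so contaminant scaffolds with a
distinct GC/coverage regime are separable by the scaffold classifier but no
finer sequence evolution is modelled.

Fixing ``seed`` fixes every output byte.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .intervals import Interval, IntervalSet
from .io import (GenomeAnnotation, Gene, Transcript, logger,
                 write_fasta, write_gff3, write_bed, write_ortholog_table,
                 write_genotype_matrix)

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesParams:
    """Per-species deviation from the simulated ancestor."""

    name: str
    gene_loss: float = 0.0            # fraction of ancestor genes deleted
    intron_scale_autosome: float = 1.0
    intron_scale_x: float = 1.0       # e.g. 1.5 = X introns 50% longer
    translocation_rate: float = 0.0   # per-gene chance of moving chromosome


@dataclass(frozen=True)
class ArchitectureParams:
    """Genome-architecture parameters for the ancestor simulation.

    Defaults mirror compact nematode genomes: ~6 exons of ~200 bp per gene,
    log-normal introns and intergenic gaps with longer gaps on the X, ~15%
    repeat density, and a two-species contrast of an outcrossing-like genome
    against a selfing-like genome that has lost 20% of its genes and carries
    rare translocations (chromosome retention ~0.95).
    """

    n_genes: int = 2000
    n_scaffolds: int = 6
    fraction_x: float = 1 / 6         # fraction of scaffolds labelled X
    exon_count_mean: float = 6.0
    exon_length_meanlog: float = math.log(170.0)   # mean length ~200 bp
    exon_length_sdlog: float = 0.55
    intron_median_autosome: float = 250.0
    intron_median_x: float = 250.0
    intron_sdlog: float = 0.9
    intergenic_median_autosome: float = 800.0
    intergenic_median_x: float = 1600.0
    intergenic_sdlog: float = 1.0
    repeat_density: float = 0.15
    te_family_count: int = 5
    repeat_length_meanlog: float = math.log(300.0)
    repeat_length_sdlog: float = 0.7
    gc_content: float = 0.36
    utr5_max: int = 100
    utr3_max: int = 150
    desert_scaffold: Optional[int] = None  # plant an ortholog desert here ...
    desert_bp: int = 0                     # ... of roughly this many bases
    species: Tuple[SpeciesParams, ...] = (
        SpeciesParams("outcrosser"),
        SpeciesParams("selfer", gene_loss=0.2, translocation_rate=0.05),
    )
    seed: int = 0

    def validate(self) -> None:
        for name, frac in (("fraction_x", self.fraction_x),
                           ("repeat_density", self.repeat_density),
                           ("gc_content", self.gc_content)):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {frac}")
        for val in (self.intron_median_autosome, self.intron_median_x,
                    self.intergenic_median_autosome, self.intergenic_median_x,
                    self.exon_count_mean):
            if val <= 0:
                raise ValueError("distribution parameters must be positive")
        for sp in self.species:
            if not 0.0 <= sp.gene_loss < 1.0:
                raise ValueError(f"gene_loss must be in [0, 1): {sp.gene_loss}")
            if not 0.0 <= sp.translocation_rate <= 1.0:
                raise ValueError("translocation_rate must be in [0, 1]")
            if sp.intron_scale_autosome <= 0 or sp.intron_scale_x <= 0:
                raise ValueError("intron scales must be positive")


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass
class ContentTruth:
    """Exact bookkeeping of one emitted genome (all values in bp)."""

    gene_count: int
    exonic_bp: int
    intronic_bp: int
    intergenic_bp: int
    total_bp: int
    repeat_bp: int = 0


@dataclass
class GroundTruth:
    """What the generator actually planted, keyed to emitted entities."""

    chrom_class: Dict[str, str] = field(default_factory=dict)
    ortholog_groups: Dict[str, Dict[str, str]] = field(default_factory=dict)
    deleted_genes: Dict[str, Set[str]] = field(default_factory=dict)
    translocated_genes: Dict[str, Set[str]] = field(default_factory=dict)
    desert_regions: Dict[str, Interval] = field(default_factory=dict)
    content: Dict[str, ContentTruth] = field(default_factory=dict)
    het_rate_by_class: Dict[str, float] = field(default_factory=dict)
    contaminant_reads: Set[str] = field(default_factory=set)
    contaminant_scaffolds: Set[str] = field(default_factory=set)
    distorted_scaffolds: Set[str] = field(default_factory=set)


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

@dataclass
class _AncestorGene:
    group: str
    scaffold: int
    strand: str
    exon_lens: List[int]
    intron_lens: List[int]
    gap_len: int  # intergenic gap downstream of this gene


@dataclass
class SpeciesBundle:
    name: str
    annotation: GenomeAnnotation
    sequences: Optional[Dict[str, str]] = None
    files: Dict[str, str] = field(default_factory=dict)


@dataclass
class SimulationResult:
    params: ArchitectureParams
    species: Dict[str, SpeciesBundle]
    ortholog_table: pd.DataFrame
    truth: GroundTruth
    manifest_path: Optional[str] = None


def _lognormal_ints(rng: np.random.Generator, meanlog: float, sdlog: float,
                    n: int, minimum: int = 1) -> np.ndarray:
    return np.maximum(minimum, np.rint(rng.lognormal(meanlog, sdlog, n))).astype(int)


def _scaffold_classes(params: ArchitectureParams) -> Dict[str, str]:
    n_x = max(1, round(params.fraction_x * params.n_scaffolds))
    classes = {}
    for i in range(params.n_scaffolds):
        name = f"scf{i + 1:02d}"
        classes[name] = "X" if i < n_x else "autosome"
    return classes


def _simulate_ancestor(params: ArchitectureParams,
                       rng: np.random.Generator) -> List[_AncestorGene]:
    classes = list(_scaffold_classes(params).values())
    per_scaffold = np.full(params.n_scaffolds, params.n_genes // params.n_scaffolds)
    per_scaffold[: params.n_genes % params.n_scaffolds] += 1
    genes: List[_AncestorGene] = []
    idx = 0
    for scf, n in enumerate(per_scaffold):
        cls = classes[scf]
        intron_mu = math.log(params.intron_median_x if cls == "X"
                             else params.intron_median_autosome)
        gap_mu = math.log(params.intergenic_median_x if cls == "X"
                          else params.intergenic_median_autosome)
        exon_counts = 1 + rng.poisson(params.exon_count_mean - 1.0, n)
        gap_lens = _lognormal_ints(rng, gap_mu, params.intergenic_sdlog, n)
        strands = rng.choice(["+", "-"], n)
        for j in range(n):
            k = int(exon_counts[j])
            genes.append(_AncestorGene(
                group=f"og{idx:05d}",
                scaffold=scf,
                strand=str(strands[j]),
                exon_lens=_lognormal_ints(
                    rng, params.exon_length_meanlog, params.exon_length_sdlog,
                    k, minimum=30).tolist(),
                intron_lens=_lognormal_ints(
                    rng, intron_mu, params.intron_sdlog, max(0, k - 1),
                    minimum=10).tolist(),
                gap_len=int(gap_lens[j]),
            ))
            idx += 1
    return genes


def _spliced_to_genomic(exons: List[Interval], lo: int, hi: int) -> List[Interval]:
    """Map spliced offsets [lo, hi) onto genomic intervals across exons."""
    out: List[Interval] = []
    offset = 0
    for ex in exons:
        ex_lo, ex_hi = offset, offset + ex.length
        a, b = max(lo, ex_lo), min(hi, ex_hi)
        if a < b:
            out.append(Interval(ex.seqid, ex.start + (a - ex_lo),
                                ex.start + (b - ex_lo)))
        offset = ex_hi
    return out


def _build_gene(gene_id: str, seqid: str, strand: str, cursor: int,
                exon_lens: Sequence[int], intron_lens: Sequence[int],
                utr5_max: int, utr3_max: int) -> Tuple[Gene, int]:
    """Lay one single-transcript gene down at ``cursor``; return it and its end."""
    exons: List[Interval] = []
    pos = cursor
    for i, elen in enumerate(exon_lens):
        exons.append(Interval(seqid, pos, pos + elen))
        pos += elen
        if i < len(intron_lens):
            pos += intron_lens[i]
    spliced = sum(exon_lens)
    # Split the spliced transcript into UTR5 / CDS / UTR3 with CDS % 3 == 0.
    u5 = min(utr5_max, spliced // 4)
    u3 = min(utr3_max, spliced // 4)
    cds_len = spliced - u5 - u3
    u3 += cds_len % 3
    cds_len -= cds_len % 3
    if strand == "+":
        utr5 = _spliced_to_genomic(exons, 0, u5)
        cds = _spliced_to_genomic(exons, u5, u5 + cds_len)
        utr3 = _spliced_to_genomic(exons, u5 + cds_len, spliced)
    else:  # 5' end of the transcript is at the genomic right
        utr3 = _spliced_to_genomic(exons, 0, u3)
        cds = _spliced_to_genomic(exons, u3, u3 + cds_len)
        utr5 = _spliced_to_genomic(exons, u3 + cds_len, spliced)
    tx = Transcript(id=f"{gene_id}.t1", gene_id=gene_id, seqid=seqid,
                    strand=strand, start=cursor, end=pos,
                    exons=exons, cds=cds, utr5=utr5, utr3=utr3)
    gene = Gene(id=gene_id, seqid=seqid, strand=strand, start=cursor, end=pos,
                transcripts=[tx])
    return gene, pos


def _realize_species(sp: SpeciesParams, ancestor: List[_AncestorGene],
                     params: ArchitectureParams, rng: np.random.Generator,
                     classes: Dict[str, str],
                     truth: GroundTruth) -> GenomeAnnotation:
    scf_names = list(classes)
    n = len(ancestor)
    n_drop = round(sp.gene_loss * n)
    dropped = set(rng.choice(n, size=n_drop, replace=False)) if n_drop else set()

    # translocations move a surviving gene to a uniformly chosen other scaffold
    placement: Dict[int, int] = {}
    translocated: Set[str] = set()
    for i, g in enumerate(ancestor):
        if i in dropped:
            continue
        scf = g.scaffold
        if sp.translocation_rate and rng.random() < sp.translocation_rate:
            others = [s for s in range(params.n_scaffolds) if s != scf]
            scf = int(rng.choice(others))
            translocated.add(f"{sp.name}_{g.group}")
        placement[i] = scf

    per_scaffold: Dict[int, List[int]] = {s: [] for s in range(params.n_scaffolds)}
    for i in sorted(placement):  # ancestral order preserved; movers appended
        if placement[i] == ancestor[i].scaffold:
            per_scaffold[placement[i]].append(i)
    for i in sorted(placement):
        if placement[i] != ancestor[i].scaffold:
            per_scaffold[placement[i]].append(i)

    genes: Dict[str, Gene] = {}
    seq_lengths: Dict[str, int] = {}
    exonic = intronic = intergenic = 0
    for scf in range(params.n_scaffolds):
        seqid = scf_names[scf]
        cls = classes[seqid]
        scale = sp.intron_scale_x if cls == "X" else sp.intron_scale_autosome
        flank = ancestor[per_scaffold[scf][0]].gap_len if per_scaffold[scf] else 100
        cursor = flank
        intergenic += flank
        for i in per_scaffold[scf]:
            anc = ancestor[i]
            introns = [max(1, round(l * scale)) for l in anc.intron_lens]
            gid = f"{sp.name}_{anc.group}"
            gene, end = _build_gene(gid, seqid, anc.strand, cursor,
                                    anc.exon_lens, introns,
                                    params.utr5_max, params.utr3_max)
            genes[gid] = gene
            exonic += sum(anc.exon_lens)
            intronic += sum(introns)
            intergenic += anc.gap_len
            cursor = end + anc.gap_len
        seq_lengths[seqid] = int(cursor)

    truth.deleted_genes[sp.name] = {f"{sp.name}_{ancestor[i].group}"
                                    for i in dropped}
    truth.translocated_genes[sp.name] = translocated
    truth.content[sp.name] = ContentTruth(
        gene_count=len(genes), exonic_bp=exonic, intronic_bp=intronic,
        intergenic_bp=intergenic, total_bp=sum(seq_lengths.values()))
    return GenomeAnnotation(seq_lengths=seq_lengths, genes=genes,
                            chrom_class=dict(classes))


def _plant_repeats(annotation: GenomeAnnotation, params: ArchitectureParams,
                   rng: np.random.Generator) -> Tuple[IntervalSet, List[str]]:
    """Repeat intervals at ~repeat_density, drawn from a few TE 'families'."""
    motifs = ["".join(rng.choice(_BASES, 25)) for _ in range(params.te_family_count)]
    intervals: List[Interval] = []
    families: List[str] = []
    for seqid, length in annotation.seq_lengths.items():
        target = params.repeat_density * length
        covered = 0
        while covered < target:
            rlen = int(_lognormal_ints(rng, params.repeat_length_meanlog,
                                       params.repeat_length_sdlog, 1,
                                       minimum=50)[0])
            rlen = min(rlen, length - 1)
            start = int(rng.integers(0, length - rlen))
            fam = int(rng.integers(0, params.te_family_count))
            intervals.append(Interval(seqid, start, start + rlen))
            families.append(f"TE{fam + 1}")
            covered += rlen
    _ = motifs  # motif identity only matters when sequence is emitted
    return IntervalSet(intervals), families


def _emit_sequence(annotation: GenomeAnnotation, repeats: IntervalSet,
                   params: ArchitectureParams,
                   rng: np.random.Generator) -> Dict[str, str]:
    gc = params.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    sequences: Dict[str, str] = {}
    motifs = {f"TE{i + 1}": "".join(rng.choice(_BASES, 25))
              for i in range(params.te_family_count)}
    tiles = {fam: (motif * 4000) for fam, motif in motifs.items()}
    for seqid, length in annotation.seq_lengths.items():
        arr = rng.choice(_BASES, size=length, p=probs)
        for iv in repeats.intervals(seqid):
            fam = f"TE{1 + (iv.start % params.te_family_count)}"
            arr[iv.start:iv.end] = list(tiles[fam][: iv.length])
        sequences[seqid] = "".join(arr)
    return sequences


def generate_genomes(params: ArchitectureParams,
                     outdir: Optional[str | Path] = None,
                     emit_sequence: bool = True) -> SimulationResult:
    """Simulate every species in ``params`` and (optionally) write files.

    Returns in-memory annotations, the ortholog table over surviving genes,
    and the :class:`GroundTruth`.  With ``outdir`` set, writes per-species
    FASTA / GFF3 / repeat BED, a shared ortholog TSV, a chromosome-class TSV
    and a manifest JSON naming every file and the seed.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    classes = _scaffold_classes(params)
    ancestor = _simulate_ancestor(params, rng)
    truth = GroundTruth(chrom_class=dict(classes))

    species: Dict[str, SpeciesBundle] = {}
    for sp in params.species:
        ann = _realize_species(sp, ancestor, params, rng, classes, truth)
        repeats, _families = _plant_repeats(ann, params, rng)
        ann.repeats = repeats
        truth.content[sp.name].repeat_bp = repeats.total_length
        seqs = _emit_sequence(ann, repeats, params, rng) if emit_sequence else None
        species[sp.name] = SpeciesBundle(name=sp.name, annotation=ann,
                                         sequences=seqs)

    # ortholog desert: genes of the FIRST species overlapping the planted
    # window keep their annotation but lose their orthology records
    desert_groups: Set[str] = set()
    first = params.species[0].name
    if params.desert_scaffold is not None and params.desert_bp > 0:
        seqid = list(classes)[params.desert_scaffold]
        ann = species[first].annotation
        length = ann.seq_lengths[seqid]
        mid = length // 2
        window = Interval(seqid, max(0, mid - params.desert_bp // 2),
                          min(length, mid + params.desert_bp // 2))
        truth.desert_regions[first] = window
        for g in ann.genes.values():
            if g.seqid == seqid and g.span.overlaps(window):
                desert_groups.add(g.id.split("_", 1)[1])

    rows = []
    for anc in ancestor:
        if anc.group in desert_groups:
            continue
        members = {}
        for sp in params.species:
            gid = f"{sp.name}_{anc.group}"
            g = species[sp.name].annotation.genes.get(gid)
            if g is not None:
                members[sp.name] = gid
                rows.append({"gene_id": gid, "species": sp.name,
                             "seqid": g.seqid, "start": g.start, "end": g.end,
                             "group": anc.group})
        if len(members) > 1:
            truth.ortholog_groups[anc.group] = members
    ortho = pd.DataFrame(rows, columns=["gene_id", "species", "seqid",
                                        "start", "end", "group"])

    result = SimulationResult(params=params, species=species,
                              ortholog_table=ortho, truth=truth)
    if outdir is not None:
        _write_bundle(result, Path(outdir))
    return result


def _write_bundle(result: SimulationResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: Dict[str, object] = {"seed": result.params.seed, "files": {}}
    files: Dict[str, str] = {}
    for name, bundle in result.species.items():
        gff = outdir / f"{name}.gff3"
        write_gff3(bundle.annotation, gff)
        bed = outdir / f"{name}.repeats.bed"
        write_bed(bundle.annotation.repeats, bed)
        bundle.files["gff3"] = files[f"{name}.gff3"] = str(gff)
        bundle.files["repeats"] = files[f"{name}.repeats.bed"] = str(bed)
        if bundle.sequences is not None:
            fa = outdir / f"{name}.fasta"
            write_fasta(bundle.sequences, fa)
            bundle.files["fasta"] = files[f"{name}.fasta"] = str(fa)
    ortho_path = outdir / "orthologs.tsv"
    write_ortholog_table(result.ortholog_table, ortho_path)
    files["orthologs.tsv"] = str(ortho_path)
    classes_path = outdir / "chrom_classes.tsv"
    with open(classes_path, "w") as out:
        for seqid, cls in result.truth.chrom_class.items():
            out.write(f"{seqid}\t{cls}\n")
    files["chrom_classes.tsv"] = str(classes_path)
    manifest["files"] = files
    manifest["params"] = _params_dict(result.params)
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    result.manifest_path = str(manifest_path)


def _params_dict(params: ArchitectureParams) -> dict:
    d = asdict(params)
    d["species"] = [asdict(sp) for sp in params.species]
    return d


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def generate_reads(sequences: Mapping[str, str], coverage: float,
                   read_len: int = 100, insert: int = 180,
                   error_rate: float = 0.0,
                   contaminant: Optional[Mapping[str, str]] = None,
                   contaminant_fraction: float = 0.0,
                   seed: int = 0,
                   out_prefix: Optional[str | Path] = None,
                   truth: Optional[GroundTruth] = None,
                   ) -> Tuple[List[Tuple[str, str, str]], List[Tuple[str, str, str]]]:
    """Paired-end reads from short overlapping fragments.

    Fragments of ``insert`` bp are sampled uniformly over the genome; R1 is
    the fragment's first ``read_len`` bases, R2 the reverse complement of its
    last ``read_len``.  Substitution errors are planted per base at
    ``error_rate``; a ``contaminant_fraction`` of pairs is drawn from the
    contaminant genome and recorded in ``truth.contaminant_reads``.
    Returns the two mates as lists of ``(name, sequence, quality)``; writes
    FASTQ when ``out_prefix`` is given.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(seed)
    usable = {k: v for k, v in sequences.items() if len(v) >= insert}
    for k in set(sequences) - set(usable):
        logger.warning("scaffold %s shorter than the %d bp insert; skipped",
                       k, insert)
    if not usable:
        raise ValueError("no scaffold long enough for the requested insert")
    total = sum(len(v) for v in usable.values())
    n_pairs = max(1, round(coverage * total / (2 * read_len)))
    n_cont = round(contaminant_fraction * n_pairs) if contaminant else 0

    def _sample(pool: Mapping[str, str], n: int, tag: str, start_index: int):
        names = list(pool)
        weights = np.array([len(pool[s]) - insert + 1 for s in names], float)
        weights /= weights.sum()
        choices = rng.choice(len(names), size=n, p=weights)
        r1, r2 = [], []
        for j, ci in enumerate(choices):
            seq = pool[names[ci]]
            start = int(rng.integers(0, len(seq) - insert + 1))
            frag = seq[start:start + insert]
            a, b = frag[:read_len], _revcomp(frag[-read_len:])
            if error_rate > 0:
                a, b = (_mutate(s, error_rate, rng) for s in (a, b))
            rid = f"{tag}_{start_index + j:07d}"
            qual = "I" * read_len
            r1.append((rid, a, qual))
            r2.append((rid, b, qual))
        return r1, r2

    r1, r2 = _sample(usable, n_pairs - n_cont, "frag", 0)
    if n_cont:
        cusable = {k: v for k, v in contaminant.items() if len(v) >= insert}
        c1, c2 = _sample(cusable, n_cont, "cont", n_pairs - n_cont)
        r1 += c1
        r2 += c2
        if truth is not None:
            truth.contaminant_reads.update(name for name, _, _ in c1)
    if out_prefix is not None:
        for mate, reads in (("1", r1), ("2", r2)):
            path = Path(f"{out_prefix}_R{mate}.fastq")
            with open(path, "w") as out:
                for name, seq, qual in reads:
                    out.write(f"@{name}/{mate}\n{seq}\n+\n{qual}\n")
    return r1, r2


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        current = arr[i].decode()
        alternatives = [b for b in "ACGT" if b != current]
        arr[i] = rng.choice(alternatives).encode()
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# Variant sites (all-sites VCF)
# ---------------------------------------------------------------------------

def generate_vcf(annotation: GenomeAnnotation,
                 per_class_het_rate: Mapping[str, float],
                 depth_mean: float = 60.0,
                 depth_overdispersion: float = 0.3,
                 high_depth_fraction: float = 0.003,
                 low_qual_fraction: float = 0.003,
                 base_quality: float = 30.0,
                 seed: int = 0,
                 out_path: str | Path = "sites.vcf",
                 tss_window_bp: int = 200) -> Dict[str, Dict[str, int]]:
    """Emit an all-sites VCF with Bernoulli-planted variants per site class.

    Every genomic position gets a record with a depth drawn from a gamma-
    mixed Poisson (negative-binomial-like) model; ``high_depth_fraction`` of
    sites are pushed above 600x and ``low_qual_fraction`` below Q10 so the
    downstream filters have work to do.  Returns per-class truth counts
    ``{class: {planted, sites}}``.
    """
    from .variants import SITE_CLASSES, classify_sites

    unknown = set(per_class_het_rate) - set(SITE_CLASSES)
    if unknown:
        raise ValueError(f"unknown site classes: {sorted(unknown)}")
    for rate in per_class_het_rate.values():
        if not 0.0 <= rate <= 0.05:
            raise ValueError("heterozygosity rates must be in [0, 0.05]")
    rng = np.random.default_rng(seed)
    class_map = classify_sites(annotation, tss_window_bp=tss_window_bp)
    rate_vector = np.zeros(len(SITE_CLASSES))
    for cls, rate in per_class_het_rate.items():
        rate_vector[SITE_CLASSES.index(cls)] = rate

    truth_counts = {cls: {"planted": 0, "sites": 0} for cls in SITE_CLASSES}
    shape = 1.0 / max(depth_overdispersion, 1e-9)
    with open(out_path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write('##INFO=<ID=DP,Number=1,Type=Integer,'
                  'Description="Raw read depth">\n')
        for seqid in annotation.seq_lengths:
            out.write(f"##contig=<ID={seqid},"
                      f"length={annotation.seq_lengths[seqid]}>\n")
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for seqid, length in annotation.seq_lengths.items():
            codes = class_map[seqid]
            rates = rate_vector[codes]
            is_var = rng.random(length) < rates
            lam = rng.gamma(shape, depth_mean / shape, length)
            depth = rng.poisson(lam)
            high = rng.random(length) < high_depth_fraction
            depth[high] = 601 + rng.integers(0, 400, int(high.sum()))
            qual = np.full(length, base_quality)
            low = rng.random(length) < low_qual_fraction
            qual[low] = 5.0
            for cls_idx in range(len(SITE_CLASSES)):
                mask = codes == cls_idx
                truth_counts[SITE_CLASSES[cls_idx]]["sites"] += int(mask.sum())
                truth_counts[SITE_CLASSES[cls_idx]]["planted"] += int(
                    is_var[mask].sum())
            alts = np.where(is_var, "A", ".")
            lines = [
                f"{seqid}\t{pos + 1}\t.\tN\t{alts[pos]}\t{qual[pos]:g}\t.\t"
                f"DP={depth[pos]}"
                for pos in range(length)
            ]
            out.write("\n".join(lines))
            out.write("\n")
    return truth_counts


# ---------------------------------------------------------------------------
# RIL genotypes
# ---------------------------------------------------------------------------

def generate_ril_genotypes(n_lines: int, n_markers: int,
                           scaffold_map: Mapping[str, str],
                           distorted_scaffolds: Iterable[str] = (),
                           distortion_level: float = 0.9,
                           missing_rate: float = 0.05,
                           het_rate: float = 0.02,
                           seed: int = 0,
                           out_path: Optional[str | Path] = None,
                           ) -> pd.DataFrame:
    """Markers x lines genotype matrix with planted segregation distortion.

    ``scaffold_map`` assigns each marker id to a scaffold; markers on
    ``distorted_scaffolds`` draw the parental A allele at ``distortion_level``
    instead of 0.5.  Heterozygous calls (residual in RILs) and missing data
    are applied i.i.d. at ``het_rate`` and ``missing_rate``.
    """
    if n_lines < 2:
        raise ValueError("need at least 2 RIL lines")
    if not 0.5 < distortion_level <= 1.0:
        raise ValueError("distortion_level must be in (0.5, 1]")
    markers = list(scaffold_map)[:n_markers]
    if len(markers) < n_markers:
        raise ValueError("scaffold_map names fewer markers than n_markers")
    distorted = set(distorted_scaffolds)
    rng = np.random.default_rng(seed)
    lines = [f"RIL{i + 1:03d}" for i in range(n_lines)]
    data = np.empty((n_markers, n_lines), dtype="<U1")
    for mi, marker in enumerate(markers):
        p = distortion_level if scaffold_map[marker] in distorted else 0.5
        calls = np.where(rng.random(n_lines) < p, "A", "B")
        hets = rng.random(n_lines) < het_rate
        calls[hets] = "H"
        miss = rng.random(n_lines) < missing_rate
        calls[miss] = "-"
        data[mi] = calls
    df = pd.DataFrame(data, index=pd.Index(markers, name="marker"),
                      columns=lines)
    if out_path is not None:
        write_genotype_matrix(df, out_path)
    return df
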