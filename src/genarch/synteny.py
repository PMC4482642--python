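"""Synteny blocks from ortholog positions, chromosome-retention accounting,
divergent-region scanning and the indel size-bias test.

Blocks are chains of orthologous genes: sorted by position in species A, a
pair joins the running block when its gap to the previous member is within
``join_distance`` (50 kb by default) in *both* genomes and the chromosome
matches in both.  Gap means the nucleotide distance between gene ends, not
midpoints — the strictest consistent reading.  Single-gene blocks sitting on
non-homologous chromosomes (lone translocations) can be filtered out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import Interval
from .io import GenomeAnnotation, logger
from .architecture import TestResult

DEFAULT_JOIN_DISTANCE = 50_000


@dataclass(frozen=True)
class GenePos:
    gene_id: str
    seqid: str
    start: int
    end: int


@dataclass(frozen=True)
class OrthologPair:
    """A 1:1 ortholog with its position in each of the two species."""

    a: GenePos
    b: GenePos


@dataclass
class SyntenyBlock:
    species_pair: Tuple[str, str]
    members: List[OrthologPair]
    same_chromosome: bool = True

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def span_a(self) -> int:
        return (max(m.a.end for m in self.members)
                - min(m.a.start for m in self.members))

    @property
    def span_b(self) -> int:
        return (max(m.b.end for m in self.members)
                - min(m.b.start for m in self.members))


# ---------------------------------------------------------------------------
# Pair construction
# ---------------------------------------------------------------------------

def pairs_from_table(table: pd.DataFrame, species_a: str, species_b: str,
                     group_col: str = "group") -> List[OrthologPair]:
    """Build 1:1 ortholog pairs from a position table.

    The table holds one row per gene per species (columns ``gene_id species
    seqid start end`` plus an ortholog-group column).  Groups with several
    members in one species are reduced to one representative by longest gene
    (ties by lexicographic gene id) — a reciprocal-best-by-length reduction.
    """
    if group_col not in table.columns:
        raise ValueError(f"ortholog table needs a {group_col!r} column")
    pairs: List[OrthologPair] = []
    for _, grp in table.groupby(group_col, sort=True):
        best: Dict[str, GenePos] = {}
        for row in grp.itertuples(index=False):
            pos = GenePos(row.gene_id, row.seqid, int(row.start), int(row.end))
            if row.species in (species_a, species_b):
                cur = best.get(row.species)
                key = (-(pos.end - pos.start), pos.gene_id)
                if cur is None or key < (-(cur.end - cur.start), cur.gene_id):
                    best[row.species] = pos
        if species_a in best and species_b in best:
            pairs.append(OrthologPair(a=best[species_a], b=best[species_b]))
    return pairs


# ---------------------------------------------------------------------------
# Chaining
# ---------------------------------------------------------------------------

def _gap(u: GenePos, v: GenePos) -> int:
    """Nucleotide distance between two gene bodies (0 when they overlap)."""
    return max(0, max(u.start, v.start) - min(u.end, v.end))


def _compatible(u: OrthologPair, v: OrthologPair, join_distance: int,
                both_genomes: bool) -> bool:
    if u.a.seqid != v.a.seqid or u.b.seqid != v.b.seqid:
        return False
    if _gap(u.a, v.a) > join_distance:
        return False
    if both_genomes and _gap(u.b, v.b) > join_distance:
        return False
    return True


def chain_blocks(pairs: Sequence[OrthologPair],
                 join_distance: int = DEFAULT_JOIN_DISTANCE,
                 species_pair: Tuple[str, str] = ("A", "B"),
                 both_genomes: bool = True) -> List[SyntenyBlock]:
    """Chain ortholog pairs into synteny blocks.

    Pairs are sorted by species-A position; a pair extends the current block
    iff its gap to the previous member is within ``join_distance`` (in both
    genomes unless ``both_genomes=False``) and chromosomes match in both.
    Input order is irrelevant; every pair lands in exactly one block.
    """
    ordered = sorted(pairs, key=lambda p: (p.a.seqid, p.a.start, p.a.gene_id))
    blocks: List[SyntenyBlock] = []
    for pair in ordered:
        if blocks and _compatible(blocks[-1].members[-1], pair,
                                  join_distance, both_genomes):
            blocks[-1].members.append(pair)
        else:
            blocks.append(SyntenyBlock(species_pair=species_pair,
                                       members=[pair]))
    return blocks


def filter_single_translocations(blocks: Iterable[SyntenyBlock],
                                 homology_map: Optional[Mapping[str, str]] = None,
                                 ) -> Tuple[List[SyntenyBlock], int]:
    """Drop size-1 blocks whose two positions sit on non-homologous
    chromosomes (lone translocations); returns (kept, n_removed).

    ``homology_map`` maps species-A seqids to their homologous species-B
    seqid; identity is assumed when omitted.  Multi-gene blocks are on one
    chromosome pair by construction (asserted).
    """
    kept: List[SyntenyBlock] = []
    removed = 0
    for block in blocks:
        a_chrom = block.members[0].a.seqid
        b_chrom = block.members[0].b.seqid
        assert all(m.a.seqid == a_chrom and m.b.seqid == b_chrom
                   for m in block.members), "block spans chromosomes"
        homolog = (homology_map or {}).get(a_chrom, a_chrom)
        block.same_chromosome = (b_chrom == homolog)
        if block.size == 1 and not block.same_chromosome:
            removed += 1
        else:
            kept.append(block)
    if removed:
        logger.info("removed %d single-gene translocation(s)", removed)
    return kept, removed


# ---------------------------------------------------------------------------
# Retention / divergence / indel bias
# ---------------------------------------------------------------------------

def chromosome_retention(pairs: Sequence[OrthologPair],
                         homology_map: Optional[Mapping[str, str]] = None,
                         ) -> Tuple[float, pd.DataFrame]:
    """Fraction of ortholog pairs found on homologous chromosomes.

    Pairs whose species-A chromosome has no entry in the homology map are
    counted as unassigned and excluded from the denominator.  Returns the
    fraction and a per-chromosome breakdown.
    """
    if not pairs:
        raise ValueError("no ortholog pairs")
    counts: Dict[str, Dict[str, int]] = {}
    unassigned = 0
    for pair in pairs:
        if homology_map is None:
            homolog = pair.a.seqid
        elif pair.a.seqid in homology_map:
            homolog = homology_map[pair.a.seqid]
        else:
            unassigned += 1
            continue
        row = counts.setdefault(pair.a.seqid, {"same": 0, "different": 0})
        row["same" if pair.b.seqid == homolog else "different"] += 1
    if unassigned:
        logger.warning("%d pair(s) on unmapped chromosomes excluded", unassigned)
    total = sum(r["same"] + r["different"] for r in counts.values())
    if total == 0:
        raise ValueError("no pairs on mapped chromosomes")
    same = sum(r["same"] for r in counts.values())
    breakdown = pd.DataFrame([
        {"seqid": seqid, "same": r["same"], "different": r["different"]}
        for seqid, r in sorted(counts.items())
    ])
    return same / total, breakdown


@dataclass(frozen=True)
class DivergentRegion:
    interval: Interval
    n_genes: int
    n_orthologous: int


def divergent_regions(annotation: GenomeAnnotation,
                      orthologous_genes: Iterable[str],
                      window_bp: int = 100_000,
                      min_length_bp: int = 300_000,
                      max_density: float = 0.1) -> List[DivergentRegion]:
    """Scan for ortholog-poor regions with tiling windows.

    A window is flagged when the fraction of its genes carrying an ortholog
    is at most ``max_density`` (a geneless window is flagged too); maximal
    runs of flagged windows of total length >= ``min_length_bp`` are
    reported with their gene and ortholog counts.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    has_ortholog = set(orthologous_genes)
    regions: List[DivergentRegion] = []
    for seqid, length in annotation.seq_lengths.items():
        genes = sorted((g for g in annotation.genes.values()
                        if g.seqid == seqid), key=lambda g: g.start)
        n_windows = max(1, -(-length // window_bp))
        flagged = np.zeros(n_windows, dtype=bool)
        for w in range(n_windows):
            lo, hi = w * window_bp, min(length, (w + 1) * window_bp)
            in_window = [g for g in genes if g.start < hi and g.end > lo]
            if not in_window:
                flagged[w] = True
                continue
            with_orth = sum(1 for g in in_window if g.id in has_ortholog)
            flagged[w] = (with_orth / len(in_window)) <= max_density
        w = 0
        while w < n_windows:
            if not flagged[w]:
                w += 1
                continue
            run_start = w
            while w < n_windows and flagged[w]:
                w += 1
            lo = run_start * window_bp
            hi = min(length, w * window_bp)
            if hi - lo >= min_length_bp:
                in_region = [g for g in genes if g.start < hi and g.end > lo]
                regions.append(DivergentRegion(
                    interval=Interval(seqid, lo, hi),
                    n_genes=len(in_region),
                    n_orthologous=sum(1 for g in in_region
                                      if g.id in has_ortholog)))
    return regions


def indel_size_bias(blocks: Sequence[SyntenyBlock],
                    min_members: int = 2) -> Tuple[TestResult, pd.DataFrame]:
    """Per-block span log-ratio r = ln(span_a / span_b), tested against 0
    with the one-sample Wilcoxon signed-rank test.

    Blocks under ``min_members`` members or with zero span are excluded
    (logged).  Returns the test plus a per-block table with spans, ratio and
    log-ratio; the table is what an aligned-span scatter plots from.
    """
    rows = []
    excluded = 0
    for i, block in enumerate(blocks):
        if block.size < min_members:
            continue
        sa, sb = block.span_a, block.span_b
        if sa <= 0 or sb <= 0:
            excluded += 1
            continue
        rows.append({"block": i, "members": block.size,
                     "span_a": sa, "span_b": sb,
                     "ratio": sa / sb, "log_ratio": np.log(sa / sb)})
    if excluded:
        logger.warning("%d block(s) with zero span excluded", excluded)
    table = pd.DataFrame(rows, columns=["block", "members", "span_a",
                                        "span_b", "ratio", "log_ratio"])
    if len(table) < 5:
        raise ValueError("need >=5 multi-gene blocks for the bias test")
    r = table["log_ratio"].to_numpy()
    if np.allclose(r, 0.0):
        result = TestResult(statistic=0.0, df=1, p_raw=1.0, p_adjusted=1.0,
                            method="wilcoxon-signed-rank",
                            groups=("log span ratio", "0"), degenerate=True)
    else:
        res = stats.wilcoxon(r, alternative="two-sided")
        result = TestResult(statistic=float(res.statistic), df=1,
                            p_raw=float(res.pvalue),
                            p_adjusted=float(res.pvalue),
                            method="wilcoxon-signed-rank",
                            groups=("log span ratio", "0"))
    table.attrs["median_ratio"] = float(table["ratio"].median())
    return result, table


def blocks_to_frame(blocks: Sequence[SyntenyBlock]) -> pd.DataFrame:
    return pd.DataFrame([{
        "block": i,
        "members": b.size,
        "chrom_a": b.members[0].a.seqid,
        "chrom_b": b.members[0].b.seqid,
        "start_a": min(m.a.start for m in b.members),
        "end_a": max(m.a.end for m in b.members),
        "span_a": b.span_a if b.size > 1 else 0,
        "span_b": b.span_b if b.size > 1 else 0,
        "same_chromosome": b.same_chromosome,
        "genes_a": ",".join(m.a.gene_id for m in b.members),
    } for i, b in enumerate(blocks)])
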