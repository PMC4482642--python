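"""Gene-structure and intergenic-space statistics with the nonparametric
test battery: Kruskal-Wallis across groups and Bonferroni-corrected pairwise
Wilcoxon rank-sum tests, compared within species between the X chromosome
and autosomes and between species per chromosome class.

Length distributions here are counts of nucleotides — heavy-tailed, severely
heteroscedastic and unbalanced between groups — which is why only rank-based
one-way tests are run.

The Kruskal-Wallis H statistic is computed in-house (tie-corrected rank
formula, chi-square upper tail with df = k - 1); rank-sum p-values come from
scipy (exact when both samples are <= 8 without ties, normal approximation
with continuity correction otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import IntervalSet
from .io import GenomeAnnotation, logger

EXACT_MAX_N = 8  # exact rank-sum distribution up to this group size


@dataclass(frozen=True)
class TestResult:
    """One group comparison: statistic, df, raw and adjusted p."""

    statistic: float
    df: int
    p_raw: float
    p_adjusted: float
    method: str
    groups: Tuple[str, ...]
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_raw <= 1.0 and 0.0 <= self.p_adjusted <= 1.0):
            raise ValueError("p-values must lie in [0, 1]")
        if self.p_adjusted < self.p_raw:
            raise ValueError("adjusted p below raw p")


@dataclass(frozen=True)
class GeneMetrics:
    """Size metrics of one gene, from its canonical transcript."""

    gene_id: str
    species: str
    chrom_class: str
    exon_sum_bp: int
    intron_sum_bp: int
    span_bp: int
    protein_aa: Optional[int]


# ---------------------------------------------------------------------------
# Distributions
# ---------------------------------------------------------------------------

def intergenic_spaces(annotation: GenomeAnnotation,
                      class_filter: Optional[str] = None) -> List[int]:
    """Gaps between consecutive gene spans per scaffold.

    Overlapping genes are unioned first; flanks at scaffold ends and
    zero-length gaps are excluded.  ``class_filter`` restricts to scaffolds
    of one chromosome class ("autosome" or "X").
    """
    gaps: List[int] = []
    spans = IntervalSet(annotation.gene_spans())
    for seqid in spans.seqids:
        if class_filter is not None and annotation.class_of(seqid) != class_filter:
            continue
        merged = list(spans.intervals(seqid))
        for a, b in zip(merged, merged[1:]):
            if b.start > a.end:
                gaps.append(b.start - a.end)
    return gaps


def gene_metrics(annotation: GenomeAnnotation, species: str = "",
                 ortholog_filter: Optional[Set[str]] = None) -> List[GeneMetrics]:
    """One record per gene using its canonical (longest summed-exon)
    transcript; genes without CDS keep size metrics but no protein length."""
    out: List[GeneMetrics] = []
    for gid in sorted(annotation.genes):
        if ortholog_filter is not None and gid not in ortholog_filter:
            continue
        gene = annotation.genes[gid]
        tx = gene.canonical_transcript()
        cds = tx.cds_sum
        out.append(GeneMetrics(
            gene_id=gid,
            species=species,
            chrom_class=annotation.class_of(gene.seqid),
            exon_sum_bp=tx.exon_sum,
            intron_sum_bp=sum(iv.length for iv in tx.introns()),
            span_bp=gene.end - gene.start,
            protein_aa=(cds // 3 - 1) if cds >= 6 else None,
        ))
    return out


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------

def kruskal_wallis(groups: Sequence[Sequence[float]],
                   names: Optional[Sequence[str]] = None) -> TestResult:
    """Kruskal-Wallis rank-sum test with tie correction.

    H = [12 / (N (N+1)) * sum R_i^2 / n_i - 3 (N+1)] / (1 - sum(t^3 - t)/(N^3 - N))
    with average ranks for ties; p from the chi-square upper tail at
    df = k - 1.  All-identical data is degenerate: H = 0, p = 1, flagged.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    sizes = [len(g) for g in groups]
    if min(sizes) < 1 or sum(sizes) < 3:
        raise ValueError("each group needs >=1 observation and total >= 3")
    names = tuple(names) if names is not None else tuple(
        f"group{i + 1}" for i in range(len(groups)))

    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n_total = pooled.size
    ranks = stats.rankdata(pooled)  # average ranks for ties
    df = len(groups) - 1

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    correction = 1.0 - tie_term / (n_total**3 - n_total)
    if correction == 0.0:  # every observation identical
        return TestResult(statistic=0.0, df=df, p_raw=1.0, p_adjusted=1.0,
                          method="kruskal-wallis", groups=names,
                          degenerate=True)

    h = 12.0 / (n_total * (n_total + 1))
    offset = 0
    accum = 0.0
    for size in sizes:
        r_sum = float(ranks[offset:offset + size].sum())
        accum += r_sum**2 / size
        offset += size
    h = (h * accum - 3.0 * (n_total + 1)) / correction
    p = float(stats.chi2.sf(h, df))
    return TestResult(statistic=h, df=df, p_raw=p, p_adjusted=p,
                      method="kruskal-wallis", groups=names)


def rank_sum_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact distribution when both samples are small (<= 8) and tie-free,
    otherwise the normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    if x.size <= EXACT_MAX_N and y.size <= EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.pvalue)


def pairwise_wilcoxon(groups: Sequence[Sequence[float]],
                      names: Optional[Sequence[str]] = None,
                      correction: str = "bonferroni") -> List[TestResult]:
    """Rank-sum test for every unordered pair, Bonferroni-adjusted.

    ``p_adjusted = min(1, p * m)`` with m = number of tested pairs; empty
    groups skip their pairs with a warning (and shrink m).
    """
    if correction != "bonferroni":
        raise ValueError("only bonferroni correction is supported")
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    names = list(names) if names is not None else [
        f"group{i + 1}" for i in range(len(groups))]
    pairs = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            if len(groups[i]) == 0 or len(groups[j]) == 0:
                logger.warning("pair (%s, %s) skipped: empty group",
                               names[i], names[j])
                continue
            pairs.append((i, j))
    m = len(pairs)
    results = []
    for i, j in pairs:
        x = np.asarray(groups[i], dtype=float)
        y = np.asarray(groups[j], dtype=float)
        p = rank_sum_p(x, y)
        w = float(stats.rankdata(np.concatenate([x, y]))[: x.size].sum())
        results.append(TestResult(
            statistic=w, df=1, p_raw=p, p_adjusted=min(1.0, p * m),
            method="wilcoxon-rank-sum", groups=(names[i], names[j])))
    return results


# ---------------------------------------------------------------------------
# The full battery
# ---------------------------------------------------------------------------

_METRICS = ("intergenic_space", "gene_span", "protein_size")


def _metric_values(annotation: GenomeAnnotation, metrics: List[GeneMetrics],
                   metric: str, chrom_class: str) -> List[float]:
    if metric == "intergenic_space":
        return [float(v) for v in intergenic_spaces(annotation, chrom_class)]
    if metric == "gene_span":
        return [float(m.span_bp) for m in metrics if m.chrom_class == chrom_class]
    if metric == "protein_size":
        return [float(m.protein_aa) for m in metrics
                if m.chrom_class == chrom_class and m.protein_aa is not None]
    raise ValueError(f"unknown metric {metric!r}")


def compare_architecture(annotations: Dict[str, GenomeAnnotation],
                         orthologs: Optional[Dict[str, Set[str]]] = None,
                         ) -> Tuple[pd.DataFrame, List[TestResult]]:
    """Within-species X-vs-autosome and between-species per-class battery.

    For each species and each metric (intergenic space, gene span, protein
    size) a Kruskal-Wallis X-vs-autosome test is run; for each chromosome
    class and metric, a between-species Kruskal-Wallis plus Bonferroni
    pairwise Wilcoxon tests.  Returns a summary table (mean/median per
    species x class x metric, n per cell) and the test results.
    ``orthologs`` optionally restricts gene-level metrics per species.
    """
    summaries = []
    tests: List[TestResult] = []
    per_species_metrics = {
        sp: gene_metrics(ann, species=sp,
                         ortholog_filter=None if orthologs is None
                         else orthologs.get(sp))
        for sp, ann in annotations.items()
    }

    values: Dict[Tuple[str, str, str], List[float]] = {}
    for sp, ann in annotations.items():
        for metric in _METRICS:
            for cls in ("autosome", "X"):
                vals = _metric_values(ann, per_species_metrics[sp], metric, cls)
                values[(sp, metric, cls)] = vals
                summaries.append({
                    "species": sp, "metric": metric, "chrom_class": cls,
                    "n": len(vals),
                    "mean": float(np.mean(vals)) if vals else float("nan"),
                    "median": float(np.median(vals)) if vals else float("nan"),
                })

    # within species: X vs autosome
    for sp in annotations:
        has_x = any(c == "X" for c in annotations[sp].chrom_class.values())
        if not has_x:
            logger.warning("species %s has no X-class scaffolds; "
                           "within-species comparison skipped", sp)
            continue
        for metric in _METRICS:
            auto = values[(sp, metric, "autosome")]
            x = values[(sp, metric, "X")]
            if not auto or not x or len(auto) + len(x) < 3:
                logger.warning("species %s metric %s: too few observations "
                               "(n=%d), comparison skipped",
                               sp, metric, len(auto) + len(x))
                continue
            res = kruskal_wallis([auto, x], names=(f"{sp}:autosome", f"{sp}:X"))
            tests.append(TestResult(
                statistic=res.statistic, df=res.df, p_raw=res.p_raw,
                p_adjusted=res.p_adjusted, groups=res.groups,
                method=f"kruskal-wallis[{metric}]",
                degenerate=res.degenerate))

    # between species per chromosome class
    species_names = list(annotations)
    if len(species_names) >= 2:
        for cls in ("autosome", "X"):
            for metric in _METRICS:
                groups = [values[(sp, metric, cls)] for sp in species_names]
                keep = [i for i, g in enumerate(groups) if g]
                if len(keep) < 2:
                    continue
                kept_groups = [groups[i] for i in keep]
                kept_names = [f"{species_names[i]}:{cls}" for i in keep]
                res = kruskal_wallis(kept_groups, names=kept_names)
                tests.append(TestResult(
                    statistic=res.statistic, df=res.df, p_raw=res.p_raw,
                    p_adjusted=res.p_adjusted, groups=res.groups,
                    method=f"kruskal-wallis[{metric}]",
                    degenerate=res.degenerate))
                for pw in pairwise_wilcoxon(kept_groups, names=kept_names):
                    tests.append(TestResult(
                        statistic=pw.statistic, df=pw.df, p_raw=pw.p_raw,
                        p_adjusted=pw.p_adjusted, groups=pw.groups,
                        method=f"wilcoxon-rank-sum[{metric}]"))

    return pd.DataFrame(summaries), tests


def tests_to_frame(tests: Iterable[TestResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "method": t.method,
        "groups": " vs ".join(t.groups),
        "statistic": t.statistic,
        "df": t.df,
        "p_raw": t.p_raw,
        "p_adjusted": t.p_adjusted,
        "degenerate": t.degenerate,
    } for t in tests])
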