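"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's interval algebra: they paint
per-base bitmaps (numpy boolean/uint8 arrays) or recount from scratch, so a
test comparing implementation to oracle exercises two independent routes.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pytest

from genarch.intervals import Interval
from genarch.io import GenomeAnnotation, Gene, Transcript


# ---------------------------------------------------------------------------
# Bitmap oracles
# ---------------------------------------------------------------------------

def bitmap_occupancy(intervals: Iterable[Interval],
                     seq_lengths: Dict[str, int]) -> Dict[str, np.ndarray]:
    """Per-base boolean coverage mask, one array per sequence."""
    masks = {s: np.zeros(n, dtype=bool) for s, n in seq_lengths.items()}
    for iv in intervals:
        masks[iv.seqid][iv.start:iv.end] = True
    return masks


def bitmap_total(intervals: Iterable[Interval],
                 seq_lengths: Dict[str, int]) -> int:
    return int(sum(m.sum() for m in
                   bitmap_occupancy(intervals, seq_lengths).values()))


# ---------------------------------------------------------------------------
# Annotation builder
# ---------------------------------------------------------------------------

def build_annotation(seq_lengths: Dict[str, int],
                     genes: Sequence[dict],
                     chrom_class: Dict[str, str] | None = None,
                     ) -> GenomeAnnotation:
    """Construct an annotation from compact gene dicts.

    Each gene dict: ``id``, ``seqid``, optional ``strand`` ('+'),
    ``transcripts``: list of dicts with ``id``, ``exons`` [(start, end)...],
    optional ``cds``, ``utr5``, ``utr3``.
    """
    out: Dict[str, Gene] = {}
    for g in genes:
        seqid = g["seqid"]
        strand = g.get("strand", "+")
        txs = []
        for t in g["transcripts"]:
            exons = [Interval(seqid, a, b) for a, b in t["exons"]]
            txs.append(Transcript(
                id=t["id"], gene_id=g["id"], seqid=seqid, strand=strand,
                start=min(iv.start for iv in exons),
                end=max(iv.end for iv in exons),
                exons=exons,
                cds=[Interval(seqid, a, b) for a, b in t.get("cds", [])],
                utr5=[Interval(seqid, a, b) for a, b in t.get("utr5", [])],
                utr3=[Interval(seqid, a, b) for a, b in t.get("utr3", [])]))
        out[g["id"]] = Gene(
            id=g["id"], seqid=seqid, strand=strand,
            start=min(t.start for t in txs), end=max(t.end for t in txs),
            transcripts=txs)
    ann = GenomeAnnotation(seq_lengths=dict(seq_lengths), genes=out,
                           chrom_class=dict(chrom_class or {}))
    ann.validate()
    return ann


def random_interval_fixture(rng: np.random.Generator, n: int = 50,
                            n_seqs: int = 3, seq_len: int = 2000,
                            ) -> Tuple[List[Interval], Dict[str, int]]:
    seq_lengths = {f"s{i}": seq_len for i in range(n_seqs)}
    intervals = []
    for _ in range(n):
        seqid = f"s{int(rng.integers(n_seqs))}"
        start = int(rng.integers(0, seq_len - 1))
        end = int(rng.integers(start + 1, min(seq_len, start + 200) + 1))
        intervals.append(Interval(seqid, start, end))
    return intervals, seq_lengths


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20150626)


@pytest.fixture
def two_gene_annotation() -> GenomeAnnotation:
    """100-bp scaffold with a 2-exon gene plus a single-exon gene."""
    return build_annotation(
        {"chr1": 100},
        [
            {"id": "g1", "seqid": "chr1", "transcripts": [
                {"id": "g1.t1", "exons": [(10, 20), (30, 40)],
                 "cds": [(12, 20), (30, 38)], "utr5": [(10, 12)],
                 "utr3": [(38, 40)]},
            ]},
            {"id": "g2", "seqid": "chr1", "strand": "-", "transcripts": [
                {"id": "g2.t1", "exons": [(60, 80)], "cds": [(63, 78)],
                 "utr5": [(78, 80)], "utr3": [(60, 63)]},
            ]},
        ],
        chrom_class={"chr1": "autosome"})
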