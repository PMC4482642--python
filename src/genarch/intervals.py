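"""Interval algebra on genomic coordinates.

All coordinates throughout the package are 0-based, half-open ``[start, end)``
— the BED convention.  GFF3 and VCF inputs are converted at the parsing
boundary (:mod:`genarch.io`).  Strand never enters length arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Mapping, Tuple


@dataclass(frozen=True, order=True)
class Interval:
    """Half-open genomic interval ``[start, end)`` on one sequence."""

    seqid: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.seqid}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval [{self.start}, {self.end}) on {self.seqid}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.seqid == other.seqid
            and self.start < other.end
            and other.start < self.end
        )


class IntervalSet:
    """Normalized per-seqid collection of intervals.

    After construction the intervals on each seqid are sorted,
    non-overlapping and non-adjacent (touching intervals are merged: a gap
    of zero bases is not a gap).
    """

    def __init__(self, intervals: Iterable[Interval] = ()) -> None:
        self._by_seqid: Dict[str, List[Tuple[int, int]]] = {}
        self._extend(intervals)

    def _extend(self, intervals: Iterable[Interval]) -> None:
        raw: Dict[str, List[Tuple[int, int]]] = {}
        for seqid, ivs in self._by_seqid.items():
            raw.setdefault(seqid, []).extend(ivs)
        for iv in intervals:
            raw.setdefault(iv.seqid, []).append((iv.start, iv.end))
        self._by_seqid = {s: _merge(sorted(v)) for s, v in raw.items()}

    # -- accessors ---------------------------------------------------------

    @property
    def seqids(self) -> List[str]:
        return sorted(self._by_seqid)

    def intervals(self, seqid: str | None = None) -> Iterator[Interval]:
        seqids = [seqid] if seqid is not None else self.seqids
        for s in seqids:
            for start, end in self._by_seqid.get(s, []):
                yield Interval(s, start, end)

    def __iter__(self) -> Iterator[Interval]:
        return self.intervals()

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_seqid.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self._by_seqid == other._by_seqid

    def __repr__(self) -> str:
        return f"IntervalSet({len(self)} intervals on {len(self._by_seqid)} seqids)"

    @property
    def total_length(self) -> int:
        return sum(e - s for v in self._by_seqid.values() for s, e in v)

    # -- algebra -----------------------------------------------------------

    def union(self, other: "IntervalSet | Iterable[Interval]" = ()) -> "IntervalSet":
        out = IntervalSet()
        out._by_seqid = dict(self._by_seqid)
        out._extend(other if not isinstance(other, IntervalSet) else list(other))
        return out

    def complement(self, seq_lengths: Mapping[str, int]) -> "IntervalSet":
        """Bases of each sequence in ``seq_lengths`` not covered by this set."""
        out: List[Interval] = []
        for seqid, length in seq_lengths.items():
            cursor = 0
            for start, end in self._by_seqid.get(seqid, []):
                if end > length:
                    raise ValueError(
                        f"interval [{start}, {end}) exceeds length {length} of {seqid}"
                    )
                if start > cursor:
                    out.append(Interval(seqid, cursor, start))
                cursor = end
            if cursor < length:
                out.append(Interval(seqid, cursor, length))
        return IntervalSet(out)

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        out: List[Interval] = []
        for seqid in self._by_seqid:
            a = self._by_seqid[seqid]
            b = other._by_seqid.get(seqid, [])
            i = j = 0
            while i < len(a) and j < len(b):
                lo = max(a[i][0], b[j][0])
                hi = min(a[i][1], b[j][1])
                if lo < hi:
                    out.append(Interval(seqid, lo, hi))
                if a[i][1] <= b[j][1]:
                    i += 1
                else:
                    j += 1
        return IntervalSet(out)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        bounds: Dict[str, int] = {
            s: max(e for _, e in v) for s, v in self._by_seqid.items()
        }
        for s, v in other._by_seqid.items():
            bounds[s] = max(bounds.get(s, 0), max(e for _, e in v))
        return self.intersect(other.complement(bounds))


def _merge(sorted_pairs: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    merged: List[Tuple[int, int]] = []
    for start, end in sorted_pairs:
        if merged and start <= merged[-1][1]:  # overlap or adjacency
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def union(intervals: Iterable[Interval]) -> IntervalSet:
    """Normalize an arbitrary interval collection (sort / merge / dedupe)."""
    return IntervalSet(intervals)


def complement(intervals: "IntervalSet | Iterable[Interval]",
               seq_lengths: Mapping[str, int]) -> IntervalSet:
    ivs = intervals if isinstance(intervals, IntervalSet) else IntervalSet(intervals)
    return ivs.complement(seq_lengths)
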