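"""Two-pass k-mer-spectrum read filter used before genome assembly.

Pass one counts every canonical k-mer (k = 15 by default) across the whole
read set; pass two drops reads carrying too many singleton k-mers (likely
sequencing errors) or too many highly abundant k-mers (likely over-
represented repeats).  Defaults mirror the published thresholds: a read
fails with more than 12 singletons, or with more than 51 k-mers each seen
more than 20,000 times in the dataset (the abundance threshold is dataset-
scale and is configurable for small inputs).

Canonical counting collapses a k-mer with its reverse complement (odd k, so
no k-mer is its own complement); windows containing non-ACGT characters
neither count in the spectrum nor against a read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .io import logger

DEFAULT_K = 15

_COMP = str.maketrans("ACGT", "TGCA")


def canonical(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = kmer.translate(_COMP)[::-1]
    return kmer if kmer <= rc else rc


def iter_kmers(seq: str, k: int) -> Iterable[str]:
    """Canonical k-mers of every ACGT-only window of length k."""
    seq = seq.upper()
    for i in range(len(seq) - k + 1):
        window = seq[i:i + k]
        if set(window) <= set("ACGT"):
            yield canonical(window)


@dataclass
class KmerSpectrum:
    """Canonical k-mer -> occurrence count over a read set."""

    k: int
    counts: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k < 3 or self.k % 2 == 0:
            raise ValueError("k must be odd and >= 3")

    @property
    def total_kmers(self) -> int:
        return sum(self.counts.values())

    @property
    def distinct_kmers(self) -> int:
        return len(self.counts)

    def add_sequence(self, seq: str) -> None:
        for kmer in iter_kmers(seq, self.k):
            self.counts[kmer] = self.counts.get(kmer, 0) + 1

    def save(self, path: str | Path) -> None:
        """Persist as a TSV sidecar so filtering is reproducible sans recount."""
        with open(path, "w") as out:
            out.write(f"#k={self.k}\n")
            for kmer in sorted(self.counts):
                out.write(f"{kmer}\t{self.counts[kmer]}\n")

    @classmethod
    def load(cls, path: str | Path) -> "KmerSpectrum":
        counts: Dict[str, int] = {}
        k = None
        with open(path) as handle:
            for line in handle:
                if line.startswith("#k="):
                    k = int(line.strip().split("=", 1)[1])
                    continue
                kmer, count = line.split("\t")
                counts[kmer] = int(count)
        if k is None:
            raise ValueError(f"{path}: missing #k= header")
        return cls(k=k, counts=counts)


@dataclass(frozen=True)
class FilterPolicy:
    """Read-level failure thresholds for the spectrum filter."""

    max_singletons: int = 12
    high_count_threshold: int = 20_000
    max_high_count_kmers: int = 51
    pair_mode: str = "drop_pair"  # or "drop_read"

    def __post_init__(self) -> None:
        if min(self.max_singletons, self.high_count_threshold,
               self.max_high_count_kmers) <= 0:
            raise ValueError("all thresholds must be positive")
        if self.pair_mode not in ("drop_pair", "drop_read"):
            raise ValueError("pair_mode must be drop_pair or drop_read")


Read = Tuple[str, str, str]  # (name, sequence, quality)


def build_spectrum(reads: Iterable[str | Read], k: int = DEFAULT_K) -> KmerSpectrum:
    """Count canonical k-mers over a read set (sequences or read tuples)."""
    spectrum = KmerSpectrum(k=k)
    n_short = 0
    for read in reads:
        seq = read if isinstance(read, str) else read[1]
        if len(seq) < k:
            n_short += 1
            continue
        spectrum.add_sequence(seq)
    if n_short:
        logger.warning("%d read(s) shorter than k=%d contributed no k-mers",
                       n_short, k)
    return spectrum


def read_fails(seq: str, spectrum: KmerSpectrum,
               policy: FilterPolicy) -> Optional[str]:
    """Failure reason for one read, or None when it passes.

    Fails "singleton" when more than ``max_singletons`` of its k-mers occur
    exactly once in the spectrum; fails "abundant" when more than
    ``max_high_count_kmers`` of them occur more than ``high_count_threshold``
    times.
    """
    singletons = 0
    abundant = 0
    for kmer in iter_kmers(seq, spectrum.k):
        count = spectrum.counts.get(kmer, 0)
        if count == 1:
            singletons += 1
        elif count > policy.high_count_threshold:
            abundant += 1
    if singletons > policy.max_singletons:
        return "singleton"
    if abundant > policy.max_high_count_kmers:
        return "abundant"
    return None


def filter_reads(r1: Sequence[Read], r2: Sequence[Read],
                 spectrum: KmerSpectrum, policy: FilterPolicy = FilterPolicy(),
                 ) -> Tuple[List[Read], List[Read], Dict[str, int]]:
    """Apply the spectrum filter to a read pair set (two-pass contract:
    the spectrum must have been built over this same read set).

    In ``drop_pair`` mode both mates go when either fails; ``drop_read``
    replaces a failing mate with None-like removal of just that read while
    keeping its partner (pairing is then broken — counts are reported).
    Returns (kept R1, kept R2, report).
    """
    if len(r1) != len(r2):
        raise ValueError(f"mismatched pair counts: {len(r1)} vs {len(r2)}")
    report = {"pairs_in": len(r1), "reads_in": 2 * len(r1),
              "failed_singleton": 0, "failed_abundant": 0,
              "pairs_out": 0, "reads_out": 0}
    kept1: List[Read] = []
    kept2: List[Read] = []
    for mate1, mate2 in zip(r1, r2):
        reasons = [read_fails(mate1[1], spectrum, policy),
                   read_fails(mate2[1], spectrum, policy)]
        for reason in reasons:
            if reason is not None:
                report[f"failed_{reason}"] += 1
        if policy.pair_mode == "drop_pair":
            if reasons[0] is None and reasons[1] is None:
                kept1.append(mate1)
                kept2.append(mate2)
        else:
            if reasons[0] is None:
                kept1.append(mate1)
            if reasons[1] is None:
                kept2.append(mate2)
    report["pairs_out"] = min(len(kept1), len(kept2))
    report["reads_out"] = len(kept1) + len(kept2)
    return kept1, kept2, report


def write_report(report: Dict[str, int], path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True))
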