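"""Scaffold contamination screening from GC content and sequencing coverage.

Assembly scaffolds are profiled by GC fraction (over ACGT bases only) and
mean per-base coverage, and classified target-organism vs contaminant with
class-conditional bivariate Gaussians on (GC, log10 coverage) fitted to a
labelled training set with empirical class priors.  A scaffold is retained
when its posterior probability of target origin exceeds 0.2 — deliberately
permissive, erring toward keeping sequence — or when an independent homology
label (e.g. from BLAST) says it is target DNA regardless of its profile.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import multivariate_normal

from .io import logger

RETAIN_THRESHOLD = 0.2
_MIN_PER_CLASS = 5
_COV_REGULARIZATION = 1e-6


@dataclass
class ScaffoldProfile:
    scaffold_id: str
    length: int
    gc_fraction: float
    mean_coverage: Optional[float]
    homology_label: str = "none"  # target | contaminant | none
    posterior_target: Optional[float] = None
    retained: Optional[bool] = None


def gc_fraction(seq: str) -> float:
    """GC over ACGT bases only; N and other ambiguity codes are excluded
    from the denominator.  A sequence with no ACGT bases yields 0.0."""
    seq = seq.upper()
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / acgt


def profile_scaffolds(sequences: Mapping[str, str],
                      coverage: Mapping[str, float],
                      labels: Optional[Mapping[str, str]] = None,
                      ) -> List[ScaffoldProfile]:
    """Profile every scaffold; scaffolds missing from the coverage track get
    ``mean_coverage=None`` and are excluded from classification (logged)."""
    labels = labels or {}
    profiles = []
    n_missing = 0
    for name, seq in sequences.items():
        cov = coverage.get(name)
        if cov is None:
            n_missing += 1
        profiles.append(ScaffoldProfile(
            scaffold_id=name, length=len(seq), gc_fraction=gc_fraction(seq),
            mean_coverage=cov, homology_label=labels.get(name, "none")))
    if n_missing:
        logger.warning("%d scaffold(s) missing from the coverage track are "
                       "excluded from classification", n_missing)
    return profiles


def read_coverage_tsv(path: str | Path) -> Dict[str, float]:
    """Two-column TSV ``scaffold <tab> mean_depth``."""
    out: Dict[str, float] = {}
    with open(path) as handle:
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            name, depth = line.split("\t")[:2]
            out[name] = float(depth)
    return out


@dataclass
class GaussianClassifier:
    """Two-class Gaussian model on (GC fraction, log10 coverage)."""

    means: Dict[str, List[float]]
    covariances: Dict[str, List[List[float]]]
    priors: Dict[str, float]

    CLASSES = ("target", "contaminant")

    def posterior_target(self, gc: float, cov: float) -> float:
        x = np.array([gc, math.log10(max(cov, 1e-12))])
        densities = {
            cls: self.priors[cls] * multivariate_normal.pdf(
                x, mean=self.means[cls], cov=np.array(self.covariances[cls]))
            for cls in self.CLASSES
        }
        total = sum(densities.values())
        if total == 0.0:  # far outside both classes: fall back to priors
            return self.priors["target"]
        return densities["target"] / total

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"means": self.means, "covariances": self.covariances,
             "priors": self.priors}, indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "GaussianClassifier":
        data = json.loads(Path(path).read_text())
        return cls(**data)


def train_classifier(profiles: Sequence[ScaffoldProfile]) -> GaussianClassifier:
    """Fit the two-class Gaussian model from homology-labelled profiles.

    Needs at least 5 labelled examples per class with coverage present.
    Degenerate covariances (identical points) are regularized with a small
    ridge and warned about.
    """
    by_class: Dict[str, List[List[float]]] = {c: [] for c
                                              in GaussianClassifier.CLASSES}
    for p in profiles:
        if p.homology_label in by_class and p.mean_coverage is not None:
            by_class[p.homology_label].append(
                [p.gc_fraction, math.log10(max(p.mean_coverage, 1e-12))])
    for cls, rows in by_class.items():
        if len(rows) < _MIN_PER_CLASS:
            raise ValueError(
                f"need >= {_MIN_PER_CLASS} labelled {cls} scaffolds, "
                f"got {len(rows)}")
    n_total = sum(len(rows) for rows in by_class.values())
    means, covs, priors = {}, {}, {}
    for cls, rows in by_class.items():
        arr = np.array(rows)
        mean = arr.mean(axis=0)
        cov = np.cov(arr.T)
        if np.linalg.det(cov) < _COV_REGULARIZATION**2:
            logger.warning("degenerate covariance for class %s; "
                           "ridge regularization applied", cls)
            cov = cov + np.eye(2) * _COV_REGULARIZATION
        means[cls] = mean.tolist()
        covs[cls] = cov.tolist()
        priors[cls] = len(rows) / n_total
    return GaussianClassifier(means=means, covariances=covs, priors=priors)


def classify(model: GaussianClassifier, profiles: Sequence[ScaffoldProfile],
             retain_threshold: float = RETAIN_THRESHOLD,
             ) -> Tuple[List[ScaffoldProfile], Dict[str, float]]:
    """Fill posteriors and retention decisions.

    Retained iff ``posterior_target > retain_threshold`` OR the homology
    label says target (the override keeps BLAST-confirmed scaffolds whose
    GC/coverage profile looks foreign).  Returns the updated profiles and a
    summary with retained/removed counts and removed megabases.
    """
    out: List[ScaffoldProfile] = []
    removed_bp = 0
    n_retained = n_removed = n_unclassified = 0
    for p in profiles:
        if p.mean_coverage is None:
            out.append(replace(p))
            n_unclassified += 1
            continue
        post = model.posterior_target(p.gc_fraction, p.mean_coverage)
        retained = (post > retain_threshold) or (p.homology_label == "target")
        if retained:
            n_retained += 1
        else:
            n_removed += 1
            removed_bp += p.length
        out.append(replace(p, posterior_target=post, retained=retained))
    summary = {"retained": n_retained, "removed": n_removed,
               "unclassified": n_unclassified,
               "removed_mb": removed_bp / 1e6}
    return out, summary
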