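"""ChIP-seq peak post-processing and TF-association scoring.

Operates downstream of peak calling, on interval tables in the narrowPeak /
BED dialect (0-based, half-open).  Provided operations:

* IgG **background subtraction** — drop sample peaks overlapping any mock-IP
  (IgG) peak;
* **new peaks** — condition peaks absent from the control that also pass
  fold-enrichment and p-value thresholds (defaults FE > 30, or 15 for the
  elongating PhosphoS2 form, and p < 1e-9);
* **cross-antibody containment** — the percentage of one antibody's peaks
  (e.g. PhosphoS5) also found by another (e.g. total Pol II), a consistency
  check on paired ChIP experiments;
* **gene assignment** — nearest strand-aware TSS to the peak midpoint;
* **association score** — a PASTAA-style statistic linking an
  affinity-ranked gene list to a target gene set: the hypergeometric
  upper-tail p-value of the overlap between the top-k genes and the targets,
  minimized over a grid of rank cutoffs, reported as -log10(p).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom

log = logging.getLogger(__name__)

__all__ = [
    "PeakRecord",
    "PeakSet",
    "NewPeaksConfig",
    "GeneRecord",
    "AssociationScore",
    "read_peaks",
    "write_peaks",
    "read_genes_bed",
    "subtract_background",
    "new_peaks",
    "containment_fraction",
    "peak_count_ratio",
    "assign_peaks_to_genes",
    "association_score",
]


@dataclasses.dataclass(frozen=True)
class PeakRecord:
    """One called peak; 0-based half-open coordinates, raw p-value."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: int = 0
    strand: str = "."
    fold_enrichment: float = 0.0
    p_value: float = 1.0
    summit: int = -1  # offset from start, or -1 if absent

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"start must be < end, got [{self.start}, {self.end})")
        if self.start < 0:
            raise ValueError("start must be >= 0")
        if not (0 < self.p_value <= 1):
            raise ValueError(f"p_value must lie in (0, 1], got {self.p_value}")
        if self.fold_enrichment < 0:
            raise ValueError("fold_enrichment must be >= 0")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


class PeakSet:
    """An ordered, labelled collection of peaks, sorted by (chrom, start)."""

    def __init__(self, records: Iterable[PeakRecord], label: str = ""):
        recs = sorted(records, key=lambda r: (r.chrom, r.start, r.end))
        self.records: list[PeakRecord] = recs
        self.label = label

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __eq__(self, other) -> bool:
        return isinstance(other, PeakSet) and self.records == other.records

    def __repr__(self) -> str:
        return f"PeakSet(label={self.label!r}, n={len(self)})"

    def _trees(self) -> dict[str, IntervalTree]:
        trees: dict[str, IntervalTree] = {}
        for r in self.records:
            trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end)
        return trees


def _overlaps_any(peaks: PeakSet, targets: PeakSet, min_overlap: int) -> np.ndarray:
    """Boolean per peak: shares >= min_overlap bases with some target peak."""
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1 bp")
    trees = targets._trees()
    out = np.zeros(len(peaks), dtype=bool)
    for i, r in enumerate(peaks):
        tree = trees.get(r.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(r.start, r.end):
            if min(r.end, hit.end) - max(r.start, hit.begin) >= min_overlap:
                out[i] = True
                break
    return out


@dataclasses.dataclass(frozen=True)
class NewPeaksConfig:
    """Thresholds for condition-specific ("new") peaks.

    Defaults: fold enrichment above 30 (use 15 for the PhosphoS2 antibody)
    and p-value below 1e-9; a condition peak must share no >= min_overlap bp
    stretch with any control peak.
    """

    fe_threshold: float = 30.0
    p_threshold: float = 1e-9
    min_overlap: int = 1

    def __post_init__(self) -> None:
        if self.fe_threshold <= 0:
            raise ValueError("fe_threshold must be positive")
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must lie in (0, 1)")

    @classmethod
    def phospho_s2(cls) -> "NewPeaksConfig":
        return cls(fe_threshold=15.0)


# ---------------------------------------------------------------------------
# I/O — narrowPeak (BED6+4) and BED6+FE+P dialects

_NP_COLS = [
    "chrom", "start", "end", "name", "score",
    "strand", "signalValue", "pValue", "qValue", "peak",
]


def read_peaks(path, dialect: str = "narrowPeak", label: str = "") -> PeakSet:
    """Read a peak table.

    ``narrowPeak``: 10 columns, pValue encoded as -log10.
    ``bed6+FE+P``: 8 columns — BED6 then fold_enrichment and a raw p-value.
    Malformed lines raise with the offending line number; records with
    start >= end are dropped with a logged notice.
    """
    if dialect not in ("narrowPeak", "bed6+FE+P"):
        raise ValueError(f"unknown dialect {dialect!r}")
    ncols = 10 if dialect == "narrowPeak" else 8
    records = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < ncols:
                raise ValueError(
                    f"{path}:{lineno}: expected {ncols} columns for {dialect}, "
                    f"got {len(fields)}"
                )
            try:
                chrom, start, end, name, score, strand = fields[:6]
                start, end, score = int(start), int(end), int(float(score))
                if dialect == "narrowPeak":
                    fe = float(fields[6])
                    p = 10.0 ** (-float(fields[7]))
                    summit = int(fields[9])
                else:
                    fe = float(fields[6])
                    p = float(fields[7])
                    summit = -1
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed line ({exc})") from None
            if start >= end:
                dropped += 1
                continue
            records.append(
                PeakRecord(chrom, start, end, name, score, strand, fe, min(p, 1.0), summit)
            )
    if dropped:
        log.warning("%s: dropped %d records with start >= end", path, dropped)
    return PeakSet(records, label=label or str(path))


def write_peaks(peaks: PeakSet, path, dialect: str = "narrowPeak") -> None:
    """Write a peak table; narrowPeak encodes the p-value as -log10."""
    with open(path, "w") as fh:
        for r in peaks:
            base = [r.chrom, str(r.start), str(r.end), r.name, str(r.score), r.strand]
            if dialect == "narrowPeak":
                row = base + [
                    format(r.fold_enrichment, ".17g"),
                    format(-math.log10(r.p_value), ".17g"),
                    "-1",
                    str(r.summit),
                ]
            elif dialect == "bed6+FE+P":
                row = base + [format(r.fold_enrichment, ".17g"), format(r.p_value, ".17g")]
            else:
                raise ValueError(f"unknown dialect {dialect!r}")
            fh.write("\t".join(row) + "\n")


@dataclasses.dataclass(frozen=True)
class GeneRecord:
    """A gene annotation interval; TSS is start on '+' and end on '-'."""

    chrom: str
    start: int
    end: int
    name: str
    strand: str

    @property
    def tss(self) -> int:
        return self.start if self.strand != "-" else self.end


def read_genes_bed(path) -> list[GeneRecord]:
    """Read a BED6 gene annotation (chrom, start, end, name, score, strand)."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{lineno}: BED6 needs 6 columns, got {len(f)}")
            genes.append(GeneRecord(f[0], int(f[1]), int(f[2]), f[3], f[5]))
    return genes


# ---------------------------------------------------------------------------
# Interval operations

def subtract_background(sample: PeakSet, igg: PeakSet, min_overlap: int = 1) -> PeakSet:
    """Remove sample peaks overlapping any IgG (mock-IP) background peak.

    Whole peaks are dropped, not trimmed; the output is a subset of the
    input, so the operation is idempotent.
    """
    keep = ~_overlaps_any(sample, igg, min_overlap)
    return PeakSet(
        (r for r, k in zip(sample, keep) if k), label=f"{sample.label}-minus-{igg.label}"
    )


def new_peaks(
    condition: PeakSet, control: PeakSet, config: NewPeaksConfig = NewPeaksConfig()
) -> PeakSet:
    """Condition-specific peaks passing enrichment and significance filters.

    A peak qualifies when it has no overlap with any control peak, its fold
    enrichment exceeds ``config.fe_threshold`` and its p-value is below
    ``config.p_threshold``.
    """
    absent = ~_overlaps_any(condition, control, config.min_overlap)
    return PeakSet(
        (
            r
            for r, a in zip(condition, absent)
            if a and r.fold_enrichment > config.fe_threshold and r.p_value < config.p_threshold
        ),
        label=f"{condition.label}-new",
    )


def containment_fraction(
    subset_peaks: PeakSet, superset_peaks: PeakSet, min_overlap: int = 1
) -> float:
    """Percent of ``subset_peaks`` overlapping >= 1 peak of ``superset_peaks``."""
    if len(subset_peaks) == 0:
        raise ValueError("containment undefined for an empty subset")
    hits = _overlaps_any(subset_peaks, superset_peaks, min_overlap)
    return 100.0 * float(np.count_nonzero(hits)) / len(subset_peaks)


def peak_count_ratio(set_a: PeakSet, set_b: PeakSet) -> float:
    """Fold change in peak count, A / B."""
    if len(set_b) == 0:
        raise ValueError("set_b is empty; ratio undefined")
    return len(set_a) / len(set_b)


def assign_peaks_to_genes(peaks: PeakSet, genes: Sequence[GeneRecord]) -> set[str]:
    """Assign each peak to the gene with the nearest TSS to the peak midpoint.

    TSS is strand-aware (start on '+', end on '-').  Distance ties go to the
    first gene in (chrom, start) sorted order and are logged, as are peaks on
    chromosomes absent from the annotation.  Returns the deduplicated set of
    gene names.
    """
    if not genes:
        raise ValueError("gene annotation is empty")
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
        by_chrom.setdefault(g.chrom, []).append(g)
    assigned: set[str] = set()
    unassigned = ties = 0
    for r in peaks:
        cands = by_chrom.get(r.chrom)
        if not cands:
            unassigned += 1
            continue
        dists = [abs(g.tss - r.midpoint) for g in cands]
        dmin = min(dists)
        winners = [g for g, d in zip(cands, dists) if d == dmin]
        if len(winners) > 1:
            ties += 1
        assigned.add(winners[0].name)
    if unassigned:
        log.warning("%d peaks on chromosomes absent from the annotation", unassigned)
    if ties:
        log.info("%d peaks had tied TSS distances; first gene in sorted order used", ties)
    return assigned


# ---------------------------------------------------------------------------
# PASTAA-style association score

@dataclasses.dataclass(frozen=True)
class AssociationScore:
    """Max-over-cutoffs hypergeometric association of a ranking with targets.

    ``score`` is -log10 (or -ln) of the most significant upper-tail
    hypergeometric p-value over the scanned rank cutoffs.
    ``bonferroni_p`` is a diagnostic: min(1, best p * number of cutoffs).
    """

    score: float
    best_cutoff: int
    overlap_at_best: int
    p_value: float
    bonferroni_p: float

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("score must be >= 0")


def association_score(
    ranking: Sequence[str],
    target_set: Iterable[str],
    cutoff_grid: Sequence[int],
    log_base: float = 10.0,
) -> AssociationScore:
    """PASTAA-style TF-association score.

    For each cutoff k the overlap o between the top-k genes of the
    affinity ranking and the target set is scored with the hypergeometric
    upper tail P(X >= o) (population N = ranking length, successes = target
    size, draws = k); the score is -log of the minimum p over the grid.
    Ties on p go to the smallest cutoff.
    """
    ranking = list(ranking)
    n = len(ranking)
    if len(set(ranking)) != n:
        raise ValueError("ranking contains duplicate genes")
    targets = set(target_set)
    if not targets:
        raise ValueError("target_set is empty")
    if not targets <= set(ranking):
        raise ValueError("target_set must be a subset of the ranked gene universe")
    grid = list(cutoff_grid)
    if not grid:
        raise ValueError("cutoff_grid is empty")
    if any(not (1 <= k <= n) for k in grid):
        raise ValueError("every cutoff must lie in [1, ranking length]")
    big_k = len(targets)
    is_target = np.fromiter((g in targets for g in ranking), dtype=bool, count=n)
    cum = np.cumsum(is_target)
    best_p, best_k, best_o = math.inf, None, None
    for k in grid:
        o = int(cum[k - 1])
        p = float(hypergeom.sf(o - 1, n, big_k, k))
        if p < best_p:
            best_p, best_k, best_o = p, k, o
    best_p = min(best_p, 1.0)
    if log_base == 10.0:
        score = -math.log10(best_p) if best_p > 0 else math.inf
    else:
        score = -math.log(best_p) / math.log(log_base) if best_p > 0 else math.inf
    return AssociationScore(
        score=max(score, 0.0),
        best_cutoff=best_k,
        overlap_at_best=best_o,
        p_value=best_p,
        bonferroni_p=min(1.0, best_p * len(grid)),
    )
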