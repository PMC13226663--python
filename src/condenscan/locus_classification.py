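"""Co-occupancy taxonomies over peak sets.

Implements the locus classes used throughout the analysis:

* RYBP-targeted *active* loci (H3K4me3 present, H3K27me3 absent) vs
  *repressive* loci (H3K27me3 present, regardless of H3K4me3);
* the RING1B-lacked / RING1B-enriched partition of RYBP+WDR5 co-localized
  regions;
* RYBP-WDR5 vs RYBP-WDR5-RING1B condensate loci (condensate members split by
  WDR5/RING1B co-occupancy);
* promoter classes (active / poised / other) around gene TSSs.

Overlap everywhere means >= 1 bp intersection of 0-based half-open intervals
(the bedtools-intersect default), strand-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .apex_condensate import CondensateCall
from .genomic_io import GeneModel, GenomicInterval, PeakSet

__all__ = [
    "LocusClassification",
    "OverlapReport",
    "overlaps",
    "overlap_flags",
    "classify_rybp_loci",
    "partition_by_ring1b",
    "classify_condensate_loci",
    "annotate_promoter_classes",
    "peak_overlap_ratio",
    "define_gene_sets_by_loci",
]


@dataclass
class LocusClassification:
    """One classified region with its labels and supporting mark presence."""

    interval: GenomicInterval
    labels: Set[str]
    marks: Dict[str, bool]


@dataclass(frozen=True)
class OverlapReport:
    """Fraction of query peaks overlapping any subject peak."""

    query_label: str
    subject_label: str
    n_query: int
    n_overlapping: int

    @property
    def overlap_ratio(self) -> float:
        return self.n_overlapping / self.n_query


def _flags_against(
    queries: Sequence[GenomicInterval], subject: PeakSet, min_bp: int
) -> np.ndarray:
    """Sweep over sorted subject intervals; flag queries sharing >= min_bp."""
    by_chrom = subject.by_chrom()
    starts = {
        c: np.array([iv.start for iv in ivs]) for c, ivs in by_chrom.items()
    }
    ends = {c: np.array([iv.end for iv in ivs]) for c, ivs in by_chrom.items()}
    flags = np.zeros(len(queries), dtype=bool)
    for i, q in enumerate(queries):
        if q.chrom not in starts:
            continue
        s, e = starts[q.chrom], ends[q.chrom]
        # candidates: subject intervals with start < q.end and end > q.start
        lo = int(np.searchsorted(e, q.start, side="right"))
        hi = int(np.searchsorted(s, q.end, side="left"))
        if lo >= hi:
            continue
        ov = np.minimum(e[lo:hi], q.end) - np.maximum(s[lo:hi], q.start)
        flags[i] = bool(np.any(ov >= min_bp))
    return flags


def overlaps(
    a: PeakSet, b: PeakSet, min_bp: int = 1
) -> Tuple[np.ndarray, List[Tuple[GenomicInterval, GenomicInterval]]]:
    """Per-interval overlap flags of ``a`` against ``b``, plus the pairs.

    An interval of ``a`` is flagged iff it shares at least ``min_bp`` bases
    with some interval of ``b``. Returns the boolean flags (in the order of
    ``a``) and all intersecting (a, b) interval pairs.
    """
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    queries = list(a)
    flags = _flags_against(queries, b, min_bp)
    pairs: List[Tuple[GenomicInterval, GenomicInterval]] = []
    by_chrom = b.by_chrom()
    for q, f in zip(queries, flags):
        if not f:
            continue
        for sub in by_chrom.get(q.chrom, []):
            if min(sub.end, q.end) - max(sub.start, q.start) >= min_bp:
                pairs.append((q, sub))
    return flags, pairs


def overlap_flags(a: PeakSet, b: PeakSet, min_bp: int = 1) -> np.ndarray:
    """Boolean flags only (cheaper companion to :func:`overlaps`)."""
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    return _flags_against(list(a), b, min_bp)


def classify_rybp_loci(
    rybp: PeakSet, h3k4me3: PeakSet, h3k27me3: PeakSet
) -> List[LocusClassification]:
    """Label each RYBP peak active / repressive / other.

    active: H3K4me3 overlap and no H3K27me3 overlap. repressive: H3K27me3
    overlap, regardless of H3K4me3 (bivalent regions count as repressive).
    other: neither mark.
    """
    peaks = list(rybp)
    k4 = _flags_against(peaks, h3k4me3, 1)
    k27 = _flags_against(peaks, h3k27me3, 1)
    out = []
    for iv, has_k4, has_k27 in zip(peaks, k4, k27):
        if has_k27:
            label = "repressive"
        elif has_k4:
            label = "active"
        else:
            label = "other"
        out.append(
            LocusClassification(
                iv, {label}, {"H3K4me3": bool(has_k4), "H3K27me3": bool(has_k27)}
            )
        )
    return out


def partition_by_ring1b(
    rybp: PeakSet, wdr5: PeakSet, ring1b: PeakSet
) -> Dict[str, List[GenomicInterval]]:
    """Split RYBP+WDR5 co-localized regions by RING1B presence.

    The base set is RYBP peaks overlapping WDR5 (the RYBP interval is kept as
    the region unit); those also overlapping RING1B are RING1B_enriched, the
    rest RING1B_lacked. The two classes partition the base set exactly.
    """
    peaks = list(rybp)
    has_wdr5 = _flags_against(peaks, wdr5, 1)
    has_ring1b = _flags_against(peaks, ring1b, 1)
    out: Dict[str, List[GenomicInterval]] = {
        "RING1B_lacked": [],
        "RING1B_enriched": [],
    }
    for iv, w, r in zip(peaks, has_wdr5, has_ring1b):
        if not w:
            continue
        out["RING1B_enriched" if r else "RING1B_lacked"].append(iv)
    return out


def classify_condensate_loci(
    calls: Sequence[CondensateCall], wdr5: PeakSet, ring1b: PeakSet
) -> Dict[str, List[GenomicInterval]]:
    """Split condensate-member regions into RYBP_WDR5 / RYBP_WDR5_RING1B.

    Only member calls (es above the cutoff) may be passed. Members
    overlapping WDR5 split by RING1B presence; members without WDR5 are
    labeled ``other``.
    """
    for c in calls:
        if not c.member:
            raise ValueError(
                f"non-member region {c.region_id} passed to condensate "
                "classification"
            )
        if c.region is None:
            raise ValueError(f"call {c.region_id} carries no interval")
    regions = [c.region for c in calls]
    has_wdr5 = _flags_against(regions, wdr5, 1)
    has_ring1b = _flags_against(regions, ring1b, 1)
    out: Dict[str, List[GenomicInterval]] = {
        "RYBP_WDR5": [],
        "RYBP_WDR5_RING1B": [],
        "other": [],
    }
    for iv, w, r in zip(regions, has_wdr5, has_ring1b):
        if not w:
            out["other"].append(iv)
        elif r:
            out["RYBP_WDR5_RING1B"].append(iv)
        else:
            out["RYBP_WDR5"].append(iv)
    return out


def annotate_promoter_classes(
    genes: Sequence[GeneModel],
    rybp: PeakSet,
    h3k4me3: PeakSet,
    h3k27me3: PeakSet,
    tss_window: int = 2000,
) -> Tuple[Dict[str, str], Dict[str, float]]:
    """Classify gene promoters (TSS +/- tss_window) by RYBP/K4/K27 state.

    poised: RYBP and H3K4me3 and H3K27me3; active: RYBP and H3K4me3 without
    H3K27me3; other: everything else (including promoters without RYBP).
    Returns per-gene classes and the class fractions over RYBP-bound
    promoters and over all promoters.
    """
    if tss_window <= 0:
        raise ValueError("tss_window must be positive")
    promoters = [g.promoter(tss_window) for g in genes]
    has_rybp = _flags_against(promoters, rybp, 1)
    has_k4 = _flags_against(promoters, h3k4me3, 1)
    has_k27 = _flags_against(promoters, h3k27me3, 1)
    classes: Dict[str, str] = {}
    for g, r, k4, k27 in zip(genes, has_rybp, has_k4, has_k27):
        if r and k4 and k27:
            classes[g.gene_id] = "promoter_poised"
        elif r and k4:
            classes[g.gene_id] = "promoter_active"
        else:
            classes[g.gene_id] = "promoter_other"
    n_total = len(genes)
    n_bound = int(has_rybp.sum())
    fractions: Dict[str, float] = {}
    for label in ("promoter_poised", "promoter_active", "promoter_other"):
        n = sum(1 for v in classes.values() if v == label)
        fractions[f"{label}_of_all"] = n / n_total if n_total else 0.0
        fractions[f"{label}_of_rybp_bound"] = n / n_bound if n_bound else 0.0
    return classes, fractions


def peak_overlap_ratio(query: PeakSet, subject: PeakSet) -> OverlapReport:
    """Fraction of query peaks sharing >= 1 bp with any subject peak."""
    if len(query) == 0:
        raise ValueError("empty query peak set")
    flags = overlap_flags(query, subject)
    return OverlapReport(
        query_label=query.source_label,
        subject_label=subject.source_label,
        n_query=len(query),
        n_overlapping=int(flags.sum()),
    )


def define_gene_sets_by_loci(
    classified: Mapping[str, Sequence[GenomicInterval]],
    genes: Sequence[GeneModel],
    tss_window: int = 2000,
) -> Dict[str, Set[str]]:
    """Assign genes to locus classes by promoter-window overlap."""
    out: Dict[str, Set[str]] = {}
    promoters = [g.promoter(tss_window) for g in genes]
    for label, regions in classified.items():
        region_set = PeakSet(list(regions), source_label=label)
        flags = _flags_against(promoters, region_set, 1)
        out[label] = {g.gene_id for g, f in zip(genes, flags) if f}
    return out
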