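"""Differential-region (DR) calling between two LAD sets.

A DR is genome in a LAD in one condition but not the other. Direction
follows the nuclear-movement reading: PI (periphery -> interior) marks
LADs lost from condition A to condition B, IP (interior -> periphery)
marks LADs gained. Edge classes describe how a DR relates to the
pre-existing LAD landscape (truncation of an edge, expansion of an edge,
an internal hole, a whole LAD lost, or a de-novo LAD).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .damid import LadSet
from .intervals import GenomicInterval, interval_ops, jaccard, total_bp

__all__ = [
    "DifferentialRegion",
    "ParalogPartition",
    "call_differential_regions",
    "classify_dr_edges",
    "retained_lad_fraction",
    "paralog_specificity",
]

EDGE_CLASSES = ("truncation", "expansion", "internal_loss", "de_novo", "whole_lad_loss")


@dataclass
class DifferentialRegion:
    interval: GenomicInterval
    direction: str  # "IP" (LAD gained) or "PI" (LAD lost)
    edge_class: str | None = None
    source_pair: tuple[str, str] = ("", "")

    def __post_init__(self) -> None:
        if self.direction not in ("IP", "PI"):
            raise ValueError(f"direction must be IP or PI, got {self.direction!r}")
        if self.edge_class is not None and self.edge_class not in EDGE_CLASSES:
            raise ValueError(f"unknown edge_class {self.edge_class!r}")


@dataclass
class ParalogPartition:
    """3-way partition of KD-affected regions/loci by paralog specificity."""

    categories: dict[str, str] = field(default_factory=dict)  # region id -> category
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def call_differential_regions(
    lads_a: LadSet, lads_b: LadSet, min_dr_size: int = 5_000
) -> list[DifferentialRegion]:
    """DRs between condition A and condition B.

    PI = merged(A - B), IP = merged(B - A), each kept only if
    >= ``min_dr_size`` bp (suppresses segmentation-boundary jitter).
    """
    pair = (lads_a.condition, lads_b.condition)
    out: list[DifferentialRegion] = []
    for direction, first, second in (("PI", lads_a, lads_b), ("IP", lads_b, lads_a)):
        diff = interval_ops(first.lads, second.lads, "subtract")
        for iv in diff:
            if len(iv) >= min_dr_size:
                out.append(DifferentialRegion(iv, direction, source_pair=pair))
    out.sort(key=lambda d: d.interval)
    return out


def _containing(iv: GenomicInterval, lads: list[GenomicInterval]) -> GenomicInterval | None:
    for lad in lads:
        if lad.chrom == iv.chrom and lad.start <= iv.start and iv.end <= lad.end:
            return lad
    return None


def _near(iv: GenomicInterval, lads: list[GenomicInterval], tol: int) -> bool:
    for lad in lads:
        if lad.chrom == iv.chrom and iv.start - tol <= lad.end and lad.start <= iv.end + tol:
            return True
    return False


def classify_dr_edges(
    drs: list[DifferentialRegion],
    lads_a: LadSet,
    lads_b: LadSet,
    edge_tol: int = 256,
) -> tuple[list[DifferentialRegion], dict]:
    """Fill ``edge_class`` on each DR and summarise edge behaviour.

    PI DRs are located within their source A-LAD: equal to it (within
    ``edge_tol`` at both ends) -> whole_lad_loss; strictly interior ->
    internal_loss; touching an end -> truncation. IP DRs abutting an
    A-LAD within ``edge_tol`` -> expansion, otherwise de_novo.

    The summary reports the paper-style per-pre-existing-LAD fractions
    (fraction of A-LADs with >= 1 truncation / >= 1 expansion) alongside
    the per-DR fractions, since either denominator is defensible.
    """
    truncated_lads: set[GenomicInterval] = set()
    expanded_lads: set[GenomicInterval] = set()
    for dr in drs:
        if dr.direction == "PI":
            src = _containing(dr.interval, lads_a.lads)
            if src is None:
                raise ValueError(f"PI DR {dr.interval} not contained in any A-LAD")
            left = dr.interval.start - src.start <= edge_tol
            right = src.end - dr.interval.end <= edge_tol
            if left and right:
                dr.edge_class = "whole_lad_loss"
            elif not left and not right:
                dr.edge_class = "internal_loss"
            else:
                dr.edge_class = "truncation"
                truncated_lads.add(src)
        else:
            if total_bp(interval_ops([dr.interval], lads_b.lads, "subtract")) > 0:
                raise ValueError(f"IP DR {dr.interval} not contained in B-LADs")
            if _near(dr.interval, lads_a.lads, edge_tol):
                dr.edge_class = "expansion"
                for lad in lads_a.lads:
                    if (
                        lad.chrom == dr.interval.chrom
                        and dr.interval.start - edge_tol <= lad.end
                        and lad.start <= dr.interval.end + edge_tol
                    ):
                        expanded_lads.add(lad)
            else:
                dr.edge_class = "de_novo"
    n_pre = len(lads_a.lads)
    n_pi = sum(1 for d in drs if d.direction == "PI")
    n_ip = sum(1 for d in drs if d.direction == "IP")
    summary = {
        "n_pre_lads": n_pre,
        "frac_pre_lads_truncated": len(truncated_lads) / n_pre if n_pre else 0.0,
        "frac_pre_lads_expanded": len(expanded_lads) / n_pre if n_pre else 0.0,
        "frac_pi_drs_truncation": (
            sum(1 for d in drs if d.edge_class == "truncation") / n_pi if n_pi else 0.0
        ),
        "frac_ip_drs_expansion": (
            sum(1 for d in drs if d.edge_class == "expansion") / n_ip if n_ip else 0.0
        ),
        "edge_class_counts": {
            c: sum(1 for d in drs if d.edge_class == c) for c in EDGE_CLASSES
        },
    }
    return drs, summary


def retained_lad_fraction(
    lads_a: LadSet, lads_b: LadSet, min_reciprocal_overlap: float = 0.5
) -> float:
    """Fraction of A-LADs retained in B.

    An A-LAD is retained if some single B-LAD covers at least
    ``min_reciprocal_overlap`` of each of the two (reciprocal overlap).
    Returns NaN (with a warning) when A is empty.
    """
    if not lads_a.lads:
        warnings.warn("retained_lad_fraction undefined for empty A", stacklevel=2)
        return float("nan")
    retained = 0
    for a in lads_a.lads:
        for b in lads_b.lads:
            ov = a.overlap_bp(b)
            if ov >= min_reciprocal_overlap * len(a) and ov >= min_reciprocal_overlap * len(b):
                retained += 1
                break
    return retained / len(lads_a.lads)


def paralog_specificity(
    lads_wt: LadSet,
    lads_akd: LadSet,
    lads_abkd: LadSet,
    jaccard_tol: float = 0.5,
    min_dr_size: int = 5_000,
    loci=None,
) -> ParalogPartition:
    """Partition knockdown-affected regions by paralog specificity.

    Deviations of the single-knockdown (aKD) and double-knockdown (abKD)
    LAD landscapes from the wild-type landscape are computed as symmetric
    differences (size-filtered). Each connected affected region is then
    classified: the single-KD deviation matching the double-KD deviation
    with Jaccard >= ``jaccard_tol`` (no further change when both paralogs
    are lost) -> ``a_unique``; deviation present only in the double KD ->
    ``b_unique``; otherwise -> ``mixed``.

    With ``loci`` (LocusAnnotation list) the same rule is applied to the
    deviations overlapping each affected locus instead of to raw regions.
    """

    def symdiff(x: LadSet) -> list[GenomicInterval]:
        d = interval_ops(x.lads, lads_wt.lads, "subtract") + interval_ops(
            lads_wt.lads, x.lads, "subtract"
        )
        return [iv for iv in d if len(iv) >= min_dr_size]

    dev_a = symdiff(lads_akd)
    dev_ab = symdiff(lads_abkd)

    if loci is not None:
        units = [
            (loc.locus_id, [loc.interval])
            for loc in loci
            if any(loc.interval.overlaps(iv) for iv in dev_a + dev_ab)
        ]
    else:
        components = interval_ops(dev_a, dev_ab, "union")
        units = [(f"{iv.chrom}:{iv.start}-{iv.end}", [iv]) for iv in components]

    part = ParalogPartition(counts={"a_unique": 0, "b_unique": 0, "mixed": 0})
    for uid, region in units:
        in_a = interval_ops(dev_a, region, "intersect")
        in_ab = interval_ops(dev_ab, region, "intersect")
        if not in_a and not in_ab:
            continue
        if not in_a:
            cat = "b_unique"
        elif jaccard(in_a, in_ab) >= jaccard_tol:
            cat = "a_unique"
        else:
            cat = "mixed"
        part.categories[uid] = cat
        part.counts[cat] += 1
    return part
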