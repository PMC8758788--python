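"""DamID log-ratio tracks, segmentation and LAD calling.

A DamID experiment yields two read-count tracks over the genome's
DpnI (GATC) fragments: the Dam-LaminB1 fusion and the soluble Dam-only
control. Lamina association is scored as log2(fusion/Dam) per fragment;
positive segments of that track are lamina-associated domains (LADs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from ._segment import segment_values
from .intervals import FragmentMap, GenomicInterval, merge_intervals, total_bp

__all__ = [
    "DamProfile",
    "SegmentTrack",
    "LadSet",
    "compute_log_ratio",
    "bin_track",
    "segment_track",
    "call_lads",
    "lad_metrics",
]


@dataclass
class DamProfile:
    """Per-fragment paired counts and derived log-ratio for one condition.

    ``log_ratio`` is NaN where masked (no usable counts).
    """

    condition: str
    fragment_map: FragmentMap
    counts_fusion: np.ndarray
    counts_dam: np.ndarray
    log_ratio: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.fragment_map.n_fragments
        self.counts_fusion = np.asarray(self.counts_fusion)
        self.counts_dam = np.asarray(self.counts_dam)
        for name in ("counts_fusion", "counts_dam"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise ValueError(f"{name} length {arr.shape} != n fragments {n}")
            if (arr < 0).any():
                raise ValueError(f"{name} contains negative counts")
        if self.log_ratio is not None and np.asarray(self.log_ratio).shape != (n,):
            raise ValueError("log_ratio length mismatch")

    @property
    def n_masked(self) -> int:
        if self.log_ratio is None:
            return 0
        return int(np.isnan(self.log_ratio).sum())


@dataclass
class SegmentTrack:
    """Piecewise-constant summary of a log-ratio track.

    Each element is ``(interval, mean log-ratio, n data points)``; the
    intervals cover every data point exactly once.
    """

    segments: list[tuple[GenomicInterval, float, int]]
    genome: dict[str, int] = field(default_factory=dict)


@dataclass
class LadSet:
    """Called LADs for one condition plus summary metrics."""

    condition: str
    lads: list[GenomicInterval]
    metrics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = merge_intervals(self.lads)
        if total_bp(merged) != sum(len(iv) for iv in self.lads):
            raise ValueError("LADs overlap")
        self.lads = merged


def compute_log_ratio(
    profile: DamProfile,
    pseudocount: float = 1.0,
    normalize: str = "library_size",
) -> DamProfile:
    """Fill ``log_ratio`` = log2((fusion*s_f + c) / (dam*s_d + c)).

    With ``normalize='library_size'`` each track is first scaled so both
    totals equal their mean; fragments where both raw counts are zero are
    masked (NaN). A zero pseudocount with a zero denominator also masks
    the fragment (counted and warned about) rather than yielding inf.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if normalize not in ("library_size", "none"):
        raise ValueError(f"unknown normalize mode {normalize!r}")
    f = profile.counts_fusion.astype(np.float64)
    d = profile.counts_dam.astype(np.float64)
    if normalize == "library_size":
        tf, td = f.sum(), d.sum()
        if tf > 0 and td > 0:
            target = (tf + td) / 2.0
            f = f * (target / tf)
            d = d * (target / td)
    num = f + pseudocount
    den = d + pseudocount
    mask = (profile.counts_fusion == 0) & (profile.counts_dam == 0)
    bad = (num <= 0) | (den <= 0)
    n_zero_denom = int((bad & ~mask).sum())
    if n_zero_denom:
        warnings.warn(
            f"{n_zero_denom} fragments masked for zero numerator/denominator "
            "with pseudocount=0",
            stacklevel=2,
        )
    mask = mask | bad
    log_ratio = np.full(f.shape, np.nan)
    ok = ~mask
    log_ratio[ok] = np.log2(num[ok] / den[ok])
    return replace(profile, log_ratio=log_ratio)


def bin_track(
    profile: DamProfile, bin_size: int
) -> tuple[list[GenomicInterval], np.ndarray, np.ndarray]:
    """Average the log-ratio track into fixed genomic bins.

    The mean is weighted by the number of bases each unmasked fragment
    contributes to the bin (equivalently the per-base average of the
    piecewise-constant fragment track). Bins with no unmasked coverage
    are dropped. Returns ``(bin intervals, means, n_fragments per bin)``.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if profile.log_ratio is None:
        raise ValueError("profile has no log_ratio; run compute_log_ratio first")
    lengths = np.array([len(fr) for fr in profile.fragment_map.fragments])
    if bin_size < np.median(lengths):
        warnings.warn("bin_size below median fragment length", stacklevel=2)
    ivs: list[GenomicInterval] = []
    means: list[float] = []
    nfrag: list[int] = []
    fm = profile.fragment_map
    for chrom, clen in fm.genome.items():
        sl = fm.chrom_slice(chrom)
        frags = fm.fragments[sl]
        vals = profile.log_ratio[sl]
        n_bins = -(-clen // bin_size)
        wsum = np.zeros(n_bins)
        w = np.zeros(n_bins)
        cnt = np.zeros(n_bins, dtype=np.int64)
        for fr, v in zip(frags, vals):
            if np.isnan(v):
                continue
            b0, b1 = fr.start // bin_size, (fr.end - 1) // bin_size
            for b in range(b0, b1 + 1):
                ov = min(fr.end, (b + 1) * bin_size) - max(fr.start, b * bin_size)
                wsum[b] += v * ov
                w[b] += ov
                cnt[b] += 1
        for b in range(n_bins):
            if w[b] > 0:
                ivs.append(
                    GenomicInterval(chrom, b * bin_size, min((b + 1) * bin_size, clen))
                )
                means.append(wsum[b] / w[b])
                nfrag.append(int(cnt[b]))
    return ivs, np.array(means), np.array(nfrag)


def segment_track(
    intervals: list[GenomicInterval],
    values: np.ndarray,
    genome: dict[str, int],
    alpha: float = 0.01,
    min_width: int = 2,
    n_perm: int = 1000,
    seed: int = 0,
) -> SegmentTrack:
    """Segment a (fragment- or bin-level) log-ratio track per chromosome.

    Missing (NaN) points are dropped before segmentation; each resulting
    segment spans from the start of its first data point to the end of
    its last. Deterministic for a given seed.
    """
    values = np.asarray(values, dtype=np.float64)
    rng = np.random.default_rng(seed)
    segments: list[tuple[GenomicInterval, float, int]] = []
    chroms = list(dict.fromkeys(iv.chrom for iv in intervals))
    for chrom in chroms:
        idx = [i for i, iv in enumerate(intervals) if iv.chrom == chrom]
        pts = [intervals[i] for i in idx]
        x = values[idx]
        ok = ~np.isnan(x)
        pts = [p for p, o in zip(pts, ok) if o]
        x = x[ok]
        if x.size == 0:
            continue
        if x.size == 1:
            segments.append((pts[0], float(x[0]), 1))
            continue
        breaks = segment_values(x, alpha=alpha, min_width=min_width, n_perm=n_perm, rng=rng)
        bounds = [0, *breaks, x.size]
        for a, b in zip(bounds[:-1], bounds[1:]):
            iv = GenomicInterval(chrom, pts[a].start, pts[b - 1].end)
            segments.append((iv, float(x[a:b].mean()), b - a))
    return SegmentTrack(segments=segments, genome=dict(genome))


def call_lads(
    segments: SegmentTrack,
    condition: str = "",
    threshold: float = 0.0,
    min_lad_size: int = 10_000,
    merge_gap: int = 5_000,
    track: tuple[list[GenomicInterval], np.ndarray] | None = None,
) -> LadSet:
    """Call LADs as above-threshold segments, merged and size-filtered.

    Segments with mean log-ratio > ``threshold`` are LAD candidates;
    candidates on the same chromosome separated by < ``merge_gap`` bp are
    merged (LADs are genomic regions, so short data gaps do not split
    them); merged candidates shorter than ``min_lad_size`` are dropped.
    """
    cands = [iv for iv, mean, _ in segments.segments if mean > threshold]
    cands = merge_intervals(cands)
    merged: list[GenomicInterval] = []
    for iv in cands:
        if (
            merged
            and merged[-1].chrom == iv.chrom
            and iv.start - merged[-1].end < merge_gap
        ):
            merged[-1] = GenomicInterval(iv.chrom, merged[-1].start, iv.end)
        else:
            merged.append(iv)
    lads = [iv for iv in merged if len(iv) >= min_lad_size]
    ladset = LadSet(condition=condition, lads=lads)
    ladset.metrics = lad_metrics(ladset, segments.genome, track=track)
    return ladset


def lad_metrics(
    ladset: LadSet,
    genome: dict[str, int],
    track: tuple[list[GenomicInterval], np.ndarray] | None = None,
) -> dict:
    """Summary metrics: count, % genome coverage, median size, and (when a
    log-ratio track is supplied) mean log-ratio inside vs outside LADs."""
    if not genome or sum(genome.values()) <= 0:
        raise ValueError("empty genome")
    sizes = np.array([len(iv) for iv in ladset.lads], dtype=np.int64)
    out = {
        "n_lads": int(len(ladset.lads)),
        "genome_coverage_pct": 100.0 * sizes.sum() / sum(genome.values()),
        "median_size_bp": float(np.median(sizes)) if sizes.size else 0.0,
        "mean_log_ratio_inside": np.nan,
        "mean_log_ratio_outside": np.nan,
    }
    if track is not None:
        ivs, vals = track
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for lad in ladset.lads:
            by_chrom.setdefault(lad.chrom, []).append((lad.start, lad.end))
        inside = np.zeros(len(ivs), dtype=bool)
        for i, iv in enumerate(ivs):
            mid = (iv.start + iv.end) // 2
            inside[i] = any(
                s <= mid < e for s, e in by_chrom.get(iv.chrom, ())
            )
        vals = np.asarray(vals, dtype=np.float64)
        ok = ~np.isnan(vals)
        if (ok & inside).any():
            out["mean_log_ratio_inside"] = float(vals[ok & inside].mean())
        if (ok & ~inside).any():
            out["mean_log_ratio_outside"] = float(vals[ok & ~inside].mean())
    return out
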