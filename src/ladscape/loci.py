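"""Positional classification of loci and expression concordance.

Loci (gene bodies, enhancers, miRNA-encoding intervals) are assigned to
positional classes relative to differential regions: ``released``
(inside a PI DR, moving periphery -> interior), ``recruited`` (inside an
IP DR), ``proximal_*`` (within a window of a DR without overlapping it),
or ``unchanged``. Knockdown dependence marks loci that normally
reposition during differentiation but fail to when a tether is depleted.
Expression tables from any DE tool are consumed after the post-fit
filters (intensity, fold-change, FDR) and cross-tabulated against the
positional calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .damid import LadSet
from .intervals import LocusAnnotation
from .repositioning import DifferentialRegion

__all__ = [
    "PositionalCall",
    "ExpressionRecord",
    "assign_positional_class",
    "kd_dependence",
    "apply_de_filters",
    "concordance_table",
    "venn_positional_sets",
    "mirna_target_concordance",
]

CORE_CLASSES = ("released", "recruited")
ALL_CLASSES = (
    "released",
    "recruited",
    "proximal_released",
    "proximal_recruited",
    "unchanged",
)


@dataclass
class PositionalCall:
    locus_id: str
    positional_class: str
    interval: object = None  # GenomicInterval of the locus
    ambiguous: bool = False
    kd_flags: dict[str, bool] = field(default_factory=dict)
    source_pair: tuple[str, str] = ("", "")

    def __post_init__(self) -> None:
        if self.positional_class not in ALL_CLASSES:
            raise ValueError(f"unknown positional class {self.positional_class!r}")


@dataclass
class ExpressionRecord:
    locus_id: str
    log2fc: float
    adj_p: float
    mean_intensity: float | None = None
    direction: str = "ns"

    def __post_init__(self) -> None:
        if not (0.0 <= self.adj_p <= 1.0):
            raise ValueError(f"adj_p out of [0,1] for {self.locus_id}: {self.adj_p}")
        if self.direction not in ("up", "down", "ns"):
            raise ValueError(f"unknown direction {self.direction!r}")


def _distance(iv, dr) -> int:
    if iv.chrom != dr.interval.chrom:
        return 1 << 62
    if iv.start < dr.interval.end and dr.interval.start < iv.end:
        return 0
    return max(dr.interval.start - iv.end, iv.start - dr.interval.end) + 1


def assign_positional_class(
    loci: list[LocusAnnotation],
    drs: list[DifferentialRegion],
    proximity_window: int = 5_000,
) -> list[PositionalCall]:
    """Classify each locus against the DR set.

    Overlap of >= 1 bp with a PI DR -> released, with an IP DR ->
    recruited (ties broken by larger overlap and flagged ambiguous).
    A non-overlapping locus within ``proximity_window`` bp of a DR is
    proximal to it (nearer DR wins). Everything else is unchanged.
    """
    ids = [loc.locus_id for loc in loci]
    if len(set(ids)) != len(ids):
        dupes = {i for i in ids if ids.count(i) > 1}
        raise ValueError(f"duplicate locus ids: {sorted(dupes)}")
    pi = [d for d in drs if d.direction == "PI"]
    ip = [d for d in drs if d.direction == "IP"]
    pair = drs[0].source_pair if drs else ("", "")
    calls = []
    for loc in loci:
        ov_pi = max((loc.interval.overlap_bp(d.interval) for d in pi), default=0)
        ov_ip = max((loc.interval.overlap_bp(d.interval) for d in ip), default=0)
        ambiguous = False
        if ov_pi > 0 or ov_ip > 0:
            if ov_pi > 0 and ov_ip > 0:
                ambiguous = True
            cls = "released" if ov_pi >= ov_ip else "recruited"
        else:
            d_pi = min((_distance(loc.interval, d) for d in pi), default=1 << 62)
            d_ip = min((_distance(loc.interval, d) for d in ip), default=1 << 62)
            nearest = min(d_pi, d_ip)
            if nearest <= proximity_window:
                cls = "proximal_released" if d_pi <= d_ip else "proximal_recruited"
            else:
                cls = "unchanged"
        calls.append(
            PositionalCall(loc.locus_id, cls, interval=loc.interval,
                           ambiguous=ambiguous, source_pair=pair)
        )
    return calls


def kd_dependence(
    calls: list[PositionalCall], lads_kd: dict[str, LadSet]
) -> list[PositionalCall]:
    """Flag loci whose normal repositioning fails under a knockdown.

    For each knockdown condition label: a normally released locus still
    overlapping a knockdown-condition LAD fails to release; a normally
    recruited locus overlapping no knockdown LAD fails to recruit.
    Flags are only set on released/recruited loci.
    """
    for call in calls:
        for label, ladset in lads_kd.items():
            in_lad = any(call.interval.overlaps(lad) for lad in ladset.lads)
            if call.positional_class == "released" and in_lad:
                call.kd_flags[f"fails_to_release_{label}"] = True
            elif call.positional_class == "recruited" and not in_lad:
                call.kd_flags[f"fails_to_recruit_{label}"] = True
    return calls


def apply_de_filters(
    records: list[ExpressionRecord],
    min_abs_log2fc: float = 0.5,
    min_intensity: float = 6.5,
    fdr: float = 0.05,
) -> list[ExpressionRecord]:
    """Post-fit differential-expression filters.

    Keeps records with |log2FC| >= ``min_abs_log2fc`` (default 0.5, i.e.
    1.4-fold; boundary inclusive), adjusted p < ``fdr``, and — when an
    intensity is present — intensity >= ``min_intensity`` (default 6.5
    on the log2 scale). Sets ``direction`` from the fold-change sign.
    """
    out = []
    for r in records:
        if r.mean_intensity is not None and r.mean_intensity < min_intensity:
            continue
        if abs(r.log2fc) < min_abs_log2fc or r.adj_p >= fdr:
            continue
        r.direction = "up" if r.log2fc > 0 else "down"
        out.append(r)
    return out


def concordance_table(
    calls: list[PositionalCall], records: list[ExpressionRecord]
) -> dict:
    """Cross-tab of positional class x expression direction.

    Rows are the repositioned classes (released, recruited); columns are
    up/down/ns. Loci in ``calls`` absent from ``records`` count as ns
    (their number is reported). Also returns the fraction of repositioned
    loci with any expression change, and the concordant-stratum counts
    (released & up, recruited & down).
    """
    by_id = {r.locus_id: r for r in records}
    table = pd.DataFrame(0, index=list(CORE_CLASSES), columns=["up", "down", "ns"])
    n_missing = 0
    for call in calls:
        if call.positional_class not in CORE_CLASSES:
            continue
        rec = by_id.get(call.locus_id)
        if rec is None:
            n_missing += 1
            direction = "ns"
        else:
            direction = rec.direction
        table.loc[call.positional_class, direction] += 1
    n_repos = int(table.to_numpy().sum())
    n_changed = int(table[["up", "down"]].to_numpy().sum())
    return {
        "table": table,
        "n_repositioned": n_repos,
        "n_changed": n_changed,
        "fraction_changed": n_changed / n_repos if n_repos else 0.0,
        "released_up": int(table.loc["released", "up"]),
        "recruited_down": int(table.loc["recruited", "down"]),
        "n_missing_records": n_missing,
    }


def venn_positional_sets(
    loci: list[LocusAnnotation],
    drs_wt: list[DifferentialRegion],
    lads_kd: dict[str, LadSet],
    proximity_window: int = 0,
) -> dict:
    """Venn-ready counts of normal vs knockdown-dependent repositioning."""
    calls = assign_positional_class(loci, drs_wt, proximity_window=proximity_window)
    calls = kd_dependence(calls, lads_kd)
    out: dict[str, object] = {
        "normally_released": sum(c.positional_class == "released" for c in calls),
        "normally_recruited": sum(c.positional_class == "recruited" for c in calls),
    }
    for label in lads_kd:
        out[f"fails_release_{label}"] = sum(
            c.kd_flags.get(f"fails_to_release_{label}", False) for c in calls
        )
        out[f"fails_recruit_{label}"] = sum(
            c.kd_flags.get(f"fails_to_recruit_{label}", False) for c in calls
        )
    out["calls"] = calls
    return out


def mirna_target_concordance(
    mirna_changes: list[tuple[str, str]],
    target_map: dict[str, list[str]],
    records: list[ExpressionRecord],
) -> dict:
    """Fraction of each changed miRNA's targets moving opposite to it.

    A target is concordant with miRNA biology when its direction is
    opposite to the miRNA's (an up-regulated miRNA represses its
    targets). Targets without a record count as ns in the denominator.
    miRNAs with no mapped targets are reported and excluded.
    """
    if not target_map:
        warnings.warn("empty miRNA target map", stacklevel=2)
        return {"per_mirna": {}, "no_target_mirnas": [m for m, _ in mirna_changes],
                "mean_concordance": float("nan"), "pooled_concordance": float("nan")}
    by_id = {r.locus_id: r for r in records}
    per: dict[str, dict] = {}
    skipped: list[str] = []
    conc_tot = n_tot = 0
    for mirna, direction in mirna_changes:
        if direction not in ("up", "down"):
            raise ValueError(f"miRNA direction must be up/down, got {direction!r}")
        targets = target_map.get(mirna, [])
        if not targets:
            skipped.append(mirna)
            continue
        opposite = "down" if direction == "up" else "up"
        counts = {"up": 0, "down": 0, "ns": 0}
        for t in targets:
            rec = by_id.get(t)
            counts[rec.direction if rec is not None else "ns"] += 1
        frac = counts[opposite] / len(targets)
        per[mirna] = {"direction": direction, "counts": counts, "concordant_fraction": frac}
        conc_tot += counts[opposite]
        n_tot += len(targets)
    mean = (
        sum(v["concordant_fraction"] for v in per.values()) / len(per) if per else float("nan")
    )
    return {
        "per_mirna": per,
        "no_target_mirnas": skipped,
        "mean_concordance": mean,
        "pooled_concordance": conc_tot / n_tot if n_tot else float("nan"),
    }
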