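"""Synthetic DamID adipogenesis study with planted truth.

Generates every input the pipeline consumes: a small multi-chromosome
genome tiled into GATC-like fragments; planted LAD landscapes for four
conditions (pre-adipocyte, adipocyte, adipocyte + single knockdown,
adipocyte + double knockdown); negative-binomial fragment counts with
LAD-dependent enrichment; gene/enhancer/miRNA loci placed inside,
adjacent to, or far from differential regions; expression tables in
which a set fraction of repositioned loci change concordantly; a Ct
matrix with planted up/down miRNAs; OCR stress-test traces with known
parameters; FISH distance samples and glucose curves. Everything is a
pure function of (spec, seed) and every planted quantity is recorded in
the truth manifest.

Default condition structure: ~44% of the genome in LADs; during
differentiation ~3.9% of the genome leaves LADs (whole-LAD losses,
edge truncations, internal holes) and ~4.1% is gained (edge expansions,
de-novo LADs); 10% of pre-adipocyte LADs are lost outright (retention
0.90); 35% of released genes fail to release in the single knockdown;
10% of repositioned genes change expression concordantly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .damid import DamProfile, LadSet
from .intervals import (
    FragmentMap,
    GenomicInterval,
    LocusAnnotation,
    interval_ops,
    total_bp,
    write_bed,
    write_bedgraph,
)
from .loci import ExpressionRecord
from .pheno import OcrTrace
from .qpcr import CtMatrix
from .repositioning import DifferentialRegion, retained_lad_fraction

__all__ = ["SyntheticSpec", "SyntheticBundle", "generate", "write_bundle"]

CONDITIONS = ("pre", "adip", "akd", "abkd")


@dataclass
class SyntheticSpec:
    seed: int = 1
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 2_000_000, "chr2": 2_000_000, "chr3": 2_000_000}
    )
    mean_fragment_length: int = 256
    min_fragment_length: int = 4

    # LAD landscape
    n_lads_per_chrom: int = 10
    lad_coverage: float = 0.44
    deletion_lad_size: int = 30_000  # one purpose-built small LAD per chromosome

    # differentiation changes (fractions of genome bp)
    frac_genome_lost: float = 0.039
    frac_genome_gained: float = 0.041
    frac_lads_deleted: float = 0.10
    n_truncations: int = 10
    n_internal_losses: int = 2
    internal_loss_size: int = 10_000
    n_expansions: int = 10
    n_de_novo: int = 4
    de_novo_size: int = 30_000

    # knockdown / paralog structure
    frac_released_kd_dependent: float = 0.35
    n_paralog_a_unique: int = 6
    n_paralog_b_unique: int = 9
    n_paralog_mixed: int = 4
    mixed_revert_fraction: float = 0.4  # single-KD partial reversion of a mixed event

    # fragment count model
    mean_reads_per_fragment: float = 20.0
    nb_dispersion: float = 10.0  # negative-binomial size parameter
    lad_log2_enrichment: float = 1.5
    noise_free: bool = False

    # loci
    n_genes_released: int = 20
    n_genes_recruited: int = 10
    n_genes_proximal: int = 6
    n_genes_unchanged: int = 64
    gene_length: int = 2_000
    enhancer_length: int = 1_000
    mirna_length: int = 500
    locus_margin: int = 2_500
    locus_spacing: int = 1_000
    proximal_offset: int = 3_000
    n_enhancers_recruited: int = 30
    n_enhancers_recruited_kd: int = 10
    n_enhancers_released: int = 15
    n_mirna_recruited: int = 3
    n_mirna_released: int = 2
    n_mirna_unchanged: int = 3

    # expression model
    frac_repositioned_expressed: float = 0.10
    de_log2fc: float = 2.0
    de_adj_p: float = 1e-4
    targets_per_mirna: int = 10
    target_concordance: float = 0.7

    # Ct model
    n_null_mirnas: int = 300
    n_up_mirnas: int = 12
    n_down_mirnas: int = 9
    n_housekeeping: int = 4
    n_plates_per_group: int = 5
    ct_plate_sd: float = 0.3
    ct_noise_sd: float = 0.15
    ct_effect: float = 1.5  # |ddCt| of planted miRNAs

    # OCR model (phase means, pmol O2/min)
    ocr_vehicle: dict[str, float] = field(
        default_factory=lambda: {"basal": 100.0, "oligo": 40.0, "fccp": 150.0, "rot_aa": 10.0}
    )
    ocr_uk5099: dict[str, float] = field(
        default_factory=lambda: {"basal": 70.0, "oligo": 30.0, "fccp": 90.0, "rot_aa": 10.0}
    )
    ocr_noise_sd: float = 3.0
    n_ocr_replicates: int = 5

    # FISH distances (µm) and GTT
    fish_mean_wt: float = 0.4
    fish_mean_kd: float = 1.2
    fish_sd: float = 0.3
    fish_n: int = 105
    gtt_times: tuple = (0, 15, 30, 60, 120)
    gtt_mice_per_group: int = 8
    gtt_noise_sd: float = 0.8

    def validate(self) -> None:
        for name in ("frac_genome_lost", "frac_genome_gained", "frac_lads_deleted",
                     "frac_released_kd_dependent", "frac_repositioned_expressed",
                     "target_concordance"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.frac_genome_lost >= self.lad_coverage:
            raise ValueError("cannot lose more LAD genome than exists in LADs")
        genome = sum(self.chrom_lengths.values())
        if (self.frac_genome_gained + self.lad_coverage) * genome > genome:
            raise ValueError("gained LADs exceed available non-LAD genome")


@dataclass
class _Event:
    eid: str
    kind: str  # deletion | truncation | internal | expansion | de_novo
    direction: str  # PI | IP
    interval: GenomicInterval
    paralog: str = "none"  # a | b | mixed | none
    akd_revert: GenomicInterval | None = None
    abkd_revert: GenomicInterval | None = None


@dataclass
class SyntheticBundle:
    spec: SyntheticSpec
    fragment_map: FragmentMap
    profiles: dict[str, DamProfile]
    truth_lads: dict[str, LadSet]
    truth_drs: list[DifferentialRegion]
    events: list[_Event]
    loci: list[LocusAnnotation]
    truth_loci: dict[str, dict]
    expression: list[ExpressionRecord]
    mirna_changes: list[tuple[str, str]]
    target_map: dict[str, list[str]]
    ct: CtMatrix
    ocr_vehicle: list[OcrTrace]
    ocr_uk5099: list[OcrTrace]
    fish_distances: dict[str, np.ndarray]
    gtt: dict[str, np.ndarray]
    truth: dict


# ---------------------------------------------------------------------------
# genome / LAD layout helpers
# ---------------------------------------------------------------------------


def _make_fragments(rng: np.random.Generator, spec: SyntheticSpec) -> FragmentMap:
    frags: list[GenomicInterval] = []
    lo = spec.min_fragment_length
    p = 1.0 / max(spec.mean_fragment_length - lo + 1, 2)
    for chrom, length in spec.chrom_lengths.items():
        pos = 0
        starts = [0]
        while pos < length:
            pos += lo - 1 + int(rng.geometric(p))
            if pos >= length:
                break
            starts.append(pos)
        if len(starts) > 1 and length - starts[-1] < lo:
            starts.pop()
        bounds = starts + [length]
        for s, e in zip(bounds[:-1], bounds[1:]):
            frags.append(GenomicInterval(chrom, s, e))
    return FragmentMap(genome=dict(spec.chrom_lengths), fragments=frags)


def _snapper(fm: FragmentMap):
    bounds = {
        chrom: np.append(fm.starts(chrom), fm.genome[chrom]) for chrom in fm.genome
    }

    def snap(chrom: str, pos: int) -> int:
        b = bounds[chrom]
        i = np.searchsorted(b, pos)
        if i == 0:
            return int(b[0])
        if i == len(b):
            return int(b[-1])
        return int(b[i] if b[i] - pos < pos - b[i - 1] else b[i - 1])

    return snap


def _layout_pre_lads(rng, spec: SyntheticSpec, snap) -> list[GenomicInterval]:
    lads: list[GenomicInterval] = []
    n = spec.n_lads_per_chrom
    for chrom, length in spec.chrom_lengths.items():
        lad_bp = spec.lad_coverage * length
        small = min(spec.deletion_lad_size, lad_bp / n) if n else 0
        w = rng.uniform(0.7, 1.3, size=max(n - 1, 0))
        sizes = list((w / w.sum()) * (lad_bp - small)) if n > 1 else []
        small_at = int(rng.integers(0, n)) if n else 0
        sizes.insert(small_at, small)
        gw = rng.uniform(0.7, 1.3, size=n + 1)
        gaps = (gw / gw.sum()) * (length - sum(sizes))
        pos = 0.0
        for i in range(n):
            pos += gaps[i]
            s = snap(chrom, int(round(pos)))
            e = snap(chrom, int(round(pos + sizes[i])))
            lads.append(GenomicInterval(chrom, s, e))
            pos += sizes[i]
    return lads


def _plan_events(rng, spec: SyntheticSpec, snap, pre_lads) -> list[_Event]:
    genome = sum(spec.chrom_lengths.values())
    lost_bp = spec.frac_genome_lost * genome
    gained_bp = spec.frac_genome_gained * genome
    events: list[_Event] = []
    if lost_bp <= 0 and gained_bp <= 0:
        return events

    by_size = sorted(pre_lads, key=len)
    n_del = int(round(spec.frac_lads_deleted * len(pre_lads))) if lost_bp > 0 else 0
    deleted = by_size[:n_del]
    deleted_bp = sum(len(lad) for lad in deleted)
    for k, lad in enumerate(deleted, 1):
        events.append(_Event(f"D{k}", "deletion", "PI", lad))

    survivors = [lad for lad in pre_lads if lad not in deleted]
    used: set[GenomicInterval] = set()

    n_int = spec.n_internal_losses if lost_bp > 0 else 0
    trunc_total = lost_bp - deleted_bp - n_int * spec.internal_loss_size
    n_trunc = spec.n_truncations if trunc_total > 0 else 0
    if n_trunc:
        if trunc_total / n_trunc < 2 * spec.locus_margin + spec.gene_length:
            raise ValueError(
                "infeasible layout: truncation events too small to host loci "
                "(reduce n_truncations or locus sizes)"
            )
        idx = rng.choice(len(survivors), size=min(n_trunc, len(survivors)), replace=False)
        per = trunc_total / len(idx)
        for k, i in enumerate(sorted(idx), 1):
            lad = survivors[i]
            e = snap(lad.chrom, lad.start + int(per))
            e = min(max(e, lad.start + spec.min_fragment_length), lad.end - 10_000)
            events.append(_Event(f"T{k}", "truncation", "PI", GenomicInterval(lad.chrom, lad.start, e)))
            used.add(lad)

    if n_int:
        candidates = [lad for lad in survivors if lad not in used and len(lad) >= 4 * spec.internal_loss_size]
        for k in range(min(n_int, len(candidates))):
            lad = candidates[k]
            # off-centre so the larger remnant keeps >= half the LAD and
            # the original LAD still counts as retained
            at = lad.start + len(lad) // 5
            s = snap(lad.chrom, at)
            e = snap(lad.chrom, at + spec.internal_loss_size)
            events.append(_Event(f"I{k + 1}", "internal", "PI", GenomicInterval(lad.chrom, s, e)))
            used.add(lad)

    n_dn = spec.n_de_novo if gained_bp > 0 else 0
    exp_total = gained_bp - n_dn * spec.de_novo_size
    n_exp = spec.n_expansions if exp_total > 0 else 0
    if n_exp:
        # expand the right edge of a LAD into the following gap
        nxt: dict[GenomicInterval, int] = {}
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for lad in pre_lads:
            by_chrom.setdefault(lad.chrom, []).append(lad)
        for chrom, lads in by_chrom.items():
            lads = sorted(lads, key=lambda x: x.start)
            for a, b in zip(lads[:-1], lads[1:]):
                nxt[a] = b.start
            nxt[lads[-1]] = spec.chrom_lengths[chrom]
        per = exp_total / n_exp
        cands = [lad for lad in survivors if lad not in used and nxt[lad] - lad.end > per + 12_000]
        if len(cands) < n_exp:
            cands = [lad for lad in survivors if nxt[lad] - lad.end > per + 12_000]
        idx = rng.choice(len(cands), size=min(n_exp, len(cands)), replace=False)
        for k, i in enumerate(sorted(idx), 1):
            lad = cands[i]
            e = snap(lad.chrom, lad.end + int(per))
            events.append(_Event(f"E{k}", "expansion", "IP", GenomicInterval(lad.chrom, lad.end, e)))
            used.add(lad)

    if n_dn:
        # centre de-novo LADs in the largest inter-LAD gaps
        gaps: list[GenomicInterval] = interval_ops(
            [GenomicInterval(c, 0, L) for c, L in spec.chrom_lengths.items()],
            pre_lads + [ev.interval for ev in events if ev.direction == "IP"],
            "subtract",
        )
        gaps = sorted(gaps, key=len, reverse=True)
        for k in range(min(n_dn, len(gaps))):
            gap = gaps[k]
            if len(gap) < spec.de_novo_size + 24_000:
                raise ValueError("infeasible layout: no gap large enough for de-novo LAD")
            mid = (gap.start + gap.end) // 2
            s = snap(gap.chrom, mid - spec.de_novo_size // 2)
            e = snap(gap.chrom, mid + spec.de_novo_size // 2)
            events.append(_Event(f"N{k + 1}", "de_novo", "IP", GenomicInterval(gap.chrom, s, e)))
    return events


def _assign_paralogs(spec: SyntheticSpec, snap, events: list[_Event]) -> None:
    """Mark events a_unique / b_unique / mixed and set reversion intervals."""
    by_kind = {k: [e for e in events if e.kind == k] for k in
               ("deletion", "truncation", "internal", "expansion", "de_novo")}
    a_order = (by_kind["deletion"][:1] + by_kind["truncation"][:3] + by_kind["expansion"][:2])
    a_set = a_order[: spec.n_paralog_a_unique]
    taken = set(id(e) for e in a_set)
    mixed_pool = [
        e for e in by_kind["de_novo"] + by_kind["expansion"][::-1]
        if id(e) not in taken and len(e.interval) * spec.mixed_revert_fraction >= 5_000
    ]
    mixed = mixed_pool[: spec.n_paralog_mixed]
    taken |= set(id(e) for e in mixed)
    b_pool = [e for e in events if id(e) not in taken]
    b_set = b_pool[: spec.n_paralog_b_unique]

    for e in a_set:
        e.paralog = "a"
        e.akd_revert = e.interval
        e.abkd_revert = e.interval
    for e in b_set:
        e.paralog = "b"
        e.abkd_revert = e.interval
    for e in mixed:
        e.paralog = "mixed"
        iv = e.interval
        cut = snap(iv.chrom, iv.end - int(len(iv) * spec.mixed_revert_fraction))
        e.akd_revert = GenomicInterval(iv.chrom, cut, iv.end)  # outer portion only
        e.abkd_revert = iv


def _condition_lads(spec: SyntheticSpec, pre: list[GenomicInterval], events: list[_Event]):
    pi = [e.interval for e in events if e.direction == "PI"]
    ip = [e.interval for e in events if e.direction == "IP"]
    adip = interval_ops(interval_ops(pre, pi, "subtract"), ip, "union")

    def kd(which: str) -> list[GenomicInterval]:
        add = [getattr(e, which) for e in events
               if e.direction == "PI" and getattr(e, which) is not None]
        rem = [getattr(e, which) for e in events
               if e.direction == "IP" and getattr(e, which) is not None]
        return interval_ops(interval_ops(adip, rem, "subtract"), add, "union")

    return {
        "pre": LadSet("pre", list(pre)),
        "adip": LadSet("adip", adip),
        "akd": LadSet("akd", kd("akd_revert")),
        "abkd": LadSet("abkd", kd("abkd_revert")),
    }


# ---------------------------------------------------------------------------
# locus placement
# ---------------------------------------------------------------------------


class _RegionAlloc:
    """Sequential sub-interval allocator inside one region with margins."""

    def __init__(self, interval: GenomicInterval, margin: int, spacing: int):
        self.chrom = interval.chrom
        self.cursor = interval.start + margin
        self.limit = interval.end - margin
        self.spacing = spacing

    def take(self, length: int) -> GenomicInterval | None:
        if self.cursor + length > self.limit:
            return None
        iv = GenomicInterval(self.chrom, self.cursor, self.cursor + length)
        self.cursor += length + self.spacing
        return iv


class _Placer:
    def __init__(self, spec: SyntheticSpec, events: list[_Event]):
        self.spec = spec
        self.allocs: dict[tuple[str, str], _RegionAlloc] = {}
        self.events = {e.eid: e for e in events}
        self.loci: list[LocusAnnotation] = []
        self.truth: dict[str, dict] = {}

    def _alloc(self, ev: _Event, region: str) -> _RegionAlloc:
        key = (ev.eid, region)
        if key not in self.allocs:
            if region == "full":
                iv = ev.interval
            elif region == "akd_part":
                iv = ev.akd_revert
            elif region == "non_akd_part":
                if ev.akd_revert is None:
                    iv = ev.interval
                else:
                    rest = interval_ops([ev.interval], [ev.akd_revert], "subtract")
                    iv = rest[0]
            else:
                raise ValueError(region)
            self.allocs[key] = _RegionAlloc(iv, self.spec.locus_margin, self.spec.locus_spacing)
        return self.allocs[key]

    def place(self, kind: str, length: int, ev: _Event, region: str, prefix: str) -> bool:
        iv = self._alloc(ev, region).take(length)
        if iv is None:
            return False
        lid = f"{prefix}{len(self.loci):03d}"
        self.loci.append(LocusAnnotation(lid, iv, kind))
        cls = "released" if ev.direction == "PI" else "recruited"
        covered_a = ev.akd_revert is not None and (
            ev.akd_revert.start <= iv.start and iv.end <= ev.akd_revert.end
        )
        covered_ab = ev.abkd_revert is not None and (
            ev.abkd_revert.start <= iv.start and iv.end <= ev.abkd_revert.end
        )
        self.truth[lid] = {
            "class": cls,
            "event": ev.eid,
            "fails_akd": covered_a,
            "fails_abkd": covered_ab,
        }
        return True

    def place_many(
        self, kind: str, length: int, n: int, pool: list[tuple[_Event, str]], prefix: str
    ) -> int:
        placed = 0
        guard = 0
        while placed < n and guard < 10 * n * max(len(pool), 1):
            progressed = False
            for ev, region in pool:
                if placed >= n:
                    break
                if self.place(kind, length, ev, region, prefix):
                    placed += 1
                    progressed = True
            guard += 1
            if not progressed:
                break
        return placed


def _place_loci(rng, spec: SyntheticSpec, events: list[_Event], lads_by_cond):
    placer = _Placer(spec, events)
    pi_a = [(e, "full") for e in events if e.direction == "PI" and e.paralog == "a"]
    pi_other = [(e, "full") for e in events if e.direction == "PI" and e.paralog in ("none", "b")]
    ip_non_akd = [
        (e, "non_akd_part" if e.paralog == "mixed" else "full")
        for e in events
        if e.direction == "IP" and e.paralog in ("none", "b", "mixed")
    ]
    ip_akd = [(e, "full") for e in events if e.direction == "IP" and e.paralog == "a"] + [
        (e, "akd_part") for e in events if e.direction == "IP" and e.paralog == "mixed"
    ]

    # genes: exact knockdown-dependent fraction among released loci
    n_kd = int(round(spec.frac_released_kd_dependent * spec.n_genes_released))
    got = placer.place_many("gene", spec.gene_length, n_kd, pi_a, "g")
    got += placer.place_many("gene", spec.gene_length, spec.n_genes_released - n_kd, pi_other, "g")
    if spec.n_genes_released and got < spec.n_genes_released:
        raise ValueError("infeasible layout: not enough differential-region room for released genes")
    if placer.place_many("gene", spec.gene_length, spec.n_genes_recruited, ip_non_akd, "g") < spec.n_genes_recruited:
        raise ValueError("infeasible layout: not enough room for recruited genes")

    # enhancers: exact knockdown-dependent count among recruited enhancers
    placer.place_many("enhancer", spec.enhancer_length, spec.n_enhancers_recruited_kd, ip_akd, "e")
    placer.place_many(
        "enhancer",
        spec.enhancer_length,
        spec.n_enhancers_recruited - spec.n_enhancers_recruited_kd,
        ip_non_akd,
        "e",
    )
    placer.place_many("enhancer", spec.enhancer_length, spec.n_enhancers_released, pi_a + pi_other, "e")

    # miRNA loci inside DRs
    placer.place_many("mirna", spec.mirna_length, spec.n_mirna_recruited, ip_akd + ip_non_akd, "m")
    placer.place_many("mirna", spec.mirna_length, spec.n_mirna_released, pi_a + pi_other, "m")

    # proximal genes: just outside a DR's outer edge
    ip_events = [e for e in events if e.direction == "IP"]
    pi_events = [e for e in events if e.direction == "PI"]
    n_prox = spec.n_genes_proximal
    k = 0
    for i in range(n_prox):
        side_ip = i % 2 == 0
        pool = ip_events if side_ip else pi_events
        if not pool:
            pool = ip_events or pi_events
        if not pool:
            break
        ev = pool[(i // 2) % len(pool)]
        if ev.direction == "IP":
            start = ev.interval.end + spec.proximal_offset
        else:
            start = ev.interval.start - spec.proximal_offset - spec.gene_length
        iv = GenomicInterval(ev.interval.chrom, start, start + spec.gene_length)
        lid = f"g{len(placer.loci):03d}"
        placer.loci.append(LocusAnnotation(lid, iv, "gene"))
        placer.truth[lid] = {
            "class": "proximal_recruited" if ev.direction == "IP" else "proximal_released",
            "event": ev.eid,
            "fails_akd": False,
            "fails_abkd": False,
        }
        k += 1

    # unchanged loci: far (>6 kb) from every event, clear of placed loci
    genome_ivs = [GenomicInterval(c, 0, L) for c, L in spec.chrom_lengths.items()]
    pad = 6_000
    forbidden = [
        GenomicInterval(e.interval.chrom, max(0, e.interval.start - pad), e.interval.end + pad)
        for e in events
    ] + [
        GenomicInterval(l.interval.chrom, max(0, l.interval.start - 1_000), l.interval.end + 1_000)
        for l in placer.loci
    ]
    safe = sorted(interval_ops(genome_ivs, forbidden, "subtract"), key=len, reverse=True)
    todo = [("gene", spec.gene_length, spec.n_genes_unchanged, "g"),
            ("mirna", spec.mirna_length, spec.n_mirna_unchanged, "m")]
    allocs = [_RegionAlloc(iv, 2_000, 8_000) for iv in safe if len(iv) > 20_000]
    for kind, length, n, prefix in todo:
        placed = 0
        for al in allocs:
            while placed < n:
                iv = al.take(length)
                if iv is None:
                    break
                lid = f"{prefix}{len(placer.loci):03d}"
                placer.loci.append(LocusAnnotation(lid, iv, kind))
                placer.truth[lid] = {"class": "unchanged", "event": None,
                                     "fails_akd": False, "fails_abkd": False}
                placed += 1
            if placed >= n:
                break
        if placed < n:
            raise ValueError(f"infeasible layout: no room for {n} unchanged {kind} loci")
    return placer.loci, placer.truth


# ---------------------------------------------------------------------------
# measurement-side generators
# ---------------------------------------------------------------------------


def _make_counts(rng, spec: SyntheticSpec, fm: FragmentMap, ladset: LadSet, cond: str) -> DamProfile:
    inside = np.zeros(fm.n_fragments, dtype=bool)
    lads_by_chrom: dict[str, np.ndarray] = {}
    for lad in ladset.lads:
        lads_by_chrom.setdefault(lad.chrom, [])
        lads_by_chrom[lad.chrom].append((lad.start, lad.end))
    for chrom in fm.genome:
        sl = fm.chrom_slice(chrom)
        starts, ends = fm.starts(chrom), fm.ends(chrom)
        mids = (starts + ends) // 2
        flags = np.zeros(mids.size, dtype=bool)
        for s, e in lads_by_chrom.get(chrom, ()):
            flags |= (mids >= s) & (mids < e)
        inside[sl] = flags
    base = spec.mean_reads_per_fragment
    mean_fusion = np.where(inside, base * 2.0**spec.lad_log2_enrichment, base)
    if spec.noise_free:
        fusion = np.round(mean_fusion).astype(np.int64)
        dam = np.full(fm.n_fragments, int(round(base)), dtype=np.int64)
    else:
        size = spec.nb_dispersion
        fusion = rng.negative_binomial(size, size / (size + mean_fusion))
        dam = rng.negative_binomial(size, size / (size + base), size=fm.n_fragments)
    return DamProfile(condition=cond, fragment_map=fm, counts_fusion=fusion, counts_dam=dam)


def _make_expression(rng, spec: SyntheticSpec, loci, truth_loci):
    genes = [l.locus_id for l in loci if l.locus_kind == "gene"]
    released = [g for g in genes if truth_loci[g]["class"] == "released"]
    recruited = [g for g in genes if truth_loci[g]["class"] == "recruited"]
    unchanged = [g for g in genes if truth_loci[g]["class"] == "unchanged"]
    n_repos = len(released) + len(recruited)
    n_changed = int(round(spec.frac_repositioned_expressed * n_repos))
    n_up = int(round(n_changed * len(released) / n_repos)) if n_repos else 0
    up_ids = set(released[: n_up])
    down_ids = set(recruited[: n_changed - n_up])

    records: list[ExpressionRecord] = []
    for g in genes:
        if g in up_ids:
            records.append(ExpressionRecord(g, spec.de_log2fc, spec.de_adj_p, 8.0))
        elif g in down_ids:
            records.append(ExpressionRecord(g, -spec.de_log2fc, spec.de_adj_p, 8.0))
        else:
            records.append(
                ExpressionRecord(
                    g,
                    float(rng.normal(0.0, 0.1)),
                    float(rng.uniform(0.2, 0.99)),
                    float(rng.uniform(7.0, 9.0)),
                )
            )
    # decoys that each fail exactly one post-fit filter
    for g, fc, p, inten in zip(unchanged[:3],
                               (spec.de_log2fc, 0.4, spec.de_log2fc),
                               (spec.de_adj_p, spec.de_adj_p, 0.5),
                               (6.0, 8.0, 8.0)):
        rec = next(r for r in records if r.locus_id == g)
        rec.log2fc, rec.adj_p, rec.mean_intensity = fc, p, inten

    # changed miRNAs: DR-overlapping miRNA loci; targets move opposite
    mirna_changes: list[tuple[str, str]] = []
    target_map: dict[str, list[str]] = {}
    for l in loci:
        if l.locus_kind != "mirna":
            continue
        cls = truth_loci[l.locus_id]["class"]
        if cls == "recruited":
            direction = "up"
        elif cls == "released":
            direction = "down"
        else:
            continue
        mirna_changes.append((l.locus_id, direction))
        opp = "down" if direction == "up" else "up"
        n_conc = int(round(spec.target_concordance * spec.targets_per_mirna))
        tids = []
        for k in range(spec.targets_per_mirna):
            tid = f"tgt_{l.locus_id}_{k:02d}"
            tids.append(tid)
            if k < n_conc:
                fc = spec.de_log2fc if opp == "up" else -spec.de_log2fc
                records.append(ExpressionRecord(tid, fc, spec.de_adj_p, 8.0))
            else:
                records.append(
                    ExpressionRecord(tid, float(rng.normal(0, 0.1)),
                                     float(rng.uniform(0.2, 0.99)), 8.0)
                )
        target_map[l.locus_id] = tids
    return records, mirna_changes, target_map


def _make_ct(rng, spec: SyntheticSpec) -> tuple[CtMatrix, dict]:
    assays = (
        [f"mir_up_{i:03d}" for i in range(spec.n_up_mirnas)]
        + [f"mir_down_{i:03d}" for i in range(spec.n_down_mirnas)]
        + [f"mir_null_{i:03d}" for i in range(spec.n_null_mirnas)]
        + [f"hk_{i}" for i in range(spec.n_housekeeping)]
    )
    plates = [f"ctrl_{i}" for i in range(spec.n_plates_per_group)] + [
        f"ko_{i}" for i in range(spec.n_plates_per_group)
    ]
    groups = {p: ("control" if p.startswith("ctrl") else "knockout") for p in plates}
    base = rng.uniform(22.0, 30.0, size=len(assays))
    base[-spec.n_housekeeping:] = 20.0
    plate_eff = rng.normal(0.0, spec.ct_plate_sd, size=len(plates))
    values = np.empty((len(assays), len(plates)))
    for j, plate in enumerate(plates):
        eff = np.zeros(len(assays))
        if groups[plate] == "knockout":
            eff[: spec.n_up_mirnas] = -spec.ct_effect  # lower Ct = more abundant
            eff[spec.n_up_mirnas: spec.n_up_mirnas + spec.n_down_mirnas] = spec.ct_effect
        noise = rng.normal(0.0, spec.ct_noise_sd, size=len(assays))
        noise[-spec.n_housekeeping:] = rng.normal(0.0, 0.05, size=spec.n_housekeeping)
        values[:, j] = base + plate_eff[j] + eff + noise
    values = np.clip(values, 1.0, 45.0)
    ct = CtMatrix(
        values=pd.DataFrame(values, index=assays, columns=plates),
        groups=groups,
        housekeeping_ids=[f"hk_{i}" for i in range(spec.n_housekeeping)],
    )
    truth = {"n_up": spec.n_up_mirnas, "n_down": spec.n_down_mirnas, "ddct": spec.ct_effect}
    return ct, truth


def _make_ocr(rng, spec: SyntheticSpec, means: dict[str, float], rep: str) -> OcrTrace:
    phase_t = {"basal": [1, 7, 13], "oligo": [16, 22, 28], "fccp": [31, 37, 43], "rot_aa": [46, 52, 58]}
    times, vals = [], []
    for phase in ("basal", "oligo", "fccp", "rot_aa"):
        for t in phase_t[phase]:
            times.append(float(t))
            noise = 0.0 if spec.noise_free else float(rng.normal(0.0, spec.ocr_noise_sd))
            vals.append(means[phase] + noise)
    injections = [("oligomycin", 15.0), ("FCCP", 30.0), ("rotenone+antimycinA", 45.0)]
    return OcrTrace(np.array(times), np.array(vals), injections, replicate_id=rep)


def _make_gtt(rng, spec: SyntheticSpec) -> dict[str, np.ndarray]:
    times = np.array(spec.gtt_times, dtype=float)
    shapes = {
        "control": np.array([7.0, 16.0, 14.0, 10.0, 8.0]),
        "knockout": np.array([7.5, 19.0, 18.0, 14.0, 10.0]),
    }
    out = {"times": times}
    for grp, shape in shapes.items():
        out[grp] = shape + rng.normal(0.0, spec.gtt_noise_sd, size=(spec.gtt_mice_per_group, times.size))
    return out


# ---------------------------------------------------------------------------
# top-level generation
# ---------------------------------------------------------------------------


def generate(spec: SyntheticSpec | None = None) -> SyntheticBundle:
    """Build the full fixture bundle; pure function of the spec (and its seed)."""
    spec = spec or SyntheticSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    fm = _make_fragments(rng, spec)
    snap = _snapper(fm)
    pre = _layout_pre_lads(rng, spec, snap)
    events = _plan_events(rng, spec, snap, pre)
    _assign_paralogs(spec, snap, events)
    lads = _condition_lads(spec, pre, events)

    truth_drs = [
        DifferentialRegion(e.interval, e.direction, source_pair=("pre", "adip"))
        for e in events
    ]
    loci, truth_loci = _place_loci(rng, spec, events, lads)
    expression, mirna_changes, target_map = _make_expression(rng, spec, loci, truth_loci)
    profiles = {c: _make_counts(rng, spec, fm, lads[c], c) for c in CONDITIONS}
    ct, ct_truth = _make_ct(rng, spec)
    ocr_vehicle = [_make_ocr(rng, spec, spec.ocr_vehicle, f"veh_{i}") for i in range(spec.n_ocr_replicates)]
    ocr_uk = [_make_ocr(rng, spec, spec.ocr_uk5099, f"uk_{i}") for i in range(spec.n_ocr_replicates)]
    fish = {
        "wt": np.abs(rng.normal(spec.fish_mean_wt, spec.fish_sd, size=spec.fish_n)),
        "akd": np.abs(rng.normal(spec.fish_mean_kd, spec.fish_sd, size=spec.fish_n)),
    }
    gtt = _make_gtt(rng, spec)

    genome = sum(spec.chrom_lengths.values())
    pi_bp = total_bp([e.interval for e in events if e.direction == "PI"])
    ip_bp = total_bp([e.interval for e in events if e.direction == "IP"])
    released = [l for l in loci if truth_loci[l.locus_id]["class"] == "released" and l.locus_kind == "gene"]
    recruited = [l for l in loci if truth_loci[l.locus_id]["class"] == "recruited" and l.locus_kind == "gene"]
    n_kd = sum(truth_loci[l.locus_id]["fails_akd"] for l in released)
    enh_rec = [l for l in loci if l.locus_kind == "enhancer" and truth_loci[l.locus_id]["class"] == "recruited"]
    truth = {
        "seed": spec.seed,
        "genome_bp": genome,
        "lad_coverage_pct": {
            c: 100.0 * total_bp(lads[c].lads) / genome for c in CONDITIONS
        },
        "n_pre_lads": len(pre),
        "pct_genome_lost": 100.0 * pi_bp / genome,
        "pct_genome_gained": 100.0 * ip_bp / genome,
        "retained_lad_fraction": (
            retained_lad_fraction(lads["pre"], lads["adip"]) if pre else float("nan")
        ),
        "n_genes_released": len(released),
        "n_genes_recruited": len(recruited),
        "kd_dependent_released_fraction": n_kd / len(released) if released else 0.0,
        "repositioned_expression_change_fraction": spec.frac_repositioned_expressed,
        "paralog_counts": {
            "a_unique": sum(1 for e in events if e.paralog == "a"),
            "b_unique": sum(1 for e in events if e.paralog == "b"),
            "mixed": sum(1 for e in events if e.paralog == "mixed"),
        },
        "enhancers_recruited": len(enh_rec),
        "enhancers_recruited_kd_dependent": sum(
            truth_loci[l.locus_id]["fails_akd"] for l in enh_rec
        ),
        "mirna_up": ct_truth["n_up"],
        "mirna_down": ct_truth["n_down"],
        "mirna_target_concordance": spec.target_concordance,
        "ocr_vehicle": dict(spec.ocr_vehicle),
        "ocr_uk5099": dict(spec.ocr_uk5099),
    }
    return SyntheticBundle(
        spec=spec,
        fragment_map=fm,
        profiles=profiles,
        truth_lads=lads,
        truth_drs=truth_drs,
        events=events,
        loci=loci,
        truth_loci=truth_loci,
        expression=expression,
        mirna_changes=mirna_changes,
        target_map=target_map,
        ct=ct,
        ocr_vehicle=ocr_vehicle,
        ocr_uk5099=ocr_uk,
        fish_distances=fish,
        gtt=gtt,
        truth=truth,
    )


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> None:
    """Emit the bundle in the external formats each pipeline stage reads."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    fm = bundle.fragment_map
    for cond, prof in bundle.profiles.items():
        write_bedgraph(out / f"{cond}_fusion.bedgraph", fm.fragments, prof.counts_fusion)
        write_bedgraph(out / f"{cond}_dam.bedgraph", fm.fragments, prof.counts_dam)
        write_bed(out / f"{cond}_truth_lads.bed", bundle.truth_lads[cond].lads)
    write_bed(
        out / "loci.bed",
        [l.interval for l in bundle.loci],
        names=[f"{l.locus_id}|{l.locus_kind}" for l in bundle.loci],
    )
    pd.DataFrame(
        [
            {
                "locus_id": r.locus_id,
                "log2fc": r.log2fc,
                "adj_p": r.adj_p,
                "mean_intensity": r.mean_intensity,
            }
            for r in bundle.expression
        ]
    ).to_csv(out / "expression.csv", index=False)
    bundle.ct.values.to_csv(out / "ct_matrix.csv")
    with open(out / "ct_groups.csv", "w") as fh:
        fh.write("plate,group\n")
        for p, g in bundle.ct.groups.items():
            fh.write(f"{p},{g}\n")
    rows = []
    for tr in bundle.ocr_vehicle + bundle.ocr_uk5099:
        for t, v in zip(tr.timepoints, tr.ocr):
            rows.append({"replicate": tr.replicate_id, "time_min": t, "ocr": v})
    pd.DataFrame(rows).to_csv(out / "ocr_traces.csv", index=False)
    with open(out / "chrom_sizes.tsv", "w") as fh:
        for c, L in fm.genome.items():
            fh.write(f"{c}\t{L}\n")
    with open(out / "truth.json", "w") as fh:
        json.dump(_jsonable(bundle.truth), fh, indent=2)
    with open(out / "spec.json", "w") as fh:
        json.dump(_jsonable(dataclasses.asdict(bundle.spec)), fh, indent=2)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
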