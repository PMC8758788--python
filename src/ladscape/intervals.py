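"""Genomic interval algebra and text-format I/O.

All coordinates are 0-based, half-open (BED convention). GFF3 input
(1-based, inclusive) is converted on read. Strand is carried but ignored
by all overlap logic. Chromosome names are taken verbatim from input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "FragmentMap",
    "LocusAnnotation",
    "merge_intervals",
    "interval_ops",
    "jaccard",
    "total_bp",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_gff3",
]


class BedParseError(ValueError):
    """Raised on a malformed line in a BED/bedGraph file."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class FragmentMap:
    """Genome tiled into restriction fragments (e.g. DpnI/GATC fragments).

    ``genome`` maps chromosome name to length; ``fragments`` is the full,
    ordered, disjoint tiling of every chromosome. Fragments are the unit
    of DamID resolution, so every per-fragment array in the pipeline is
    indexed in this order.
    """

    genome: dict[str, int]
    fragments: list[GenomicInterval]
    _index: dict[str, slice] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.validate()
        self._build_index()

    def validate(self) -> None:
        pos: dict[str, int] = {c: 0 for c in self.genome}
        seen: list[str] = []
        for frag in self.fragments:
            if frag.chrom not in self.genome:
                raise ValueError(f"fragment on unknown chromosome {frag.chrom}")
            if not seen or seen[-1] != frag.chrom:
                if frag.chrom in seen:
                    raise ValueError("fragments not grouped by chromosome")
                seen.append(frag.chrom)
            if frag.start != pos[frag.chrom]:
                raise ValueError(
                    f"fragments do not tile {frag.chrom}: gap/overlap at "
                    f"{pos[frag.chrom]} vs fragment start {frag.start}"
                )
            if len(frag) < 4:
                raise ValueError(f"fragment shorter than 4 bp: {frag}")
            pos[frag.chrom] = frag.end
        for chrom, length in self.genome.items():
            if pos[chrom] != length:
                raise ValueError(
                    f"fragments cover {pos[chrom]} of {length} bp on {chrom}"
                )

    def _build_index(self) -> None:
        self._index = {}
        start = 0
        current: str | None = None
        for i, frag in enumerate(self.fragments):
            if frag.chrom != current:
                if current is not None:
                    self._index[current] = slice(start, i)
                current, start = frag.chrom, i
        if current is not None:
            self._index[current] = slice(start, len(self.fragments))

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    @property
    def genome_size(self) -> int:
        return sum(self.genome.values())

    def chrom_slice(self, chrom: str) -> slice:
        """Slice of the fragment array belonging to one chromosome."""
        return self._index[chrom]

    def starts(self, chrom: str) -> np.ndarray:
        sl = self.chrom_slice(chrom)
        return np.array([f.start for f in self.fragments[sl]], dtype=np.int64)

    def ends(self, chrom: str) -> np.ndarray:
        sl = self.chrom_slice(chrom)
        return np.array([f.end for f in self.fragments[sl]], dtype=np.int64)


@dataclass(frozen=True)
class LocusAnnotation:
    """A named locus (gene body, enhancer, or miRNA-encoding interval)."""

    locus_id: str
    interval: GenomicInterval
    locus_kind: str = "gene"

    def __post_init__(self) -> None:
        if self.locus_kind not in ("gene", "enhancer", "mirna"):
            raise ValueError(f"unknown locus_kind {self.locus_kind!r}")


# ---------------------------------------------------------------------------
# interval algebra (per-chromosome sorted numpy arrays under the hood)
# ---------------------------------------------------------------------------


def _by_chrom(ivs: Iterable[GenomicInterval]) -> dict[str, np.ndarray]:
    out: dict[str, list[tuple[int, int]]] = {}
    for iv in ivs:
        out.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return {
        c: np.array(sorted(pairs), dtype=np.int64).reshape(-1, 2)
        for c, pairs in out.items()
    }


def _merge_arr(arr: np.ndarray) -> np.ndarray:
    if arr.shape[0] <= 1:
        return arr
    merged = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.array(merged, dtype=np.int64)


def _subtract_arr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """a minus b; both merged+sorted."""
    out: list[tuple[int, int]] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def _intersect_arr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def _to_ivs(per_chrom: dict[str, np.ndarray]) -> list[GenomicInterval]:
    out: list[GenomicInterval] = []
    for chrom in sorted(per_chrom):
        for s, e in per_chrom[chrom]:
            out.append(GenomicInterval(chrom, int(s), int(e)))
    return out


def merge_intervals(ivs: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Sort and merge overlapping or book-ended intervals per chromosome."""
    return _to_ivs({c: _merge_arr(arr) for c, arr in _by_chrom(ivs).items()})


def total_bp(ivs: Iterable[GenomicInterval]) -> int:
    """Total bases covered (input is merged first)."""
    return sum(len(iv) for iv in merge_intervals(ivs))


def interval_ops(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    mode: str,
    genome: dict[str, int] | None = None,
):
    """Set algebra on two interval sets with half-open semantics.

    ``mode`` is one of ``intersect``, ``subtract``, ``union``,
    ``coverage_fraction``. For ``coverage_fraction``, ``b`` is ignored and
    ``genome`` (chrom -> length) is required; the result is
    covered bp / genome bp.
    """
    if mode == "coverage_fraction":
        if genome is None:
            raise ValueError("coverage_fraction requires a genome map")
        merged = merge_intervals(a)
        for iv in merged:
            if iv.chrom not in genome:
                raise ValueError(f"chromosome {iv.chrom} absent from genome map")
            if iv.end > genome[iv.chrom]:
                raise ValueError(f"{iv} extends past chromosome end")
        size = sum(genome.values())
        if size <= 0:
            raise ValueError("empty genome")
        return sum(len(iv) for iv in merged) / size

    am = {c: _merge_arr(arr) for c, arr in _by_chrom(a).items()}
    bm = {c: _merge_arr(arr) for c, arr in _by_chrom(b).items()}
    empty = np.empty((0, 2), dtype=np.int64)
    out: dict[str, np.ndarray] = {}
    if mode == "union":
        for c in set(am) | set(bm):
            both = np.vstack([am.get(c, empty), bm.get(c, empty)])
            out[c] = _merge_arr(both[np.lexsort((both[:, 1], both[:, 0]))])
    elif mode == "intersect":
        for c in set(am) & set(bm):
            out[c] = _intersect_arr(am[c], bm[c])
    elif mode == "subtract":
        for c in am:
            out[c] = _subtract_arr(am[c], bm.get(c, empty))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return _to_ivs(out)


def jaccard(a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]) -> float:
    """Jaccard index |a ∩ b| / |a ∪ b| in base pairs (0 if both empty)."""
    inter = total_bp(interval_ops(a, b, "intersect"))
    union = total_bp(interval_ops(a, b, "union"))
    return inter / union if union else 0.0


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------


def _data_lines(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def read_bed(
    path: str | Path, with_names: bool = False
) -> list[GenomicInterval] | list[tuple[GenomicInterval, str, float | None]]:
    """Read BED3-BED6. Returns intervals in file order.

    With ``with_names=True`` returns ``(interval, name, score)`` tuples
    (score ``None`` when the column is absent or '.').
    """
    plain: list[GenomicInterval] = []
    named: list[tuple[GenomicInterval, str, float | None]] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise BedParseError(f"{path}: line {lineno}: fewer than 3 columns")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise BedParseError(
                f"{path}: line {lineno}: non-integer coordinate"
            ) from exc
        strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
        try:
            iv = GenomicInterval(chrom, start, end, strand)
        except ValueError as exc:
            raise BedParseError(f"{path}: line {lineno}: {exc}") from exc
        if with_names:
            name = fields[3] if len(fields) > 3 else "."
            score: float | None = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            named.append((iv, name, score))
        else:
            plain.append(iv)
    return named if with_names else plain


def write_bed(
    path: str | Path,
    intervals: Sequence[GenomicInterval],
    names: Sequence[str] | None = None,
    scores: Sequence[float] | None = None,
) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if names is not None or scores is not None or iv.strand != ".":
                cols.append(names[i] if names is not None else ".")
                cols.append(
                    format(scores[i], "g") if scores is not None else "0"
                )
                cols.append(iv.strand)
            fh.write("\t".join(cols) + "\n")


def read_bedgraph(path: str | Path) -> list[tuple[GenomicInterval, float]]:
    """Read a 4-column bedGraph (0-based half-open, value in column 4)."""
    out: list[tuple[GenomicInterval, float]] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 4:
            raise BedParseError(f"{path}: line {lineno}: need 4 columns")
        try:
            iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            value = float(fields[3])
        except ValueError as exc:
            raise BedParseError(f"{path}: line {lineno}: {exc}") from exc
        out.append((iv, value))
    return out


def write_bedgraph(
    path: str | Path,
    intervals: Sequence[GenomicInterval],
    values: Sequence[float],
) -> None:
    with open(path, "w") as fh:
        for iv, v in zip(intervals, values, strict=True):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{v:g}\n")


def read_gff3(
    path: str | Path,
    feature_types: set[str] | None = None,
    id_attribute: str = "ID",
    kind: str = "gene",
) -> list[LocusAnnotation]:
    """Read loci from GFF3, converting 1-based inclusive to half-open."""
    out: list[LocusAnnotation] = []
    for lineno, fields in _data_lines(path):
        if len(fields) != 9:
            raise BedParseError(f"{path}: line {lineno}: need 9 columns")
        chrom, _, ftype, start, end, _, strand, _, attrs = fields
        if feature_types is not None and ftype not in feature_types:
            continue
        attr_map = dict(
            kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
        )
        locus_id = attr_map.get(id_attribute, f"{chrom}:{start}-{end}")
        iv = GenomicInterval(
            chrom, int(start) - 1, int(end), strand if strand in "+-" else "."
        )
        out.append(LocusAnnotation(locus_id, iv, kind))
    return out
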