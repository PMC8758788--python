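"""miRNA qPCR array normalization, testing, ranking and selection.

Ct values (cycle thresholds; larger = less abundant) arrive as an
assay x plate matrix. Normalization is two-step: per plate to the
geometric mean of the housekeeping assays on that plate (delta-Ct),
then quantile normalization across plates so every plate shares one
value distribution. Per-assay group differences are tested with a
two-sample t-test on the normalized delta-Ct; assays are ranked by
p-value, and the selected set is the union of the top-ranked fraction
and those changing by at least the fold threshold in either direction
(fold change = 2^(-ddCt)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CtMatrix", "MirnaResult", "normalize_ct", "test_and_rank", "select_mirnas"]


@dataclass
class CtMatrix:
    """Assay x plate Ct matrix with plate group labels.

    ``values``: DataFrame, rows = assay ids, columns = plate ids, NaN for
    missing wells. ``groups`` maps plate id -> 'control' or 'knockout'.
    ``housekeeping_ids`` are rows used for per-plate delta-Ct reference.
    """

    values: pd.DataFrame
    groups: dict[str, str]
    housekeeping_ids: list[str] = field(default_factory=list)
    normalized: bool = False  # delta-Ct values may be <= 0; skip range check

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if not self.normalized:
            bad = (~np.isnan(v)) & ((v <= 0) | (v > 45))
            if bad.any():
                raise ValueError("Ct values must be in (0, 45] or missing")
        missing = set(self.groups) - set(self.values.columns)
        if missing:
            raise ValueError(f"group labels for unknown plates: {sorted(missing)}")
        for g in self.groups.values():
            if g not in ("control", "knockout"):
                raise ValueError(f"unknown group {g!r}")
        absent = set(self.housekeeping_ids) - set(self.values.index)
        if absent:
            raise ValueError(f"housekeeping assays not in matrix: {sorted(absent)}")

    def plates(self, group: str) -> list[str]:
        return [p for p in self.values.columns if self.groups[p] == group]


def normalize_ct(ct: CtMatrix) -> CtMatrix:
    """Per-plate delta-Ct then cross-plate quantile normalization.

    Step 1 subtracts the geometric mean of the housekeeping Cts of each
    plate from every value on that plate. Step 2 replaces each plate's
    sorted values by the across-plate mean of order statistics (tied
    values averaged); plates with missing wells are mapped through their
    fractional ranks against the mean quantile curve. Housekeeping rows
    are the normalization reference, not assays: they keep their
    plate-normalized delta-Ct and do not enter the quantile step.
    Missing values stay missing.
    """
    if not ct.housekeeping_ids:
        raise ValueError("housekeeping_ids must be non-empty")
    values = ct.values.astype(float).copy()
    for plate in values.columns:
        hk = values.loc[ct.housekeeping_ids, plate].to_numpy()
        hk = hk[~np.isnan(hk)]
        if hk.size == 0:
            raise ValueError(f"all housekeeping assays missing on plate {plate!r}")
        values[plate] = values[plate] - stats.gmean(hk)

    assay_rows = [a for a in values.index if a not in set(ct.housekeeping_ids)]
    arr = values.loc[assay_rows].to_numpy()
    n_assays, n_plates = arr.shape
    # mean quantile curve on a common grid of plotting positions
    grid = (np.arange(n_assays) + 0.5) / n_assays
    curves = np.full((n_plates, n_assays), np.nan)
    for j in range(n_plates):
        col = np.sort(arr[~np.isnan(arr[:, j]), j])
        if col.size:
            pos = (np.arange(col.size) + 0.5) / col.size
            curves[j] = np.interp(grid, pos, col)
    ref = np.nanmean(curves, axis=0)
    out = arr.copy()
    for j in range(n_plates):
        ok = ~np.isnan(arr[:, j])
        m = ok.sum()
        if m == 0:
            continue
        ranks = stats.rankdata(arr[ok, j], method="average")
        out[ok, j] = np.interp((ranks - 0.5) / m, grid, ref)
    values.loc[assay_rows] = out
    return replace(ct, values=values, normalized=True)


@dataclass
class MirnaResult:
    assay_id: str
    delta_ct_control: np.ndarray
    delta_ct_knockout: np.ndarray
    ddct: float
    fold_change: float
    t_stat: float
    p_value: float
    rank: int = 0
    selected: bool = False
    reason: str | None = None  # top_rank | fold_change | both
    zero_variance: bool = False

    @property
    def direction(self) -> str:
        return "up" if self.fold_change > 1 else ("down" if self.fold_change < 1 else "ns")


def test_and_rank(ct_norm: CtMatrix) -> list[MirnaResult]:
    """Two-sided two-sample t-test per assay; rank ascending by p-value.

    ddCt = mean(knockout) - mean(control); fold change = 2^(-ddCt), so a
    lower Ct in the knockout reads as up-regulation. Housekeeping assays
    are excluded. Assays with zero variance in both groups get p = 1
    when means agree, else p ~ 0 with a flag. Ties in p are broken by
    |ddCt| (larger first) then assay id.
    """
    ctrl_plates = ct_norm.plates("control")
    ko_plates = ct_norm.plates("knockout")
    if len(ctrl_plates) < 2 or len(ko_plates) < 2:
        raise ValueError("need >= 2 plates per group")
    results: list[MirnaResult] = []
    hk = set(ct_norm.housekeeping_ids)
    for assay in ct_norm.values.index:
        if assay in hk:
            continue
        a = ct_norm.values.loc[assay, ctrl_plates].to_numpy(dtype=float)
        b = ct_norm.values.loc[assay, ko_plates].to_numpy(dtype=float)
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if a.size < 2 or b.size < 2:
            continue
        ddct = float(b.mean() - a.mean())
        zero_var = a.std(ddof=1) == 0 and b.std(ddof=1) == 0
        if zero_var:
            t, p = (0.0, 1.0) if ddct == 0 else (math.inf * np.sign(ddct), 0.0)
        else:
            t, p = stats.ttest_ind(b, a)
        results.append(
            MirnaResult(
                assay_id=str(assay),
                delta_ct_control=a,
                delta_ct_knockout=b,
                ddct=ddct,
                fold_change=2.0 ** (-ddct),
                t_stat=float(t),
                p_value=float(p),
                zero_variance=zero_var,
            )
        )
    results.sort(key=lambda r: (r.p_value, -abs(r.ddct), r.assay_id))
    for i, r in enumerate(results, start=1):
        r.rank = i
    return results


def select_mirnas(
    results: list[MirnaResult],
    top_frac: float = 0.15,
    fc_threshold: float = 2.0,
) -> dict:
    """Union of the top-ranked fraction and the >= fold-threshold set.

    An assay is selected when rank <= ceil(top_frac * n) or when its
    fold change is >= ``fc_threshold`` or <= 1/``fc_threshold``
    (boundaries inclusive). The selected set is split by direction.
    """
    n = len(results)
    cutoff = math.ceil(top_frac * n)
    up: list[MirnaResult] = []
    down: list[MirnaResult] = []
    for r in results:
        by_rank = r.rank <= cutoff
        by_fc = r.fold_change >= fc_threshold or r.fold_change <= 1.0 / fc_threshold
        r.selected = by_rank or by_fc
        r.reason = "both" if by_rank and by_fc else ("top_rank" if by_rank else ("fold_change" if by_fc else None))
        if r.selected:
            (up if r.fold_change > 1 else down).append(r)
    return {
        "selected": up + down,
        "up": up,
        "down": down,
        "rank_cutoff": cutoff,
        "n_selected": len(up) + len(down),
        "n_up_by_fold": sum(1 for r in up if r.fold_change >= fc_threshold),
        "n_down_by_fold": sum(1 for r in down if r.fold_change <= 1.0 / fc_threshold),
    }
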