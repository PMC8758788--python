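"""Phenotype-side computations.

Mitochondrial stress-test (Seahorse) parameter extraction from OCR
traces, pyruvate-dependency arithmetic, glucose-tolerance-test AUC,
lipid-droplet size binning, and FISH locus-distance statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "OcrTrace",
    "MitoParams",
    "DistanceSample",
    "mito_stress_params",
    "pyruvate_dependency",
    "auc_trapezoid",
    "droplet_size_histogram",
    "droplet_group_summary",
    "fish_distance_compare",
]

# canonical injection labels and how free-text labels map onto them
_PHASE_KEYS = {"oligomycin": "oligo", "fccp": "fccp", "rotenone": "rot_aa", "antimycin": "rot_aa"}


@dataclass
class OcrTrace:
    """One well's oxygen-consumption-rate trace with injection times.

    ``injections`` is an ordered list of (label, time in minutes); the
    measurements before the first injection form the basal phase, those
    after each injection belong to that injection's phase.
    """

    timepoints: np.ndarray
    ocr: np.ndarray
    injections: list[tuple[str, float]]
    replicate_id: str = ""

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.ocr = np.asarray(self.ocr, dtype=float)
        if self.timepoints.shape != self.ocr.shape:
            raise ValueError("timepoints and ocr must have equal length")
        if not (np.diff(self.timepoints) > 0).all():
            raise ValueError("timepoints must be strictly increasing")
        for _, t in self.injections:
            if not (self.timepoints[0] <= t <= self.timepoints[-1]):
                raise ValueError(f"injection time {t} outside trace span")

    def phase_values(self) -> dict[str, np.ndarray]:
        """Measurements per phase keyed basal/oligo/fccp/rot_aa (plus any
        extra injection labels verbatim, e.g. uk5099/vehicle)."""
        bounds = sorted(self.injections, key=lambda x: x[1])
        out: dict[str, np.ndarray] = {}
        times = [t for _, t in bounds] + [np.inf]
        out["basal"] = self.ocr[self.timepoints < times[0]]
        for k, (label, _) in enumerate(bounds):
            key = label.strip().lower()
            for needle, canon in _PHASE_KEYS.items():
                if needle in key:
                    key = canon
                    break
            sel = (self.timepoints >= times[k]) & (self.timepoints < times[k + 1])
            vals = self.ocr[sel]
            out[key] = np.concatenate([out[key], vals]) if key in out else vals
        return out


@dataclass
class MitoParams:
    """Stress-test parameters (same units as the input OCR).

    Raw phase means: basal_raw, oligo_raw, fccp_raw, non_mito (rot/AA
    floor). Derived: basal = basal_raw - non_mito, maximal = fccp_raw -
    non_mito, atp_linked = basal_raw - oligo_raw, proton_leak = basal -
    atp_linked, spare_capacity = maximal - basal.
    """

    basal_raw: float
    oligo_raw: float
    fccp_raw: float
    non_mito: float
    basal: float
    maximal: float
    atp_linked: float
    proton_leak: float
    spare_capacity: float
    quality_flags: list[str] = field(default_factory=list)

    FIELDS = ("non_mito", "basal", "maximal", "atp_linked", "proton_leak", "spare_capacity")


def mito_stress_params(trace: OcrTrace, robust: bool = False) -> MitoParams:
    """Extract stress-test parameters from one trace.

    Phase summaries are means of all measurements in the phase (medians
    with ``robust=True``). A negative ATP-linked or proton-leak value is
    returned but flagged. Missing rotenone/antimycin phase is an error:
    the non-mitochondrial floor would be undefined.
    """
    phases = trace.phase_values()
    for needed in ("basal", "oligo", "fccp", "rot_aa"):
        if needed not in phases or len(phases[needed]) == 0:
            raise ValueError(f"missing measurements for phase {needed!r}")
    agg = np.median if robust else np.mean
    basal_raw = float(agg(phases["basal"]))
    oligo_raw = float(agg(phases["oligo"]))
    fccp_raw = float(agg(phases["fccp"]))
    non_mito = float(agg(phases["rot_aa"]))
    basal = basal_raw - non_mito
    maximal = fccp_raw - non_mito
    atp_linked = basal_raw - oligo_raw
    proton_leak = basal - atp_linked
    flags = []
    if atp_linked < 0:
        flags.append("negative_atp_linked")
    if proton_leak < 0:
        flags.append("negative_proton_leak")
    return MitoParams(
        basal_raw=basal_raw,
        oligo_raw=oligo_raw,
        fccp_raw=fccp_raw,
        non_mito=non_mito,
        basal=basal,
        maximal=maximal,
        atp_linked=atp_linked,
        proton_leak=proton_leak,
        spare_capacity=maximal - basal,
        quality_flags=flags,
    )


def pyruvate_dependency(trace_vehicle: OcrTrace, trace_uk5099: OcrTrace) -> dict[str, float]:
    """Pyruvate dependency per parameter: vehicle minus UK5099-inhibited."""
    pv = trace_vehicle.phase_values()
    pu = trace_uk5099.phase_values()
    shared = {"basal", "oligo", "fccp", "rot_aa"}
    if not shared <= set(pv) or not shared <= set(pu):
        raise ValueError("traces do not share the stress-test phase structure")
    mv = mito_stress_params(trace_vehicle)
    mu = mito_stress_params(trace_uk5099)
    return {f: getattr(mv, f) - getattr(mu, f) for f in MitoParams.FIELDS}


def auc_trapezoid(times, values) -> float:
    """Trapezoidal area under a sampled curve (e.g. GTT glucose, mM*min)."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size < 2:
        raise ValueError("need at least 2 timepoints")
    if not (np.diff(times) > 0).all():
        raise ValueError("timepoints must be strictly increasing")
    return float(np.trapezoid(values, times))


def droplet_size_histogram(areas, bin_edges) -> dict:
    """Bin droplet areas into size classes and report frequencies.

    Bins are left-closed right-open on ``bin_edges``; the last bin is
    open-ended. Areas below the first edge fall in the first bin, so
    counts conserve n and frequencies sum to 1.
    """
    areas = np.asarray(areas, dtype=float)
    if areas.size == 0:
        raise ValueError("empty area list")
    if (areas <= 0).any():
        raise ValueError("areas must be positive")
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size < 1 or (np.diff(edges) <= 0).any():
        raise ValueError("bin edges must be increasing")
    idx = np.clip(np.searchsorted(edges, areas, side="right") - 1, 0, edges.size - 1)
    counts = np.bincount(idx, minlength=edges.size)
    return {
        "bin_edges": edges,
        "counts": counts,
        "frequencies": counts / counts.sum(),
    }


def droplet_group_summary(per_animal_areas: list, bin_edges) -> dict:
    """Per-animal frequencies, then group mean +/- SEM per bin."""
    freqs = np.vstack(
        [droplet_size_histogram(a, bin_edges)["frequencies"] for a in per_animal_areas]
    )
    n = freqs.shape[0]
    sem = freqs.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(freqs.shape[1])
    return {"mean_frequencies": freqs.mean(axis=0), "sem": sem, "n_animals": n}


@dataclass(frozen=True)
class DistanceSample:
    """One locus-to-nuclear-envelope distance measurement (µm)."""

    locus_id: str
    group: str
    distance: float
    nucleus_id: str = ""

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("distance must be >= 0")


def _tukey_summary(x: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo) & (x <= hi)]
    outliers = np.sort(x[(x < lo) | (x > hi)])
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "outliers": outliers,
        "mean": float(x.mean()),
        "n": int(x.size),
    }


def fish_distance_compare(a, b, equal_var: bool = True) -> dict:
    """Compare two distance samples.

    Unpaired two-sided t-test (pooled variance by default; Welch with
    ``equal_var=False``) plus a Tukey box summary per group (whiskers at
    the most extreme points within 1.5 IQR of the quartiles).
    """

    def to_arr(s):
        if len(s) and isinstance(next(iter(s)), DistanceSample):
            return np.array([d.distance for d in s], dtype=float)
        return np.asarray(s, dtype=float)

    xa, xb = to_arr(a), to_arr(b)
    if xa.size < 2 or xb.size < 2:
        raise ValueError("need n >= 2 per group")
    if xa.std(ddof=1) == 0 and xb.std(ddof=1) == 0 and equal_var:
        if np.allclose(xa.mean(), xb.mean()):
            t, p = 0.0, 1.0
        else:
            raise ValueError("zero pooled variance with distinct means")
    else:
        t, p = stats.ttest_ind(xa, xb, equal_var=equal_var)
    return {
        "t": float(t),
        "p": float(p),
        "mean_a": float(xa.mean()),
        "mean_b": float(xb.mean()),
        "tukey_a": _tukey_summary(xa),
        "tukey_b": _tukey_summary(xb),
    }
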