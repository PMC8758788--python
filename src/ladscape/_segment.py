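"""Circular-binary-segmentation core.

Recursive binary splitting of a 1-D signal: at each step the arc
(i, j) maximising the standardised mean-shift statistic between the arc
and its complement is found; the split is kept if a within-segment
permutation test gives p < alpha. The scale factor sigma cancels in the
permutation comparison, so the statistic is left unstandardised by the
sample variance.

The O(n^2) arc scan is the hot loop; it is compiled with numba when
available and falls back to a vectorised numpy sweep over arc lengths.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=False)
def _max_arc_stat_nb(S: np.ndarray, min_width: int):
    n = S.shape[0] - 1
    tot = S[n]
    best = -1.0
    bi = 0
    bj = 0
    for k in range(min_width, n - min_width + 1):
        denom = math.sqrt(1.0 / k + 1.0 / (n - k))
        for i in range(0, n - k + 1):
            d = S[i + k] - S[i]
            z = (d / k - (tot - d) / (n - k)) / denom
            if z < 0:
                z = -z
            if z > best:
                best = z
                bi = i
                bj = i + k
    return best, bi, bj


@njit(cache=False)
def _scan_exceeds_nb(S: np.ndarray, min_width: int, t_obs: float) -> bool:
    n = S.shape[0] - 1
    tot = S[n]
    for k in range(min_width, n - min_width + 1):
        denom = math.sqrt(1.0 / k + 1.0 / (n - k))
        for i in range(0, n - k + 1):
            d = S[i + k] - S[i]
            z = (d / k - (tot - d) / (n - k)) / denom
            if z < 0:
                z = -z
            if z >= t_obs:
                return True
    return False


def _max_arc_stat_np(S: np.ndarray, min_width: int):
    n = S.shape[0] - 1
    tot = S[n]
    best, bi, bj = -1.0, 0, 0
    for k in range(min_width, n - min_width + 1):
        d = S[k:] - S[: n - k + 1]
        z = np.abs((d / k - (tot - d) / (n - k)) / math.sqrt(1.0 / k + 1.0 / (n - k)))
        i = int(np.argmax(z))
        if z[i] > best:
            best, bi, bj = float(z[i]), i, i + k
    return best, bi, bj


def _scan_exceeds_np(S: np.ndarray, min_width: int, t_obs: float) -> bool:
    n = S.shape[0] - 1
    tot = S[n]
    for k in range(min_width, n - min_width + 1):
        d = S[k:] - S[: n - k + 1]
        z = np.abs((d / k - (tot - d) / (n - k)) / math.sqrt(1.0 / k + 1.0 / (n - k)))
        if z.max() >= t_obs:
            return True
    return False


if _HAVE_NUMBA:
    _max_arc_stat, _scan_exceeds = _max_arc_stat_nb, _scan_exceeds_nb
else:  # pragma: no cover
    _max_arc_stat, _scan_exceeds = _max_arc_stat_np, _scan_exceeds_np


def max_arc_stat(x: np.ndarray, min_width: int) -> tuple[float, int, int]:
    """Best arc (i, j) of the mean-shift statistic over ``x``.

    Returns ``(stat, i, j)``; ``stat`` is -1 when ``x`` is too short to
    host any candidate arc of width >= ``min_width`` on both sides.
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.shape[0]
    if n < 2 * min_width:
        return -1.0, 0, 0
    S = np.concatenate(([0.0], np.cumsum(x)))
    return _max_arc_stat(S, min_width)


def segment_values(
    x: np.ndarray,
    alpha: float = 0.01,
    min_width: int = 2,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> list[int]:
    """Breakpoint indices for a 1-D signal by recursive CBS.

    Returns sorted interior breakpoints b so that segments are
    ``x[0:b1], x[b1:b2], ..., x[bk:n]``. Deterministic for a given rng
    state (segments are processed left to right, depth first).
    """
    x = np.asarray(x, dtype=np.float64)
    if rng is None:
        rng = np.random.default_rng(0)
    # reject a split as soon as p >= alpha is certain: p = (exc+1)/(n_perm+1)
    reject_at = math.ceil(alpha * (n_perm + 1))
    breaks: list[int] = []
    stack: list[tuple[int, int]] = [(0, x.shape[0])]
    while stack:
        lo, hi = stack.pop()
        seg = x[lo:hi]
        n = hi - lo
        if n < 2 * min_width:
            continue
        S = np.concatenate(([0.0], np.cumsum(seg)))
        t_obs, i, j = _max_arc_stat(S, min_width)
        if t_obs <= 0:
            continue
        exceed = 0
        work = seg.copy()
        accepted = True
        for _ in range(n_perm):
            rng.shuffle(work)
            Sp = np.concatenate(([0.0], np.cumsum(work)))
            if _scan_exceeds(Sp, min_width, t_obs):
                exceed += 1
                if exceed >= reject_at:
                    accepted = False
                    break
        if not accepted:
            continue
        cuts = sorted({lo + i, lo + j} - {lo, hi})
        if not cuts:
            continue
        breaks.extend(cuts)
        bounds = [lo, *cuts, hi]
        # push right-to-left so the leftmost child is processed first
        for a, b in reversed(list(zip(bounds[:-1], bounds[1:]))):
            stack.append((a, b))
    return sorted(breaks)
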