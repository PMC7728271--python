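"""Change-point detection in the daily-entropy series.

The series of daily real-entropy rates ``s = (s_1 ... s_n)`` is modelled as
piecewise constant: ``s_j = mu_k + eps_j`` within segment ``k``. For a fixed
segment count ``K`` the best segmentation minimizes the least-squares
contrast

    J(tau, s) = (1/n) * sum_k sum_{j in segment k} (s_j - mean_k)^2

which we solve exactly by dynamic programming over segment boundaries
(prefix-sum segment costs, O(K n^2) time). The number of segments itself is
chosen by a penalized model-selection rule: the optimal contrasts
``J_1 >= J_2 >= ... >= J_Kmax`` are rescaled affinely to span
``[1, K_max]``, candidate K are restricted to the lower convex hull of
``(K, J_K)``, and the selected ``K_hat`` is the largest hull point where
the convex minorant of the normalized contrast curve bends by more than a
threshold ``rho`` (default 0.75) while the slope beyond it is shallower
than the average decrement. This automatic rule replaces an explicit sweep
of the penalty weight beta in ``J + beta * K``: each hull point is the
minimizer of ``J + beta*K`` for an interval of beta whose length is
exactly the slope change at that point, so thresholding the bend selects
the K that would be chosen over the widest range of penalties.

Index convention: ``tau_k`` is the 1-based index of the **last** day of
segment ``k``; a segmentation with K segments reports K-1 change points
``0 < tau_1 < ... < tau_{K-1} < n``. The series is indexed by position
(kept days), not calendar time, so excluded days do not create gaps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .entropy import EntropySeries

__all__ = [
    "EntropySeries",
    "Segmentation",
    "ModelSelection",
    "contrast",
    "best_segmentation",
    "select_k",
    "segment_stats",
    "default_k_max",
]


@dataclass(frozen=True)
class Segmentation:
    k: int
    taus: tuple[int, ...]  # 1-based last index of segments 1..K-1
    means: tuple[float, ...]
    residuals: np.ndarray = field(repr=False)
    contrast: float

    @property
    def boundaries(self) -> tuple[int, ...]:
        """0-based exclusive segment ends, including n."""
        return self.taus + (len(self.residuals),)


@dataclass(frozen=True)
class ModelSelection:
    k_max: int
    l_min: int
    contrasts: np.ndarray  # J_K for K = 1..k_max (index K-1)
    normalized: np.ndarray
    second_diffs: np.ndarray  # nan at K=1 and K=k_max
    hull_member: np.ndarray  # bool per K
    threshold: float
    k_hat: int


def _as_values(series) -> np.ndarray:
    vals = getattr(series, "values", series)
    return np.asarray(vals, dtype=float)


def _validate_taus(n: int, taus: Sequence[int], l_min: int = 1) -> list[int]:
    taus = list(taus)
    bounds = [0] + taus + [n]
    if any(b <= a for a, b in zip(bounds, bounds[1:])):
        raise ValueError(f"invalid change points {taus} for series of length {n}")
    if any(b - a < l_min for a, b in zip(bounds, bounds[1:])):
        raise ValueError(f"segment shorter than l_min={l_min}")
    return taus


def contrast(series, taus: Sequence[int]) -> float:
    """Mean squared within-segment deviation ``J(tau, s)`` in bits^2."""
    x = _as_values(series)
    n = x.size
    taus = _validate_taus(n, taus)
    bounds = [0] + taus + [n]
    sse = 0.0
    for a, b in zip(bounds, bounds[1:]):
        seg = x[a:b]
        sse += float(np.sum((seg - seg.mean()) ** 2))
    return sse / n


def _sse_matrix(x: np.ndarray) -> np.ndarray:
    """S[a, b] = sum of squared deviations of x[a..b] (inclusive, 0-based)."""
    n = x.size
    cs = np.concatenate(([0.0], np.cumsum(x)))
    cs2 = np.concatenate(([0.0], np.cumsum(x * x)))
    a = np.arange(n)
    length = a[None, :] - a[:, None] + 1
    seg_sum = cs[a[None, :] + 1] - cs[a[:, None]]
    seg_sq = cs2[a[None, :] + 1] - cs2[a[:, None]]
    with np.errstate(invalid="ignore", divide="ignore"):
        sse = seg_sq - seg_sum * seg_sum / length
    sse[length < 1] = np.inf
    return np.maximum(sse, 0.0)  # clip float-cancellation negatives


def _dp_tables(x: np.ndarray, k_max: int, l_min: int):
    """Backward DP: B[k, j] = min SSE covering x[j:] with k segments.

    The argmin table keeps the *smallest* feasible segment end at every
    state, so greedy reconstruction from the left yields the
    lexicographically smallest optimal change-point vector.
    """
    n = x.size
    sse = _sse_matrix(x)
    B = np.full((k_max + 1, n + 1), np.inf)
    arg = np.full((k_max + 1, n), -1, dtype=np.intp)
    B[0, n] = 0.0
    for k in range(1, k_max + 1):
        for j in range(n - k * l_min, -1, -1):
            e_lo = j + l_min - 1
            cand = sse[j, e_lo:n] + B[k - 1, e_lo + 1 : n + 1]
            i = int(np.argmin(cand))
            B[k, j] = cand[i]
            arg[k, j] = e_lo + i
    return B, arg


def best_segmentation(series, k: int, l_min: int = 1) -> Segmentation:
    """Globally optimal K-segmentation by dynamic programming.

    Ties are broken toward the lexicographically smallest change-point
    vector.
    """
    x = _as_values(series)
    n = x.size
    if k < 1 or k * l_min > n:
        raise ValueError(f"infeasible k={k} with l_min={l_min} for n={n}")
    B, arg = _dp_tables(x, k, l_min)
    taus: list[int] = []
    pos = 0
    for seg in range(k, 0, -1):
        end = int(arg[seg, pos])
        if seg > 1:
            taus.append(end + 1)  # 1-based last index == 0-based exclusive end
        pos = end + 1
    means, residuals, _ = segment_stats(x, taus)
    return Segmentation(
        k=k,
        taus=tuple(taus),
        means=means,
        residuals=residuals,
        contrast=float(B[k, 0] / n),
    )


def segment_stats(series, segmentation) -> tuple[tuple[float, ...], np.ndarray, tuple[float, ...]]:
    """Per-segment means, per-day residuals, and per-segment sample SDs.

    Accepts a Segmentation or a plain change-point sequence. SD of a
    single-day segment is nan (sample SD undefined).
    """
    x = _as_values(series)
    taus = list(getattr(segmentation, "taus", segmentation))
    bounds = [0] + _validate_taus(x.size, taus) + [x.size]
    means: list[float] = []
    sds: list[float] = []
    residuals = np.empty_like(x)
    for a, b in zip(bounds, bounds[1:]):
        seg = x[a:b]
        mu = float(seg.mean())
        means.append(mu)
        residuals[a:b] = seg - mu
        sds.append(float(np.std(seg, ddof=1)) if b - a > 1 else float("nan"))
    return tuple(means), residuals, tuple(sds)


def default_k_max(series) -> int:
    """Number of weeks spanned by the series (distinct ISO weeks when dates
    are available, otherwise ceil(n/7))."""
    dates = getattr(series, "dates", None)
    if dates:
        return len({d.isocalendar()[:2] for d in dates})
    return math.ceil(_as_values(series).size / 7)


def _lower_hull(ks: np.ndarray, js: np.ndarray) -> np.ndarray:
    """Boolean mask of the lower convex hull of the points (K, J_K)."""
    hull: list[int] = []
    for i in range(ks.size):
        while len(hull) >= 2:
            o, a = hull[-2], hull[-1]
            cross = (ks[a] - ks[o]) * (js[i] - js[o]) - (js[a] - js[o]) * (ks[i] - ks[o])
            if cross <= 0:  # a is above or on the chord o->i
                hull.pop()
            else:
                break
        hull.append(i)
    mask = np.zeros(ks.size, dtype=bool)
    mask[hull] = True
    return mask


def select_k(
    series,
    k_max: int | None = None,
    l_min: int = 1,
    rho: float = 0.75,
    hull_only: bool = True,
) -> ModelSelection:
    """Choose the number of segments automatically.

    Computes optimal contrasts ``J_K`` for ``K = 1..k_max`` and rescales
    them affinely to span ``[1, k_max]`` (so the average decrement per
    added segment is exactly 1). With ``hull_only`` (default) candidates
    are the lower-convex-hull points of ``(K, J_K)``; the reported second
    difference at a hull point is the curvature of the convex minorant
    (its change of slope, equal to the raw ``Jt_{K-1} - 2 Jt_K + Jt_{K+1}``
    when the neighbours are hull points too), and ``K_hat`` is the largest
    hull K whose bend exceeds ``rho`` *and* whose outgoing slope is
    shallower than the average decrement -1 — the elbow where added
    segments stop paying for themselves. With ``hull_only=False`` the raw
    second difference at every K is thresholded instead. Returns 1 when no
    candidate qualifies (no detectable change).
    """
    x = _as_values(series)
    n = x.size
    if k_max is None:
        k_max = default_k_max(series)
    k_max = int(min(k_max, n // l_min))
    if k_max < 2:
        raise ValueError(f"k_max must be >= 2 (got {k_max} for n={n})")
    B, _ = _dp_tables(x, k_max, l_min)
    contrasts = B[1:, 0] / n  # J_K, K = 1..k_max
    ks = np.arange(1, k_max + 1, dtype=float)

    span = contrasts[0] - contrasts[-1]
    if span <= 0:  # degenerate (e.g. constant series): nothing to detect
        normalized = np.ones_like(contrasts)
        second = np.full(k_max, np.nan)
        hull = np.zeros(k_max, dtype=bool)
        return ModelSelection(k_max, l_min, contrasts, normalized, second, hull, rho, 1)

    normalized = 1.0 + (k_max - 1.0) * (contrasts - contrasts[-1]) / span
    hull = _lower_hull(ks, contrasts)
    second = np.full(k_max, np.nan)

    k_hat = 1
    if hull_only:
        hull_idx = np.flatnonzero(hull)
        for h in range(1, hull_idx.size - 1):
            prev_i, i, next_i = hull_idx[h - 1], hull_idx[h], hull_idx[h + 1]
            slope_in = (normalized[i] - normalized[prev_i]) / (i - prev_i)
            slope_out = (normalized[next_i] - normalized[i]) / (next_i - i)
            second[i] = slope_out - slope_in  # minorant curvature
            if second[i] > rho and slope_out > -1.0:
                k_hat = int(i + 1)
    else:
        second[1:-1] = normalized[:-2] - 2.0 * normalized[1:-1] + normalized[2:]
        candidates = np.flatnonzero(~np.isnan(second) & (second > rho))
        if candidates.size:
            k_hat = int(candidates[-1] + 1)
    return ModelSelection(
        k_max=k_max,
        l_min=l_min,
        contrasts=contrasts,
        normalized=normalized,
        second_diffs=second,
        hull_member=hull,
        threshold=rho,
        k_hat=k_hat,
    )
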