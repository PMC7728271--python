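"""Entropy-rate measures for daily mobility trajectories.

Three complementary measures quantify how regular a resident's movement
between sensor viewing areas is:

* **random entropy** ``log2 N`` — the uncertainty of the next location if
  movement were completely random over the ``N`` locations visited that day;
* **temporal-uncorrelated entropy** — the Shannon entropy of the visit
  frequency distribution, ignoring the order of visits;
* **real entropy** — the entropy rate of the ordered sequence, which
  accounts for temporal correlations and is estimated here with a
  Burrows-Wheeler transform (BWT) block-sorting estimator.

For a stationary ergodic source the three are ordered
``S_real <= S_unc <= S_rand``; the gap between them measures how much
structure (repetition, routine) the trajectory carries.

The BWT estimator sorts the contexts of the sequence (we transform the
*reversed* sequence so that sorted suffixes correspond to preceding
histories), which groups together symbols emitted in similar contexts.
Zero-order plug-in entropies of contiguous blocks of the transformed
output, averaged with block-length weights, then converge to the entropy
rate as the number of blocks grows sublinearly with the sequence length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date as _date
from typing import Hashable, Mapping, Sequence

import numpy as np

__all__ = [
    "SymbolCounts",
    "BWTEstimate",
    "EntropyRecord",
    "EntropySeries",
    "symbol_counts",
    "random_entropy",
    "uncorrelated_entropy",
    "bwt_real_entropy",
    "entropy_record",
]


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class SymbolCounts:
    """Occurrence counts and plug-in probabilities of the symbols of a day."""

    counts: Mapping[Hashable, int]
    n: int
    probs: Mapping[Hashable, float]


@dataclass(frozen=True)
class BWTEstimate:
    """Result of the block-sorting entropy-rate estimator.

    ``bwt`` is a permutation of the (integer-coded) input sequence with the
    sentinel removed; ``estimate`` is the block-length-weighted mean of the
    per-block plug-in entropies, in bits per symbol.
    """

    bwt: np.ndarray
    num_blocks: int
    block_entropies: tuple[float, ...]
    estimate: float


@dataclass(frozen=True)
class EntropyRecord:
    """Per-day entropy rates and predictability bounds."""

    date: _date
    n: int
    N: int
    s_rand: float
    s_unc: float
    s_real: float
    pi_rand: float
    pi_unc: float
    pi_real: float


@dataclass(frozen=True)
class EntropySeries:
    """Chronological series of one scalar per kept day (typically s_real)."""

    dates: tuple[_date, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if len(self.dates) != vals.size:
            raise ValueError("dates and values must have equal length")
        if any(b <= a for a, b in zip(self.dates, self.dates[1:])):
            raise ValueError("dates must be strictly increasing")

    @property
    def n(self) -> int:
        return len(self.dates)


# ---------------------------------------------------------------------------
# symbol handling


def _symbols_of(traj) -> Sequence[Hashable]:
    """Accept a DailyTrajectory-like object (``.symbols``) or a raw sequence."""
    syms = getattr(traj, "symbols", traj)
    if isinstance(syms, str):
        syms = tuple(syms)
    return syms


def _encode(symbols: Sequence[Hashable]) -> np.ndarray:
    """Map symbols to ints by order of first appearance (deterministic)."""
    mapping: dict[Hashable, int] = {}
    out = np.empty(len(symbols), dtype=np.int64)
    for i, s in enumerate(symbols):
        out[i] = mapping.setdefault(s, len(mapping))
    return out


def symbol_counts(traj) -> SymbolCounts:
    symbols = _symbols_of(traj)
    if len(symbols) == 0:
        raise ValueError("empty trajectory")
    counts: dict[Hashable, int] = {}
    for s in symbols:
        counts[s] = counts.get(s, 0) + 1
    n = len(symbols)
    probs = {s: c / n for s, c in counts.items()}
    return SymbolCounts(counts=counts, n=n, probs=probs)


# ---------------------------------------------------------------------------
# the three entropy rates


def random_entropy(n_symbols: int) -> float:
    """Entropy in bits of a uniform choice over ``n_symbols`` locations."""
    if n_symbols < 1:
        raise ValueError(f"n_symbols must be >= 1, got {n_symbols}")
    return math.log2(n_symbols)


def uncorrelated_entropy(traj) -> float:
    """Shannon entropy (bits) of the plug-in visit-frequency distribution."""
    sc = symbol_counts(traj)
    p = np.fromiter(sc.probs.values(), dtype=float)
    return float(-np.sum(p * np.log2(p)))


def _suffix_array(seq: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (numpy lexsort), O(n log n) sorts."""
    n = seq.size
    if n == 1:
        return np.zeros(1, dtype=np.intp)
    rank = np.unique(seq, return_inverse=True)[1].astype(np.int64)
    k = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        changed = (rank[order[1:]] != rank[order[:-1]]) | (
            key2[order[1:]] != key2[order[:-1]]
        )
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order] = np.concatenate(([0], np.cumsum(changed)))
        rank = new_rank
        if rank[order[-1]] == n - 1:
            return order.astype(np.intp)
        k *= 2


def burrows_wheeler(codes: np.ndarray, reverse: bool = True) -> np.ndarray:
    """BWT of an integer sequence with sentinel handling.

    A unique sentinel (smaller than every code) is appended, suffixes are
    sorted, and each output symbol is the one preceding the corresponding
    suffix. The sentinel's own output position is dropped, so the result is
    a permutation of the input. With ``reverse`` (the default) the transform
    is applied to the reversed sequence, so that sorted contexts are the
    *preceding* histories of each emitted symbol.
    """
    codes = np.asarray(codes, dtype=np.int64)
    if codes.size < 1:
        raise ValueError("empty sequence")
    if codes.min(initial=0) < 0:
        raise ValueError("codes must be non-negative (sentinel is -1)")
    s = codes[::-1] if reverse else codes
    s = np.concatenate((s, [-1]))
    sa = _suffix_array(s)
    keep = sa != 0  # sentinel is the preceding symbol of suffix 0
    return s[sa[keep] - 1]


def _plugin_entropy(block: np.ndarray) -> float:
    counts = np.unique(block, return_counts=True)[1]
    p = counts / counts.sum()
    return float(-np.sum(p * np.log2(p)))


def bwt_real_entropy(traj, num_blocks: int | None = None) -> BWTEstimate:
    """Estimate the real entropy rate (bits/symbol) of an ordered trajectory.

    Parameters
    ----------
    traj
        DailyTrajectory or raw symbol sequence, length >= 2.
    num_blocks
        Number of contiguous blocks the transformed sequence is split into.
        Default ``ceil(sqrt(n))``, which grows without bound while the
        per-block length also grows — the regime in which the estimator is
        consistent.
    """
    symbols = _symbols_of(traj)
    n = len(symbols)
    if n < 2:
        raise ValueError(f"need at least 2 symbols, got {n}")
    codes = _encode(symbols)
    transformed = burrows_wheeler(codes)
    t = int(math.ceil(math.sqrt(n))) if num_blocks is None else int(num_blocks)
    t = max(1, min(t, n))
    blocks = np.array_split(transformed, t)
    ents = tuple(_plugin_entropy(b) for b in blocks)
    estimate = float(sum(len(b) * e for b, e in zip(blocks, ents)) / n)
    return BWTEstimate(
        bwt=transformed, num_blocks=t, block_entropies=ents, estimate=estimate
    )


def entropy_record(traj) -> EntropyRecord:
    """All six per-day quantities: three entropy rates and their Fano bounds."""
    from .predictability import predictability_bound

    symbols = _symbols_of(traj)
    n = len(symbols)
    n_distinct = len(set(symbols))
    s_rand = random_entropy(n_distinct)
    s_unc = uncorrelated_entropy(symbols)
    s_real = bwt_real_entropy(symbols).estimate if n >= 2 else 0.0
    day = getattr(traj, "date", None)
    return EntropyRecord(
        date=day,
        n=n,
        N=n_distinct,
        s_rand=s_rand,
        s_unc=s_unc,
        s_real=s_real,
        pi_rand=predictability_bound(s_rand, n_distinct).pi_max,
        pi_unc=predictability_bound(s_unc, n_distinct).pi_max,
        pi_real=predictability_bound(s_real, n_distinct).pi_max,
    )
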