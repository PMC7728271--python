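"""Upper bound of predictability from a Fano-type inequality.

Given an entropy rate ``S`` (bits/symbol) of a process over ``N`` locations,
the maximal achievable next-location prediction accuracy ``pi_max`` solves

    S = -pi*log2(pi) - (1-pi)*log2(1-pi) + (1-pi)*log2(N-1)

The right-hand side ``S_F(pi)`` is strictly decreasing on ``[1/N, 1]``, from
``log2 N`` down to 0, so the equation has a unique root which we find by
bisection. ``pi_max = 1`` corresponds to a fully deterministic process
(``S = 0``) and ``pi_max = 1/N`` to a completely random one (``S = log2 N``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = ["FanoSolution", "fano_entropy", "predictability_bound"]


@dataclass(frozen=True)
class FanoSolution:
    s: float
    n_symbols: int
    pi_max: float
    residual: float
    iterations: int


def fano_entropy(pi: float, n_symbols: int) -> float:
    """``S_F(pi)``: entropy consistent with top-choice accuracy ``pi``."""
    if n_symbols == 1:
        return 0.0
    h = 0.0
    if 0.0 < pi < 1.0:
        h = -pi * math.log2(pi) - (1.0 - pi) * math.log2(1.0 - pi)
    return h + (1.0 - pi) * math.log2(n_symbols - 1)


def predictability_bound(
    s: float, n_symbols: int, tol: float = 1e-9, max_iter: int = 200
) -> FanoSolution:
    """Invert the Fano bound: the largest prediction accuracy consistent
    with entropy rate ``s`` over ``n_symbols`` locations.

    Entropies slightly outside ``[0, log2 N]`` (numerical noise from the
    estimators) are clamped with a warning.
    """
    if n_symbols < 1:
        raise ValueError(f"n_symbols must be >= 1, got {n_symbols}")
    if not math.isfinite(s):
        raise ValueError(f"entropy must be finite, got {s}")
    if n_symbols == 1:
        return FanoSolution(s=s, n_symbols=1, pi_max=1.0, residual=abs(max(s, 0.0)), iterations=0)

    if s < 0.0:
        if s < -1e-9:
            warnings.warn(f"negative entropy {s} clamped to 0", stacklevel=2)
        s = 0.0
    s_max = math.log2(n_symbols)
    if s > s_max:
        if s > s_max + 1e-9:
            warnings.warn(
                f"entropy {s} exceeds log2(N)={s_max:.6g}; clamped", stacklevel=2
            )
        s = s_max

    if s == 0.0:
        return FanoSolution(s=s, n_symbols=n_symbols, pi_max=1.0, residual=abs(s), iterations=0)
    if s >= s_max:
        pi = 1.0 / n_symbols
        return FanoSolution(
            s=s,
            n_symbols=n_symbols,
            pi_max=pi,
            residual=abs(fano_entropy(pi, n_symbols) - s),
            iterations=0,
        )

    # S_F is strictly decreasing on (1/N, 1): plain bisection, driven well
    # below the requested tolerance (cheap, and keeps the round-trip
    # residual in S small even where dS/dpi is steep).
    lo, hi = 1.0 / n_symbols, 1.0
    it = 0
    while hi - lo > min(tol, 1e-13) and it < max_iter:
        mid = 0.5 * (lo + hi)
        if fano_entropy(mid, n_symbols) > s:
            lo = mid
        else:
            hi = mid
        it += 1
    pi = 0.5 * (lo + hi)
    return FanoSolution(
        s=s,
        n_symbols=n_symbols,
        pi_max=pi,
        residual=abs(fano_entropy(pi, n_symbols) - s),
        iterations=it,
    )
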