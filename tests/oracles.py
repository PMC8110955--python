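"""Independent brute-force oracles used only by the tests."""

from __future__ import annotations

import math
from functools import lru_cache


@lru_cache(maxsize=None)
def _family(r1: int, r2: int, c1: int) -> tuple[tuple[int, ...], tuple[float, ...]]:
    """Support and hypergeometric pmf for tables with the given margins."""
    N = r1 + r2
    denom = math.comb(N, r1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    support = tuple(range(lo, hi + 1))
    pmf = tuple(
        math.comb(c1, k) * math.comb(N - c1, r1 - k) / denom for k in support
    )
    return support, pmf


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by explicit enumeration of all margin-consistent
    tables: sum the probabilities of tables no more probable than observed."""
    support, pmf = _family(a + b, c + d, a + c)
    p_obs = pmf[support.index(a)]
    return sum(p for p in pmf if p <= p_obs * (1 + 1e-7))


def hochberg_step_up(p_values) -> list[float]:
    """Hand-rolled Simes-Hochberg step-up adjustment, input order preserved."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m - 1, -1, -1):  # step up from the largest p
        i = order[rank]
        running = min(running, (m - rank) * p_values[i])
        adjusted[i] = min(1.0, running)
    return adjusted
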