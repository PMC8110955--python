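"""Statistical primitives for editing detection.

Two-sided Fisher exact tests on 2x2 edited/unedited tables, Simes-Hochberg
step-up correction across the candidate family, pseudocounted odds ratios,
and median-of-ratios (pseudo-reference) count normalisation.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

_LOG_BASES = {"natural": math.e, "2": 2.0, "10": 10.0}


def _check_counts(*counts: int) -> tuple[int, ...]:
    out = []
    for c in counts:
        if c != int(c) or c < 0:
            raise ValueError(f"counts must be non-negative integers, got {c!r}")
        out.append(int(c))
    return tuple(out)


def fisher_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    The two-sided p sums the hypergeometric probabilities, over all tables
    with the observed margins, of tables no more probable than the observed
    one.
    """
    a, b, c, d = _check_counts(a, b, c, d)
    if a + b + c + d == 0:
        raise ValueError("at least one count must be positive")
    return float(scipy.stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def hochberg_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Simes-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="simes-hochberg")[1]


def pseudo_odds_ratio(
    a: int, b: int, c: int, d: int, pseudocount: float = 0.5, log_base: str = "natural"
) -> tuple[float, float]:
    """Odds ratio of a 2x2 table with a pseudocount added to every cell.

    ``OR = ((a+pi)(d+pi)) / ((b+pi)(c+pi))`` with pseudocount ``pi`` applied
    to all four observations, so the ratio is finite and positive for any
    non-negative table (an all-zero table gives OR = 1, log OR = 0).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if log_base not in _LOG_BASES:
        raise ValueError(f"log_base must be one of {sorted(_LOG_BASES)}")
    a, b, c, d = _check_counts(a, b, c, d)
    pi = float(pseudocount)
    odds = ((a + pi) * (d + pi)) / ((b + pi) * (c + pi))
    return odds, math.log(odds, _LOG_BASES[log_base])


def size_factors(
    gene_counts: pd.DataFrame, baseline: Optional[str] = None
) -> tuple[pd.Series, pd.DataFrame, Optional[pd.DataFrame]]:
    """Median-of-ratios size factors against a geometric pseudo-reference.

    The pseudo-reference is the per-gene geometric mean across samples;
    genes with any zero count are excluded from the ratio set.  Returns
    ``(factors, normalised_counts, log2_fold_vs_baseline)`` where the last
    element is ``None`` when no baseline sample is named.
    """
    if gene_counts.shape[1] < 2:
        raise ValueError("need at least two samples")
    counts = gene_counts.astype(float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has positive counts in every sample")
    log_counts = np.log(counts[positive])
    log_ref = log_counts.mean(axis=1)
    factors = np.exp(log_counts.sub(log_ref, axis=0).median(axis=0))
    factors.name = "size_factor"
    normalised = counts.div(factors, axis=1)
    fold = None
    if baseline is not None:
        if baseline not in counts.columns:
            raise KeyError(f"baseline sample {baseline!r} not in the matrix")
        with np.errstate(divide="ignore", invalid="ignore"):
            fold = np.log2(normalised.div(normalised[baseline], axis=0))
    return factors, normalised, fold
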