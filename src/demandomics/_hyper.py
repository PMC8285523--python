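"""Numerically careful hypergeometric upper-tail probabilities.

The overlap and RRHO statistics both need P[X >= m] for X hypergeometric with
population N, i marked items and j draws.  Floating-point survival functions
lose essentially all relative accuracy in -log10(p) when p is close to 1
(cancellation in 1 - cdf), so for small-to-moderate problems the tail is
computed exactly with integer binomial coefficients and converted to
-log10(p) through log1p on the exact complement.  Large problems fall back to
scipy's vectorized survival function, which is accurate wherever the tail is
actually small.
"""

from __future__ import annotations

import math
from fractions import Fraction
from math import comb

import numpy as np
from scipy.stats import hypergeom

__all__ = ["exact_tail_fraction", "exact_tail_p", "exact_tail_neglog10", "sf_grid"]

#: largest population for which RRHO map pixels use the exact integer path
EXACT_N_MAX = 64


def _validate(N: int, i: int, j: int, m: int) -> None:
    if not (0 <= m <= min(i, j) <= N) or i > N or j > N or i < 0 or j < 0:
        raise ValueError(f"invalid hypergeometric arguments N={N}, i={i}, j={j}, m={m}")


def exact_tail_fraction(N: int, i: int, j: int, m: int) -> Fraction:
    """Exact P[X >= m] as a Fraction, X ~ Hypergeometric(N, i, j)."""
    _validate(N, i, j, m)
    lo = max(m, max(0, i + j - N))
    hi = min(i, j)
    num = sum(comb(j, x) * comb(N - j, i - x) for x in range(lo, hi + 1))
    return Fraction(num, comb(N, i))


def exact_tail_p(N: int, i: int, j: int, m: int) -> float:
    """Exact upper-tail probability rounded once to float."""
    return float(exact_tail_fraction(N, i, j, m))


def exact_tail_neglog10(N: int, i: int, j: int, m: int) -> float:
    """-log10 P[X >= m] with full relative accuracy across the whole range.

    Near p = 1 the value is computed from the exact complement via log1p;
    for small p a single correctly rounded float division suffices; if p
    underflows, integer log10s of numerator and denominator are used.
    """
    frac = exact_tail_fraction(N, i, j, m)
    if frac == 1:
        return 0.0
    num, den = frac.numerator, frac.denominator
    p = num / den if den < 2**53 and num < 2**53 else float(frac)
    if p >= 0.5:
        delta = float(Fraction(den - num, den))
        return -math.log1p(-delta) / math.log(10.0)
    if p > 0.0:
        return -math.log10(p)
    # underflowed: |log10 p| is huge, so the cancellation below is benign
    return math.log10(den) - math.log10(num)


def sf_grid(N: int, i_vec, j_vec, m_grid, floor: float = 5e-324) -> np.ndarray:
    """Vectorized -log10 P[X >= m] over a threshold grid (float path).

    ``m_grid`` has shape (len(i_vec), len(j_vec)).  p is floored at the
    smallest positive representable value so the map carries no infinities.
    """
    i = np.asarray(i_vec, dtype=np.int64)[:, None]
    j = np.asarray(j_vec, dtype=np.int64)[None, :]
    m = np.asarray(m_grid, dtype=np.int64)
    p = hypergeom.sf(m - 1, N, i, j)
    p = np.clip(p, floor, 1.0)
    return -np.log10(p)
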