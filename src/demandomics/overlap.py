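"""Set algebra over protein lists: Venn partitions and Fisher's-exact overlap odds ratios.

Two accession sets A and B are compared against a background universe U via
the 2x2 table

    a = |A & B|      b = |A - B|
    c = |B - A|      d = |U - (A | B)|

with odds ratio OR = (a*d)/(b*c) and a one-sided (enrichment) p-value: the
hypergeometric upper tail P[X >= a] with the observed margins.  Degenerate
tables (b*c = 0) yield OR = +inf when a*d > 0, and OR = 0 when a*d = 0; they
are reported as-is, never smoothed with a continuity correction.

One-sided tail probabilities are computed with exact integer binomial
coefficients (see :mod:`demandomics._hyper`), so they agree with exhaustive
enumeration to float rounding.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import fisher_exact

from ._hyper import exact_tail_p

__all__ = ["SetComparison", "venn_partition", "odds_ratio_test", "overlap_grid"]


@dataclass(frozen=True)
class SetComparison:
    """2x2 overlap table with its odds ratio and Fisher p-value."""

    label: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_value: float

    @property
    def table(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return ((self.a, self.b), (self.c, self.d))


def venn_partition(set_a, set_b) -> tuple[int, int, int, int]:
    """(|A only|, |B only|, |A & B|, |A | B|) for two accession sets."""
    a, b = set(set_a), set(set_b)
    inter = len(a & b)
    return (len(a) - inter, len(b) - inter, inter, len(a | b))


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    if b * c == 0:
        # fully nested / identical sets: infinite association when any overlap exists
        return float("inf") if a > 0 else 0.0
    if a * d == 0:
        return 0.0
    return (a * d) / (b * c)


def odds_ratio_test(
    set_a,
    set_b,
    background,
    alternative: str = "greater",
    label: str = "",
) -> SetComparison:
    """Fisher's exact overlap test of two sets within a background universe.

    ``alternative='greater'`` (default, the gene-list-overlap convention)
    gives the exact enrichment tail P[overlap >= a]; ``'two-sided'`` uses the
    standard two-sided Fisher test.
    """
    A, B, U = set(set_a), set(set_b), set(background)
    out_a = sorted(A - U)
    out_b = sorted(B - U)
    if out_a or out_b:
        raise ValueError(
            f"sets exceed background: A-U={out_a[:5]}{'...' if len(out_a) > 5 else ''}, "
            f"B-U={out_b[:5]}{'...' if len(out_b) > 5 else ''}"
        )
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    d = len(U) - a - b - c
    if alternative == "greater":
        p = exact_tail_p(len(U), len(A), len(B), a)
    elif alternative == "two-sided":
        p = float(fisher_exact(((a, b), (c, d)), alternative="two-sided")[1])
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return SetComparison(
        label=label, a=a, b=b, c=c, d=d, odds_ratio=_odds_ratio(a, b, c, d), p_value=min(p, 1.0)
    )


GRID_ROWS = ("changed_f", "unchanged_f", "changed_m", "unchanged_m")
GRID_COLS = ("dimorphic", "monomorphic")


def overlap_grid(changed_f, changed_m, dimorphic, background) -> pd.DataFrame:
    """The eight overlap tests of {changed, unchanged per sex} x {dimorphic, monomorphic}.

    ``unchanged`` = background minus changed, ``monomorphic`` = background
    minus dimorphic.  Returns a tidy table with one row per comparison.
    """
    U = set(background)
    sets_rows = {
        "changed_f": set(changed_f),
        "changed_m": set(changed_m),
    }
    sets_rows["unchanged_f"] = U - sets_rows["changed_f"]
    sets_rows["unchanged_m"] = U - sets_rows["changed_m"]
    dim = set(dimorphic)
    sets_cols = {"dimorphic": dim, "monomorphic": U - dim}
    rows = []
    for rname in GRID_ROWS:
        for cname in GRID_COLS:
            cmp_ = odds_ratio_test(
                sets_rows[rname], sets_cols[cname], U, label=f"{rname}|{cname}"
            )
            rows.append(
                {
                    "row_set": rname,
                    "col_set": cname,
                    "a": cmp_.a,
                    "b": cmp_.b,
                    "c": cmp_.c,
                    "d": cmp_.d,
                    "odds_ratio": cmp_.odds_ratio,
                    "p_value": cmp_.p_value,
                }
            )
    return pd.DataFrame(rows)
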