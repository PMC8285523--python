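"""Stratified rank-rank hypergeometric overlap (RRHO) between two signed rankings.

Two differential-expression lists over the same protein universe are each
split at zero into an up stratum (score >= 0, ordered most-upregulated
first) and a down stratum (score < 0, ordered most-downregulated first).
For a pair of strata, the map pixel at thresholds (i, j) is

    -log10 P[X >= m],   X ~ Hypergeometric(N, i, j),

where N is the universe size and m = |top_i of stratum A  &  top_j of
stratum B|.  Four quadrant maps are produced: UU and DD (concordant
regulation) and UD/DU (discordant regulation).  Peaks are descriptive — no
across-pixel multiple-testing correction is applied by default; an optional
Benjamini-Yekutieli layer is available for exploratory use.

Pixels are exact (integer binomial arithmetic) for universes up to
``_hyper.EXACT_N_MAX``; larger maps use scipy's vectorized survival
function.  p-values are floored at the smallest positive float before the
log, so maps never contain infinities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._hyper import EXACT_N_MAX, exact_tail_neglog10, sf_grid

__all__ = [
    "RankedList",
    "RRHOMap",
    "rank_by_metric",
    "hypergeometric_pixel",
    "rrho_map_stratified",
    "quadrant_peaks",
    "plot_rrho",
    "QUADRANTS",
]

QUADRANTS = ("UU", "DD", "UD", "DU")


@dataclass(frozen=True)
class RankedList:
    """Accessions with signed scores, sorted descending (ties by accession)."""

    accessions: tuple[str, ...]
    scores: tuple[float, ...]

    def __post_init__(self):
        if len(self.accessions) == 0:
            raise ValueError("empty ranked list")
        if len(set(self.accessions)) != len(self.accessions):
            raise ValueError("duplicate accessions in ranked list")
        order = sorted(range(len(self.scores)), key=lambda t: (-self.scores[t], self.accessions[t]))
        if order != list(range(len(self.scores))):
            raise ValueError("entries must be sorted by score descending (ties by accession)")

    @property
    def universe_size(self) -> int:
        return len(self.accessions)

    def flipped(self) -> "RankedList":
        """The same list with every score negated (re-sorted)."""
        return rank_by_scores(self.accessions, [-s for s in self.scores])

    def up_stratum(self) -> list[str]:
        """Accessions with score >= 0, most upregulated first."""
        pairs = [(a, s) for a, s in zip(self.accessions, self.scores) if s >= 0]
        pairs.sort(key=lambda t: (-t[1], t[0]))
        return [a for a, _ in pairs]

    def down_stratum(self) -> list[str]:
        """Accessions with score < 0, most downregulated first."""
        pairs = [(a, s) for a, s in zip(self.accessions, self.scores) if s < 0]
        pairs.sort(key=lambda t: (t[1], t[0]))
        return [a for a, _ in pairs]


def rank_by_scores(accessions, scores) -> RankedList:
    """Build a RankedList from unordered (accession, score) data."""
    pairs = sorted(zip(accessions, scores), key=lambda t: (-t[1], t[0]))
    return RankedList(tuple(a for a, _ in pairs), tuple(float(s) for _, s in pairs))


def rank_by_metric(stats_table: pd.DataFrame, metric: str = "log2_fc") -> RankedList:
    """Rank a contrast-statistics table by a signed metric (default log2FC).

    ``metric='signed_logp'`` ranks by sign(log2FC) * -log10(p) instead.
    """
    if len(stats_table) == 0:
        raise ValueError("empty stats table")
    acc = list(stats_table["accession"])
    if len(set(acc)) != len(acc):
        raise ValueError("duplicate accession in stats table")
    if metric == "signed_logp":
        p = np.clip(stats_table["p_value"].to_numpy(), 5e-324, 1.0)
        scores = np.sign(stats_table["log2_fc"].to_numpy()) * (-np.log10(p))
    else:
        scores = stats_table[metric].to_numpy(dtype=float)
    if np.isnan(scores).any():
        raise ValueError("ranking metric contains NaN")
    return rank_by_scores(acc, scores)


def hypergeometric_pixel(N: int, i: int, j: int, m: int, method: str = "auto") -> float:
    """-log10 P[X >= m] for X ~ Hypergeometric(N, i marked, j drawn).

    ``method='exact'`` forces integer-binomial arithmetic; ``'auto'`` uses it
    for N <= 64 and the float survival function above.
    """
    if not (0 <= m <= min(i, j) <= N):
        raise ValueError(f"require 0 <= m <= min(i, j) <= N, got N={N}, i={i}, j={j}, m={m}")
    if method == "exact" or (method == "auto" and N <= EXACT_N_MAX):
        return exact_tail_neglog10(N, i, j, m)
    return float(sf_grid(N, [i], [j], [[m]])[0, 0])


@dataclass
class RRHOMap:
    """One quadrant of a stratified RRHO comparison."""

    quadrant: str
    threshold_indices_i: np.ndarray  # thresholds into stratum A (1-based depths)
    threshold_indices_j: np.ndarray
    values: np.ndarray  # -log10 p, shape (len(i), len(j))
    step: int

    @property
    def peak(self) -> float:
        return float(self.values.max()) if self.values.size else 0.0

    def to_frame(self) -> pd.DataFrame:
        """Grid as a DataFrame (rows = A thresholds, columns = B thresholds)."""
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.threshold_indices_i, name="i"),
            columns=[str(j) for j in self.threshold_indices_j],
        )


def _overlap_grid_counts(stratum_a, stratum_b, ii, jj) -> np.ndarray:
    """m(i, j) = |top_i(A) & top_j(B)| via a cumulative 2-D histogram."""
    pos_b = {acc: q for q, acc in enumerate(stratum_b, start=1)}
    H = np.zeros((len(stratum_a) + 1, len(stratum_b) + 1), dtype=np.int64)
    for p, acc in enumerate(stratum_a, start=1):
        q = pos_b.get(acc)
        if q is not None:
            H[p, q] = 1
    M = H.cumsum(axis=0).cumsum(axis=1)
    return M[np.ix_(ii, jj)]


def _quadrant_map(quadrant, N, stratum_a, stratum_b, step, method) -> RRHOMap:
    ii = np.arange(step, len(stratum_a) + 1, step, dtype=np.int64)
    jj = np.arange(step, len(stratum_b) + 1, step, dtype=np.int64)
    if ii.size == 0 or jj.size == 0:
        return RRHOMap(quadrant, ii, jj, np.zeros((ii.size, jj.size)), step)
    m = _overlap_grid_counts(stratum_a, stratum_b, ii, jj)
    if method == "exact" or (method == "auto" and N <= EXACT_N_MAX):
        vals = np.empty(m.shape, dtype=float)
        for r, i in enumerate(ii):
            for c, j in enumerate(jj):
                vals[r, c] = exact_tail_neglog10(N, int(i), int(j), int(m[r, c]))
    else:
        vals = sf_grid(N, ii, jj, m)
    return RRHOMap(quadrant, ii, jj, vals, step)


def default_step(N: int) -> int:
    """Default threshold step: ceil(N/100), at least 1 (grids at most ~100x100)."""
    return max(1, math.ceil(N / 100))


def rrho_map_stratified(
    list_a: RankedList,
    list_b: RankedList,
    step: int | str = "auto",
    method: str = "auto",
) -> dict[str, RRHOMap]:
    """Four stratified RRHO quadrant maps (UU, DD, UD, DU) for two rankings.

    Both lists must cover the identical accession universe.  UU crosses the
    up strata of both lists, DD the down strata, UD the up stratum of A with
    the down stratum of B, DU the reverse.
    """
    sa, sb = set(list_a.accessions), set(list_b.accessions)
    if sa != sb:
        diff = sorted(sa ^ sb)
        raise ValueError(f"accession universes differ: {diff[:10]}{'...' if len(diff) > 10 else ''}")
    N = list_a.universe_size
    if step == "auto":
        step = default_step(N)
    step = int(step)
    if step < 1:
        raise ValueError("step must be >= 1")
    a_up, a_dn = list_a.up_stratum(), list_a.down_stratum()
    b_up, b_dn = list_b.up_stratum(), list_b.down_stratum()
    return {
        "UU": _quadrant_map("UU", N, a_up, b_up, step, method),
        "DD": _quadrant_map("DD", N, a_dn, b_dn, step, method),
        "UD": _quadrant_map("UD", N, a_up, b_dn, step, method),
        "DU": _quadrant_map("DU", N, a_dn, b_up, step, method),
    }


def quadrant_peaks(maps: dict[str, RRHOMap]) -> dict:
    """Per-quadrant peak -log10(p) plus the location of the overall maximum.

    Returns ``{'peaks': {quadrant: peak}, 'argmax': (quadrant, i, j)}``;
    argmax is None when every map is empty.
    """
    peaks = {q: maps[q].peak for q in maps}
    best = None
    best_val = -1.0
    for q, mp in maps.items():
        if mp.values.size == 0:
            continue
        r, c = np.unravel_index(int(np.argmax(mp.values)), mp.values.shape)
        if mp.values[r, c] > best_val:
            best_val = float(mp.values[r, c])
            best = (q, int(mp.threshold_indices_i[r]), int(mp.threshold_indices_j[c]))
    return {"peaks": peaks, "argmax": best}


def correct_maps_by(maps: dict[str, RRHOMap], method: str = "by") -> dict[str, RRHOMap]:
    """Benjamini-Yekutieli correction across all pixels of all quadrants (optional)."""
    from statsmodels.stats.multitest import multipletests

    if method != "by":
        raise ValueError("only Benjamini-Yekutieli ('by') is supported")
    shapes = {q: maps[q].values.shape for q in maps}
    flat = np.concatenate([maps[q].values.ravel() for q in maps])
    if flat.size == 0:
        return maps
    p = np.clip(10.0 ** (-flat), 5e-324, 1.0)
    q_adj = multipletests(p, method="fdr_by")[1]
    adj = -np.log10(np.clip(q_adj, 5e-324, 1.0))
    out = {}
    pos = 0
    for q in maps:
        n = maps[q].values.size
        out[q] = RRHOMap(
            q,
            maps[q].threshold_indices_i,
            maps[q].threshold_indices_j,
            adj[pos : pos + n].reshape(shapes[q]),
            maps[q].step,
        )
        pos += n
    return out


def plot_rrho(maps: dict[str, RRHOMap], path, title: str = "") -> None:
    """Render the four quadrant maps as a 2x2 heatmap panel (PNG/PDF by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(7, 6), constrained_layout=True)
    vmax = max(maps[q].peak for q in QUADRANTS) or 1.0
    for ax, q in zip(axes.ravel(), QUADRANTS):
        v = maps[q].values
        if v.size:
            im = ax.imshow(v, origin="lower", aspect="auto", cmap="magma", vmin=0, vmax=vmax)
        else:
            im = None
            ax.text(0.5, 0.5, "empty", ha="center", va="center")
        ax.set_title(f"{q} (peak {maps[q].peak:.2f})")
        ax.set_xlabel("list B threshold")
        ax.set_ylabel("list A threshold")
    if im is not None:
        fig.colorbar(im, ax=axes, label="-log10 p", shrink=0.8)
    if title:
        fig.suptitle(title)
    fig.savefig(path, dpi=120)
    plt.close(fig)
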