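"""Detection filtering and per-protein differential expression between sample groups.

The workflow mirrors standard label-free DIA practice: proteins not detected
in more than half of all samples (irrespective of group) are excluded, the
remaining intensities are log10-transformed, group summaries are medians of
the per-sample log10 intensities, fold changes are expressed on the log2
scale (log2FC = difference of log10 medians / log10(2)), and p-values come
from Welch's unequal-variance two-sample t-test on the per-sample log10
values.  Missing cells are never imputed; they are simply absent from both
the medians and the test.  Benjamini-Hochberg adjustment is available but
off by default so that nominal-p protein lists can be reproduced.

Also provides the Pfaffl relative-quantification ratio for qRT-PCR,
E_target^dCt_target / E_ref^dCt_ref.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import IntensityMatrix

__all__ = [
    "ContrastSpec",
    "QpcrMeasurement",
    "filter_detected",
    "contrast_stats",
    "significant_set",
    "pfaffl_ratio",
    "STAT_COLUMNS",
]

LOG10_2 = np.log10(2.0)

STAT_COLUMNS = [
    "accession",
    "n_a",
    "n_b",
    "median_log10_a",
    "median_log10_b",
    "log2_fc",
    "p_value",
    "significant",
    "low_coverage",
]


@dataclass(frozen=True)
class ContrastSpec:
    """A labeled two-group comparison (group_a relative to group_b)."""

    label: str
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]

    def __post_init__(self):
        a, b = set(self.group_a), set(self.group_b)
        if not a or not b:
            raise ValueError(f"contrast {self.label!r}: both groups must be non-empty")
        if a & b:
            raise ValueError(f"contrast {self.label!r}: groups overlap: {sorted(a & b)}")


@dataclass(frozen=True)
class QpcrMeasurement:
    """Amplification efficiencies and delta-Ct values (control - sample) for qPCR."""

    efficiency_target: float
    efficiency_ref: float
    delta_ct_target: float
    delta_ct_ref: float

    def __post_init__(self):
        for e in (self.efficiency_target, self.efficiency_ref):
            if not (1.0 < e <= 2.0):
                raise ValueError(f"amplification efficiency must be in (1, 2], got {e}")


def filter_detected(matrix: IntensityMatrix, min_fraction: float = 0.5) -> IntensityMatrix:
    """Keep proteins detected in strictly more than ``min_fraction`` of ALL samples.

    The inequality is strict: with 20 samples and min_fraction=0.5, a protein
    detected in exactly 10 is excluded.  Protein order is preserved.
    """
    if not (0.0 <= min_fraction < 1.0):
        raise ValueError(f"min_fraction must be in [0, 1), got {min_fraction}")
    if matrix.data.empty:
        raise ValueError("empty intensity matrix")
    frac = matrix.detection_fraction()
    return IntensityMatrix(matrix.data.loc[frac > min_fraction])


def _log10_present(block: pd.DataFrame) -> np.ndarray:
    """log10 of present positive values; missing and exact zeros become NaN.

    A true zero is a real measurement but has no log; it is excluded from
    log-domain summaries (documented behavior, zeros are counted upstream).
    """
    vals = block.to_numpy(dtype=float)
    out = np.full_like(vals, np.nan)
    pos = vals > 0
    out[pos] = np.log10(vals[pos])
    return out


def contrast_stats(matrix: IntensityMatrix, contrast: ContrastSpec) -> pd.DataFrame:
    """Per-protein contrast statistics for group_a versus group_b.

    Returns a table with per-group present counts, log10 medians, log2 fold
    change (a relative to b), Welch p-value, a ``significant`` flag (False
    until :func:`significant_set` is applied) and a ``low_coverage`` flag for
    proteins with fewer than two usable values in either group (p forced to 1).
    """
    cols = set(matrix.sample_ids)
    missing = [s for s in (*contrast.group_a, *contrast.group_b) if s not in cols]
    if missing:
        raise ValueError(f"contrast samples absent from matrix: {missing}")
    la = _log10_present(matrix.data[list(contrast.group_a)])
    lb = _log10_present(matrix.data[list(contrast.group_b)])
    n_a = (~np.isnan(la)).sum(axis=1)
    n_b = (~np.isnan(lb)).sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med_a = np.nanmedian(la, axis=1)
        med_b = np.nanmedian(lb, axis=1)
        mean_a = np.nanmean(la, axis=1)
        mean_b = np.nanmean(lb, axis=1)
        _, p = stats.ttest_ind(la, lb, axis=1, equal_var=False, nan_policy="omit")
    p = np.asarray(p, dtype=float)
    low = (n_a < 2) | (n_b < 2)
    # zero-variance groups: Welch statistic is 0/0; decide by the mean difference
    degenerate = np.isnan(p) & ~low
    p[degenerate] = np.where(mean_a[degenerate] == mean_b[degenerate], 1.0, 0.0)
    p[low] = 1.0
    return pd.DataFrame(
        {
            "accession": matrix.protein_ids,
            "n_a": n_a,
            "n_b": n_b,
            "median_log10_a": med_a,
            "median_log10_b": med_b,
            "log2_fc": (med_a - med_b) / LOG10_2,
            "p_value": p,
            "significant": False,
            "low_coverage": low,
        }
    )


def significant_set(
    stats_table: pd.DataFrame,
    alpha: float,
    min_abs_log2fc: float = 0.0,
    adjust: str = "none",
) -> set[str]:
    """Accessions with p < alpha and |log2FC| >= min_abs_log2fc.

    Sets the ``significant`` column of ``stats_table`` in place (and adds a
    ``q_value`` column when ``adjust='bh'``, thresholding the adjusted values
    instead).
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if len(stats_table) == 0:
        return set()
    p = stats_table["p_value"].to_numpy()
    if adjust == "bh":
        q = multipletests(p, method="fdr_bh")[1]
        stats_table["q_value"] = q
        hit = q < alpha
    elif adjust == "none":
        hit = p < alpha
    else:
        raise ValueError(f"unknown adjust method {adjust!r}")
    with np.errstate(invalid="ignore"):
        hit = hit & (np.abs(stats_table["log2_fc"].to_numpy()) >= min_abs_log2fc)
    hit = hit & ~np.isnan(stats_table["log2_fc"].to_numpy())
    stats_table["significant"] = hit
    return set(stats_table.loc[hit, "accession"])


def pfaffl_ratio(m: QpcrMeasurement) -> float:
    """Pfaffl relative expression ratio E_t^dCt_t / E_ref^dCt_ref."""
    return (m.efficiency_target**m.delta_ct_target) / (m.efficiency_ref**m.delta_ct_ref)
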