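"""End-to-end study orchestration: filter -> contrasts -> overlaps -> RRHO -> demand -> report.

``run_study`` executes the full analysis graph of a sex-by-cocaine
self-administration proteomics study on either real input files or the
package's seeded simulators:

1. detection filter (> 50% of all samples by default);
2. four group contrasts — baseline dimorphism (female-saline vs male-saline),
   the cocaine effect within each sex, and post-cocaine dimorphism
   (female-cocaine vs male-cocaine);
3. significant sets, Venn partition of the two cocaine-regulated lists, and
   the {changed, unchanged per sex} x {dimorphic, monomorphic} odds-ratio grid;
4. three stratified RRHO comparisons: male vs female cocaine effects, and
   baseline dimorphism vs each sex's cocaine effect;
5. per-subject demand-curve fits when behavioral data are supplied.

Everything is deterministic given the config seed; ``make_report`` writes a
fixed set of TSV/text artifacts that are byte-identical across reruns.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .demand import bins_to_demand_points, fit_demand
from .diffexpr import ContrastSpec, contrast_stats, filter_detected, significant_set
from .overlap import overlap_grid, venn_partition
from .rrho import QUADRANTS, rank_by_metric, rrho_map_stratified, quadrant_peaks
from .simulate import (
    BehaviorSimConfig,
    ProteomeSimConfig,
    simulate_proteome,
    simulate_threshold_sessions,
)

__all__ = ["StudyConfig", "StudyReport", "run_study", "make_report", "load_study_config"]

logger = logging.getLogger("demandomics")

CONTRASTS = ("F_sal_vs_M_sal", "F_coc_vs_F_sal", "M_coc_vs_M_sal", "F_coc_vs_M_coc")

#: RRHO list pairs (names refer to contrast labels). Each sex's cocaine effect
#: is compared against the baseline dimorphism oriented toward that sex
#: (M_sal_vs_F_sal is the sign-flipped baseline list), so "cocaine opposes the
#: sex's own baseline differences" shows up as discordant quadrants in both.
RRHO_PAIRS = (
    ("M_coc_vs_M_sal", "F_coc_vs_F_sal"),
    ("F_sal_vs_M_sal", "F_coc_vs_F_sal"),
    ("M_sal_vs_F_sal", "M_coc_vs_M_sal"),
)


@dataclass
class StudyConfig:
    """Inputs and knobs for one study run.

    Exactly one proteome source must be given: (matrix_path, manifest_path)
    or proteome_sim.  The behavior source (behavior_path or behavior_sim) is
    optional; without it the demand section is marked "not run".
    """

    out_dir: str | Path = "study_out"
    alpha: float = 0.05
    min_abs_log2fc: float = 0.0
    rrho_step: int | str = "auto"
    background_policy: str = "filtered"  # or path to a custom accession list
    min_detect_fraction: float = 0.5
    seed: int = 0
    matrix_path: str | None = None
    manifest_path: str | None = None
    behavior_path: str | None = None
    proteome_sim: ProteomeSimConfig | None = None
    behavior_sim: BehaviorSimConfig | None = None
    reinforcer_magnitude: float = 1.0

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        have_files = self.matrix_path is not None and self.manifest_path is not None
        have_sim = self.proteome_sim is not None
        if have_files == have_sim:
            raise ValueError("provide exactly one proteome source: file paths or a sim config")
        if self.behavior_path is not None and self.behavior_sim is not None:
            raise ValueError("provide at most one behavior source")


@dataclass
class StudyReport:
    """All computed study artifacts, in memory."""

    config: StudyConfig
    n_proteins_input: int
    n_proteins_detected: int
    stats: dict[str, pd.DataFrame]
    sets: dict[str, set[str]]
    background: set[str]
    venn: tuple[int, int, int, int]
    grid: pd.DataFrame
    rrho_maps: dict[tuple[str, str], dict]
    rrho_peaks: pd.DataFrame
    demand_fits: pd.DataFrame | None
    truth: Any = None
    log: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def remaining_dimorphic_fraction(self) -> float:
        """|baseline-dimorphic kept post-cocaine| / |baseline-dimorphic|."""
        base = self.sets["F_sal_vs_M_sal"]
        post = self.sets["F_coc_vs_M_coc"]
        if not base:
            return float("nan")
        return len(base & post) / len(base)


def load_study_config(path: str | Path) -> StudyConfig:
    """Parse a YAML study config (see README for the schema)."""
    raw = yaml.safe_load(Path(path).read_text())
    prot = raw.pop("proteome", {}) or {}
    beh = raw.pop("behavior", {}) or {}
    kwargs: dict[str, Any] = dict(raw)
    if "simulate" in prot:
        kwargs["proteome_sim"] = ProteomeSimConfig(**prot["simulate"])
    else:
        kwargs["matrix_path"] = prot.get("matrix")
        kwargs["manifest_path"] = prot.get("manifest")
    if "simulate" in beh:
        kwargs["behavior_sim"] = BehaviorSimConfig(**beh["simulate"])
    elif "bins" in beh:
        kwargs["behavior_path"] = beh["bins"]
    if "reinforcer_magnitude" in beh:
        kwargs["reinforcer_magnitude"] = float(beh["reinforcer_magnitude"])
    return StudyConfig(**kwargs)


def _load_proteome(config: StudyConfig):
    if config.proteome_sim is not None:
        return simulate_proteome(config.proteome_sim)
    manifest = dio.read_manifest(config.manifest_path)
    matrix = dio.read_intensity_matrix(config.matrix_path, manifest=manifest)
    return matrix, manifest, None


def _fit_subjects(bins: pd.DataFrame, magnitude: float) -> pd.DataFrame:
    rows = []
    for sid, sub in bins.groupby("subject_id", sort=True):
        points = bins_to_demand_points(sub, magnitude)
        try:
            res = fit_demand(points)
            d = res.derived
            rows.append(
                {
                    "subject_id": sid,
                    "q0": res.q0,
                    "alpha": res.alpha,
                    "k": res.k,
                    "pmax": d.pmax,
                    "std_pmax": d.standardized_pmax,
                    "omax": d.omax,
                    "sse": res.sse,
                    "n_points": res.n_points,
                    "converged": res.converged,
                }
            )
        except Exception as exc:  # unusable subject: record, don't abort the study
            rows.append(
                {
                    "subject_id": sid,
                    "q0": np.nan,
                    "alpha": np.nan,
                    "k": np.nan,
                    "pmax": np.nan,
                    "std_pmax": np.nan,
                    "omax": np.nan,
                    "sse": np.nan,
                    "n_points": int((points["consumption"] > 0).sum()),
                    "converged": False,
                }
            )
            logger.warning("demand fit failed for subject %s: %s", sid, exc)
    return pd.DataFrame(rows)


def run_study(config: StudyConfig) -> StudyReport:
    """Execute the full analysis graph; see the module docstring for the stages."""
    log: list[tuple[str, int, int]] = []

    def stage(name, n_in, n_out):
        log.append((name, int(n_in), int(n_out)))
        logger.info("stage %-18s n_in=%d n_out=%d", name, n_in, n_out)

    t0 = time.perf_counter()
    matrix, manifest, truth = _load_proteome(config)
    matrix.check_manifest(manifest)
    stage("load_proteome", 0, len(matrix.protein_ids))

    filtered = filter_detected(matrix, config.min_detect_fraction)
    stage("filter_detected", len(matrix.protein_ids), len(filtered.protein_ids))

    groups = {
        "M_sal": tuple(manifest.group_ids("male", "saline")),
        "F_sal": tuple(manifest.group_ids("female", "saline")),
        "M_coc": tuple(manifest.group_ids("male", "cocaine")),
        "F_coc": tuple(manifest.group_ids("female", "cocaine")),
    }
    specs = {
        "F_sal_vs_M_sal": ContrastSpec("F_sal_vs_M_sal", groups["F_sal"], groups["M_sal"]),
        "F_coc_vs_F_sal": ContrastSpec("F_coc_vs_F_sal", groups["F_coc"], groups["F_sal"]),
        "M_coc_vs_M_sal": ContrastSpec("M_coc_vs_M_sal", groups["M_coc"], groups["M_sal"]),
        "F_coc_vs_M_coc": ContrastSpec("F_coc_vs_M_coc", groups["F_coc"], groups["M_coc"]),
    }
    stats = {}
    sets = {}
    for name in CONTRASTS:
        st = contrast_stats(filtered, specs[name])
        sets[name] = significant_set(st, config.alpha, config.min_abs_log2fc)
        stats[name] = st
        stage(f"contrast[{name}]", len(filtered.protein_ids), len(sets[name]))

    if config.background_policy == "filtered":
        background = set(filtered.protein_ids)
    else:
        background = {
            line.strip()
            for line in Path(config.background_policy).read_text().splitlines()
            if line.strip()
        }
    changed_f = sets["F_coc_vs_F_sal"]
    changed_m = sets["M_coc_vs_M_sal"]
    dimorphic = sets["F_sal_vs_M_sal"]
    venn = venn_partition(changed_f, changed_m)
    grid = overlap_grid(changed_f, changed_m, dimorphic, background)
    stage("overlap_grid", len(background), len(grid))

    ranked = {name: rank_by_metric(stats[name]) for name in CONTRASTS}
    ranked["M_sal_vs_F_sal"] = ranked["F_sal_vs_M_sal"].flipped()
    rrho_maps = {}
    peak_rows = []
    for pair in RRHO_PAIRS:
        la = ranked[pair[0]]
        lb = ranked[pair[1]]
        maps = rrho_map_stratified(la, lb, step=config.rrho_step)
        rrho_maps[pair] = maps
        pk = quadrant_peaks(maps)
        row = {"list_a": pair[0], "list_b": pair[1]}
        row.update({q: pk["peaks"][q] for q in QUADRANTS})
        peak_rows.append(row)
        stage(f"rrho[{pair[0]}~{pair[1]}]", la.universe_size, 4)
    rrho_peaks = pd.DataFrame(peak_rows)

    demand_fits = None
    if config.behavior_sim is not None:
        bins, _beh_truth = simulate_threshold_sessions(config.behavior_sim)
        demand_fits = _fit_subjects(bins, config.behavior_sim.reinforcer_magnitude)
        stage("demand_fits", bins["subject_id"].nunique(), len(demand_fits))
    elif config.behavior_path is not None:
        bins = dio.read_behavior_bins(config.behavior_path)
        demand_fits = _fit_subjects(bins, config.reinforcer_magnitude)
        stage("demand_fits", bins["subject_id"].nunique(), len(demand_fits))

    logger.info("run_study finished in %.2f s", time.perf_counter() - t0)
    return StudyReport(
        config=config,
        n_proteins_input=len(matrix.protein_ids),
        n_proteins_detected=len(filtered.protein_ids),
        stats=stats,
        sets=sets,
        background=background,
        venn=venn,
        grid=grid,
        rrho_maps=rrho_maps,
        rrho_peaks=rrho_peaks,
        demand_fits=demand_fits,
        truth=truth,
        log=log,
    )


def _summary_text(report: StudyReport) -> str:
    cfg = report.config
    lines = [
        "# Study summary",
        "",
        f"seed: {cfg.seed}  alpha: {cfg.alpha:g}  min |log2FC|: {cfg.min_abs_log2fc:g}",
        "",
        "## Detection",
        f"- proteins in input matrix: {report.n_proteins_input}",
        f"- proteins passing >{cfg.min_detect_fraction:.0%} detection filter: "
        f"{report.n_proteins_detected}",
        "",
        "## Significant proteins per contrast",
    ]
    for name in CONTRASTS:
        lines.append(f"- {name}: {len(report.sets[name])}")
    a_only, b_only, inter, union = report.venn
    lines += [
        "",
        "## Venn of cocaine-regulated lists (F vs M)",
        f"- female only: {a_only}; male only: {b_only}; both: {inter}; union: {union}",
        f"- baseline-dimorphic proteins still dimorphic post-cocaine: "
        f"{len(report.sets['F_sal_vs_M_sal'] & report.sets['F_coc_vs_M_coc'])}"
        f" / {len(report.sets['F_sal_vs_M_sal'])}",
        "",
        "## Overlap odds-ratio grid",
        "",
        "| row set | col set | a | b | c | d | OR | p |",
        "|---|---|---|---|---|---|---|---|",
    ]
    for r in report.grid.itertuples(index=False):
        lines.append(
            f"| {r.row_set} | {r.col_set} | {r.a} | {r.b} | {r.c} | {r.d} "
            f"| {r.odds_ratio:.6g} | {r.p_value:.6g} |"
        )
    lines += ["", "## RRHO quadrant peaks (-log10 p)", ""]
    lines += ["| list A | list B | UU | DD | UD | DU |", "|---|---|---|---|---|---|"]
    for r in report.rrho_peaks.itertuples(index=False):
        lines.append(
            f"| {r.list_a} | {r.list_b} | {r.UU:.6g} | {r.DD:.6g} | {r.UD:.6g} | {r.DU:.6g} |"
        )
    lines += ["", "## Demand fits"]
    if report.demand_fits is None:
        lines.append("- not run (no behavioral input)")
    else:
        df = report.demand_fits
        ok = df[df["converged"] == True]  # noqa: E712
        lines.append(f"- subjects fit: {len(df)} (converged: {len(ok)})")
        if len(ok):
            lines.append(
                f"- median q0: {ok['q0'].median():.6g}; median alpha: {ok['alpha'].median():.6g}; "
                f"median std Pmax: {ok['std_pmax'].median():.6g}"
            )
    return "\n".join(lines) + "\n"


def make_report(report: StudyReport, out_dir: str | Path | None = None) -> Path:
    """Write all report artifacts; returns the output directory.

    Deterministic file set: stats_<contrast>.tsv, sets_<contrast>.txt,
    background.txt, overlap_grid.tsv, rrho_<A>__<B>_<quadrant>.tsv,
    rrho_peaks.tsv, demand_fits.tsv (when run), truth.tsv (simulated input),
    summary.md and run.log.  Byte-identical for identical config+seed.
    On failure every file written so far is removed.
    """
    out = Path(out_dir if out_dir is not None else report.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        tables = {f"stats_{name}": report.stats[name] for name in CONTRASTS}
        tables["overlap_grid"] = report.grid
        tables["rrho_peaks"] = report.rrho_peaks
        for (a, b), maps in report.rrho_maps.items():
            for q in QUADRANTS:
                tables[f"rrho_{a}__{b}_{q}"] = maps[q].to_frame().reset_index()
        if report.demand_fits is not None:
            tables["demand_fits"] = report.demand_fits
        if report.truth is not None:
            tables["truth"] = report.truth.table
        written += list(dio.write_tables(tables, out).values())
        for name in CONTRASTS:
            p = out / f"sets_{name}.txt"
            p.write_text("".join(f"{a}\n" for a in sorted(report.sets[name])))
            written.append(p)
        p = out / "background.txt"
        p.write_text("".join(f"{a}\n" for a in sorted(report.background)))
        written.append(p)
        p = out / "summary.md"
        p.write_text(_summary_text(report))
        written.append(p)
        p = out / "run.log"
        p.write_text(
            "".join(f"stage={s}\tn_in={i}\tn_out={o}\n" for s, i, o in report.log)
        )
        written.append(p)
    except Exception:
        for w in written:
            w.unlink(missing_ok=True)
        raise
    return out
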