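"""Seeded synthetic-data generators with planted ground truth.

Two families of generators stand in for a sex-by-cocaine self-administration
study:

* :func:`simulate_proteome` — a 4-group (male/female x saline/cocaine)
  log-normal protein intensity matrix with planted sexual dimorphism,
  sex-specific cocaine effects on disjoint protein sets, and a
  reversal interaction that moves dimorphic proteins toward the cross-sex
  midline, plus abundance-dependent logistic dropout (detection limits).
* :func:`simulate_threshold_sessions` / :func:`simulate_dose_response` —
  within-session threshold-procedure bins and dose-response injection counts
  generated from the exponential demand model with Poisson count noise and
  log-normal between-subject parameter spread.

Every generator draws from a single ``numpy.random.default_rng`` stream
seeded from its config, so identical configs give identical outputs.

Default group sizes (5, 5, 5, 4) mirror a typical small DIA cohort (the
cocaine-female group one short); behavioral defaults mirror the threshold
procedure: 11 ten-minute bins at FR 1-48 with a 20-pellet per-bin cap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .demand import THRESHOLD_FR_SCHEDULE, predict_consumption
from .io import IntensityMatrix, SampleManifest

__all__ = [
    "ProteomeSimConfig",
    "BehaviorSimConfig",
    "SimTruth",
    "simulate_proteome",
    "simulate_threshold_sessions",
    "simulate_dose_response",
]

GROUPS = (("male", "saline"), ("female", "saline"), ("male", "cocaine"), ("female", "cocaine"))
GROUP_TAGS = ("Msal", "Fsal", "Mcoc", "Fcoc")


@dataclass(frozen=True)
class ProteomeSimConfig:
    """Planted-effect model for the 4-group proteome generator.

    Log10 intensity of protein p in sample s of group (sex, treatment):

        x = mu_p + sex_offset_p * [sex == female] + drug_effect_p(sex) * [cocaine]
            + Normal(0, sigma_log10)

    Dimorphic proteins carry a baseline female-vs-male offset of magnitude
    ``sex_effect_log10`` (random sign).  Under cocaine each sex moves toward
    the cross-sex midline by fraction ``reversal_rho`` of half the offset
    (rho = 1 cancels the dimorphism exactly; rho < 0 plants a *concordant*
    interaction that amplifies it instead).  A fraction of the monomorphic
    proteins receives sex-specific cocaine effects on disjoint sets per sex.
    Detection probability is logistic in the underlying log10 abundance.
    """

    n_proteins: int = 1500
    n_per_group: tuple[int, int, int, int] = (5, 5, 5, 4)  # Msal, Fsal, Mcoc, Fcoc
    frac_dimorphic: float = 0.075
    sex_effect_log10: float = 0.3
    frac_drug_specific: float = 0.04
    drug_effect_log10: float = 0.3
    reversal_rho: float = 0.8
    sigma_log10: float = 0.15
    baseline_mean_log10: float = 6.0
    baseline_sd_log10: float = 0.8
    dropout_midpoint: float = -np.inf  # no dropout unless raised into the abundance range
    dropout_slope: float = 2.0
    seed: int = 0

    def __post_init__(self):
        for f in (self.frac_dimorphic, self.frac_drug_specific):
            if not (0.0 <= f <= 1.0):
                raise ValueError("fractions must be in [0, 1]")
        if not (-1.0 <= self.reversal_rho <= 1.0):
            raise ValueError("reversal_rho must be in [-1, 1]")
        if min(self.n_per_group) < 2:
            raise ValueError("group sizes must be >= 2")
        if self.sigma_log10 <= 0 or self.sex_effect_log10 < 0 or self.drug_effect_log10 < 0:
            raise ValueError("effect magnitudes must be >= 0 and sigma_log10 > 0")


@dataclass
class SimTruth:
    """Planted-effect bookkeeping: per-protein truth table plus the config echo."""

    table: pd.DataFrame  # accession, is_dimorphic, sex_offset, drug_effect_m, drug_effect_f
    config: ProteomeSimConfig

    @property
    def dimorphic(self) -> set[str]:
        t = self.table
        return set(t.loc[t["is_dimorphic"], "accession"])

    @property
    def drug_regulated_m(self) -> set[str]:
        t = self.table
        return set(t.loc[t["drug_effect_m"] != 0, "accession"])

    @property
    def drug_regulated_f(self) -> set[str]:
        t = self.table
        return set(t.loc[t["drug_effect_f"] != 0, "accession"])


def _make_manifest(cfg: ProteomeSimConfig, rng: np.random.Generator) -> SampleManifest:
    rows = []
    for (sex, treatment), tag, n in zip(GROUPS, GROUP_TAGS, cfg.n_per_group):
        base_w = 28.0 if sex == "male" else 22.0
        for i in range(n):
            rows.append(
                {
                    "sample_id": f"{tag}{i + 1}",
                    "subject_id": f"m_{tag}{i + 1}",
                    "species": "mouse",
                    "sex": sex,
                    "treatment": treatment,
                    "body_weight_g": round(float(base_w + rng.normal(0, 1.5)), 2),
                }
            )
    return SampleManifest(pd.DataFrame(rows))


def simulate_proteome(
    config: ProteomeSimConfig,
) -> tuple[IntensityMatrix, SampleManifest, SimTruth]:
    """Generate a 4-group intensity matrix, its manifest and the planted truth."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_proteins
    acc = np.array([f"P{i:05d}" for i in range(n)])
    mu = rng.normal(cfg.baseline_mean_log10, cfg.baseline_sd_log10, size=n)

    n_dim = int(round(cfg.frac_dimorphic * n))
    perm = rng.permutation(n)
    dim_idx = perm[:n_dim]
    mono_idx = perm[n_dim:]
    is_dim = np.zeros(n, dtype=bool)
    is_dim[dim_idx] = True

    sex_offset = np.zeros(n)
    sex_offset[dim_idx] = cfg.sex_effect_log10 * rng.choice([-1.0, 1.0], size=n_dim)

    # reversal/amplification interaction on dimorphic proteins:
    # female moves by -rho*offset/2, male by +rho*offset/2 (toward the midline when rho>0)
    drug_m = np.zeros(n)
    drug_f = np.zeros(n)
    drug_f[dim_idx] = -cfg.reversal_rho * sex_offset[dim_idx] / 2.0
    drug_m[dim_idx] = +cfg.reversal_rho * sex_offset[dim_idx] / 2.0

    # sex-specific cocaine effects on disjoint monomorphic sets
    n_ds = int(round(cfg.frac_drug_specific * len(mono_idx)))
    ds_m = mono_idx[:n_ds]
    ds_f = mono_idx[n_ds : 2 * n_ds]
    drug_m[ds_m] = cfg.drug_effect_log10 * rng.choice([-1.0, 1.0], size=len(ds_m))
    drug_f[ds_f] = cfg.drug_effect_log10 * rng.choice([-1.0, 1.0], size=len(ds_f))

    manifest = _make_manifest(cfg, rng)
    cols = {}
    for (sex, treatment), tag, n_g in zip(GROUPS, GROUP_TAGS, cfg.n_per_group):
        mean = mu.copy()
        if sex == "female":
            mean = mean + sex_offset
        if treatment == "cocaine":
            mean = mean + (drug_f if sex == "female" else drug_m)
        for i in range(n_g):
            x = mean + rng.normal(0.0, cfg.sigma_log10, size=n)
            p_detect = 1.0 / (1.0 + np.exp(-(x - cfg.dropout_midpoint) * cfg.dropout_slope))
            detected = rng.random(n) < p_detect
            vals = 10.0**x
            vals[~detected] = np.nan
            cols[f"{tag}{i + 1}"] = vals
    matrix = IntensityMatrix(pd.DataFrame(cols, index=pd.Index(acc, name="accession")))
    truth = SimTruth(
        table=pd.DataFrame(
            {
                "accession": acc,
                "is_dimorphic": is_dim,
                "sex_offset": sex_offset,
                "drug_effect_m": drug_m,
                "drug_effect_f": drug_f,
            }
        ),
        config=cfg,
    )
    return matrix, manifest, truth


@dataclass(frozen=True)
class BehaviorSimConfig:
    """Demand-model generator for within-session threshold-procedure bins."""

    q0_true: float = 20.0
    alpha_true: float = 0.005
    k: float = 2.0
    fr_schedule: tuple[int, ...] = THRESHOLD_FR_SCHEDULE
    per_bin_cap: int = 20
    bin_minutes: float = 10.0
    noise: str = "poisson"  # or "none"
    n_subjects: int = 20
    between_subject_cv: float = 0.2
    reinforcer_magnitude: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if any(b <= a for a, b in zip(self.fr_schedule, self.fr_schedule[1:])):
            raise ValueError("fr_schedule must be strictly increasing")
        if self.per_bin_cap < 1:
            raise ValueError("per_bin_cap must be >= 1")
        if self.noise not in ("none", "poisson"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.q0_true <= 0 or self.alpha_true <= 0 or self.k <= 0:
            raise ValueError("q0_true, alpha_true, k must be > 0")
        if self.between_subject_cv < 0:
            raise ValueError("between_subject_cv must be >= 0")


def _lognormal_around(rng: np.random.Generator, center: float, cv: float, size: int) -> np.ndarray:
    """Median-preserving log-normal spread with the given coefficient of variation."""
    if cv == 0:
        return np.full(size, center)
    sigma = np.sqrt(np.log1p(cv**2))
    return center * np.exp(rng.normal(0.0, sigma, size=size))


def simulate_threshold_sessions(config: BehaviorSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate bin records for n subjects plus the per-subject true parameters.

    Per subject, (q0, alpha) are drawn log-normally around the true values;
    per bin at price C = fr/magnitude, expected consumption is the demand
    prediction and earned counts are Poisson (or rounded, under
    ``noise='none'``), truncated at the per-bin cap.  Responses are exactly
    fr x earned.  Returns (bins, subject_truth).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    q0s = _lognormal_around(rng, cfg.q0_true, cfg.between_subject_cv, cfg.n_subjects)
    alphas = _lognormal_around(rng, cfg.alpha_true, cfg.between_subject_cv, cfg.n_subjects)
    rows = []
    for s in range(cfg.n_subjects):
        sid = f"r{s + 1:03d}"
        for b, fr in enumerate(cfg.fr_schedule, start=1):
            price = fr / cfg.reinforcer_magnitude
            lam = predict_consumption(q0s[s], alphas[s], price, k=cfg.k) / cfg.reinforcer_magnitude
            if cfg.noise == "poisson":
                earned = int(min(cfg.per_bin_cap, rng.poisson(lam)))
            else:
                earned = int(min(cfg.per_bin_cap, round(lam)))
            rows.append(
                {
                    "subject_id": sid,
                    "session_id": "thr1",
                    "bin_index": b,
                    "fr_value": fr,
                    "reinforcers_earned": earned,
                    "responses": fr * earned,
                    "bin_minutes": cfg.bin_minutes,
                }
            )
    truth = pd.DataFrame(
        {
            "subject_id": [f"r{s + 1:03d}" for s in range(cfg.n_subjects)],
            "q0_true": q0s,
            "alpha_true": alphas,
        }
    )
    return pd.DataFrame(rows), truth


def simulate_dose_response(
    q0: float,
    alpha: float,
    k: float,
    doses_mg_per_kg,
    body_weight_g: float,
    seed: int,
    fr_value: int = 1,
) -> pd.DataFrame:
    """Per-dose injection counts from the demand model with Poisson noise.

    At dose d the unit price is fr / (d * weight_g/1000) responses per mg;
    expected mg/kg intake is the demand prediction and the expected number
    of injections is intake / d.
    """
    doses = np.asarray(doses_mg_per_kg, dtype=float)
    if (doses <= 0).any():
        raise ValueError("doses must be > 0")
    rng = np.random.default_rng(seed)
    prices = fr_value / (doses * body_weight_g / 1000.0)
    q_pred = predict_consumption(q0, alpha, prices, k=k)
    injections = rng.poisson(q_pred / doses)
    return pd.DataFrame(
        {"dose_mg_per_kg": doses, "injections": injections.astype(int)}
    )
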