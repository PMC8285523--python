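# Methods

This note documents the models, estimators and numerical conventions
implemented in `demandomics`, the assumptions behind the synthetic-data
generators, and the design choices made where more than one defensible
option existed.

## Exponential demand model

Consumption `Q` of a reinforcer at unit price `C` (responses required per
unit) is modelled as

    log10 Q(C) = log10 Q0 + k (e^(-α Q0 C) - 1)

`Q0` (units of `Q`) is consumption at a minimally constraining price;
`α` (units 1/(C·Q)) sets how fast consumption decays with price; `k`
(dimensionless, default 2) fixes the log10 range of the decline and is held
constant during fitting so that `α` is comparable across subjects and
groups.  The curve is strictly decreasing with `Q(0) = Q0` and a floor of
`Q0·10^-k` — a consequence worth knowing: predicted *expenditure*
`E(C) = C·Q(C)` rises again at extreme prices, so the behaviorally
meaningful output peak is the **first local maximum** of `E`.

**Pmax.** Substituting `u = α·Q0·C`, the unit-elasticity condition
(log-log slope −1) reads `k·ln(10)·u·e^(-u) = 1`.  For `k·ln 10 > e`
(always true at k = 2) it has two roots; the smaller is the
inelastic-to-elastic transition where output peaks and is available in
closed form via the principal Lambert W branch:

    u* = -W0(-1/(k ln 10)),    Pmax = u* / (α Q0)

`u*` depends only on `k` (≈ 0.29028 at k = 2), so `Pmax ∝ 1/(αQ0)` and
standardized `Pmax = Pmax·Q0 = u*/α` is a pure intake-controlled index of
`α`.  `Omax = Pmax·Q(Pmax)`.  A model with `k·ln 10 ≤ e` has no
unit-slope crossing and raises a degeneracy error rather than returning a
meaningless price.  Tests verify the closed form against an independent
brute-force expenditure-grid search (first local maximum, refined to
< 0.1 % relative) and check the numerical log-log slope at `Pmax` to 1e-4.

**Fitting.** Three estimators share deterministic starts (`Q0` at the
maximum observed consumption, `α` from a 20-point log-spaced grid scan)
and bounds (`Q0 ∈ (0, 10·maxQ]`, `α ∈ (0, 10]`):

* `method="ls"` (default): bounded trust-region least squares on the
  log10-consumption residuals of the points with `Q > 0`.
  Zero-consumption points have no logarithm; they are dropped and counted
  in the diagnostics.  This mirrors standard practice (Prism-style curve
  fitting on log consumption) and is the package default for fidelity, but
  it is *biased for integer count data*: the log of a small Poisson count
  is biased low, and dropping zeros while keeping ones selects the tail
  upward.  In recovery experiments at `Q0 = 20, α = 0.005` under Poisson
  noise this biases median `Q0` by −25 % or worse.
* `weights="poisson"`: iteratively reweighted least squares with
  delta-method weights (`Var log10 X ≈ 1/(λ ln²10)` ⇒ weight ∝ predicted
  consumption).  Removes most of the small-count bias while remaining a
  log-space least-squares estimator.
* `method="mle"`: maximizes the Poisson likelihood of the observed counts,
  using **all** bins including zeros, with an optional per-bin cap handled
  as right censoring.  The zero bins at high prices carry most of the
  information about `α`; this is the recommended estimator for count
  consumption data and the one used in the parameter-recovery experiments
  (median `Q0` within ±15 % and `α` within ±20 % at 20 subjects,
  between-subject CV 0.2).

All three recover noise-free model-generated data to ≤ 1e-6 relative, and
all are scale-consistent: multiplying every consumption by `c` multiplies
`Q0` by `c` and preserves `α·Q0`.  Standard errors (least-squares paths)
come from the Gauss–Newton covariance `s²(JᵀJ)⁻¹`; the likelihood path
reports none rather than an approximation of dubious coverage at n = 11.

**Unit conventions.** Price and consumption units (pellets, mg, mg/kg;
body-weight normalization) are explicit arguments, never inferred.  The
threshold-procedure converter uses `C = FR / magnitude`,
`Q = earned × magnitude [/ bodyweight]`; the dose–response converter prices
dose `d` (mg/kg) for a `w`-gram animal at `C = FR / (d·w/1000)` responses
per mg with consumption in mg/kg.

## Proteome contrasts

* **Detection filter**: a protein is kept only when detected
  (non-missing) in strictly more than half of *all* samples, irrespective
  of group.  The inequality is strict: 10 of 20 is excluded.  Missingness
  is a first-class state distinct from an intensity of zero.
* **Contrast statistics**: present intensities are log10-transformed;
  group summaries are medians of per-sample log10 values;
  `log2FC = (median_a − median_b)/log10 2`; p-values from Welch's
  unequal-variance t-test on the per-sample log10 values.  The test is a
  documented assumption — the upstream software used in the motivating
  study does not name its statistic — and is pluggable in principle
  (the fold change and the test are computed by separate code paths).
  Proteins with fewer than two usable values in either group are flagged
  `low_coverage` with p = 1.  True zeros are real measurements but have no
  log; they are excluded from log-domain statistics.  Two zero-variance
  groups compare by their means (p = 1 when equal, 0 otherwise).
* **Significance**: nominal p < α (default 0.05), optional |log2FC| gate,
  optional Benjamini–Hochberg adjustment (off by default so nominal-p
  protein lists are reproducible).  Type-I calibration on null simulations
  (1000 proteins, 5 vs 5) lands inside the binomial band [0.037, 0.064].

## Set overlaps

Two accession sets are compared within an explicit background universe via
the 2×2 table (a = |A∩B|, b = |A∖B|, c = |B∖A|, d = rest).  The odds
ratio is the closed form `ad/bc`; degenerate tables are reported as-is
(`bc = 0` with any overlap → +∞; no overlap between non-trivial sets → 0)
rather than continuity-corrected.  The one-sided enrichment p-value is the
exact hypergeometric upper tail `P[X ≥ a]`, computed with integer binomial
coefficients (no floating-point survival function), so it matches
exhaustive enumeration to float rounding for every table; a two-sided
Fisher test is available by flag.  The default background is the set of
proteins surviving the detection filter and is configurable — published
overlap odds ratios are often not reproducible from printed counts
precisely because the background is unstated.

The `overlap_grid` convenience computes the eight tests of
{changed, unchanged per sex} × {dimorphic, monomorphic}, where unchanged
and monomorphic are complements within the background.

## Stratified RRHO

Each signed ranking (default metric: log2FC) is split at zero into an up
stratum (score ≥ 0, most upregulated first) and a down stratum (score < 0,
most downregulated first); zeros belong to the up stratum by convention and
ties break lexicographically by accession, making every map deterministic.
For strata A-stratum/B-stratum, the pixel at depth thresholds (i, j) is
`-log10 P[X ≥ m]` with `X ~ Hypergeometric(N, i, j)`, `N` the universe
size and `m` the overlap of the top-i and top-j prefixes.  Four quadrants:
UU/DD concordant, UD/DU discordant.

Numerics: for `N ≤ 64` every pixel is computed exactly (integer tail sums;
`-log10 p` via `log1p` on the exact complement near p = 1, so the value is
accurate to ~1e-15 relative everywhere — a naive `1 − cdf` loses all
precision in exactly the pixels where p ≈ 1).  Larger maps use scipy's
vectorized survival function, accurate wherever the tail is meaningfully
small.  p is floored at the smallest positive float, so maps carry no
infinities.  The default threshold step is `ceil(N/100)` (≤ ~100×100
grids).  Peaks are descriptive maxima; no across-pixel multiple-testing
correction is applied by default (an optional Benjamini–Yekutieli layer
exists for exploration).  Exact symmetries hold and are tested: transposing
the comparison exchanges UD and DU; negating both lists exchanges UU↔DD
and UD↔DU.

**Shared-control coupling.** In the study design this package serves, the
baseline-dimorphism list (F-sal vs M-sal) and each sex's drug-effect list
(e.g. F-coc vs F-sal) share a saline group.  Their noise is therefore
correlated (covariance = ∓ the sampling variance of the shared group's
median), and the corresponding RRHO comparison shows substantial
discordant (or concordant, depending on orientation) structure *even for a
null proteome*.  This is a property of the comparator design, not an
artifact of the implementation; only the comparison between the two sexes'
drug effects (no shared samples) is null-quiet.  Tests assert both facts.
Relatedly, each sex's drug effect is compared against the dimorphism
*oriented toward that sex* (the male comparison uses the sign-flipped
baseline list), which is what makes "the drug opposes each sex's own
baseline differences" appear as discordant quadrants in both maps.

## Synthetic-data generators

**Proteome.** Log10 intensity of protein p in a sample of group
(sex, treatment) is

    x = μ_p + s_p·[female] + δ_p(sex)·[drug] + ε,   ε ~ N(0, σ)

with `μ_p ~ N(6, 0.8)` (log10 arbitrary-intensity units spanning the
typical DIA dynamic range), σ = 0.15 by default.  A fraction of proteins
(default 0.075, the rough dimorphic fraction of a ~1500-protein
post-filter matrix) is dimorphic with offset magnitude 0.3 and random
sign.  Under drug, each sex moves toward the cross-sex midline by
`ρ/2 × offset` (`reversal_rho = 1` cancels the dimorphism exactly in
expectation; negative ρ plants the opposite, concordant interaction —
used to show that the RRHO direction test can reject as well as accept).
Disjoint subsets of the monomorphic proteins receive sex-specific drug
effects (default 4 % per sex, magnitude 0.3), emulating nearly
non-overlapping regulated lists.  Detection is logistic in the underlying
log10 abundance (abundance-dependent dropout, exercising the >50 % filter
realistically); the default midpoint of −∞ disables dropout.  Group sizes
default to (5, 5, 5, 4), a typical small DIA cohort.  Every draw comes
from one `default_rng(seed)` stream; identical configs give identical
matrices, manifests and truth tables.

What the generator does *not* emulate — and what passing tests therefore
do not show about real data: protein–protein correlation, batch and run
order effects, peptide-to-protein rollup and shared-peptide ambiguity,
intensity-dependent variance, normalization artifacts, estrous-cycle
variation, and any real biological effect-size distribution (the defaults
are chosen for testability, not biological fidelity).

**Behavior.** Per subject, (Q0, α) are drawn log-normally around the true
values with a given CV (median-preserving, so medians across subjects are
the natural recovery target).  Per bin at price `C = FR/magnitude`,
expected consumption is the demand prediction; earned counts are
`min(cap, Poisson(λ))` (or deterministic rounding under `noise="none"`),
and responses are exactly `FR × earned`.  Defaults mirror the
within-session threshold procedure: 11 ten-minute bins, FR
1–2–3–5–8–10–14–18–25–31–48, 20-pellet cap.  The dose–response generator
draws injection counts as `Poisson(Q(C_d)/d)` at each dose.

## Pipeline and reproducibility

`run_study` executes filter → four contrasts (baseline dimorphism, drug
effect per sex, post-drug dimorphism) → significant sets → Venn +
odds-ratio grid → three RRHO comparisons → per-subject demand fits →
report.  It fails fast: any stage error aborts and removes partial
outputs.  The report directory (stats/sets/grid/RRHO/fit tables,
`summary.md`, `run.log`) is byte-identical across reruns of the same
config and seed: floats are rendered at 6 significant digits, file names
are fixed, and the run log records (stage, n_in, n_out) without wall-clock
times.  Demand fitting inside the pipeline uses the default log-LS
estimator; the recovery experiments call the count-likelihood estimator
explicitly.

Problem sizes in the test and acceptance experiments (600-protein studies
with 10 per group, 300-protein direction runs over 50 seeds, 1000-protein
null calibrations, 20-subject recovery) were chosen as the smallest scales
at which the planted effects are comfortably detectable and the whole
suite runs in seconds; results are not sensitive to modest scaling up.

## Known limitations

* Single-protein inference is nominal-p by default; the BH option exists
  but the motivating workflow reports nominal lists.
* RRHO peak magnitudes depend on universe size and step; only directions
  and exact pixel values are validated, not any particular published peak.
* `Q0` from a single 11-bin session is an extrapolation and is wide;
  standardized `Pmax` and cross-subject medians are the stable quantities.
* The odds-ratio background must be chosen by the analyst; different
  backgrounds change the OR and p, and no universal default can recover
  every published value.
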